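"""Synthetic data with planted, recorded ground truth.

Generates the four kinds of inputs the analysis consumes:

* transcript models (5'UTR + CDS + 3'UTR, stop-terminated, no internal
  stops) with FASTA/GFF3 output;
* per-transcript 5'P end tracks with 3-nt frame periodicity and a
  multiplicative pile-up at the ribosome boundary 16-17 nt upstream of the
  stop codon;
* negative-binomial gene x sample count matrices for the three assays
  (total, polysomal, degradome) over the SAT (p1-p5) and BT (pA-pC)
  time courses, with planted differentially expressed genes and planted
  "degradome-only" (CTRD-regulated) genes;
* sucrose-gradient OD254 absorbance traces with a configurable
  polysome / total-ribosome area fraction.

Every perturbation is recorded in a :class:`GroundTruth` object so that
recovery can be scored exactly. All generators are deterministic given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation_io import STOP_CODONS, AssayCounts, SampleKey, TranscriptModel
from .degradome_profiling import BOUNDARY_DISTANCES, FivePEndTrack
from .polysome_quantification import AbsorbanceTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_DESIGN",
    "generate_transcriptome",
    "simulate_5p_track",
    "simulate_5p_tracks",
    "simulate_counts",
    "simulate_absorbance_trace",
    "tracks_to_end_table",
]

#: the study design: SAT regime with a 37 degC priming step (p1 control,
#: p2 37 degC, p3 recovery, p4 44 degC, p5 late recovery) and BT without
#: priming (pA control-equivalent, pB 44 degC, pC late recovery),
#: biological triplicates throughout.
DEFAULT_DESIGN: tuple[tuple[str, str, int], ...] = (
    ("SAT", "p1", 3), ("SAT", "p2", 3), ("SAT", "p3", 3),
    ("SAT", "p4", 3), ("SAT", "p5", 3),
    ("BT", "pA", 3), ("BT", "pB", 3), ("BT", "pC", 3),
)

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world; defaults are the study conditions.

    Expression baselines are log-normal in count space; counts are NB with
    a common dispersion; per-sample library-size factors are log-normal
    with sd 0.1 (mild, realistic depth variation). Perturbed timepoints are
    the non-reference ones (p2-p5, pB, pC); pA mirrors the 20 degC
    reference, which the study found equivalent to p1.
    """

    seed: int = 0
    n_transcripts: int = 200
    cds_length_range: tuple[int, int] = (300, 900)
    utr5_range: tuple[int, int] = (40, 100)
    utr3_range: tuple[int, int] = (60, 120)
    frame_weights: tuple[float, float, float] = (0.55, 0.25, 0.20)
    stop_boundary_boost: float = 8.0
    mean_track_coverage: float = 500.0
    design: tuple[tuple[str, str, int], ...] = DEFAULT_DESIGN
    nb_dispersion: float = 0.05
    baseline_expression_log_mean: float = 5.0
    baseline_expression_log_sd: float = 1.0
    de_fraction_per_assay: float = 0.15
    de_log2fc: float = 2.0
    ctrd_only_fraction: float = 0.05
    ctrd_only_log2fc: float = 2.0
    library_size_log_sd: float = 0.1
    reference_timepoint: str = "p1"
    #: timepoints that never carry a planted effect (the reference and its
    #: unprimed twin pA)
    unperturbed_timepoints: tuple[str, ...] = ("p1", "pA")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        for name in ("cds_length_range", "utr5_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"invalid {name}: ({lo}, {hi})")
        if self.cds_length_range[1] < 6:
            raise ConfigurationError("CDS must fit at least start+stop codons")
        w = np.asarray(self.frame_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("frame_weights must be 3 non-negative "
                                     "values summing to 1")
        if self.stop_boundary_boost <= 0:
            raise ConfigurationError("stop_boundary_boost must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not self.design:
            raise ConfigurationError("design must be non-empty")
        if not (0 <= self.de_fraction_per_assay <= 1
                and 0 <= self.ctrd_only_fraction <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.de_fraction_per_assay + self.ctrd_only_fraction > 1:
            raise ConfigurationError(
                "de_fraction_per_assay + ctrd_only_fraction must be <= 1")

    @property
    def timepoints(self) -> list[str]:
        return [tp for _, tp, _ in self.design]

    def perturbable_timepoints(self) -> list[str]:
        return [tp for tp in self.timepoints
                if tp not in self.unperturbed_timepoints]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = [list(x) for x in self.design]
        return d


@dataclass
class GroundTruth:
    """Record of every planted perturbation.

    ``effects`` rows are (gene_id, assay, timepoint, true_log2fc); a gene
    absent from an (assay, timepoint) pair is unperturbed there. CTRD-only
    genes carry effects exclusively in the degradome assay; shared DE genes
    carry the same effect in all three assays (a steady-state change
    propagates through the polysome and the degradome).
    """

    effects: pd.DataFrame
    de_genes: frozenset = frozenset()
    ctrd_only_genes: frozenset = frozenset()
    baseline_expression: pd.Series | None = None
    library_factors: pd.DataFrame | None = None
    track_params: pd.DataFrame | None = None

    def genes_de_in(self, assay: str, timepoint: str | None = None) -> set[str]:
        e = self.effects
        m = e["assay"] == assay
        if timepoint is not None:
            m &= e["timepoint"] == timepoint
        return set(e.loc[m, "gene_id"])

    def true_log2fc(self, gene_id: str, assay: str, timepoint: str) -> float:
        e = self.effects
        m = ((e["gene_id"] == gene_id) & (e["assay"] == assay)
             & (e["timepoint"] == timepoint))
        return float(e.loc[m, "log2fc"].sum())

    def validate(self) -> None:
        if len(self.effects) and (self.effects["log2fc"] == 0).any():
            raise ValueError("flagged effect with zero log2fc")
        for g in self.ctrd_only_genes:
            assays = set(self.effects.loc[self.effects["gene_id"] == g, "assay"])
            if assays != {"degradome"}:
                raise ValueError(f"CTRD-only gene {g} perturbed outside degradome")


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_transcriptome(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           ) -> list[TranscriptModel]:
    """Generate stop-terminated transcript models, one per gene.

    CDS length is a multiple of 3 inside ``cds_length_range``; the CDS is
    ATG + non-stop codons + one of TAA/TAG/TGA, so translations never hit
    an internal stop. Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    c_lo, c_hi = -(-lo // 3), hi // 3  # codon counts spanning the range
    if c_hi < max(c_lo, 2):
        raise ConfigurationError("cds_length_range admits no valid codon count")
    c_lo = max(c_lo, 2)
    stops = sorted(STOP_CODONS)
    out: list[TranscriptModel] = []
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(c_lo, c_hi + 1))
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        cds = "ATG" + _random_codons(rng, n_codons - 2) + stops[rng.integers(0, 3)]
        seq = _random_nt(rng, u5) + cds + _random_nt(rng, u3)
        gid = f"G{i:05d}"
        out.append(TranscriptModel(transcript_id=f"{gid}.1", gene_id=gid,
                                   sequence=seq, cds_start=u5,
                                   cds_end=u5 + 3 * n_codons))
    return out


# ---------------------------------------------------------------------------
# 5'P tracks
# ---------------------------------------------------------------------------

def _position_weights(transcript: TranscriptModel,
                      frame_weights: np.ndarray,
                      boost: float) -> np.ndarray:
    """3-periodic per-position sampling weights with the boundary boost.

    The frame index (position - cds_start, mod 3) is extended over the
    whole transcript so that the flanking density around the stop boundary
    is homogeneous; the two boundary positions (distances 16 and 17 nt
    from the first stop nt) are multiplied by ``boost``.
    """
    L = transcript.length
    pos = np.arange(L)
    w = frame_weights[(pos - transcript.cds_start) % 3].astype(float)
    stop = transcript.stop_first_nt
    for d in BOUNDARY_DISTANCES:
        p = stop - d
        if 0 <= p < L:
            w[p] *= boost
    return w


def simulate_5p_track(transcript: TranscriptModel,
                      config: SimulationConfig,
                      rng: np.random.Generator | int | None = None,
                      ) -> FivePEndTrack:
    """Draw one transcript's 5'P end track.

    Total ends ~ Poisson(mean_track_coverage); positions are multinomial
    with probability proportional to the frame weight times the boundary
    boost at distances 16-17 nt upstream of the stop.
    """
    if transcript.cds_length <= 0:
        raise ValueError("transcript has no CDS")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    w = _position_weights(transcript, np.asarray(config.frame_weights),
                          config.stop_boundary_boost)
    n = rng.poisson(config.mean_track_coverage)
    counts = rng.multinomial(n, w / w.sum()) if n > 0 else np.zeros(
        transcript.length, dtype=np.int64)
    return FivePEndTrack(transcript.transcript_id, counts.astype(np.int64))


def simulate_5p_tracks(transcripts: list[TranscriptModel],
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[dict[str, FivePEndTrack], pd.DataFrame]:
    """Tracks for a transcript set plus their recorded true parameters."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tracks = {}
    rows = []
    for t in transcripts:
        tracks[t.transcript_id] = simulate_5p_track(t, config, rng)
        rows.append({"transcript_id": t.transcript_id,
                     "f0": config.frame_weights[0],
                     "f1": config.frame_weights[1],
                     "f2": config.frame_weights[2],
                     "stop_boundary_boost": config.stop_boundary_boost})
    return tracks, pd.DataFrame(rows)


def tracks_to_end_table(tracks: dict[str, FivePEndTrack]) -> pd.DataFrame:
    """BED-like end table (transcript_id, start, end, count), 0-based."""
    rows = []
    for tid in sorted(tracks):
        arr = tracks[tid].counts
        for pos in np.flatnonzero(arr):
            rows.append((tid, int(pos), int(pos) + 1, int(arr[pos])))
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "count"])


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _choose_affected_timepoints(rng: np.random.Generator,
                                timepoints: list[str]) -> list[str]:
    picked = [tp for tp in timepoints if rng.random() < 0.5]
    if not picked:
        picked = [timepoints[rng.integers(0, len(timepoints))]]
    return picked


def simulate_counts(config: SimulationConfig,
                    transcripts: list[TranscriptModel] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[dict[str, AssayCounts], GroundTruth]:
    """Simulate the triple-assay NB count matrices with planted truth.

    One shared set of DE genes is perturbed coherently in all three assays
    (steady-state regulation); a disjoint CTRD-only set is perturbed in the
    degradome assay alone, each at a random non-empty subset of the
    perturbable timepoints with a random sign.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if transcripts is None:
        transcripts = generate_transcriptome(config, rng)
    genes = [t.gene_id for t in transcripts]
    lengths = pd.Series({t.gene_id: t.length for t in transcripts}, name="length")
    n = len(genes)

    expr = np.exp(rng.normal(config.baseline_expression_log_mean,
                             config.baseline_expression_log_sd, size=n))
    baseline = pd.Series(expr, index=genes, name="baseline_expression")

    n_ctrd = int(round(config.ctrd_only_fraction * n))
    n_de = int(round(config.de_fraction_per_assay * n))
    order = rng.permutation(n)
    ctrd_genes = [genes[i] for i in order[:n_ctrd]]
    de_genes = [genes[i] for i in order[n_ctrd:n_ctrd + n_de]]

    perturbable = config.perturbable_timepoints()
    effect_rows = []
    for g in de_genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for tp in _choose_affected_timepoints(rng, perturbable):
            for assay in ("total", "polysomal", "degradome"):
                effect_rows.append((g, assay, tp, sign * config.de_log2fc))
    for g in ctrd_genes:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for tp in _choose_affected_timepoints(rng, perturbable):
            effect_rows.append((g, "degradome", tp, sign * config.ctrd_only_log2fc))
    effects = pd.DataFrame(effect_rows,
                           columns=["gene_id", "assay", "timepoint", "log2fc"])

    lfc = {assay: pd.DataFrame(0.0, index=genes, columns=config.timepoints)
           for assay in ("total", "polysomal", "degradome")}
    for row in effects.itertuples(index=False):
        lfc[row.assay].loc[row.gene_id, row.timepoint] = row.log2fc

    assay_counts: dict[str, AssayCounts] = {}
    lib_rows = []
    for assay in ("total", "polysomal", "degradome"):
        cols = {}
        for regime, tp, n_rep in config.design:
            for rep in range(1, n_rep + 1):
                key = SampleKey(assay, regime, tp, rep)
                libf = float(np.exp(rng.normal(0.0, config.library_size_log_sd)))
                lib_rows.append({"sample": str(key), "library_factor": libf})
                mu = libf * expr * np.exp2(lfc[assay][tp].to_numpy())
                cols[str(key)] = _nb_draw(rng, mu, config.nb_dispersion)
        counts = pd.DataFrame(cols, index=genes)
        assay_counts[assay] = AssayCounts(counts, lengths.copy())

    truth = GroundTruth(effects=effects,
                        de_genes=frozenset(de_genes),
                        ctrd_only_genes=frozenset(ctrd_genes),
                        baseline_expression=baseline,
                        library_factors=pd.DataFrame(lib_rows))
    truth.validate()
    return assay_counts, truth


# ---------------------------------------------------------------------------
# absorbance traces
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area * np.exp(-0.5 * ((x - center) / sigma) ** 2) / (
        sigma * np.sqrt(2.0 * np.pi))

#: gradient layout (positions in arbitrary gradient units, 0 = top)
_REGIONS = {
    "free": (0.0, 2.5),
    "s40": (2.5, 3.5),
    "s60": (3.5, 4.5),
    "monosome": (4.5, 6.5),
    "polysome": (6.5, 12.0),
}
_BASELINE_OD = 0.05


def simulate_absorbance_trace(polysome_fraction: float,
                              noise_sd: float = 0.0,
                              seed: int | None = None,
                              n_points: int = 2400,
                              total_ribosome_area: float = 2.0,
                              ) -> AbsorbanceTrace:
    """Synthetic OD254 sucrose-gradient trace.

    Gaussian peaks for the free-mRNP region, 40S, 60S, monosome and a
    polysome ladder sit on a flat baseline; the polysome peak areas sum to
    ``polysome_fraction`` of the total ribosome area (40S + 60S + monosome
    + polysomes) before noise is added.
    """
    if not 0.0 <= polysome_fraction <= 1.0:
        raise ValueError("polysome_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 12.0, n_points)
    poly_area = polysome_fraction * total_ribosome_area
    sub_area = (total_ribosome_area - poly_area) / 3.0  # 40S, 60S, monosome

    od = np.full_like(x, _BASELINE_OD)
    od += _gauss(x, 1.0, 0.30, 1.5)          # free mRNPs (not ribosomes)
    od += _gauss(x, 3.0, 0.15, sub_area)     # 40S
    od += _gauss(x, 4.0, 0.15, sub_area)     # 60S
    od += _gauss(x, 5.4, 0.20, sub_area)     # 80S monosome
    ladder = np.array([0.35, 0.27, 0.22, 0.16])  # di- to penta-some
    for c, share in zip((7.4, 8.4, 9.4, 10.4), ladder):
        od += _gauss(x, c, 0.25, poly_area * share)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return AbsorbanceTrace(position=x, od=od, regions=dict(_REGIONS),
                           baseline="linear")
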