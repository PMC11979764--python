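"""Nascent-peptide window scoring: hydrophobicity and HSP70 affinity.

Severe heat stress redistributes HSP70 chaperones away from ribosomes,
pausing early elongation when the emerging N-terminal peptide is
hydrophobic or a strong HSP70 substrate; paused ribosomes in turn attract
co-translational decay. This module scores the first 80 residues of each
protein with 13-aa sliding windows (shifted by one residue), averages per
position across a gene set, smooths the mean curve with an interpolating
cubic spline, and compares two sets with a Welch t-test on gene-level
mean scores (one summary value per gene, avoiding window-level
pseudo-replication).

Two score tables ship with the package: the Kyte-Doolittle hydropathy
scale, and a synthetic default HSP70/HSC70 binding-propensity table (the
window mechanics are fixed; the table is swappable via any
``residue<TAB>score`` TSV). The HSP70 window score weights the central
7-residue core (the span an HSP70 binding site occupies) at twice the
flanks; weights are normalised so a homopolymer window scores exactly the
residue's table value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy import stats

__all__ = [
    "ScoreTable",
    "PeptideScoreProfile",
    "ProfileComparison",
    "load_score_table",
    "window_scores",
    "set_profile",
    "compare_profiles",
    "random_control_set",
    "AA20",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_BUILTIN_TABLES = {
    "kyte_doolittle": ("kyte_doolittle.tsv", None),
    # central 7 residues weighted 2x the 3-residue flanks, normalised
    "hsp70_binding": ("hsp70_binding_synthetic.tsv",
                      np.array([1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1],
                               dtype=float)),
}


@dataclass
class ScoreTable:
    """Per-residue scores plus an optional positional weighting scheme.

    ``window_weights`` (length = window size) turn the plain window mean
    into a weighted mean; they are normalised internally, so homopolymer
    windows always score the residue's table value.
    """

    name: str
    scores: dict[str, float]
    window_weights: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [aa for aa in AA20 if aa not in self.scores]
        if missing:
            raise ValueError(f"score table {self.name!r} lacks residues {missing}")
        if self.window_weights is not None:
            w = np.asarray(self.window_weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("window weights must be non-negative, sum > 0")
            self.window_weights = w / w.sum()

    @property
    def mean_score(self) -> float:
        """Table mean, used for nonstandard residues (X, U, B, Z)."""
        return float(np.mean([self.scores[aa] for aa in AA20]))

    def residue_scores(self, sequence: str) -> tuple[np.ndarray, int]:
        """Per-residue score vector and the count of nonstandard residues."""
        fallback = self.mean_score
        vals = np.empty(len(sequence))
        n_nonstd = 0
        for i, aa in enumerate(sequence):
            s = self.scores.get(aa)
            if s is None:
                s = fallback
                n_nonstd += 1
            vals[i] = s
        return vals, n_nonstd


def load_score_table(name_or_path: str) -> ScoreTable:
    """Load a packaged table by name or a user TSV by path."""
    if name_or_path in _BUILTIN_TABLES:
        fname, weights = _BUILTIN_TABLES[name_or_path]
        ref = resources.files("ctrdseq.data").joinpath(fname)
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
        prov = f"packaged:{fname}"
        name = name_or_path
    else:
        df = pd.read_csv(name_or_path, sep="\t", comment="#")
        weights = None
        prov = f"user:{name_or_path}"
        name = "user_table"
    scores = dict(zip(df["residue"].str.upper(), df["score"].astype(float)))
    return ScoreTable(name=name, scores=scores, window_weights=weights,
                      provenance=prov)


def window_scores(protein_sequence: str, table: ScoreTable,
                  window: int = 13, prefix: int = 80) -> np.ndarray:
    """Sliding-window scores over the N-terminal ``prefix`` residues.

    Window *i* covers residues [i, i+window); only complete windows within
    the prefix (and the sequence) are emitted, so a sequence shorter than
    ``window`` yields an empty vector. Sequences with internal stops are
    rejected.
    """
    seq = protein_sequence.upper().rstrip("*")
    if "*" in seq:
        raise ValueError("sequence contains an internal stop")
    span = min(len(seq), prefix)
    n_windows = span - window + 1
    if n_windows <= 0:
        return np.empty(0)
    vals, _ = table.residue_scores(seq[:span])
    if table.window_weights is None:
        kernel = np.full(window, 1.0 / window)
    else:
        kernel = table.window_weights
    return np.convolve(vals, kernel[::-1], mode="valid")


@dataclass
class PeptideScoreProfile:
    """Position-wise mean window scores over a gene set's N-termini.

    ``centers`` are 1-based center-residue positions of each 13-aa window
    (the first window, residues 1-13, has center 7). ``gene_means`` holds
    one summary value per contributing gene (its mean over all windows),
    the unit of the between-set t-test.
    """

    label: str
    centers: np.ndarray
    mean_scores: np.ndarray
    n_contributing: np.ndarray
    smoothed: np.ndarray
    gene_means: pd.Series
    n_excluded: int = 0
    table_name: str = ""

    def spline(self) -> CubicSpline:
        return CubicSpline(self.centers, self.mean_scores)


def set_profile(sequences: dict[str, str], table: ScoreTable,
                window: int = 13, prefix: int = 80,
                label: str = "") -> PeptideScoreProfile:
    """Mean window-score profile of a gene set.

    Sequences shorter than one window are excluded and tallied. Each
    position's mean runs over the genes that have a window there; the
    smoothed curve is the interpolating cubic spline through the means
    (it reproduces them exactly at the knots).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences for a set profile")
    max_windows = prefix - window + 1
    sums = np.zeros(max_windows)
    counts = np.zeros(max_windows, dtype=int)
    gene_means = {}
    n_excluded = 0
    for gid in sorted(sequences):
        ws = window_scores(sequences[gid], table, window=window, prefix=prefix)
        if ws.size == 0:
            n_excluded += 1
            continue
        sums[:ws.size] += ws
        counts[:ws.size] += 1
        gene_means[gid] = float(ws.mean())
    if not gene_means:
        raise ValueError("all sequences shorter than one window")
    have = counts > 0
    centers = np.arange(max_windows)[have] + (window + 1) // 2
    means = sums[have] / counts[have]
    smoothed = CubicSpline(centers, means)(centers) if have.sum() > 1 else means
    return PeptideScoreProfile(label=label, centers=centers, mean_scores=means,
                               n_contributing=counts[have], smoothed=smoothed,
                               gene_means=pd.Series(gene_means),
                               n_excluded=n_excluded, table_name=table.name)


@dataclass
class ProfileComparison:
    statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int


def compare_profiles(profile_a: PeptideScoreProfile,
                     profile_b: PeptideScoreProfile) -> ProfileComparison:
    """Welch two-sample t-test on gene-level mean scores."""
    a = profile_a.gene_means.to_numpy()
    b = profile_b.gene_means.to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs >= 2 genes")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ProfileComparison(statistic=float(res.statistic),
                             df=float(res.df), p_value=float(res.pvalue),
                             n_a=len(a), n_b=len(b))


def random_control_set(universe: list[str], n: int,
                       seed: int | np.random.Generator | None = None,
                       ) -> list[str]:
    """Uniform sample of gene ids without replacement (seeded)."""
    if n > len(universe):
        raise ValueError(f"cannot draw {n} from a universe of {len(universe)}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in sorted(idx)]
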