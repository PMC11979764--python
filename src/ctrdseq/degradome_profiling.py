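"""5'P degradome profiling: end tracks, metagene profiles, periodicity, TSI.

5'P-seq (degradome) read 5' ends mark in-vivo decay intermediates produced
by co-translational 5'->3' decay (CTRD). Because the exonuclease trails the
last translating ribosome, end positions show 3-nt periodicity in the CDS
and pile up 16-17 nt upstream of the stop codon where termination is slow.
This module turns per-transcript end-count vectors into the three summaries
used to read those signatures: anchored metagene profiles (RPM), CDS frame
fractions, and the translational termination stalling index (TSI).

Distance convention (shared with the simulator): the distance from a 5'P
end to the stop codon is ``index(first stop nt) - index(end)``, so the
ribosome boundary "16-17 nt upstream" is the pair of positions at distances
16 and 17.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel

__all__ = [
    "FivePEndTrack",
    "ExtractionReport",
    "MetaProfile",
    "TSIRecord",
    "extract_5p_ends",
    "metagene_profile",
    "frame_periodicity",
    "compute_tsi",
    "BOUNDARY_DISTANCES",
]

#: distances (nt, first-stop-nt minus end position) defining the ribosome
#: boundary at termination
BOUNDARY_DISTANCES = (16, 17)


@dataclass
class FivePEndTrack:
    """Per-nucleotide counts of 5'P read ends on one transcript."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("track must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("negative end counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ExtractionReport:
    n_records: int = 0
    n_assigned: int = 0
    n_out_of_range: int = 0
    unknown_transcripts: list = field(default_factory=list)


def extract_5p_ends(end_table: pd.DataFrame,
                    transcripts: list[TranscriptModel],
                    ) -> tuple[dict[str, FivePEndTrack], ExtractionReport]:
    """Tally a BED-like end table into per-transcript tracks.

    ``end_table`` columns: transcript_id, start, end, count (0-based
    half-open in transcript coordinates; the read 5' end is ``start``).
    Every transcript gets a track (all-zero if unseen). Records on unknown
    transcripts are skipped and reported; positions outside [0, length)
    are rejected and tallied.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    tracks = {tid: np.zeros(t.length, dtype=np.int64) for tid, t in by_id.items()}
    report = ExtractionReport()
    for row in end_table.itertuples(index=False):
        report.n_records += 1
        tid = row.transcript_id
        if tid not in tracks:
            report.unknown_transcripts.append(tid)
            continue
        pos = int(row.start)
        n = int(getattr(row, "count", 1))
        if 0 <= pos < len(tracks[tid]):
            tracks[tid][pos] += n
            report.n_assigned += n
        else:
            report.n_out_of_range += n
    return ({tid: FivePEndTrack(tid, arr) for tid, arr in tracks.items()}, report)


@dataclass
class MetaProfile:
    """Anchored metagene profile of 5'P ends.

    Offsets are nucleotides relative to the first nt of the anchor codon
    (negative = upstream); values are summed counts, in reads-per-million
    of the library when RPM-normalised.
    """

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    n_transcripts: int
    n_excluded: int
    normalized: str = "rpm"

    def argmax_offset(self, lo: int, hi: int) -> int:
        """Offset of the profile maximum restricted to [lo, hi]."""
        mask = (self.offsets >= lo) & (self.offsets <= hi)
        if not mask.any():
            raise ValueError("window outside profile")
        sub_off, sub_val = self.offsets[mask], self.values[mask]
        return int(sub_off[np.argmax(sub_val)])


def _anchor_position(t: TranscriptModel, anchor: str) -> int:
    if anchor == "start_codon":
        return t.cds_start
    if anchor == "stop_codon":
        return t.stop_first_nt
    raise ValueError(f"anchor must be start_codon or stop_codon, got {anchor!r}")


def metagene_profile(tracks: dict[str, FivePEndTrack],
                     transcripts: list[TranscriptModel],
                     anchor: str = "stop_codon",
                     window_up: int = 100,
                     window_down: int = 50,
                     normalize: str = "rpm") -> MetaProfile:
    """Sum 5'P end counts over transcripts aligned at a codon anchor.

    Transcripts whose track cannot host the full window are excluded (and
    counted), never padded. With ``normalize="rpm"`` the summed profile is
    divided by (total mapped ends across all supplied tracks) / 1e6.
    """
    offsets = np.arange(-window_up, window_down + 1)
    profile = np.zeros(offsets.size, dtype=float)
    n_inc = n_exc = 0
    total_ends = 0
    for t in transcripts:
        tr = tracks.get(t.transcript_id)
        if tr is None:
            continue
        total_ends += tr.total
        a = _anchor_position(t, anchor)
        if a - window_up < 0 or a + window_down >= t.length:
            n_exc += 1
            continue
        profile += tr.counts[a - window_up:a + window_down + 1]
        n_inc += 1
    if n_inc == 0:
        raise ValueError("no transcript can host the requested window")
    if normalize == "rpm":
        if total_ends == 0:
            raise ValueError("cannot RPM-normalise: zero mapped ends")
        profile = profile / (total_ends / 1e6)
    elif normalize not in (None, "none", "raw"):
        raise ValueError(f"unknown normalisation {normalize!r}")
    return MetaProfile(anchor, offsets, profile, n_inc, n_exc,
                       normalized=normalize or "raw")


def frame_periodicity(tracks: dict[str, FivePEndTrack],
                      transcripts: list[TranscriptModel],
                      exclude_codons: int = 25) -> np.ndarray:
    """Fractions of CDS-internal 5'P ends in each reading frame.

    Frame is the end position minus ``cds_start``, mod 3. The first and
    last ``exclude_codons`` codons of each CDS are excluded to avoid
    initiation/termination artefacts. Returns (f0, f1, f2) summing to 1.
    """
    sums = np.zeros(3, dtype=float)
    margin = 3 * exclude_codons
    for t in transcripts:
        tr = tracks.get(t.transcript_id)
        if tr is None:
            continue
        lo = t.cds_start + margin
        hi = t.cds_end - margin
        if hi <= lo:
            continue
        seg = tr.counts[lo:hi]
        phase0 = (lo - t.cds_start) % 3
        for f in range(3):
            start = (f - phase0) % 3
            sums[f] += seg[start::3].sum()
    total = sums.sum()
    if total == 0:
        raise ValueError("no CDS-internal 5'P ends; frame fractions undefined")
    return sums / total


@dataclass
class TSIRecord:
    """Translational termination stalling index for one transcript.

    TSI = (sum of 5'P ends at the two ribosome-boundary positions, 16 and
    17 nt upstream of the stop codon) / (mean per-nt ends in the flanking
    100 nt: 50 nt on each side of, and excluding, the boundary pair).
    Under this sum-numerator convention a uniform track gives TSI = 2, so
    2 (not 1) is the neutral reference value. When the flank carries no
    signal the index is undefined (``defined=False``), never infinite.
    """

    transcript_id: str
    boundary_count: float
    flank_mean: float
    tsi: float | None
    defined: bool


def compute_tsi(track: FivePEndTrack, transcript: TranscriptModel,
                flank: int = 100) -> TSIRecord:
    """Compute the stalling index of one transcript's 5'P track."""
    if flank % 2:
        raise ValueError("flank must be even (split symmetrically)")
    half = flank // 2
    stop = transcript.stop_first_nt
    b_lo = stop - max(BOUNDARY_DISTANCES)   # distance 17
    b_hi = stop - min(BOUNDARY_DISTANCES)   # distance 16
    if b_lo - half < 0 or b_hi + half >= transcript.length:
        raise ValueError(
            f"{transcript.transcript_id}: flank window does not fit the transcript")
    counts = track.counts
    boundary = float(counts[b_lo] + counts[b_hi])
    flank_vals = np.concatenate([counts[b_lo - half:b_lo],
                                 counts[b_hi + 1:b_hi + 1 + half]])
    flank_mean = float(flank_vals.mean())
    if flank_mean == 0:
        return TSIRecord(transcript.transcript_id, boundary, 0.0, None, False)
    return TSIRecord(transcript.transcript_id, boundary, flank_mean,
                     boundary / flank_mean, True)
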