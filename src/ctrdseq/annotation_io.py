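"""Transcript coordinate frames, standard-format I/O and TPM normalisation.

All transcript-local coordinates in this package are 0-based, half-open and
run 5'->3' on the mature transcript; GFF3 I/O converts to/from the 1-based
inclusive convention at the boundary. The coding region (``cds_start``,
``cds_end``) includes the stop codon.

Count matrices use a flat sample-name grammar
``<assay>_<regime>_<timepoint>_rep<k>`` (e.g. ``degradome_SAT_p2_rep1``)
so that a single table can carry any subset of the three assays
(total mRNA-seq, polysomal mRNA-seq, degradome 5'P-seq) over the SAT
(primed, p1-p5) and BT (unprimed, pA-pC) heat-stress time courses.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STOP_CODONS",
    "ASSAYS",
    "SampleKey",
    "TranscriptModel",
    "AssayCounts",
    "TPMTable",
    "read_annotation",
    "write_annotation",
    "read_transcript_fasta",
    "compute_tpm",
    "replicate_mean_tpm",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ASSAYS = ("total", "polysomal", "degradome")

_SAMPLE_RE = re.compile(
    r"^(?P<assay>total|polysomal|degradome)_(?P<regime>SAT|BT)_"
    r"(?P<timepoint>[A-Za-z0-9]+)_rep(?P<replicate>\d+)$"
)


@dataclass(frozen=True, order=True)
class SampleKey:
    """One sequencing sample: assay x regime x timepoint x replicate."""

    assay: str
    regime: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.regime not in ("SAT", "BT"):
            raise ValueError(f"unknown regime {self.regime!r}; expected SAT or BT")

    def __str__(self) -> str:
        return f"{self.assay}_{self.regime}_{self.timepoint}_rep{self.replicate}"

    @property
    def condition(self) -> str:
        """Condition label without the replicate (assay_regime_timepoint)."""
        return f"{self.assay}_{self.regime}_{self.timepoint}"

    @classmethod
    def parse(cls, name: str) -> "SampleKey":
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(f"sample name {name!r} does not match "
                             "'<assay>_<regime>_<timepoint>_rep<k>'")
        return cls(m["assay"], m["regime"], m["timepoint"], int(m["replicate"]))


@dataclass(frozen=True)
class TranscriptModel:
    """A mature transcript with its coding region.

    The CDS interval is transcript-local, 0-based half-open, and includes
    the stop codon; this anchors every stop-proximal 5'P analysis (the
    ribosome boundary sits 16-17 nt upstream of the first stop-codon
    nucleotide).
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}")
        new_flags = list(self.flags)
        if (self.cds_end - self.cds_start) % 3 != 0:
            if "cds_not_multiple_of_3" not in new_flags:
                new_flags.append("cds_not_multiple_of_3")
        elif self.stop_codon not in STOP_CODONS:
            if "no_stop_codon" not in new_flags:
                new_flags.append("no_stop_codon")
        object.__setattr__(self, "flags", tuple(new_flags))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def utr3_length(self) -> int:
        return len(self.sequence) - self.cds_end

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start:self.cds_end]

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.cds_end - 3:self.cds_end].upper()

    @property
    def stop_first_nt(self) -> int:
        """Transcript position of the first nucleotide of the stop codon."""
        return self.cds_end - 3

    def protein_sequence(self, include_stop: bool = False) -> str:
        aa = str(Seq(self.cds_sequence).translate())
        if not include_stop and aa.endswith("*"):
            aa = aa[:-1]
        return aa


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def read_transcript_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_annotation(gff_path: str | os.PathLike,
                    fasta_path: str | os.PathLike,
                    ) -> list[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a GFF3 annotation.

    ``fasta_path`` holds the sequences the GFF3 seqids refer to (a genome,
    or per-transcript contigs as written by :func:`write_annotation`).
    Exon features are concatenated in genomic order; minus-strand
    transcripts are reverse-complemented so the model runs 5'->3'.
    Transcripts without a CDS feature are excluded (they cannot anchor any
    CDS-based analysis); a CDS whose length is not a multiple of 3 is kept
    but flagged.
    """
    import gffutils

    gff_path = str(gff_path)
    with open(gff_path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []

    genome = read_transcript_fasta(fasta_path)
    db = gffutils.create_db(gff_path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            for parent in feat.attributes.get("Parent", []):
                store.setdefault(parent, []).append(feat)

    gene_of: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            tid = feat.id
            parents = feat.attributes.get("Parent", [])
            gene_of[tid] = parents[0] if parents else tid

    models: list[TranscriptModel] = []
    for tid, ex in sorted(exons.items()):
        if tid not in cds:
            continue  # no CDS: excluded from CDS-anchored analyses
        ex = sorted(ex, key=lambda f: f.start)
        strand = ex[0].strand
        seqid = ex[0].seqid
        contig = genome[seqid]
        plus_seq = "".join(contig[f.start - 1:f.end] for f in ex)
        length = len(plus_seq)

        # map genomic coordinate -> plus-strand transcript offset
        offsets: dict[int, int] = {}
        pos = 0
        for f in ex:
            for g in range(f.start, f.end + 1):
                offsets[g] = pos
                pos += 1

        cds_feats = sorted(cds[tid], key=lambda f: f.start)
        g_lo, g_hi = cds_feats[0].start, cds_feats[-1].end
        lo_t, hi_t = offsets[g_lo], offsets[g_hi]
        if strand == "-":
            sequence = _revcomp(plus_seq)
            cds_start = length - 1 - hi_t
            cds_end = (length - 1 - lo_t) + 1
        else:
            sequence = plus_seq
            cds_start, cds_end = lo_t, hi_t + 1

        models.append(TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of.get(tid, tid),
            sequence=sequence,
            cds_start=cds_start,
            cds_end=cds_end,
        ))
    return models


def write_annotation(transcripts: list[TranscriptModel],
                     gff_path: str | os.PathLike,
                     fasta_path: str | os.PathLike) -> None:
    """Write transcripts as per-transcript GFF3 contigs plus a FASTA.

    Each transcript is emitted on its own seqid (the transcript id) on the
    plus strand with gene/mRNA/exon/CDS features in 1-based inclusive GFF3
    coordinates; :func:`read_annotation` round-trips this exactly.
    """
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for t in transcripts:
            tid, gid, L = t.transcript_id, t.gene_id, t.length
            gff.write(f"{tid}\tctrdseq\tgene\t1\t{L}\t.\t+\t.\tID={gid}\n")
            gff.write(f"{tid}\tctrdseq\tmRNA\t1\t{L}\t.\t+\t.\tID={tid};Parent={gid}\n")
            gff.write(f"{tid}\tctrdseq\texon\t1\t{L}\t.\t+\t.\t"
                      f"ID={tid}.exon1;Parent={tid}\n")
            gff.write(f"{tid}\tctrdseq\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t0\t"
                      f"ID={tid}.cds;Parent={tid}\n")
    records = [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
               for t in transcripts]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Count matrices and TPM
# ---------------------------------------------------------------------------

@dataclass
class AssayCounts:
    """Raw gene x sample count matrix with gene lengths.

    ``counts`` columns are sample names following the SampleKey grammar;
    ``lengths`` gives each gene's transcript length in nucleotides (one
    transcript model per gene).
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample columns in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = list(self.lengths.index[self.lengths.isna()][:5])
            raise ValueError(f"genes without a length, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive gene lengths")
        for c in self.counts.columns:
            SampleKey.parse(c)  # validates the grammar

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey.parse(c) for c in self.counts.columns]

    def columns_for(self, assay: str | None = None, regime: str | None = None,
                    timepoint: str | None = None) -> list[str]:
        cols = []
        for c in self.counts.columns:
            k = SampleKey.parse(c)
            if assay is not None and k.assay != assay:
                continue
            if regime is not None and k.regime != regime:
                continue
            if timepoint is not None and k.timepoint != timepoint:
                continue
            cols.append(c)
        return cols

    def subset(self, **kw) -> "AssayCounts":
        cols = self.columns_for(**kw)
        return AssayCounts(self.counts[cols].copy(), self.lengths.copy())

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "AssayCounts":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(df, lengths)


@dataclass
class TPMTable:
    """TPM values, same shape as the source counts (or replicate-averaged)."""

    values: pd.DataFrame
    replicate_averaged: bool = False

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)


def compute_tpm(counts: AssayCounts) -> TPMTable:
    """Transcripts-per-million normalisation.

    Per sample: reads-per-kilobase rpk = count / (length/1000); the
    per-million scaling factor is sum(rpk) / 1e6; TPM = rpk / factor.
    Every column therefore sums to 1e6. Genes with zero counts get TPM 0.
    """
    len_kb = counts.lengths.to_numpy(dtype=float) / 1000.0
    rpk = counts.counts.to_numpy(dtype=float) / len_kb[:, None]
    colsum = rpk.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(
            f"all-zero count column(s): {list(counts.counts.columns[zero])}")
    tpm = rpk / (colsum / 1e6)
    return TPMTable(pd.DataFrame(tpm, index=counts.counts.index,
                                 columns=counts.counts.columns))


def replicate_mean_tpm(tpm: TPMTable) -> TPMTable:
    """Arithmetic mean of TPM across replicates per condition.

    Output columns are condition labels ``<assay>_<regime>_<timepoint>``.
    """
    if tpm.replicate_averaged:
        return tpm
    groups: dict[str, list[str]] = {}
    for c in tpm.values.columns:
        groups.setdefault(SampleKey.parse(c).condition, []).append(c)
    out = pd.DataFrame(
        {cond: tpm.values[cols].mean(axis=1) for cond, cols in groups.items()},
        index=tpm.values.index)
    return TPMTable(out, replicate_averaged=True)
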