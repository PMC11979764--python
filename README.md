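# ctrdseq

Analysis toolkit for polysome-related gene regulation under heat-stress
priming: degradome (5′P-seq) profiling, degradome-based translation
efficiency, selection of co-translational-decay (CTRD) regulated
transcripts, nascent-peptide chaperone-demand scoring, and sucrose-gradient
polysome quantification — all exercised end to end on synthetic data with
planted, recorded ground truth.

## Who this is for

Groups studying translation and mRNA decay in stress time courses who work
from three count assays per sample — total mRNA-seq, polysomal mRNA-seq and
degradome 5′P-seq — plus per-transcript 5′P read-end positions and OD254
gradient traces. The package starts where read mapping ends: its inputs are
end tables, count matrices and traces, in plain text formats (GFF3, FASTA,
TSV, CSV, YAML).

## The statistics at the core

**5′P signatures.** Co-translational decay leaves the 5′→3′ exonuclease
trailing the last translating ribosome, so 5′P read ends show 3-nt
periodicity within the CDS and pile up at the ribosome boundary 16–17 nt
upstream of the stop codon. The *translational termination stalling index*
for a transcript is

&nbsp;&nbsp;&nbsp;&nbsp;TSI = (n₁₆ + n₁₇) / mean(flanking 100 nt),

with n_d the 5′P end count at distance d from the first stop-codon
nucleotide and the flank taken as 50 nt on each side of (and excluding) the
boundary pair. Under this sum-numerator convention a uniform track scores
exactly 2, which is the neutral reference value.

**Translation efficiency.** TE(g, t) = (polysomal TPM + ε) / (degradome
TPM + ε) on replicate-mean TPM with ε = 0.1; dividing by decay products
rather than total mRNA makes TE sensitive to decay-level regulation.
Per-gene log₂ ratios are taken against the unstressed reference timepoint;
shifts are tested with two-sample Kolmogorov–Smirnov (vs reference) and
unpaired Wilcoxon rank-sum (primed vs unprimed) tests.

**CTRD selection cascade.** From genes expressed at ≥ 1 TPM in every
condition, remove genes differentially expressed (NB Wald test, raw
p < 0.05 and TPM fold change > 2, either direction) in the total assay at
any stress timepoint, then in the polysomal assay; of the remaining stable
genes, those significantly altered in the degradome at ≥ 1 timepoint form
the CTRD database, clustered by Ward/Euclidean hierarchical clustering of
their degradome log₂ ratios.

**Nascent-peptide scores.** Kyte–Doolittle hydrophobicity and HSP70-binding
propensity averaged over 13-aa windows slid one residue at a time across
the first 80 aa of each protein; set profiles are position-wise means with
an interpolating cubic spline, and sets are compared with a Welch t-test on
gene-level mean scores.

## Worked example

```python
import numpy as np, pandas as pd, ctrdseq as cq

cfg = cq.SimulationConfig(seed=7, n_transcripts=400, ctrd_only_fraction=0.05,
                          de_fraction_per_assay=0.15)
transcripts = cq.generate_transcriptome(cfg)
tracks, _ = cq.simulate_5p_tracks(transcripts, cfg)

print("frame fractions:", np.round(cq.frame_periodicity(tracks, transcripts), 3))
prof = cq.metagene_profile(tracks, transcripts, anchor="stop_codon")
print("stop-profile peak offset:", prof.argmax_offset(-30, -1))
tsi = [cq.compute_tsi(tracks[t.transcript_id], t).tsi for t in transcripts]
print("median TSI:", round(float(np.median([v for v in tsi if v])), 2))

assays, truth = cq.simulate_counts(cfg, transcripts)
tpm = {a: cq.compute_tpm(c) for a, c in assays.items()}
mean_tpm = pd.concat([cq.replicate_mean_tpm(t).values for t in tpm.values()], axis=1)
ubiquitous = cq.filter_ubiquitous(mean_tpm, min_tpm=1.0)
contrasts = ["p2", "p3", "p4", "p5", "pB", "pC"]
de = {a: {tp: cq.de_test(assays[a], tp, "p1", tpm=tpm[a].values)
          for tp in contrasts} for a in assays}
sel = cq.build_ctrd_db(ubiquitous, de["total"], de["polysomal"], de["degradome"])
print("cascade:", sel.report())
planted, found = set(truth.ctrd_only_genes), set(sel.ctrd_db)
print("planted CTRD-only recovered:", len(planted & found), "of", len(planted))
```

prints

```
frame fractions: [0.55  0.251 0.199]
stop-profile peak offset: -17
median TSI: 10.46
cascade: {'n_ubiquitous': 400, 'n_de_total': 64, 'n_stable_total': 336,
          'n_de_polysomal_in_stable_total': 0, 'n_stable_polysomal': 336,
          'n_ctrd_db': 23}
planted CTRD-only recovered: 20 of 20
```

The frame fractions recover the configured periodicity (0.55/0.25/0.20),
the stop-anchored metagene profile peaks at the ribosome boundary (−17 nt),
the median TSI reflects the simulated termination-stalling boost, and the
cascade recovers every planted degradome-only gene (23 calls include 3
borderline false positives at low expression).

The same stages are available from the shell:

```sh
ctrdseq simulate --seed 7 --out run/
ctrdseq tpm run/counts_total.tsv -o run/tpm_total.tsv
ctrdseq tsi --ends run/fivep_ends.tsv --gff run/transcripts.gff3 \
        --fasta run/transcripts.fasta -o run/tsi.tsv
ctrdseq run --seed 7 --out run_full/   # full pipeline + manifest.json
```

## Layout

- `src/ctrdseq/synthetic_data.py` — generators with planted ground truth
- `src/ctrdseq/annotation_io.py` — GFF3/FASTA/TSV I/O, transcript models, TPM
- `src/ctrdseq/degradome_profiling.py` — 5′P tracks, metagene, periodicity, TSI
- `src/ctrdseq/translation_metrics.py` — TE, log₂ ratios, KS/rank-sum tests
- `src/ctrdseq/ctrd_selection.py` — ubiquity filter, NB Wald DE test, cascade,
  Venn algebra, clustering
- `src/ctrdseq/nascent_peptide_scores.py` — KD/HSP70 window scoring
- `src/ctrdseq/polysome_quantification.py` — gradient-trace quantification
- `src/ctrdseq/pipeline.py`, `cli.py` — orchestration and the `ctrdseq` CLI

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
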