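"""End-to-end pipeline: simulate -> TPM -> metagene/TSI -> TE -> cascade ->
cluster -> peptide scores, with a run manifest.

All randomness flows from one master seed through named substreams (one
per stage), so reruns with the same configuration are byte-identical
except for the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation_io import (AssayCounts, compute_tpm, replicate_mean_tpm,
                            write_annotation)
from .ctrd_selection import (build_ctrd_db, cluster_ctrd_levels, de_test,
                             filter_ubiquitous)
from .degradome_profiling import compute_tsi, frame_periodicity, metagene_profile
from .nascent_peptide_scores import (compare_profiles, load_score_table,
                                     random_control_set, set_profile)
from .synthetic_data import (SimulationConfig, generate_transcriptome,
                             simulate_5p_tracks, simulate_counts,
                             tracks_to_end_table)
from .translation_metrics import (log2_ratio_vs_reference,
                                  translation_efficiency)

__all__ = ["RunConfig", "run_pipeline", "stage_rng"]

_STAGE_STREAMS = {
    "transcriptome": 1,
    "tracks": 2,
    "counts": 3,
    "peptide_control": 4,
    "traces": 5,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, _STAGE_STREAMS[stage]]))


@dataclass
class RunConfig:
    """Pipeline configuration; threshold defaults are the study's."""

    seed: int = 0
    outdir: str = "ctrdseq_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_tpm: float = 1.0
    alpha: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 0.1
    window: int = 13
    prefix: int = 80
    flank: int = 100
    k_clusters: int = 4
    reference_timepoint: str = "p1"
    stages: tuple[str, ...] = ("simulate", "tpm", "degradome", "te",
                               "cascade", "peptide")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "design" in sim_raw:
            sim_raw["design"] = tuple(tuple(x) for x in sim_raw["design"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw, sim=SimulationConfig(**sim_raw))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    hash_dict = {k: v for k, v in cfg_dict.items() if k != "outdir"}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(hash_dict, sort_keys=True).encode()).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    sim = dataclasses.replace(config.sim, seed=config.seed)

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest["outputs"][name] = _sha256(path)

    # ---- simulate ---------------------------------------------------------
    transcripts = generate_transcriptome(sim, stage_rng(config.seed, "transcriptome"))
    tracks, track_truth = simulate_5p_tracks(
        transcripts, sim, stage_rng(config.seed, "tracks"))
    assays, truth = simulate_counts(sim, transcripts,
                                    stage_rng(config.seed, "counts"))
    if "simulate" in config.stages:
        write_annotation(transcripts, out / "transcripts.gff3",
                         out / "transcripts.fasta")
        manifest["outputs"]["transcripts.gff3"] = _sha256(out / "transcripts.gff3")
        manifest["outputs"]["transcripts.fasta"] = _sha256(out / "transcripts.fasta")
        save_df(tracks_to_end_table(tracks), "fivep_ends.tsv", index=False)
        for assay, ac in assays.items():
            ac.to_tsv(out / f"counts_{assay}.tsv")
            manifest["outputs"][f"counts_{assay}.tsv"] = _sha256(
                out / f"counts_{assay}.tsv")
        save_df(truth.effects, "ground_truth_effects.tsv", index=False)
        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(hash_dict, fh, sort_keys=True)
        manifest["outputs"]["config_echo.yaml"] = _sha256(out / "config_echo.yaml")
        manifest["stages"]["simulate"] = {
            "n_transcripts": len(transcripts),
            "n_de_genes": len(truth.de_genes),
            "n_ctrd_only_genes": len(truth.ctrd_only_genes),
        }

    # ---- tpm --------------------------------------------------------------
    tpm = {a: compute_tpm(ac) for a, ac in assays.items()}
    mean_tpm = {a: replicate_mean_tpm(t) for a, t in tpm.items()}
    if "tpm" in config.stages:
        for a in assays:
            save_df(tpm[a].values, f"tpm_{a}.tsv", index_label="gene_id")
        manifest["stages"]["tpm"] = {
            a: {"n_genes": len(t.values)} for a, t in tpm.items()}

    # ---- degradome profiling ---------------------------------------------
    if "degradome" in config.stages:
        profile = metagene_profile(tracks, transcripts, anchor="stop_codon",
                                   window_up=100, window_down=50)
        save_df(pd.DataFrame({"offset": profile.offsets, "rpm": profile.values}),
                "metagene_stop.tsv", index=False)
        frames = frame_periodicity(tracks, transcripts)
        tsi_rows = []
        for t in transcripts:
            try:
                rec = compute_tsi(tracks[t.transcript_id], t, flank=config.flank)
            except ValueError:
                continue
            tsi_rows.append({"transcript_id": rec.transcript_id,
                             "boundary_count": rec.boundary_count,
                             "flank_mean": rec.flank_mean,
                             "tsi": rec.tsi if rec.defined else np.nan,
                             "defined": rec.defined})
        tsi_df = pd.DataFrame(tsi_rows)
        save_df(tsi_df, "tsi.tsv", index=False)
        manifest["stages"]["degradome"] = {
            "frame_fractions": [round(float(f), 6) for f in frames],
            "n_profiled": profile.n_transcripts,
            "n_tsi_defined": int(tsi_df["defined"].sum()) if len(tsi_df) else 0,
            "median_tsi": (float(tsi_df["tsi"].median())
                           if len(tsi_df) else None),
        }

    # ---- translation efficiency ------------------------------------------
    by_tp = {a: mean_tpm[a].values.rename(columns={
        c: c.split("_", 2)[2] for c in mean_tpm[a].values.columns})
        for a in assays}
    te = translation_efficiency(by_tp["polysomal"], by_tp["degradome"],
                                pseudocount=config.pseudocount)
    ref = config.reference_timepoint
    te_log2 = log2_ratio_vs_reference(te, ref, pseudocount=0.0)
    deg_log2 = log2_ratio_vs_reference(by_tp["degradome"], ref,
                                       pseudocount=config.pseudocount)
    if "te" in config.stages:
        save_df(te, "te.tsv", index_label="gene_id")
        save_df(te_log2, "te_log2_vs_ref.tsv", index_label="gene_id")
        manifest["stages"]["te"] = {"n_genes": len(te),
                                    "reference": ref,
                                    "pseudocount": config.pseudocount}

    # ---- cascade + clustering --------------------------------------------
    selection = None
    if "cascade" in config.stages:
        all_mean = pd.concat([mean_tpm[a].values for a in assays], axis=1)
        ubiquitous = filter_ubiquitous(all_mean, min_tpm=config.min_tpm)
        contrasts = [tp for tp in sim.timepoints
                     if tp not in sim.unperturbed_timepoints]
        de = {a: {tp: de_test(assays[a], tp, reference=ref,
                              alpha=config.alpha,
                              fc_threshold=config.fc_threshold,
                              pseudocount=config.pseudocount,
                              tpm=tpm[a].values)
                  for tp in contrasts} for a in assays}
        selection = build_ctrd_db(ubiquitous, de["total"], de["polysomal"],
                                  de["degradome"], reference=ref)
        ctrd_sorted = sorted(selection.ctrd_db)
        report = selection.report()
        if len(ctrd_sorted) >= max(config.k_clusters, 2):
            mat = deg_log2.loc[ctrd_sorted].drop(columns=[ref])
            labels, ordered, cluster_means = cluster_ctrd_levels(
                mat, k=config.k_clusters)
            selection.clusters = labels
            save_df(labels.to_frame(), "ctrd_clusters.tsv", index_label="gene_id")
            save_df(cluster_means, "ctrd_cluster_means.tsv")
            report["cluster_sizes"] = labels.value_counts().sort_index().to_dict()
        pd.Series(ctrd_sorted, name="gene_id").to_csv(
            out / "ctrd_db.tsv", sep="\t", index=False)
        manifest["outputs"]["ctrd_db.tsv"] = _sha256(out / "ctrd_db.tsv")
        with open(out / "cascade_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=int)
        manifest["outputs"]["cascade_report.json"] = _sha256(
            out / "cascade_report.json")
        manifest["stages"]["cascade"] = report

    # ---- peptide scoring --------------------------------------------------
    if "peptide" in config.stages and selection is not None \
            and selection.clusters is not None:
        proteins = {t.gene_id: t.protein_sequence() for t in transcripts}
        counts = selection.clusters.value_counts()
        focus_cluster = int(counts.idxmax())
        focus = [g for g, c in selection.clusters.items() if c == focus_cluster]
        universe = sorted(set(proteins) - set(focus))
        n_ctl = min(len(focus), len(universe))
        control = random_control_set(universe, n_ctl,
                                     stage_rng(config.seed, "peptide_control"))
        results = {}
        for table_name in ("kyte_doolittle", "hsp70_binding"):
            table = load_score_table(table_name)
            prof_a = set_profile({g: proteins[g] for g in focus}, table,
                                 window=config.window, prefix=config.prefix,
                                 label=f"cluster{focus_cluster}")
            prof_b = set_profile({g: proteins[g] for g in control}, table,
                                 window=config.window, prefix=config.prefix,
                                 label="random_control")
            cmp = compare_profiles(prof_a, prof_b)
            save_df(pd.DataFrame({"center_aa": prof_a.centers,
                                  "mean_set": prof_a.mean_scores,
                                  "mean_control": prof_b.mean_scores,
                                  "spline_set": prof_a.smoothed,
                                  "spline_control": prof_b.smoothed}),
                    f"peptide_profile_{table_name}.tsv", index=False)
            results[table_name] = {"t": cmp.statistic, "df": cmp.df,
                                   "p_value": cmp.p_value,
                                   "n_set": cmp.n_a, "n_control": cmp.n_b}
        manifest["stages"]["peptide"] = {"focus_cluster": focus_cluster,
                                         "tests": results}

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
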