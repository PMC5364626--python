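"""End-to-end pipeline: simulate → shortlist → annotate → overlap → integrate.

A single YAML-serialisable config drives every stage; all randomness flows
from explicit seeds, so re-running the same config yields a byte-identical
summary.  Every output names the config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, filtering, overlap, regpot, synth
from .genome import GenomeLayout, write_bedgraph, write_genes, write_intervals

log = logging.getLogger("regulomekit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "shortlist": True,
        "annotate": True,
        "overlap": True,
        "integrate": True,
    },
    "synthetic": {
        "chrom_lengths": {"chr1": 10_000_000, "chr2": 10_000_000},
        "genes_per_class": {
            "protein_coding": 1600,
            "lincRNA": 200,
            "snRNA": 80,
            "snoRNA": 80,
            "miRNA": 40,
        },
        "min_gene_gap": 200,
        "n_peaks": 5000,
        "tss_bias": 0.6,
        "proximity_window": 1000,
        "n_features": 3000,
        "overlap_fraction": 0.5,
        "feature_width": 500,
        "track_bin_width": 1000,
        "track_correlation": 0.8,
        "conservation_bump_height": 0.5,
        "conservation_bump_width": 400,
        "venn_counts": {"A": 120, "C": 150, "U": 90, "AC": 46, "AU": 20, "CU": 25, "ACU": 61},
        "opposite_direction": 21,
        "silenced_fraction": 0.3,
    },
    "alpha": 0.05,
    "promoter_window": 3000,
    "proximal_window": 1000,
    "downstream_window": 3000,
    "n_permutations": 1000,
    "gap": 0,
    "window_w": 100_000,
    "regulome_window": 1000,
    "metagene": {"body_bins": 60, "flank_bp": 2000, "flank_bins": 20},
    "summit_window": 2000,
}


def merge_config(overrides: dict | None = None) -> dict:
    """Deep-merge user overrides onto the defaults."""

    def merge(base, over):
        out = dict(base)
        for k, v in (over or {}).items():
            out[k] = merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
        return out

    return merge(DEFAULT_CONFIG, overrides or {})


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def run_pipeline(config: dict, outdir) -> dict:
    """Run the enabled stages and write the report bundle to ``outdir``.

    Returns the summary dict (also written as ``summary.json``).  Disabled
    stages are marked "skipped"; a downstream stage missing its inputs
    fails with a dependency error naming the stage.
    """
    config = merge_config(config)
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config["seed"])
    stages = config["stages"]
    syn = config["synthetic"]
    summary: dict = {"config_hash": chash, "seed": seed, "stages": {}}
    state: dict = {}

    def stamp(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df.attrs["config_hash"] = chash
        return df

    def write_table(name: str, df: pd.DataFrame) -> None:
        path = outdir / "tables" / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash} seed={seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    # ---- simulate -------------------------------------------------------
    if stages.get("simulate"):
        t0 = time.perf_counter()
        layout, genes, _ = synth.gen_genome(
            dict(syn["chrom_lengths"]), dict(syn["genes_per_class"]),
            min_gene_gap=int(syn["min_gene_gap"]), seed=seed,
        )
        peaks, peak_truth = synth.gen_peaks(
            genes, layout, int(syn["n_peaks"]), tss_bias=float(syn["tss_bias"]),
            proximity_window=int(syn["proximity_window"]), seed=seed,
        )
        features, feat_truth = synth.gen_feature_set(
            peaks, layout, float(syn["overlap_fraction"]), int(syn["n_features"]),
            feature_width=int(syn["feature_width"]), seed=seed,
        )
        track_a, track_b, sig_truth = synth.gen_signal_pair(
            layout, int(syn["track_bin_width"]), float(syn["track_correlation"]), seed=seed,
        )
        cons, cons_truth = synth.gen_conservation_track(
            layout, 50, peaks.summit_positions(),
            bump_height=float(syn["conservation_bump_height"]),
            bump_width=int(syn["conservation_bump_width"]), seed=seed,
        )
        de_tables, de_truth = synth.gen_de_tables(
            [g.gene_id for g in genes], dict(syn["venn_counts"]),
            int(syn["opposite_direction"]), alpha=float(config["alpha"]), seed=seed,
        )
        fpkm, expr_truth = synth.gen_expression(
            [g.gene_id for g in genes], float(syn["silenced_fraction"]), seed=seed,
        )
        state.update(
            layout=layout, genes=genes, peaks=peaks, features=features,
            track_a=track_a, track_b=track_b, conservation=cons,
            de_tables=de_tables, fpkm=fpkm,
        )
        truth = {
            "tss_bias": peak_truth.tss_bias,
            "overlap_fraction": feat_truth.overlap_fraction,
            "track_correlation": sig_truth.track_correlation,
            "conservation_bump": list(cons_truth.conservation_bump),
            "venn_counts": de_truth.venn_counts,
            "opposite_direction": de_truth.opposite_direction,
            "silenced_fraction": expr_truth.extras["silenced_fraction"],
        }
        summary["synthetic_truth"] = truth
        layout.write(outdir / "tables" / "chrom.sizes")
        write_intervals(peaks, outdir / "tables" / "peaks.bed")
        write_genes(genes, outdir / "tables" / "genes.gtf")
        with open(outdir / "tables" / "synthetic_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        summary["stages"]["simulate"] = {"status": "ok"}
        log.info("simulate: %d genes, %d peaks in %.1fs",
                 len(genes), len(peaks), time.perf_counter() - t0)
    else:
        summary["stages"]["simulate"] = {"status": "skipped"}

    def need(key: str, stage: str):
        if key not in state:
            raise StageError(stage, f"requires {key!r} from the simulate stage")
        return state[key]

    # ---- shortlist ------------------------------------------------------
    if stages.get("shortlist"):
        de_tables = need("de_tables", "shortlist")
        result = filtering.consensus_shortlist(de_tables, alpha=float(config["alpha"]))
        write_table("core_regulome", result.to_frame())
        summary["stages"]["shortlist"] = {"status": "ok", **result.summary()}
        state["core"] = result
    else:
        summary["stages"]["shortlist"] = {"status": "skipped"}

    # ---- annotate -------------------------------------------------------
    if stages.get("annotate"):
        peaks = need("peaks", "annotate")
        genes = need("genes", "annotate")
        layout = need("layout", "annotate")
        cfg = annotation.AnnotationConfig(
            promoter_window=int(config["promoter_window"]),
            proximal_window=int(config["proximal_window"]),
            downstream_window=int(config["downstream_window"]),
        )
        ann = annotation.assign_features(peaks, genes, cfg)
        write_table("annotation", ann.to_frame())
        mg = config["metagene"]
        profile = annotation.metagene_profile(
            peaks, genes, body_bins=int(mg["body_bins"]),
            flank_bp=int(mg["flank_bp"]), flank_bins=int(mg["flank_bins"]),
        )
        prof_path = outdir / "profiles" / "metagene.tsv"
        profile.to_frame().to_csv(prof_path, sep="\t", index=False)
        corr = annotation.chrom_correlation(peaks, genes, layout) \
            if len(layout.names) >= 3 else {"r_genes": None, "r_length": None}
        summary["stages"]["annotate"] = {
            "status": "ok",
            "percentages": ann.percentages,
            "promoter_proximal_fraction": ann.promoter_proximal_fraction,
            "chrom_correlation": corr,
        }
    else:
        summary["stages"]["annotate"] = {"status": "skipped"}

    # ---- overlap --------------------------------------------------------
    if stages.get("overlap"):
        peaks = need("peaks", "overlap")
        features = need("features", "overlap")
        layout = need("layout", "overlap")
        test = overlap.randomized_overlap_test(
            peaks, features, layout,
            n_permutations=int(config["n_permutations"]),
            gap=int(config["gap"]), seed=seed,
        )
        rho = overlap.signal_correlation(state["track_a"], state["track_b"])
        cons_profile = overlap.profile_around_summits(
            state["conservation"], peaks, window=int(config["summit_window"])
        )
        pd.DataFrame(
            {"offset": cons_profile.offsets(), "value": cons_profile.values}
        ).to_csv(outdir / "profiles" / "conservation_summit.tsv", sep="\t", index=False)
        summary["stages"]["overlap"] = {
            "status": "ok",
            "overlap_test": test.to_dict(),
            "signal_correlation": rho,
            "conservation_fwhm_bins": cons_profile.fwhm_bins(),
        }
    else:
        summary["stages"]["overlap"] = {"status": "skipped"}

    # ---- integrate ------------------------------------------------------
    if stages.get("integrate"):
        peaks = need("peaks", "integrate")
        genes = need("genes", "integrate")
        layout = need("layout", "integrate")
        de = need("de_tables", "integrate")["NC_vs_A"]
        scores = regpot.binding_scores(genes, peaks, window=int(config["window_w"]))
        records = regpot.regulatory_potential(scores, de, alpha=float(config["alpha"]))
        write_table("regulatory_potential", records)
        classes = dict(zip(records["gene"], records["direction"]))
        fractions, regulome = regpot.regulome_classify(
            peaks, genes, classes, layout,
            promoter_window=int(config["regulome_window"]),
        )
        write_table("regulome", regulome)
        expr = regpot.classify_expression(need("fpkm", "integrate"))
        by_gene = {e.gene_id: e.expressed for e in expr}
        sets = {
            "expressed": [g for g in genes if by_gene[g.gene_id]],
            "silenced": [g for g in genes if not by_gene[g.gene_id]],
        }
        folds = regpot.tss_binding_enrichment(
            peaks, sets, layout, window=int(config["regulome_window"])
        )
        ks_summary = None
        directions = set(records["direction"])
        if {"up", "down", "static"} <= directions:
            ks = regpot.ks_direction_test(records)
            ks_summary = {
                "d_up": ks.d_up, "p_up": ks.p_up,
                "d_down": ks.d_down, "p_down": ks.p_down,
                "stronger_down_fraction": ks.stronger_down_fraction,
            }
            for cls, (rp, frac) in ks.curves.items():
                pd.DataFrame({"rp": rp, "cumulative_fraction": frac}).to_csv(
                    outdir / "profiles" / f"rp_curve_{cls}.tsv", sep="\t", index=False
                )
        summary["stages"]["integrate"] = {
            "status": "ok",
            "bound_fractions": fractions,
            "regulome_size": int(len(regulome)),
            "expression_enrichment_folds": folds,
            "ks_direction": ks_summary,
        }
    else:
        summary["stages"]["integrate"] = {"status": "skipped"}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
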