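"""Regulatory-potential regulome inference from binding and DE evidence.

Each gene receives a TSS-proximal binding score that decays with distance,

    S_binding = Σ_{i=1..k} exp(−(0.5 + 4·Δ_i)),   Δ_i = |summit_i − TSS| / W,

summing over the k peak summits within ±W of the TSS (W defaults to
100 kb so Δ is dimensionless on [0, 1]).  The regulatory potential is the
product of the gene's normalized ranks of binding strength (descending)
and differential-expression significance (q-value ascending),

    RP = (rank_binding / n) · (rank_DE / n),

so smaller RP means stronger combined evidence of regulation.  Comparing
the RP distributions of up-, down- and non-regulated genes with two-sample
Kolmogorov–Smirnov tests asks whether binding preferentially drives
induction or suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomeLayout, PeakSet, tss_tes


@dataclass(frozen=True)
class BindingScore:
    gene_id: str
    k: int
    deltas: tuple[float, ...]  # normalized distances in [0, 1]
    s_binding: float

    def __post_init__(self):
        assert self.k == len(self.deltas)


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    fpkm: tuple[float, float, float]
    expressed: bool  # FPKM > 0 in ≥1 replicate; silenced otherwise


@dataclass
class KSDirectionResult:
    """Direction-of-regulation diagnostics from RP distributions."""

    d_up: float
    p_up: float
    d_down: float
    p_down: float
    stronger_down_fraction: float  # down genes with RP below the up median
    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (rp sorted, cumfrac)


def classify_expression(fpkm_table: pd.DataFrame) -> list[ExpressionClass]:
    """Partition genes into expressed / silenced from FPKM triplets.

    Expects columns gene, fpkm_1..fpkm_3.  Expressed means FPKM > 0 in at
    least one replicate; silenced means zero in all three.  Negative FPKM
    raises.
    """
    cols = ["fpkm_1", "fpkm_2", "fpkm_3"]
    for col in ["gene"] + cols:
        if col not in fpkm_table.columns:
            raise ValueError(f"FPKM table missing column {col!r}")
    vals = fpkm_table[cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative FPKM")
    out = []
    for gid, row in zip(fpkm_table["gene"], vals):
        out.append(ExpressionClass(str(gid), tuple(row), bool((row > 0).any())))
    return out


def binding_score(
    gene: GeneModel, peaks: PeakSet, window: int = 100_000
) -> BindingScore:
    """Distance-decay binding score of one gene from peak summits near its TSS."""
    if window <= 0:
        raise ValueError("window must be positive")
    tss = tss_tes(gene)[0]
    arr = peaks.summit_positions().get(gene.interval.chrom)
    if arr is None:
        return BindingScore(gene.gene_id, 0, (), 0.0)
    dists = np.abs(arr - tss)
    dists = dists[dists <= window]
    deltas = np.sort(dists / window)
    s = float(np.sum(np.exp(-(0.5 + 4.0 * deltas))))
    return BindingScore(gene.gene_id, len(deltas), tuple(float(d) for d in deltas), s)


def binding_scores(
    genes: list[GeneModel], peaks: PeakSet, window: int = 100_000
) -> pd.DataFrame:
    """Vectorised binding scores for a gene collection (gene, k, s_binding)."""
    summit_idx = {c: np.sort(v) for c, v in peaks.summit_positions().items()}
    rows = []
    for g in genes:
        tss = tss_tes(g)[0]
        arr = summit_idx.get(g.interval.chrom)
        if arr is None:
            rows.append((g.gene_id, 0, 0.0))
            continue
        lo = np.searchsorted(arr, tss - window, side="left")
        hi = np.searchsorted(arr, tss + window, side="right")
        deltas = np.abs(arr[lo:hi] - tss) / window
        rows.append((g.gene_id, hi - lo, float(np.sum(np.exp(-(0.5 + 4.0 * deltas))))))
    return pd.DataFrame(rows, columns=["gene", "k", "s_binding"])


def regulatory_potential(
    scores: pd.DataFrame, de: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank-product regulatory potential over a shared gene universe.

    ``scores`` carries (gene, s_binding); ``de`` is a DE table with (gene,
    log2fc, qvalue).  rank 1 = strongest binding / most significant; ties
    get average ranks; q-values of exactly 0 are clamped to the smallest
    positive float before ranking.  Output adds rank_binding, rank_de, rp
    and a direction class in {up, down, static} (static = not significant
    at ``alpha``).
    """
    s = scores.set_index("gene")["s_binding"]
    d = de.set_index("gene")
    if set(s.index) != set(d.index):
        missing = set(s.index).symmetric_difference(d.index)
        raise ValueError(f"gene universes differ, e.g. {sorted(missing)[:5]}")
    d = d.loc[s.index]
    n = len(s)
    q = d["qvalue"].to_numpy(dtype=float)
    q = np.where(q <= 0, np.nextafter(0, 1), q)
    rank_binding = stats.rankdata(-s.to_numpy(), method="average")
    rank_de = stats.rankdata(q, method="average")
    rp = (rank_binding / n) * (rank_de / n)
    sig = d["qvalue"].to_numpy() < alpha
    sign = np.sign(d["log2fc"].to_numpy())
    if np.any(sig & (sign == 0)):
        raise ValueError("significant gene with log2fc == 0: direction undecidable")
    direction = np.where(~sig, "static", np.where(sign > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene": s.index,
            "s_binding": s.to_numpy(),
            "qvalue": d["qvalue"].to_numpy(),
            "rank_binding": rank_binding,
            "rank_de": rank_de,
            "rp": rp,
            "direction": direction,
        }
    ).reset_index(drop=True)


def ks_direction_test(records: pd.DataFrame) -> KSDirectionResult:
    """Two-sample KS comparison of RP for up/down genes against static genes.

    Smaller RP = stronger evidence, so the ``stronger_down_fraction`` is
    the share of downregulated genes whose RP falls below the median RP of
    upregulated genes.  Emits cumulative-fraction curves per class for
    plotting.
    """
    groups = {}
    for cls in ("up", "down", "static"):
        vals = records.loc[records["direction"] == cls, "rp"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no genes in class {cls!r}")
        groups[cls] = np.sort(vals)
    d_up, p_up = stats.ks_2samp(groups["up"], groups["static"])
    d_down, p_down = stats.ks_2samp(groups["down"], groups["static"])
    up_median = float(np.median(groups["up"]))
    stronger = float(np.mean(groups["down"] < up_median))
    curves = {
        cls: (v, np.arange(1, len(v) + 1) / len(v)) for cls, v in groups.items()
    }
    return KSDirectionResult(
        d_up=float(d_up),
        p_up=float(p_up),
        d_down=float(d_down),
        p_down=float(p_down),
        stronger_down_fraction=stronger,
        curves=curves,
    )


def _merged_tss_windows(
    genes: list[GeneModel], window: int, layout: GenomeLayout
) -> dict[str, np.ndarray]:
    """Merged ±window TSS intervals per chromosome, clipped to bounds."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        tss = tss_tes(g)[0]
        lo = max(0, tss - window)
        hi = min(layout[g.interval.chrom], tss + window + 1)
        by_chrom.setdefault(g.interval.chrom, []).append((lo, hi))
    merged = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out = []
        for s, e in pairs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def tss_binding_enrichment(
    peaks: PeakSet,
    gene_sets: dict[str, list[GeneModel]],
    layout: GenomeLayout,
    window: int = 1000,
) -> dict[str, float]:
    """Fold enrichment of summit density in TSS windows over genome background.

    Per label: observed density = summits inside the merged ±window TSS
    footprint per bp of that footprint; background density = all summits
    per bp of genome; fold = observed / background.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    summit_idx = {c: np.sort(v) for c, v in peaks.summit_positions().items()}
    n_total = len(peaks)
    background = n_total / layout.total_bp
    folds = {}
    for label, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"empty gene set {label!r}")
        merged = _merged_tss_windows(genes, window, layout)
        footprint = sum(int((arr[:, 1] - arr[:, 0]).sum()) for arr in merged.values())
        inside = 0
        for chrom, arr in merged.items():
            pos = summit_idx.get(chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, arr[:, 0], side="left")
            hi = np.searchsorted(pos, arr[:, 1], side="left")
            inside += int((hi - lo).sum())
        observed = inside / footprint if footprint else 0.0
        folds[label] = observed / background if background > 0 else 0.0
    return folds


def regulome_classify(
    peaks: PeakSet,
    genes: list[GeneModel],
    de_classes: dict[str, str],
    layout: GenomeLayout,
    promoter_window: int = 1000,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Promoter-bound fraction per DE class plus the inferred regulome.

    ``de_classes`` maps every gene id to up/down/static (a partition; any
    gene appearing twice or unclassified raises).  A gene is bound if ≥1
    peak summit lies within ±promoter_window of its TSS.  The regulome is
    the bound ∧ (up ∨ down) gene list with direction labels.
    """
    ids = [g.gene_id for g in genes]
    if set(de_classes) != set(ids):
        raise ValueError("DE classes must cover the gene universe exactly")
    if not set(de_classes.values()) <= {"up", "down", "static"}:
        raise ValueError("classes must be up/down/static")
    summit_idx = {c: np.sort(v) for c, v in peaks.summit_positions().items()}
    bound = {}
    for g in genes:
        tss = tss_tes(g)[0]
        pos = summit_idx.get(g.interval.chrom)
        if pos is None:
            bound[g.gene_id] = False
            continue
        lo = np.searchsorted(pos, tss - promoter_window, side="left")
        hi = np.searchsorted(pos, tss + promoter_window, side="right")
        bound[g.gene_id] = hi > lo
    fractions = {}
    for cls in ("up", "down", "static"):
        members = [gid for gid in ids if de_classes[gid] == cls]
        fractions[cls] = (
            sum(bound[gid] for gid in members) / len(members) if members else float("nan")
        )
    regulome = pd.DataFrame(
        [
            {"gene": gid, "direction": de_classes[gid]}
            for gid in ids
            if bound[gid] and de_classes[gid] in ("up", "down")
        ],
        columns=["gene", "direction"],
    )
    return fractions, regulome
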