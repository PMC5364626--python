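"""Synthetic genomes, peak sets, signal tracks and DE tables with recorded truth.

Every generator is a pure function of its parameters and a seed, and every
generated dataset can carry a :class:`SyntheticTruth` sidecar recording the
planted quantities, so downstream recovery tests never peek at internals.

Seeds are split deterministically: a global seed expands into per-generator
streams through ``numpy.random.SeedSequence`` child keys, so adding one
generator never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    GENE_CLASSES,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    tss_tes,
)

# fixed child keys of the global SeedSequence, one per generator
_STREAM = {
    "genome": 11,
    "peaks": 23,
    "features": 37,
    "signal": 41,
    "de": 53,
    "conservation": 67,
    "expression": 79,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator random stream from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


@dataclass
class SyntheticTruth:
    """Planted parameters recorded alongside every generated dataset."""

    seed: int
    tss_bias: float | None = None
    overlap_fraction: float | None = None
    track_correlation: float | None = None
    venn_counts: dict[str, int] | None = None
    opposite_direction: int | None = None
    bound_de_odds: float | None = None
    conservation_bump: tuple[float, float] | None = None  # (height, width bp)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("conservation_bump") is not None:
            payload["conservation_bump"] = tuple(payload["conservation_bump"])
        return cls(**payload)


# gene length medians (bp) per class, loosely matching genome annotation scale
# but compressed so a 10-Mb toy chromosome holds thousands of genes
_CLASS_LENGTH = {
    "protein_coding": (3000, 0.5),  # (median, lognormal sigma)
    "lincRNA": (1500, 0.5),
    "snRNA": (150, 0.15),
    "snoRNA": (120, 0.15),
    "miRNA": (85, 0.1),
}


def gen_genome(
    chrom_lengths: dict[str, int] | list[int],
    genes_per_class: dict[str, int],
    min_gene_gap: int = 200,
    seed: int = 0,
) -> tuple[GenomeLayout, list[GeneModel], SyntheticTruth]:
    """Generate a genome layout and non-overlapping gene models.

    Genes are distributed over chromosomes proportionally to length, strands
    are Bernoulli(1/2), and class counts are honoured exactly.  Raises if a
    chromosome cannot hold its allotted genes at the requested gap.
    """
    if isinstance(chrom_lengths, list):
        chrom_lengths = {f"chr{i + 1}": L for i, L in enumerate(chrom_lengths)}
    layout = GenomeLayout(chrom_lengths)
    rng = rng_for(seed, "genome")

    for cls in genes_per_class:
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")

    # draw lengths per gene, shuffle class labels, then pack per chromosome
    records: list[tuple[str, int]] = []  # (class, length)
    for cls, count in genes_per_class.items():
        median, sigma = _CLASS_LENGTH[cls]
        lengths = np.maximum(
            50, rng.lognormal(math.log(median), sigma, size=count)
        ).astype(int)
        records.extend((cls, int(L)) for L in lengths)
    rng.shuffle(records)

    chroms = list(layout.names)
    weights = np.asarray([layout[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(chroms), size=len(records), p=weights)

    genes: list[GeneModel] = []
    counter = 0
    for ci, chrom in enumerate(chroms):
        mine = [records[i] for i in np.flatnonzero(assignment == ci)]
        footprint = sum(L for _, L in mine) + min_gene_gap * max(0, len(mine))
        L_chrom = layout[chrom]
        if footprint > L_chrom:
            raise ValueError(
                f"cannot pack {len(mine)} genes ({footprint} bp footprint) "
                f"into {chrom} of length {L_chrom}"
            )
        # stick-breaking: spread the free space as random gaps between genes
        free = L_chrom - footprint
        cuts = np.sort(rng.integers(0, free + 1, size=len(mine)))
        pos = 0
        prev_cut = 0
        for k, (cls, L) in enumerate(mine):
            gap_here = int(cuts[k] - prev_cut)
            prev_cut = int(cuts[k])
            start = pos + gap_here
            end = start + L
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, end, strand)
            exons = _make_exons(iv, cls, rng)
            genes.append(GeneModel(f"gene_{counter:05d}", iv, exons, cls))
            counter += 1
            pos = end + min_gene_gap
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    truth = SyntheticTruth(seed=seed, extras={"genes_per_class": dict(genes_per_class)})
    return layout, genes, truth


def _make_exons(iv: GenomicInterval, cls: str, rng: np.random.Generator):
    """Small-RNA genes are single-exon; others get 1–5 non-overlapping exons."""
    if cls in ("snRNA", "snoRNA", "miRNA") or len(iv) < 400:
        return (iv,)
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        return (iv,)
    # choose 2*(n-1) interior cut points; alternate exon / intron segments
    cuts = np.sort(rng.choice(np.arange(iv.start + 1, iv.end), size=2 * (n_exons - 1), replace=False))
    bounds = [iv.start, *cuts.tolist(), iv.end]
    exons = []
    for k in range(0, len(bounds) - 1, 2):
        exons.append(GenomicInterval(iv.chrom, bounds[k], bounds[k + 1], iv.strand))
    return tuple(exons)


def gen_peaks(
    genes: list[GeneModel],
    layout: GenomeLayout,
    n_peaks: int,
    tss_bias: float = 0.5,
    proximity_window: int = 1000,
    width_mean: float = 300.0,
    width_sd: float = 80.0,
    seed: int = 0,
) -> tuple[PeakSet, SyntheticTruth]:
    """Peaks whose summits are TSS-proximal with probability ``tss_bias``.

    A biased peak's summit lands uniformly within ±proximity_window of a
    uniformly chosen gene's TSS; the rest land uniformly over the genome.
    Widths are truncated-normal positive, the summit at the interval centre
    jittered within the central third.
    """
    if not (0.0 <= tss_bias <= 1.0):
        raise ValueError("tss_bias must lie in [0, 1]")
    rng = rng_for(seed, "peaks")
    chroms = list(layout.names)
    lengths = np.asarray([layout[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    tss_list = [(g.interval.chrom, tss_tes(g)[0]) for g in genes]

    peaks: list[Peak] = []
    seen: set[tuple[str, int, int]] = set()
    attempts = 0
    while len(peaks) < n_peaks:
        attempts += 1
        if attempts > 50 * max(1, n_peaks):
            raise RuntimeError("could not place requested peaks without duplicates")
        width = max(20, int(rng.normal(width_mean, width_sd)))
        if tss_list and rng.random() < tss_bias:
            chrom, tss = tss_list[int(rng.integers(len(tss_list)))]
            summit_pos = int(tss + rng.integers(-proximity_window, proximity_window + 1))
        else:
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            summit_pos = int(rng.integers(0, layout[chrom]))
        summit_pos = min(max(summit_pos, 0), layout[chrom] - 1)
        offset = width // 3 + int(rng.integers(0, max(1, width // 3)))
        start = max(0, summit_pos - offset)
        end = min(layout[chrom], start + width)
        if end - start < 2 or not (start <= summit_pos < end):
            continue
        key = (chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), summit_pos - start, float(rng.uniform(1, 100)))
        )
    truth = SyntheticTruth(seed=seed, tss_bias=tss_bias,
                           extras={"proximity_window": proximity_window})
    return PeakSet(peaks, label=f"synthetic_seed{seed}"), truth


def gen_feature_set(
    peaks: PeakSet,
    layout: GenomeLayout,
    overlap_fraction: float,
    n_features: int,
    feature_width: int = 500,
    seed: int = 0,
) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Feature intervals planted to overlap a chosen fraction of the peaks.

    ``round(overlap_fraction * len(peaks))`` features are centred inside
    distinct randomly chosen peaks; the remainder are placed uniformly while
    avoiding all peaks, so the planted overlap fraction is exact by
    construction against the chosen peaks.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = rng_for(seed, "features")
    n_hit = round(overlap_fraction * len(peaks))
    if n_features < n_hit:
        raise ValueError(
            f"need at least {n_hit} features to overlap {overlap_fraction:.0%} "
            f"of {len(peaks)} peaks, got {n_features}"
        )
    chosen = rng.choice(len(peaks), size=n_hit, replace=False) if n_hit else []
    features: list[GenomicInterval] = []
    for i in chosen:
        p = peaks.peaks[int(i)]
        centre = p.summit_pos
        start = max(0, centre - feature_width // 2)
        end = min(layout[p.interval.chrom], start + feature_width)
        features.append(GenomicInterval(p.interval.chrom, start, end))

    peak_idx = {c: arr for c, arr in peaks.by_chromosome().items()}
    chroms = list(layout.names)
    lengths = np.asarray([layout[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    guard = 0
    while len(features) < n_features:
        guard += 1
        if guard > 200 * n_features:
            raise RuntimeError("could not place non-overlapping features")
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        start = int(rng.integers(0, max(1, layout[chrom] - feature_width)))
        end = start + feature_width
        arr = peak_idx.get(chrom)
        if arr is not None and np.any((arr[:, 0] < end) & (arr[:, 1] > start)):
            continue
        features.append(GenomicInterval(chrom, start, end))
    truth = SyntheticTruth(seed=seed, overlap_fraction=overlap_fraction)
    return features, truth


def gen_signal_pair(
    layout: GenomeLayout,
    bin_width: int,
    correlation: float,
    mean: float = 10.0,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack, SyntheticTruth]:
    """Two binned tracks with planted population correlation.

    Bivariate-normal construction: y = ρ·x + √(1−ρ²)·z, then both shifted to
    ``mean`` and clipped at zero (negligible mass at mean/sd = 10).
    """
    if not (-1.0 <= correlation <= 1.0):
        raise ValueError("|correlation| must be ≤ 1")
    rng = rng_for(seed, "signal")
    a = SignalTrack.from_layout(layout, bin_width)
    b = SignalTrack.from_layout(layout, bin_width)
    for chrom in layout.names:
        n = len(a.values[chrom])
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = correlation * x + math.sqrt(max(0.0, 1 - correlation**2)) * z
        a.values[chrom] = np.clip(mean + sd * x, 0, None)
        b.values[chrom] = np.clip(mean + sd * y, 0, None)
    truth = SyntheticTruth(seed=seed, track_correlation=correlation)
    return a, b, truth


def gen_conservation_track(
    layout: GenomeLayout,
    bin_width: int,
    summits: dict[str, np.ndarray],
    baseline: float = 0.1,
    noise_sd: float = 0.02,
    bump_height: float = 0.5,
    bump_width: int = 200,
    seed: int = 0,
) -> tuple[SignalTrack, SyntheticTruth]:
    """Baseline noise plus a Gaussian bump of given height/width per summit.

    ``bump_width`` is the full width at half maximum in bp; the Gaussian
    sigma follows as FWHM / (2√(2 ln 2)).
    """
    if bump_width <= 0:
        raise ValueError("bump width must be positive")
    rng = rng_for(seed, "conservation")
    sigma = bump_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    track = SignalTrack.from_layout(layout, bin_width)
    for chrom in layout.names:
        n = len(track.values[chrom])
        vec = baseline + rng.normal(0, noise_sd, size=n)
        centres = np.arange(n) * bin_width + bin_width / 2.0
        for pos in summits.get(chrom, ()):
            lo = max(0, int((pos - 5 * sigma) // bin_width))
            hi = min(n, int((pos + 5 * sigma) // bin_width) + 1)
            vec[lo:hi] += bump_height * np.exp(
                -0.5 * ((centres[lo:hi] - pos) / sigma) ** 2
            )
        track.values[chrom] = np.clip(vec, 0, None)
    truth = SyntheticTruth(
        seed=seed, conservation_bump=(bump_height, float(bump_width))
    )
    return track, truth


# ---------------------------------------------------------------------------
# Differential-expression tables with planted Venn structure

VENN_REGIONS = ("A", "C", "U", "AC", "AU", "CU", "ACU")
COMPARISONS = ("NC_vs_A", "NC_vs_C", "UT_vs_NC")


def gen_de_tables(
    gene_ids: list[str],
    venn_counts: dict[str, int],
    opposite_direction: int = 0,
    log2fc_mean: float = 1.5,
    log2fc_sd: float = 0.75,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Three DE tables whose per-table significance Venn matches ``venn_counts``.

    ``venn_counts`` maps exclusive regions of the three-set Venn (keys among
    ``A, C, U, AC, AU, CU, ACU`` — A and C the two knockdown comparisons, U
    the transfection-control comparison) to gene counts.  Within the triple
    intersection exactly ``opposite_direction`` genes get a knockdown sign
    opposite to their control-comparison sign; all other shared genes agree.

    Significant genes receive p-values far below the Benjamini–Hochberg
    threshold for their table; the rest draw p ~ Uniform(0,1), re-drawing the
    rare collisions that would otherwise pass BH, so re-deriving the Venn
    from the emitted q-values reproduces the requested counts exactly.
    """
    from .filtering import bh_fdr  # local import to avoid a cycle

    for region in venn_counts:
        if region not in VENN_REGIONS:
            raise ValueError(f"unknown Venn region {region!r}")
    counts = {r: int(venn_counts.get(r, 0)) for r in VENN_REGIONS}
    if any(v < 0 for v in counts.values()):
        raise ValueError("Venn counts must be nonnegative")
    total_sig = sum(counts.values())
    n = len(gene_ids)
    if total_sig > n:
        raise ValueError(f"Venn counts sum to {total_sig} > {n} genes")
    if opposite_direction > counts["ACU"]:
        raise ValueError("opposite-direction count exceeds triple intersection")

    rng = rng_for(seed, "de")
    ids = np.asarray(gene_ids)
    perm = rng.permutation(n)
    membership: dict[str, set[int]] = {"A": set(), "C": set(), "U": set()}
    region_of: dict[int, str] = {}
    cursor = 0
    for region in VENN_REGIONS:
        take = perm[cursor:cursor + counts[region]]
        cursor += counts[region]
        for g in take:
            region_of[int(g)] = region
            for letter in region:
                membership[letter].add(int(g))

    # directions: one latent knockdown sign per gene, shared by A and C
    kd_sign = rng.choice([-1.0, 1.0], size=n)
    ut_sign = kd_sign.copy()
    triple = sorted(g for g, r in region_of.items() if r == "ACU")
    flip = rng.choice(len(triple), size=opposite_direction, replace=False) if triple else []
    flip_set = {triple[int(i)] for i in flip}
    for g in triple:
        ut_sign[g] = -kd_sign[g] if g in flip_set else kd_sign[g]

    tables: dict[str, pd.DataFrame] = {}
    for label, letter, signs in (
        ("NC_vs_A", "A", kd_sign),
        ("NC_vs_C", "C", kd_sign),
        ("UT_vs_NC", "U", ut_sign),
    ):
        sig = np.zeros(n, dtype=bool)
        sig[sorted(membership[letter])] = True
        m = int(sig.sum())
        p = rng.uniform(0.0, 1.0, size=n)
        if m:
            # below alpha*m/(2n): guarantees q = p·n/rank ≤ alpha/2 < alpha
            p[sig] = rng.uniform(0.0, alpha * m / (2.0 * n), size=m)
        # redraw non-significant genes that would sneak past BH
        for _ in range(1000):
            q = bh_fdr(p)
            rogue = (~sig) & (q < alpha)
            if not rogue.any():
                break
            p[rogue] = rng.uniform(alpha, 1.0, size=int(rogue.sum()))
        else:
            raise RuntimeError("could not stabilise planted significance")
        q = bh_fdr(p)
        if not np.array_equal(q < alpha, sig):
            raise RuntimeError("planted significance does not reproduce")
        lfc = signs * np.abs(rng.normal(log2fc_mean, log2fc_sd, size=n))
        lfc[np.abs(lfc) < 1e-6] = 1e-6 * signs[np.abs(lfc) < 1e-6]
        # shrink effects for non-significant genes toward zero
        lfc[~sig] *= 0.15
        tables[label] = pd.DataFrame(
            {"gene": ids, "log2fc": lfc, "pvalue": p, "qvalue": q}
        )
    truth = SyntheticTruth(
        seed=seed,
        venn_counts=counts,
        opposite_direction=opposite_direction,
        extras={"alpha": alpha},
    )
    return tables, truth


def gen_expression(
    gene_ids: list[str],
    silenced_fraction: float = 0.3,
    fpkm_mean_log: float = 2.0,
    fpkm_sd_log: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """FPKM triplets with a planted silenced fraction (all-zero replicates)."""
    if not (0.0 <= silenced_fraction <= 1.0):
        raise ValueError("silenced_fraction must lie in [0, 1]")
    rng = rng_for(seed, "expression")
    n = len(gene_ids)
    n_silenced = round(silenced_fraction * n)
    silenced = np.zeros(n, dtype=bool)
    silenced[rng.choice(n, size=n_silenced, replace=False)] = True
    fpkm = rng.lognormal(fpkm_mean_log, fpkm_sd_log, size=(n, 3))
    fpkm[silenced] = 0.0
    df = pd.DataFrame(
        {"gene": gene_ids, "fpkm_1": fpkm[:, 0], "fpkm_2": fpkm[:, 1], "fpkm_3": fpkm[:, 2]}
    )
    truth = SyntheticTruth(seed=seed, extras={"silenced_fraction": silenced_fraction})
    return df, truth


def plant_binding_dependent_de(
    genes: list[GeneModel],
    peaks: PeakSet,
    window: int = 1000,
    base_rate: float = 0.08,
    bound_odds: float = 5.0,
    down_bias: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """DE tables where promoter binding raises the odds of (down)regulation.

    Genes with ≥1 peak summit within ±window of their TSS become significant
    with probability ``base_rate`` scaled (on the odds scale) by
    ``bound_odds``; significant bound genes are downregulated with
    probability ``down_bias``, unbound ones 50/50.  Supports testing of the
    regulatory-potential direction analysis against a planted truth.
    """
    rng = rng_for(seed, "de")
    summit_idx = peaks.summit_positions()
    bound = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        tss = tss_tes(g)[0]
        arr = summit_idx.get(g.interval.chrom)
        if arr is not None and np.any((arr >= tss - window) & (arr <= tss + window)):
            bound[i] = True
    base_odds = base_rate / (1 - base_rate)
    odds = np.where(bound, base_odds * bound_odds, base_odds)
    p_sig = odds / (1 + odds)
    sig = rng.random(len(genes)) < p_sig
    down_p = np.where(bound, down_bias, 0.5)
    kd_sign = np.where(rng.random(len(genes)) < down_p, -1.0, 1.0)

    ids = [g.gene_id for g in genes]
    n = len(ids)
    counts = {r: 0 for r in VENN_REGIONS}
    counts["AC"] = int(sig.sum())
    # reuse the Venn planter but force membership to the chosen genes
    tables, _ = gen_de_tables(ids, counts, 0, alpha=alpha, seed=seed)
    # overwrite membership: move significance onto the bound-driven selection
    from .filtering import bh_fdr

    for label in ("NC_vs_A", "NC_vs_C"):
        p = rng.uniform(0.0, 1.0, size=n)
        m = int(sig.sum())
        if m:
            p[sig] = rng.uniform(0.0, alpha * m / (2.0 * n), size=m)
        for _ in range(1000):
            q = bh_fdr(p)
            rogue = (~sig) & (q < alpha)
            if not rogue.any():
                break
            p[rogue] = rng.uniform(alpha, 1.0, size=int(rogue.sum()))
        q = bh_fdr(p)
        lfc = kd_sign * np.abs(rng.normal(1.5, 0.75, size=n))
        lfc[~sig] *= 0.15
        tables[label] = pd.DataFrame({"gene": ids, "log2fc": lfc, "pvalue": p, "qvalue": q})
    truth = SyntheticTruth(
        seed=seed,
        bound_de_odds=bound_odds,
        extras={
            "n_bound": int(bound.sum()),
            "n_significant": int(sig.sum()),
            "down_bias": down_bias,
            "window": window,
        },
    )
    return tables, truth
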