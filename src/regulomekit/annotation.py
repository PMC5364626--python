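"""Peak-to-feature assignment, chromosome correlations and metagene profiles.

Peaks are assigned to a single fixed genomic feature by their summit
position, so the categories form a partition and the reported percentages
sum to 100.  Precedence (configurable): promoter > exon > intron >
downstream > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GeneModel,
    GenomeLayout,
    PeakSet,
    SignalTrack,
    build_index,
    tss_tes,
)

CATEGORIES = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True)
class AnnotationConfig:
    """Windows (bp) and category precedence for feature assignment."""

    promoter_window: int = 3000  # each side of the TSS
    proximal_window: int = 1000  # "close to the TSS" sub-window
    downstream_window: int = 3000  # past the TES
    precedence: tuple[str, ...] = CATEGORIES

    def __post_init__(self):
        if self.proximal_window > self.promoter_window:
            raise ValueError("proximal window cannot exceed promoter window")
        if sorted(self.precedence) != sorted(CATEGORIES):
            raise ValueError(f"precedence must cover {CATEGORIES} exactly once")


@dataclass
class AnnotationSummary:
    """Per-peak categories and their percentage breakdown."""

    categories: list[str]  # aligned with the PeakSet order
    percentages: dict[str, float]
    promoter_proximal_fraction: float
    config: AnnotationConfig

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for c in self.categories:
            out[c] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        counts = self.counts()
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [counts[c] for c in CATEGORIES],
                "percent": [self.percentages[c] for c in CATEGORIES],
            }
        )


def _per_chrom_positions(values: list[tuple[str, int]]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for chrom, pos in values:
        out.setdefault(chrom, []).append(pos)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def assign_features(
    peaks: PeakSet,
    genes: list[GeneModel],
    config: AnnotationConfig = AnnotationConfig(),
) -> AnnotationSummary:
    """Assign each peak summit to its highest-precedence feature category.

    The promoter is TSS ± promoter_window; downstream extends
    downstream_window bp past the TES in the direction of transcription;
    intron is any position in a gene body outside its exons.  The
    promoter-proximal fraction is the share of promoter peaks whose summit
    lies within ± proximal_window of the nearest TSS.
    """
    tss_positions = _per_chrom_positions(
        [(g.interval.chrom, tss_tes(g)[0]) for g in genes]
    )
    # half-open member intervals per category (promoter handled via TSS array)
    exon_ivs = [ex for g in genes for ex in g.exons]
    body_ivs = [g.interval for g in genes]
    down_ivs = []
    from .genome import GenomicInterval

    for g in genes:
        tes = tss_tes(g)[1]
        if g.interval.strand == "+":
            down_ivs.append(
                GenomicInterval(g.interval.chrom, tes + 1, tes + 1 + config.downstream_window)
            )
        else:
            start = max(0, tes - config.downstream_window)
            if start < tes:
                down_ivs.append(GenomicInterval(g.interval.chrom, start, tes))
    exon_idx = build_index(exon_ivs)
    body_idx = build_index(body_ivs)
    down_idx = build_index(down_ivs)

    def in_category(cat: str, chrom: str, pos: int) -> bool:
        if cat == "promoter":
            tss = tss_positions.get(chrom)
            if tss is None or len(tss) == 0:
                return False
            j = np.searchsorted(tss, pos)
            best = min(
                (abs(pos - int(tss[k])) for k in (j - 1, j) if 0 <= k < len(tss)),
                default=None,
            )
            return best is not None and best <= config.promoter_window
        q = (np.asarray([pos]), np.asarray([pos + 1]))
        if cat == "exon":
            idx = exon_idx.get(chrom)
        elif cat == "intron":
            idx = body_idx.get(chrom)
        elif cat == "downstream":
            idx = down_idx.get(chrom)
        else:
            return True  # intergenic is the fallback
        return idx is not None and bool(idx.any_overlap(*q)[0])

    categories: list[str] = []
    proximal = 0
    n_promoter = 0
    for p in peaks:
        chrom, pos = p.interval.chrom, p.summit_pos
        for cat in config.precedence:
            if in_category(cat, chrom, pos):
                categories.append(cat)
                break
        if categories[-1] == "promoter":
            n_promoter += 1
            tss = tss_positions[chrom]
            j = np.searchsorted(tss, pos)
            best = min(
                abs(pos - int(tss[k])) for k in (j - 1, j) if 0 <= k < len(tss)
            )
            if best <= config.proximal_window:
                proximal += 1
    n = len(peaks)
    percentages = {
        c: (100.0 * categories.count(c) / n if n else 0.0) for c in CATEGORIES
    }
    return AnnotationSummary(
        categories=categories,
        percentages=percentages,
        promoter_proximal_fraction=(proximal / n_promoter if n_promoter else float("nan")),
        config=config,
    )


@dataclass
class MetageneProfile:
    """Mean enrichment over scaled gene bodies with fixed-bp flanks.

    Bin 0 is always the far 5′ flank regardless of strand; the body occupies
    bins [flank_bins, flank_bins + body_bins).
    """

    body_bins: int
    flank_bins: int
    flank_bp: int
    values: np.ndarray
    n_genes: int
    n_skipped: int = 0

    def __post_init__(self):
        assert len(self.values) == self.body_bins + 2 * self.flank_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": np.arange(len(self.values)), "value": self.values})

    @property
    def tss_bin(self) -> int:
        return self.flank_bins

    @property
    def tes_bin(self) -> int:
        return self.flank_bins + self.body_bins - 1


def metagene_profile(
    data: PeakSet | SignalTrack,
    genes: list[GeneModel],
    body_bins: int = 60,
    flank_bp: int = 2000,
    flank_bins: int = 20,
) -> MetageneProfile:
    """TSS→TES-oriented average profile over a gene set.

    Each gene body is scaled to ``body_bins``; flanks are fixed ``flank_bp``
    windows split into ``flank_bins``.  Minus-strand genes are reversed so
    the profile always reads 5′→3′.  For a PeakSet the per-bin value is the
    mean summit density (summits per kb); for a SignalTrack it is the mean
    signal sampled at bin centres.  Genes shorter than ``body_bins`` bp are
    skipped and counted.
    """
    if not genes:
        raise ValueError("empty gene set")
    total_bins = body_bins + 2 * flank_bins
    acc = np.zeros(total_bins)
    used = 0
    skipped = 0
    flank_bin_bp = flank_bp / flank_bins

    is_peaks = isinstance(data, PeakSet)
    summits = data.summit_positions() if is_peaks else None

    for g in genes:
        iv = g.interval
        L = len(iv)
        if L < body_bins:
            skipped += 1
            continue
        body_bin_bp = L / body_bins
        # genomic bin edges 5'->3' in transcription orientation
        if iv.strand == "+":
            edges = np.concatenate(
                [
                    iv.start - flank_bp + np.arange(flank_bins) * flank_bin_bp,
                    iv.start + np.arange(body_bins) * body_bin_bp,
                    iv.end + np.arange(flank_bins + 1) * flank_bin_bp,
                ]
            )
        else:
            edges = np.concatenate(
                [
                    iv.end + flank_bp - np.arange(flank_bins) * flank_bin_bp,
                    iv.end - np.arange(body_bins) * body_bin_bp,
                    iv.start - np.arange(flank_bins + 1) * flank_bin_bp,
                ]
            )
        if is_peaks:
            pos = summits.get(iv.chrom)
            if pos is None:
                used += 1
                continue
            if iv.strand == "+":
                counts, _ = np.histogram(pos, bins=edges)
            else:
                counts, _ = np.histogram(pos, bins=edges[::-1])
                counts = counts[::-1]
            widths = np.abs(np.diff(edges))
            acc += counts / widths * 1000.0  # summits per kb
        else:
            centres = (edges[:-1] + edges[1:]) / 2.0
            vec = data.values.get(iv.chrom)
            if vec is None:
                used += 1
                continue
            idx = np.clip((centres // data.bin_width).astype(int), 0, len(vec) - 1)
            acc += vec[idx]
        used += 1
    if used == 0:
        raise ValueError("no usable genes (all shorter than the bin count)")
    return MetageneProfile(
        body_bins=body_bins,
        flank_bins=flank_bins,
        flank_bp=flank_bp,
        values=acc / used,
        n_genes=used,
        n_skipped=skipped,
    )


def chrom_correlation(
    peaks: PeakSet, genes: list[GeneModel], layout: GenomeLayout
) -> dict[str, float]:
    """Per-chromosome peak counts vs gene counts and vs chromosome length.

    Returns Pearson r for both pairings (``r_genes``, ``r_length``); NaN
    when a vector has zero variance.
    """
    chroms = list(layout.names)
    if len(chroms) < 3:
        raise ValueError("need ≥3 chromosomes for a correlation")
    peak_counts = np.zeros(len(chroms))
    gene_counts = np.zeros(len(chroms))
    index = {c: i for i, c in enumerate(chroms)}
    for p in peaks:
        peak_counts[index[p.interval.chrom]] += 1
    for g in genes:
        gene_counts[index[g.interval.chrom]] += 1
    lengths = np.asarray([layout[c] for c in chroms], dtype=float)

    def safe_r(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    return {
        "r_genes": safe_r(peak_counts, gene_counts),
        "r_length": safe_r(peak_counts, lengths),
    }
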