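"""Randomization overlap tests, signal correlations and summit-centred profiles.

The permutation null re-places every query interval uniformly at random
within its own chromosome, preserving its length and the per-chromosome
interval count — shuffling position while holding the genomic composition
of the query set fixed.  The test statistic is the fraction of query
intervals that hit at least one feature (optionally after expanding
features by a gap, the "vicinity" parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeLayout, GenomicInterval, PeakSet, SignalTrack, build_index


@dataclass
class OverlapTestResult:
    """Observed overlap against a per-chromosome randomization null."""

    observed: float  # fraction of query intervals hitting ≥1 feature
    perm_mean: float
    perm_sd: float
    zscore: float  # NaN when the permutation sd is zero
    pvalue: float  # empirical, add-one corrected, never exactly 0
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "zscore": self.zscore,
            "pvalue": self.pvalue,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _overlap_fraction_perms(
    lengths_by_chrom: dict[str, np.ndarray],
    starts_by_chrom: dict[str, np.ndarray] | None,
    feature_index,
    layout: GenomeLayout,
    n_perm: int,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Hit counts per permutation (or the single observed arrangement)."""
    total_hits = np.zeros(n_perm, dtype=np.int64)
    for chrom, lens in lengths_by_chrom.items():
        idx = feature_index.get(chrom)
        if rng is None:
            starts = starts_by_chrom[chrom][None, :]
        else:
            L = layout[chrom]
            max_start = np.maximum(1, L - lens + 1)  # start in [0, L - len]
            starts = (rng.random((n_perm, len(lens))) * max_start).astype(np.int64)
        ends = starts + lens[None, :]
        if idx is None or len(idx.starts) == 0:
            continue
        left = np.searchsorted(idx.ends, starts.ravel(), side="right")
        right = np.searchsorted(idx.starts, ends.ravel(), side="left")
        hits = (left < right).reshape(starts.shape)
        total_hits += hits.sum(axis=1)
    return total_hits


def randomized_overlap_test(
    query: PeakSet,
    features: list[GenomicInterval],
    layout: GenomeLayout,
    n_permutations: int = 1000,
    gap: int = 0,
    seed: int = 0,
) -> OverlapTestResult:
    """Per-chromosome randomization test of query/feature overlap.

    Z = (observed − null mean) / null sd over the permutation distribution
    of the overlap fraction; the empirical p-value is
    (1 + #{perm ≥ obs}) / (1 + n).  When the null distribution is
    degenerate (sd = 0) Z is NaN and only the empirical p is meaningful.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    n_q = len(query)
    if n_q == 0:
        raise ValueError("empty query set")
    by_chrom = query.by_chromosome()
    lengths = {c: (arr[:, 1] - arr[:, 0]) for c, arr in by_chrom.items()}
    starts = {c: arr[:, 0] for c, arr in by_chrom.items()}
    index = build_index(features, gap=gap)

    observed = (
        _overlap_fraction_perms(lengths, starts, index, layout, 1, None)[0] / n_q
    )
    rng = np.random.default_rng(seed)
    perm = (
        _overlap_fraction_perms(lengths, None, index, layout, n_permutations, rng)
        / n_q
    )
    mean, sd = float(perm.mean()), float(perm.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (1 + int(np.sum(perm >= observed))) / (1 + n_permutations)
    return OverlapTestResult(
        observed=float(observed),
        perm_mean=mean,
        perm_sd=sd,
        zscore=float(z),
        pvalue=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def signal_correlation(
    track_a: SignalTrack,
    track_b: SignalTrack,
    regions: list[GenomicInterval] | None = None,
) -> float:
    """Pearson correlation of two binned tracks, optionally region-restricted.

    With ``regions``, only bins intersecting at least one region enter the
    correlation (promoter windows, peak unions, …).  Returns NaN on zero
    variance; raises when fewer than 3 usable bins remain.
    """
    if track_a.bin_width != track_b.bin_width:
        raise ValueError("bin widths differ")
    if set(track_a.values) != set(track_b.values):
        raise ValueError("chromosome sets differ")
    xs, ys = [], []
    region_index = build_index(regions) if regions is not None else None
    for chrom in track_a.values:
        va, vb = track_a.values[chrom], track_b.values[chrom]
        if len(va) != len(vb):
            raise ValueError(f"bin counts differ on {chrom}")
        if region_index is None:
            mask = np.ones(len(va), dtype=bool)
        else:
            idx = region_index.get(chrom)
            if idx is None:
                continue
            starts = np.arange(len(va), dtype=np.int64) * track_a.bin_width
            mask = idx.any_overlap(starts, starts + track_a.bin_width)
        xs.append(va[mask])
        ys.append(vb[mask])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if len(x) < 3:
        raise ValueError(f"need ≥3 usable bins, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class SummitProfile:
    """Mean track value by offset from peak summits."""

    window: int  # bp each side
    bin_width: int
    values: np.ndarray  # length 2*(window // bin_width) + 1
    n_summits: int
    n_skipped: int

    def offsets(self) -> np.ndarray:
        k = self.window // self.bin_width
        return np.arange(-k, k + 1) * self.bin_width

    def fwhm_bins(self) -> float:
        """Full width at half maximum of the profile above its baseline."""
        v = self.values - np.median(self.values)
        peak = v.max()
        if peak <= 0:
            return float("nan")
        return float(np.sum(v >= peak / 2.0))


def profile_around_summits(
    track: SignalTrack, peaks: PeakSet, window: int
) -> SummitProfile:
    """Average a binned track over ±window around every usable peak summit.

    Summits whose window extends past a chromosome end are skipped and
    counted; raises if none remain.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    k = window // track.bin_width
    acc = np.zeros(2 * k + 1)
    used = skipped = 0
    for chrom, pos_arr in peaks.summit_positions().items():
        vec = track.values.get(chrom)
        if vec is None:
            skipped += len(pos_arr)
            continue
        bins = pos_arr // track.bin_width
        ok = (bins - k >= 0) & (bins + k < len(vec))
        skipped += int((~ok).sum())
        for b in bins[ok]:
            acc += vec[b - k : b + k + 1]
            used += 1
    if used == 0:
        raise ValueError("no summit window fits inside chromosome bounds")
    return SummitProfile(
        window=window,
        bin_width=track.bin_width,
        values=acc / used,
        n_summits=used,
        n_skipped=skipped,
    )


@dataclass
class MotifPositionalProfile:
    """Positional distribution of motif occurrences around peak summits."""

    window: int
    probabilities: np.ndarray  # smoothed, sums to 1 over [-window, window]
    central_half_width: int  # smallest symmetric half-width holding 50% of mass
    pvalue: float  # one-sided binomial central-enrichment test
    n_occurrences: int

    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)


def motif_central_enrichment(
    offsets,
    window: int,
    central_half_width: int | None = None,
    smoothing_sd: float = 10.0,
) -> MotifPositionalProfile:
    """Central-enrichment analysis of motif offsets relative to peak summits.

    The positional probability curve is a Gaussian-kernel-smoothed histogram
    of the offsets.  The central half-width is the smallest symmetric ±h
    containing at least half the (raw) occurrence mass, unless given.  The
    enrichment p-value is a one-sided binomial test of the count inside ±h
    against the uniform expectation (2h+1)/(2·window+1).
    """
    offs = np.asarray(offsets, dtype=np.int64)
    if offs.size == 0:
        raise ValueError("no motif occurrences")
    if np.any(np.abs(offs) > window):
        raise ValueError("offsets outside ±window")
    support = np.arange(-window, window + 1)
    hist = np.bincount(offs + window, minlength=2 * window + 1).astype(float)
    if smoothing_sd > 0:
        k = np.arange(-int(4 * smoothing_sd), int(4 * smoothing_sd) + 1)
        kernel = np.exp(-0.5 * (k / smoothing_sd) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(hist, kernel, mode="same")
    else:
        smooth = hist
    prob = smooth / smooth.sum()

    n = offs.size
    if central_half_width is None:
        abs_sorted = np.sort(np.abs(offs))
        h = int(abs_sorted[int(np.ceil(n / 2.0)) - 1])  # smallest h with ≥50% mass
    else:
        h = int(central_half_width)
    inside = int(np.sum(np.abs(offs) <= h))
    p0 = (2 * h + 1) / (2 * window + 1)
    pval = float(stats.binomtest(inside, n, p0, alternative="greater").pvalue)
    return MotifPositionalProfile(
        window=window,
        probabilities=prob,
        central_half_width=h,
        pvalue=pval,
        n_occurrences=n,
    )
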