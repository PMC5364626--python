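"""Consensus shortlisting of a knockdown regulome across comparisons.

Three labelled differential-expression comparisons are expected: the two
independent knockdowns against a scrambled control (``NC_vs_A``,
``NC_vs_C``) and an un-transfected versus scrambled comparison
(``UT_vs_NC``) that captures transfection artifacts.  A gene enters the
core regulome if it is significant in both knockdowns with a consistent
direction and either is not significant in the control comparison
(*reproducible*) or is significant there but with the opposite sign
(*rescued*).  "Significant" means q < alpha strictly throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COMPARISONS = ("NC_vs_A", "NC_vs_C", "UT_vs_NC")

DE_COLUMNS = ("gene", "log2fc", "pvalue", "qvalue")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j)·n/j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_de_table(df: pd.DataFrame, label: str = "") -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {label!r} missing columns {missing}")
    if df["gene"].duplicated().any():
        raise ValueError(f"DE table {label!r} has duplicate gene rows")
    return df


@dataclass
class CoreRegulomeResult:
    """Outcome of the three-way consensus shortlist."""

    reproducible: list[str]
    rescued: list[str]
    directions: dict[str, str]  # gene -> up/down, shared knockdown direction
    sign_disagreements: int  # knockdown-significant genes dropped for sign conflict
    alpha: float

    @property
    def total(self) -> int:
        overlap = set(self.reproducible) & set(self.rescued)
        if overlap:
            raise AssertionError(f"reproducible/rescued overlap: {sorted(overlap)[:5]}")
        return len(self.reproducible) + len(self.rescued)

    def genes(self) -> list[str]:
        return sorted(self.reproducible) + sorted(self.rescued)

    def summary(self) -> dict:
        return {
            "n_reproducible": len(self.reproducible),
            "n_rescued": len(self.rescued),
            "total": self.total,
            "n_sign_disagreements": self.sign_disagreements,
            "alpha": self.alpha,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "category": "reproducible", "direction": self.directions[g]}
            for g in sorted(self.reproducible)
        ] + [
            {"gene": g, "category": "rescued", "direction": self.directions[g]}
            for g in sorted(self.rescued)
        ]
        return pd.DataFrame(rows, columns=["gene", "category", "direction"])


def _sig_and_sign(df: pd.DataFrame, alpha: float) -> tuple[pd.Series, pd.Series]:
    sig = df["qvalue"] < alpha
    sign = np.sign(df["log2fc"])
    if bool((sig & (sign == 0)).any()):
        bad = df.loc[sig & (sign == 0), "gene"].tolist()[:5]
        raise ValueError(f"significant rows with log2fc == 0 (undecidable direction): {bad}")
    return sig, sign


def consensus_shortlist(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> CoreRegulomeResult:
    """Apply the three-way consensus rule to labelled DE tables.

    Reproducible: significant in both knockdown comparisons with the same
    sign, not significant in the control comparison.  Rescued: significant
    in all three, the shared knockdown sign opposite to the control sign.
    Knockdown-significant genes whose two knockdown signs disagree are
    excluded and counted.
    """
    for label in COMPARISONS:
        if label not in tables:
            raise ValueError(f"missing comparison {label!r}")
        validate_de_table(tables[label], label)
    a, c, u = (tables[k].set_index("gene") for k in COMPARISONS)
    universe = set(a.index)
    if set(c.index) != universe or set(u.index) != universe:
        raise ValueError("gene universes differ between comparisons")
    c, u = c.loc[a.index], u.loc[a.index]

    sig_a, sign_a = _sig_and_sign(a.reset_index(), alpha)
    sig_c, sign_c = _sig_and_sign(c.reset_index(), alpha)
    sig_u, sign_u = _sig_and_sign(u.reset_index(), alpha)
    genes = a.index.to_numpy()

    both_kd = sig_a.to_numpy() & sig_c.to_numpy()
    agree = sign_a.to_numpy() == sign_c.to_numpy()
    disagreements = int((both_kd & ~agree).sum())
    consistent = both_kd & agree

    in_u = sig_u.to_numpy()
    reproducible_mask = consistent & ~in_u
    rescued_mask = consistent & in_u & (sign_a.to_numpy() == -sign_u.to_numpy())

    directions = {
        str(g): ("up" if s > 0 else "down")
        for g, s, keep in zip(genes, sign_a.to_numpy(), reproducible_mask | rescued_mask)
        if keep
    }
    return CoreRegulomeResult(
        reproducible=[str(g) for g in genes[reproducible_mask]],
        rescued=[str(g) for g in genes[rescued_mask]],
        directions=directions,
        sign_disagreements=disagreements,
        alpha=alpha,
    )


def consensus_pathways(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Pathway-mode consensus over GSEA-style result tables.

    Expects columns (pathway, nes, fdr).  Shortlists pathways with FDR <
    alpha in both knockdown comparisons with agreeing NES sign and FDR >=
    alpha in the control comparison; output ordered by mean |NES| descending.
    """
    for label in COMPARISONS:
        if label not in tables:
            raise ValueError(f"missing comparison {label!r}")
        for col in ("pathway", "nes", "fdr"):
            if col not in tables[label].columns:
                raise ValueError(f"pathway table {label!r} missing column {col!r}")
    a, c, u = (tables[k].set_index("pathway") for k in COMPARISONS)
    universe = set(a.index)
    if set(c.index) != universe or set(u.index) != universe:
        raise ValueError("pathway universes differ between comparisons")
    c, u = c.loc[a.index], u.loc[a.index]
    keep = (
        (a["fdr"] < alpha)
        & (c["fdr"] < alpha)
        & (np.sign(a["nes"]) == np.sign(c["nes"]))
        & (u["fdr"] >= alpha)
    )
    out = pd.DataFrame(
        {
            "pathway": a.index[keep],
            "nes_a": a.loc[keep, "nes"].to_numpy(),
            "nes_c": c.loc[keep, "nes"].to_numpy(),
        }
    )
    out["mean_abs_nes"] = (out["nes_a"].abs() + out["nes_c"].abs()) / 2.0
    return out.sort_values("mean_abs_nes", ascending=False, ignore_index=True)


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    condition_col: str = "condition",
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Relative quantification by the ΔΔCt convention.

    ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts the mean
    ΔCt over control-condition samples; fold change = 2^(−ΔΔCt), so the
    control samples' fold changes have geometric mean 1 by construction.
    """
    for col in (condition_col, sample_col, gene_col, ct_col):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    wide = ct.pivot_table(index=sample_col, columns=gene_col, values=ct_col)
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        raise ValueError(f"reference gene {reference_gene!r} not measured in every sample")
    condition = ct.drop_duplicates(sample_col).set_index(sample_col)[condition_col]
    control_samples = condition.index[condition == control_condition]
    if len(control_samples) == 0:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    dct = wide.sub(wide[reference_gene], axis=0)
    ddct = dct - dct.loc[control_samples].mean(axis=0)
    fc = np.power(2.0, -ddct)
    out = fc.reset_index().melt(
        id_vars=sample_col, var_name=gene_col, value_name="fold_change"
    )
    return out.merge(condition.reset_index(), on=sample_col)


def timepoint_compare(
    fc_early: pd.Series, fc_late: pd.Series, tol: float = 0.0
) -> pd.DataFrame:
    """Compare |log2FC| of shared genes between two timepoints.

    Inputs are per-gene log2 fold changes indexed by gene id.  Returns a
    frame with both magnitudes and a ``larger`` column in {early, late,
    tie}.  Any shared gene missing a value raises, naming the gene.
    """
    common = fc_early.index.intersection(fc_late.index)
    for name, s in (("early", fc_early), ("late", fc_late)):
        bad = s.loc[common][s.loc[common].isna()]
        if len(bad):
            raise ValueError(f"gene {bad.index[0]!r} missing a {name} fold change")
    e = fc_early.loc[common].abs()
    l = fc_late.loc[common].abs()
    larger = np.where(
        np.isclose(e, l, rtol=0, atol=tol) | (e == l),
        "tie",
        np.where(l > e, "late", "early"),
    )
    return pd.DataFrame(
        {"abs_log2fc_early": e, "abs_log2fc_late": l, "larger": larger}, index=common
    )


def concordance(fc_a: pd.Series, fc_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation of paired per-gene log2 fold changes.

    Pairs on the gene index; requires ≥3 shared genes.  Returns (r, p);
    zero variance in either vector yields (nan, nan), reported rather than
    raised.
    """
    common = fc_a.index.intersection(fc_b.index)
    if len(common) < 3:
        raise ValueError(f"need ≥3 paired genes, got {len(common)}")
    x = fc_a.loc[common].to_numpy(dtype=float)
    y = fc_b.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def eqtl_cross_filter(
    eqtl: pd.DataFrame,
    gwas_snps: set[str],
    fdr_threshold: float = 0.05,
    fdr_a: str = "fdr_a",
    fdr_b: str = "fdr_b",
    effect_a: str = "effect_a",
    snp_col: str = "snp",
) -> tuple[pd.DataFrame, list[str]]:
    """SNPs that are significant eQTLs for gene A but not gene B, in a GWAS set.

    Returns the filtered rows (with gene-A effect sizes) and the GWAS SNPs
    absent from the eQTL table (unmatched, not an error).
    """
    for col in (snp_col, fdr_a, fdr_b):
        if col not in eqtl.columns:
            raise ValueError(f"eQTL table missing column {col!r}")
    unmatched = sorted(gwas_snps - set(eqtl[snp_col]))
    mask = (
        eqtl[snp_col].isin(gwas_snps)
        & (eqtl[fdr_a] < fdr_threshold)
        & (eqtl[fdr_b] >= fdr_threshold)
    )
    cols = [snp_col, fdr_a, fdr_b] + ([effect_a] if effect_a in eqtl.columns else [])
    extra = [c for c in eqtl.columns if c not in cols]
    return eqtl.loc[mask, cols + extra].reset_index(drop=True), unmatched
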