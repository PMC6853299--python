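"""Expression quantification, filtering, allelic ratios and DE contrasts.

Expression is quantified as RPKM (reads per kilobase of transcript per
million mapped reads).  The species contrast works on two log2 ratios
per gene: X = log2(A/B) from species-average RPKM, and Y_i = log2(a/b)
from the allele counts of each F1 hybrid.  Allelic imbalance is also
summarised by the d-score, d = a/(a+b) - 1/2, which is 0 for balanced
expression and +-0.5 for monoallelic expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alleles import AlleleCountTable

SPECIES_GROUPS = ("ZF", "OF")
F1_GROUPS = ("ZO", "OZ")


# ---------------------------------------------------------------------------
# RPKM and filters
# ---------------------------------------------------------------------------

def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """RPKM = count * 1e9 / (gene_length_bp * mapped_reads), per cell."""
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive and complete")
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("library sizes must be positive and complete")
    return counts * 1e9 / np.outer(lengths, libs)


def filter_detectable(expr: pd.DataFrame, groups: pd.Series,
                      species: tuple[str, str] = SPECIES_GROUPS,
                      threshold: float = 1.0) -> pd.Index:
    """Genes detectably expressed in either species: species-average
    RPKM >= threshold (default 1) in at least one of the two."""
    keep = pd.Series(False, index=expr.index)
    for sp in species:
        cols = groups.index[groups == sp]
        cols = [c for c in cols if c in expr.columns]
        if not cols:
            raise ValueError(f"no individuals in group {sp!r}")
        keep |= expr[cols].mean(axis=1) >= threshold
    return expr.index[keep]


def filter_ase_eligible(allele_counts: AlleleCountTable,
                        expr: pd.DataFrame,
                        min_reads: int = 5, strict: bool = False,
                        median_rpkm: float = 10.0
                        ) -> tuple[pd.Index, pd.DataFrame]:
    """Genes eligible for allelic-ratio analysis.

    Three criteria: (i) at least one ss-SNP site with allele counts;
    (ii) at least ``min_reads`` reads at every ss-SNP site in every F1
    individual (``strict=True`` demands strictly more than ``min_reads``,
    the tighter published wording); (iii) median RPKM of at least
    ``median_rpkm`` across all individuals in ``expr``.

    Returns the eligible gene index plus a per-gene report with boolean
    columns ``has_snp``, ``depth_ok``, ``rpkm_ok`` and ``eligible``.
    """
    genes = expr.index
    n_sites = allele_counts.n_sites_per_gene().reindex(genes).fillna(0)
    has_snp = n_sites >= 1

    depths = allele_counts.site_depths()
    if len(depths):
        min_depth = depths.groupby(level="gene").min()
    else:
        min_depth = pd.Series(dtype=float)
    min_depth = min_depth.reindex(genes)
    if strict:
        depth_ok = min_depth > min_reads
    else:
        depth_ok = min_depth >= min_reads
    depth_ok = depth_ok.fillna(False)

    rpkm_ok = expr.median(axis=1) >= median_rpkm

    report = pd.DataFrame({"has_snp": has_snp, "depth_ok": depth_ok,
                           "rpkm_ok": rpkm_ok})
    report["eligible"] = report.all(axis=1)
    return genes[report["eligible"]], report


# ---------------------------------------------------------------------------
# d-score and log ratios
# ---------------------------------------------------------------------------

def d_score(reads_sp1, reads_sp2):
    """Allelic imbalance d = a/(a+b) - 0.5, in [-0.5, 0.5].

    Accepts scalars or arrays; zero total reads raises (undefined)."""
    a = np.asarray(reads_sp1, dtype=float)
    b = np.asarray(reads_sp2, dtype=float)
    total = a + b
    if np.any(total <= 0):
        raise ValueError("d-score undefined when a + b = 0")
    d = a / total - 0.5
    return float(d) if d.ndim == 0 else d


def allelic_log_ratios(allele_counts: AlleleCountTable,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Y_i = log2((a_i + pc) / (b_i + pc)) as a genes x F1 frame.

    A pseudocount (default 0.5) keeps ratios finite when one allele has
    zero reads; with ``pseudocount=0`` a zero denominator raises.
    """
    a = allele_counts.a_matrix()
    b = allele_counts.b_matrix()
    if pseudocount == 0 and ((a == 0) | (b == 0)).any().any():
        raise ValueError("zero allele counts with pseudocount 0: "
                         "log ratio undefined")
    return np.log2((a + pseudocount) / (b + pseudocount))


def parental_log_ratio(expr: pd.DataFrame, groups: pd.Series,
                       species: tuple[str, str] = SPECIES_GROUPS
                       ) -> pd.Series:
    """Scalar X = log2(A/B) from species-average RPKM (arithmetic means)."""
    cols1 = [c for c in groups.index[groups == species[0]]
             if c in expr.columns]
    cols2 = [c for c in groups.index[groups == species[1]]
             if c in expr.columns]
    a = expr[cols1].mean(axis=1)
    b = expr[cols2].mean(axis=1)
    if (b == 0).any():
        raise ValueError("species-2 average RPKM of 0: X undefined")
    return np.log2(a / b).rename("X")


def parental_pairwise_ratios(expr: pd.DataFrame, groups: pd.Series,
                             species: tuple[str, str] = SPECIES_GROUPS,
                             pseudo_rpkm: float = 1e-3) -> pd.DataFrame:
    """All pairwise log2 ratios of species-1 over species-2 individuals.

    With 4 + 4 parental birds this gives the 16-value parental-ratio
    sample used as the comparison sample in the trans contrast.  A small
    RPKM floor keeps log ratios finite at zero expression.
    """
    cols1 = [c for c in groups.index[groups == species[0]]
             if c in expr.columns]
    cols2 = [c for c in groups.index[groups == species[1]]
             if c in expr.columns]
    out = {}
    for c1 in cols1:
        for c2 in cols2:
            out[f"{c1}/{c2}"] = np.log2(
                (expr[c1] + pseudo_rpkm) / (expr[c2] + pseudo_rpkm))
    return pd.DataFrame(out, index=expr.index)


def ratio_pair(expr: pd.DataFrame, allele_counts: AlleleCountTable,
               groups: pd.Series, gene: str,
               pseudocount: float = 0.5) -> tuple[float, pd.Series]:
    """(X, Y_i) for one gene: the parental log2 ratio and the per-F1
    allelic log2 ratios."""
    x = parental_log_ratio(expr, groups).loc[gene]
    y = allelic_log_ratios(allele_counts, pseudocount=pseudocount).loc[gene]
    return float(x), y


# ---------------------------------------------------------------------------
# Differential expression (negative-binomial Wald test)
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors: per sample, the median across genes
    of the ratio to the per-gene geometric mean.  Robust to a minority of
    strongly differential genes, unlike total-count scaling."""
    logc = np.log(counts.where(counts > 0))
    log_ref = logc.mean(axis=1)
    usable = np.isfinite(log_ref)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = logc.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def sde_test(counts: pd.DataFrame, groups: pd.Series,
             group_a: str = "ZF", group_b: str = "OF",
             library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Species-differential expression: per-gene NB Wald test, BH-adjusted.

    Counts are normalised by median-of-ratios size factors (or by the
    given ``library_sizes``); each gene gets a method-of-moments
    dispersion estimate pooled across the two groups (floored at 0,
    i.e. Poisson).  The Wald statistic tests the log2 fold change of
    group means via the delta-method standard error
    var(log mu_hat) ~ (1/mu + alpha) / n.  Genes with zero counts in
    both groups are flagged and given p = 1.

    Returns a frame with ``log2_fc, p, p_adj, degenerate``.
    """
    cols_a = [c for c in groups.index[groups == group_a]
              if c in counts.columns]
    cols_b = [c for c in groups.index[groups == group_b]
              if c in counts.columns]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two individuals per group")
    sub = counts[cols_a + cols_b].astype(float)
    if library_sizes is None:
        sf = median_of_ratios_size_factors(sub)
    else:
        sf = library_sizes.reindex(sub.columns)
    sf = sf / sf.mean()
    norm = sub / sf

    res = {}
    for name, cols in (("a", cols_a), ("b", cols_b)):
        block = norm[cols]
        res[f"m_{name}"] = block.mean(axis=1)
        res[f"v_{name}"] = block.var(axis=1, ddof=1)
        res[f"n_{name}"] = len(cols)
    m_a, m_b = res["m_a"], res["m_b"]
    degenerate = (m_a == 0) & (m_b == 0)

    # pooled method-of-moments dispersion: alpha = (var - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (res["v_a"] - m_a) / m_a ** 2
        alpha_b = (res["v_b"] - m_b) / m_b ** 2
    alpha = pd.concat([alpha_a, alpha_b], axis=1).mean(axis=1)
    alpha = alpha.clip(lower=0.0).fillna(0.0)

    pc = 0.5  # continuity for zero-mean groups
    log2_fc = np.log2((m_a + pc) / (m_b + pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log_a = (1.0 / (m_a + pc) + alpha) / res["n_a"]
        var_log_b = (1.0 / (m_b + pc) + alpha) / res["n_b"]
    se_log2 = np.sqrt(var_log_a + var_log_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2_fc / se_log2
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(degenerate, 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2_fc": log2_fc, "p": p, "p_adj": p_adj,
                         "degenerate": degenerate}, index=counts.index)


def fold_change_filter(counts: pd.DataFrame, groups: pd.Series,
                       group_a: str, group_b: str,
                       fold: float = 4.0, alpha: float = 0.05,
                       library_sizes: pd.Series | None = None) -> pd.Index:
    """Genes with over ``fold``-fold change (strict) and raw test p < alpha."""
    res = sde_test(counts, groups, group_a, group_b,
                   library_sizes=library_sizes)
    keep = (res["log2_fc"].abs() > np.log2(fold)) & (res["p"] < alpha)
    return counts.index[keep]
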