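"""Classification of cis- versus trans-regulatory divergence between two species.

The central comparison is between two log2 ratios per gene:

* ``X = log2(A/B)`` — the expression ratio between the parental species
  (A, B are species-average expression levels), which carries both cis-
  and trans-acting divergence, and
* ``Y = log2(a/b)`` — the allelic expression ratio inside an F1 hybrid
  (a, b are reads from the species-1 and species-2 alleles), which carries
  only cis-acting divergence because both alleles share one trans
  environment.

A gene is called *cis* when Y differs from 0 but X does not differ from Y,
*trans* when X differs from Y but Y is 0, *cis_and_trans* when both
differences are significant, and *conserved* when neither is.

Two classifiers are provided.  The *standard* classifier uses the average
allelic ratio of all F1 hybrids for both contrasts.  Because the same
noisy cis estimate then enters both the cis term and the trans term
(t = X - Y), estimation error induces a spurious negative correlation
between the two.  The *cross-replicate* classifier breaks this coupling:
for every 4-vs-4 split of the 8 F1 hybrids, one half estimates the cis
effect and the other half enters the trans contrast.  All C(8,4) = 70
splits are evaluated, each split is classified, and a per-gene consensus
over the 70 split categories (chi-squared + Fisher's exact, both
BH-adjusted across genes) yields the final category; genes without a
consistent majority are labelled *ambiguous*.

Per-split multiple testing across genes uses the Sequential
Goodness-of-Fit (SGoF) procedure: an exact binomial meta-test on the
count of nominally significant p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: category labels, in fixed order (also the deterministic tie-break order)
CATEGORIES = ("cis", "trans", "cis_and_trans", "conserved")
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# SGoF multiple-testing correction
# ---------------------------------------------------------------------------

def sgof_adjust(pvals: Sequence[float], gamma: float = 0.05,
                alpha: float = 0.05) -> np.ndarray:
    """Sequential Goodness-of-Fit multiple-testing correction.

    Counts R = #{p <= gamma} and, while a one-sided exact binomial test of
    R successes in n trials at rate gamma is significant at level alpha,
    declares the smallest remaining p-value significant and decrements R.
    Returns a boolean array aligned with ``pvals``; the flagged set is
    always the k smallest p-values for some k (monotone).

    Parameters
    ----------
    pvals : array-like of p-values in [0, 1]
    gamma : nominal significance threshold counted by the meta-test
    alpha : level of the binomial meta-test
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    r = int(np.sum(p <= gamma))
    # Number declared = R - R_crit where R_crit is the smallest count whose
    # upper binomial tail exceeds alpha; the while-loop below is the literal
    # sequential definition and is O(R) with vectorised sf it is cheap.
    n_sig = 0
    while r - n_sig > 0 and stats.binom.sf(r - n_sig - 1, n, gamma) <= alpha:
        n_sig += 1
    flags = np.zeros(n, dtype=bool)
    if n_sig:
        order = np.argsort(p, kind="stable")
        flags[order[:n_sig]] = True
    return flags


# ---------------------------------------------------------------------------
# t tests (vectorised across genes, with degenerate-variance handling)
# ---------------------------------------------------------------------------

def one_sample_t_pvalues(values: np.ndarray, popmean: float | np.ndarray = 0.0
                         ) -> np.ndarray:
    """Two-sided one-sample t test per row of ``values`` against ``popmean``.

    Rows with zero variance get p = 1 when the mean equals the null value
    and p = 0 otherwise (degenerate but directionally correct).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    k = v.shape[1]
    if k < 2:
        raise ValueError("need at least two observations per row")
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    null = np.broadcast_to(np.asarray(popmean, dtype=float), mean.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null) / (sd / np.sqrt(k))
    p = 2.0 * stats.t.sf(np.abs(t), df=k - 1)
    degenerate = sd == 0
    p[degenerate] = np.where(np.isclose(mean[degenerate], null[degenerate]),
                             1.0, 0.0)
    return p


def two_sample_t_pvalues(sample1: np.ndarray, sample2: np.ndarray
                         ) -> np.ndarray:
    """Two-sided Student (pooled-variance) t test per row.

    ``sample1`` and ``sample2`` are (genes x m) and (genes x k) arrays.
    Zero pooled variance: p = 1 if the means coincide, else 0.
    """
    a = np.atleast_2d(np.asarray(sample1, dtype=float))
    b = np.atleast_2d(np.asarray(sample2, dtype=float))
    m, k = a.shape[1], b.shape[1]
    if m < 2 or k < 2:
        raise ValueError("need at least two observations per sample")
    diff = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = m + k - 2
    pooled = ((m - 1) * va + (k - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled * (1.0 / m + 1.0 / k))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    degenerate = pooled == 0
    p[degenerate] = np.where(np.isclose(diff[degenerate], 0.0), 1.0, 0.0)
    return p


# ---------------------------------------------------------------------------
# Split enumeration and per-split classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationSplit:
    """A disjoint 4-vs-4 partition of the F1 hybrids.

    ``group_cis`` estimates the allelic (cis) contrast; ``group_trans``
    supplies the allelic ratios entering the trans contrast.
    """
    group_cis: tuple
    group_trans: tuple

    def __post_init__(self):
        if set(self.group_cis) & set(self.group_trans):
            raise ValueError("split groups must be disjoint")


def enumerate_splits(f1_ids: Sequence, k: int | None = None
                     ) -> list[CombinationSplit]:
    """All C(n, k) cis/trans splits of the F1 individuals, in deterministic
    lexicographic order. With the study design (n=8, k=4) this yields the
    70 combinations used by the cross-replicate classifier."""
    ids = list(f1_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("F1 identifiers must be unique")
    if k is None:
        k = len(ids) // 2
    if k > len(ids) or k < 1:
        raise ValueError(f"cannot choose {k} of {len(ids)} individuals")
    splits = []
    for combo in itertools.combinations(ids, k):
        rest = tuple(i for i in ids if i not in combo)
        splits.append(CombinationSplit(group_cis=combo, group_trans=rest))
    return splits


def classify_from_flags(sig_y_nonzero, sig_x_neq_y) -> np.ndarray:
    """Map the two significance flags to a regulatory category.

    (cis significant, trans significant) -> cis_and_trans;
    (True, False) -> cis; (False, True) -> trans; (False, False) -> conserved.
    """
    cis = np.asarray(sig_y_nonzero, dtype=bool)
    trans = np.asarray(sig_x_neq_y, dtype=bool)
    out = np.where(cis & trans, "cis_and_trans",
                   np.where(cis, "cis", np.where(trans, "trans", "conserved")))
    return out


def _trans_pvalues(parental: np.ndarray, y_group: np.ndarray,
                   x_scalar: np.ndarray | None, trans_mode: str) -> np.ndarray:
    if trans_mode == "parental-sample":
        return two_sample_t_pvalues(parental, y_group)
    if trans_mode == "scalar-x":
        if x_scalar is None:
            raise ValueError("scalar-x mode requires per-gene X values")
        return one_sample_t_pvalues(y_group, popmean=x_scalar)
    raise ValueError(f"unknown trans_mode {trans_mode!r}")


def cross_replicate_classify(y: pd.DataFrame, parental_ratios: pd.DataFrame,
                             splits: list[CombinationSplit] | None = None,
                             x: pd.Series | None = None,
                             alpha: float = 0.05, gamma: float = 0.05,
                             trans_mode: str = "parental-sample"
                             ) -> pd.DataFrame:
    """Per-split regulatory categories for every gene.

    Parameters
    ----------
    y : genes x F1-individuals frame of allelic log2 ratios Y_i.
    parental_ratios : genes x pairs frame of parental log2 expression
        ratios (one ZF individual's RPKM over one OF individual's, all
        pairs); the comparison sample for the trans contrast in the
        default mode.
    splits : output of :func:`enumerate_splits`; defaults to all 4-vs-4
        splits of the columns of ``y``.
    x : per-gene scalar X = log2(A/B); only needed for
        ``trans_mode='scalar-x'``.
    trans_mode : 'parental-sample' compares the parental-ratio sample
        against group_trans's Y values with a two-sample t test;
        'scalar-x' tests group_trans's Y values against the scalar X.

    Returns
    -------
    genes x splits frame of category labels.  SGoF correction is applied
    across genes within each split, separately for the cis and trans arms.
    """
    if splits is None:
        splits = enumerate_splits(list(y.columns))
    ymat = y.to_numpy(dtype=float)
    par = parental_ratios.to_numpy(dtype=float)
    xvec = None if x is None else x.reindex(y.index).to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(y.columns)}
    out = np.empty((len(y), len(splits)), dtype=object)
    for s, split in enumerate(splits):
        ci = [col_idx[i] for i in split.group_cis]
        ti = [col_idx[i] for i in split.group_trans]
        p_cis = one_sample_t_pvalues(ymat[:, ci], popmean=0.0)
        p_trans = _trans_pvalues(par, ymat[:, ti], xvec, trans_mode)
        sig_cis = sgof_adjust(p_cis, gamma=gamma, alpha=alpha)
        sig_trans = sgof_adjust(p_trans, gamma=gamma, alpha=alpha)
        out[:, s] = classify_from_flags(sig_cis, sig_trans)
    return pd.DataFrame(out, index=y.index,
                        columns=[f"split_{i:02d}" for i in range(len(splits))])


def split_category_counts(per_split: pd.DataFrame) -> pd.DataFrame:
    """Tally per-gene category counts over the splits (genes x 4 frame)."""
    counts = pd.DataFrame(0, index=per_split.index, columns=list(CATEGORIES))
    arr = per_split.to_numpy()
    for cat in CATEGORIES:
        counts[cat] = (arr == cat).sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# Two-stage consensus over the 70 split categories
# ---------------------------------------------------------------------------

@dataclass
class ConsensusCall:
    gene: str
    counts: dict = field(default_factory=dict)
    chi2_p: float = np.nan
    chi2_p_adj: float = np.nan
    fisher_p: float = np.nan
    fisher_p_adj: float = np.nan
    final: str = AMBIGUOUS


def consensus(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Consolidate per-split category counts into one call per gene.

    Stage (i): chi-squared goodness-of-fit of the four category counts
    against an equiprobable null.  Stage (ii): Fisher's exact test on the
    2x2 table contrasting the first- and second-most frequent categories
    against their complements.  Both p-value families are BH-adjusted
    across genes; the final call is the top category only when both
    adjusted tests reach ``alpha``, otherwise *ambiguous*.  Ties for the
    top two categories are broken by the fixed order of ``CATEGORIES``.
    """
    cmat = counts[list(CATEGORIES)].to_numpy(dtype=float)
    total = cmat.sum(axis=1)
    ok = total > 0
    expected = total[:, None] / len(CATEGORIES)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_stat = np.where(ok, ((cmat - expected) ** 2 / expected).sum(axis=1),
                             np.nan)
    chi2_p = np.where(ok, stats.chi2.sf(chi2_stat, df=len(CATEGORIES) - 1),
                      np.nan)

    # stable top-two extraction with fixed-order tie break: argsort on
    # (-count, category index)
    order = np.argsort(-cmat, axis=1, kind="stable")
    top1 = order[:, 0]
    top2 = order[:, 1]
    n1 = cmat[np.arange(len(cmat)), top1]
    n2 = cmat[np.arange(len(cmat)), top2]
    fisher_p = np.ones(len(cmat))
    for i in range(len(cmat)):
        if not ok[i]:
            fisher_p[i] = np.nan
            continue
        table = [[n1[i], total[i] - n1[i]], [n2[i], total[i] - n2[i]]]
        fisher_p[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    chi2_adj = np.full(len(cmat), np.nan)
    fisher_adj = np.full(len(cmat), np.nan)
    if ok.any():
        chi2_adj[ok] = multipletests(chi2_p[ok], method="fdr_bh")[1]
        fisher_adj[ok] = multipletests(fisher_p[ok], method="fdr_bh")[1]

    final = np.full(len(cmat), AMBIGUOUS, dtype=object)
    decided = ok & (chi2_adj < alpha) & (fisher_adj < alpha)
    cats = np.array(CATEGORIES, dtype=object)
    final[decided] = cats[top1[decided]]

    out = counts[list(CATEGORIES)].copy()
    out["chi2_p"] = chi2_p
    out["chi2_p_adj"] = chi2_adj
    out["fisher_p"] = fisher_p
    out["fisher_p_adj"] = fisher_adj
    out["final"] = final
    return out


def classify_consensus(y: pd.DataFrame, parental_ratios: pd.DataFrame,
                       x: pd.Series | None = None, alpha: float = 0.05,
                       gamma: float = 0.05,
                       trans_mode: str = "parental-sample") -> pd.DataFrame:
    """Full cross-replicate pipeline: 70 splits -> counts -> consensus."""
    per_split = cross_replicate_classify(y, parental_ratios, x=x, alpha=alpha,
                                         gamma=gamma, trans_mode=trans_mode)
    return consensus(split_category_counts(per_split), alpha=alpha)


# ---------------------------------------------------------------------------
# Standard (averaged-ASE) classifier, for comparison
# ---------------------------------------------------------------------------

def standard_classify(y: pd.DataFrame, parental_ratios: pd.DataFrame,
                      x: pd.Series | None = None, alpha: float = 0.05,
                      gamma: float = 0.05,
                      trans_mode: str = "parental-sample") -> pd.Series:
    """Single classification per gene using all F1 hybrids at once.

    The cis arm is a one-sample t test of all eight Y values against 0;
    the trans arm compares the parental-ratio sample against the same
    eight Y values.  SGoF correction across genes, then the four-way flag
    rule.  This reproduces the conventional averaged-ASE approach and is
    the baseline against which the cross-replicate method's artifact
    reduction is measured.
    """
    ymat = y.to_numpy(dtype=float)
    par = parental_ratios.to_numpy(dtype=float)
    xvec = None if x is None else x.reindex(y.index).to_numpy(dtype=float)
    p_cis = one_sample_t_pvalues(ymat, popmean=0.0)
    p_trans = _trans_pvalues(par, ymat, xvec, trans_mode)
    sig_cis = sgof_adjust(p_cis, gamma=gamma, alpha=alpha)
    sig_trans = sgof_adjust(p_trans, gamma=gamma, alpha=alpha)
    return pd.Series(classify_from_flags(sig_cis, sig_trans), index=y.index,
                     name="category")


# ---------------------------------------------------------------------------
# cis / trans point estimates (for the artifact diagnostics)
# ---------------------------------------------------------------------------

def cis_trans_estimates(y: pd.DataFrame, x: pd.Series,
                        cis_ids: Sequence | None = None,
                        trans_ids: Sequence | None = None) -> pd.DataFrame:
    """Point estimates c_hat = mean(Y) and t_hat = X - mean(Y).

    With ``cis_ids``/``trans_ids`` unset, both estimates use all F1
    individuals (the shared-individuals construction whose estimation
    error couples c_hat and t_hat).  Passing two disjoint id sets
    reproduces the cross-replicate decoupling.
    """
    if cis_ids is None:
        cis_ids = list(y.columns)
    if trans_ids is None:
        trans_ids = list(y.columns)
    c_hat = y[list(cis_ids)].mean(axis=1)
    t_hat = x.reindex(y.index) - y[list(trans_ids)].mean(axis=1)
    return pd.DataFrame({"cis_hat": c_hat, "trans_hat": t_hat})
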