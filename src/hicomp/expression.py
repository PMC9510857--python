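"""Expression quantification (TPM), differential expression, and the
association of expression change with compartment-switch categories.

The differential-expression caller is a documented stand-in, not a DESeq2
reimplementation: size factors by median-of-ratios, log2 fold change of
size-factor-normalized condition means with pseudocount 0.5, and a p-value
from the exact Wilcoxon rank sum on normalized counts when both groups have
at least 4 replicates (the smallest size at which the exact test can reach
two-sided p < 0.05) or from a two-sided exact Poisson-ratio (binomial) test
on pooled normalized counts otherwise.  The pipeline also accepts an
externally produced DE table (gene, log2FC, p) in place of this caller.
Genes are called differentially expressed at |log2FC| > 2 and p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError, UndefinedValueError

logger = logging.getLogger("hicomp.expression")

DEFAULT_LFC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 0.05
_PSEUDOCOUNT = 0.5
_MIN_REPS_FOR_RANKSUM = 4
_EXACT_MAX_N = 20  # exact rank-sum enumeration up to n + m of this size


def tpm(counts, effective_lengths) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized to 1e6 per sample."""
    c = pd.DataFrame(counts).astype(float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if lengths.shape[0] != c.shape[0]:
        raise ParameterError("lengths must align with count rows")
    if np.any(lengths <= 0):
        raise ParameterError("effective lengths must be > 0")
    if np.any(c.values < 0):
        raise ParameterError("counts must be >= 0")
    rate = c.values / lengths[:, None]
    totals = rate.sum(axis=0)
    if np.any(totals == 0):
        raise ParameterError("a sample has all-zero counts; TPM undefined")
    return pd.DataFrame(1e6 * rate / totals, index=c.index, columns=c.columns)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank sum (Mann-Whitney U) with midranks for ties.

    Exact null enumeration when n + m <= 20 and there are no ties; normal
    approximation with tie and continuity correction otherwise.  Returns
    ``(U, p)`` where U counts (x > y) pairs plus half the (x == y) ties.
    Two identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(log_ratios):
    """Paired Wilcoxon signed-rank test on per-item log ratios vs 0.

    The paired complement to the rank-sum comparison: under a no-change
    null the per-item log ratios are symmetric about 0, so this test is
    exactly calibrated even when item baselines vary widely.  Zero ratios
    are dropped (Wilcoxon convention).  Returns ``(W, p)``.
    """
    r = np.asarray(log_ratios, dtype=float)
    r = r[r != 0]
    if r.size == 0:
        return 0.0, 1.0
    res = sps.wilcoxon(r)
    return float(res.statistic), float(res.pvalue)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference: per-gene geometric mean)."""
    c = counts.astype(float)
    positive = (c > 0).all(axis=1)
    if positive.sum() == 0:
        raise ParameterError("no gene expressed in all samples; size factors undefined")
    logref = np.log(c.loc[positive]).mean(axis=1)
    sf = np.exp(np.log(c.loc[positive]).sub(logref, axis=0).median(axis=0))
    return sf


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id index; log2_fold_change, p_value, significant
    method: str
    lfc_threshold: float
    p_threshold: float


def diff_expression(
    counts: pd.DataFrame,
    condition_labels,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> DEResult:
    """Stand-in differential-expression caller (see module docstring).

    ``condition_labels`` assigns each count column to condition 1 or 2;
    log2 fold changes are condition 2 over condition 1.  Genes absent in
    all samples are excluded (logged).
    """
    labels = np.asarray(condition_labels)
    if labels.size != counts.shape[1]:
        raise ParameterError("condition_labels must align with count columns")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ParameterError("exactly two conditions required")
    g1 = labels == groups[0]
    g2 = labels == groups[1]

    c = counts.astype(float)
    expressed = c.sum(axis=1) > 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("excluding %d genes absent in all samples", n_dropped)
    c = c.loc[expressed]

    sf = size_factors(c)
    norm = c / sf.values[None, :]
    m1 = norm.loc[:, g1].mean(axis=1)
    m2 = norm.loc[:, g2].mean(axis=1)
    lfc = np.log2((m2 + _PSEUDOCOUNT) / (m1 + _PSEUDOCOUNT))

    n1, n2 = int(g1.sum()), int(g2.sum())
    pvals = np.empty(c.shape[0])
    if min(n1, n2) >= _MIN_REPS_FOR_RANKSUM:
        method = "wilcoxon_rank_sum_normalized_counts"
        a = norm.loc[:, g1].values
        b = norm.loc[:, g2].values
        for i in range(c.shape[0]):
            _, pvals[i] = wilcoxon_rank_sum(a[i], b[i])
    else:
        # exact Poisson-ratio test: pooled counts split ~ binomial under H0
        method = "exact_poisson_ratio_pooled_counts"
        k1 = c.loc[:, g1].sum(axis=1).round().astype(int)
        k2 = c.loc[:, g2].sum(axis=1).round().astype(int)
        s1 = float(sf[g1].sum())
        s2 = float(sf[g2].sum())
        p0 = s2 / (s1 + s2)
        for i, (a, b) in enumerate(zip(k1.values, k2.values)):
            if a + b == 0:
                pvals[i] = 1.0
            else:
                pvals[i] = sps.binomtest(int(b), int(a + b), p0).pvalue

    table = pd.DataFrame(
        {
            "base_mean": (m1 + m2) / 2.0,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "significant": (np.abs(lfc) > lfc_threshold) & (pvals < p_threshold),
        },
        index=c.index,
    )
    return DEResult(table=table, method=method,
                    lfc_threshold=lfc_threshold, p_threshold=p_threshold)


def genes_to_bins(annotation: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Assign genes to bins by midpoint under the half-open convention.

    ``annotation`` columns: gene_id, chrom, start, end (0-based half-open
    bp).  Returns a copy with a ``bin`` column.
    """
    ann = annotation.copy()
    mid = (ann["start"].to_numpy() + ann["end"].to_numpy()) // 2
    ann["bin"] = mid // bin_size
    return ann


def expression_density_per_bin(
    tpm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom: str,
    n_bins: int,
    bin_size: int,
    sample_columns=None,
) -> np.ndarray:
    """Per-bin expression density: summed TPM of genes whose midpoint falls
    in the bin (the stand-in for an RNA-seq coverage track)."""
    ann = genes_to_bins(annotation, bin_size)
    ann = ann[(ann["chrom"] == chrom) & (ann["bin"] < n_bins)]
    cols = sample_columns if sample_columns is not None else tpm_table.columns
    dens = np.zeros(n_bins)
    vals = tpm_table.loc[ann["gene_id"], cols].mean(axis=1).to_numpy()
    np.add.at(dens, ann["bin"].to_numpy(), vals)
    return dens


@dataclass
class CategoryExpression:
    category: str
    n_genes: int
    median_tpm_c1: float
    median_tpm_c2: float
    log2_changes: np.ndarray
    p_value: float  # None when < 3 genes


def expression_by_category(
    tpm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    bin_categories: dict,
    bin_size: int,
    condition_labels,
) -> dict:
    """Associate expression change with compartment-switch categories.

    ``bin_categories`` maps chromosome -> per-bin category array (the
    SwitchTable categories).  For every category, the per-gene mean TPM
    vectors of the two conditions are compared by a two-sided Wilcoxon rank
    sum.  Categories with fewer than 3 genes get p = None (logged).
    """
    labels = np.asarray(condition_labels)
    if labels.size != tpm_table.shape[1]:
        raise ParameterError("condition_labels must align with TPM columns")
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ParameterError("exactly two conditions required")
    cols1 = tpm_table.columns[labels == groups[0]]
    cols2 = tpm_table.columns[labels == groups[1]]

    ann = genes_to_bins(annotation, bin_size)
    out = {}
    per_cat = {}
    for _, row in ann.iterrows():
        cats = bin_categories.get(row["chrom"])
        if cats is None or row["bin"] >= len(cats):
            continue
        cat = cats[int(row["bin"])]
        if cat == ".":
            continue
        per_cat.setdefault(cat, []).append(row["gene_id"])

    for cat, genes in per_cat.items():
        t1 = tpm_table.loc[genes, cols1].mean(axis=1).to_numpy()
        t2 = tpm_table.loc[genes, cols2].mean(axis=1).to_numpy()
        log2c = np.log2((t2 + _PSEUDOCOUNT) / (t1 + _PSEUDOCOUNT))
        if len(genes) >= 3:
            _, p = wilcoxon_rank_sum(t1, t2)
        else:
            logger.info("category %s has %d genes; p undefined", cat, len(genes))
            p = None
        out[cat] = CategoryExpression(
            category=cat, n_genes=len(genes),
            median_tpm_c1=float(np.median(t1)), median_tpm_c2=float(np.median(t2)),
            log2_changes=log2c, p_value=p,
        )
    return out
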