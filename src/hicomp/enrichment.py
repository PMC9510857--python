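"""Gap-aware mean contact frequency for interval pairs and its comparison.

The mean contact of an interval pair is the average over all bin pairs
(Cartesian product for two distinct intervals; unordered off-diagonal pairs
within one interval) with gap bin pairs excluded; a pair is dropped when gap
bin pairs make up more than 50% (strictly) of its total bin pairs.  The
cross-condition comparison keeps only interval pairs retained in both
conditions and reports per-category log2 ratios and a Wilcoxon rank sum p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ParameterError

logger = logging.getLogger("hicomp.enrichment")

GAP_DROP_FRACTION = 0.5  # dropped iff gap pairs exceed this (strict)


@dataclass
class PairContact:
    interval_a: tuple
    interval_b: tuple
    n_cell_pairs_total: int
    n_cell_pairs_gap: int
    mean_contact: float
    dropped: bool


def pair_mean_contact(
    matrix: np.ndarray,
    interval_a: tuple,
    interval_b: tuple,
    gap_mask: np.ndarray = None,
) -> PairContact:
    """Mean contact over the bin pairs of two half-open bin intervals.

    For the within-interval case (identical intervals) the bin pairs are the
    unordered pairs i < j, excluding the zeroed main diagonal.  A bin pair
    is a gap pair if either bin is masked.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    a0, a1 = interval_a
    b0, b1 = interval_b
    if not (0 <= a0 < a1 <= n and 0 <= b0 < b1 <= n):
        raise ParameterError(
            f"empty or out-of-range interval: {interval_a}, {interval_b} on {n} bins"
        )
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    keep = ~np.asarray(gap_mask, dtype=bool)

    same = (a0, a1) == (b0, b1)
    if same:
        L = a1 - a0
        iu, ju = np.triu_indices(L, k=1)
        ii, jj = iu + a0, ju + a0
    else:
        ii, jj = np.meshgrid(np.arange(a0, a1), np.arange(b0, b1), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
    n_total = ii.size
    if n_total == 0:
        raise ParameterError("interval pair has no bin pairs")
    ok = keep[ii] & keep[jj]
    n_gap = int(n_total - ok.sum())
    dropped = n_gap / n_total > GAP_DROP_FRACTION
    mean = float(m[ii[ok], jj[ok]].mean()) if ok.any() else float("nan")
    return PairContact(
        interval_a=tuple(interval_a),
        interval_b=tuple(interval_b),
        n_cell_pairs_total=int(n_total),
        n_cell_pairs_gap=n_gap,
        mean_contact=mean,
        dropped=bool(dropped),
    )


@dataclass
class CategoryComparison:
    category: str
    n_pairs: int
    means_c1: np.ndarray
    means_c2: np.ndarray
    log2_ratios: np.ndarray
    median_log2_ratio: float
    p_value: float  # None when < 3 retained pairs


def compare_pair_contacts(pairs_c1: list, pairs_c2: list, category_labels: list) -> dict:
    """Per-category comparison of the same interval pairs across conditions.

    ``pairs_c1``/``pairs_c2`` are aligned PairContact lists for identical
    interval pairs evaluated on the two condition matrices; pairs dropped in
    either condition (or with non-positive mean) are excluded from both.
    Returns ``{category: CategoryComparison}``; the p-value is a two-sided
    Wilcoxon rank sum comparing the two per-pair mean vectors.
    """
    from .expression import wilcoxon_rank_sum

    if not (len(pairs_c1) == len(pairs_c2) == len(category_labels)):
        raise ParameterError("pair lists and labels must be aligned")
    by_cat = {}
    for p1, p2, cat in zip(pairs_c1, pairs_c2, category_labels):
        if p1.interval_a != p2.interval_a or p1.interval_b != p2.interval_b:
            raise ParameterError("pair lists must describe identical intervals")
        if p1.dropped or p2.dropped:
            continue
        if not (p1.mean_contact > 0 and p2.mean_contact > 0):
            logger.info("pair %s-%s excluded: non-positive mean",
                        p1.interval_a, p1.interval_b)
            continue
        by_cat.setdefault(cat, []).append((p1.mean_contact, p2.mean_contact))

    out = {}
    for cat, vals in by_cat.items():
        m1 = np.array([v[0] for v in vals])
        m2 = np.array([v[1] for v in vals])
        log2r = np.log2(m2 / m1)
        if m1.size >= 3:
            _, p = wilcoxon_rank_sum(m1, m2)
        else:
            logger.info("category %s has %d retained pairs; p undefined",
                        cat, m1.size)
            p = None
        out[cat] = CategoryComparison(
            category=cat, n_pairs=int(m1.size), means_c1=m1, means_c2=m2,
            log2_ratios=log2r, median_log2_ratio=float(np.median(log2r)),
            p_value=p,
        )
    return out
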