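"""A/B compartment calling, sign orientation, switch classification.

Compartments are called per chromosome from an ICE-normalized matrix using
the standard transform: observed/expected (per-diagonal expected), then the
Pearson correlation matrix of the O/E columns, then its leading eigenvector
(PC1).  Since an eigenvector is defined only up to sign, PC1 is oriented so
that it correlates positively with an expression density track (active A
chromatin is gene-dense/transcribed); positive PC1 then defines A, negative
defines B.  A raw-matrix PCA mode is available for sensitivity checks.

Switches between two conditions are classified per bin into A-common,
B-common, AtoB and BtoA (condition-1 label first); the switched fraction is
compared against replicate noise by a 2x2 chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import ParameterError, UndefinedValueError

logger = logging.getLogger("hicomp.compartments")

CATEGORIES = ("A-common", "B-common", "AtoB", "BtoA")
MASKED = "."


def observed_over_expected(matrix: np.ndarray, gap_mask: np.ndarray = None) -> np.ndarray:
    """O/E transform: divide each cell by the mean of its diagonal.

    The expected value of diagonal d is the mean of its unmasked cells;
    cells where the expected value is 0 (or on fully masked diagonals) are
    NaN, as are all cells on masked rows/columns.  Unmasked diagonal means
    of the output equal 1.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    keep = ~np.asarray(gap_mask, dtype=bool)
    oe = np.full_like(m, np.nan)
    for d in range(n):
        sel = keep[:n - d] & keep[d:]
        if not sel.any():
            continue
        vals = np.diagonal(m, d)[sel]
        expected = vals.mean()
        if expected <= 0:
            continue
        idx = np.nonzero(sel)[0]
        oe[idx, idx + d] = np.diagonal(m, d)[sel] / expected
        oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def compartment_pc1(
    oe_matrix: np.ndarray,
    gap_mask: np.ndarray = None,
    use_correlation: bool = True,
) -> np.ndarray:
    """Leading eigenvector of the correlation of O/E columns (unit norm).

    NaN cells within the unmasked submatrix (e.g. the zeroed diagonal) are
    treated as the neutral O/E value 1 before correlating.  Masked bins get
    NaN in the output.  With ``use_correlation=False`` the eigenvector of
    the (column-centered) matrix itself is returned — the literal
    "PCA of the normalized matrix" mode.
    """
    oe = np.asarray(oe_matrix, dtype=float)
    n = oe.shape[0]
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    keep = ~np.asarray(gap_mask, dtype=bool)
    if keep.sum() < 10:
        raise ParameterError("PC1 requires at least 10 unmasked bins")
    sub = oe[np.ix_(keep, keep)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if use_correlation:
        sd = sub.std(axis=0)
        if np.any(sd == 0):
            raise ParameterError("degenerate matrix: constant O/E column")
        work = np.corrcoef(sub, rowvar=False)
    else:
        work = sub - sub.mean(axis=0, keepdims=True)
        work = work.T @ work
    evals, evecs = np.linalg.eigh(work)
    v = evecs[:, -1]
    v = v / np.linalg.norm(v)
    pc1 = np.full(n, np.nan)
    pc1[keep] = v
    return pc1


def orient_pc1(pc1: np.ndarray, expression_density: np.ndarray) -> np.ndarray:
    """Fix the eigenvector sign using an expression density per bin.

    If the Pearson correlation between PC1 and the density is negative, PC1
    is multiplied by -1; the returned vector has PCC >= 0 with the density
    and equals +/- the input.  Orienting twice is a no-op.
    """
    pc1 = np.asarray(pc1, dtype=float)
    dens = np.asarray(expression_density, dtype=float)
    if pc1.shape != dens.shape:
        raise ParameterError("PC1 and density vectors have different lengths")
    sel = np.isfinite(pc1) & np.isfinite(dens)
    if sel.sum() < 3:
        raise UndefinedValueError("orientation needs >= 3 unmasked bins")
    if np.std(dens[sel]) == 0 or np.std(pc1[sel]) == 0:
        raise UndefinedValueError("orientation undefined: zero-variance input")
    pcc = np.corrcoef(pc1[sel], dens[sel])[0, 1]
    return -pc1 if pcc < 0 else pc1.copy()


@dataclass
class CompartmentTrack:
    """Per-bin PC1 and A/B labels for one chromosome and condition."""

    pc1: np.ndarray
    labels: np.ndarray           # 'A', 'B' or '.' (masked)
    segments: list               # (start, end, label) half-open bin intervals

    @property
    def n_bins(self) -> int:
        return self.labels.size


def _segments_of(labels: np.ndarray) -> list:
    segs = []
    start = None
    for i, lab in enumerate(labels):
        if lab == MASKED:
            if start is not None:
                segs.append((start, i, labels[start]))
                start = None
            continue
        if start is None:
            start = i
        elif lab != labels[start]:
            segs.append((start, i, labels[start]))
            start = i
    if start is not None:
        segs.append((start, labels.size, labels[start]))
    return segs


def classify_bins(oriented_pc1: np.ndarray) -> CompartmentTrack:
    """A iff PC1 > 0, B iff PC1 < 0; exactly 0 (or NaN) is masked."""
    pc1 = np.asarray(oriented_pc1, dtype=float)
    labels = np.full(pc1.size, MASKED, dtype="<U1")
    labels[np.isfinite(pc1) & (pc1 > 0)] = "A"
    labels[np.isfinite(pc1) & (pc1 < 0)] = "B"
    return CompartmentTrack(pc1=pc1, labels=labels, segments=_segments_of(labels))


@dataclass
class SwitchTable:
    """Per-bin switch categories between two conditions (c1 label first)."""

    categories: np.ndarray       # per-bin str in CATEGORIES or '.'
    counts: dict                 # category -> count over unmasked bins

    @property
    def n_unmasked(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def switched_fraction(self) -> float:
        n = self.n_unmasked
        if n == 0:
            raise UndefinedValueError("no unmasked bins")
        return (self.counts["AtoB"] + self.counts["BtoA"]) / n

    @property
    def ab_share_of_switched(self) -> float:
        sw = self.counts["AtoB"] + self.counts["BtoA"]
        if sw == 0:
            raise UndefinedValueError("no switched bins")
        return self.counts["AtoB"] / sw

    def segments(self) -> list:
        """Maximal runs of one category: (start, end, category)."""
        return _segments_of(self.categories)


def category_segments(categories: np.ndarray) -> list:
    """Maximal runs of one category over a per-bin category array."""
    return _segments_of(np.asarray(categories))


def switch_classification(track_c1: CompartmentTrack, track_c2: CompartmentTrack) -> SwitchTable:
    """Per-bin switch categories; masked in either condition -> masked."""
    l1, l2 = track_c1.labels, track_c2.labels
    if l1.shape != l2.shape:
        raise ParameterError("tracks have different bin counts")
    cats = np.full(l1.size, MASKED, dtype="<U8")
    ok = (l1 != MASKED) & (l2 != MASKED)
    cats[ok & (l1 == "A") & (l2 == "A")] = "A-common"
    cats[ok & (l1 == "B") & (l2 == "B")] = "B-common"
    cats[ok & (l1 == "A") & (l2 == "B")] = "AtoB"
    cats[ok & (l1 == "B") & (l2 == "A")] = "BtoA"
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    return SwitchTable(categories=cats, counts=counts)


def compare_switch_rates(
    n_switched_ab: int, n_total_ab: int, n_switched_rep: int, n_total_rep: int
):
    """2x2 chi-squared (1 df, no continuity correction) on switch rates.

    Compares switched-vs-not between the condition comparison and the
    replicate comparison.  Returns ``(statistic, p)``.
    """
    if n_total_ab <= 0 or n_total_rep <= 0:
        raise ParameterError("totals must be positive")
    if not (0 <= n_switched_ab <= n_total_ab and 0 <= n_switched_rep <= n_total_rep):
        raise ParameterError("switched counts must lie within totals")
    table = np.array([
        [n_switched_ab, n_total_ab - n_switched_ab],
        [n_switched_rep, n_total_rep - n_switched_rep],
    ])
    if (table.sum(axis=0) == 0).any():
        # a zero column means identical (degenerate) rates
        return 0.0, 1.0
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def intra_compartment_strength(
    matrix: np.ndarray,
    segments: list,
    gap_mask: np.ndarray = None,
) -> list:
    """Mean within-segment contact for each (start, end, label) segment.

    Uses the gap-aware pair mean (unordered bin pairs, diagonal excluded);
    segments dropped by the >50% gap rule or fully masked are skipped and
    logged.  Returns a list of ``(segment, mean_contact)``.
    """
    from .enrichment import pair_mean_contact

    out = []
    for seg in segments:
        start, end, label = seg
        if end - start < 2:
            continue  # a single bin has no off-diagonal pairs
        pc = pair_mean_contact(matrix, (start, end), (start, end), gap_mask)
        if pc.dropped or not np.isfinite(pc.mean_contact):
            logger.info("segment %s dropped under the gap rule", (start, end, label))
            continue
        out.append((seg, pc.mean_contact))
    return out
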