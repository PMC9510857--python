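"""Stratum-adjusted correlation coefficient (SCC) between two contact maps.

The SCC compares two maps of the same chromosome by correlating them within
distance strata (diagonals) and averaging the per-stratum Pearson
correlations r_k with weights ``w_k = N_k * sd(X_k) * sd(Y_k)``::

    SCC = sum_k w_k r_k / sum_k w_k

Strata are diagonals k = 1..max_dist_bins; the main diagonal is excluded
(self-interactions are artifact-dominated and zeroed by the simulator).
An optional 2D mean filter of half-width h smooths both maps first; masked
cells are excluded from the window means and from the strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ParameterError, UndefinedValueError, union_gap_mask

logger = logging.getLogger("hicomp.reproducibility")

DEFAULT_MAX_DIST_BP = 5_000_000
DEFAULT_H_BY_RESOLUTION = {40_000: 1}  # h=1 at 40 kb, 0 at coarser maps


def default_h(bin_size: int) -> int:
    return DEFAULT_H_BY_RESOLUTION.get(bin_size, 0)


@dataclass
class Stratum:
    k: int          # diagonal offset in bins
    n: int          # paired cells used
    r: float        # Pearson correlation
    weight: float   # N_k * sd(X_k) * sd(Y_k)


@dataclass
class SCCResult:
    scc: float
    strata: list
    max_dist_bins: int
    h: int

    def to_dict(self) -> dict:
        return {
            "scc": self.scc,
            "max_dist_bins": self.max_dist_bins,
            "h": self.h,
            "strata": [
                {"k": s.k, "n": s.n, "r": s.r, "weight": s.weight}
                for s in self.strata
            ],
        }


def smooth_matrix(matrix: np.ndarray, h: int, gap_mask: np.ndarray = None) -> np.ndarray:
    """(2h+1)^2 mean filter; masked cells excluded from the window means.

    h = 0 returns the input unchanged (a copy); output is symmetric for
    symmetric input.
    """
    if h < 0 or int(h) != h:
        raise ParameterError("h must be a non-negative integer")
    m = np.asarray(matrix, dtype=float)
    if h == 0:
        return m.copy()
    if gap_mask is None:
        gap_mask = np.zeros(m.shape[0], dtype=bool)
    keep = ~np.asarray(gap_mask, dtype=bool)
    w = np.outer(keep, keep).astype(float)
    size = 2 * h + 1
    num = ndimage.uniform_filter(m * w, size=size, mode="constant")
    den = ndimage.uniform_filter(w, size=size, mode="constant")
    out = np.zeros_like(m)
    np.divide(num, den, out=out, where=den > 0)
    out[~keep, :] = 0.0
    out[:, ~keep] = 0.0
    return out


def scc(
    matrix_x: np.ndarray,
    matrix_y: np.ndarray,
    max_dist_bins: int,
    h: int = 0,
    gap_mask: np.ndarray = None,
) -> SCCResult:
    """SCC between two same-chromosome, same-resolution matrices.

    Strata with fewer than 2 unmasked paired cells or zero variance in
    either matrix are skipped (not counted as r = 0).
    """
    x = np.asarray(matrix_x, dtype=float)
    y = np.asarray(matrix_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ParameterError("matrices must be square and of identical shape")
    if max_dist_bins < 1:
        raise ParameterError("max_dist_bins must be >= 1")
    n = x.shape[0]
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    keep = ~np.asarray(gap_mask, dtype=bool)

    xs = smooth_matrix(x, h, gap_mask)
    ys = smooth_matrix(y, h, gap_mask)

    strata = []
    for k in range(1, min(max_dist_bins, n - 1) + 1):
        sel = keep[:n - k] & keep[k:]
        xv = np.diagonal(xs, k)[sel]
        yv = np.diagonal(ys, k)[sel]
        if xv.size < 2:
            continue
        sdx = xv.std()
        sdy = yv.std()
        if sdx == 0 or sdy == 0:
            continue
        r = float(np.corrcoef(xv, yv)[0, 1])
        strata.append(Stratum(k=k, n=int(xv.size), r=r,
                              weight=float(xv.size * sdx * sdy)))
    if not strata:
        raise UndefinedValueError("no stratum with >= 2 unmasked pairs and variance")
    wsum = sum(s.weight for s in strata)
    value = sum(s.weight * s.r for s in strata) / wsum
    return SCCResult(scc=float(value), strata=strata,
                     max_dist_bins=max_dist_bins, h=h)


def genome_scc(results: list) -> float:
    """Genome-wide SCC: weight-summed aggregate over per-chromosome results."""
    strata = [s for res in results for s in res.strata]
    if not strata:
        raise UndefinedValueError("no strata to aggregate")
    wsum = sum(s.weight for s in strata)
    return float(sum(s.weight * s.r for s in strata) / wsum)


def subsample_matrix(matrix: np.ndarray, target_total: float, seed: int) -> np.ndarray:
    """Count-matched subsampling of a raw matrix (multivariate hypergeometric).

    Draws ``target_total`` contacts without replacement from the upper
    triangle, for depth-matching maps before SCC.
    """
    m = np.asarray(matrix)
    upper = np.triu(m, 1).astype(np.int64)
    total = int(upper.sum())
    target = int(target_total)
    if target > total:
        raise ParameterError(f"cannot subsample {target} from {total} contacts")
    rng = np.random.default_rng(seed)
    flat = upper.ravel()
    sampled = rng.multivariate_hypergeometric(flat, target, method="marginals")
    up = sampled.reshape(upper.shape).astype(float)
    return up + up.T
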