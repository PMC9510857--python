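"""Gap-bin masking, ICE matrix balancing and cross-condition depth matching.

ICE (iterative correction) models the observed contact matrix as
``M_ij = b_i * b_j * T_ij`` with a "true" matrix T of equal row sums and a
multiplicative per-bin bias b.  The iteration repeatedly divides the matrix
by its normalized row sums until the unmasked row sums agree to ``tol``;
the accumulated per-bin factors are the bias vector, reported with the
convention that their geometric mean over unmasked bins is 1 (ICE fixes
the bias only up to a scalar).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import ContactMatrix, HicompError, ParameterError, contact_total

logger = logging.getLogger("hicomp.normalization")

DEFAULT_ICE_TOL = 1e-6
DEFAULT_ICE_MAX_ITER = 200
DEFAULT_MIN_NONZERO_FRACTION = 0.05


class IceConvergenceError(HicompError):
    def __init__(self, residual, max_iter):
        super().__init__(
            f"ICE did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )
        self.residual = residual


def mask_gaps(
    matrix: np.ndarray,
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
) -> np.ndarray:
    """Detect gap bins on a raw matrix.

    A bin is a gap if its marginal count is zero or if fewer than
    ``min_nonzero_fraction`` of its row cells (over bins not already
    zero-marginal) are nonzero.  Returns a boolean mask, True = gap.
    """
    m = np.asarray(matrix, dtype=float)
    marginal = m.sum(axis=1)
    mask = marginal == 0
    keep = ~mask
    if keep.sum() > 0:
        nz_frac = (m[:, keep] > 0).sum(axis=1) / keep.sum()
        mask |= nz_frac < min_nonzero_fraction
    if mask.all():
        raise HicompError("all bins masked as gaps; matrix unusable downstream")
    return mask


def ice_normalize(
    matrix: np.ndarray,
    gap_mask: np.ndarray = None,
    tol: float = DEFAULT_ICE_TOL,
    max_iter: int = DEFAULT_ICE_MAX_ITER,
):
    """ICE-balance a symmetric non-negative matrix.

    Returns ``(normalized, bias, n_iter)``.  ``normalized`` equals the input
    divided by ``outer(bias, bias)`` up to a global scalar (it is rescaled to
    preserve the unmasked contact total); its unmasked row sums agree to
    ``tol`` (max relative deviation from their mean).  ``bias`` has geometric
    mean 1 over unmasked bins and NaN at masked bins.  Masked bins never
    influence the row-sum residuals or the bias estimates.
    """
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ParameterError("ICE requires a non-negative matrix")
    if gap_mask is None:
        gap_mask = np.zeros(m.shape[0], dtype=bool)
    gap_mask = np.asarray(gap_mask, dtype=bool)
    valid = ~gap_mask
    if valid.sum() < 2:
        raise ParameterError("ICE requires at least 2 unmasked bins")

    work = m.copy()
    work[gap_mask, :] = 0.0
    work[:, gap_mask] = 0.0
    input_total = contact_total(work)
    bias = np.ones(m.shape[0])

    n_iter = 0
    residual = np.inf
    for n_iter in range(1, max_iter + 1):
        s = work.sum(axis=1)
        mean_s = s[valid].mean()
        if mean_s == 0:
            raise ParameterError("ICE: unmasked part of the matrix is all zero")
        r = np.ones_like(s)
        r[valid] = s[valid] / mean_s
        residual = np.abs(r[valid] - 1.0).max()
        if residual < tol:
            break
        bias *= r
        work /= np.outer(r, r)
    else:
        raise IceConvergenceError(residual, max_iter)

    # convention: geometric mean 1 over unmasked bins
    g = np.exp(np.log(bias[valid]).mean())
    bias = bias / g
    bias[gap_mask] = np.nan

    total = contact_total(work)
    if total > 0:
        work *= input_total / total
    return work, bias, n_iter


def depth_normalize(matrix_c1: np.ndarray, matrix_c2: np.ndarray,
                    gap_mask: np.ndarray = None):
    """Scale two same-chromosome matrices to equal unmasked contact totals.

    Both are scaled to the mean of the two input totals; relative cell
    ratios within each matrix are unchanged.  The same (union) gap mask must
    already be applied to both.
    """
    t1 = contact_total(matrix_c1, gap_mask)
    t2 = contact_total(matrix_c2, gap_mask)
    if t1 <= 0 or t2 <= 0:
        raise ParameterError("depth normalization undefined for zero-total matrix")
    target = 0.5 * (t1 + t2)
    return matrix_c1 * (target / t1), matrix_c2 * (target / t2)


def ice_contact_matrix(cm: ContactMatrix, tol: float = DEFAULT_ICE_TOL,
                       max_iter: int = DEFAULT_ICE_MAX_ITER,
                       min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION):
    """Convenience wrapper: detect gaps on a raw ContactMatrix, then ICE.

    Returns ``(ContactMatrix with norm='iced', bias, n_iter)``; the matrix
    carries the union of the pre-existing and detected gap masks.
    """
    mask = cm.gap_mask | mask_gaps(cm.matrix, min_nonzero_fraction)
    normalized, bias, n_iter = ice_normalize(cm.matrix, mask, tol, max_iter)
    out = ContactMatrix(cm.chrom, normalized, cm.bin_size, mask, "iced")
    return out, bias, n_iter
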