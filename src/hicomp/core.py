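"""Shared containers: binned genomes and per-chromosome cis contact matrices.

Conventions used throughout the package:

* genomic positions in pair records are 1-based (pairs-file convention);
* bins are 0-based half-open intervals of ``bin_size`` bp, the last bin of a
  chromosome may be short;
* contact matrices are dense, square, symmetric and non-negative; the matrix
  is stored fully symmetric but a contact (an observed ligation between two
  bins) is counted once, so the *contact total* of a matrix is the sum of its
  upper triangle including the diagonal;
* ``gap_mask`` is a boolean vector per bin, ``True`` marking gap bins that are
  excluded from normalization, eigen-analysis and enrichment averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hicomp")

#: normalization states a ContactMatrix can be in
NORM_STATES = ("raw", "iced", "depth")


class HicompError(Exception):
    """Base class for package errors."""


class ParameterError(HicompError, ValueError):
    """Invalid parameter value."""


class UndefinedValueError(HicompError, ValueError):
    """A requested quantity is undefined for the given input."""


@dataclass(frozen=True)
class BinnedGenome:
    """Chromosome order/sizes plus a binning at a fixed resolution.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp, in genome order.
    bin_size
        Bin width in bp.
    """

    chrom_sizes: dict
    bin_size: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ParameterError(f"bin_size must be positive, got {self.bin_size}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ParameterError(f"chromosome {chrom} has non-positive size {size}")

    @property
    def chroms(self) -> list:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        # ceil division: the last bin may be short
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin of a 1-based genomic position (0-based half-open bins)."""
        if pos < 1 or pos > self.chrom_sizes[chrom]:
            raise ParameterError(
                f"position {pos} outside chromosome {chrom} "
                f"(1..{self.chrom_sizes[chrom]})"
            )
        return (pos - 1) // self.bin_size

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom)) * self.bin_size


@dataclass
class ContactMatrix:
    """A symmetric cis contact matrix for one chromosome.

    ``matrix`` is dense float64 (integer-valued when raw), symmetric.
    ``gap_mask[i]`` is True for gap bins; entries on masked rows/columns are
    meaningless and must not be used (they are kept at 0, the mask — not the
    value — is authoritative).
    """

    chrom: str
    matrix: np.ndarray
    bin_size: int
    gap_mask: np.ndarray = None
    norm: str = "raw"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError(f"matrix must be square, got shape {m.shape}")
        if np.any(m < 0):
            raise ParameterError("contact matrix has negative entries")
        rtol = 0 if self.norm == "raw" else 1e-10
        if not np.allclose(m, m.T, rtol=rtol, atol=0):
            raise ParameterError("contact matrix is not symmetric")
        self.matrix = m
        if self.gap_mask is None:
            self.gap_mask = np.zeros(m.shape[0], dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != (m.shape[0],):
                raise ParameterError("gap_mask length does not match matrix")
        if self.norm not in NORM_STATES:
            raise ParameterError(f"unknown normalization state {self.norm!r}")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def contact_total(self) -> float:
        """Total contacts: upper-triangle (incl. diagonal) sum over unmasked bins."""
        return contact_total(self.matrix, self.gap_mask)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom, self.matrix.copy(), self.bin_size,
            self.gap_mask.copy(), self.norm,
        )


def contact_total(matrix: np.ndarray, gap_mask: np.ndarray = None) -> float:
    """Upper-triangle (incl. diagonal) sum over cells with both bins unmasked."""
    m = np.asarray(matrix, dtype=float)
    if gap_mask is not None and gap_mask.any():
        keep = ~np.asarray(gap_mask, dtype=bool)
        m = m * np.outer(keep, keep)
    return float(np.triu(m).sum())


def union_gap_mask(*masks: np.ndarray) -> np.ndarray:
    """Union of gap masks — applied to both conditions before any comparison."""
    out = np.asarray(masks[0], dtype=bool).copy()
    for m in masks[1:]:
        if m.shape != out.shape:
            raise ParameterError("gap masks have different lengths")
        out |= np.asarray(m, dtype=bool)
    return out
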