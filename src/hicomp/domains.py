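"""TAD segmentation by the gamma-scaled-density dynamic program.

A candidate domain [k, l) (half-open in bins) has scaled density

    s(k, l) = (sum of M_ij over k <= i <= j < l) / (l - k)**gamma

and quality q(k, l) = s(k, l) - mu_s(l - k), where mu_s(d) is the mean of s
over all length-d windows of the chromosome.  The optimal segmentation
maximizes the sum of q over a set of disjoint domains (domains with q <= 0
are never worth including); the dynamic program

    OPT(l) = max( OPT(l-1),  max_{k <= l - min_len} OPT(k) + max(q(k,l), 0) )

finds it exactly.  Ties are broken toward more domains, then earlier left
borders, so output is deterministic.  gamma tunes domain scale (higher
gamma favors smaller domains); the working default is 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ParameterError, UndefinedValueError

logger = logging.getLogger("hicomp.domains")

DEFAULT_GAMMA = 0.8
DEFAULT_MIN_LEN = 2
DEFAULT_BORDER_TOL_BINS = 1
_TIE_RTOL = 1e-9


@dataclass
class DomainSet:
    """Sorted, non-overlapping TAD intervals [k, l) in bins for one chromosome."""

    domains: list            # list of (start, end) bin half-open
    gamma: float
    objective: float
    n_bins: int

    def borders(self) -> np.ndarray:
        """Sorted unique domain endpoints (starts and ends)."""
        b = set()
        for k, l in self.domains:
            b.add(k)
            b.add(l)
        return np.array(sorted(b), dtype=int)

    def sizes_bp(self, bin_size: int) -> np.ndarray:
        return np.array([(l - k) * bin_size for k, l in self.domains], dtype=float)


def scaled_density_quality(matrix: np.ndarray, gamma: float, min_len: int):
    """q(k, l) for all windows with l - k >= min_len (NaN elsewhere).

    Returned as an (n+1) x (n+1) array indexed [k, l].
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    # 2D prefix sums: P[a, b] = sum of m[:a, :b]
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = m.cumsum(axis=0).cumsum(axis=1)
    dcum = np.concatenate([[0.0], np.diag(m).cumsum()])

    s = np.full((n + 1, n + 1), np.nan)
    for d in range(min_len, n + 1):
        k = np.arange(0, n - d + 1)
        l = k + d
        block = P[l, l] - P[k, l] - P[l, k] + P[k, k]
        diag = dcum[l] - dcum[k]
        upper = (block + diag) / 2.0
        s[k, l] = upper / d**gamma
    q = np.full_like(s, np.nan)
    for d in range(min_len, n + 1):
        k = np.arange(0, n - d + 1)
        q[k, k + d] = s[k, k + d] - s[k, k + d].mean()
    return q


def armatus_segment(
    matrix: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    min_len: int = DEFAULT_MIN_LEN,
) -> DomainSet:
    """Optimal single-gamma segmentation of one chromosome.

    An all-zero (or constant) matrix yields no domains: every window's
    quality is 0 there.
    """
    if gamma < 0:
        raise ParameterError("gamma must be >= 0")
    if min_len < 2:
        raise ParameterError("min_len must be >= 2 bins")
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if n < min_len:
        return DomainSet([], gamma, 0.0, n)
    q = scaled_density_quality(m, gamma, min_len)
    scale = np.nanmax(np.abs(q))
    tie_eps = _TIE_RTOL * (scale if scale > 0 else 1.0)

    opt = np.zeros(n + 1)
    ndom = np.zeros(n + 1, dtype=int)
    back = np.full(n + 1, -1, dtype=int)  # k of domain [k, l), or -1 = skip bin
    for l in range(1, n + 1):
        best_val = opt[l - 1]
        best_nd = ndom[l - 1]
        best_k = -1
        kmax = l - min_len
        if kmax >= 0:
            ks = np.arange(kmax + 1)
            qs = q[ks, l]
            good = qs > 0
            if good.any():
                cand = opt[ks[good]] + qs[good]
                order = np.argsort(ks[good])  # ascending k (already sorted)
                for k, val in zip(ks[good][order], cand[order]):
                    nd = ndom[k] + 1
                    if val > best_val + tie_eps or (
                        abs(val - best_val) <= tie_eps
                        and (nd > best_nd or (nd == best_nd and (best_k == -1 or k < best_k)))
                    ):
                        best_val, best_nd, best_k = val, nd, int(k)
        opt[l] = best_val
        ndom[l] = best_nd
        back[l] = best_k

    domains = []
    l = n
    while l > 0:
        k = back[l]
        if k < 0:
            l -= 1
        else:
            domains.append((int(k), int(l)))
            l = k
    domains.reverse()
    return DomainSet(domains, gamma, float(opt[n]), n)


@dataclass
class BorderOverlap:
    n_borders_c1: int
    n_borders_c2: int
    n_shared: int
    jaccard: float
    fraction_shared_of_c1: float
    fraction_shared_of_c2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def border_overlap(domains_c1: DomainSet, domains_c2: DomainSet,
                   tol_bins: int = DEFAULT_BORDER_TOL_BINS) -> BorderOverlap:
    """One-to-one greedy nearest-neighbor border matching within +/- tol_bins."""
    b1 = domains_c1.borders()
    b2 = domains_c2.borders()
    if b1.size == 0 or b2.size == 0:
        return BorderOverlap(b1.size, b2.size, 0, 0.0, 0.0, 0.0)
    pairs = [
        (abs(int(x) - int(y)), i, j)
        for i, x in enumerate(b1)
        for j, y in enumerate(b2)
        if abs(int(x) - int(y)) <= tol_bins
    ]
    pairs.sort()
    used1, used2 = set(), set()
    shared = 0
    for _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        shared += 1
    union = b1.size + b2.size - shared
    return BorderOverlap(
        n_borders_c1=int(b1.size),
        n_borders_c2=int(b2.size),
        n_shared=shared,
        jaccard=shared / union if union else 0.0,
        fraction_shared_of_c1=shared / b1.size,
        fraction_shared_of_c2=shared / b2.size,
    )


def tad_size_stats(domains: DomainSet, bin_size: int) -> dict:
    """Median/quartiles/histogram of domain sizes in bp."""
    sizes = domains.sizes_bp(bin_size)
    if sizes.size == 0:
        raise UndefinedValueError("no domains: size statistics undefined")
    hist, edges = np.histogram(sizes, bins="auto")
    return {
        "n": int(sizes.size),
        "median_bp": float(np.median(sizes)),
        "q1_bp": float(np.percentile(sizes, 25)),
        "q3_bp": float(np.percentile(sizes, 75)),
        "mean_bp": float(sizes.mean()),
        "histogram": {"counts": hist.tolist(), "edges_bp": edges.tolist()},
    }


def inter_tad_contacts(
    matrix: np.ndarray,
    domains: DomainSet,
    compartment_labels: np.ndarray,
    gap_mask: np.ndarray = None,
) -> list:
    """Mean contact for every TAD pair lying within one compartment type.

    A TAD's compartment category is the common label of its unmasked bins
    ('A' or 'B'); TADs spanning both types are skipped.  Returns a list of
    ``(tad_a, tad_b, category, PairContact)`` for all pairs of same-category
    TADs; pairs dropped under the 50% gap rule are logged and kept flagged.
    """
    from .enrichment import pair_mean_contact

    labels = np.asarray(compartment_labels)
    cat = {}
    for dom in domains.domains:
        k, l = dom
        labs = labels[k:l]
        labs = labs[labs != "."]
        if labs.size and (labs == labs[0]).all():
            cat[dom] = str(labs[0])
    doms = [d for d in domains.domains if d in cat]
    out = []
    for a in range(len(doms)):
        for b in range(a + 1, len(doms)):
            if cat[doms[a]] != cat[doms[b]]:
                continue
            pc = pair_mean_contact(matrix, doms[a], doms[b], gap_mask)
            if pc.dropped:
                logger.info("TAD pair %s-%s dropped under the gap rule",
                            doms[a], doms[b])
            out.append((doms[a], doms[b], cat[doms[a]], pc))
    return out
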