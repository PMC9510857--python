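"""Two-condition synthetic Hi-C experiments with full planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-chromosome cis maps with power-law distance decay, compartment
plaid, TAD blocks, multiplicative per-bin biases and Poisson counting noise;
two conditions that share TAD borders but differ by contiguous compartment
switches (default ~6% of bins, majority A->B) and by strengthened B-B
contacts in condition 2; replicate pairs; and a matched expression table in
which genes in B->A-switching bins are preferentially up-regulated in
condition 2.

Expected-count model for a cell (i, j), i != j::

    E_ij = C * |i-j|**(-alpha)
             * (1 + p * [same compartment label])
             * (1 + t * [same TAD])
             * boost_ij
             * b_i * b_j

with ``boost_ij = bb_boost`` iff condition 2 and both bins are labelled B in
condition 2, else 1.  The main diagonal is zero (self-ligation bins carry no
information for any stage used here and would dominate ICE and SCC strata).
``C`` is calibrated per condition on the *boost-free* expectation so that the
expected contact total (upper-triangle sum) equals ``depth``; the B-B boost
then adds contacts on top, the way a genuine gain of B-B interactions would,
instead of being silently renormalized away.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import BinnedGenome, ContactMatrix, ParameterError

logger = logging.getLogger("hicomp.synthetic")

# Study-condition defaults: switch fraction and A->B share mirror the observed
# ~6% of 100-kb units switching, ~72% of them A->B; segment/TAD sizing gives
# ~2 Mb compartment segments and a median TAD around 240 kb at 40 kb bins.
DEFAULT_SWITCH_FRACTION = 0.06
DEFAULT_AB_TO_BA_RATIO = 0.72
DEFAULT_COMP_SEG_MEAN_BINS = 20.0
DEFAULT_TAD_MEAN_BINS = 6.0
DEFAULT_TAD_MIN_BINS = 2
DEFAULT_BB_BOOST = 2.0
BIAS_LOG_SD = 0.25  # lognormal sd of planted multiplicative bin biases

FRAGMENT_BP = 500  # synthetic restriction-fragment grid for pair streams


@dataclass
class SimulationParams:
    """Tunable knobs of the contact/expression simulator.

    decay_exponent
        alpha of the cis distance decay ``d**(-alpha)``; 1.0 is typical of
        mammalian cis maps.
    plaid_strength
        p >= 0; same-compartment cells are enriched by (1 + p).
    tad_enrichment
        t >= 0; same-TAD cells are enriched by (1 + t).
    depth
        expected total cis contacts per chromosome (upper-triangle sum).
    n_replicates
        replicates per condition.
    dispersion
        negative-binomial dispersion of expression counts (var = mu + d*mu^2).
    n_genes
        genes in the simulated expression table.
    """

    decay_exponent: float = 1.0
    plaid_strength: float = 0.3
    tad_enrichment: float = 1.0
    depth: float = 1e6
    n_replicates: int = 2
    dispersion: float = 0.1
    n_genes: int = 2000

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ParameterError("decay_exponent must be > 0")
        if self.plaid_strength < 0 or self.tad_enrichment < 0:
            raise ParameterError("plaid_strength and tad_enrichment must be >= 0")
        if self.depth <= 0 or self.n_replicates < 1:
            raise ParameterError("depth must be > 0 and n_replicates >= 1")
        if self.dispersion <= 0 or self.n_genes <= 0:
            raise ParameterError("dispersion and n_genes must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth of one planted two-condition architecture.

    Labels are per-bin 'A'/'B' arrays per chromosome; TAD borders are sorted
    bin indices (first 0, last < n_bins) shared by both conditions; ``bias``
    is the planted positive per-bin multiplier; ``de_genes`` is filled by
    :func:`simulate_expression`.
    """

    bin_size: int
    chrom_lengths: dict            # chrom -> n_bins
    labels_c1: dict                # chrom -> np.ndarray of 'A'/'B'
    labels_c2: dict
    tad_borders: dict              # chrom -> list[int]
    bias: dict                     # chrom -> np.ndarray > 0
    gap_bins: dict                 # chrom -> list[int] (planted gaps; default none)
    bb_boost: float
    switch_fraction: float
    ab_to_ba_ratio: float
    seed: int
    de_genes: list = field(default_factory=list)

    @property
    def chroms(self) -> list:
        return list(self.chrom_lengths)

    def n_bins_total(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def switched_bins(self, chrom: str) -> np.ndarray:
        return self.labels_c1[chrom] != self.labels_c2[chrom]

    def n_switched(self) -> int:
        return int(sum(self.switched_bins(c).sum() for c in self.chroms))

    def n_switched_ab(self) -> int:
        """Bins that are A in condition 1 and B in condition 2."""
        return int(
            sum(
                ((self.labels_c1[c] == "A") & (self.labels_c2[c] == "B")).sum()
                for c in self.chroms
            )
        )

    def genome(self) -> BinnedGenome:
        return BinnedGenome(
            {c: n * self.bin_size for c, n in self.chrom_lengths.items()},
            self.bin_size,
        )

    def tad_id(self, chrom: str) -> np.ndarray:
        """TAD index of each bin (borders are domain start bins)."""
        borders = np.asarray(self.tad_borders[chrom])
        return np.searchsorted(borders, np.arange(self.chrom_lengths[chrom]),
                               side="right") - 1

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        for key in ("labels_c1", "labels_c2", "bias"):
            d[key] = {c: np.asarray(v).tolist() for c, v in d[key].items()}
        d["tad_borders"] = {c: list(map(int, v)) for c, v in d["tad_borders"].items()}
        d["gap_bins"] = {c: list(map(int, v)) for c, v in d["gap_bins"].items()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        for key in ("labels_c1", "labels_c2"):
            d[key] = {c: np.asarray(v, dtype="<U1") for c, v in d[key].items()}
        d["bias"] = {c: np.asarray(v, dtype=float) for c, v in d["bias"].items()}
        return cls(**d)


def _draw_segments(rng, n_bins: int, mean_len: float, min_len: int = 1) -> list:
    """Segment lengths: geometric with the given mean, floored, tiling n_bins."""
    if n_bins < min_len:
        raise ParameterError(
            f"chromosome of {n_bins} bins shorter than one segment (min {min_len})"
        )
    p = min(1.0, 1.0 / max(mean_len - min_len + 1, 1.0))
    lengths = []
    total = 0
    while total < n_bins:
        ln = min_len - 1 + int(rng.geometric(p))
        ln = min(ln, n_bins - total)
        lengths.append(ln)
        total += ln
    return lengths


def plant_architecture(
    chrom_lengths: dict,
    bin_size: int,
    switch_fraction: float = DEFAULT_SWITCH_FRACTION,
    ab_to_ba_ratio: float = DEFAULT_AB_TO_BA_RATIO,
    tad_len_mean: float = DEFAULT_TAD_MEAN_BINS,
    tad_len_min: int = DEFAULT_TAD_MIN_BINS,
    comp_seg_len_mean: float = DEFAULT_COMP_SEG_MEAN_BINS,
    bb_boost: float = DEFAULT_BB_BOOST,
    gap_fraction: float = 0.0,
    seed: int = 0,
) -> PlantedTruth:
    """Plant a two-condition compartment/TAD architecture.

    Condition-1 labels are alternating A/B segments with geometric lengths;
    condition 2 flips whole (or truncated) segments so that the exact rounded
    targets ``round(N * switch_fraction)`` switched bins and
    ``round(switched * ab_to_ba_ratio)`` A->B bins are met — switches are
    contiguous runs, the way compartment flips appear in real maps.  TAD
    borders are shared between conditions.
    """
    if not 0 <= switch_fraction <= 0.5:
        raise ParameterError("switch_fraction must be in [0, 0.5]")
    if not 0 <= ab_to_ba_ratio <= 1:
        raise ParameterError("ab_to_ba_ratio must be in [0, 1]")
    for chrom, n in chrom_lengths.items():
        if n < 50:
            raise ParameterError(
                f"chromosome {chrom} has {n} bins; at least 50 required"
            )
    rng = np.random.default_rng(seed)

    labels_c1, tad_borders, bias, gap_bins = {}, {}, {}, {}
    segments = []  # (chrom, start, end, label) over all chromosomes
    for chrom, n in chrom_lengths.items():
        lab = np.empty(n, dtype="<U1")
        cur = "A" if rng.random() < 0.5 else "B"
        pos = 0
        for ln in _draw_segments(rng, n, comp_seg_len_mean):
            lab[pos:pos + ln] = cur
            segments.append((chrom, pos, pos + ln, cur))
            pos += ln
            cur = "B" if cur == "A" else "A"
        labels_c1[chrom] = lab

        borders = [0]
        pos = 0
        for ln in _draw_segments(rng, n, tad_len_mean, tad_len_min):
            pos += ln
            if pos < n:
                borders.append(pos)
        tad_borders[chrom] = borders

        bias[chrom] = rng.lognormal(0.0, BIAS_LOG_SD, n)
        if gap_fraction > 0:
            k = int(round(gap_fraction * n))
            gap_bins[chrom] = sorted(rng.choice(n, size=k, replace=False).tolist())
        else:
            gap_bins[chrom] = []

    n_total = int(sum(chrom_lengths.values()))
    target_switch = int(round(n_total * switch_fraction))
    target_ab = int(round(target_switch * ab_to_ba_ratio))
    target_ba = target_switch - target_ab

    labels_c2 = {c: labels_c1[c].copy() for c in chrom_lengths}

    def flip(from_label: str, n_needed: int):
        pool = [s for s in segments if s[3] == from_label]
        if sum(s[2] - s[1] for s in pool) < n_needed:
            raise ParameterError(
                f"not enough {from_label} bins to plant {n_needed} switches"
            )
        order = rng.permutation(len(pool))
        to_label = "B" if from_label == "A" else "A"
        remaining = n_needed
        for idx in order:
            if remaining == 0:
                break
            chrom, start, end, _ = pool[idx]
            take = min(end - start, remaining)
            labels_c2[chrom][start:start + take] = to_label
            remaining -= take

    flip("A", target_ab)
    flip("B", target_ba)

    return PlantedTruth(
        bin_size=bin_size,
        chrom_lengths=dict(chrom_lengths),
        labels_c1=labels_c1,
        labels_c2=labels_c2,
        tad_borders=tad_borders,
        bias=bias,
        gap_bins=gap_bins,
        bb_boost=float(bb_boost),
        switch_fraction=float(switch_fraction),
        ab_to_ba_ratio=float(ab_to_ba_ratio),
        seed=int(seed),
    )


def _labels(truth: PlantedTruth, chrom: str, condition: int) -> np.ndarray:
    if condition == 1:
        return truth.labels_c1[chrom]
    if condition == 2:
        return truth.labels_c2[chrom]
    raise ParameterError(f"condition must be 1 or 2, got {condition}")


def expected_contact_matrix(
    truth: PlantedTruth, params: SimulationParams, chrom: str, condition: int
) -> np.ndarray:
    """Expected (noise-free) contact matrix E for one chromosome/condition."""
    n = truth.chrom_lengths[chrom]
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, d ** (-params.decay_exponent), 0.0)

    tid = truth.tad_id(chrom)
    same_tad = tid[:, None] == tid[None, :]
    tadf = 1.0 + params.tad_enrichment * same_tad

    b = truth.bias[chrom]
    base = decay * tadf * np.outer(b, b)

    gaps = truth.gap_bins[chrom]
    if gaps:
        base[gaps, :] = 0.0
        base[:, gaps] = 0.0

    def with_plaid(labels):
        same_comp = labels[:, None] == labels[None, :]
        return base * (1.0 + params.plaid_strength * same_comp)

    # C is the experiment's library-scale constant: calibrated once, on the
    # condition-1 boost-free expectation, so that unswitched regions have
    # identical expectations in both conditions and the B-B boost genuinely
    # adds contacts instead of being renormalized away.
    ref = with_plaid(truth.labels_c1[chrom])
    total = np.triu(ref, 1).sum()
    if total <= 0:
        raise ParameterError(f"chromosome {chrom} has zero expected contacts")
    C = params.depth / total

    lab = _labels(truth, chrom, condition)
    E = C * (ref if condition == 1 else with_plaid(lab))
    if condition == 2 and truth.bb_boost != 1.0:
        bb = (lab == "B")[:, None] & (lab == "B")[None, :]
        E = np.where(bb, E * truth.bb_boost, E)
    return E


def simulate_contact_map(
    truth: PlantedTruth,
    params: SimulationParams,
    condition: int,
    replicate_seed: int,
) -> dict:
    """Poisson-sample one replicate: chrom -> raw ContactMatrix (zero diagonal)."""
    rng = np.random.default_rng(replicate_seed)
    out = {}
    for chrom in truth.chroms:
        E = expected_contact_matrix(truth, params, chrom, condition)
        upper = rng.poisson(np.triu(E, 1))
        m = (upper + upper.T).astype(float)
        mask = np.zeros(truth.chrom_lengths[chrom], dtype=bool)
        gaps = truth.gap_bins[chrom]
        if gaps:
            mask[gaps] = True
        out[chrom] = ContactMatrix(chrom, m, truth.bin_size, mask, "raw")
    return out


def truth_switch_categories(truth: PlantedTruth, chrom: str) -> np.ndarray:
    """Per-bin planted switch category (A-common/B-common/AtoB/BtoA)."""
    l1, l2 = truth.labels_c1[chrom], truth.labels_c2[chrom]
    cats = np.empty(l1.size, dtype="<U8")
    cats[(l1 == "A") & (l2 == "A")] = "A-common"
    cats[(l1 == "B") & (l2 == "B")] = "B-common"
    cats[(l1 == "A") & (l2 == "B")] = "AtoB"
    cats[(l1 == "B") & (l2 == "A")] = "BtoA"
    return cats


# --------------------------------------------------------------------------
# pair-record streams
# --------------------------------------------------------------------------

PAIRS_COLUMNS = (
    "readID chrom1 pos1 chrom2 pos2 strand1 strand2 frag1 frag2 mapq1 mapq2"
).split()


def simulate_pairs(
    truth: PlantedTruth,
    params: SimulationParams,
    n_pairs: int,
    artifact_rates: dict = None,
    seed: int = 0,
    trans_fraction: float = 0.0,
    condition: int = 1,
) -> list:
    """Emit a pairs-dialect text stream (list of lines, '#' headers first).

    ``artifact_rates`` gives the fractions of low-MAPQ, same-fragment and
    dangling records (keys ``low_mapq``, ``same_fragment``, ``dangling``);
    the remainder are valid, of which ``trans_fraction`` are trans.  Valid
    cis pairs are drawn from the expected contact map, so binning the stream
    reproduces the planted architecture.
    """
    rates = dict(low_mapq=0.0, same_fragment=0.0, dangling=0.0)
    if artifact_rates:
        unknown = set(artifact_rates) - set(rates)
        if unknown:
            raise ParameterError(f"unknown artifact rate keys: {sorted(unknown)}")
        rates.update(artifact_rates)
    if any(r < 0 for r in rates.values()) or sum(rates.values()) > 1:
        raise ParameterError("artifact rates must be >= 0 and sum to <= 1")
    if not 0 <= trans_fraction <= 1:
        raise ParameterError("trans_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    chroms = truth.chroms
    genome = truth.genome()
    bs = truth.bin_size
    csizes = np.array([genome.chrom_sizes[c] for c in chroms])

    # class per record: 0 valid, 1 low_mapq, 2 same_fragment, 3 dangling
    p_valid = 1.0 - sum(rates.values())
    cls = rng.choice(
        4, size=n_pairs,
        p=[p_valid, rates["low_mapq"], rates["same_fragment"], rates["dangling"]],
    )
    is_trans = (cls == 0) & (rng.random(n_pairs) < trans_fraction)

    chrom_w = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    cidx1 = rng.choice(len(chroms), size=n_pairs, p=chrom_w)
    cidx2 = cidx1.copy()
    strand1 = np.where(rng.random(n_pairs) < 0.5, "+", "-")
    strand2 = np.where(rng.random(n_pairs) < 0.5, "+", "-")
    mapq1 = rng.integers(31, 61, n_pairs)
    mapq2 = rng.integers(31, 61, n_pairs)
    low = cls == 1
    mapq1[low] = rng.integers(0, 31, int(low.sum()))
    pos1 = np.zeros(n_pairs, dtype=np.int64)
    pos2 = np.zeros(n_pairs, dtype=np.int64)

    # valid-looking cis pairs: cells drawn from the expected contact map
    cis_valid = (cls <= 1) & ~is_trans
    for ci, chrom in enumerate(chroms):
        sel = cis_valid & (cidx1 == ci)
        k = int(sel.sum())
        if k == 0:
            continue
        E = np.triu(expected_contact_matrix(truth, params, chrom, condition), 1)
        probs = E.ravel() / E.sum()
        n = truth.chrom_lengths[chrom]
        cells = rng.choice(n * n, size=k, p=probs)
        i, j = np.divmod(cells, n)
        size_i = np.minimum(bs, csizes[ci] - i * bs)
        size_j = np.minimum(bs, csizes[ci] - j * bs)
        pos1[sel] = i * bs + rng.integers(1, size_i + 1)
        pos2[sel] = j * bs + rng.integers(1, size_j + 1)

    k = int(is_trans.sum())
    if k:
        if len(chroms) < 2:
            raise ParameterError("trans pairs need at least 2 chromosomes")
        cidx2[is_trans] = (
            cidx1[is_trans] + rng.integers(1, len(chroms), k)
        ) % len(chroms)
        pos1[is_trans] = rng.integers(1, csizes[cidx1[is_trans]] + 1)
        pos2[is_trans] = rng.integers(1, csizes[cidx2[is_trans]] + 1)

    for c in (2, 3):
        sel = cls == c
        k = int(sel.sum())
        if k == 0:
            continue
        frag_start = rng.integers(0, csizes[cidx1[sel]] // FRAGMENT_BP - 1)
        if c == 2:  # same restriction fragment, tiny separation
            pos1[sel] = frag_start * FRAGMENT_BP + rng.integers(1, 250, k)
            pos2[sel] = pos1[sel] + rng.integers(1, 240, k)
        else:  # dangling: < 500 bp apart but crossing a fragment boundary
            pos1[sel] = frag_start * FRAGMENT_BP + 400
            pos2[sel] = pos1[sel] + rng.integers(150, 450, k)

    frag1 = cidx1 * 10**7 + (pos1 - 1) // FRAGMENT_BP
    frag2 = cidx2 * 10**7 + (pos2 - 1) // FRAGMENT_BP

    lines = ["## pairs format v1.0", "#columns: " + " ".join(PAIRS_COLUMNS)]
    names = np.asarray(chroms)
    lines.extend(
        f"read{k}\t{names[cidx1[k]]}\t{pos1[k]}\t{names[cidx2[k]]}\t{pos2[k]}"
        f"\t{strand1[k]}\t{strand2[k]}\t{frag1[k]}\t{frag2[k]}"
        f"\t{mapq1[k]}\t{mapq2[k]}"
        for k in range(n_pairs)
    )
    return lines


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

# Active (A) chromatin is transcribed more: baseline mean expression of genes
# in A bins (condition-1 labels) exceeds B-bin genes by this log2 amount.
# This is what lets the PC1 sign be oriented by expression density.
BASELINE_A_MINUS_B_LOG2 = 2.0
BASELINE_MEAN_COUNT = 100.0
BASELINE_LOG_SD = 0.7  # natural-log sd of per-gene baseline means


def simulate_expression(
    truth: PlantedTruth,
    params: SimulationParams,
    effect_log2fc: float = 3.0,
    seed: int = 0,
):
    """Simulate an expression experiment matched to the planted architecture.

    Returns ``(counts, annotation)``: a genes x (2 * n_replicates) integer
    count DataFrame (columns ``c1_r*`` then ``c2_r*``) and a gene annotation
    DataFrame (gene_id, chrom, start, end, length; 0-based half-open bp).
    Genes are placed uniformly over bins; genes whose bin is B in condition 1
    and A in condition 2 get their condition-2 mean multiplied by
    ``2**effect_log2fc``; their ids are recorded in ``truth.de_genes``.
    Counts are negative binomial with ``var = mu + dispersion * mu**2``.
    """
    import pandas as pd

    if params.n_genes < 100:
        raise ParameterError("n_genes must be >= 100")
    rng = np.random.default_rng(seed)
    chroms = truth.chroms
    n_bins = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    bs = truth.bin_size

    chrom_of = rng.choice(len(chroms), size=params.n_genes, p=n_bins / n_bins.sum())
    rows = []
    mu1 = np.empty(params.n_genes)
    mu2 = np.empty(params.n_genes)
    de_genes = []
    for g in range(params.n_genes):
        chrom = chroms[chrom_of[g]]
        b = int(rng.integers(0, truth.chrom_lengths[chrom]))
        length = int(rng.integers(500, 5001))
        half = length // 2
        lo = b * bs + half
        hi = (b + 1) * bs - (length - half)
        mid = int(rng.integers(lo, max(hi, lo + 1)))
        start, end = mid - half, mid - half + length
        gene_id = f"gene{g:05d}"
        rows.append((gene_id, chrom, start, end, length))

        lab1 = truth.labels_c1[chrom][b]
        lab2 = truth.labels_c2[chrom][b]
        base = BASELINE_MEAN_COUNT * float(rng.lognormal(0.0, BASELINE_LOG_SD))
        if lab1 == "B":
            base /= 2.0 ** BASELINE_A_MINUS_B_LOG2
        mu1[g] = base
        if lab1 == "B" and lab2 == "A":
            mu2[g] = base * 2.0 ** effect_log2fc
            de_genes.append(gene_id)
        else:
            mu2[g] = base

    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "length"]
    )

    def nb(mu, size):
        r = 1.0 / params.dispersion
        return rng.negative_binomial(r, r / (r + mu), size=size)

    cols = {}
    for rep in range(params.n_replicates):
        cols[f"c1_r{rep + 1}"] = nb(mu1, params.n_genes)
    for rep in range(params.n_replicates):
        cols[f"c2_r{rep + 1}"] = nb(mu2, params.n_genes)
    counts = pd.DataFrame(cols, index=annotation["gene_id"])
    truth.de_genes = de_genes
    return counts, annotation
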