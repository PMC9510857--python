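"""Valid-pair filtering and binning of mapped Hi-C pair records.

Input is a pairs-dialect TSV (header lines start with ``#``) with columns::

    readID chrom1 pos1 chrom2 pos2 strand1 strand2 frag1 frag2 mapq1 mapq2

Filtering keeps a read pair iff both mates map with MAPQ larger than
``mapq_min`` (default 30, i.e. keep iff both >= 31), the mates are on
different restriction fragments, and — for cis pairs — the separating
genomic distance is at least ``dangling_max_bp`` (default 500 bp; shorter
cis pairs are unligated "dangling ends").  The rules are applied in the
fixed precedence MAPQ -> same-fragment -> dangling so that every input
record lands in exactly one FilterStats bucket.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple

import numpy as np

from .core import BinnedGenome, ContactMatrix, HicompError, UndefinedValueError

logger = logging.getLogger("hicomp.pairs")

DEFAULT_MAPQ_MIN = 30
DEFAULT_DANGLING_MAX_BP = 500


class PairRecord(NamedTuple):
    read_id: str
    chrom1: str
    pos1: int        # 1-based bp
    chrom2: str
    pos2: int
    strand1: str
    strand2: str
    frag1: int
    frag2: int
    mapq1: int
    mapq2: int

    @property
    def is_cis(self) -> bool:
        return self.chrom1 == self.chrom2


class MalformedRecordError(HicompError):
    def __init__(self, lineno, message):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class FilterStats:
    """Disjoint bookkeeping of the pair filter.

    ``n_input = n_low_mapq + n_same_fragment + n_dangling + n_valid`` and
    ``n_valid = n_cis + n_trans``.
    """

    n_input: int = 0
    n_low_mapq: int = 0
    n_same_fragment: int = 0
    n_dangling: int = 0
    n_valid: int = 0
    n_cis: int = 0
    n_trans: int = 0

    def check(self):
        assert self.n_input == (
            self.n_low_mapq + self.n_same_fragment + self.n_dangling + self.n_valid
        )
        assert self.n_valid == self.n_cis + self.n_trans

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def parse_pairs(lines: Iterable[str], strict: bool = True) -> Iterable[PairRecord]:
    """Yield PairRecords from a pairs-dialect text stream.

    Malformed lines raise :class:`MalformedRecordError` carrying the line
    number under ``strict``; under lenient mode they are logged and skipped.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if len(fields) != 11:
                raise ValueError(f"expected 11 columns, got {len(fields)}")
            rec = PairRecord(
                fields[0], fields[1], int(fields[2]), fields[3], int(fields[4]),
                fields[5], fields[6], int(fields[7]), int(fields[8]),
                int(fields[9]), int(fields[10]),
            )
            if rec.pos1 < 1 or rec.pos2 < 1:
                raise ValueError("positions must be >= 1")
            if rec.mapq1 < 0 or rec.mapq2 < 0:
                raise ValueError("MAPQ must be >= 0")
        except ValueError as exc:
            if strict:
                raise MalformedRecordError(lineno, str(exc)) from exc
            logger.warning("skipping malformed pair record at line %d: %s", lineno, exc)
            continue
        yield rec


def filter_pairs(
    records: Iterable[PairRecord],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    dangling_max_bp: int = DEFAULT_DANGLING_MAX_BP,
):
    """Apply the validity rules; return (valid records, FilterStats)."""
    stats = FilterStats()
    valid = []
    for rec in records:
        stats.n_input += 1
        if rec.mapq1 <= mapq_min or rec.mapq2 <= mapq_min:
            stats.n_low_mapq += 1
        elif rec.is_cis and rec.frag1 == rec.frag2:
            stats.n_same_fragment += 1
        elif rec.is_cis and abs(rec.pos2 - rec.pos1) < dangling_max_bp:
            stats.n_dangling += 1
        else:
            stats.n_valid += 1
            if rec.is_cis:
                stats.n_cis += 1
            else:
                stats.n_trans += 1
            valid.append(rec)
    stats.check()
    return valid, stats


def bin_pairs(
    records: Iterable[PairRecord],
    genome: BinnedGenome,
    strict: bool = True,
):
    """Bin filtered records into per-chromosome cis matrices.

    Returns ``(matrices, n_trans)`` where ``matrices`` maps chromosome to a
    raw :class:`ContactMatrix`.  Each cis record increments the symmetric
    cell pair once (contact_total counts it once); trans records are counted
    but not matrixed.  Positions beyond the chromosome end raise under
    strict mode and are skipped (logged) otherwise.
    """
    counts = {c: np.zeros((genome.n_bins(c), genome.n_bins(c))) for c in genome.chroms}
    n_trans = 0
    for rec in records:
        if not rec.is_cis:
            n_trans += 1
            continue
        try:
            i = genome.bin_index(rec.chrom1, rec.pos1)
            j = genome.bin_index(rec.chrom2, rec.pos2)
        except (KeyError, HicompError) as exc:
            if strict:
                raise
            logger.warning("skipping unbinnable record %s: %s", rec.read_id, exc)
            continue
        i, j = min(i, j), max(i, j)
        counts[rec.chrom1][i, j] += 1
        if i != j:
            counts[rec.chrom1][j, i] += 1
    matrices = {
        c: ContactMatrix(c, m, genome.bin_size) for c, m in counts.items()
    }
    return matrices, n_trans


def trans_fraction(stats: FilterStats) -> float:
    """Fraction of trans interactions among valid pairs."""
    if stats.n_valid == 0:
        raise UndefinedValueError("trans fraction undefined: no valid pairs")
    return stats.n_trans / stats.n_valid
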