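"""Genomic bin grids and interval arithmetic.

Coordinates are 0-based half-open throughout (BED convention); VCF positions
are converted to 0-based at the I/O boundary.

The genome is tiled by a :class:`BinGrid` of fixed-width bins (100 bp by
default).  Bins are addressed by a single global integer id, assigned
chromosome by chromosome in the order the chromosome sizes were given, so a
bin id maps bijectively to a ``(chrom, start, end)`` interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class IntervalError(ValueError):
    """Malformed genomic interval input."""


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.  Order is preserved and
        defines the global bin-id order.
    bin_size
        Bin width in bp (default 100).  The last bin of a chromosome may be
        shorter than ``bin_size``.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = 100
    _offsets: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise IntervalError(f"bin_size must be positive, got {self.bin_size}")
        offsets: dict[str, int] = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise IntervalError(f"chromosome {chrom!r} has non-positive size {size}")
            offsets[chrom] = total
            total += self.n_bins_chrom(chrom)
        object.__setattr__(self, "_offsets", offsets)

    # -- size accounting -------------------------------------------------
    def n_bins_chrom(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return -(-size // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_chrom(c) for c in self.chrom_sizes)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    # -- id <-> interval bijection ---------------------------------------
    def bin_id(self, chrom: str, pos: int) -> int:
        """Global id of the bin containing 0-based position ``pos``."""
        if chrom not in self._offsets:
            raise IntervalError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        if not 0 <= pos < size:
            raise IntervalError(f"position {pos} outside {chrom} (size {size})")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval(self, bin_id: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin id; end is clipped to the chromosome."""
        if not 0 <= bin_id < self.n_bins:
            raise IntervalError(f"bin id {bin_id} out of range [0, {self.n_bins})")
        for chrom in self.chrom_sizes:
            n = self.n_bins_chrom(chrom)
            off = self._offsets[chrom]
            if bin_id < off + n:
                local = bin_id - off
                start = local * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[chrom])
                return chrom, start, end
        raise AssertionError("unreachable")

    def bin_intervals(self, bin_ids: Sequence[int]) -> list[tuple[str, int, int]]:
        return [self.bin_interval(int(b)) for b in bin_ids]

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global id range [lo, hi) of a chromosome's bins."""
        off = self._offsets[chrom]
        return off, off + self.n_bins_chrom(chrom)

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global ids of all bins overlapping [start, end) on ``chrom``."""
        if end <= start:
            raise IntervalError(f"empty interval {chrom}:{start}-{end}")
        size = self.chrom_sizes[chrom]
        start = max(0, start)
        end = min(size, end)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        off = self._offsets[chrom]
        first = start // self.bin_size
        last = (end - 1) // self.bin_size
        return np.arange(off + first, off + last + 1, dtype=np.int64)


# -- plain interval helpers ----------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended [start, end) intervals into a disjoint
    sorted list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise IntervalError(f"malformed interval ({s}, {e}): end <= start")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_union_overlap(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> int:
    """Total bp of [start, end) covered by the *union* of ``intervals``."""
    covered = 0
    for s, e in merge_intervals(intervals) if intervals else []:
        covered += max(0, min(end, e) - max(start, s))
    return covered


def bins_to_intervals(grid: BinGrid, bin_ids: Sequence[int]) -> list[tuple[str, int, int]]:
    """Merge a set of bin ids into maximal genomic intervals.

    Adjacent bins (consecutive global ids on the same chromosome) coalesce
    into a single interval; output is sorted genome order, disjoint.
    """
    ids = np.unique(np.asarray(list(bin_ids), dtype=np.int64))
    out: list[tuple[str, int, int]] = []
    if ids.size == 0:
        return out
    run_start = ids[0]
    prev = ids[0]
    chrom_prev, s_prev, _ = grid.bin_interval(int(ids[0]))

    def flush(lo: int, hi: int) -> None:
        c0, s0, _ = grid.bin_interval(int(lo))
        c1, _, e1 = grid.bin_interval(int(hi))
        assert c0 == c1
        out.append((c0, s0, e1))

    for b in ids[1:]:
        c, _, _ = grid.bin_interval(int(b))
        if b == prev + 1 and c == chrom_prev:
            prev = b
        else:
            flush(run_start, prev)
            run_start = prev = b
            chrom_prev = c
    flush(run_start, prev)
    return out


# -- text I/O --------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise IntervalError(f"{path}:{i}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3 (extra columns ignored); validates end > start."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise IntervalError(f"{path}:{i}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise IntervalError(f"{path}:{i}: end <= start ({start}, {end})")
            out.append((chrom, start, end))
    return out


def write_bed(records: Iterable[tuple], path) -> None:
    """Write BED rows; tuples may carry extra columns beyond chrom/start/end."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise IntervalError(f"{path}:{i}: bedGraph needs 4 columns")
            s, e = int(f[1]), int(f[2])
            if e <= s:
                raise IntervalError(f"{path}:{i}: end <= start")
            out.append((f[0], s, e, float(f[3])))
    return out
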