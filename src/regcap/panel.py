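"""Capture-panel design from per-sample DNase-I hypersensitivity signal.

The design pipeline mirrors targeted regulatory capture panels built from
open-chromatin maps: the genome is tiled into 100-bp bins, each sample's
read counts are normalized to fractions of its library, the top-N bins per
sample are ranked, rank strata are filtered by inter-sample concordance,
a per-cell-type consensus is taken, exome-overlapping bins are subtracted,
and the union across cell types is merged into target intervals annotated
with the number of cell types sharing each bin (the "sharing level").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    BinGrid,
    IntervalError,
    bins_to_intervals,
    interval_union_overlap,
    merge_intervals,
)

DEFAULT_N_TOP = 300_000
DEFAULT_BLOCK_SIZE = 50_000
# GRCh37 primary-assembly ungapped (golden path) length in bp
GRCH37_GENOME_BP = 3_095_677_412


def top_fraction_of_genome(n_top: int = DEFAULT_N_TOP, bin_size: int = 100,
                           genome_bp: int = GRCH37_GENOME_BP) -> float:
    """Fraction of the genome covered by the top-``n_top`` bins.

    With the defaults, 300,000 bins x 100 bp over GRCh37 — the "top 1%"
    selection a per-sample ranking targets.
    """
    return n_top * bin_size / genome_bp


class PanelDesignError(ValueError):
    pass


@dataclass
class SignalTrack:
    """Per-bin normalized DNase signal for one sample.

    ``signal[i]`` is reads assigned to bin i divided by total reads, so the
    values are non-negative and sum to at most 1 (exactly 1 when every read
    falls inside a grid bin).
    """

    sample_id: str
    cell_type: str
    grid: BinGrid
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.grid.n_bins,):
            raise PanelDesignError(
                f"signal length {self.signal.shape} != grid bins {self.grid.n_bins}"
            )
        if np.any(self.signal < 0):
            raise PanelDesignError("negative signal values")


@dataclass
class RankedBinSet:
    """The top-``n_top`` bins of one sample, ordered by descending signal."""

    sample_id: str
    cell_type: str
    bin_ids: np.ndarray  # rank order: bin_ids[0] is the strongest bin

    def __post_init__(self) -> None:
        self.bin_ids = np.asarray(self.bin_ids, dtype=np.int64)
        if len(np.unique(self.bin_ids)) != len(self.bin_ids):
            raise PanelDesignError("duplicate bin ids in ranked set")

    def __len__(self) -> int:
        return len(self.bin_ids)

    def as_set(self) -> set[int]:
        return set(int(b) for b in self.bin_ids)


@dataclass
class CapturePanel:
    """Merged non-coding target intervals with per-bin cell-type sharing.

    ``sharing`` maps each retained global bin id to the number of cell types
    (1..K) whose consensus set contains it.  ``intervals`` are maximal merged
    [start, end) runs of retained bins, disjoint and genome-sorted.
    ``extra_tracks`` carries appended region sets (e.g. exome, HLA baits)
    that have no sharing annotation.
    """

    grid: BinGrid
    sharing: dict[int, int]
    cell_types: list[str]
    extra_tracks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sharing:
            raise PanelDesignError("empty panel: no bins retained")
        if min(self.sharing.values()) < 1:
            raise PanelDesignError("sharing level below 1 in panel")
        self._bins = np.array(sorted(self.sharing), dtype=np.int64)
        self.intervals = bins_to_intervals(self.grid, self._bins)
        # per-chrom sorted interval arrays for O(log n) point queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.grid.chroms:
            ivs = [(s, e) for c, s, e in self.intervals if c == chrom]
            self._by_chrom[chrom] = (
                np.array([s for s, _ in ivs], dtype=np.int64),
                np.array([e for _, e in ivs], dtype=np.int64),
            )

    @property
    def bins(self) -> np.ndarray:
        return self._bins

    @property
    def total_target_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position in the merged target intervals."""
        starts, ends = self._by_chrom.get(chrom, (None, None))
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def sharing_at(self, chrom: str, pos: int) -> int:
        """Sharing level of the bin containing the position; 0 if off-panel."""
        try:
            b = self.grid.bin_id(chrom, pos)
        except IntervalError:
            return 0
        return self.sharing.get(int(b), 0)

    def sharing_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for level in self.sharing.values():
            hist[level] = hist.get(level, 0) + 1
        return dict(sorted(hist.items()))

    # -- I/O ----------------------------------------------------------------
    def to_bed(self, path) -> None:
        """BED4: one row per maximal run of equal-sharing bins."""
        rows = []
        ids = self._bins
        levels = np.array([self.sharing[int(b)] for b in ids])
        i = 0
        while i < len(ids):
            j = i
            while (
                j + 1 < len(ids)
                and ids[j + 1] == ids[j] + 1
                and levels[j + 1] == levels[i]
                and self.grid.bin_interval(int(ids[j + 1]))[0]
                == self.grid.bin_interval(int(ids[i]))[0]
            ):
                j += 1
            chrom, start, _ = self.grid.bin_interval(int(ids[i]))
            _, _, end = self.grid.bin_interval(int(ids[j]))
            rows.append((chrom, start, end, int(levels[i])))
            i = j + 1
        with open(path, "w") as fh:
            for chrom, start, end, level in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{level}\n")

    @classmethod
    def from_bed(cls, path, grid: BinGrid, cell_types: Sequence[str] = ()) -> "CapturePanel":
        sharing: dict[int, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise PanelDesignError(f"{path}:{i}: expected BED4 with sharing column")
                chrom, start, end, level = f[0], int(f[1]), int(f[2]), int(f[3])
                for b in grid.overlapping_bins(chrom, start, end):
                    sharing[int(b)] = level
        return cls(grid=grid, sharing=sharing, cell_types=list(cell_types))


# -- pipeline operations ---------------------------------------------------

def bin_and_normalize(
    coverage: Iterable[tuple[str, int, int, float]] | np.ndarray,
    grid: BinGrid,
    sample_id: str = "sample",
    cell_type: str = "NA",
) -> SignalTrack:
    """Assign read coverage to grid bins and normalize to library fraction.

    ``coverage`` is either a per-bin count vector (length ``grid.n_bins``) or
    bedGraph-style records ``(chrom, start, end, value)``.  Record values are
    apportioned to bins by bp-overlap fraction, which conserves total mass
    regardless of how records straddle bin boundaries.
    """
    counts = np.zeros(grid.n_bins, dtype=float)
    if isinstance(coverage, np.ndarray) and coverage.ndim == 1:
        if coverage.shape[0] != grid.n_bins:
            raise PanelDesignError(
                f"count vector length {coverage.shape[0]} != {grid.n_bins} bins"
            )
        counts[:] = coverage
    else:
        unknown: set[str] = set()
        for chrom, start, end, value in coverage:
            if chrom not in grid.chrom_sizes:
                unknown.add(chrom)
                continue
            span = end - start
            for b in grid.overlapping_bins(chrom, start, end):
                bc, bs, be = grid.bin_interval(int(b))
                frac = (min(end, be) - max(start, bs)) / span
                counts[b] += value * frac
        if unknown:
            raise PanelDesignError(
                "coverage on chromosomes absent from the grid: "
                + ", ".join(sorted(unknown))
            )
    total = counts.sum()
    if total <= 0:
        raise PanelDesignError("total read count is zero; cannot normalize")
    return SignalTrack(sample_id=sample_id, cell_type=cell_type, grid=grid, signal=counts / total)


def select_top_bins(track: SignalTrack, n_top: int = DEFAULT_N_TOP) -> RankedBinSet:
    """Rank bins by descending signal and keep the top ``n_top``.

    Ties are broken by genome order (chromosome order, then start), so the
    selection is deterministic.  Zero-signal bins are rankable, so ``n_top``
    bins are always returned when the grid is large enough.
    """
    if n_top < 1:
        raise PanelDesignError(f"n_top must be >= 1, got {n_top}")
    n = track.grid.n_bins
    if n_top > n:
        warnings.warn(
            f"n_top={n_top} exceeds total bins {n}; returning all bins", stacklevel=2
        )
        n_top = n
    # stable argsort on -signal: equal signals keep ascending bin-id order
    order = np.argsort(-track.signal, kind="stable")[:n_top]
    return RankedBinSet(sample_id=track.sample_id, cell_type=track.cell_type, bin_ids=order)


def consensus_bins(ranked_sets: Sequence[RankedBinSet]) -> set[int]:
    """Per-cell-type replicate consensus.

    With m >= 3 samples a bin is kept if present in at least ceil(m/2) of
    them; with exactly two samples it must be present in both; a single
    sample's set is kept unchanged.
    """
    if not ranked_sets:
        raise PanelDesignError("consensus_bins: empty input")
    cell_types = {r.cell_type for r in ranked_sets}
    if len(cell_types) > 1:
        raise PanelDesignError(f"consensus across mixed cell types: {sorted(cell_types)}")
    m = len(ranked_sets)
    sets = [r.as_set() for r in ranked_sets]
    if m == 1:
        return sets[0]
    if m == 2:
        return sets[0] & sets[1]
    need = -(-m // 2)  # ceil(m/2)
    count: dict[int, int] = {}
    for s in sets:
        for b in s:
            count[b] = count.get(b, 0) + 1
    return {b for b, c in count.items() if c >= need}


def filter_rank_blocks(
    ranked_sets: Sequence[RankedBinSet],
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_overlap: float = 0.5,
) -> tuple[list[int], list[RankedBinSet]]:
    """Drop rank strata whose inter-sample concordance is poor.

    Each sample's ranked list is cut into consecutive blocks of
    ``block_size`` bins (ranks [0,B), [B,2B), ...).  Stratum j survives iff
    the mean over sample pairs of |intersection of their stratum-j sets| /
    block size is >= ``min_overlap``.  Returns the retained stratum indices
    and each sample's ranked set restricted to surviving strata (rank order
    preserved).  A single-sample cell type retains every stratum.
    """
    if not ranked_sets:
        raise PanelDesignError("filter_rank_blocks: empty input")
    min_len = min(len(r) for r in ranked_sets)
    if min_len < block_size:
        raise PanelDesignError(
            f"ranked sets shorter ({min_len}) than block_size ({block_size})"
        )
    n_strata = -(-min_len // block_size)
    m = len(ranked_sets)
    retained: list[int] = []
    for j in range(n_strata):
        lo, hi = j * block_size, min((j + 1) * block_size, min_len)
        width = hi - lo
        if m == 1:
            retained.append(j)
            continue
        strata = [set(int(b) for b in r.bin_ids[lo:hi]) for r in ranked_sets]
        overlaps = [
            len(strata[i] & strata[k]) / width
            for i in range(m)
            for k in range(i + 1, m)
        ]
        if float(np.mean(overlaps)) >= min_overlap:
            retained.append(j)
    surviving = []
    for r in ranked_sets:
        keep = np.concatenate(
            [r.bin_ids[j * block_size : min((j + 1) * block_size, min_len)] for j in retained]
        ) if retained else np.empty(0, dtype=np.int64)
        surviving.append(
            RankedBinSet(sample_id=r.sample_id, cell_type=r.cell_type, bin_ids=keep)
        )
    return retained, surviving


def subtract_exome(
    bins: Iterable[int],
    exome: Sequence[tuple[str, int, int]],
    grid: BinGrid,
    min_frac: float = 0.5,
) -> set[int]:
    """Remove bins whose overlap with the exome-interval union is >= min_frac
    of the bin length."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, (chrom, s, e) in enumerate(exome):
        if e <= s:
            raise PanelDesignError(f"exome interval {i + 1}: end <= start ({s}, {e})")
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    kept: set[int] = set()
    for b in bins:
        chrom, s, e = grid.bin_interval(int(b))
        ov = interval_union_overlap(s, e, merged.get(chrom, []))
        if ov < min_frac * (e - s):
            kept.add(int(b))
    return kept


def build_panel(
    cell_type_bin_sets: Mapping[str, Iterable[int]],
    grid: BinGrid,
    exome: Sequence[tuple[str, int, int]] = (),
    extra_regions: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
    exome_min_frac: float = 0.5,
) -> CapturePanel:
    """Combine per-cell-type consensus bin sets into a capture panel.

    The union of all cell types' bins is taken, exome-overlapping bins are
    subtracted, sharing levels are counted per bin, and adjacent bins are
    merged into maximal target intervals.  ``extra_regions`` (e.g. the exome
    or HLA baits themselves) are appended as separate tracks without sharing
    annotation.
    """
    if not cell_type_bin_sets:
        raise PanelDesignError("build_panel: need at least one cell type")
    sets = {ct: set(int(b) for b in bins) for ct, bins in cell_type_bin_sets.items()}
    union: set[int] = set().union(*sets.values())
    if exome:
        union = subtract_exome(union, exome, grid, min_frac=exome_min_frac)
    if not union:
        raise PanelDesignError("build_panel: no bins survive exome subtraction")
    sharing = {b: sum(b in s for s in sets.values()) for b in union}
    return CapturePanel(
        grid=grid,
        sharing=sharing,
        cell_types=list(sets),
        extra_tracks={k: list(v) for k, v in (extra_regions or {}).items()},
    )


def design_panel(
    tracks_by_cell_type: Mapping[str, Sequence[SignalTrack]],
    grid: BinGrid,
    exome: Sequence[tuple[str, int, int]] = (),
    n_top: int = DEFAULT_N_TOP,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_overlap: float = 0.5,
    exome_min_frac: float = 0.5,
) -> CapturePanel:
    """Full design: rank, block-filter, consensus, subtract exome, merge."""
    consensus: dict[str, set[int]] = {}
    for ct, tracks in tracks_by_cell_type.items():
        ranked = [select_top_bins(t, n_top=n_top) for t in tracks]
        _, surviving = filter_rank_blocks(ranked, block_size=block_size, min_overlap=min_overlap)
        consensus[ct] = consensus_bins(surviving)
    return build_panel(consensus, grid, exome=exome, exome_min_frac=exome_min_frac)


def design_report(panel: CapturePanel, consensus: Mapping[str, Iterable[int]] | None = None):
    """Per-cell-type and per-sharing-level bin accounting as a DataFrame."""
    import pandas as pd

    rows = [
        {"metric": "total_target_bp", "value": panel.total_target_bp},
        {"metric": "n_bins", "value": len(panel.bins)},
        {"metric": "n_intervals", "value": len(panel.intervals)},
    ]
    for level, n in panel.sharing_histogram().items():
        rows.append({"metric": f"bins_sharing_{level}", "value": n})
    if consensus:
        for ct, bins in consensus.items():
            rows.append({"metric": f"consensus_bins_{ct}", "value": len(set(bins))})
    return pd.DataFrame(rows)
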