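"""Capture sensitivity and region-set enrichment statistics.

Given a capture panel and sets of GWAS/eQTL hit SNPs (with optional
linkage-disequilibrium proxies, r^2 > 0.9), these routines quantify what
fraction of hits the panel captures, and test whether hits are enriched in
the panel relative to alternative region sets or matched random-bin nulls
(Fisher's exact test, and an empirical permutation-style test over random
draws of an equal number of bins).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import BinGrid
from .panel import CapturePanel


class EnrichmentError(ValueError):
    pass


@dataclass
class SnpHitSet:
    """A labelled set of lead SNPs with optional LD-proxy positions.

    ``snps`` maps snp id -> (chrom, pos) with 0-based positions;
    ``proxies`` maps lead snp id -> list of (chrom, pos) proxy positions.
    """

    label: str
    snps: dict[str, tuple[str, int]]
    proxies: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.proxies) - set(self.snps)
        if extra:
            raise EnrichmentError(f"proxy map keys not in hit set: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.snps)

    @classmethod
    def from_tables(cls, hits: pd.DataFrame, proxies: pd.DataFrame | None = None,
                    label: str = "hits") -> "SnpHitSet":
        """Build from TSV-shaped frames: hits(id, chrom, pos[, category]),
        proxies(lead_id, proxy_chrom, proxy_pos[, r2])."""
        snps = {str(r.id): (str(r.chrom), int(r.pos)) for r in hits.itertuples()}
        pmap: dict[str, list[tuple[str, int]]] = {}
        if proxies is not None:
            for r in proxies.itertuples():
                lead = str(r.lead_id)
                if lead in snps:
                    pmap.setdefault(lead, []).append((str(r.proxy_chrom), int(r.proxy_pos)))
        return cls(label=label, snps=snps, proxies=pmap)


@dataclass
class EnrichmentResult:
    """2x2 contingency outcome: table (a,b,c,d), odds ratio, p, fold."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    fold_enrichment: float
    null_summary: dict | None = None


def capture_fraction(
    hits: SnpHitSet, panel: CapturePanel
) -> tuple[float, int, set[str]]:
    """Fraction of lead SNPs captured directly or through an LD proxy.

    A lead counts as captured iff its own position or at least one proxy
    position lies inside a panel target interval.  Returns (fraction,
    captured count, ids of captured leads).
    """
    if len(hits) == 0:
        raise EnrichmentError("empty hit set")
    captured: set[str] = set()
    for snp_id, (chrom, pos) in hits.snps.items():
        positions = [(chrom, pos)] + hits.proxies.get(snp_id, [])
        if any(panel.contains(c, p) for c, p in positions):
            captured.add(snp_id)
    return len(captured) / len(hits), len(captured), captured


def sample_random_bins(
    universe: np.ndarray | Sequence[int],
    n_bins: int,
    iterations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Draw ``iterations`` sets of ``n_bins`` distinct bins uniformly from the
    universe (the grid minus any exclusion mask, applied by the caller)."""
    universe = np.asarray(universe, dtype=np.int64)
    if universe.size < n_bins:
        raise EnrichmentError(
            f"universe of {universe.size} bins smaller than requested {n_bins}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [rng.choice(universe, size=n_bins, replace=False) for _ in range(iterations)]


def fisher_enrichment(
    hits_in_a: int, hits_out_a: int, hits_in_b: int, hits_out_b: int
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 table
    [[hits_in_a, hits_out_a], [hits_in_b, hits_out_b]].

    Odds ratio is the cross-product ratio a*d/(b*c); a zero denominator with a
    positive numerator yields the +inf sentinel, 0/0 yields NaN.  Fold
    enrichment is the ratio of row proportions a/(a+b) over c/(c+d).
    """
    a, b, c, d = (int(x) for x in (hits_in_a, hits_out_a, hits_in_b, hits_out_b))
    if min(a, b, c, d) < 0:
        raise EnrichmentError("negative count in 2x2 table")
    if a + b + c + d == 0:
        raise EnrichmentError("all-zero 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if a + b == 0 or c + d == 0 or c == 0:
        fold = math.inf if a > 0 else math.nan
    else:
        fold = (a / (a + b)) / (c / (c + d))
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=float(p),
                            fold_enrichment=fold)


def empirical_enrichment(
    observed_overlap: int,
    null_overlaps: Sequence[int] | np.ndarray,
) -> EnrichmentResult:
    """Permutation-style empirical enrichment against random region draws.

    p = (1 + #{null >= observed}) / (1 + iterations) — the add-one estimator,
    never exactly zero; fold = observed / mean(null).
    """
    null = np.asarray(null_overlaps, dtype=float)
    if null.size < 100:
        raise EnrichmentError(f"need >= 100 null iterations, got {null.size}")
    n_ge = int(np.sum(null >= observed_overlap))
    p = (1 + n_ge) / (1 + null.size)
    mean_null = float(null.mean())
    if mean_null == 0:
        warnings.warn("zero mean null overlap; fold reported as inf", stacklevel=2)
        fold = math.inf
    else:
        fold = observed_overlap / mean_null
    summary = {
        "iterations": int(null.size),
        "null_mean": mean_null,
        "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
        "null_max": float(null.max()),
    }
    # the 2x2 slots are not meaningful for the empirical test; report the
    # observed count in `a` and leave the rest zero
    return EnrichmentResult(a=int(observed_overlap), b=0, c=0, d=0,
                            odds_ratio=math.nan, p_value=float(p),
                            fold_enrichment=fold, null_summary=summary)


def count_hits_in_bins(
    hits: SnpHitSet, bins: Iterable[int], grid: BinGrid, use_proxies: bool = True
) -> int:
    """Number of lead SNPs whose own (or proxy) position falls in a bin set."""
    bin_set = set(int(b) for b in bins)
    n = 0
    for snp_id, (chrom, pos) in hits.snps.items():
        positions = [(chrom, pos)]
        if use_proxies:
            positions += hits.proxies.get(snp_id, [])
        for c, p in positions:
            try:
                b = grid.bin_id(c, p)
            except Exception:
                continue
            if int(b) in bin_set:
                n += 1
                break
    return n


def empirical_panel_enrichment(
    hits: SnpHitSet,
    panel: CapturePanel,
    universe: np.ndarray,
    iterations: int = 1000,
    seed: int = 0,
    use_proxies: bool = True,
) -> EnrichmentResult:
    """Observed hit overlap with the panel vs random equal-size bin draws."""
    observed = count_hits_in_bins(hits, panel.bins, panel.grid, use_proxies=use_proxies)
    draws = sample_random_bins(universe, n_bins=len(panel.bins),
                               iterations=iterations, seed=seed)
    null = [count_hits_in_bins(hits, d, panel.grid, use_proxies=use_proxies) for d in draws]
    return empirical_enrichment(observed, null)
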