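"""Allele-specific expression (ASE) statistics and rare-variant enrichment.

Allelic imbalance is measured from haplotype-resolved RNA-seq allele counts
as the fold difference max/min between the two alleles, so 1 means equal
expression.  Transcripts are binned into allelic-imbalance (AI) classes:
equal (fold <= 1.5), intermediate (1.5 < fold < 2), AI (2 <= fold <= 9) and
excluded (fold > 9, enriched for imprinting and artefacts — dropped from
enrichment denominators).  The enrichment routines then ask whether rare and
novel variants concentrate near AI transcripts: in the +/-20 kb gene
vicinity, in DHS bins whose accessibility correlates with the promoter
across datasets, in Hi-C-linked regions, and as a function of distance from
the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import BinGrid
from .variants import TranscriptModel

AI_EQUAL_MAX = 1.5
AI_LOW = 2.0
AI_HIGH = 9.0
DEFAULT_VICINITY = 20_000
DEFAULT_AI_LEVELS = (1.5, 2.0, 2.5, 3.0, 3.5)
R_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


class AseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fold difference and AI class
# ---------------------------------------------------------------------------

def compute_fold_difference(
    count_a: float, count_b: float, zero_policy: str = "pseudocount"
) -> tuple[float | None, str | None]:
    """Fold difference (most abundant / least abundant allele) and AI class.

    Both counts zero drops the record (returns (None, None)).  A single zero
    count gets a +1 pseudocount on both alleles by default
    (``zero_policy='drop'`` drops instead).
    """
    a, b = float(count_a), float(count_b)
    if a < 0 or b < 0:
        raise AseError("negative allele count")
    if a == 0 and b == 0:
        return None, None
    if a == 0 or b == 0:
        if zero_policy == "drop":
            return None, None
        a, b = a + 1, b + 1
    fold = max(a, b) / min(a, b)
    return fold, ai_class(fold)


def ai_class(fold: float) -> str:
    if fold > AI_HIGH:
        return "excluded"
    if fold >= AI_LOW:
        return "ai"
    if fold > AI_EQUAL_MAX:
        return "intermediate"
    return "equal"


def annotate_records(records: pd.DataFrame, zero_policy: str = "pseudocount") -> pd.DataFrame:
    """Attach ``fold`` and ``ai_class`` to an allele-count table
    (columns: transcript, individual, hap_a, hap_b, n_snps)."""
    folds, classes, keep = [], [], []
    for r in records.itertuples():
        fold, cls = compute_fold_difference(r.hap_a, r.hap_b, zero_policy)
        keep.append(fold is not None)
        folds.append(fold)
        classes.append(cls)
    n_drop = len(keep) - sum(keep)
    if n_drop:
        warnings.warn(f"{n_drop} records with zero counts on both alleles dropped",
                      stacklevel=2)
    out = records.loc[keep].copy()
    out["fold"] = [f for f in folds if f is not None]
    out["ai_class"] = [c for c in classes if c is not None]
    return out.reset_index(drop=True)


def pool_by_transcript(records: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript summary: median fold across individuals, mean
    informative-SNP count, and the AI class of the median fold."""
    g = records.groupby("transcript", sort=True)
    out = pd.DataFrame({
        "fold": g["fold"].median(),
        "n_snps": g["n_snps"].mean(),
        "n_individuals": g.size(),
    }).reset_index()
    out["ai_class"] = [ai_class(f) for f in out["fold"]]
    return out


# ---------------------------------------------------------------------------
# Transcript filtering
# ---------------------------------------------------------------------------

def filter_transcripts(
    table: pd.DataFrame, association_p_max: float = 1e-5
) -> pd.DataFrame:
    """Keep transcripts with ASE-association p strictly below the threshold,
    one per gene — the best-covered isoform (highest normalized read count).

    ``table`` columns: gene, transcript, assoc_p, total_count.
    """
    kept = table[table["assoc_p"] < association_p_max]
    if kept.empty:
        return kept.copy()
    idx = kept.sort_values(["total_count", "transcript"],
                           ascending=[False, True], kind="stable") \
              .drop_duplicates(subset="gene", keep="first").index
    return table.loc[sorted(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Vicinity variant counting
# ---------------------------------------------------------------------------

def vicinity_variant_counts(
    transcripts: Sequence[TranscriptModel],
    variants: pd.DataFrame,
    window: int = DEFAULT_VICINITY,
    predicate: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-transcript counts of nearby variants by frequency class.

    A variant counts for a transcript when its position lies in the closed
    interval [gene start - window, gene end + window].  ``predicate``
    (boolean, aligned with ``variants``) restricts which variants are
    eligible (e.g. non-coding only, or in-DHS only).
    """
    v = variants if predicate is None else variants.loc[predicate.values]
    rows = []
    for t in transcripts:
        pos0 = v["pos"].to_numpy() - 1
        in_win = (v["chrom"].to_numpy() == t.chrom) & \
                 (pos0 >= t.start - window) & (pos0 <= t.end - 1 + window)
        sub = v.loc[in_win]
        counts = sub["freq_class"].value_counts()
        rows.append({
            "transcript": t.transcript_id,
            "n_common": int(counts.get("common", 0)),
            "n_rare": int(counts.get("rare", 0)),
            "n_novel": int(counts.get("novel", 0)),
        })
    out = pd.DataFrame(rows)
    out["n_rare_novel"] = out["n_rare"] + out["n_novel"]
    return out


# ---------------------------------------------------------------------------
# Adjusted AI proportions across imbalance levels
# ---------------------------------------------------------------------------

def adjusted_ai_proportions(
    per_transcript: pd.DataFrame,
    ai_levels: Sequence[float] = DEFAULT_AI_LEVELS,
    upper: float = AI_HIGH,
    classes: Sequence[str] = ("common", "rare", "novel"),
) -> pd.DataFrame:
    """Proportion of AI transcripts with >=1 vicinity variant of each class,
    at increasing imbalance cut-offs, adjusted for informative-SNP count.

    ``per_transcript`` needs ``fold``, ``n_snps`` and ``n_<class>`` columns.
    For each level L the transcripts with fold in [L, upper] are taken; the
    raw proportion is multiplicatively rescaled by (grand mean n_snps / mean
    n_snps at that level), compensating for deeper-genotyped transcripts
    being more likely to both show AI and harbour detected variants.
    """
    df = per_transcript[per_transcript["fold"] <= upper]
    if df.empty:
        raise AseError("no transcripts below the exclusion bound")
    grand_mean = float(df["n_snps"].mean())
    rows = []
    for level in ai_levels:
        sub = df[df["fold"] >= level]
        if sub.empty:
            warnings.warn(f"no transcripts at AI level {level}", stacklevel=2)
            continue
        adj_factor = grand_mean / float(sub["n_snps"].mean())
        for cls in classes:
            col = f"n_{cls}" if f"n_{cls}" in sub.columns else cls
            raw = float((sub[col] >= 1).mean())
            rows.append({"level": level, "class": cls, "n_transcripts": len(sub),
                         "raw_proportion": raw,
                         "adjusted_proportion": raw * adj_factor})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Promoter-correlated DHS bins
# ---------------------------------------------------------------------------

def correlate_promoter_dhs(
    signal_matrix: np.ndarray,
    grid: BinGrid,
    transcripts: Sequence[TranscriptModel],
    promoter_halfwidth: int = 500,
    max_dist: int = 1_000_000,
    candidate_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation of promoter accessibility with nearby DHS bins.

    ``signal_matrix`` is datasets x bins of normalized signal (>= 3 datasets).
    The promoter signal of a transcript is the mean over the bins overlapping
    TSS +/- ``promoter_halfwidth`` per dataset; it is correlated across
    datasets with every candidate bin within ``max_dist`` of the TSS.
    Zero-variance vectors are skipped with a warning.
    """
    signal_matrix = np.asarray(signal_matrix, dtype=float)
    if signal_matrix.shape[0] < 3:
        raise AseError("need >= 3 datasets for Pearson correlation")
    if signal_matrix.shape[1] != grid.n_bins:
        raise AseError("signal matrix width != grid bins")
    rows = []
    for t in transcripts:
        tss = t.tss
        size = grid.chrom_sizes[t.chrom]
        prom = grid.overlapping_bins(
            t.chrom, max(0, tss - promoter_halfwidth),
            min(size, tss + promoter_halfwidth + 1))
        pvec = signal_matrix[:, prom].mean(axis=1)
        if np.std(pvec) == 0:
            warnings.warn(f"zero-variance promoter signal for {t.transcript_id}",
                          stacklevel=2)
            continue
        lo = max(0, tss - max_dist)
        hi = min(size, tss + max_dist)
        near = grid.overlapping_bins(t.chrom, lo, hi)
        if candidate_bins is not None:
            near = np.intersect1d(near, candidate_bins)
        prom_set = set(int(b) for b in prom)
        for b in near:
            if int(b) in prom_set:
                continue
            bvec = signal_matrix[:, int(b)]
            if np.std(bvec) == 0:
                continue
            r = float(np.corrcoef(pvec, bvec)[0, 1])
            _, s, e = grid.bin_interval(int(b))
            rows.append({"transcript": t.transcript_id, "bin": int(b),
                         "r": r, "distance": (s + e) // 2 - tss})
    return pd.DataFrame(rows, columns=["transcript", "bin", "r", "distance"])


# ---------------------------------------------------------------------------
# AI enrichment folds and threshold trend
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    thresholds: np.ndarray
    folds: np.ndarray
    slope: float
    p_value: float            # OLS t-test p (reported, as in figure legends)
    permutation_p: float | None  # AI-label permutation p (calibrated inference)


def ai_enrichment(
    is_ai: np.ndarray | pd.Series,
    presence: np.ndarray | pd.Series,
) -> float:
    """Fold enrichment: P(>=1 qualifying variant | AI transcript) over
    P(>=1 qualifying variant | all tested transcripts)."""
    is_ai = np.asarray(is_ai, dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    if is_ai.shape != presence.shape:
        raise AseError("is_ai and presence must align")
    if is_ai.sum() == 0 or len(is_ai) == 0:
        raise AseError("empty AI or background set")
    denom = presence.mean()
    if denom == 0:
        return float("nan")
    return float(presence[is_ai].mean() / denom)


def ai_enrichment_trend(
    is_ai: np.ndarray | pd.Series,
    presence_by_threshold: Mapping[float, np.ndarray | pd.Series],
    n_permutations: int = 199,
    seed: int = 0,
) -> TrendResult:
    """Trend of AI-enrichment fold across correlation thresholds.

    Folds at the different thresholds share transcripts (the link sets are
    nested), so alongside the OLS slope and its t-test p-value a permutation
    p is computed by shuffling the AI labels, which respects that
    dependence.  Set ``n_permutations=0`` to skip the permutation test.
    """
    is_ai = np.asarray(is_ai, dtype=bool)
    thr = np.array(sorted(presence_by_threshold), dtype=float)
    pres = np.column_stack([
        np.asarray(presence_by_threshold[t], dtype=bool) for t in thr
    ])
    overall = pres.mean(axis=0)
    if np.any(overall == 0):
        raise AseError("a threshold has zero overall variant presence")

    def slope_of(labels: np.ndarray) -> float:
        folds = pres[labels].mean(axis=0) / overall
        return float(stats.linregress(thr, folds).slope)

    folds = pres[is_ai].mean(axis=0) / overall
    fit = stats.linregress(thr, folds)
    perm_p = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        obs = abs(fit.slope)
        labels = is_ai.copy()
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(labels)
            if abs(slope_of(labels)) >= obs - 1e-15:
                hits += 1
        perm_p = (1 + hits) / (1 + n_permutations)
    return TrendResult(thresholds=thr, folds=folds, slope=float(fit.slope),
                       p_value=float(fit.pvalue), permutation_p=perm_p)


# ---------------------------------------------------------------------------
# Homozygous-eSNP stratification
# ---------------------------------------------------------------------------

def stratify_homozygous(
    records: pd.DataFrame, esnp_genotypes: pd.DataFrame
) -> pd.DataFrame:
    """Keep (transcript, individual) records where the individual is
    homozygous (0/0 or 1/1) at the transcript's top eSNP.

    ``esnp_genotypes`` columns: transcript, individual, gt.  Transcripts
    without an eSNP annotation are excluded from the homozygous stratum.
    """
    hom = esnp_genotypes[esnp_genotypes["gt"].isin(["0/0", "1/1", "0|0", "1|1"])]
    key = set(zip(hom["transcript"], hom["individual"]))
    mask = [
        (r.transcript, r.individual) in key for r in records.itertuples()
    ]
    out = records.loc[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("homozygous-eSNP stratum is empty", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Dose response and TSS-distance profile
# ---------------------------------------------------------------------------

def count_dose_response(
    per_transcript: pd.DataFrame,
    count_col: str = "n_rare_novel",
    max_count: int = 4,
    upper: float = AI_HIGH,
) -> pd.DataFrame:
    """Adjusted AI proportion stratified by the number of vicinity variants.

    Transcripts (fold <= upper) are binned by ``count_col`` (values above
    ``max_count`` pooled into the top stratum); per stratum the fraction in
    the AI band, rescaled by relative mean informative-SNP count.
    """
    df = per_transcript[per_transcript["fold"] <= upper].copy()
    if df.empty:
        raise AseError("no transcripts below the exclusion bound")
    df["stratum"] = np.minimum(df[count_col], max_count)
    grand_mean = float(df["n_snps"].mean())
    rows = []
    for stratum, sub in df.groupby("stratum", sort=True):
        raw = float((sub["fold"] >= AI_LOW).mean())
        adj = raw * grand_mean / float(sub["n_snps"].mean())
        rows.append({"stratum": int(stratum), "n_transcripts": len(sub),
                     "raw_ai_proportion": raw, "adjusted_ai_proportion": adj})
    return pd.DataFrame(rows)


def tss_distance_enrichment(
    variants: pd.DataFrame,
    ai_transcripts: Sequence[TranscriptModel],
    all_transcripts: Sequence[TranscriptModel],
    window: int = 80_000,
    step: int = 10_000,
    max_dist: int = 200_000,
    freq_classes: Sequence[str] = ("rare", "novel"),
) -> pd.DataFrame:
    """Fold enrichment of variants near AI-transcript TSSs, by signed distance.

    A sliding window of ``window`` bp advanced every ``step`` bp spans
    [-max_dist, +max_dist] around the TSS (distance is strand-aware: positive
    downstream).  Per window, the mean variant count per AI transcript is
    divided by the same quantity over all tested transcripts; windows with
    zero background density are omitted.
    """
    v = variants[variants["freq_class"].isin(freq_classes)]
    centers = np.arange(-max_dist, max_dist + 1, step)

    def per_window_counts(transcripts: Sequence[TranscriptModel]) -> np.ndarray:
        totals = np.zeros(len(centers))
        for t in transcripts:
            on_chrom = v[v["chrom"] == t.chrom]
            d = (on_chrom["pos"].to_numpy() - 1) - t.tss
            if t.strand == "-":
                d = -d
            for i, c in enumerate(centers):
                totals[i] += int(np.sum((d >= c - window // 2) & (d <= c + window // 2)))
        return totals / max(len(transcripts), 1)

    ai_density = per_window_counts(ai_transcripts)
    bg_density = per_window_counts(all_transcripts)
    rows = []
    for c, num, den in zip(centers, ai_density, bg_density):
        if den == 0:
            continue
        rows.append({"center": int(c), "ai_density": num, "background_density": den,
                     "fold": num / den})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Residual variance explained
# ---------------------------------------------------------------------------

def residual_variance_explained(
    hom_records: pd.DataFrame, count_col: str = "n_rare_novel"
) -> float | None:
    """R^2 of log2(fold difference) on the rare+novel vicinity variant count,
    over records from individuals homozygous at the local common eSNP.

    This operationalizes "residual allelic imbalance explained by rare and
    novel variants" as an ordinary least-squares coefficient of
    determination.  Returns None when the response has zero variance.
    Requires >= 10 records.
    """
    if len(hom_records) < 10:
        raise AseError(f"need >= 10 homozygous records, got {len(hom_records)}")
    y = np.log2(hom_records["fold"].to_numpy(dtype=float))
    x = hom_records[count_col].to_numpy(dtype=float)
    if np.var(y) == 0:
        warnings.warn("zero variance in log2 fold; R^2 undefined", stacklevel=2)
        return None
    if np.var(x) == 0:
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue ** 2)


# ---------------------------------------------------------------------------
# Hi-C links
# ---------------------------------------------------------------------------

def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE anchor pairs (first six columns; extras ignored)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise AseError(f"{path}:{i}: BEDPE needs 6 columns")
            rows.append({"chrom1": f[0], "start1": int(f[1]), "end1": int(f[2]),
                         "chrom2": f[3], "start2": int(f[4]), "end2": int(f[5])})
    return pd.DataFrame(rows,
                        columns=["chrom1", "start1", "end1",
                                 "chrom2", "start2", "end2"])


def hic_promoter_links(
    pairs: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    promoter_halfwidth: int = 1500,
) -> pd.DataFrame:
    """Map Hi-C anchor pairs to transcripts whose promoter (TSS +/- 1500 bp)
    overlaps one anchor; the other anchor becomes the linked distal region.

    ``pairs`` is BEDPE-shaped: chrom1,start1,end1,chrom2,start2,end2.
    """
    rows = []
    for t in transcripts:
        p_lo, p_hi = t.tss - promoter_halfwidth, t.tss + promoter_halfwidth + 1
        for r in pairs.itertuples():
            for (ac, as_, ae), (oc, os_, oe) in (
                ((r.chrom1, r.start1, r.end1), (r.chrom2, r.start2, r.end2)),
                ((r.chrom2, r.start2, r.end2), (r.chrom1, r.start1, r.end1)),
            ):
                if ac == t.chrom and as_ < p_hi and ae > p_lo:
                    rows.append({"transcript": t.transcript_id, "chrom": oc,
                                 "start": int(os_), "end": int(oe)})
    return pd.DataFrame(rows, columns=["transcript", "chrom", "start", "end"]) \
             .drop_duplicates().reset_index(drop=True)


def variant_in_linked_regions(
    variants: pd.DataFrame, links: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    freq_classes: Sequence[str] = ("rare", "novel"),
) -> pd.Series:
    """Per-transcript flag: >=1 variant of the given classes inside any
    linked region of that transcript."""
    v = variants[variants["freq_class"].isin(freq_classes)]
    flags = {}
    by_t = dict(tuple(links.groupby("transcript"))) if len(links) else {}
    for t in transcripts:
        sub = by_t.get(t.transcript_id)
        hit = False
        if sub is not None:
            for r in sub.itertuples():
                pos0 = v.loc[v["chrom"] == r.chrom, "pos"] - 1
                if ((pos0 >= r.start) & (pos0 < r.end)).any():
                    hit = True
                    break
        flags[t.transcript_id] = hit
    return pd.Series(flags, name="in_hic_link")
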