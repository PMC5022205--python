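"""Variant QC, frequency classification and regulatory-context annotation.

Variants live in two parallel pandas frames:

``sites``
    one row per SNV: ``variant_id, chrom, pos`` (1-based, VCF convention),
    ``ref, alt, mq`` plus annotation columns added by the operations below
    (``freq_class``, ``effect``, ``sharing``, ``gerp``, ``cadd``...).
``calls``
    one row per (variant, sample) genotype call: ``variant_id, sample, gt``
    (one of ``0/0 0/1 1/1 ./.``), ``dp, gq, ad_ref, ad_alt``.

Frequency classes follow the usual population-reference convention: common
means minor allele frequency >= 1% in the reference panel, rare means known
to the references but MAF < 1%, novel means absent from both the frequency
reference and the known-sites catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .panel import CapturePanel

SITE_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "mq"]
CALL_COLUMNS = ["variant_id", "sample", "gt", "dp", "gq", "ad_ref", "ad_alt"]
HET_GTS = {"0/1", "1/0", "0|1", "1|0"}
HOM_ALT_GTS = {"1/1", "1|1"}
HOM_REF_GTS = {"0/0", "0|0"}


class VariantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def write_vcf(sites: pd.DataFrame, calls: pd.DataFrame, path,
              chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Write sites+calls as a VCF 4.2 text file (FORMAT GT:DP:GQ:AD, INFO MQ)."""
    samples = sorted(calls["sample"].unique()) if len(calls) else []
    calls_ix = calls.set_index(["variant_id", "sample"]) if len(calls) else None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_sizes:
            for c, s in chrom_sizes.items():
                fh.write(f"##contig=<ID={c},length={s}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = sites.sort_values(["chrom", "pos"], kind="stable")
        for row in order.itertuples():
            fields = [row.chrom, str(int(row.pos)), str(row.variant_id), row.ref,
                      row.alt, ".", "PASS", f"MQ={float(row.mq):g}", "GT:DP:GQ:AD"]
            for s in samples:
                try:
                    c = calls_ix.loc[(row.variant_id, s)]
                except KeyError:
                    fields.append("./.:.:.:.")
                    continue
                fields.append(
                    f"{c['gt']}:{int(c['dp'])}:{int(c['gq'])}:"
                    f"{int(c['ad_ref'])},{int(c['ad_alt'])}"
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (sites, calls) frames via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows, call_rows = [], []
    for i, v in enumerate(vcf):
        vid = v.ID if v.ID not in (None, ".") else f"var{i}"
        alt = v.ALT[0] if v.ALT else "."
        mq = v.INFO.get("MQ")
        site_rows.append({"variant_id": vid, "chrom": v.CHROM, "pos": int(v.POS),
                          "ref": v.REF, "alt": alt,
                          "mq": float(mq) if mq is not None else np.nan})
        dp = v.format("DP")
        gq = v.format("GQ")
        ad = v.format("AD")
        gts = v.genotypes
        for si, s in enumerate(samples):
            g = gts[si]
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                gt = "./."
            else:
                gt = "/".join(str(int(a)) for a in alleles)
            def _val(arr, j=None):
                if arr is None:
                    return np.nan
                x = arr[si] if j is None else arr[si][j]
                x = float(np.asarray(x).ravel()[0])
                return np.nan if x < 0 else x
            call_rows.append({
                "variant_id": vid, "sample": s, "gt": gt,
                "dp": _val(dp), "gq": _val(gq),
                "ad_ref": _val(ad, 0), "ad_alt": _val(ad, 1),
            })
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    calls = pd.DataFrame(call_rows, columns=CALL_COLUMNS)
    return sites, calls


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QcResult:
    sites: pd.DataFrame          # sites with >= 1 passing genotype call
    calls: pd.DataFrame          # the passing genotype calls
    rejections: pd.DataFrame     # variant_id, sample, reason


def qc_filter(
    sites: pd.DataFrame,
    calls: pd.DataFrame,
    dp_min: float = 10,
    gq_min: float = 70,
    mq_min: float = 50,
    ab_range: tuple[float, float] = (0.10, 0.90),
) -> QcResult:
    """Apply hard QC cut-offs per genotype call.

    A call passes iff DP >= dp_min AND GQ >= gq_min AND site MQ >= mq_min AND,
    for heterozygous calls only, the reference-read fraction lies in
    ``ab_range`` (inclusive).  Missing required fields fail the call.  Indels
    and non-variant (hom-ref / missing) genotypes are excluded.  A site is
    retained iff at least one of its genotype calls passes.  Idempotent.
    """
    sites = sites.copy()
    is_snv = (sites["ref"].str.len() == 1) & (sites["alt"].str.len() == 1) & \
             (sites["ref"] != sites["alt"]) & sites["alt"].isin(list("ACGT"))
    snv_ids = set(sites.loc[is_snv, "variant_id"])
    mq_map = sites.set_index("variant_id")["mq"]

    df = calls.copy()
    df["mq"] = df["variant_id"].map(mq_map)
    carries_alt = df["gt"].isin(HET_GTS | HOM_ALT_GTS)
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[~df["variant_id"].isin(snv_ids)] += "not_snv;"
    reasons[~carries_alt] += "no_alt_allele;"
    reasons[~(df["dp"] >= dp_min)] += "low_dp;"          # NaN fails the >= test
    reasons[~(df["gq"] >= gq_min)] += "low_gq;"
    reasons[~(df["mq"] >= mq_min)] += "low_mq;"
    het = df["gt"].isin(HET_GTS)
    with np.errstate(invalid="ignore"):
        ab = df["ad_ref"] / (df["ad_ref"] + df["ad_alt"])
    bad_ab = het & ~((ab >= ab_range[0]) & (ab <= ab_range[1]))
    reasons[bad_ab] += "allele_balance;"
    passing = reasons == ""
    rejections = df.loc[~passing & carries_alt, ["variant_id", "sample"]].copy()
    rejections["reason"] = reasons[~passing & carries_alt].str.rstrip(";")
    kept_calls = calls.loc[passing.values].copy()
    kept_sites = sites[sites["variant_id"].isin(set(kept_calls["variant_id"]))].copy()
    return QcResult(sites=kept_sites.reset_index(drop=True),
                    calls=kept_calls.reset_index(drop=True),
                    rejections=rejections.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Frequency classification
# ---------------------------------------------------------------------------

def classify_frequency(
    sites: pd.DataFrame,
    frequency_reference: pd.DataFrame,
    known_sites: pd.DataFrame | None = None,
    maf_threshold: float = 0.01,
) -> pd.DataFrame:
    """Attach ``freq_class`` in {common, rare, novel} and ``maf`` columns.

    Matching is allele-aware on (chrom, pos, ref, alt).  Reference allele
    frequencies are folded to minor allele frequency before thresholding.
    A position present in the reference with a *different* alt allele is
    treated as novel-at-allele (and flagged in ``allele_mismatch``).  Records
    listed only in ``known_sites`` (no frequency) classify as rare.
    """
    ref = frequency_reference.copy()
    key = ["chrom", "pos", "ref", "alt"]
    for c in key:
        if c not in ref.columns:
            raise VariantError(f"frequency reference missing column {c!r}")
    ref = ref[key + ["af"]].drop_duplicates(subset=key)
    out = sites.merge(ref, on=key, how="left")
    out["maf"] = np.minimum(out["af"], 1.0 - out["af"])

    pos_known = set(zip(frequency_reference["chrom"], frequency_reference["pos"]))
    known_set: set[tuple] = set()
    if known_sites is not None and len(known_sites):
        cols = ["chrom", "pos", "ref", "alt"]
        if all(c in known_sites.columns for c in cols):
            known_set = set(zip(*(known_sites[c] for c in cols)))
        else:
            known_set = set(zip(known_sites["chrom"], known_sites["pos"]))

    def classify(row) -> str:
        if not np.isnan(row.maf):
            return "common" if row.maf >= maf_threshold else "rare"
        k = (row.chrom, row.pos, row.ref, row.alt)
        if k in known_set or (len(known_set) and len(next(iter(known_set))) == 2
                              and (row.chrom, row.pos) in known_set):
            return "rare"
        return "novel"

    out["freq_class"] = [classify(r) for r in out.itertuples()]
    out["allele_mismatch"] = out["maf"].isna() & np.array(
        [(c, p) in pos_known for c, p in zip(out["chrom"], out["pos"])], dtype=bool
    )
    n_mm = int(out["allele_mismatch"].sum())
    if n_mm:
        warnings.warn(f"{n_mm} variants match a reference position with a "
                      "different allele; classified as novel", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Coding-effect annotation (minimal codon-level annotator)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A transcript with exon structure and a CDS on a synthetic gene model."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]          # 0-based half-open, sorted
    cds_start: int                        # genomic, 0-based
    cds_end: int                          # genomic, half-open

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        if self.strand not in "+-":
            raise VariantError(f"bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based transcription start position (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                out.append((lo, hi))
        return out

    def cds_positions(self) -> np.ndarray:
        """Genomic 0-based positions of the CDS in *transcript* (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds_intervals()]) \
            if self.cds_intervals() else np.empty(0, dtype=np.int64)
        return pos[::-1] if self.strand == "-" else pos


def transcripts_to_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - t.start) for s, e in t.exons) + ","
            fh.write("\t".join(map(str, [
                t.chrom, t.start, t.end, f"{t.gene_id}|{t.transcript_id}", 0,
                t.strand, t.cds_start, t.cds_end, "0,0,0", len(t.exons),
                sizes, starts])) + "\n")


def bed12_to_transcripts(path) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise VariantError(f"{path}:{i}: BED12 needs 12 columns")
            chrom, start = f[0], int(f[1])
            gene_id, _, tid = f[3].partition("|")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            out.append(TranscriptModel(
                transcript_id=tid or f[3], gene_id=gene_id, chrom=chrom,
                strand=f[5], exons=exons, cds_start=int(f[6]), cds_end=int(f[7])))
    return out


def annotate_coding_effect(
    sites: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> pd.DataFrame:
    """Attach ``effect`` in {synonymous, non-synonymous, stop-gained, non-coding}.

    The codon containing each SNV is translated for both alleles; gain of a
    stop codon is reported as stop-gained, any other amino-acid change as
    non-synonymous.  Variants outside every CDS are non-coding.  Records whose
    VCF ref disagrees with the genome are flagged ``ref_mismatch`` and left
    unannotated (effect NaN).
    """
    # genomic position -> (transcript, cds index); first transcript wins
    cds_map: dict[tuple[str, int], tuple[TranscriptModel, int]] = {}
    for t in transcripts:
        cds_pos = t.cds_positions()
        if len(cds_pos) % 3 != 0:
            raise VariantError(
                f"CDS length of {t.transcript_id} not divisible by 3")
        for idx, gpos in enumerate(cds_pos):
            cds_map.setdefault((t.chrom, int(gpos)), (t, idx))

    effects, mismatches = [], []
    comp = str.maketrans("ACGT", "TGCA")
    for row in sites.itertuples():
        pos0 = int(row.pos) - 1
        gbase = genome[row.chrom][pos0]
        if gbase != row.ref:
            effects.append(np.nan)
            mismatches.append(True)
            continue
        mismatches.append(False)
        hit = cds_map.get((row.chrom, pos0))
        if hit is None:
            effects.append("non-coding")
            continue
        t, idx = hit
        cds_pos = t.cds_positions()
        codon_i = idx // 3
        codon_pos = cds_pos[3 * codon_i: 3 * codon_i + 3]
        def base(gpos: int, allele: str | None = None) -> str:
            b = allele if (gpos == pos0 and allele) else genome[t.chrom][gpos]
            return b.translate(comp) if t.strand == "-" else b
        ref_codon = "".join(base(int(g)) for g in codon_pos)
        alt_codon = "".join(base(int(g), row.alt) for g in codon_pos)
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            effects.append("synonymous")
        elif aa_alt == "*":
            effects.append("stop-gained")
        else:
            effects.append("non-synonymous")
    out = sites.copy()
    out["effect"] = effects
    out["ref_mismatch"] = mismatches
    n_bad = int(sum(mismatches))
    if n_bad:
        warnings.warn(f"{n_bad} records rejected: VCF ref disagrees with genome",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# DHS context
# ---------------------------------------------------------------------------

def assign_dhs_sharing(sites: pd.DataFrame, panel: CapturePanel) -> pd.DataFrame:
    """Attach ``sharing``: cell-type sharing level of the containing panel
    bin, 0 when the variant lies outside the panel."""
    out = sites.copy()
    out["sharing"] = [
        panel.sharing_at(r.chrom, int(r.pos) - 1) for r in sites.itertuples()
    ]
    return out


@dataclass
class SharingEnrichment:
    levels: np.ndarray
    folds: np.ndarray
    counts: pd.DataFrame          # per level: n_numerator, n_common
    slope: float
    p_value: float
    fold_span: float              # fitted ratio change from lowest to highest level
    numerator: tuple[str, ...]


def sharing_level_enrichment(
    sites: pd.DataFrame,
    numerator: Sequence[str] = ("rare", "novel"),
) -> SharingEnrichment:
    """Fold enrichment of rare/novel vs common variants across DHS sharing levels.

    fold(k) = [numerator_k / common_k] / [numerator_allDHS / common_allDHS];
    an ordinary least-squares fit of fold on level gives the trend slope and
    its two-sided t-test p-value.  ``fold_span`` is exp of the analogous
    log-fold fit evaluated across the level range — an estimate of the
    multiplicative enrichment between the least- and most-shared bins.
    """
    df = sites[sites["sharing"] >= 1]
    numerator = tuple(numerator)
    is_num = df["freq_class"].isin(numerator)
    is_com = df["freq_class"] == "common"
    n_all, c_all = int(is_num.sum()), int(is_com.sum())
    if c_all == 0 or n_all == 0:
        raise VariantError("need both numerator-class and common variants in DHSs")
    levels_all = np.array(sorted(df["sharing"].unique()))
    levels, folds, n_rows = [], [], []
    for k in levels_all:
        at_k = df["sharing"] == k
        n_k = int((is_num & at_k).sum())
        c_k = int((is_com & at_k).sum())
        if c_k == 0:
            warnings.warn(f"sharing level {k} has no common variants; omitted",
                          stacklevel=2)
            continue
        levels.append(int(k))
        folds.append((n_k / c_k) / (n_all / c_all))
        n_rows.append({"level": int(k), "n_numerator": n_k, "n_common": c_k})
    if len(levels) < 2:
        raise VariantError("need >= 2 populated sharing levels for the trend")
    levels_arr = np.array(levels, dtype=float)
    folds_arr = np.array(folds, dtype=float)
    fit = stats.linregress(levels_arr, folds_arr)
    pos = folds_arr > 0
    span = np.nan
    if pos.sum() >= 2:
        logfit = stats.linregress(levels_arr[pos], np.log(folds_arr[pos]))
        span = float(np.exp(logfit.slope * (levels_arr.max() - levels_arr.min())))
    return SharingEnrichment(
        levels=levels_arr, folds=folds_arr, counts=pd.DataFrame(n_rows),
        slope=float(fit.slope), p_value=float(fit.pvalue), fold_span=span,
        numerator=numerator)


# ---------------------------------------------------------------------------
# Conservation / deleteriousness strata
# ---------------------------------------------------------------------------

def constraint_proportions(
    sites: pd.DataFrame,
    gerp_thresholds: Sequence[float] = (1.0, 2.0),
    cadd_thresholds: Sequence[float] = (10.0, 20.0),
    count_missing_in_denominator: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class proportions of constrained variants, with Fisher contrasts.

    Returns (proportions, contrasts).  Proportions: one row per
    (score, threshold, class) with n_above / n_total.  Contrasts: pairwise
    class comparisons of above/below counts via Fisher's exact test.
    Missing scores count as below-threshold in the denominator by default.
    """
    from .enrichment import fisher_enrichment

    specs = [("gerp", t) for t in gerp_thresholds] + \
            [("cadd", t) for t in cadd_thresholds]
    prop_rows, contrast_rows = [], []
    classes = [c for c in ("common", "rare", "novel")
               if (sites["freq_class"] == c).any()]
    for score, thr in specs:
        if score not in sites.columns:
            continue
        per_class = {}
        for cls in classes:
            sub = sites[sites["freq_class"] == cls]
            vals = sub[score]
            if not count_missing_in_denominator:
                vals = vals.dropna()
            n_tot = len(vals)
            n_above = int((vals >= thr).sum())  # NaN compares False
            per_class[cls] = (n_above, n_tot)
            prop_rows.append({"score": score, "threshold": thr, "class": cls,
                              "n_above": n_above, "n_total": n_tot,
                              "proportion": n_above / n_tot if n_tot else np.nan})
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                (a, na), (b, nb) = per_class[ca], per_class[cb]
                res = fisher_enrichment(a, na - a, b, nb - b)
                contrast_rows.append({"score": score, "threshold": thr,
                                      "class_a": ca, "class_b": cb,
                                      "odds_ratio": res.odds_ratio,
                                      "p_value": res.p_value})
    return pd.DataFrame(prop_rows), pd.DataFrame(contrast_rows)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def summary_table(sites: pd.DataFrame, calls: pd.DataFrame | None = None,
                  in_exome: pd.Series | None = None) -> pd.DataFrame:
    """Count variants by category row x frequency-class column.

    Rows: all, coding, non-synonymous, synonymous, stop-gained, exome,
    non-coding, all-DHS; columns: all/common/rare/novel, with per-sample
    averages (variant genotype calls per sample) when ``calls`` is given.
    The identity total = coding + non-coding holds per class by construction.
    """
    df = sites.copy()
    coding = df["effect"].isin(["synonymous", "non-synonymous", "stop-gained"])
    masks = {
        "all": pd.Series(True, index=df.index),
        "coding": coding,
        "non-synonymous": df["effect"] == "non-synonymous",
        "synonymous": df["effect"] == "synonymous",
        "stop-gained": df["effect"] == "stop-gained",
        "exome": in_exome if in_exome is not None else pd.Series(False, index=df.index),
        "non-coding": ~coding,
        "all-DHS": df.get("sharing", pd.Series(0, index=df.index)) >= 1,
    }
    n_samples = calls["sample"].nunique() if calls is not None and len(calls) else 0
    alt_calls = None
    if n_samples:
        alt_calls = calls[calls["gt"].isin(HET_GTS | HOM_ALT_GTS)]
    rows = []
    for name, mask in masks.items():
        row = {"category": name}
        for cls in ("all", "common", "rare", "novel"):
            sel = mask if cls == "all" else (mask & (df["freq_class"] == cls))
            row[cls] = int(sel.sum())
            if n_samples:
                ids = set(df.loc[sel, "variant_id"])
                per = alt_calls[alt_calls["variant_id"].isin(ids)]
                row[f"{cls}_avg_per_sample"] = len(per) / n_samples
        rows.append(row)
    return pd.DataFrame(rows)
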