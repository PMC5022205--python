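"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs a
regulatory-capture study consumes — replicate-correlated DNase peaks with
shared vs cell-type-specific architecture, an allele-frequency spectrum with
common/rare/novel classes, variants planted to create or disrupt
transcription-factor motifs, and beta-binomially dispersed allele counts
with planted rare-variant cis effects — so that each downstream statistic
can be tested against a known truth without external downloads.

All randomness flows from a single master seed through named substreams, so
any single output is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import BinGrid
from .motifs import BASES, COMPLEMENT, PWM
from .panel import CapturePanel
from .variants import TranscriptModel


class SimulationError(ValueError):
    pass


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named output, derived from the master seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big") % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), tag]))


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Everything planted by the generators, serializable to JSON."""

    seed: int
    planted_shared_peaks: list = field(default_factory=list)
    planted_rare_enrichment_fold: float | None = None
    planted_motif_events: list = field(default_factory=list)
    planted_cis_effects: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(seed: int, chrom_sizes: Mapping[str, int],
                base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> dict[str, str]:
    """Random genome with the given chromosome sizes (>= 10 kb each)."""
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise SimulationError(f"chromosome {chrom!r} has non-positive size {size}")
    rng = substream(seed, "genome")
    return {
        chrom: "".join(rng.choice(list(BASES), size=size, p=list(base_probs)))
        for chrom, size in chrom_sizes.items()
    }


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# DNase-I hypersensitivity experiments
# ---------------------------------------------------------------------------

@dataclass
class PeakConfig:
    """Architecture of planted DHS peaks.

    ``sharing_counts`` lists, for each planted peak, how many cell types
    carry it (K = all cell types -> a fully shared peak; 1 -> specific).
    Carrying cell types are drawn without replacement per peak, unless
    ``carriers`` pins them explicitly (one cell-type list per peak), which
    lets a test build symmetric architectures where every cell type carries
    the same number of peak bins.
    """

    sharing_counts: Sequence[int] = ()
    width_bins: int = 3
    peak_reads: float = 50.0      # mean extra reads per peak bin
    carriers: Sequence[Sequence[str]] | None = None

    def n_peaks(self) -> int:
        return len(self.carriers) if self.carriers is not None \
            else len(self.sharing_counts)


@dataclass
class DhsSimulation:
    grid: BinGrid
    counts: dict[str, np.ndarray]         # sample_id -> raw per-bin counts
    cell_type_of: dict[str, str]
    truth: SyntheticTruth


def simulate_dhs_experiments(
    chrom_sizes: Mapping[str, int],
    cell_types: Sequence[str],
    replicates_per_type: Mapping[str, int],
    peak_config: PeakConfig,
    depth: float,
    seed: int,
    bin_size: int = 100,
    noise: str = "poisson",
) -> DhsSimulation:
    """Per-sample DNase read counts on a bin grid with planted peaks.

    Background reads are low-rate Poisson (``depth`` expected reads spread
    uniformly over bins); planted peaks add ``peak_reads`` expected reads per
    peak bin in every sample of a carrying cell type, with independent
    replicate noise.  ``noise='none'`` emits the expected counts exactly
    (for noise-free recovery checks).
    """
    if depth <= 0:
        raise SimulationError(f"depth must be positive, got {depth}")
    for ct in cell_types:
        if replicates_per_type.get(ct, 0) < 1:
            raise SimulationError(f"cell type {ct!r} needs >= 1 replicate")
    grid = BinGrid(chrom_sizes, bin_size=bin_size)
    rng = substream(seed, "dhs")
    n_bins = grid.n_bins
    bg_rate = depth / n_bins
    k_total = len(cell_types)

    # place non-overlapping peaks
    width = peak_config.width_bins
    n_peaks = peak_config.n_peaks()
    slots = n_bins // (2 * width)
    if n_peaks > slots:
        raise SimulationError(f"too many peaks ({n_peaks}) for {n_bins} bins")
    starts = rng.choice(slots, size=n_peaks, replace=False) * 2 * width
    peaks = []
    if peak_config.carriers is not None:
        carrier_lists = [sorted(c) for c in peak_config.carriers]
    else:
        carrier_lists = []
        for k in peak_config.sharing_counts:
            if not 1 <= k <= k_total:
                raise SimulationError(
                    f"peak sharing count {k} outside [1, {k_total}]")
            carrier_lists.append(
                sorted(rng.choice(list(cell_types), size=k, replace=False)))
    for start, carriers in zip(np.sort(starts), carrier_lists):
        bin_ids = list(range(int(start), int(start) + width))
        chrom, s, _ = grid.bin_interval(bin_ids[0])
        _, _, e = grid.bin_interval(bin_ids[-1])
        peaks.append({"chrom": chrom, "start": int(s), "end": int(e),
                      "bins": bin_ids, "cell_types": carriers})

    counts: dict[str, np.ndarray] = {}
    cell_type_of: dict[str, str] = {}
    for ct in cell_types:
        for rep in range(replicates_per_type[ct]):
            sample_id = f"{ct}_rep{rep + 1}"
            rate = np.full(n_bins, bg_rate)
            for p in peaks:
                if ct in p["cell_types"]:
                    rate[p["bins"]] += peak_config.peak_reads
            if noise == "none":
                c = rate.copy()
            else:
                c = rng.poisson(rate).astype(float)
            counts[sample_id] = c
            cell_type_of[sample_id] = ct
    truth = SyntheticTruth(
        seed=seed,
        planted_shared_peaks=[
            {k: v for k, v in p.items() if k != "bins"} | {"bins": p["bins"]}
            for p in peaks
        ],
    )
    return DhsSimulation(grid=grid, counts=counts, cell_type_of=cell_type_of,
                         truth=truth)


def write_bedgraph(counts: np.ndarray, grid: BinGrid, path) -> None:
    with open(path, "w") as fh:
        for b, value in enumerate(counts):
            if value == 0:
                continue
            chrom, s, e = grid.bin_interval(b)
            fh.write(f"{chrom}\t{s}\t{e}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Variant spectrum
# ---------------------------------------------------------------------------

@dataclass
class AfSpectrumConfig:
    """Per-bin expected variant counts and the frequency spectrum.

    ``common_density`` and ``rare_novel_density`` are expected variants per
    100-bp panel bin at sharing level 1; the rare+novel density scales up
    with sharing level per the configured enrichment fold.  ``novel_fraction``
    is the share of the rare+novel class absent from the references.
    """

    common_density: float = 0.10
    rare_novel_density: float = 0.05
    novel_fraction: float = 0.4
    off_panel_per_class: int = 0          # extra variants outside the panel
    mean_depth: float = 50.0
    low_dp_fraction: float = 0.0          # sites planted to fail the DP cut


@dataclass
class SimulatedVariants:
    sites: pd.DataFrame
    calls: pd.DataFrame
    freq_ref: pd.DataFrame
    known_sites: pd.DataFrame
    truth: SyntheticTruth


def simulate_variants(
    panel: CapturePanel,
    af_config: AfSpectrumConfig,
    enrichment_fold: float,
    n_samples: int,
    seed: int,
    genome: Mapping[str, str] | None = None,
    with_genotypes: bool = True,
) -> SimulatedVariants:
    """Plant SNVs on (and off) the panel with a known frequency spectrum.

    The planted (rare+novel)/common density ratio rises log-linearly with
    sharing level k: ratio(k) = ratio(1) * fold^((k-1)/(K-1)), so
    ``enrichment_fold`` is the ratio span between the least- and most-shared
    bins; fold 1 is the null.  Genotypes follow Hardy-Weinberg draws from
    the assigned allele frequency (novel variants get a single het carrier);
    DP/GQ/MQ are populated to pass QC except for a configurable fraction of
    sites planted at DP=5.
    """
    if enrichment_fold < 1:
        raise SimulationError(f"enrichment_fold must be >= 1, got {enrichment_fold}")
    if len(panel.bins) == 0:
        raise SimulationError("empty panel")
    rng = substream(seed, "variants")
    grid = panel.grid
    levels = np.array([panel.sharing[int(b)] for b in panel.bins])
    k_max = int(levels.max())

    rows = []
    vid = 0

    def place(bin_id: int, cls: str) -> None:
        nonlocal vid
        chrom, s, e = grid.bin_interval(int(bin_id))
        pos0 = int(rng.integers(s, e))
        if genome is not None:
            ref = genome[chrom][pos0]
        else:
            ref = BASES[rng.integers(4)]
        alt = BASES[rng.integers(4)]
        while alt == ref:
            alt = BASES[rng.integers(4)]
        if cls == "common":
            af = float(rng.uniform(0.01, 0.5))
        elif cls == "rare":
            af = float(rng.uniform(0.0005, 0.0095))
        else:
            af = np.nan
        rows.append({"variant_id": f"v{vid}", "chrom": chrom, "pos": pos0 + 1,
                     "ref": ref, "alt": alt, "mq": 60.0, "true_class": cls,
                     "true_af": af, "true_sharing": panel.sharing.get(int(bin_id), 0)})
        vid += 1

    for k in range(1, k_max + 1):
        bins_k = panel.bins[levels == k]
        if bins_k.size == 0:
            continue
        scale = enrichment_fold ** ((k - 1) / max(k_max - 1, 1))
        n_common = rng.poisson(af_config.common_density * bins_k.size)
        n_rn = rng.poisson(af_config.rare_novel_density * scale * bins_k.size)
        n_novel = rng.binomial(n_rn, af_config.novel_fraction)
        for n, cls in ((n_common, "common"), (n_rn - n_novel, "rare"),
                       (n_novel, "novel")):
            for b in rng.choice(bins_k, size=n, replace=True):
                place(int(b), cls)

    if af_config.off_panel_per_class:
        panel_set = set(int(b) for b in panel.bins)
        universe = np.array([b for b in range(grid.n_bins) if b not in panel_set])
        for cls in ("common", "rare", "novel"):
            for b in rng.choice(universe, size=af_config.off_panel_per_class,
                                replace=True):
                place(int(b), cls)

    sites = pd.DataFrame(rows)
    if sites.empty:
        raise SimulationError("no variants generated; densities too low")
    # drop coincident duplicates (same chrom/pos): keep the first
    sites = sites.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)

    known = sites["true_class"].isin(["common", "rare"])
    freq_ref = sites.loc[known, ["chrom", "pos", "ref", "alt", "true_af"]] \
        .rename(columns={"true_af": "af"}).reset_index(drop=True)
    freq_ref["known_flag"] = 1
    known_sites = freq_ref[["chrom", "pos", "ref", "alt"]].copy()

    calls = pd.DataFrame(columns=["variant_id", "sample", "gt", "dp", "gq",
                                  "ad_ref", "ad_alt"])
    if with_genotypes and n_samples > 0:
        samples = [f"S{i + 1}" for i in range(n_samples)]
        low_dp = rng.random(len(sites)) < af_config.low_dp_fraction
        call_rows = []
        for i, r in enumerate(sites.itertuples()):
            af = r.true_af if not np.isnan(r.true_af) else 0.0
            if r.true_class == "novel":
                dosages = np.zeros(n_samples, dtype=int)
                dosages[rng.integers(n_samples)] = 1
            else:
                dosages = rng.binomial(2, af, size=n_samples)
                if dosages.sum() == 0:
                    dosages[rng.integers(n_samples)] = 1
            for s, dose in zip(samples, dosages):
                if dose == 0:
                    continue
                dp = 5 if low_dp[i] else int(20 + rng.poisson(af_config.mean_depth - 20))
                if dose == 1:
                    ad_ref = int(rng.binomial(dp, 0.5))
                    # keep planted het calls inside the allele-balance band so
                    # QC failures are exactly the planted low-DP sites
                    ad_ref = int(np.clip(ad_ref, int(np.ceil(0.1 * dp)),
                                         int(np.floor(0.9 * dp))))
                    gt = "0/1"
                else:
                    ad_ref, gt = 0, "1/1"
                call_rows.append({"variant_id": r.variant_id, "sample": s,
                                  "gt": gt, "dp": dp, "gq": 99,
                                  "ad_ref": ad_ref, "ad_alt": dp - ad_ref})
        calls = pd.DataFrame(call_rows)
        sites = sites.copy()
        sites["planted_low_dp"] = low_dp

    truth = SyntheticTruth(seed=seed, planted_rare_enrichment_fold=float(enrichment_fold))
    return SimulatedVariants(sites=sites, calls=calls, freq_ref=freq_ref,
                             known_sites=known_sites, truth=truth)


# ---------------------------------------------------------------------------
# Motif creation/disruption variants
# ---------------------------------------------------------------------------

def make_informative_pwm(pwm_id: str, width: int, seed: int,
                         consensus_prob: float = 0.95) -> PWM:
    """A sharply peaked PWM with a random consensus (for planting tests)."""
    rng = substream(seed, f"pwm-{pwm_id}")
    consensus = rng.integers(4, size=width)
    m = np.full((width, 4), (1 - consensus_prob) / 3)
    m[np.arange(width), consensus] = consensus_prob
    return PWM(id=pwm_id, matrix=m)


def simulate_motif_variants(
    pwms: Sequence[PWM],
    genome: Mapping[str, str],
    n_create: int,
    n_disrupt: int,
    n_neutral: int,
    seed: int,
    flank: int = 15,
) -> tuple[dict[str, str], pd.DataFrame, SyntheticTruth]:
    """Plant motif-creating/disrupting/neutral SNVs into a genome copy.

    A *create* variant sits at the most informative position of a planted
    consensus site: the genome carries the weakest base there (the reference
    allele) and the alternate allele restores the consensus.  A *disrupt*
    variant is the reverse: the genome carries the full consensus and the
    alternate allele is the weakest base.  Neutral variants are random
    substitutions in untouched background sequence.  Returns the mutated
    genome, a variant table and the truth event list.
    """
    width_max = max(p.width for p in pwms)
    if width_max > 2 * flank + 1:
        raise SimulationError(
            f"motif width {width_max} exceeds scan window {2 * flank + 1}")
    rng = substream(seed, "motif-variants")
    chrom = next(iter(genome))
    seq = list(genome[chrom])
    spacing = 2 * flank + width_max + 10
    n_total = n_create + n_disrupt + n_neutral
    first = flank + width_max
    n_slots = (len(seq) - 2 * first) // spacing
    if n_total > n_slots:
        raise SimulationError(f"genome too small for {n_total} planted variants")
    slot_pos = first + np.sort(rng.choice(n_slots, size=n_total, replace=False)) * spacing
    kinds = (["created"] * n_create + ["disrupted"] * n_disrupt
             + ["neutral"] * n_neutral)
    rng.shuffle(kinds)

    rows, events = [], []
    for vid, (pos0, kind) in enumerate(zip(slot_pos, kinds)):
        pos0 = int(pos0)
        if kind == "neutral":
            ref = seq[pos0]
            alt = BASES[int(rng.integers(4))]
            while alt == ref:
                alt = BASES[int(rng.integers(4))]
            rows.append({"variant_id": f"m{vid}", "chrom": chrom, "pos": pos0 + 1,
                         "ref": ref, "alt": alt, "true_event": "neutral",
                         "true_pwm": None})
            continue
        pwm = pwms[int(rng.integers(len(pwms)))]
        consensus = [BASES[j] for j in pwm.log_odds.argmax(axis=1)]
        weak = [BASES[j] for j in pwm.log_odds.argmin(axis=1)]
        info = pwm.log_odds.max(axis=1) - pwm.log_odds.min(axis=1)
        j = int(info.argmax())                      # most informative column
        start = pos0 - j                            # motif start in the genome
        site = consensus.copy()
        if kind == "created":
            site[j] = weak[j]                       # genome carries the weak base
            ref, alt = weak[j], consensus[j]
        else:
            ref, alt = consensus[j], weak[j]
        seq[start:start + pwm.width] = site
        rows.append({"variant_id": f"m{vid}", "chrom": chrom, "pos": pos0 + 1,
                     "ref": ref, "alt": alt, "true_event": kind,
                     "true_pwm": pwm.id})
        events.append([f"m{vid}", pwm.id, kind])

    mutated = dict(genome)
    mutated[chrom] = "".join(seq)
    variants = pd.DataFrame(rows)
    variants["mq"] = 60.0
    truth = SyntheticTruth(seed=seed, planted_motif_events=events)
    return mutated, variants, truth


# ---------------------------------------------------------------------------
# Allele-specific expression
# ---------------------------------------------------------------------------

@dataclass
class AseEffectConfig:
    n_transcripts: int = 200
    n_affected: int = 0               # transcripts carrying a planted cis effect
    log2_effect: float = 1.0          # allelic log2 fold in rare-allele carriers
    carrier_fraction: float = 0.25    # chance an individual carries the rare allele
    mean_reads: int = 100             # total reads per transcript per individual
    n_snps_lambda: float = 3.0        # informative SNPs ~ 1 + Poisson(lambda)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   overdispersion: float) -> np.ndarray:
    if overdispersion == 0:
        return rng.binomial(n, p)
    nu = (1 - overdispersion) / overdispersion
    q = rng.beta(np.maximum(p * nu, 1e-9), np.maximum((1 - p) * nu, 1e-9))
    return rng.binomial(n, q)


def simulate_ase(
    effect_config: AseEffectConfig,
    overdispersion: float,
    n_individuals: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Haplotype allele counts with planted rare-variant cis effects.

    Every (transcript, individual) pair gets beta-binomial allele counts at
    balance 0.5, except individuals carrying the planted rare allele of an
    affected transcript, whose expected allelic ratio is shifted to
    2**log2_effect.  Also emits a common-eSNP genotype table (HWE draws,
    MAF ~ U(0.1, 0.5)) for homozygous stratification.  Returns
    (records, esnp_genotypes, truth).
    """
    if overdispersion < 0:
        raise SimulationError(f"overdispersion must be >= 0, got {overdispersion}")
    cfg = effect_config
    rng = substream(seed, "ase")
    transcripts = [f"T{i + 1}" for i in range(cfg.n_transcripts)]
    individuals = [f"I{j + 1}" for j in range(n_individuals)]
    affected = set(transcripts[:cfg.n_affected])

    rec_rows, cis_events = [], []
    for t in transcripts:
        n_snps = 1 + int(rng.poisson(cfg.n_snps_lambda))
        carriers = (rng.random(n_individuals) < cfg.carrier_fraction) \
            if t in affected else np.zeros(n_individuals, dtype=bool)
        ratio = 2.0 ** cfg.log2_effect
        p = np.where(carriers, ratio / (1 + ratio), 0.5)
        n = np.maximum(rng.poisson(cfg.mean_reads, size=n_individuals), 2)
        hap_a = _beta_binomial(rng, n, p, overdispersion)
        for j, ind in enumerate(individuals):
            rec_rows.append({"transcript": t, "individual": ind,
                             "hap_a": int(hap_a[j]), "hap_b": int(n[j] - hap_a[j]),
                             "n_snps": n_snps,
                             "carrier": bool(carriers[j])})
        if t in affected:
            cis_events.append([t, f"rv_{t}", float(cfg.log2_effect)])

    geno_rows = []
    for t in transcripts:
        af = float(rng.uniform(0.1, 0.5))
        doses = rng.binomial(2, af, size=n_individuals)
        for ind, d in zip(individuals, doses):
            geno_rows.append({"transcript": t, "individual": ind,
                              "gt": ["0/0", "0/1", "1/1"][d]})
    truth = SyntheticTruth(seed=seed, planted_cis_effects=cis_events)
    return pd.DataFrame(rec_rows), pd.DataFrame(geno_rows), truth


def simulate_residual_ai(
    n_records: int,
    variance_share: float,
    seed: int,
    count_lambda: float = 2.0,
    sigma: float = 0.3,
    base_log2: float = 1.0,
    depth: int = 2000,
) -> pd.DataFrame:
    """Homozygous-eSNP ASE records whose log2 imbalance is partly explained
    by the rare+novel vicinity variant count.

    The planted model is log2 ratio = base + beta * count + N(0, sigma^2)
    with beta chosen so the count term explains ``variance_share`` of the
    response variance; counts are deep (``depth`` reads) so binomial noise is
    negligible and the realized R^2 matches the planted share.  The base
    offset keeps ratios positive, so folding to max/min preserves the signal.
    """
    if not 0 <= variance_share < 1:
        raise SimulationError("variance_share must be in [0, 1)")
    rng = substream(seed, "residual-ai")
    x = rng.poisson(count_lambda, size=n_records).astype(float)
    beta = 0.0
    if variance_share > 0:
        beta = sigma * np.sqrt(variance_share / (1 - variance_share)) \
            / np.sqrt(count_lambda)
    mu = base_log2 + beta * x + rng.normal(0, sigma, size=n_records)
    ratio = 2.0 ** mu
    p = ratio / (1 + ratio)
    hap_a = rng.binomial(depth, p)
    hap_b = depth - hap_a
    hap_a = np.maximum(hap_a, 1)
    hap_b = np.maximum(hap_b, 1)
    fold = np.maximum(hap_a, hap_b) / np.minimum(hap_a, hap_b)
    return pd.DataFrame({
        "transcript": [f"T{i}" for i in range(n_records)],
        "individual": "I1",
        "hap_a": hap_a, "hap_b": hap_b, "fold": fold,
        "n_rare_novel": x.astype(int), "n_snps": 3,
        "true_mu": mu,
    })


# ---------------------------------------------------------------------------
# Synthetic transcript models
# ---------------------------------------------------------------------------

def make_transcripts(
    chrom_sizes: Mapping[str, int], n_genes: int, seed: int,
    n_codons: int = 30, spacing: int = 5000,
) -> list[TranscriptModel]:
    """Single-exon synthetic genes with in-frame CDSs, evenly spaced."""
    rng = substream(seed, "transcripts")
    out = []
    chroms = list(chrom_sizes)
    i = 0
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        start = 1000 + (g // len(chroms)) * spacing
        cds_len = 3 * n_codons
        end = start + cds_len + 200
        if end >= chrom_sizes[chrom]:
            raise SimulationError("chromosomes too small for requested genes")
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(TranscriptModel(
            transcript_id=f"tx{g + 1}", gene_id=f"gene{g + 1}", chrom=chrom,
            strand=strand, exons=[(start, end)],
            cds_start=start + 100, cds_end=start + 100 + cds_len))
        i += 1
    return out
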