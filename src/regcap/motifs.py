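"""Transcription-factor motif creation/disruption scanning.

Each variant's reference and alternate alleles are scored against a PWM
library inside a +/-15 nt window.  Scoring is log2 odds against a 0-order
background with a small background-proportional pseudocount; p-values come
from the exact distribution of the (discretized) score over random w-mers
drawn from the background, computed by dynamic programming.  A motif is
*created* when only the alternate allele reaches significance at the chosen
alpha (Bonferroni-corrected across scanned variants), *disrupted* when only
the reference allele does.

The scanner keeps all arithmetic on a shared integer score grid, so the
p-value looked up for a scanned placement is the exact tail mass of the
discretized distribution at that placement's integer score; discretization
only enters when converting a real-valued score from outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")
MAX_WIDTH = 31
DEFAULT_FLANK = 15
PSEUDOCOUNT_TOTAL = 0.01


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    """A position probability matrix with background model and score grid.

    ``matrix`` has shape (w, 4) over A,C,G,T; rows sum to 1.  Pseudocounts of
    total mass ``pseudocount`` are distributed by the background before
    log-odds conversion (so zero probabilities stay finite).  The log-odds
    scores are mapped to an integer grid of ``granularity`` steps per
    position, on which the exact background score distribution is computed.
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = PSEUDOCOUNT_TOTAL
    granularity: int = 20_000

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        w = self.width
        if not 1 <= w <= MAX_WIDTH:
            raise MotifError(f"PWM width {w} outside [1, {MAX_WIDTH}]")
        if self.matrix.shape != (w, 4):
            raise MotifError(f"matrix shape {self.matrix.shape} != (w, 4)")
        row_sums = self.matrix.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-4):
            raise MotifError(f"PWM {self.id}: rows must sum to 1")
        self.matrix = self.matrix / row_sums[:, None]
        if abs(self.background.sum() - 1.0) > 1e-9 or np.any(self.background <= 0):
            raise MotifError("background must be a positive distribution")
        adj = (self.matrix + self.pseudocount * self.background) / (1 + self.pseudocount)
        self.log_odds = np.log2(adj / self.background)
        # integer grid: per-position offset at the column minimum
        self._offsets = self.log_odds.min(axis=1)
        total_range = float((self.log_odds.max(axis=1) - self._offsets).sum())
        self._scale = (self.granularity * w) / total_range if total_range > 0 else 1.0
        self.int_scores = np.rint(
            (self.log_odds - self._offsets[:, None]) * self._scale
        ).astype(np.int64)
        self._tail = self._score_tail()

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    # -- exact discretized null distribution ----------------------------
    def _score_tail(self) -> np.ndarray:
        """tail[t] = P(integer score >= t) for a background-random w-mer."""
        max_total = int(self.int_scores.max(axis=1).sum())
        dist = np.zeros(max_total + 1)
        dist[0] = 1.0
        top = 0
        for i in range(self.width):
            new = np.zeros(max_total + 1)
            for j in range(4):
                s = int(self.int_scores[i, j])
                new[s: top + s + 1] += dist[: top + 1] * self.background[j]
            row_max = int(self.int_scores[i].max())
            top += row_max
            dist = new
        return np.cumsum(dist[::-1])[::-1]

    def int_score(self, kmer: str) -> int | None:
        """Integer grid score of a w-mer; None if it has non-ACGT letters."""
        total = 0
        for i, ch in enumerate(kmer):
            j = BASE_INDEX.get(ch)
            if j is None:
                return None
            total += int(self.int_scores[i, j])
        return total

    def real_score(self, kmer: str) -> float:
        return float(sum(self.log_odds[i, BASE_INDEX[c]] for i, c in enumerate(kmer)))

    def pvalue_from_int(self, t: int) -> float:
        t = max(0, min(int(t), len(self._tail) - 1))
        return float(self._tail[t])

    def pvalue_from_score(self, score: float) -> float:
        """p-value of a real-valued log-odds score under the background model.

        The score is snapped to the integer grid (nearest step), then the
        exact DP tail of the discretized distribution is returned; the
        discretization error is bounded by half a grid step per position.
        """
        if score > self.max_score + 1e-9 or score < self.min_score - 1e-9:
            raise MotifError(
                f"score {score} outside attainable range "
                f"[{self.min_score}, {self.max_score}]")
        t = int(np.rint((score - float(self._offsets.sum())) * self._scale))
        return self.pvalue_from_int(t)


def pvalue_from_score(pwm: PWM, score: float) -> float:
    return pwm.pvalue_from_score(score)


# ---------------------------------------------------------------------------
# MEME-format I/O (probability matrices)
# ---------------------------------------------------------------------------

def write_meme(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width}\n")
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            background = np.array([float(toks[k] ) for k in range(1, 8, 2)])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(1, w + 1):
                rows.append([float(x) for x in lines[i + k].split()])
            pwms.append(PWM(id=motif_id, matrix=np.array(rows), background=background))
            i += w
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# Window extraction and scanning
# ---------------------------------------------------------------------------

@dataclass
class AlleleWindows:
    variant_id: str
    ref_seq: str
    alt_seq: str
    center: int           # index of the variant base within the window
    truncated: bool


def extract_allele_windows(
    chrom: str, pos: int, ref: str, alt: str,
    genome: Mapping[str, str], flank: int = DEFAULT_FLANK,
    variant_id: str = "",
) -> AlleleWindows:
    """Sequence windows of +/-``flank`` nt around a SNV for both alleles.

    ``pos`` is 1-based (VCF).  Windows near chromosome ends are truncated and
    flagged.  Raises if the genome base disagrees with the VCF ref.
    """
    seq = genome[chrom]
    pos0 = pos - 1
    if seq[pos0] != ref:
        raise MotifError(
            f"{variant_id or chrom + ':' + str(pos)}: genome base "
            f"{seq[pos0]!r} != VCF ref {ref!r}")
    lo = max(0, pos0 - flank)
    hi = min(len(seq), pos0 + flank + 1)
    window = seq[lo:hi]
    center = pos0 - lo
    alt_seq = window[:center] + alt + window[center + 1:]
    return AlleleWindows(variant_id=variant_id, ref_seq=window, alt_seq=alt_seq,
                         center=center,
                         truncated=(hi - lo) < 2 * flank + 1)


@dataclass
class MotifCall:
    variant_id: str
    pwm_id: str
    allele: str               # 'ref' or 'alt'
    offset: int | None        # placement start within the window; None if no placement
    strand: str | None
    score: float
    p_value: float
    significant: bool


def scan_allele(seq: str, center: int, pwm: PWM, alpha: float,
                variant_id: str = "", allele: str = "ref") -> MotifCall:
    """Best-scoring placement of ``pwm`` whose footprint covers ``center``.

    Both strands are evaluated; the minus strand scores the reverse
    complement of the placement.  The call reports the placement with the
    lowest p-value (ties: plus strand, then leftmost offset) and whether it
    clears ``alpha``.
    """
    w = pwm.width
    best: tuple[int, int, str] | None = None  # (int score, offset, strand)
    lo = max(0, center - w + 1)
    hi = min(len(seq) - w, center)
    for o in range(lo, hi + 1):
        kmer = seq[o:o + w]
        for strand, s in (("+", pwm.int_score(kmer)),
                          ("-", pwm.int_score(kmer[::-1].translate(COMPLEMENT)))):
            if s is None:
                continue
            if best is None or s > best[0]:
                best = (s, o, strand)
    if best is None:
        return MotifCall(variant_id=variant_id, pwm_id=pwm.id, allele=allele,
                         offset=None, strand=None, score=float("-inf"),
                         p_value=1.0, significant=False)
    t, offset, strand = best
    kmer = seq[offset:offset + w]
    if strand == "-":
        kmer = kmer[::-1].translate(COMPLEMENT)
    p = pwm.pvalue_from_int(t)
    return MotifCall(variant_id=variant_id, pwm_id=pwm.id, allele=allele,
                     offset=offset, strand=strand, score=pwm.real_score(kmer),
                     p_value=p, significant=p < alpha)


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test alpha after Bonferroni correction across ``n_tests``."""
    if n_tests < 1:
        raise MotifError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


@dataclass
class MotifImpact:
    variant_id: str
    pwm_id: str
    verdict: str              # 'created', 'disrupted', 'none'
    ref_call: MotifCall
    alt_call: MotifCall

    @property
    def score_delta(self) -> float:
        return self.alt_call.score - self.ref_call.score


def classify_motif_impact(
    windows: AlleleWindows, pwms: Sequence[PWM], alpha: float
) -> tuple[list[MotifImpact], bool, bool]:
    """Per-PWM created/disrupted verdicts for one variant, plus any-flags.

    created: only the alternate allele has a significant best placement;
    disrupted: only the reference allele does; significant for both or
    neither: verdict 'none' (the score delta stays available on the impact).
    """
    impacts = []
    any_created = any_disrupted = False
    for pwm in pwms:
        ref_call = scan_allele(windows.ref_seq, windows.center, pwm, alpha,
                               variant_id=windows.variant_id, allele="ref")
        alt_call = scan_allele(windows.alt_seq, windows.center, pwm, alpha,
                               variant_id=windows.variant_id, allele="alt")
        if alt_call.significant and not ref_call.significant:
            verdict = "created"
            any_created = True
        elif ref_call.significant and not alt_call.significant:
            verdict = "disrupted"
            any_disrupted = True
        else:
            verdict = "none"
        impacts.append(MotifImpact(variant_id=windows.variant_id, pwm_id=pwm.id,
                                   verdict=verdict, ref_call=ref_call,
                                   alt_call=alt_call))
    return impacts, any_created, any_disrupted


def scan_variants(
    sites: pd.DataFrame, genome: Mapping[str, str], pwms: Sequence[PWM],
    alpha: float | None = None, family_alpha: float = 0.05,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Scan every SNV in ``sites`` against the PWM library.

    ``alpha=None`` applies the Bonferroni correction across the number of
    scanned variants (family alpha 0.05 by default).  Returns ``sites`` with
    ``any_created`` / ``any_disrupted`` flag columns; per-(variant, PWM)
    verdicts are in the ``motif_calls`` attribute of the result frame.
    """
    if alpha is None:
        alpha = bonferroni_alpha(family_alpha, len(sites))
    created, disrupted, call_rows = [], [], []
    for row in sites.itertuples():
        try:
            win = extract_allele_windows(row.chrom, int(row.pos), row.ref, row.alt,
                                         genome, flank=flank,
                                         variant_id=str(row.variant_id))
        except MotifError as exc:
            warnings.warn(str(exc), stacklevel=2)
            created.append(False)
            disrupted.append(False)
            continue
        impacts, any_c, any_d = classify_motif_impact(win, pwms, alpha)
        created.append(any_c)
        disrupted.append(any_d)
        for im in impacts:
            if im.verdict != "none":
                call_rows.append({
                    "variant_id": im.variant_id, "pwm_id": im.pwm_id,
                    "verdict": im.verdict,
                    "ref_score": im.ref_call.score, "alt_score": im.alt_call.score,
                    "ref_p": im.ref_call.p_value, "alt_p": im.alt_call.p_value,
                })
    out = sites.copy()
    out["any_created"] = created
    out["any_disrupted"] = disrupted
    out.attrs["motif_calls"] = pd.DataFrame(call_rows)
    out.attrs["alpha"] = alpha
    return out


def impact_proportion_test(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frequency-class proportions of variants creating/disrupting motifs,
    with pairwise Fisher exact contrasts."""
    from .enrichment import fisher_enrichment

    classes = [c for c in ("common", "rare", "novel")
               if (sites["freq_class"] == c).any()]
    if len(classes) < 2:
        warnings.warn("fewer than two populated frequency classes", stacklevel=2)
    prop_rows, contrast_rows = [], []
    for flag in ("any_created", "any_disrupted"):
        per = {}
        for cls in classes:
            sub = sites[sites["freq_class"] == cls]
            k, n = int(sub[flag].sum()), len(sub)
            per[cls] = (k, n)
            prop_rows.append({"flag": flag, "class": cls, "n_flagged": k,
                              "n_total": n, "proportion": k / n if n else np.nan})
        for i, ca in enumerate(classes):
            for cb in classes[i + 1:]:
                (a, na), (b, nb) = per[ca], per[cb]
                res = fisher_enrichment(a, na - a, b, nb - b)
                contrast_rows.append({"flag": flag, "class_a": ca, "class_b": cb,
                                      "odds_ratio": res.odds_ratio,
                                      "p_value": res.p_value})
    return pd.DataFrame(prop_rows), pd.DataFrame(contrast_rows)
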