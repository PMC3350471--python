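"""Localization classes and enrichment statistics.

Implements the five-class SNP localization (intergenic / intronic / 5'-UTR /
CDS / 3'-UTR), odds-ratio estimation with Woolf log confidence intervals and
Haldane-Anscombe correction, the resampled empirical null for enrichment
significance, MAF-binned and r2-swept enrichment, Fisher's combined
probability, the rough FDR level and the Pearson chi-squared test.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_core import SnpRecord, TranscriptModel
from . import ld_toolkit

log = logging.getLogger(__name__)


class LocationClass(enum.Enum):
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    UTR5 = "5'-UTR"
    CDS = "CDS"
    UTR3 = "3'-UTR"


#: multi-transcript precedence, most specific first (configurable at call sites)
DEFAULT_PRECEDENCE = (LocationClass.CDS, LocationClass.UTR3, LocationClass.UTR5,
                      LocationClass.INTRONIC, LocationClass.INTERGENIC)


def _locate_in_transcript(pos: int, t: TranscriptModel) -> LocationClass:
    tpos = t.genomic_to_tx(pos)
    if tpos is None:
        if t.tx_start <= pos < t.tx_end:
            return LocationClass.INTRONIC
        return LocationClass.INTERGENIC
    cds_lo, cds_hi = t.cds_tx_interval()
    if tpos < cds_lo:
        return LocationClass.UTR5
    if tpos < cds_hi:
        return LocationClass.CDS
    return LocationClass.UTR3


def classify_snp_location(snp: SnpRecord, transcripts: Sequence[TranscriptModel],
                          precedence: Sequence[LocationClass] = DEFAULT_PRECEDENCE
                          ) -> LocationClass:
    """Single deterministic label per SNP under the documented precedence."""
    labels = {_locate_in_transcript(snp.pos, t) for t in transcripts
              if t.chrom == snp.chrom}
    for cls in precedence:
        if cls in labels:
            return cls
    return LocationClass.INTERGENIC


def build_transcript_index(transcripts: Sequence[TranscriptModel]) -> dict:
    """Per-chromosome interval tree over transcript spans."""
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.tx_start, t.tx_end, t)
    return trees


def classify_locations(snps: Iterable[SnpRecord], transcripts: Sequence[TranscriptModel],
                       precedence: Sequence[LocationClass] = DEFAULT_PRECEDENCE) -> dict:
    """{snp_id: LocationClass} for many SNPs via an interval index."""
    trees = build_transcript_index(transcripts)
    out = {}
    for snp in snps:
        tree = trees.get(snp.chrom)
        hits = [iv.data for iv in tree[snp.pos]] if tree is not None else []
        labels = {_locate_in_transcript(snp.pos, t) for t in hits}
        out[snp.snp_id] = next((c for c in precedence if c in labels),
                               LocationClass.INTERGENIC)
    return out


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = test in-class, b = test not, c = background in-class,
    d = background not.  OR = (a d)/(b c)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def column_swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class EnrichmentResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_empirical: float = math.nan
    n_null: int = 0
    corrected: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def odds_ratio_ci(table: ContingencyTable2x2, alpha: float = 0.05) -> EnrichmentResult:
    """Odds ratio with a Woolf (log-scale) CI.

    If any cell is zero, the Haldane-Anscombe +0.5 correction is applied to
    all four cells and the result flagged ``corrected``.  An empty margin
    (a+b = 0 or c+d = 0) is an error.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("empty margin: odds ratio undefined")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return EnrichmentResult(or_est, math.exp(math.log(or_est) - z * se),
                            math.exp(math.log(or_est) + z * se),
                            corrected=corrected)


def class_table(test_ids: Iterable[str], classes: Mapping[str, LocationClass],
                location_class: LocationClass = LocationClass.UTR3,
                mode: str = "snp", blocks: Sequence | None = None,
                min_block_size: int = 1) -> ContingencyTable2x2:
    """2x2 table of in-class membership, test set vs full background.

    ``mode='snp'`` counts SNPs; ``mode='block'`` counts each LD block once
    (one LD bin, a single signal), a block being in-class when its class set
    contains the target class and in the test set when it holds >= 1 test
    SNP; ``min_block_size`` restricts to larger blocks (blocks-only mode).
    """
    test = set(test_ids)
    if mode == "snp":
        a = sum(1 for s in test if classes.get(s) == location_class)
        b = len(test & set(classes)) - a
        c = sum(1 for v in classes.values() if v == location_class)
        d = len(classes) - c
        return ContingencyTable2x2(a, b, c, d)
    if mode != "block":
        raise ValueError(f"unknown mode {mode!r}")
    if blocks is None:
        raise ValueError("block mode requires blocks")
    a = b = c = d = 0
    for blk in blocks:
        if len(blk.member_snp_ids) < min_block_size:
            continue
        in_class = location_class in blk.location_classes
        in_test = bool(blk.member_snp_ids & test)
        c += in_class
        d += not in_class
        if in_test:
            a += in_class
            b += not in_class
    return ContingencyTable2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# Resampled empirical null
# ---------------------------------------------------------------------------

def _log_or(table: ContingencyTable2x2) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a * d) / (b * c))


def null_enrichment_distribution(panel: "ld_toolkit.HaplotypePanel",
                                 classes: Mapping[str, LocationClass],
                                 n_sentinels: int, reps: int = 1000,
                                 r2_min: float = 0.8, seed: int = 0,
                                 location_class: LocationClass = LocationClass.UTR3,
                                 neighbors: list | None = None) -> np.ndarray:
    """Per-replicate log odds ratios under random sentinel choice.

    Each replicate draws ``n_sentinels`` panel SNPs uniformly without
    replacement, extends them by LD exactly as the observed set is extended,
    and records the in-class log OR against the full panel.  Deterministic
    under ``seed``.
    """
    if reps < 30:
        log.warning("reps=%d < 30: null distribution fit is unreliable", reps)
    if neighbors is None:
        neighbors = ld_toolkit.neighbor_lists(panel, r2_min=r2_min)
    rng = np.random.default_rng(seed)
    ids = np.asarray(panel.snp_ids, dtype=object)
    out = np.empty(reps)
    for r in range(reps):
        chosen = rng.choice(panel.n_snps, size=n_sentinels, replace=False)
        ext: set[int] = set()
        for i in chosen:
            ext.update(neighbors[int(i)])
        table = class_table((ids[j] for j in ext), classes, location_class)
        out[r] = _log_or(table)
    return out


def empirical_p(observed: float, null_values: Sequence[float]) -> float:
    """Probability of a null value at least as extreme (one-sided, upper).

    Both the rank-based exceedance (r+1)/(n+1) and the tail of a normal fit
    to the null are computed; the conservative maximum is returned and both
    components are logged.
    """
    null = np.asarray(null_values, dtype=float)
    n = null.size
    if n == 0:
        raise ValueError("empty null sample")
    emp = (np.count_nonzero(null >= observed) + 1) / (n + 1)
    mu, sd = null.mean(), null.std(ddof=1) if n > 1 else 0.0
    fit = float(stats.norm.sf(observed, loc=mu, scale=sd)) if sd > 0 else float(observed <= mu)
    log.info("empirical_p components: exceedance=%.4g normal_fit=%.4g", emp, fit)
    return max(emp, fit)


# ---------------------------------------------------------------------------
# MAF-binned and r2-swept enrichment
# ---------------------------------------------------------------------------

DEFAULT_MAF_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def maf_binned_or(test_snps: Sequence[SnpRecord], background_snps: Sequence[SnpRecord],
                  classes: Mapping[str, LocationClass],
                  bins: Sequence[float] = DEFAULT_MAF_BINS,
                  location_class: LocationClass = LocationClass.UTR3) -> dict:
    """Per-MAF-bin odds ratio of in-class membership, test vs background.

    SNP counts are compared within the respective bins; a bin with no test
    SNPs (or an empty margin) maps to None (undefined, not zero).
    """
    def bin_of(maf):
        for i in range(len(bins) - 1):
            lo, hi = bins[i], bins[i + 1]
            if lo <= maf < hi or (i == len(bins) - 2 and maf == hi):
                return i
        return None

    out = {}
    for i in range(len(bins) - 1):
        key = (bins[i], bins[i + 1])
        test = [s for s in test_snps if bin_of(s.maf) == i]
        bg = [s for s in background_snps if bin_of(s.maf) == i]
        if not test or not bg:
            out[key] = None
            continue
        a = sum(1 for s in test if classes.get(s.snp_id) == location_class)
        c = sum(1 for s in bg if classes.get(s.snp_id) == location_class)
        table = ContingencyTable2x2(a, len(test) - a, c, len(bg) - c)
        try:
            out[key] = odds_ratio_ci(table)
        except ValueError:
            out[key] = None
    return out


def r2_sweep_or(sentinels: Iterable[str], panel, classes: Mapping[str, LocationClass],
                thresholds: Sequence[float] = tuple(np.arange(0.5, 1.0001, 0.05)),
                location_class: LocationClass = LocationClass.UTR3,
                window: int = ld_toolkit.DEFAULT_WINDOW) -> dict:
    """Accumulative LD extension per r2 threshold with the resulting OR.

    Returns {threshold: (EnrichmentResult, extended-set size)}; lowering the
    threshold can only grow the extended set.
    """
    sentinels = list(sentinels)
    out = {}
    for thr in thresholds:
        ext = ld_toolkit.extend_sentinels(sentinels, panel, r2_min=float(thr),
                                          window=window)
        table = class_table(ext, classes, location_class)
        try:
            res = odds_ratio_ci(table)
        except ValueError:
            res = None
        out[round(float(thr), 6)] = (res, len(ext))
    return out


# ---------------------------------------------------------------------------
# Small statistics
# ---------------------------------------------------------------------------

def fisher_combined_p(pvalues: Sequence[float]) -> float:
    """Fisher's combined probability: chi2 = -2 sum(ln p) on 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(statistic, df=2 * p.size))


def rough_fdr_level(alpha: float, m: int) -> float:
    """Rough-FDR adjusted significance level alpha (m+1)/(2m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha * (m + 1) / (2 * m)


Chi2Result = namedtuple("Chi2Result", "statistic p_value low_expected")


def contingency_chi2(table) -> Chi2Result:
    """Pearson chi-squared on an r x c count table, (r-1)(c-1) df, no
    continuity correction; ``low_expected`` flags any expected count < 5."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.size == 0:
        raise ValueError("table must be 2-dimensional")
    stat, p, _, expected = stats.chi2_contingency(obs, correction=False)
    return Chi2Result(float(stat), float(p), bool((expected < 5).any()))
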