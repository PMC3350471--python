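"""Sequence-level mechanism classifiers for 3'-UTR variants.

Three classifiers operate on transcript-sense sequence around a SNP:

* poly(A)-signal change -- scan the 11-nt window centered on the SNP for the
  abundant poly(A) hexamer variants, for SNPs lying 10-30 nt upstream of an
  annotated cleavage site;
* splice-site change -- a trainable position-weight-matrix scorer with
  logistic likelihood calibration (donor: 9-nt window, 3 exonic + 6 intronic;
  acceptor: 23-nt window, 20 intronic + 3 exonic), applied to a 60-nt window
  centered on the SNP in both alleles, with gain/loss/increase/decrease
  taxonomy, border-distance retention filters and RISC-site-loss accounting;
* miRNA-recognition-element (MRE) change -- exact canonical seed matching
  (6mer, 7mer-A1, 7mer-m8, 8mer) restricted to functional sites near CLIP
  cluster centers with miRNA read support, an in-cluster enrichment filter
  for the candidate miRNA pools, and disruption / creation / substitution
  calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .io_core import ClipCluster, MiRna, TranscriptModel, revcomp

log = logging.getLogger(__name__)

#: the 12 most abundant poly(A) signal hexamer variants (DNA alphabet),
#: most frequent first; configurable at every call site
DEFAULT_POLYA_HEXAMERS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)

POLYA_MIN_DIST = 10   # nt from SNP to cleavage site, transcript orientation
POLYA_MAX_DIST = 30

_DNA = str.maketrans("Uu", "Tt")


def _dna(seq: str) -> str:
    return seq.upper().translate(_DNA)


# ---------------------------------------------------------------------------
# poly(A) signals
# ---------------------------------------------------------------------------

@dataclass
class PolyAClassification:
    snp_id: str
    call: str  # CREATED | DISRUPTED | SYNONYMOUS | NONE
    hexamer_ref: str | None = None
    hexamer_alt: str | None = None
    reason: str | None = None

    def __post_init__(self):
        if self.call == "CREATED" and self.hexamer_alt is None:
            raise ValueError("CREATED requires the created hexamer")
        if self.call == "DISRUPTED" and self.hexamer_ref is None:
            raise ValueError("DISRUPTED requires the disrupted hexamer")


def _hexamer_hits(window: str, hexamers: Sequence[str], offset: int) -> set:
    """{(absolute frame position, hexamer)} for listed hexamers in a window."""
    hits = set()
    for i in range(len(window) - 5):
        hx = window[i:i + 6]
        if hx in hexamers:
            hits.add((offset + i, hx))
    return hits


def scan_polya(snp_id: str, snp_tx_pos: int, seq_ref: str, seq_alt: str,
               polya_tx_positions: Sequence[int],
               hexamers: Sequence[str] = DEFAULT_POLYA_HEXAMERS) -> PolyAClassification:
    """Classify a SNP's effect on poly(A) signal hexamers.

    Sequences are transcript-sense (DNA or RNA typed); positions are
    transcript coordinates.  Only SNPs 10-30 nt upstream of an annotated
    cleavage position are in range; others return NONE / "out of range".
    All six hexamer frames of the 11-nt SNP-centered window are scanned in
    both alleles; a swap of one listed hexamer for another is SYNONYMOUS.
    """
    if not any(POLYA_MIN_DIST <= p - snp_tx_pos <= POLYA_MAX_DIST
               for p in polya_tx_positions):
        return PolyAClassification(snp_id, "NONE", reason="out of range")
    lo = max(0, snp_tx_pos - 5)
    hi = min(len(seq_ref), snp_tx_pos + 6)
    if hi - lo < 11:
        log.info("%s: poly(A) window truncated to %d nt by the UTR end",
                 snp_id, hi - lo)
    ref_hits = _hexamer_hits(_dna(seq_ref[lo:hi]), hexamers, lo)
    alt_hits = _hexamer_hits(_dna(seq_alt[lo:hi]), hexamers, lo)
    if ref_hits == alt_hits:
        if ref_hits:
            return PolyAClassification(snp_id, "NONE", reason="signal unaffected")
        return PolyAClassification(snp_id, "NONE", reason="no signal in window")
    if ref_hits and not alt_hits:
        return PolyAClassification(snp_id, "DISRUPTED",
                                   hexamer_ref=sorted(ref_hits)[0][1])
    if alt_hits and not ref_hits:
        return PolyAClassification(snp_id, "CREATED",
                                   hexamer_alt=sorted(alt_hits)[0][1])
    return PolyAClassification(snp_id, "SYNONYMOUS",
                               hexamer_ref=sorted(ref_hits)[0][1],
                               hexamer_alt=sorted(alt_hits)[0][1])


# ---------------------------------------------------------------------------
# splice-site model
# ---------------------------------------------------------------------------

DONOR_WINDOW = 9       # 3 exonic + 6 intronic, GT at offsets 3-4
DONOR_EXONIC = 3
ACCEPTOR_WINDOW = 23   # 20 intronic + 3 exonic, AG at offsets 18-19
ACCEPTOR_INTRONIC = 20

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _core_ok(window: str, site_type: str) -> bool:
    if site_type == "DONOR":
        return window[DONOR_EXONIC:DONOR_EXONIC + 2] == "GT"
    return window[ACCEPTOR_INTRONIC - 2:ACCEPTOR_INTRONIC] == "AG"


@dataclass
class SpliceModel:
    """Weight-matrix splice-site scorer with logistic likelihood calibration.

    The weight matrices hold per-position log-odds against a stated
    background; ``*_calibration`` are (slope, intercept) of a monotone
    logistic map from total log-odds to a likelihood in [0, 1].  Windows
    lacking the canonical GT/AG core score likelihood 0.
    """

    donor_pwm: np.ndarray
    acceptor_pwm: np.ndarray
    donor_calibration: tuple
    acceptor_calibration: tuple
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def _score(self, window: str, pwm: np.ndarray) -> float:
        return float(sum(pwm[_BASE_INDEX[b], i] for i, b in enumerate(window)))

    def score(self, window: str, site_type: str) -> float:
        pwm = self.donor_pwm if site_type == "DONOR" else self.acceptor_pwm
        if len(window) != pwm.shape[1]:
            raise ValueError(f"{site_type} window must be {pwm.shape[1]} nt")
        return self._score(_dna(window), pwm)

    def likelihood(self, window: str, site_type: str) -> float:
        window = _dna(window)
        if not _core_ok(window, site_type):
            return 0.0
        slope, intercept = (self.donor_calibration if site_type == "DONOR"
                            else self.acceptor_calibration)
        from scipy.special import expit
        return float(expit(slope * self.score(window, site_type) + intercept))


def _pwm_from_examples(examples: Sequence[str], width: int,
                       background: Sequence[float]) -> np.ndarray:
    counts = np.ones((4, width))  # additive pseudocount 1
    for ex in examples:
        for i, b in enumerate(ex):
            counts[_BASE_INDEX[b], i] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return np.log(freqs / np.asarray(background)[:, None])


def train_splice_model(donor_examples: Sequence[str], acceptor_examples: Sequence[str],
                       background_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                       n_negatives: int = 500, seed: int = 0,
                       min_examples: int = 50) -> SpliceModel:
    """Fit donor/acceptor weight matrices and their likelihood calibration.

    Examples lacking the canonical GT/AG core are rejected (count reported).
    Calibration fits a one-dimensional logistic regression of site identity
    on the PWM score, using core-bearing random background windows as
    negatives, so that true sites map to likelihoods >= 0.5 at the training
    rate.
    """
    rng = np.random.default_rng(seed)
    sets = {}
    for name, examples, width in (("DONOR", donor_examples, DONOR_WINDOW),
                                  ("ACCEPTOR", acceptor_examples, ACCEPTOR_WINDOW)):
        kept = []
        rejected = 0
        for ex in examples:
            ex = _dna(ex)
            if len(ex) != width or set(ex) - set("ACGT"):
                raise ValueError(f"{name} example of wrong width/alphabet: {ex!r}")
            if _core_ok(ex, name):
                kept.append(ex)
            else:
                rejected += 1
        if rejected:
            log.warning("train_splice_model: rejected %d %s examples without "
                        "canonical core", rejected, name)
        if len(kept) < min_examples:
            raise ValueError(f"need >= {min_examples} {name} examples, got {len(kept)}")
        sets[name] = (kept, width)

    bg = np.asarray(background_freqs, dtype=float)
    bg = bg / bg.sum()
    pwms, calibs = {}, {}
    for name, (kept, width) in sets.items():
        pwm = _pwm_from_examples(kept, width, bg)
        # negatives: background windows with the core dinucleotide imposed
        negs = []
        for _ in range(n_negatives):
            w = "".join(rng.choice(list("ACGT"), size=width, p=bg))
            if name == "DONOR":
                w = w[:DONOR_EXONIC] + "GT" + w[DONOR_EXONIC + 2:]
            else:
                w = w[:ACCEPTOR_INTRONIC - 2] + "AG" + w[ACCEPTOR_INTRONIC:]
            negs.append(w)
        def score(window):
            return sum(pwm[_BASE_INDEX[b], i] for i, b in enumerate(window))
        x = np.array([[score(w)] for w in kept + negs])
        y = np.array([1] * len(kept) + [0] * len(negs))
        # negatives upweighted so the 0.5 likelihood cut is conservative for
        # non-sites; weights are relative to balanced classes
        w = np.where(y == 1, 1.0 / max(len(kept), 1), 1.6 / n_negatives)
        clf = LogisticRegression(C=10.0).fit(x, y, sample_weight=w)
        pwms[name] = pwm
        calibs[name] = (float(clf.coef_[0, 0]), float(clf.intercept_[0]))
    return SpliceModel(pwms["DONOR"], pwms["ACCEPTOR"],
                       calibs["DONOR"], calibs["ACCEPTOR"], tuple(bg))


# ---------------------------------------------------------------------------
# splice-change classification
# ---------------------------------------------------------------------------

@dataclass
class SpliceChangeEvent:
    snp_id: str
    transcript_id: str
    site_type: str       # DONOR | ACCEPTOR
    change: str          # GAIN | LOSS | INCREASE | DECREASE
    likelihood_ref: float
    likelihood_alt: float
    position: int        # junction position, transcript coordinates
    retained: bool = True
    risc_loss_fraction: float = 0.0

    def __post_init__(self):
        if self.change == "GAIN" and not (self.likelihood_alt >= 0.5 > self.likelihood_ref):
            raise ValueError("GAIN requires alt >= 0.5 > ref")
        if self.change == "LOSS" and not (self.likelihood_ref >= 0.5 > self.likelihood_alt):
            raise ValueError("LOSS requires ref >= 0.5 > alt")


LIKELIHOOD_CUTOFF = 0.5
CHANGE_TOLERANCE = 0.05
ACCEPTOR_BORDER_RANGE = (-100, 10)   # relative to an annotated border, nt
DONOR_BORDER_RANGE = (-10, 10)
SCAN_WINDOW = 60


def classify_splice_changes(snp_id: str, snp_tx_pos: int, seq_ref: str, seq_alt: str,
                            model: SpliceModel, transcript_id: str = "",
                            junctions: Sequence[int] = (),
                            tolerance: float = CHANGE_TOLERANCE,
                            scan_window: int = SCAN_WINDOW,
                            filter_semantics: str = "retain") -> list:
    """Score every donor/acceptor frame touching the SNP-centered window in
    both alleles and classify the differences.

    Likelihood changes below ``tolerance`` are ignored.  A gain of a
    completely new site is always kept; LOSS / INCREASE / DECREASE events are
    retained only near an annotated border (acceptor: -100..+10 nt, donor:
    +-10 nt) under the default semantics, or excluded near borders under
    ``filter_semantics='exclude'``.
    """
    if filter_semantics not in ("retain", "exclude"):
        raise ValueError("filter_semantics must be 'retain' or 'exclude'")
    half = scan_window // 2
    win_lo, win_hi = snp_tx_pos - half, snp_tx_pos + half
    events = []
    for site_type, width, junction_off, border_range in (
            ("DONOR", DONOR_WINDOW, DONOR_EXONIC, DONOR_BORDER_RANGE),
            ("ACCEPTOR", ACCEPTOR_WINDOW, ACCEPTOR_INTRONIC, ACCEPTOR_BORDER_RANGE)):
        lo = max(0, win_lo - width + 1)
        hi = min(len(seq_ref) - width, win_hi - 1)
        for s in range(lo, hi + 1):
            l_ref = model.likelihood(seq_ref[s:s + width], site_type)
            l_alt = model.likelihood(seq_alt[s:s + width], site_type)
            if abs(l_alt - l_ref) < tolerance:
                continue
            if l_alt >= LIKELIHOOD_CUTOFF > l_ref:
                change = "GAIN"
            elif l_ref >= LIKELIHOOD_CUTOFF > l_alt:
                change = "LOSS"
            elif min(l_ref, l_alt) >= LIKELIHOOD_CUTOFF:
                change = "INCREASE" if l_alt > l_ref else "DECREASE"
            else:
                continue
            junction = s + junction_off
            if change == "GAIN":
                retained = True
            else:
                near = any(border_range[0] <= junction - b <= border_range[1]
                           for b in junctions)
                retained = near if filter_semantics == "retain" else not near
            events.append(SpliceChangeEvent(snp_id, transcript_id, site_type,
                                            change, l_ref, l_alt, junction,
                                            retained))
    return events


def risc_loss_fraction(gain_event: SpliceChangeEvent, transcript: TranscriptModel,
                       clusters: Sequence[ClipCluster]) -> float:
    """Fraction of the transcript's RISC-binding sites lost to the novel
    splice junction.

    An acceptor gain excises the exonic region from the annotated upstream
    border (or the transcript start) to the novel site; a donor gain excises
    from the novel site to the annotated downstream border (or the transcript
    end).  A cluster is lost when its center lies in the excised region.
    """
    own = [c for c in clusters if c.transcript_id == transcript.transcript_id]
    if not own:
        return 0.0
    junctions = transcript.splice_junction_tx_positions()
    p = gain_event.position
    if gain_event.site_type == "ACCEPTOR":
        upstream = [b for b in junctions if b <= p]
        excised = (max(upstream) if upstream else 0, p)
    else:
        downstream = [b for b in junctions if b >= p]
        excised = (p, min(downstream) if downstream else transcript.length)
    lost = 0
    for c in own:
        center_tx = transcript.genomic_to_tx(c.center)
        if center_tx is not None and excised[0] <= center_tx < excised[1]:
            lost += 1
    return lost / len(own)


# ---------------------------------------------------------------------------
# MRE matching
# ---------------------------------------------------------------------------

MATCH_TYPES = ("6MER", "7MER_A1", "7MER_M8", "8MER")
_SITE_LENGTH = {"6MER": 6, "7MER_A1": 7, "7MER_M8": 7, "8MER": 8}


@dataclass
class MreMatch:
    mirna_id: str
    match_type: str
    utr_start: int            # 5' end of the seed-complementary site
    within_cluster: bool = False
    cluster_distance: int | None = None

    @property
    def span(self):
        return (self.utr_start, self.utr_start + _SITE_LENGTH[self.match_type])


def find_seed_matches(utr_seq: str, mirna: MiRna,
                      match_types: Sequence[str] = MATCH_TYPES) -> list:
    """All canonical seed-complementary sites of one miRNA in a sequence.

    Site definitions (target 5'->3'): 6mer = reverse complement of miRNA
    positions 2-7; 7mer-m8 = reverse complement of 2-8; 7mer-A1 = 6mer
    followed by A (opposite miRNA position 1); 8mer = 7mer-m8 followed by A.
    Overlapping sites are all reported; at each seed-core locus only the most
    specific requested type is reported.
    """
    bad = set(match_types) - set(MATCH_TYPES)
    if bad:
        raise ValueError(f"unknown match types: {sorted(bad)}")
    seq = _dna(utr_seq)
    mseq = _dna(mirna.mature_seq)
    core = revcomp(mseq[1:7])          # seed 2-7 complement, 6 nt
    m8_comp = revcomp(mseq[7])         # complement of miRNA position 8
    out = []
    start = seq.find(core)
    while start != -1:
        has_m8 = start >= 1 and seq[start - 1] == m8_comp
        has_a1 = start + 6 < len(seq) and seq[start + 6] == "A"
        if has_m8 and has_a1 and "8MER" in match_types:
            out.append(MreMatch(mirna.mirna_id, "8MER", start - 1))
        elif has_m8 and "7MER_M8" in match_types:
            out.append(MreMatch(mirna.mirna_id, "7MER_M8", start - 1))
        elif has_a1 and "7MER_A1" in match_types:
            out.append(MreMatch(mirna.mirna_id, "7MER_A1", start))
        elif "6MER" in match_types:
            out.append(MreMatch(mirna.mirna_id, "6MER", start))
        start = seq.find(core, start + 1)
    return out


MAX_CENTER_DISTANCE = 21


def functional_mres(matches: Iterable[MreMatch], clusters: Sequence[ClipCluster],
                    transcript: TranscriptModel, tx_offset: int = 0,
                    max_center_distance: int = MAX_CENTER_DISTANCE) -> list:
    """Restrict seed matches to functional ones: within ``max_center_distance``
    nt (inclusive) of a same-transcript cluster center AND >= 1 sequencing
    read for the matched miRNA in that cluster.

    ``tx_offset`` converts match coordinates (e.g. UTR-relative) to
    transcript coordinates.
    """
    own = [(c, transcript.genomic_to_tx(c.center)) for c in clusters
           if c.transcript_id == transcript.transcript_id]
    out = []
    for m in matches:
        pos = m.utr_start + tx_offset
        best = None
        for c, center_tx in own:
            if center_tx is None:
                continue
            dist = abs(pos - center_tx)
            if dist <= max_center_distance and c.mirna_reads.get(m.mirna_id, 0) >= 1:
                if best is None or dist < best:
                    best = dist
        if best is not None:
            out.append(MreMatch(m.mirna_id, m.match_type, m.utr_start,
                                within_cluster=True, cluster_distance=best))
    return out


def mre_enrichment_filter(mirnas: Sequence[MiRna], utr_seqs: Mapping[str, str],
                          cluster_regions: Mapping[str, Sequence[tuple]],
                          alpha: float = 0.05) -> tuple:
    """Per-miRNA enrichment of seed matches inside RISC-binding regions.

    For each miRNA a 2x2 table of seed-match counts inside vs outside the
    cluster regions, corrected for per-nucleotide opportunity, is tested with
    a one-sided Fisher exact test; the kept pool is the set whose
    Benjamini-Hochberg adjusted p is < ``alpha``.

    ``cluster_regions`` maps transcript id -> half-open intervals in the same
    coordinates as ``utr_seqs``.  Returns ({mirna_id: p}, kept-id set).
    """
    inside_nt = outside_nt = 0
    for tid, seq in utr_seqs.items():
        regions = _merge_intervals(cluster_regions.get(tid, ()))
        cov = sum(min(hi, len(seq)) - max(lo, 0) for lo, hi in regions
                  if hi > 0 and lo < len(seq))
        inside_nt += cov
        outside_nt += len(seq) - cov
    pvals = {}
    for m in mirnas:
        a = c = 0
        for tid, seq in utr_seqs.items():
            regions = _merge_intervals(cluster_regions.get(tid, ()))
            for match in find_seed_matches(seq, m):
                if any(lo <= match.utr_start < hi for lo, hi in regions):
                    a += 1
                else:
                    c += 1
        table = [[a, max(inside_nt - a, 0)], [c, max(outside_nt - c, 0)]]
        pvals[m.mirna_id] = float(stats.fisher_exact(table, alternative="greater")[1])
    ids = list(pvals)
    adj = stats.false_discovery_control([pvals[i] for i in ids], method="bh")
    kept = {i for i, q in zip(ids, adj) if q < alpha}
    return pvals, kept


def _merge_intervals(intervals):
    ivs = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    out = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


# ---------------------------------------------------------------------------
# MRE change calling
# ---------------------------------------------------------------------------

@dataclass
class MreChangeResult:
    snp_id: str
    transcript_id: str
    disrupted: frozenset = frozenset()
    created: frozenset = frozenset()

    def __post_init__(self):
        self.disrupted = frozenset(self.disrupted)
        self.created = frozenset(self.created)

    @property
    def substitution(self) -> bool:
        return bool(self.disrupted) and bool(self.created)


def classify_mre_change(snp_id: str, transcript_id: str, snp_pos: int,
                        ref_functional: Sequence[MreMatch],
                        alt_functional: Sequence[MreMatch],
                        kept_mirnas_disrupt: set, kept_mirnas_create: set) -> MreChangeResult:
    """Disruption/creation/substitution calling at one SNP.

    A miRNA is disrupted when a functional MRE overlapping the SNP exists
    under the reference allele but not the alternate (or only a less specific
    one remains); created symmetrically, which counts the extension of an
    existing seed match to a longer type as a creation.  Pools restrict which
    miRNAs are eligible on each side; substitution = both sets non-empty.
    ``snp_pos`` must be in the same coordinates as the match positions.
    """
    def best_span(matches, mirna_id):
        lengths = [_SITE_LENGTH[m.match_type] for m in matches
                   if m.mirna_id == mirna_id and m.span[0] <= snp_pos < m.span[1]]
        return max(lengths) if lengths else 0

    mirnas = {m.mirna_id for m in ref_functional} | {m.mirna_id for m in alt_functional}
    disrupted, created = set(), set()
    for mid in mirnas:
        ref_len = best_span(ref_functional, mid)
        alt_len = best_span(alt_functional, mid)
        if ref_len > alt_len and mid in kept_mirnas_disrupt:
            disrupted.add(mid)
        elif alt_len > ref_len and mid in kept_mirnas_create:
            created.add(mid)
    return MreChangeResult(snp_id, transcript_id, frozenset(disrupted),
                           frozenset(created))


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

CONSERVATION_CUTOFF = 0.57


def conservation_flag(score: float | None, cutoff: float = CONSERVATION_CUTOFF):
    """Conserved iff score strictly exceeds the cutoff; None when the score
    is missing (excluded from conservation summaries)."""
    if score is None:
        return None
    return score > cutoff
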