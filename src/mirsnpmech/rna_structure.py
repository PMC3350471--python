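"""Equilibrium RNA base-pairing probabilities and the structure-change
statistic for 3'-UTR variants.

The ensemble model is deliberately simple: pseudoknot-free secondary
structures over Watson-Crick + GU pairs, a per-pair formation cost and a
nearest-neighbor stacking bonus, hairpin loops of >= 3 nt, Boltzmann weights
at a configurable kT.  It is not a full Turner model (no dangles, no special
loops); its partition function and base-pair probability matrix are computed
exactly by a McCaskill-style inside/outside dynamic program and validated
against exhaustive structure enumeration.  The downstream statistic -- the
Pearson correlation of per-nucleotide pairing scores between the two alleles
in a 41-nt window centered on a RISC-binding site -- only compares two nearly
identical sequences under the same model, which is what makes the simplified
energetics acceptable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import stats

log = logging.getLogger(__name__)

_CANONICAL_PAIRS = ("CG", "GC", "AU", "UA", "GU", "UG")

#: default stacking free energies, kcal/mol, keyed (outer pair, inner pair)
#: written 5'->3' on the outer strand; published-style nearest-neighbor values.
DEFAULT_STACK_ENERGIES = {
    ("CG", "CG"): -3.3, ("CG", "GC"): -2.4, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("GC", "AU"): -2.2, ("GC", "UA"): -2.4,
    ("AU", "CG"): -2.4, ("AU", "GC"): -2.1, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("AU", "AU"): -1.1, ("AU", "UA"): -1.3, ("UA", "AU"): -1.0, ("UA", "UA"): -1.1,
    ("CG", "GU"): -1.4, ("CG", "UG"): -1.5, ("GC", "GU"): -1.5, ("GC", "UG"): -1.3,
    ("GU", "CG"): -1.5, ("UG", "CG"): -1.4, ("GU", "GC"): -1.3, ("UG", "GC"): -1.5,
    ("AU", "GU"): -0.6, ("AU", "UG"): -0.5, ("UA", "GU"): -0.5, ("UA", "UG"): -0.7,
    ("GU", "AU"): -0.5, ("UG", "AU"): -0.6, ("GU", "UA"): -0.7, ("UG", "UA"): -0.5,
    ("GU", "GU"): -0.5, ("GU", "UG"): -0.6, ("UG", "GU"): -0.6, ("UG", "UG"): -0.5,
}


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbor energy model.

    ``pair_cost`` is a per-pair formation penalty (kcal/mol) standing in for
    loop-entropy terms; stacked helices earn the (negative) stacking energies
    on top of it, so isolated pairs are disfavored and contiguous helices
    favored.  ``kT`` defaults to 0.616 kcal/mol (37 degrees C).
    """

    pair_cost: float = 1.0
    stack_energies: Mapping = field(default_factory=lambda: dict(DEFAULT_STACK_ENERGIES))
    min_hairpin_loop: int = 3
    kT: float = 0.616

    def __post_init__(self):
        if self.min_hairpin_loop < 3:
            raise ValueError("min hairpin loop must be >= 3")
        if not (math.isfinite(self.pair_cost) and self.kT > 0):
            raise ValueError("energies must be finite and kT positive")

    def pairable(self, b1: str, b2: str) -> bool:
        return b1 + b2 in _CANONICAL_PAIRS

    def weights(self, seq: str):
        """Pair-weight and stack-weight matrices for a sequence.

        wp[i, j] = Boltzmann weight of forming pair (i, j), 0 if disallowed;
        ws[i, j] = extra weight when pair (i+1, j-1) is also formed.
        """
        n = len(seq)
        wp = np.zeros((n, n))
        ws = np.ones((n, n))
        w_pair = math.exp(-self.pair_cost / self.kT)
        hl = self.min_hairpin_loop
        for i in range(n):
            for j in range(i + hl + 1, n):
                if self.pairable(seq[i], seq[j]):
                    wp[i, j] = w_pair
                    inner = seq[i + 1] + seq[j - 1]
                    if i + 1 < j - 1 and inner in _CANONICAL_PAIRS:
                        e = self.stack_energies.get((seq[i] + seq[j], inner), -1.0)
                        ws[i, j] = math.exp(-e / self.kT)
        return wp, ws


@dataclass
class BppMatrix:
    """Symmetric matrix of equilibrium base-pair probabilities."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("BPP matrix must be square")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


@dataclass
class PairingScoreVector:
    """Per-nucleotide probability of being paired (row sums of the BPP
    matrix), with optional window-extraction metadata."""

    scores: np.ndarray
    center: int | None = None
    halfwidth: int | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class StructureChangeResult:
    snp_id: str
    transcript_id: str
    rho_min: float
    per_site: tuple  # ((site_center, rho), ...)


# ---------------------------------------------------------------------------
# inside / outside dynamic program
# ---------------------------------------------------------------------------

@njit(cache=False)
def _inside(wp, ws, hl):  # pragma: no cover - exercised via partition_bpp
    n = wp.shape[0]
    Z = np.ones((n + 1, n + 1))
    Zb = np.zeros((n + 1, n + 1))
    for d in range(n):
        for i in range(n - d):
            j = i + d
            if wp[i, j] > 0.0:
                z_in = Z[i + 1, j - 1]
                zb_in = Zb[i + 1, j - 1]
                Zb[i, j] = wp[i, j] * ((z_in - zb_in) + ws[i, j] * zb_in)
            s = 0.0
            for k in range(i + hl + 1, j + 1):
                if Zb[i, k] > 0.0:
                    s += Zb[i, k] * Z[k + 1, j]
            Z[i, j] = Z[i + 1, j] + s
    return Z, Zb


@njit(cache=False)
def _outside(wp, ws, hl, Z, Zb):  # pragma: no cover - exercised via partition_bpp
    n = wp.shape[0]
    OZ = np.zeros((n + 1, n + 1))
    OZb = np.zeros((n + 1, n + 1))
    OZ[0, n - 1] = 1.0
    for d in range(n - 1, -1, -1):
        for i in range(n - d):
            j = i + d
            oz = OZ[i, j]
            if oz != 0.0:
                if i < j:
                    OZ[i + 1, j] += oz
                for k in range(i + hl + 1, j + 1):
                    if Zb[i, k] > 0.0:
                        OZb[i, k] += oz * Z[k + 1, j]
                        if k < j:
                            OZ[k + 1, j] += oz * Zb[i, k]
            ob = OZb[i, j]
            if ob != 0.0 and wp[i, j] > 0.0:
                w = wp[i, j]
                OZ[i + 1, j - 1] += ob * w
                OZb[i + 1, j - 1] += ob * w * (ws[i, j] - 1.0)
    return OZ, OZb


def partition_bpp(seq: str, model: EnergyModel | None = None) -> BppMatrix:
    """Base-pair probability matrix over the Boltzmann ensemble.

    Accepts RNA (ACGU) or DNA-typed (T for U) sequences; any other symbol is
    an error.  Deterministic; exact for the declared energy model.
    """
    model = model or EnergyModel()
    rna = seq.upper().replace("T", "U")
    if set(rna) - set("ACGU"):
        raise ValueError(f"invalid alphabet in sequence: {sorted(set(rna) - set('ACGU'))}")
    n = len(rna)
    if n < model.min_hairpin_loop + 2:
        raise ValueError(f"sequence shorter than {model.min_hairpin_loop + 2} nt")
    wp, ws = model.weights(rna)
    Z, Zb = _inside(wp, ws, model.min_hairpin_loop)
    OZ, OZb = _outside(wp, ws, model.min_hairpin_loop, Z, Zb)
    total = Z[0, n - 1]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if Zb[i, j] > 0.0:
                p[i, j] = Zb[i, j] * OZb[i, j] / total
    p = p + p.T
    np.clip(p, 0.0, 1.0, out=p)
    return BppMatrix(p)


def pairing_scores(bpp: BppMatrix) -> PairingScoreVector:
    """Per-nucleotide pairing score: probability that the base is paired."""
    return PairingScoreVector(bpp.row_sums())


# ---------------------------------------------------------------------------
# wild-type / mutant site correlation
# ---------------------------------------------------------------------------

def _windowed(scores: np.ndarray, center: int, halfwidth: int) -> np.ndarray:
    lo = max(0, center - halfwidth)
    hi = min(len(scores), center + halfwidth + 1)
    return scores[lo:hi]


def site_correlation(seq_ref: str, seq_alt: str, site_center: int,
                     halfwidth: int = 20, model: EnergyModel | None = None,
                     max_fold_len: int = 4000) -> float:
    """Pearson correlation of the two alleles' pairing-score windows.

    The (2*halfwidth + 1)-nt score windows are centered on the RISC-binding
    site and truncated at the sequence ends, identically for both alleles.
    Sequences longer than ``max_fold_len`` are truncated around the site
    before folding.  If both windows are constant: rho = 1.0 when they are
    equal (no change), NaN (flagged, excluded downstream) otherwise; a single
    constant window is also NaN.
    """
    if len(seq_ref) != len(seq_alt):
        raise ValueError("alleles must be placed in equal-length sequences")
    n_diff = sum(a != b for a, b in zip(seq_ref, seq_alt))
    if n_diff > 1:
        raise ValueError(f"sequences differ at {n_diff} positions; expected <= 1")
    if not (0 <= site_center < len(seq_ref)):
        raise ValueError("site_center outside the sequence")
    if len(seq_ref) > max_fold_len:
        lo = max(0, min(site_center - max_fold_len // 2, len(seq_ref) - max_fold_len))
        seq_ref, seq_alt = seq_ref[lo:lo + max_fold_len], seq_alt[lo:lo + max_fold_len]
        site_center -= lo
    if seq_ref == seq_alt:
        return 1.0
    v_ref = _windowed(pairing_scores(partition_bpp(seq_ref, model)).scores,
                      site_center, halfwidth)
    v_alt = _windowed(pairing_scores(partition_bpp(seq_alt, model)).scores,
                      site_center, halfwidth)
    const_ref = np.ptp(v_ref) < 1e-12
    const_alt = np.ptp(v_alt) < 1e-12
    if const_ref and const_alt:
        return 1.0 if np.allclose(v_ref, v_alt) else math.nan
    if const_ref or const_alt:
        return math.nan
    return float(stats.pearsonr(v_ref, v_alt)[0])


DEFAULT_FOLD_WINDOW = 120


def site_rho(seq_ref: str, seq_alt: str, snp_pos: int, site_center: int,
             model: EnergyModel | None = None, halfwidth: int = 20,
             fold_window: int | None = DEFAULT_FOLD_WINDOW) -> float:
    """Structure-change correlation at one site, folding a fixed window.

    With ``fold_window`` set, only a window of that length centered on the
    site is folded; a SNP outside the window is scored rho = 1.0 (no local
    structural effect considered).  ``fold_window=None`` folds the whole
    supplied sequence.
    """
    if fold_window is None:
        return site_correlation(seq_ref, seq_alt, site_center, halfwidth, model)
    lo = max(0, min(site_center - fold_window // 2, len(seq_ref) - fold_window))
    hi = lo + fold_window
    if not (lo <= snp_pos < hi):
        return 1.0
    return site_correlation(seq_ref[lo:hi], seq_alt[lo:hi], site_center - lo,
                            halfwidth, model)


def min_rho_per_snp(snp_id: str, per_transcript: Mapping[str, tuple],
                    model: EnergyModel | None = None, halfwidth: int = 20,
                    fold_window: int | None = DEFAULT_FOLD_WINDOW) -> list:
    """Smallest site correlation per transcript for one SNP.

    ``per_transcript`` maps transcript_id -> (seq_ref, seq_alt, snp_pos,
    site_centers); one result is produced per transcript with >= 1 site,
    rho_min being the NaN-excluded minimum over that transcript's sites
    (NaN if every site is flagged).
    """
    out = []
    for tid, (seq_ref, seq_alt, snp_pos, centers) in per_transcript.items():
        if not centers:
            continue
        per_site = tuple(
            (c, site_rho(seq_ref, seq_alt, snp_pos, c, model, halfwidth, fold_window))
            for c in centers)
        rhos = [r for _, r in per_site if not math.isnan(r)]
        rho_min = min(rhos) if rhos else math.nan
        out.append(StructureChangeResult(snp_id, tid, rho_min, per_site))
    return out


def calibrate_rho_threshold(null_rhos: Sequence[float], alpha: float = 0.05) -> float:
    """Empirical alpha-quantile of a null rho_min sample.

    SNPs with rho_min strictly below the returned threshold are called as
    structure-changing (FOLDING).  NaN (flagged) null values are excluded.
    At alpha = 0 the threshold is the null minimum, so no null SNP is called
    under the strict-inequality rule.  Monotone in alpha.
    """
    vals = np.asarray([r for r in null_rhos if not math.isnan(r)], dtype=float)
    if vals.size == 0:
        raise ValueError("no usable null correlations")
    if np.ptp(vals) < 1e-12:
        log.warning("degenerate null: all correlations equal %.3f", vals[0])
        return float(vals[0])
    return float(np.quantile(vals, alpha))
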