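"""Linkage-disequilibrium utilities: haplotype r-squared, sentinel extension
and all-vs-all LD-block binning with unique assignment.

r-squared is computed from phased haplotypes as D^2 / (pA pa pB pb), which for
0/1 haplotype columns equals the squared Pearson correlation; a squared
dosage-correlation fallback is available for unphased data.  Both sentinel
extension and binning restrict the search to a locality window (default 1 Mb)
on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import ValidationError, _read_tsv, _write_tsv

log = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.8
DEFAULT_WINDOW = 1_000_000


class LdUndefinedError(ValueError):
    """r-squared is undefined for a monomorphic SNP."""


@dataclass
class HaplotypePanel:
    """Phased haplotypes: a (haplotype x SNP) 0/1 matrix plus SNP placement.

    ``chroms``/``positions`` give each SNP's genomic location, used for the
    locality window in extension and binning.
    """

    snp_ids: list
    haplotypes: np.ndarray
    chroms: list
    positions: np.ndarray

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n_hap, n_snp = self.haplotypes.shape
        if not (len(self.snp_ids) == n_snp == len(self.chroms) == len(self.positions)):
            raise ValidationError("panel dimensions are inconsistent")
        if n_hap % 2:
            raise ValidationError("number of haplotypes must be even")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValidationError("haplotype matrix must be 0/1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.haplotypes[:, self._index[snp_id]]

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class LdBlock:
    block_id: str
    member_snp_ids: frozenset
    location_classes: frozenset = frozenset()

    def __post_init__(self):
        if not self.member_snp_ids:
            raise ValidationError(f"{self.block_id}: block must hold >= 1 SNP")


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def _check_polymorphic(col: np.ndarray, snp_id: str) -> None:
    if col.min() == col.max():
        raise LdUndefinedError(f"SNP {snp_id} is monomorphic; r2 undefined")


def compute_r2(panel: HaplotypePanel, snp_a: str, snp_b: str,
               method: str = "haplotype") -> float:
    """Pairwise LD between two panel SNPs.

    ``method='haplotype'`` is D^2/(pA pa pB pb) from phased haplotype counts;
    ``method='dosage'`` is the squared Pearson correlation of per-individual
    dosages (sum of the two haplotype alleles), the standard fallback when
    phase is not trusted.
    """
    a = panel.column(snp_a).astype(float)
    b = panel.column(snp_b).astype(float)
    _check_polymorphic(a, snp_a)
    _check_polymorphic(b, snp_b)
    if method == "haplotype":
        p_a, p_b = a.mean(), b.mean()
        p_ab = (a * b).mean()
        d = p_ab - p_a * p_b
        return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))
    if method == "dosage":
        dos_a = a.reshape(-1, 2).sum(axis=1)
        dos_b = b.reshape(-1, 2).sum(axis=1)
        if dos_a.std() == 0 or dos_b.std() == 0:
            raise LdUndefinedError("constant dosage; r2 undefined")
        return float(np.corrcoef(dos_a, dos_b)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")


def r2_matrix(panel: HaplotypePanel, indices: Sequence[int] | None = None) -> np.ndarray:
    """All-vs-all haplotype r^2 for the given column indices (default: all).

    Monomorphic columns yield NaN rows/columns rather than raising; callers
    exclude them explicitly.
    """
    h = panel.haplotypes if indices is None else panel.haplotypes[:, list(indices)]
    h = h.astype(float)
    sd = h.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(h, rowvar=False)
    r2 = c * c
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    return r2


# ---------------------------------------------------------------------------
# Sentinel extension
# ---------------------------------------------------------------------------

def neighbor_lists(panel: HaplotypePanel, r2_min: float = DEFAULT_R2_MIN,
                   window: int = DEFAULT_WINDOW) -> list:
    """Precomputed per-SNP lists of panel indices with r2 >= r2_min within the
    locality window.  A SNP is always its own neighbor.  Shared by extension,
    binning and the resampled enrichment null."""
    n = panel.n_snps
    order = np.lexsort((panel.positions, np.asarray(panel.chroms, dtype=object)))
    neighbors = [[] for _ in range(n)]
    h = panel.haplotypes.astype(float)
    sd = h.std(axis=0)
    # sweep in genomic order; compare each SNP against the trailing window
    active: list[int] = []
    for oi in order:
        chrom, pos = panel.chroms[oi], panel.positions[oi]
        active = [j for j in active
                  if panel.chroms[j] == chrom and pos - panel.positions[j] <= window]
        if active and sd[oi] > 0:
            cols = h[:, active]
            x = h[:, oi]
            with np.errstate(invalid="ignore", divide="ignore"):
                num = ((cols - cols.mean(0)) * (x - x.mean())[:, None]).mean(0)
                denom = cols.std(0) * sd[oi]
                r2 = np.where(denom > 0, (num / denom) ** 2, np.nan)
            for j, v in zip(active, r2):
                if v >= r2_min:
                    neighbors[oi].append(j)
                    neighbors[j].append(oi)
        neighbors[oi].append(oi)
        active.append(oi)
    return neighbors


def extend_sentinels(sentinels: Iterable[str], panel: HaplotypePanel,
                     r2_min: float = DEFAULT_R2_MIN, window: int = DEFAULT_WINDOW,
                     neighbors: list | None = None) -> set:
    """Extend sentinel SNPs by all panel SNPs in strong LD (r2 >= r2_min)
    with at least one sentinel.  Sentinels absent from the panel are logged
    and skipped, emulating catalog/panel identifier mismatch."""
    if neighbors is None:
        neighbors = neighbor_lists(panel, r2_min=r2_min, window=window)
    out: set[str] = set()
    for s in sentinels:
        if s not in panel._index:
            log.warning("sentinel %s absent from panel; skipped", s)
            continue
        out.add(s)
        for j in neighbors[panel.index_of(s)]:
            out.add(panel.snp_ids[j])
    return out


# ---------------------------------------------------------------------------
# All-vs-all block binning
# ---------------------------------------------------------------------------

def bin_ld_blocks(panel: HaplotypePanel, r2_min: float = DEFAULT_R2_MIN,
                  window: int = DEFAULT_WINDOW,
                  classes: Mapping[str, object] | None = None) -> list:
    """Greedy unique assignment of every panel SNP to an all-vs-all LD block.

    SNPs are visited in genomic order; each unassigned SNP seeds a block, and
    every later unassigned SNP within the locality window joins iff its r2
    with *all* current members is >= r2_min.  Deterministic and order-stable;
    a documented heuristic for the (intractable) maximal-clique binning.
    Monomorphic SNPs become singleton blocks.
    """
    n = panel.n_snps
    order = np.lexsort((panel.positions, np.asarray(panel.chroms, dtype=object)))
    h = panel.haplotypes.astype(float)
    sd = h.std(axis=0)
    centered = h - h.mean(axis=0)
    assigned = np.zeros(n, dtype=bool)
    blocks = []
    for k, oi in enumerate(order):
        if assigned[oi]:
            continue
        members = [int(oi)]
        assigned[oi] = True
        if sd[oi] > 0:
            chrom, pos = panel.chroms[oi], panel.positions[oi]
            for oj in order[k + 1:]:
                oj = int(oj)
                if panel.chroms[oj] != chrom or panel.positions[oj] - pos > window:
                    break
                if assigned[oj] or sd[oj] == 0:
                    continue
                ok = True
                for m in members:
                    num = float((centered[:, m] * centered[:, oj]).mean())
                    r2 = (num / (sd[m] * sd[oj])) ** 2
                    if r2 < r2_min:
                        ok = False
                        break
                if ok:
                    members.append(oj)
                    assigned[oj] = True
        ids = frozenset(panel.snp_ids[m] for m in members)
        cls = frozenset(classes[panel.snp_ids[m]] for m in members
                        if classes is not None and panel.snp_ids[m] in classes) \
            if classes is not None else frozenset()
        blocks.append(LdBlock(f"block{len(blocks):05d}", ids, cls))
    return blocks


def block_reduction_ratio(blocks: Sequence[LdBlock], snp_classes: Mapping[str, object],
                          location_class) -> float:
    """(#blocks whose class set contains the class) / (#SNPs of the class)."""
    n_snps = sum(1 for c in snp_classes.values() if c == location_class)
    if n_snps == 0:
        raise ValueError(f"no SNPs of class {location_class!r}")
    n_blocks = sum(1 for b in blocks if location_class in b.location_classes)
    return n_blocks / n_snps


# ---------------------------------------------------------------------------
# Panel / block I/O
# ---------------------------------------------------------------------------

_PANEL_COLS_FIXED = ("snp_id", "chrom", "pos")


def write_panel(path, panel: HaplotypePanel) -> None:
    cols = _PANEL_COLS_FIXED + tuple(f"h{i}" for i in range(panel.n_haplotypes))
    rows = []
    for i, sid in enumerate(panel.snp_ids):
        rows.append((sid, panel.chroms[i], int(panel.positions[i]),
                     *panel.haplotypes[:, i].tolist()))
    _write_tsv(path, cols, rows)


def read_panel(path) -> HaplotypePanel:
    snp_ids, chroms, positions, cols = [], [], [], []
    expected = None
    for lineno, f in _read_tsv_any_header(path):
        if expected is None:
            expected = len(f)
        snp_ids.append(f[0])
        chroms.append(f[1])
        positions.append(int(f[2]))
        cols.append([int(x) for x in f[3:]])
    h = np.array(cols, dtype=np.int8).T if cols else np.zeros((0, 0), dtype=np.int8)
    return HaplotypePanel(snp_ids, h, chroms, np.asarray(positions))


def _read_tsv_any_header(path):
    """TSV rows for files whose header width is data dependent (the panel)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not header_seen:
            if not line.startswith("#"):
                raise ValidationError(f"{path}:{lineno}: missing '#' header")
            header_seen = True
            continue
        yield lineno, line.split("\t")


def write_blocks(path, blocks: Sequence[LdBlock]) -> None:
    _write_tsv(path, ("block_id", "snp_ids", "classes"),
               ((b.block_id, ",".join(sorted(b.member_snp_ids)),
                 ",".join(sorted(str(getattr(c, "name", c)) for c in b.location_classes)) or ".")
                for b in blocks))
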