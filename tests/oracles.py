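"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive -- exhaustive enumeration, direct
summation, O(n^2) scans -- and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_PAIRS = {"CG", "GC", "AU", "UA", "GU", "UG"}
_COMP = str.maketrans("ACGTU", "TGCAA")


def enumerate_structures(seq: str, min_loop: int = 3):
    """All pseudoknot-free pair sets over the sequence (recursive interval
    enumeration)."""
    n = len(seq)

    def pairable(i, j):
        return seq[i] + seq[j] in _PAIRS and j - i - 1 >= min_loop

    def enum(positions):
        if not positions:
            return [()]
        i, rest = positions[0], positions[1:]
        out = list(enum(rest))
        for j in rest:
            if pairable(i, j):
                inside = tuple(p for p in rest if p < j)
                outside = tuple(p for p in rest if p > j)
                for sin in enum(inside):
                    for sout in enum(outside):
                        out.append(((i, j),) + sin + sout)
        return out

    return enum(tuple(range(n)))


def structure_weight(seq: str, pairs, model) -> float:
    """Boltzmann weight of one structure under the package's energy model
    (per-pair cost plus nearest-neighbor stacks), computed independently."""
    energy = 0.0
    pair_set = set(pairs)
    for (i, j) in pairs:
        energy += model.pair_cost
        if (i + 1, j - 1) in pair_set:
            energy += model.stack_energies.get(
                (seq[i] + seq[j], seq[i + 1] + seq[j - 1]), -1.0)
    return math.exp(-energy / model.kT)


def bpp_bruteforce(seq: str, model) -> np.ndarray:
    """Base-pair probabilities by exhaustive Boltzmann-weighted enumeration."""
    n = len(seq)
    p = np.zeros((n, n))
    total = 0.0
    for pairs in enumerate_structures(seq, model.min_hairpin_loop):
        w = structure_weight(seq, pairs, model)
        total += w
        for (i, j) in pairs:
            p[i, j] += w
    p /= total
    return p + p.T


def naive_seed_scan(utr_seq: str, mirna_seq: str) -> list:
    """Every canonical site as (type, start) by checking each substring of the
    UTR against the explicitly constructed site strings."""
    seq = utr_seq.upper().replace("U", "T")
    m = mirna_seq.upper().replace("U", "T")
    rc = lambda s: s.translate(_COMP)[::-1]
    site6, site7m8 = rc(m[1:7]), rc(m[1:8])
    site7a1, site8 = site6 + "A", site7m8 + "A"
    out = []
    for start in range(len(seq)):
        if seq[start:start + 8] == site8:
            out.append(("8MER", start))
        elif seq[start:start + 7] == site7m8:
            out.append(("7MER_M8", start))
    for start in range(len(seq)):
        core_at = seq[start:start + 6] == site6
        if not core_at:
            continue
        if any(typ in ("8MER", "7MER_M8") and s == start - 1 for typ, s in out):
            continue
        if seq[start:start + 7] == site7a1:
            out.append(("7MER_A1", start))
        else:
            out.append(("6MER", start))
    return sorted(out, key=lambda x: (x[1], x[0]))


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by direct hypergeometric summation."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
              / math.comb(n, row1))
    return p


def brute_extend(sentinels, panel, r2_min=0.8):
    """O(n^2) all-pairs sentinel extension, no locality window shortcuts
    beyond the same 1-Mb / same-chromosome rule."""
    from mirsnpmech.ld_toolkit import compute_r2, LdUndefinedError
    out = set()
    for s in sentinels:
        if s not in panel._index:
            continue
        out.add(s)
        si = panel.index_of(s)
        for j, other in enumerate(panel.snp_ids):
            if other in out or panel.chroms[j] != panel.chroms[si]:
                continue
            if abs(int(panel.positions[j]) - int(panel.positions[si])) > 1_000_000:
                continue
            try:
                if compute_r2(panel, s, other) >= r2_min:
                    out.add(other)
            except LdUndefinedError:
                pass
    return out


def check_blocks(blocks, panel, r2_min=0.8):
    """Verify a binning: true partition, and all-vs-all r2 within each block."""
    from mirsnpmech.ld_toolkit import compute_r2, LdUndefinedError
    seen = set()
    for b in blocks:
        for sid in b.member_snp_ids:
            assert sid not in seen, f"{sid} in two blocks"
            seen.add(sid)
        members = sorted(b.member_snp_ids)
        for x, y in itertools.combinations(members, 2):
            r2 = compute_r2(panel, x, y)
            assert r2 >= r2_min - 1e-12, f"{x},{y}: r2={r2} in {b.block_id}"
    assert seen == set(panel.snp_ids), "binning is not covering"
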