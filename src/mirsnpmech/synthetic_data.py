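"""Synthetic study generator with a planted-truth ledger.

Generates every input the pipeline consumes -- gene models with canonical
GT/AG introns and 200-2000 nt 3'-UTRs, a phased haplotype panel with
class-dependent LD-block structure, CLIP clusters centered on genuine seed
matches, a mature-miRNA pool with unique seeds, poly(A) signal/site pairs,
an association catalog with a configurable 3'-UTR enrichment, conservation
scores, and splice-site training windows -- together with a ledger of
planted per-SNP effects (MRE disruption / creation / substitution, splice
acceptor/donor gain, poly(A) disruption, structure switch, and no-effect
controls) against which recovery is scored.

The haplotype model is founder-copy-with-flips: within a block every
haplotype copies a founder allele and flips it independently with a small
probability tuned so realized pairwise r^2 meets the target; only block-wise
r^2 structure matters to the downstream analysis, so no coalescent machinery
is used.  Intronic/intergenic blocks are larger than exonic ones, emulating
the less extensive LD of exonic SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import enrichment, io_core, ld_toolkit, rna_structure, utr_mechanisms
from .enrichment import LocationClass
from .io_core import (AssociationRecord, ClipCluster, MiRna, PolyASiteRec,
                      SnpRecord, TranscriptModel, revcomp)

log = logging.getLogger(__name__)

MECHANISMS = ("MRE_DISRUPTION", "MRE_CREATION", "MRE_SUBSTITUTION",
              "ACCEPTOR_GAIN", "DONOR_GAIN", "POLYA", "FOLDING")
CONTROL = "CONTROL"

#: donor emission probabilities (A,C,G,T rows; 3 exonic + GT + 4 intronic)
DONOR_EMISSION = np.array([
    [.30, .80, .05, 0, 0, .80, .85, .04, .10],
    [.45, .07, .03, 0, 0, .03, .05, .03, .10],
    [.15, .06, .90, 1, 0, .14, .06, .90, .10],
    [.10, .07, .02, 0, 1, .03, .04, .03, .70],
])

#: acceptor emission probabilities (18 intronic + AG + 3 exonic); the last
#: 12 intronic positions form a strong polypyrimidine tract
ACCEPTOR_EMISSION = np.array(
    [[.22] * 6 + [.05] * 12 + [1, 0] + [.25, .25, .25],
     [.28] * 6 + [.44] * 12 + [0, 0] + [.15, .25, .25],
     [.18] * 6 + [.04] * 12 + [0, 1] + [.55, .25, .25],
     [.32] * 6 + [.47] * 12 + [0, 0] + [.05, .25, .25]])

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``block_size_by_class`` gives the mean SNPs per LD block for blocks
    seeded in each location class; ``target_r2_within_block`` is the average
    pairwise r^2 the founder-copy model aims at; ``utr_enrichment_or`` is the
    3'-UTR odds ratio the LD-extended catalog should realize against the full
    panel; ``planted_effects`` maps mechanism name to the number of planted
    SNPs of that mechanism.
    """

    seed: int = 0
    n_genes: int = 24
    n_haplotypes: int = 120
    n_snps: int = 1200
    block_size_by_class: Mapping = field(default_factory=lambda: {
        LocationClass.INTERGENIC: 6.0, LocationClass.INTRONIC: 5.0,
        LocationClass.UTR5: 2.0, LocationClass.CDS: 2.0, LocationClass.UTR3: 2.0})
    target_r2_within_block: float = 0.9
    n_sentinels: int = 60
    utr_enrichment_or: float = 4.0
    planted_effects: Mapping = field(default_factory=lambda: {
        "MRE_DISRUPTION": 3, "MRE_CREATION": 3, "MRE_SUBSTITUTION": 2,
        "ACCEPTOR_GAIN": 2, "DONOR_GAIN": 1, "POLYA": 2, "FOLDING": 2})
    n_controls: int = 6
    mirna_pool: int = 16
    background_clusters_per_mirna: int = 8
    utr_len_range: tuple = (200, 2000)
    catalog_p_max: float = 1e-5
    n_splice_train: int = 150

    def __post_init__(self):
        if self.n_haplotypes % 2 or self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be even and >= 4")
        for name, v in (("n_genes", self.n_genes), ("n_snps", self.n_snps),
                        ("mirna_pool", self.mirna_pool)):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.target_r2_within_block <= 1):
            raise ValueError("target_r2_within_block must be in (0, 1]")
        if self.utr_enrichment_or < 1:
            raise ValueError("utr_enrichment_or must be >= 1")
        unknown = set(self.planted_effects) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """One planted effect: what was planted, where, and with which miRNA."""

    snp_id: str
    mechanism: str
    transcript_id: str
    mirna_id: str | None = None
    mirna_created: str | None = None
    location_class: str = "3'-UTR"
    block_id: str | None = None
    site_center_tx: int | None = None


@dataclass
class GenomeBundle:
    chrom_seqs: dict
    transcripts: list
    polya_sites: list
    reserved: dict            # transcript_id -> [(tx_lo, tx_hi)]
    polya_signal_tx: dict     # transcript_id -> [tx position of hexamer start]
    donor_examples: list
    acceptor_examples: list

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes plus the planted truth."""

    config: SyntheticConfig
    chrom_seqs: dict
    transcripts: list
    snps: list
    panel: "ld_toolkit.HaplotypePanel"
    block_map: dict           # snp_id -> block_id (generator's planted blocks)
    classes: dict             # snp_id -> LocationClass
    clusters: list
    mirnas: list
    polya_sites: list
    catalog: list
    conservation: dict
    donor_examples: list
    acceptor_examples: list
    truth: list
    control_ids: set

    @property
    def tx_seqs(self) -> dict:
        if not hasattr(self, "_tx_seqs"):
            self._tx_seqs = {t.transcript_id: t.spliced_sequence(self.chrom_seqs[t.chrom])
                             for t in self.transcripts}
        return self._tx_seqs

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_core.write_snp_table(outdir / "snps.tsv", self.snps)
        io_core.write_gene_models(outdir / "genes.tsv", self.transcripts)
        io_core.write_fasta(outdir / "transcripts.fa", self.tx_seqs)
        io_core.write_fasta(outdir / "genome.fa", self.chrom_seqs)
        io_core.write_clip_clusters(outdir / "clip.tsv", self.clusters)
        io_core.write_mirnas(outdir / "mirna.fa", self.mirnas)
        io_core.write_polya_sites(outdir / "polya.tsv", self.polya_sites)
        io_core.write_associations(outdir / "catalog.tsv", self.catalog)
        io_core.write_conservation(outdir / "conservation.tsv", self.conservation)
        ld_toolkit.write_panel(outdir / "panel.tsv", self.panel)
        io_core._write_tsv(outdir / "donor_train.tsv", ("window",),
                           ((w,) for w in self.donor_examples))
        io_core._write_tsv(outdir / "acceptor_train.tsv", ("window",),
                           ((w,) for w in self.acceptor_examples))
        write_truth(outdir / "truth.tsv", self.truth)


_TRUTH_COLS = ("snp_id", "mechanism", "transcript_id", "mirna_id",
               "mirna_created", "location_class", "block_id", "site_center_tx")


def write_truth(path, truth: Sequence[TruthRecord]) -> None:
    io_core._write_tsv(path, _TRUTH_COLS,
                       ((r.snp_id, r.mechanism, r.transcript_id, r.mirna_id or ".",
                         r.mirna_created or ".", r.location_class, r.block_id or ".",
                         r.site_center_tx if r.site_center_tx is not None else ".")
                        for r in truth))


def read_truth(path) -> list:
    out = []
    for _, f in io_core._read_tsv(path, _TRUTH_COLS):
        out.append(TruthRecord(f[0], f[1], f[2],
                               None if f[3] == "." else f[3],
                               None if f[4] == "." else f[4], f[5],
                               None if f[6] == "." else f[6],
                               None if f[7] == "." else int(f[7])))
    return out


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _sample_window(pwm: np.ndarray, rng) -> str:
    return "".join(_BASES[rng.choice(4, p=pwm[:, i] / pwm[:, i].sum())]
                   for i in range(pwm.shape[1]))


def generate_genome(config: SyntheticConfig, rng=None) -> GenomeBundle:
    """Build the chromosome, gene models, poly(A) annotation and splice
    training windows.

    Each gene has 2-4 exons with canonical GT/AG introns whose junction
    windows are drawn from the donor/acceptor emission models, a CDS, and a
    3'-UTR of 200-2000 nt in the terminal exon; some 3'-UTRs carry AATAAA
    hexamers 16-28 nt upstream of an emitted cleavage site.  Roughly a third
    of genes lie on the minus strand.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom = "chr1"
    genome = bytearray()
    transcripts, polya_sites = [], []
    reserved, polya_signal_tx = {}, {}
    donor_examples, acceptor_examples = [], []

    for g in range(config.n_genes):
        genome.extend(bytes("".join(rng.choice(_BASES, rng.integers(1500, 4000))),
                            "ascii"))  # intergenic gap
        n_ex = int(rng.integers(2, 5))
        utr_len = int(rng.integers(*config.utr_len_range))
        exon_lens = [int(rng.integers(120, 300)) for _ in range(n_ex - 1)]
        exon_lens.append(utr_len + int(rng.integers(60, 150)))
        intron_lens = [int(rng.integers(80, 400)) for _ in range(n_ex - 1)]
        prem_len = sum(exon_lens) + sum(intron_lens)
        prem = list("".join(rng.choice(_BASES, prem_len)))
        # exon boundaries in pre-mRNA coordinates
        bounds, cur = [], 0
        for k in range(n_ex):
            bounds.append((cur, cur + exon_lens[k]))
            cur += exon_lens[k]
            if k < n_ex - 1:
                cur += intron_lens[k]
        for k in range(n_ex - 1):
            d_end = bounds[k][1]
            dwin = _sample_window(DONOR_EMISSION, rng)
            prem[d_end - 3:d_end + 6] = list(dwin)
            donor_examples.append(dwin)
            a_start = bounds[k + 1][0]
            awin = _sample_window(ACCEPTOR_EMISSION, rng)
            prem[a_start - 20:a_start + 3] = list(awin)
            acceptor_examples.append(awin)

        strand = "+" if rng.random() < 0.65 else "-"
        tid, gene_name = f"T{g:03d}", f"GENE{g:03d}"
        tx_len = sum(exon_lens)
        utr_tx_lo = tx_len - utr_len
        cds_start_tx = int(rng.integers(30, min(90, exon_lens[0] - 10)))

        # background poly(A) signal/site pairs inside the 3'-UTR
        sig_tx, res = [], []
        n_intron_total = sum(intron_lens)
        for _ in range(int(rng.integers(0, 3))):
            if utr_len < 120:
                break
            q = int(rng.integers(utr_tx_lo + 40, tx_len - 45))
            if any(abs(q - s) < 45 for s in sig_tx):
                continue
            prem_q = q + n_intron_total  # UTR is past every intron
            prem[prem_q:prem_q + 6] = list("AATAAA")
            site_tx = q + int(rng.integers(16, 29))
            sig_tx.append(q)
            res.append((q - 5, q + 40))
            polya_sites.append((tid, site_tx))

        offset = len(genome)
        prem_str = "".join(prem)
        if strand == "+":
            genome.extend(bytes(prem_str, "ascii"))
            exons = tuple((offset + s, offset + e) for s, e in bounds)
        else:
            genome.extend(bytes(revcomp(prem_str), "ascii"))
            exons = tuple(sorted((offset + prem_len - e, offset + prem_len - s)
                                 for s, e in bounds))
        # CDS pre-mRNA interval -> genomic
        cs_prem = cds_start_tx  # within first exon
        ce_tx = utr_tx_lo
        ce_prem = ce_tx + n_intron_total
        if strand == "+":
            cds_lo, cds_hi = offset + cs_prem, offset + ce_prem
        else:
            cds_lo, cds_hi = offset + prem_len - ce_prem, offset + prem_len - cs_prem
        t = TranscriptModel(tid, gene_name, chrom, strand, exons, cds_lo, cds_hi)
        transcripts.append(t)
        reserved[tid] = res
        polya_signal_tx[tid] = sig_tx

    genome.extend(bytes("".join(rng.choice(_BASES, rng.integers(1500, 4000))), "ascii"))
    chrom_seqs = {chrom: genome.decode()}
    # resolve poly(A) genomic positions now that transcripts exist
    by_id = {t.transcript_id: t for t in transcripts}
    polya_recs = [PolyASiteRec(by_id[tid].chrom, by_id[tid].strand,
                               by_id[tid].tx_to_genomic(site_tx))
                  for tid, site_tx in polya_sites]
    while len(donor_examples) < config.n_splice_train:
        donor_examples.append(_sample_window(DONOR_EMISSION, rng))
    while len(acceptor_examples) < config.n_splice_train:
        acceptor_examples.append(_sample_window(ACCEPTOR_EMISSION, rng))
    return GenomeBundle(chrom_seqs, transcripts, polya_recs, reserved,
                        polya_signal_tx, donor_examples, acceptor_examples)


# ---------------------------------------------------------------------------
# miRNA pool
# ---------------------------------------------------------------------------

def generate_mirnas(config: SyntheticConfig, rng) -> list:
    """Random mature miRNAs with pairwise-distinct 2-7 seeds (so seed-site to
    miRNA mapping is unambiguous)."""
    out, seeds = [], set()
    rna = np.array(list("ACGU"))
    while len(out) < config.mirna_pool:
        seq = "".join(rng.choice(rna, 21))
        seed = seq[1:7]
        if seed in seeds:
            continue
        seeds.add(seed)
        out.append(MiRna(f"mir{len(out):03d}", seq, int(rng.integers(10, 5000))))
    return out


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

_RNA_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


class _Planter:
    """Stateful helper that mutates the genome and tracks reservations."""

    def __init__(self, config, genome: GenomeBundle, rng):
        self.config = config
        self.genome = genome
        self.rng = rng
        self.byte_seqs = {c: bytearray(s, "ascii") for c, s in genome.chrom_seqs.items()}
        self.clusters: list[ClipCluster] = []
        self.snp_counter = 0

    def finish_seqs(self) -> dict:
        return {c: b.decode() for c, b in self.byte_seqs.items()}

    # -- primitive operations -------------------------------------------------

    def write_tx(self, t: TranscriptModel, tx_start: int, s: str) -> None:
        arr = self.byte_seqs[t.chrom]
        for i, ch in enumerate(s):
            g = t.tx_to_genomic(tx_start + i)
            arr[g] = ord(ch if t.strand == "+" else revcomp(ch))

    def tx_seq(self, t: TranscriptModel) -> str:
        return t.spliced_sequence(self.byte_seqs[t.chrom].decode())

    def reserve(self, t: TranscriptModel, lo: int, hi: int) -> None:
        self.genome.reserved.setdefault(t.transcript_id, []).append((lo, hi))

    def sample_utr_pos(self, t: TranscriptModel, span: int, margin: int = 45,
                       tries: int = 80, clearance: int = 30):
        utr_lo, utr_hi = t.utr3_tx_interval()
        lo, hi = utr_lo + margin, utr_hi - margin - span
        if hi <= lo:
            return None
        res = self.genome.reserved.get(t.transcript_id, [])
        for _ in range(tries):
            s = int(self.rng.integers(lo, hi))
            if all(s + span + clearance <= rlo or s >= rhi + clearance
                   for rlo, rhi in res):
                return s
        return None

    def pick_host(self, span: int, margin: int = 45):
        order = self.rng.permutation(len(self.genome.transcripts))
        for i in order:
            t = self.genome.transcripts[int(i)]
            s = self.sample_utr_pos(t, span, margin)
            if s is not None:
                return t, s
        raise RuntimeError("no 3'-UTR can host the requested effect")

    def add_cluster(self, t: TranscriptModel, center_tx: int, reads: Mapping[str, int]):
        g1 = t.tx_to_genomic(center_tx - 20)
        g2 = t.tx_to_genomic(center_tx + 20)
        lo, hi = min(g1, g2), max(g1, g2) + 1
        total = max(sum(reads.values()), 1) + int(self.rng.integers(3, 30))
        c = ClipCluster(t.chrom, t.strand, lo, hi, t.transcript_id, total, dict(reads))
        self.clusters.append(c)
        return c

    def new_snp(self, t: TranscriptModel, snp_tx: int, ref_tx: str, alt_tx: str,
                prefix: str = "rsP"):
        self.snp_counter += 1
        gpos = t.tx_to_genomic(snp_tx)
        if t.strand == "+":
            ref_g, alt_g = ref_tx, alt_tx
        else:
            ref_g, alt_g = revcomp(ref_tx), revcomp(alt_tx)
        assert chr(self.byte_seqs[t.chrom][gpos]) == ref_g, "planting inconsistency"
        return {"snp_id": f"{prefix}{self.snp_counter:04d}", "chrom": t.chrom,
                "pos": gpos, "ref": ref_g, "alt": alt_g}

    # -- seed-site utilities ---------------------------------------------------

    def overlapping_matches(self, t: TranscriptModel, mirnas, snp_tx: int,
                            alt: str | None = None) -> set:
        """miRNA ids with a canonical seed site overlapping the (possibly
        mutated) transcript position; scanned on a local window."""
        seq = self.tx_seq(t)
        if alt is not None:
            seq = seq[:snp_tx] + alt + seq[snp_tx + 1:]
        lo = max(0, snp_tx - 12)
        window = seq[lo:snp_tx + 13]
        hit = set()
        for m in mirnas:
            for match in utr_mechanisms.find_seed_matches(window, m):
                span = match.span
                if lo + span[0] <= snp_tx < lo + span[1]:
                    hit.add(m.mirna_id)
        return hit


def _site6(mirna: MiRna) -> str:
    return revcomp(mirna.mature_seq[1:7].replace("U", "T"))


def plant_effects(config: SyntheticConfig, genome: GenomeBundle,
                  mirnas: Sequence[MiRna], rng=None):
    """Plant every requested mechanism plus controls into the genome.

    Returns (snp_specs, clusters, truth_records, extended_mirna_list,
    control_ids, mutated_chrom_seqs).  Each planted SNP's reference allele is
    written into the genome so the effect is verifiable by direct sequence
    inspection; clusters are emitted centered on the planted sites with >= 1
    read for the relevant miRNA.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    planter = _Planter(config, genome, rng)
    mirnas = list(mirnas)
    truth: list[TruthRecord] = []
    snp_specs: list[dict] = []
    counts = dict(config.planted_effects)

    # substitution partners: derive a second miRNA whose site differs at one
    # position from the first's, guaranteeing an unambiguous swap
    partners = []
    for _ in range(counts.get("MRE_SUBSTITUTION", 0)):
        a = mirnas[int(rng.integers(0, config.mirna_pool))]
        for _ in range(40):
            m = int(rng.integers(1, 5))
            site = _site6(a)
            new_base = str(rng.choice([b for b in "ACGT" if b != site[m]]))
            site_b = site[:m] + new_base + site[m + 1:]
            # site6 position m pairs miRNA seed position 7-m (1-based 2..7)
            seed_idx = 6 - m
            b_seq = (a.mature_seq[:seed_idx]
                     + _RNA_COMP[new_base.replace("T", "U") if new_base != "T" else "U"]
                     + a.mature_seq[seed_idx + 1:])
            if all(x.mature_seq[1:7] != b_seq[1:7] for x in mirnas):
                b = MiRna(f"mirS{len(partners):02d}", b_seq,
                          int(rng.integers(10, 5000)))
                mirnas.append(b)
                partners.append((a, b, m, site, site_b))
                break
        else:
            raise RuntimeError("could not derive a substitution partner")

    def plant_mre(mechanism: str, k: int):
        for _ in range(k):
            if mechanism == "MRE_SUBSTITUTION":
                mir_a, mir_b, m, site_a, site_b = partners.pop()
            else:
                mir_a = mirnas[int(rng.integers(0, config.mirna_pool))]
                site_a = _site6(mir_a)
                m = int(rng.integers(1, 5))
                mir_b = site_b = None
            t, start = planter.pick_host(6)
            center = start + 3
            snp_tx = start + m
            if mechanism == "MRE_CREATION":
                # write a one-mismatch core; the alt allele completes the site
                for cand in rng.permutation([b for b in "ACGT" if b != site_a[m]]):
                    core = site_a[:m] + str(cand) + site_a[m + 1:]
                    planter.write_tx(t, start, core)
                    if not planter.overlapping_matches(t, mirnas, snp_tx):
                        break
                ref_tx, alt_tx = core[m], site_a[m]
                created = planter.overlapping_matches(t, mirnas, snp_tx, alt=alt_tx)
                assert mir_a.mirna_id in created, "creation site not realized"
                reads = {mir_a.mirna_id: int(rng.integers(1, 20))}
                truth.append(TruthRecord("", mechanism, t.transcript_id,
                                         mirna_created=mir_a.mirna_id,
                                         mirna_id=None, site_center_tx=center))
            else:
                planter.write_tx(t, start, site_a)
                ref_hits = planter.overlapping_matches(t, mirnas, snp_tx)
                assert mir_a.mirna_id in ref_hits, "planted site not realized"
                if mechanism == "MRE_DISRUPTION":
                    alt_tx = None
                    for cand in rng.permutation([b for b in "ACGT" if b != site_a[m]]):
                        if not planter.overlapping_matches(t, mirnas, snp_tx,
                                                           alt=str(cand)):
                            alt_tx = str(cand)
                            break
                    assert alt_tx is not None, "no clean disrupting allele"
                    ref_tx = site_a[m]
                    reads = {mir_a.mirna_id: int(rng.integers(1, 20))}
                    truth.append(TruthRecord("", mechanism, t.transcript_id,
                                             mirna_id=mir_a.mirna_id,
                                             site_center_tx=center))
                else:  # substitution
                    ref_tx, alt_tx = site_a[m], site_b[m]
                    alt_hits = planter.overlapping_matches(t, mirnas, snp_tx,
                                                           alt=alt_tx)
                    assert mir_b.mirna_id in alt_hits and mir_a.mirna_id not in alt_hits
                    reads = {mir_a.mirna_id: int(rng.integers(1, 20)),
                             mir_b.mirna_id: int(rng.integers(1, 20))}
                    truth.append(TruthRecord("", mechanism, t.transcript_id,
                                             mirna_id=mir_a.mirna_id,
                                             mirna_created=mir_b.mirna_id,
                                             site_center_tx=center))
            planter.add_cluster(t, center, reads)
            planter.reserve(t, center - 30, center + 30)
            spec = planter.new_snp(t, snp_tx, ref_tx, alt_tx)
            truth[-1].snp_id = spec["snp_id"]
            snp_specs.append(spec)

    def plant_splice(site_type: str, k: int):
        pwm = ACCEPTOR_EMISSION if site_type == "ACCEPTOR" else DONOR_EMISSION
        width = pwm.shape[1]
        core_off = 18 if site_type == "ACCEPTOR" else 4
        core_base = "A" if site_type == "ACCEPTOR" else "T"
        for _ in range(k):
            consensus = "".join(_BASES[int(np.argmax(pwm[:, i]))]
                                for i in range(width))
            broken = consensus[:core_off] + "C" + consensus[core_off + 1:]
            t, start = planter.pick_host(width, margin=50)
            planter.write_tx(t, start, broken)
            planter.reserve(t, start - 10, start + width + 10)
            spec = planter.new_snp(t, start + core_off, "C", core_base)
            snp_specs.append(spec)
            mech = "ACCEPTOR_GAIN" if site_type == "ACCEPTOR" else "DONOR_GAIN"
            truth.append(TruthRecord(spec["snp_id"], mech, t.transcript_id,
                                     site_center_tx=start + core_off))

    def plant_polya(k: int):
        for _ in range(k):
            for _ in range(40):
                t, q = planter.pick_host(6, margin=60)
                site_tx = q + int(rng.integers(16, 29))
                planter.write_tx(t, q, "AATAAA")
                seq = planter.tx_seq(t)
                m = 2  # SNP at the central T of AATAAA
                snp_tx = q + m
                window = seq[snp_tx - 5:snp_tx + 6]
                ref_hits = utr_mechanisms._hexamer_hits(
                    window, utr_mechanisms.DEFAULT_POLYA_HEXAMERS, 0)
                if len(ref_hits) != 1:
                    continue  # flanks formed a second signal; resample
                alt_tx = None
                for cand in "CG":
                    alt_win = (window[:5] + cand + window[6:])
                    if not utr_mechanisms._hexamer_hits(
                            alt_win, utr_mechanisms.DEFAULT_POLYA_HEXAMERS, 0):
                        alt_tx = cand
                        break
                if alt_tx is None:
                    continue
                break
            else:
                raise RuntimeError("could not plant a clean poly(A) effect")
            genome.polya_sites.append(
                PolyASiteRec(t.chrom, t.strand, t.tx_to_genomic(site_tx)))
            genome.polya_signal_tx.setdefault(t.transcript_id, []).append(q)
            planter.reserve(t, q - 10, site_tx + 10)
            spec = planter.new_snp(t, snp_tx, "T", alt_tx)
            snp_specs.append(spec)
            truth.append(TruthRecord(spec["snp_id"], "POLYA", t.transcript_id,
                                     site_center_tx=q))

    def plant_folding(k: int, stem: int = 10, flank: int = 45, loop: int = 4):
        """A two-register hairpin switch: the reference allele completes the
        upstream stem, the alternate completes the downstream one.  Stems are
        redrawn until the isolated-construct correlation is < 0.5, so every
        planted effect is a genuine structure switch."""
        swap = {"G": "C", "C": "G"}
        for _ in range(k):
            for _ in range(60):
                s_arm = "".join(rng.choice(list("GC"), stem))
                m = int(rng.integers(2, stem - 2))
                s_alt = s_arm[:m] + swap[s_arm[m]] + s_arm[m + 1:]
                x_arm, y_arm = revcomp(s_arm), revcomp(s_alt)
                construct = ("A" * flank + x_arm + "A" * loop + s_arm
                             + "A" * loop + y_arm + "A" * flank)
                snp_off = flank + stem + loop + m
                center_off = flank + stem + loop + stem // 2
                alt_construct = (construct[:snp_off] + swap[s_arm[m]]
                                 + construct[snp_off + 1:])
                rho = rna_structure.site_rho(construct, alt_construct, snp_off,
                                             center_off, fold_window=None)
                if not math.isnan(rho) and rho < 0.5:
                    break
            else:
                raise RuntimeError("no switching hairpin found")
            t, start = planter.pick_host(len(construct), margin=50)
            planter.write_tx(t, start, construct)
            planter.reserve(t, start - 10, start + len(construct) + 10)
            center = start + center_off
            mir = mirnas[int(rng.integers(0, config.mirna_pool))]
            planter.add_cluster(t, center, {mir.mirna_id: int(rng.integers(1, 10))})
            spec = planter.new_snp(t, start + snp_off, s_arm[m], swap[s_arm[m]])
            snp_specs.append(spec)
            truth.append(TruthRecord(spec["snp_id"], "FOLDING", t.transcript_id,
                                     site_center_tx=center))

    plant_mre("MRE_DISRUPTION", counts.get("MRE_DISRUPTION", 0))
    plant_mre("MRE_CREATION", counts.get("MRE_CREATION", 0))
    plant_mre("MRE_SUBSTITUTION", counts.get("MRE_SUBSTITUTION", 0))
    plant_splice("ACCEPTOR", counts.get("ACCEPTOR_GAIN", 0))
    plant_splice("DONOR", counts.get("DONOR_GAIN", 0))
    plant_polya(counts.get("POLYA", 0))
    plant_folding(counts.get("FOLDING", 0))

    # background clusters centered on genuine seed matches, giving every pool
    # miRNA in-cluster support for the enrichment filter; miRNAs carrying a
    # planted effect get extra sites so the filter retains them by construction
    effect_mirs = ({r.mirna_id for r in truth if r.mirna_id}
                   | {r.mirna_created for r in truth if r.mirna_created})
    for mir in mirnas:
        site = _site6(mir)
        n_bg = config.background_clusters_per_mirna
        if mir.mirna_id in effect_mirs:
            n_bg += 4
        for _ in range(n_bg):
            try:
                t, start = planter.pick_host(6, margin=40)
            except RuntimeError:
                log.warning("3'-UTR space exhausted while placing background "
                            "clusters for %s", mir.mirna_id)
                break
            planter.write_tx(t, start, site)
            planter.add_cluster(t, start + 3, {mir.mirna_id: int(rng.integers(1, 20))})
            planter.reserve(t, start - 24, start + 30)

    # controls: no-effect SNPs far from clusters, borders and signals
    control_ids: set[str] = set()
    cluster_tx = {}
    for c in planter.clusters:
        t = genome.transcript(c.transcript_id)
        ctx = t.genomic_to_tx(c.center)
        if ctx is not None:
            cluster_tx.setdefault(c.transcript_id, []).append(ctx)
    hosts = [t for t in genome.transcripts if t.transcript_id in cluster_tx]
    # controls are verified inert: no splice-likelihood change under a model
    # trained on this genome's junction windows, and no poly(A)-hexamer change
    ctl_model = utr_mechanisms.train_splice_model(
        genome.donor_examples, genome.acceptor_examples,
        seed=int(rng.integers(2 ** 31)))
    tx_seq_cache = {t.transcript_id: planter.tx_seq(t) for t in hosts}
    planted_ctrl = 0
    guard = 0
    while planted_ctrl < config.n_controls and guard < 4000:
        guard += 1
        t = hosts[int(rng.integers(0, len(hosts)))]
        pos = planter.sample_utr_pos(t, 1, margin=20, clearance=10)
        if pos is None:
            continue
        if any(abs(pos - ctx) < 150 for ctx in cluster_tx[t.transcript_id]):
            continue
        if any(abs(pos - b) < 50 for b in t.splice_junction_tx_positions()):
            continue
        if any(abs(pos - q) < 50
               for q in genome.polya_signal_tx.get(t.transcript_id, [])):
            continue
        if any(abs(pos - t.genomic_to_tx(p.pos) if t.genomic_to_tx(p.pos) is not None
                   else 999) < 50 for p in genome.polya_sites
               if p.chrom == t.chrom):
            continue
        seq_ref = tx_seq_cache[t.transcript_id]
        ref_tx = seq_ref[pos]
        alt_tx = str(rng.choice([b for b in "ACGT" if b != ref_tx]))
        seq_alt = seq_ref[:pos] + alt_tx + seq_ref[pos + 1:]
        if utr_mechanisms.classify_splice_changes(
                "ctl", pos, seq_ref, seq_alt, ctl_model, t.transcript_id,
                junctions=t.splice_junction_tx_positions()):
            continue
        w_ref = seq_ref[max(0, pos - 5):pos + 6]
        w_alt = seq_alt[max(0, pos - 5):pos + 6]
        if (utr_mechanisms._hexamer_hits(w_ref, utr_mechanisms.DEFAULT_POLYA_HEXAMERS, 0)
                != utr_mechanisms._hexamer_hits(w_alt, utr_mechanisms.DEFAULT_POLYA_HEXAMERS, 0)):
            continue
        planter.reserve(t, pos - 5, pos + 5)
        spec = planter.new_snp(t, pos, ref_tx, alt_tx, prefix="rsC")
        snp_specs.append(spec)
        control_ids.add(spec["snp_id"])
        truth.append(TruthRecord(spec["snp_id"], CONTROL, t.transcript_id,
                                 site_center_tx=pos))
        planted_ctrl += 1
    if planted_ctrl < config.n_controls:
        log.warning("placed only %d of %d control SNPs", planted_ctrl,
                    config.n_controls)
    return (snp_specs, planter.clusters, truth, mirnas, control_ids,
            planter.finish_seqs())


# ---------------------------------------------------------------------------
# haplotypes and LD blocks
# ---------------------------------------------------------------------------

def generate_haplotypes(config: SyntheticConfig, snp_positions: Sequence[tuple],
                        classes: Mapping[str, LocationClass], rng=None):
    """Founder-copy haplotype panel with class-dependent block sizes.

    ``snp_positions`` is a sequence of (snp_id, chrom, pos) already placed on
    the genome.  SNPs are grouped in genomic order into blocks whose mean
    size depends on the location class of the block's first SNP; within a
    block each haplotype copies a founder allele with a per-SNP flip
    probability tuned so mean pairwise r^2 meets the target.  Returns
    (HaplotypePanel, {snp_id: block_id}).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if config.n_haplotypes < 40:
        log.warning("n_haplotypes=%d may be too small to realize r2 target",
                    config.n_haplotypes)
    order = sorted(range(len(snp_positions)),
                   key=lambda i: (snp_positions[i][1], snp_positions[i][2]))
    eps = (1.0 - config.target_r2_within_block ** 0.25) / 2.0
    n_hap = config.n_haplotypes
    haplotypes = np.zeros((n_hap, len(snp_positions)), dtype=np.int8)
    block_map: dict[str, str] = {}
    i = 0
    n_blocks = 0
    while i < len(order):
        first = snp_positions[order[i]]
        cls = classes.get(first[0], LocationClass.INTERGENIC)
        mean = float(config.block_size_by_class.get(cls, 3.0))
        size = max(1, int(rng.poisson(mean)))
        members = [order[i]]
        j = i + 1
        while (j < len(order) and len(members) < size
               and snp_positions[order[j]][1] == first[1]
               and snp_positions[order[j]][2] - first[2] <= 60_000):
            members.append(order[j])
            j += 1
        block_id = f"tb{n_blocks:05d}"
        n_blocks += 1
        founder_freq = rng.uniform(0.15, 0.5)
        founder = (rng.random(n_hap) < founder_freq).astype(np.int8)
        if founder.min() == founder.max():
            founder[int(rng.integers(n_hap))] ^= 1
        for m in members:
            col = founder ^ (rng.random(n_hap) < eps).astype(np.int8)
            if col.min() == col.max():
                col[int(rng.integers(n_hap))] ^= 1
            haplotypes[:, m] = col
            block_map[snp_positions[m][0]] = block_id
        i = j
    panel = ld_toolkit.HaplotypePanel(
        [s[0] for s in snp_positions], haplotypes,
        [s[1] for s in snp_positions],
        np.asarray([s[2] for s in snp_positions]))
    return panel, block_map


# ---------------------------------------------------------------------------
# association catalog
# ---------------------------------------------------------------------------

_TRAITS = ("Height", "Type 2 Diabetes", "Crohn's Disease", "Ulcerative Colitis",
           "Cholesterol levels", "PBC", "Breast Cancer", "Parkinson's Disease",
           "Body Mass Index", "Celiac Disease")


def _expected_log_or(m: int, k2: int, blocks: Sequence[tuple], n_u: int, n_o: int):
    """Expected extended-set log OR when m sentinels are drawn uniformly from
    3'-UTR SNPs and k2 from the rest, extension pulling whole blocks."""
    ea = eb = 0.0
    for u_b, o_b in blocks:
        p_miss_u = 1.0
        if n_u > 0 and m > 0 and u_b > 0:
            p_miss_u = math.comb(n_u - u_b, m) / math.comb(n_u, m) \
                if n_u - u_b >= m else 0.0
        p_miss_o = 1.0
        if n_o > 0 and k2 > 0 and o_b > 0:
            p_miss_o = math.comb(n_o - o_b, k2) / math.comb(n_o, k2) \
                if n_o - o_b >= k2 else 0.0
        p_hit = 1.0 - p_miss_u * p_miss_o
        ea += p_hit * u_b
        eb += p_hit * o_b
    if min(ea, eb, n_u, n_o) <= 0:
        return math.nan
    return math.log((ea / eb) / (n_u / n_o))


def generate_catalog(config: SyntheticConfig, snps: Sequence[SnpRecord],
                     classes: Mapping[str, LocationClass],
                     block_map: Mapping[str, str], rng=None,
                     extra_sentinels: Sequence[str] = ()) -> list:
    """Sentinel associations whose LD-extended set realizes (in expectation)
    the configured 3'-UTR odds ratio against the full panel.

    The number of 3'-UTR-sourced sentinels is solved deterministically from
    the realized block composition; the remainder are drawn from non-3'-UTR
    SNPs.  ``extra_sentinels`` (planted/control SNPs) are appended as
    associations of their own.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    out: list[AssociationRecord] = []
    k = config.n_sentinels
    chosen: list[str] = []
    if k > 0 and config.utr_enrichment_or == 1.0:
        # no enrichment: sentinels are exchangeable with the resampling null
        chosen = list(rng.choice([s.snp_id for s in snps],
                                 size=min(k, len(snps)), replace=False))
    elif k > 0:
        utr_ids = [s.snp_id for s in snps if classes[s.snp_id] == LocationClass.UTR3]
        other_ids = [s.snp_id for s in snps if classes[s.snp_id] != LocationClass.UTR3]
        comp: dict[str, list[int]] = {}
        for s in snps:
            b = comp.setdefault(block_map[s.snp_id], [0, 0])
            b[0 if classes[s.snp_id] == LocationClass.UTR3 else 1] += 1
        blocks = [tuple(v) for v in comp.values()]
        n_u, n_o = len(utr_ids), len(other_ids)
        target = math.log(config.utr_enrichment_or)
        best_m, best_err = 0, math.inf
        for m in range(0, min(k, n_u) + 1):
            got = _expected_log_or(m, k - m, blocks, n_u, n_o)
            if not math.isnan(got) and abs(got - target) < best_err:
                best_m, best_err = m, abs(got - target)
        m = best_m
        chosen = list(rng.choice(utr_ids, size=m, replace=False)) if m else []
        chosen += list(rng.choice(other_ids, size=min(k - m, n_o), replace=False))
    for sid in list(chosen) + [s for s in extra_sentinels if s not in chosen]:
        trait = str(rng.choice(_TRAITS))
        p = 10.0 ** rng.uniform(-35, math.log10(config.catalog_p_max))
        out.append(AssociationRecord(sid, trait, p))
    return out


# ---------------------------------------------------------------------------
# top-level dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    mirnas = generate_mirnas(config, rng)
    (snp_specs, clusters, truth, mirnas, control_ids,
     chrom_seqs) = plant_effects(config, genome, mirnas, rng)

    # background SNPs at unique positions not colliding with planted ones
    taken = {(s["chrom"], s["pos"]) for s in snp_specs}
    chrom = "chr1"
    glen = len(chrom_seqs[chrom])
    positions = rng.choice(glen, size=min(config.n_snps * 2, glen), replace=False)
    background = []
    for p in positions:
        if len(background) >= config.n_snps:
            break
        p = int(p)
        if (chrom, p) in taken:
            continue
        taken.add((chrom, p))
        ref = chrom_seqs[chrom][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        background.append({"snp_id": f"rs{len(background):05d}", "chrom": chrom,
                           "pos": p, "ref": ref, "alt": alt})
    all_specs = background + snp_specs

    # location classes (MAF not needed for classification)
    tmp = [SnpRecord(s["snp_id"], s["chrom"], s["pos"], s["ref"], s["alt"], 0.25)
           for s in all_specs]
    classes = enrichment.classify_locations(tmp, genome.transcripts)

    panel, block_map = generate_haplotypes(
        config, [(s["snp_id"], s["chrom"], s["pos"]) for s in all_specs],
        classes, rng)
    freqs = panel.allele_freqs()
    snps = [SnpRecord(s["snp_id"], s["chrom"], s["pos"], s["ref"], s["alt"],
                      float(min(freqs[i], 1 - freqs[i])))
            for i, s in enumerate(all_specs)]
    for rec in truth:
        rec.block_id = block_map.get(rec.snp_id)
        rec.location_class = classes[rec.snp_id].value

    background_ids = {s["snp_id"] for s in background}
    planted_ids = [r.snp_id for r in truth]
    catalog = generate_catalog(
        config, [s for s in snps if s.snp_id in background_ids], classes,
        block_map, rng, extra_sentinels=planted_ids)

    conservation = {s.snp_id: float(np.round(rng.beta(0.8, 1.2), 4))
                    for s in snps if rng.random() < 0.8}
    return SyntheticDataset(config, chrom_seqs, genome.transcripts, snps, panel,
                            block_map, classes, clusters, mirnas,
                            genome.polya_sites, catalog, conservation,
                            genome.donor_examples, genome.acceptor_examples,
                            truth, control_ids)


def verify_truth(dataset: SyntheticDataset) -> None:
    """Direct sequence inspection of every truth record; raises on failure."""
    by_id = {t.transcript_id: t for t in dataset.transcripts}
    snp_by_id = {s.snp_id: s for s in dataset.snps}
    for rec in dataset.truth:
        snp = snp_by_id[rec.snp_id]
        t = by_id[rec.transcript_id]
        tx = t.genomic_to_tx(snp.pos)
        assert tx is not None, f"{rec.snp_id} not exonic"
        seq = dataset.tx_seqs[rec.transcript_id]
        ref_tx, alt_tx = t.tx_allele(snp)
        assert seq[tx] == ref_tx, f"{rec.snp_id}: genome/allele mismatch"
        lo, hi = t.utr3_tx_interval()
        assert lo <= tx < hi, f"{rec.snp_id} not in the 3'-UTR"
        if rec.mechanism in ("MRE_DISRUPTION", "MRE_SUBSTITUTION"):
            mir = next(m for m in dataset.mirnas if m.mirna_id == rec.mirna_id)
            assert _site6(mir) in seq[tx - 8:tx + 9]
        if rec.mechanism in ("MRE_CREATION", "MRE_SUBSTITUTION"):
            mir = next(m for m in dataset.mirnas if m.mirna_id == rec.mirna_created)
            alt_seq = seq[:tx] + alt_tx + seq[tx + 1:]
            assert _site6(mir) in alt_seq[tx - 8:tx + 9]
        if rec.mechanism == "POLYA":
            assert "AATAAA" in seq[tx - 5:tx + 6]
        if rec.mechanism == "ACCEPTOR_GAIN":
            alt_seq = seq[:tx] + alt_tx + seq[tx + 1:]
            assert alt_seq[tx:tx + 2] == "AG" and seq[tx:tx + 2] != "AG"
        if rec.mechanism == "DONOR_GAIN":
            alt_seq = seq[:tx] + alt_tx + seq[tx + 1:]
            assert alt_seq[tx - 1:tx + 1] == "GT" and seq[tx - 1:tx + 1] != "GT"
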