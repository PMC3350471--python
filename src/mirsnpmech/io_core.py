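"""Domain types and file I/O for the 3'-UTR variant mechanism pipeline.

All coordinates are 0-based, half-open, genome-forward internally.  Writers
emit the same convention and say so in their headers.  Tabular files use a
plain TSV dialect: one '#'-prefixed header line, tab separators, no quoting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_BASES = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


class ParseError(ValueError):
    """Raised when a file is structurally malformed."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a domain invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Effect(enum.Enum):
    MRE_DISRUPTION = "MRE disruption"
    MRE_CREATION = "MRE creation"
    FOLDING = "Folding"
    ACCEPTOR_GAIN = "Acceptor gain"
    DONOR_GAIN = "Donor gain"
    POLYA = "Poly(A)"


_EFFECT_BY_PHRASE = {e.value: e for e in Effect}


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic variant with its minor allele frequency.

    Alleles are given on the genomic forward strand; ``maf`` is the minor
    allele frequency and therefore lies in [0, 0.5].
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"{self.snp_id}: pos must be >= 0")
        if self.ref_allele not in IUPAC_BASES or self.alt_allele not in IUPAC_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases in ACGT "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.snp_id}: ref and alt alleles are identical")
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript; exons are genomic half-open intervals.

    ``cds_start``/``cds_end`` are genomic coordinates irrespective of strand.
    The 3'-UTR is the exonic sequence downstream of the CDS in transcript
    orientation -- the high-coordinate side for '+' transcripts and the
    low-coordinate side for '-' transcripts.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"{self.transcript_id}: empty exon [{start},{end})")
            if start < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = end
        if not (self.cds_start < self.cds_end):
            raise ValidationError(f"{self.transcript_id}: cds_start must be < cds_end")
        if not (self.exons[0][0] <= self.cds_start and self.cds_end <= self.exons[-1][1]):
            raise ValidationError(f"{self.transcript_id}: CDS outside the exon span")

    # -- coordinate machinery ------------------------------------------------

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _exonic_offset(self, gpos: int) -> int:
        """Number of exonic bases strictly before genomic position ``gpos``."""
        off = 0
        for s, e in self.exons:
            if gpos >= e:
                off += e - s
            elif gpos > s:
                off += gpos - s
        return off

    def genomic_to_tx(self, gpos: int):
        """Transcript coordinate of a genomic position, or None if intronic
        or outside the transcript."""
        for s, e in self.exons:
            if s <= gpos < e:
                plus = self._exonic_offset(gpos)
                return plus if self.strand == "+" else self.length - 1 - plus
        return None

    def tx_to_genomic(self, tpos: int) -> int:
        if not (0 <= tpos < self.length):
            raise ValueError(f"tx position {tpos} outside transcript of length {self.length}")
        plus = tpos if self.strand == "+" else self.length - 1 - tpos
        for s, e in self.exons:
            if plus < e - s:
                return s + plus
            plus -= e - s
        raise AssertionError("unreachable")

    def cds_tx_interval(self):
        """Half-open transcript-coordinate interval of the CDS."""
        if self.strand == "+":
            return (self._exonic_offset(self.cds_start), self._exonic_offset(self.cds_end))
        return (self.length - self._exonic_offset(self.cds_end),
                self.length - self._exonic_offset(self.cds_start))

    def utr3_tx_interval(self):
        """Half-open transcript-coordinate interval of the 3'-UTR."""
        if self.strand == "+":
            start = self._exonic_offset(self.cds_end)
        else:
            start = self.length - self._exonic_offset(self.cds_start)
        return (start, self.length)

    def splice_junction_tx_positions(self):
        """Transcript coordinates of exon/exon junctions (position of the
        first base of each downstream exon in transcript orientation)."""
        cum, out = 0, []
        for s, e in self.exons[:-1]:
            cum += e - s
            out.append(cum)
        if self.strand == "-":
            out = [self.length - c for c in out]
        return sorted(out)

    def spliced_sequence(self, chrom_seq: str) -> str:
        parts = [chrom_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def tx_allele(self, snp: SnpRecord) -> str:
        """The SNP allele pair on the transcript sense strand: (ref, alt)."""
        if self.strand == "+":
            return snp.ref_allele, snp.alt_allele
        return revcomp(snp.ref_allele), revcomp(snp.alt_allele)


@dataclass
class ClipCluster:
    """A CLIP-seq RISC-binding interval with per-miRNA read support."""

    chrom: str
    strand: str
    start: int
    end: int
    transcript_id: str
    total_reads: int
    mirna_reads: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"cluster {self.chrom}:{self.start}-{self.end}: end must exceed start")
        if self.total_reads < 1:
            raise ValidationError(
                f"cluster {self.chrom}:{self.start}-{self.end}: total_reads must be >= 1")

    @property
    def center(self) -> int:
        # floor midpoint; declared convention for even-length intervals
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MiRna:
    mirna_id: str
    mature_seq: str
    read_count: int = 0

    def __post_init__(self):
        if len(self.mature_seq) < 8:
            raise ValidationError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        if set(self.mature_seq) - set("ACGU"):
            raise ValidationError(f"{self.mirna_id}: mature sequence must be RNA (ACGU)")
        if self.read_count < 0:
            raise ValidationError(f"{self.mirna_id}: negative read count")


@dataclass(frozen=True)
class AssociationRecord:
    snp_id: str
    trait: str
    p_value: float

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.snp_id}: p_value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class PolyASiteRec:
    chrom: str
    strand: str
    pos: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError("poly(A) site position must be >= 0")
        if self.strand not in "+-":
            raise ValidationError("poly(A) site strand must be + or -")


@dataclass
class MechanismAnnotation:
    """Per-SNP mechanism labels, the row type of the Table-1-style report."""

    snp_id: str
    gene: str
    effects: frozenset
    traits: tuple = ()
    conserved: bool | None = None

    def __post_init__(self):
        self.effects = frozenset(self.effects)
        if not self.effects:
            raise ValidationError(f"{self.snp_id}: effects must be non-empty")
        self.traits = tuple(self.traits)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path, columns: Sequence[str]):
    """Yield (line_number, fields) for a '#'-headed TSV, checking the header."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not header_seen:
            if not line.startswith("#"):
                raise ParseError(f"{path}:{lineno}: missing '#'-prefixed header line")
            got = line.lstrip("#").strip().split("\t")
            if got != list(columns):
                raise ParseError(
                    f"{path}:{lineno}: header {got} != expected {list(columns)}")
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}")
        yield lineno, fields
    if not header_seen:
        raise ParseError(f"{path}: empty file (no header)")


def _write_tsv(path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: uppercase sequence} map.

    U/T are preserved as read.  Malformed headers or empty sequences raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        raw = fh.read().splitlines()
    current = None
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(raw, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].strip() else ""
            if not name:
                raise ParseError(f"{path}:{lineno}: FASTA header with no identifier")
            if current is not None and lengths[current] == 0:
                raise ParseError(f"{path}:{lineno}: record {current!r} has empty sequence")
            current = name
            lengths[name] = 0
        else:
            if current is None:
                raise ParseError(f"{path}:{lineno}: sequence data before any header")
            lengths[current] += len(line.strip())
    if current is not None and lengths[current] == 0:
        raise ParseError(f"{path}: record {current!r} has empty sequence")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------

_SNP_COLS = ("snp_id", "chrom", "pos", "ref", "alt", "maf")


def read_snp_table(path) -> list:
    out = []
    for lineno, f in _read_tsv(path, _SNP_COLS):
        try:
            out.append(SnpRecord(f[0], f[1], int(f[2]), f[3], f[4], float(f[5])))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_snp_table(path, snps: Iterable[SnpRecord]) -> None:
    _write_tsv(path, _SNP_COLS,
               ((s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele,
                 format(s.maf, "g")) for s in snps))


# ---------------------------------------------------------------------------
# Gene models (BED12-like)
# ---------------------------------------------------------------------------

_GENE_COLS = ("chrom", "start", "end", "id", "gene", "strand",
              "cds_start", "cds_end", "exon_count", "exon_starts", "exon_sizes")


def read_gene_models(path) -> list:
    """Read transcripts from a BED12-like TSV (exon starts relative to
    transcript start, comma separated; 0-based half-open)."""
    out = []
    for lineno, f in _read_tsv(path, _GENE_COLS):
        try:
            start = int(f[1])
            n = int(f[8])
            rel = [int(x) for x in f[9].rstrip(",").split(",")]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            if len(rel) != n or len(sizes) != n:
                raise ValidationError("exon_count does not match exon lists")
            exons = tuple((start + r, start + r + z) for r, z in zip(rel, sizes))
            tm = TranscriptModel(f[3], f[4], f[0], f[5], exons, int(f[6]), int(f[7]))
            if tm.tx_start != start or tm.tx_end != int(f[2]):
                raise ValidationError("start/end do not bracket the exons")
            out.append(tm)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_models(path, transcripts: Iterable[TranscriptModel]) -> None:
    rows = []
    for t in transcripts:
        rel = ",".join(str(s - t.tx_start) for s, e in t.exons)
        sizes = ",".join(str(e - s) for s, e in t.exons)
        rows.append((t.chrom, t.tx_start, t.tx_end, t.transcript_id, t.gene,
                     t.strand, t.cds_start, t.cds_end, len(t.exons), rel, sizes))
    _write_tsv(path, _GENE_COLS, rows)


# ---------------------------------------------------------------------------
# CLIP clusters
# ---------------------------------------------------------------------------

_CLUSTER_COLS = ("chrom", "start", "end", "transcript_id", "total_reads",
                 "strand", "mirna_reads")


def read_clip_clusters(path, transcripts: Sequence[TranscriptModel] | None = None) -> list:
    """Read CLIP clusters; if ``transcripts`` is given, every cluster must
    reference a known transcript id."""
    known = {t.transcript_id for t in transcripts} if transcripts is not None else None
    out = []
    for lineno, f in _read_tsv(path, _CLUSTER_COLS):
        try:
            reads = {}
            if f[6] not in (".", ""):
                for pair in f[6].split(";"):
                    mid, cnt = pair.rsplit(":", 1)
                    reads[mid] = int(cnt)
            c = ClipCluster(f[0], f[5], int(f[1]), int(f[2]), f[3], int(f[4]), reads)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if known is not None and c.transcript_id not in known:
            raise ValidationError(
                f"{path}:{lineno}: cluster references unknown transcript "
                f"{c.transcript_id!r}")
        out.append(c)
    return out


def write_clip_clusters(path, clusters: Iterable[ClipCluster]) -> None:
    rows = []
    for c in clusters:
        reads = ";".join(f"{m}:{n}" for m, n in sorted(c.mirna_reads.items())) or "."
        rows.append((c.chrom, c.start, c.end, c.transcript_id, c.total_reads,
                     c.strand, reads))
    _write_tsv(path, _CLUSTER_COLS, rows)


# ---------------------------------------------------------------------------
# Associations, poly(A) sites, conservation, miRNA FASTA
# ---------------------------------------------------------------------------

_ASSOC_COLS = ("snp_id", "trait", "p_value")


def read_associations(path, p_max: float | None = None) -> list:
    out = []
    for lineno, f in _read_tsv(path, _ASSOC_COLS):
        try:
            rec = AssociationRecord(f[0], f[1], float(f[2]))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if p_max is not None and rec.p_value > p_max:
            raise ValidationError(
                f"{path}:{lineno}: p_value {rec.p_value} exceeds catalog threshold {p_max}")
        out.append(rec)
    return out


def write_associations(path, assocs: Iterable[AssociationRecord]) -> None:
    _write_tsv(path, _ASSOC_COLS,
               ((a.snp_id, a.trait, format(a.p_value, "g")) for a in assocs))


_POLYA_COLS = ("chrom", "pos", "strand")


def read_polya_sites(path) -> list:
    out = []
    for lineno, f in _read_tsv(path, _POLYA_COLS):
        try:
            out.append(PolyASiteRec(f[0], f[2], int(f[1])))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_polya_sites(path, sites: Iterable[PolyASiteRec]) -> None:
    _write_tsv(path, _POLYA_COLS, ((s.chrom, s.pos, s.strand) for s in sites))


_CONS_COLS = ("snp_id", "score")


def read_conservation(path) -> dict:
    out = {}
    for lineno, f in _read_tsv(path, _CONS_COLS):
        score = float(f[1])
        if not (0.0 <= score <= 1.0) or math.isnan(score):
            raise ValidationError(f"{path}:{lineno}: conservation score outside [0, 1]")
        out[f[0]] = score
    return out


def write_conservation(path, scores: Mapping[str, float]) -> None:
    _write_tsv(path, _CONS_COLS,
               ((k, format(v, "g")) for k, v in scores.items()))


def read_mirnas(path) -> list:
    """Read mature miRNAs from FASTA; a trailing ``|reads=N`` token in the
    header carries the sequencing read count (0 if absent)."""
    out = []
    with open(path) as fh:
        raw = fh.read().splitlines()
    # reuse the validated FASTA reader for sequences, parse counts from headers
    seqs = read_fasta(path)
    counts = {}
    for line in raw:
        if line.startswith(">"):
            toks = line[1:].split()
            counts[toks[0]] = 0
            for t in toks[1:]:
                if t.startswith("reads="):
                    counts[toks[0]] = int(t[6:])
    for name, seq in seqs.items():
        out.append(MiRna(name, seq.replace("T", "U"), counts.get(name, 0)))
    return out


def write_mirnas(path, mirnas: Iterable[MiRna], width: int = 60) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id} reads={m.read_count}\n")
            for i in range(0, len(m.mature_seq), width):
                fh.write(m.mature_seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Table-1-style effects report
# ---------------------------------------------------------------------------

_EFFECT_COLS = ("SNP", "Gene", "Effects", "Traits")


def parse_effects_table(path) -> list:
    """Parse a Table-1-layout report into MechanismAnnotation records.

    Effect phrases are the printed ones ("MRE disruption", "MRE creation",
    "Folding", "Acceptor gain", "Donor gain", "Poly(A)"); anything else is an
    error, as are duplicate SNP ids and empty effect lists.
    """
    out, seen = [], set()
    for lineno, f in _read_tsv(path, _EFFECT_COLS):
        snp_id, gene = f[0], f[1]
        if snp_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        phrases = [p.strip() for p in f[2].split(";") if p.strip()]
        if not phrases:
            raise ValidationError(f"{path}:{lineno}: empty Effects field")
        effects = set()
        for p in phrases:
            if p not in _EFFECT_BY_PHRASE:
                raise ValidationError(f"{path}:{lineno}: unknown effect phrase {p!r}")
            effects.add(_EFFECT_BY_PHRASE[p])
        traits = tuple(t.strip() for t in f[3].split(";") if t.strip())
        out.append(MechanismAnnotation(snp_id, gene, frozenset(effects), traits))
    return out


def write_effects_table(path, annotations: Iterable[MechanismAnnotation]) -> None:
    order = list(Effect)
    rows = []
    for a in annotations:
        effs = "; ".join(e.value for e in sorted(a.effects, key=order.index))
        rows.append((a.snp_id, a.gene, effs, "; ".join(a.traits)))
    _write_tsv(path, _EFFECT_COLS, rows)


def table1_fixture_path() -> Path:
    """Path of the packaged Table-1 report fixture."""
    return Path(__file__).parent / "data" / "table1.tsv"
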