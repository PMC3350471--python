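"""End-to-end orchestration: LD extension, localization, the four mechanism
classifiers, and the Table-1-style aggregation.

The stage order mirrors the analysis: sentinel associations are extended by
LD, SNPs are classified into the five localization classes, the 3'-UTR
enrichment is scored against a resampled null, and every extended 3'-UTR SNP
on a cluster-bearing transcript is screened for poly(A)-signal changes,
splice-site changes, structure switches at RISC sites, and MRE
disruption/creation.  All decision flags are echoed into the run metadata
and every stage is deterministic under the configured seeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import enrichment, io_core, ld_toolkit, rna_structure, utr_mechanisms
from .enrichment import LocationClass
from .io_core import Effect, MechanismAnnotation

log = logging.getLogger(__name__)

SUMMARY_CATEGORIES = ("TOTAL_ANNOTATED", "MRE_DISRUPTION", "MRE_CREATION",
                      "MRE_BOTH", "MRE_UNIQUE", "FOLDING", "SPLICE_TOTAL",
                      "ACCEPTOR_GAIN", "DONOR_GAIN", "POLYA")


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run; every field is echoed into the
    run metadata."""

    r2_min: float = 0.8
    ld_window: int = 1_000_000
    alpha_fold: float = 0.05
    alpha_mre_disrupt: float = 0.05
    alpha_mre_create: float = 0.05
    n_null_fold: int = 120
    fold_window: int | None = rna_structure.DEFAULT_FOLD_WINDOW
    halfwidth: int = 20
    seed: int = 0
    filter_semantics: str = "retain"
    conservation_cutoff: float = 0.57
    compute_enrichment: bool = True
    enrichment_reps: int = 200
    splice_tolerance: float = 0.05
    mre_center_distance: int = 21


@dataclass
class PipelineInputs:
    """The in-memory bundle of every input table/sequence set."""

    transcripts: list
    tx_seqs: Mapping[str, str]
    snps: list
    panel: "ld_toolkit.HaplotypePanel"
    clusters: list
    mirnas: list
    polya_sites: list
    catalog: list
    conservation: Mapping[str, float] = field(default_factory=dict)
    donor_examples: Sequence[str] = ()
    acceptor_examples: Sequence[str] = ()

    @classmethod
    def from_dataset(cls, ds) -> "PipelineInputs":
        return cls(ds.transcripts, ds.tx_seqs, ds.snps, ds.panel, ds.clusters,
                   ds.mirnas, ds.polya_sites, ds.catalog, ds.conservation,
                   ds.donor_examples, ds.acceptor_examples)

    @classmethod
    def from_dir(cls, path) -> "PipelineInputs":
        from pathlib import Path
        path = Path(path)
        transcripts = io_core.read_gene_models(path / "genes.tsv")
        return cls(
            transcripts,
            io_core.read_fasta(path / "transcripts.fa"),
            io_core.read_snp_table(path / "snps.tsv"),
            ld_toolkit.read_panel(path / "panel.tsv"),
            io_core.read_clip_clusters(path / "clip.tsv", transcripts),
            io_core.read_mirnas(path / "mirna.fa"),
            io_core.read_polya_sites(path / "polya.tsv"),
            io_core.read_associations(path / "catalog.tsv"),
            io_core.read_conservation(path / "conservation.tsv")
            if (path / "conservation.tsv").exists() else {},
            [f[0] for _, f in io_core._read_tsv(path / "donor_train.tsv", ("window",))]
            if (path / "donor_train.tsv").exists() else (),
            [f[0] for _, f in io_core._read_tsv(path / "acceptor_train.tsv", ("window",))]
            if (path / "acceptor_train.tsv").exists() else ())


@dataclass
class MechanismSummary:
    """Aggregated per-category SNP counts and conserved fractions."""

    counts: dict
    conserved: dict = field(default_factory=dict)

    def __post_init__(self):
        c = self.counts
        assert c["MRE_UNIQUE"] == c["MRE_DISRUPTION"] + c["MRE_CREATION"] - c["MRE_BOTH"]


@dataclass
class PipelineResult:
    annotations: list
    summary: MechanismSummary
    metadata: dict
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def summarize_mechanisms(annotations: Sequence[MechanismAnnotation]) -> MechanismSummary:
    """Per-category SNP counts; a SNP contributes once per category however
    many transcripts carry it, and SPLICE_TOTAL counts SNPs (a SNP with both
    an acceptor and a donor gain counts once)."""
    per_effect: dict[Effect, set] = {e: set() for e in Effect}
    all_ids = set()
    for a in annotations:
        all_ids.add(a.snp_id)
        for e in a.effects:
            per_effect[e].add(a.snp_id)
    disr = per_effect[Effect.MRE_DISRUPTION]
    crea = per_effect[Effect.MRE_CREATION]
    counts = {
        "TOTAL_ANNOTATED": len(all_ids),
        "MRE_DISRUPTION": len(disr),
        "MRE_CREATION": len(crea),
        "MRE_BOTH": len(disr & crea),
        "MRE_UNIQUE": len(disr | crea),
        "FOLDING": len(per_effect[Effect.FOLDING]),
        "SPLICE_TOTAL": len(per_effect[Effect.ACCEPTOR_GAIN]
                            | per_effect[Effect.DONOR_GAIN]),
        "ACCEPTOR_GAIN": len(per_effect[Effect.ACCEPTOR_GAIN]),
        "DONOR_GAIN": len(per_effect[Effect.DONOR_GAIN]),
        "POLYA": len(per_effect[Effect.POLYA]),
    }
    return MechanismSummary(counts, conserved_fractions(annotations))


_CATEGORY_EFFECTS = {
    "MRE_DISRUPTION": (Effect.MRE_DISRUPTION,),
    "MRE_CREATION": (Effect.MRE_CREATION,),
    "FOLDING": (Effect.FOLDING,),
    "SPLICE_TOTAL": (Effect.ACCEPTOR_GAIN, Effect.DONOR_GAIN),
    "POLYA": (Effect.POLYA,),
}


def conserved_fractions(annotations: Sequence[MechanismAnnotation]) -> dict:
    """Fraction of conservation-flagged SNPs per category; None where no SNP
    in the category carries a flag."""
    out = {}
    for cat, effects in _CATEGORY_EFFECTS.items():
        flagged = [a for a in annotations
                   if a.conserved is not None and any(e in a.effects for e in effects)]
        out[cat] = (sum(1 for a in flagged if a.conserved) / len(flagged)
                    if flagged else None)
    return out


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _empty_summary() -> MechanismSummary:
    return MechanismSummary({k: 0 for k in SUMMARY_CATEGORIES}, {})


def run_pipeline(inputs: PipelineInputs,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage on in-memory inputs.

    Returns the per-SNP mechanism annotations, the aggregated summary and a
    metadata record of every decision flag, threshold and intermediate count.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    meta: dict = {"config": asdict(config),
                  "precedence": [c.name for c in enrichment.DEFAULT_PRECEDENCE],
                  "conventions": {
                      "coordinates": "0-based half-open",
                      "cluster_center": "floor((start+end)/2)",
                      "mre_position": "5' end of the seed-complementary site",
                      "mre_center_distance": "inclusive <= bound"}}

    classes = enrichment.classify_locations(inputs.snps, inputs.transcripts)
    sentinels = {a.snp_id for a in inputs.catalog}
    meta["n_sentinels"] = len(sentinels)
    if not sentinels:
        return PipelineResult([], _empty_summary(), meta)

    neighbors = ld_toolkit.neighbor_lists(inputs.panel, r2_min=config.r2_min,
                                          window=config.ld_window)
    extended = ld_toolkit.extend_sentinels(sentinels, inputs.panel,
                                           r2_min=config.r2_min,
                                           window=config.ld_window,
                                           neighbors=neighbors)
    meta["n_extended"] = len(extended)

    if config.compute_enrichment:
        table = enrichment.class_table(extended, classes)
        res = enrichment.odds_ratio_ci(table)
        null = enrichment.null_enrichment_distribution(
            inputs.panel, classes, n_sentinels=len(sentinels),
            reps=config.enrichment_reps, r2_min=config.r2_min,
            seed=int(rng.integers(2 ** 31)), neighbors=neighbors)
        res.p_empirical = enrichment.empirical_p(math.log(res.or_estimate), null)
        res.n_null = len(null)
        meta["utr3_enrichment"] = {"or": res.or_estimate, "ci": [res.ci_low, res.ci_high],
                                   "p_empirical": res.p_empirical,
                                   "n_null": res.n_null}

    # --- per-transcript context -------------------------------------------
    by_id = {t.transcript_id: t for t in inputs.transcripts}
    cluster_centers_tx: dict[str, list] = {}
    for c in inputs.clusters:
        t = by_id.get(c.transcript_id)
        if t is None:
            continue
        ctx = t.genomic_to_tx(c.center)
        if ctx is not None:
            cluster_centers_tx.setdefault(c.transcript_id, []).append(ctx)
    hosts = set(cluster_centers_tx)
    polya_tx: dict[str, list] = {}
    for p in inputs.polya_sites:
        for t in inputs.transcripts:
            if t.chrom == p.chrom and t.strand == p.strand:
                tp = t.genomic_to_tx(p.pos)
                if tp is not None:
                    polya_tx.setdefault(t.transcript_id, []).append(tp)

    snp_by_id = {s.snp_id: s for s in inputs.snps}

    def utr3_hosts(snp):
        out = []
        for t in inputs.transcripts:
            if t.transcript_id not in hosts or t.chrom != snp.chrom:
                continue
            tx = t.genomic_to_tx(snp.pos)
            if tx is None:
                continue
            lo, hi = t.utr3_tx_interval()
            if lo <= tx < hi:
                out.append((t, tx))
        return out

    test_ids = sorted(s for s in extended
                      if classes.get(s) == LocationClass.UTR3
                      and s in snp_by_id and utr3_hosts(snp_by_id[s]))
    meta["n_test_utr3"] = len(test_ids)

    # --- splice model ------------------------------------------------------
    splice_model = None
    if inputs.donor_examples and inputs.acceptor_examples:
        splice_model = utr_mechanisms.train_splice_model(
            inputs.donor_examples, inputs.acceptor_examples,
            seed=int(rng.integers(2 ** 31)))
    else:
        log.warning("no splice training examples supplied; splice stage skipped")

    # --- structure-threshold calibration -----------------------------------
    def alt_seq_for(t, tx, snp):
        seq = inputs.tx_seqs[t.transcript_id]
        ref_tx, alt_tx = t.tx_allele(snp)
        if seq[tx] != ref_tx:
            raise ValueError(f"{snp.snp_id}: reference allele mismatch on "
                             f"{t.transcript_id}")
        return seq, seq[:tx] + alt_tx + seq[tx + 1:]

    def min_rho(snp):
        per_tx = {}
        for t, tx in utr3_hosts(snp):
            seq_ref, seq_alt = alt_seq_for(t, tx, snp)
            per_tx[t.transcript_id] = (seq_ref, seq_alt, tx,
                                       sorted(cluster_centers_tx[t.transcript_id]))
        results = rna_structure.min_rho_per_snp(
            snp.snp_id, per_tx, halfwidth=config.halfwidth,
            fold_window=config.fold_window)
        rhos = [r.rho_min for r in results if not math.isnan(r.rho_min)]
        return (min(rhos) if rhos else math.nan), results

    null_pool = sorted(s.snp_id for s in inputs.snps
                       if classes.get(s.snp_id) == LocationClass.UTR3
                       and s.snp_id not in sentinels and utr3_hosts(s))
    n_null = min(config.n_null_fold, len(null_pool))
    null_ids = list(rng.choice(null_pool, size=n_null, replace=False)) if n_null else []
    null_rhos = [min_rho(snp_by_id[s])[0] for s in null_ids]
    null_rhos = [r for r in null_rhos if not math.isnan(r)]
    rho_threshold = (rna_structure.calibrate_rho_threshold(null_rhos, config.alpha_fold)
                     if null_rhos else None)
    meta["fold_null_size"] = len(null_rhos)
    meta["rho_threshold"] = rho_threshold

    # --- MRE miRNA pools ----------------------------------------------------
    utr_seqs, utr_offsets, utr_regions = {}, {}, {}
    for tid in hosts:
        t = by_id[tid]
        lo, hi = t.utr3_tx_interval()
        utr_seqs[tid] = inputs.tx_seqs[tid][lo:hi]
        utr_offsets[tid] = lo
        utr_regions[tid] = [(c - config.mre_center_distance - lo,
                             c + config.mre_center_distance + 1 - lo)
                            for c in cluster_centers_tx[tid]]
    mre_pvals, kept_disrupt = utr_mechanisms.mre_enrichment_filter(
        inputs.mirnas, utr_seqs, utr_regions, alpha=config.alpha_mre_disrupt)
    if config.alpha_mre_create == config.alpha_mre_disrupt:
        kept_create = kept_disrupt
    else:
        _, kept_create = utr_mechanisms.mre_enrichment_filter(
            inputs.mirnas, utr_seqs, utr_regions, alpha=config.alpha_mre_create)
    meta["mre_pool_disrupt"] = len(kept_disrupt)
    meta["mre_pool_create"] = len(kept_create)

    # --- per-SNP mechanism calls -------------------------------------------
    catalog_traits: dict[str, list] = {}
    for a in inputs.catalog:
        catalog_traits.setdefault(a.snp_id, []).append(a.trait)

    annotations: list[MechanismAnnotation] = []
    details: dict = {"splice_events": [], "structure": [], "mre": [], "polya": []}
    for sid in test_ids:
        snp = snp_by_id[sid]
        effects: set[Effect] = set()
        gene = None
        for t, tx in utr3_hosts(snp):
            gene = gene or t.gene
            seq_ref, seq_alt = alt_seq_for(t, tx, snp)
            # poly(A)
            pa = utr_mechanisms.scan_polya(sid, tx, seq_ref, seq_alt,
                                           polya_tx.get(t.transcript_id, ()))
            if pa.call in ("CREATED", "DISRUPTED"):
                effects.add(Effect.POLYA)
            if pa.call != "NONE":
                details["polya"].append(pa)
            # splicing
            if splice_model is not None:
                events = utr_mechanisms.classify_splice_changes(
                    sid, tx, seq_ref, seq_alt, splice_model, t.transcript_id,
                    junctions=t.splice_junction_tx_positions(),
                    tolerance=config.splice_tolerance,
                    filter_semantics=config.filter_semantics)
                for ev in events:
                    if ev.change == "GAIN" and ev.retained:
                        ev.risc_loss_fraction = utr_mechanisms.risc_loss_fraction(
                            ev, t, inputs.clusters)
                        effects.add(Effect.ACCEPTOR_GAIN if ev.site_type == "ACCEPTOR"
                                    else Effect.DONOR_GAIN)
                details["splice_events"].extend(events)
            # MREs
            lo = utr_offsets[t.transcript_id]
            uref = utr_seqs[t.transcript_id]
            ualt = seq_alt[lo:lo + len(uref)]
            ref_functional, alt_functional = [], []
            for mir in inputs.mirnas:
                ref_functional += utr_mechanisms.functional_mres(
                    utr_mechanisms.find_seed_matches(uref, mir), inputs.clusters,
                    t, tx_offset=lo, max_center_distance=config.mre_center_distance)
                alt_functional += utr_mechanisms.functional_mres(
                    utr_mechanisms.find_seed_matches(ualt, mir), inputs.clusters,
                    t, tx_offset=lo, max_center_distance=config.mre_center_distance)
            change = utr_mechanisms.classify_mre_change(
                sid, t.transcript_id, tx - lo, ref_functional, alt_functional,
                kept_disrupt, kept_create)
            if change.disrupted:
                effects.add(Effect.MRE_DISRUPTION)
            if change.created:
                effects.add(Effect.MRE_CREATION)
            if change.disrupted or change.created:
                details["mre"].append(change)
        # structure (min over transcripts' sites)
        rho, results = min_rho(snp)
        details["structure"].extend(results)
        if rho_threshold is not None and not math.isnan(rho) and rho < rho_threshold:
            effects.add(Effect.FOLDING)
        if effects:
            score = inputs.conservation.get(sid)
            annotations.append(MechanismAnnotation(
                sid, gene or "", frozenset(effects),
                tuple(catalog_traits.get(sid, ())),
                utr_mechanisms.conservation_flag(score, config.conservation_cutoff)))

    summary = summarize_mechanisms(annotations)
    meta["counts"] = summary.counts
    return PipelineResult(annotations, summary, meta, details)
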