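"""Synthetic study generator: genome structure, LD realization, planted
effects and ledger completeness."""

import math

import numpy as np
import pytest

from mirsnpmech import ld_toolkit, rna_structure, synthetic_data
from mirsnpmech.enrichment import LocationClass
from mirsnpmech.synthetic_data import (SyntheticConfig, generate_dataset,
                                       generate_genome, generate_haplotypes,
                                       verify_truth)


def test_config_validation():
    with pytest.raises(ValueError, match="even"):
        SyntheticConfig(n_haplotypes=7)
    with pytest.raises(ValueError, match="positive"):
        SyntheticConfig(n_genes=0)
    with pytest.raises(ValueError, match="mechanisms"):
        SyntheticConfig(planted_effects={"NOPE": 1})
    with pytest.raises(ValueError, match="utr_enrichment_or"):
        SyntheticConfig(utr_enrichment_or=0.5)


def test_generate_genome_invariants():
    cfg = SyntheticConfig(seed=1, n_genes=5)
    g = generate_genome(cfg)
    assert len(g.transcripts) == 5
    chrom = g.chrom_seqs["chr1"]
    for t in g.transcripts:
        assert 2 <= len(t.exons) <= 4
        lo, hi = t.utr3_tx_interval()
        assert cfg.utr_len_range[0] <= hi - lo <= cfg.utr_len_range[1]
        cds_lo, cds_hi = t.cds_tx_interval()
        assert 0 < cds_lo < cds_hi == lo
        # every intron starts GT and ends AG (exhaustive scan, sense strand)
        spans = sorted(t.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            intron = chrom[e1:s2]
            if t.strand == "-":
                from mirsnpmech.io_core import revcomp
                intron = revcomp(intron)
            assert intron[:2] == "GT" and intron[-2:] == "AG"


def test_generate_genome_deterministic():
    a = generate_genome(SyntheticConfig(seed=4, n_genes=4))
    b = generate_genome(SyntheticConfig(seed=4, n_genes=4))
    assert a.chrom_seqs == b.chrom_seqs
    assert a.transcripts == b.transcripts
    assert a.polya_sites == b.polya_sites


def test_polya_signal_site_geometry():
    g = generate_genome(SyntheticConfig(seed=2, n_genes=10))
    by_id = {t.transcript_id: t for t in g.transcripts}
    n_checked = 0
    for tid, signals in g.polya_signal_tx.items():
        t = by_id[tid]
        seq = t.spliced_sequence(g.chrom_seqs[t.chrom])
        for q in signals:
            assert seq[q:q + 6] == "AATAAA"
            n_checked += 1
    assert n_checked >= 1
    assert g.polya_sites  # cleavage records emitted


def _positions(n, rng, spacing=500):
    pos = np.cumsum(rng.integers(50, spacing, n))
    return [(f"s{i}", "chr1", int(p)) for i, p in enumerate(pos)]


def test_haplotypes_flip_probability_zero_gives_perfect_blocks(rng):
    cfg = SyntheticConfig(seed=0, target_r2_within_block=1.0)
    snp_pos = _positions(40, rng)
    classes = {sid: LocationClass.INTRONIC for sid, _, _ in snp_pos}
    panel, block_map = generate_haplotypes(cfg, snp_pos, classes)
    blocks = {}
    for sid, b in block_map.items():
        blocks.setdefault(b, []).append(sid)
    for members in blocks.values():
        for a in members:
            for b in members:
                assert ld_toolkit.compute_r2(panel, a, b) == pytest.approx(1.0)


def test_haplotypes_deterministic(rng):
    cfg = SyntheticConfig(seed=5)
    snp_pos = _positions(30, rng)
    classes = {sid: LocationClass.UTR3 for sid, _, _ in snp_pos}
    p1, m1 = generate_haplotypes(cfg, snp_pos, classes)
    p2, m2 = generate_haplotypes(cfg, snp_pos, classes)
    assert (p1.haplotypes == p2.haplotypes).all() and m1 == m2


def test_realized_within_block_r2_meets_target(rng):
    cfg = SyntheticConfig(seed=8, n_haplotypes=120, target_r2_within_block=0.9)
    snp_pos = _positions(300, rng, spacing=200)
    classes = {sid: LocationClass.INTRONIC for sid, _, _ in snp_pos}
    panel, block_map = generate_haplotypes(cfg, snp_pos, classes)
    blocks = {}
    for sid, b in block_map.items():
        blocks.setdefault(b, []).append(sid)
    r2s = []
    for members in blocks.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                r2s.append(ld_toolkit.compute_r2(panel, a, b))
    assert np.median(r2s) >= cfg.target_r2_within_block - 0.05


def test_cross_block_r2_matches_independence_expectation(rng):
    """Pairs in different blocks are independent: E[r2] = 1/(n_hap - 1)."""
    cfg = SyntheticConfig(seed=9, n_haplotypes=120)
    snp_pos = _positions(200, rng, spacing=300)
    classes = {sid: LocationClass.CDS for sid, _, _ in snp_pos}
    panel, block_map = generate_haplotypes(cfg, snp_pos, classes)
    ids = panel.snp_ids
    cross = []
    rng2 = np.random.default_rng(1)
    while len(cross) < 300:
        a, b = rng2.choice(len(ids), 2, replace=False)
        if block_map[ids[a]] != block_map[ids[b]]:
            cross.append(ld_toolkit.compute_r2(panel, ids[a], ids[b]))
    expected = 1 / (cfg.n_haplotypes - 1)
    assert 0.5 * expected < np.mean(cross) < 2.0 * expected


def test_exonic_blocks_smaller_than_intronic(default_dataset):
    ds = default_dataset
    sizes = {}
    for sid, b in ds.block_map.items():
        sizes.setdefault(b, []).append(sid)
    by_class = {}
    for b, members in sizes.items():
        cls = ds.classes[members[0]]
        by_class.setdefault(cls, []).append(len(members))
    assert (np.mean(by_class[LocationClass.INTRONIC])
            > np.mean(by_class[LocationClass.UTR3]))


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def test_truth_ledger_complete_and_verifiable(default_dataset):
    ds = default_dataset
    counts = {}
    snp_ids = set()
    for rec in ds.truth:
        counts[rec.mechanism] = counts.get(rec.mechanism, 0) + 1
        assert rec.snp_id not in snp_ids  # exactly one record per effect
        snp_ids.add(rec.snp_id)
        assert rec.block_id is not None
    for mech, k in ds.config.planted_effects.items():
        assert counts.get(mech, 0) == k
    assert counts.get("CONTROL", 0) == ds.config.n_controls
    verify_truth(ds)  # direct sequence inspection of every record


def test_planted_mre_disruption_inside_cluster(default_dataset):
    ds = default_dataset
    by_id = {t.transcript_id: t for t in ds.transcripts}
    snps = {s.snp_id: s for s in ds.snps}
    for rec in ds.truth:
        if rec.mechanism != "MRE_DISRUPTION":
            continue
        t = by_id[rec.transcript_id]
        tx = t.genomic_to_tx(snps[rec.snp_id].pos)
        near = [c for c in ds.clusters if c.transcript_id == rec.transcript_id
                and abs(t.genomic_to_tx(c.center) - tx) <= 21
                and c.mirna_reads.get(rec.mirna_id, 0) >= 1]
        assert near, f"{rec.snp_id} has no supporting cluster"


def test_planted_folding_switches_structure(default_dataset):
    """Both alleles fold differently at the planted site: rho < 0.5 by
    construction (redraw screening)."""
    ds = default_dataset
    by_id = {t.transcript_id: t for t in ds.transcripts}
    snps = {s.snp_id: s for s in ds.snps}
    n = 0
    for rec in ds.truth:
        if rec.mechanism != "FOLDING":
            continue
        t = by_id[rec.transcript_id]
        snp = snps[rec.snp_id]
        tx = t.genomic_to_tx(snp.pos)
        seq = ds.tx_seqs[rec.transcript_id]
        ref_tx, alt_tx = t.tx_allele(snp)
        alt = seq[:tx] + alt_tx + seq[tx + 1:]
        rho = rna_structure.site_rho(seq, alt, tx, rec.site_center_tx)
        assert rho < 0.5
        n += 1
    assert n == ds.config.planted_effects["FOLDING"]


def test_controls_far_from_functional_elements(default_dataset):
    ds = default_dataset
    by_id = {t.transcript_id: t for t in ds.transcripts}
    snps = {s.snp_id: s for s in ds.snps}
    for rec in ds.truth:
        if rec.mechanism != "CONTROL":
            continue
        t = by_id[rec.transcript_id]
        tx = t.genomic_to_tx(snps[rec.snp_id].pos)
        centers = [t.genomic_to_tx(c.center) for c in ds.clusters
                   if c.transcript_id == rec.transcript_id]
        assert centers and min(abs(tx - c) for c in centers) >= 50
        assert all(abs(tx - b) >= 50 for b in t.splice_junction_tx_positions())


def test_dataset_determinism():
    cfg = SyntheticConfig(seed=6, n_genes=8, n_snps=200, n_sentinels=10,
                          mirna_pool=5, background_clusters_per_mirna=2,
                          planted_effects={"MRE_DISRUPTION": 1, "FOLDING": 1},
                          n_controls=1)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    assert [s.snp_id for s in a.snps] == [s.snp_id for s in b.snps]
    assert a.chrom_seqs == b.chrom_seqs
    assert (a.panel.haplotypes == b.panel.haplotypes).all()
    assert [(c.start, c.end) for c in a.clusters] == \
        [(c.start, c.end) for c in b.clusters]
    assert [(x.snp_id, x.trait, x.p_value) for x in a.catalog] == \
        [(x.snp_id, x.trait, x.p_value) for x in b.catalog]


def test_empty_catalog_with_zero_sentinels():
    cfg = SyntheticConfig(seed=3, n_genes=6, n_snps=100, n_sentinels=0,
                          planted_effects={}, n_controls=0, mirna_pool=4,
                          background_clusters_per_mirna=1)
    ds = generate_dataset(cfg)
    assert ds.catalog == []


def test_maf_and_panel_consistency(default_dataset):
    ds = default_dataset
    freqs = ds.panel.allele_freqs()
    for i, s in enumerate(ds.snps):
        assert 0 < freqs[i] < 1  # no monomorphic columns
        assert s.maf == pytest.approx(min(freqs[i], 1 - freqs[i]))


def test_dataset_write_and_reload_round_trip(tmp_path, default_dataset):
    from mirsnpmech import pipeline_report, io_core
    ds = default_dataset
    ds.write(tmp_path)
    inputs = pipeline_report.PipelineInputs.from_dir(tmp_path)
    assert [s.snp_id for s in inputs.snps] == [s.snp_id for s in ds.snps]
    assert inputs.tx_seqs == ds.tx_seqs
    assert (inputs.panel.haplotypes == ds.panel.haplotypes).all()
    assert len(inputs.clusters) == len(ds.clusters)
    truth = synthetic_data.read_truth(tmp_path / "truth.tsv")
    assert [(r.snp_id, r.mechanism) for r in truth] == \
        [(r.snp_id, r.mechanism) for r in ds.truth]
    mirs = io_core.read_mirnas(tmp_path / "mirna.fa")
    assert mirs == ds.mirnas
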