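"""Poly(A), splice and MRE classifiers."""

import numpy as np
import pytest

import oracles
from mirsnpmech import synthetic_data, utr_mechanisms
from mirsnpmech.io_core import ClipCluster, MiRna, TranscriptModel
from mirsnpmech.utr_mechanisms import (DEFAULT_POLYA_HEXAMERS, MreMatch,
                                       SpliceChangeEvent, classify_mre_change,
                                       classify_splice_changes,
                                       conservation_flag, find_seed_matches,
                                       functional_mres, mre_enrichment_filter,
                                       risc_loss_fraction, scan_polya,
                                       train_splice_model)

# ---------------------------------------------------------------------------
# poly(A)
# ---------------------------------------------------------------------------


def polya_seq(core, pos=30, length=80):
    seq = "C" * length
    return seq[:pos] + core + seq[pos + len(core):]


def test_polya_disrupted():
    ref = polya_seq("AATAAA")
    alt = polya_seq("AACAAA")
    res = scan_polya("rs1", 32, ref, alt, [50])
    assert res.call == "DISRUPTED" and res.hexamer_ref == "AATAAA"


def test_polya_created_is_symmetric():
    ref = polya_seq("AACAAA")
    alt = polya_seq("AATAAA")
    res = scan_polya("rs1", 32, ref, alt, [50])
    assert res.call == "CREATED" and res.hexamer_alt == "AATAAA"


def test_polya_synonymous_swap():
    # AATAAA -> AATGAA exchanges one listed hexamer for another
    assert "AATGAA" in DEFAULT_POLYA_HEXAMERS
    res = scan_polya("rs1", 33, polya_seq("AATAAA"), polya_seq("AATGAA"), [50])
    assert res.call == "SYNONYMOUS"


def test_polya_none_and_out_of_range():
    ref, alt = polya_seq("CCCCCC"), polya_seq("CCCCCG")
    assert scan_polya("rs1", 32, ref, alt, [50]).call == "NONE"
    res = scan_polya("rs1", 32, polya_seq("AATAAA"), polya_seq("AACAAA"), [200])
    assert res.call == "NONE" and res.reason == "out of range"


def test_polya_truncated_window_at_utr_end():
    ref = "G" * 10 + "AATAAA"  # SNP 2 nt from the end: truncated window
    alt = "G" * 10 + "AATAGA"  # AATAGA is not a listed signal variant
    res = scan_polya("rs1", 14, ref, alt, [30])
    assert res.call == "DISRUPTED"


# ---------------------------------------------------------------------------
# splice model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_model():
    rng = np.random.default_rng(7)
    donors = [synthetic_data._sample_window(synthetic_data.DONOR_EMISSION, rng)
              for _ in range(150)]
    acceptors = [synthetic_data._sample_window(synthetic_data.ACCEPTOR_EMISSION, rng)
                 for _ in range(150)]
    return train_splice_model(donors, acceptors, seed=0)


def consensus(pwm):
    return "".join("ACGT"[int(np.argmax(pwm[:, i]))] for i in range(pwm.shape[1]))


def test_consensus_beats_every_single_mismatch(trained_model):
    # consensus of the trained matrix itself: a PWM property
    win = consensus(np.exp(trained_model.donor_pwm))
    base = trained_model.score(win, "DONOR")
    for i in range(len(win)):
        for b in "ACGT":
            if b == win[i]:
                continue
            mut = win[:i] + b + win[i + 1:]
            assert trained_model.score(mut, "DONOR") < base


def test_training_requires_enough_core_examples():
    with pytest.raises(ValueError, match=">= 50"):
        train_splice_model(["AAAAAAAAA"] * 60, ["A" * 23] * 60)


def test_heldout_true_sites_and_shuffled_rates(trained_model):
    """True emission draws score >= 0.5 in >= 90% of cases; random
    core-bearing windows in <= 5%."""
    rng = np.random.default_rng(99)
    for site_type, pwm, core_fix in (
            ("DONOR", synthetic_data.DONOR_EMISSION,
             lambda w: w[:3] + "GT" + w[5:]),
            ("ACCEPTOR", synthetic_data.ACCEPTOR_EMISSION,
             lambda w: w[:18] + "AG" + w[20:])):
        held = [synthetic_data._sample_window(pwm, rng) for _ in range(200)]
        rate = np.mean([trained_model.likelihood(w, site_type) >= 0.5 for w in held])
        assert rate >= 0.90
        width = pwm.shape[1]
        shuffled = [core_fix("".join(rng.choice(list("ACGT"), width)))
                    for _ in range(200)]
        false = np.mean([trained_model.likelihood(w, site_type) >= 0.5
                         for w in shuffled])
        assert false <= 0.05


def test_noncanonical_core_scores_zero(trained_model):
    win = consensus(synthetic_data.DONOR_EMISSION)
    broken = win[:3] + "GC" + win[5:]
    assert trained_model.likelihood(broken, "DONOR") == 0.0


def test_classify_gain_event(trained_model):
    win = consensus(synthetic_data.ACCEPTOR_EMISSION)
    broken = win[:18] + "C" + win[19:]
    seq_ref = "C" * 40 + broken + "C" * 40
    seq_alt = "C" * 40 + win + "C" * 40
    snp_tx = 40 + 18
    events = classify_splice_changes("rs1", snp_tx, seq_ref, seq_alt,
                                     trained_model, "t1")
    gains = [e for e in events if e.change == "GAIN"]
    assert len(gains) == 1
    ev = gains[0]
    assert ev.site_type == "ACCEPTOR" and ev.retained
    assert ev.position == 40 + 20  # junction at the first exonic base
    assert ev.likelihood_alt >= 0.5 > ev.likelihood_ref


def test_classify_no_event_for_identical_alleles(trained_model):
    seq = "C" * 40 + consensus(synthetic_data.DONOR_EMISSION) + "C" * 40
    assert classify_splice_changes("rs1", 44, seq, seq, trained_model, "t1") == []


def test_loss_far_from_border_not_retained(trained_model):
    win = consensus(synthetic_data.ACCEPTOR_EMISSION)
    broken = win[:18] + "C" + win[19:]
    seq_ref = "C" * 300 + win + "C" * 300
    seq_alt = "C" * 300 + broken + "C" * 300
    snp_tx = 300 + 18
    events = classify_splice_changes("rs1", snp_tx, seq_ref, seq_alt,
                                     trained_model, "t1", junctions=[5])
    losses = [e for e in events if e.change == "LOSS"]
    assert losses and not losses[0].retained
    # opposite filter semantics flips retention
    events2 = classify_splice_changes("rs1", snp_tx, seq_ref, seq_alt,
                                      trained_model, "t1", junctions=[5],
                                      filter_semantics="exclude")
    assert [e for e in events2 if e.change == "LOSS"][0].retained


def test_loss_near_border_retained(trained_model):
    win = consensus(synthetic_data.ACCEPTOR_EMISSION)
    broken = win[:18] + "C" + win[19:]
    seq_ref = "C" * 300 + win + "C" * 300
    seq_alt = "C" * 300 + broken + "C" * 300
    events = classify_splice_changes("rs1", 318, seq_ref, seq_alt,
                                     trained_model, "t1", junctions=[330])
    assert [e for e in events if e.change == "LOSS"][0].retained


# ---------------------------------------------------------------------------
# RISC-site loss accounting
# ---------------------------------------------------------------------------

def one_exon_tx(length=1000):
    return TranscriptModel("t1", "G", "chr1", "+", ((0, length),), 10, 300)


def clusters_at(tx, centers):
    return [ClipCluster(tx.chrom, tx.strand, c - 20, c + 21, tx.transcript_id,
                        5, {"m": 2}) for c in centers]


def gain(site_type, position):
    return SpliceChangeEvent("rs1", "t1", site_type, "GAIN", 0.0, 0.9, position)


def test_risc_loss_fraction_acceptor_counts_upstream_clusters():
    tx = one_exon_tx()
    cl = clusters_at(tx, [400, 500, 600, 700])
    # novel acceptor at 550: region [0, 550) excised -> 2 of 4 lost
    assert risc_loss_fraction(gain("ACCEPTOR", 550), tx, cl) == 0.5
    # acceptor downstream of every cluster: whole cluster set excised
    assert risc_loss_fraction(gain("ACCEPTOR", 900), tx, cl) == 1.0
    # acceptor upstream of every cluster: nothing excised
    assert risc_loss_fraction(gain("ACCEPTOR", 350), tx, cl) == 0.0


def test_risc_loss_fraction_donor_counts_downstream_clusters():
    tx = one_exon_tx()
    cl = clusters_at(tx, [400, 500, 600, 700])
    assert risc_loss_fraction(gain("DONOR", 550), tx, cl) == 0.5
    assert risc_loss_fraction(gain("DONOR", 300), tx, cl) == 1.0
    assert risc_loss_fraction(gain("DONOR", 800), tx, cl) == 0.0


def test_risc_loss_matches_interval_oracle(default_dataset):
    """On planted splice-gain SNPs the fraction equals a direct interval
    intersection computed independently."""
    ds = default_dataset
    by_id = {t.transcript_id: t for t in ds.transcripts}
    snps = {s.snp_id: s for s in ds.snps}
    checked = 0
    for rec in ds.truth:
        if rec.mechanism not in ("ACCEPTOR_GAIN", "DONOR_GAIN"):
            continue
        t = by_id[rec.transcript_id]
        # SNP sits at the A of the AG core (acceptor: junction 2 nt downstream)
        # or at the T of the GT core (donor: junction 1 nt upstream)
        junction = rec.site_center_tx + (2 if rec.mechanism == "ACCEPTOR_GAIN" else -1)
        ev = gain("ACCEPTOR" if rec.mechanism == "ACCEPTOR_GAIN" else "DONOR",
                  junction)
        ev.transcript_id = t.transcript_id
        got = risc_loss_fraction(ev, t, ds.clusters)
        own = [c for c in ds.clusters if c.transcript_id == t.transcript_id]
        centers = [t.genomic_to_tx(c.center) for c in own]
        borders = t.splice_junction_tx_positions()
        if ev.site_type == "ACCEPTOR":
            lo = max([b for b in borders if b <= junction], default=0)
            expected = sum(lo <= c < junction for c in centers) / len(own)
        else:
            hi = min([b for b in borders if b >= junction], default=t.length)
            expected = sum(junction <= c < hi for c in centers) / len(own)
        assert got == pytest.approx(expected)
        checked += 1
    assert checked >= 2
    del snps


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------

MIR = MiRna("mirX", "UGAGGUAGUAGGUUGUAUAGUU", 10)  # seed 2-7 = GAGGUA


def test_single_planted_6mer():
    site = "TACCTC"  # reverse complement of GAGGUA
    seq = "G" * 20 + site + "G" * 20
    matches = find_seed_matches(seq, MIR)
    assert [(m.match_type, m.utr_start) for m in matches] == [("6MER", 20)]


def test_most_specific_type_reported():
    core = "TACCTC"
    m8 = "C"  # complement of seed position 8 (G in UGAGGUAG...)
    seq = "G" * 10 + m8 + core + "A" + "G" * 10
    matches = find_seed_matches(seq, MIR)
    assert [(m.match_type, m.utr_start) for m in matches] == [("8MER", 10)]
    only7 = find_seed_matches(seq, MIR, match_types=("6MER", "7MER_M8"))
    assert [(m.match_type, m.utr_start) for m in only7] == [("7MER_M8", 10)]


def test_alt_allele_destroys_match():
    seq = "G" * 20 + "TACCTC" + "G" * 20
    alt = seq[:23] + "A" + seq[24:]
    assert find_seed_matches(seq, MIR)
    assert not find_seed_matches(alt, MIR)


def test_seed_scan_equals_naive_oracle(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 300))
        mir = MiRna("m", "".join(rng.choice(list("ACGU"), 21)), 1)
        got = sorted((m.match_type, m.utr_start) for m in find_seed_matches(seq, mir))
        assert got == sorted(oracles.naive_seed_scan(seq, mir.mature_seq))


# ---------------------------------------------------------------------------
# functional MREs and enrichment filter
# ---------------------------------------------------------------------------

def test_functional_mre_distance_and_read_rules():
    tx = one_exon_tx()
    def cluster(center, reads):
        return ClipCluster("chr1", "+", center - 20, center + 21, "t1", 5, reads)
    m = MreMatch("mirX", "6MER", 500)
    # 30 nt away: dropped
    assert not functional_mres([m], [cluster(530, {"mirX": 3})], tx)
    # close but no reads for that miRNA: dropped
    assert not functional_mres([m], [cluster(510, {"other": 3})], tx)
    # exactly 21 nt: retained (inclusive boundary)
    kept = functional_mres([m], [cluster(521, {"mirX": 1})], tx)
    assert kept and kept[0].cluster_distance == 21 and kept[0].within_cluster


def test_enrichment_filter_keeps_concentrated_mirna():
    rng = np.random.default_rng(4)
    site = "TACCTC"
    utrs, regions = {}, {}
    for i in range(6):
        seq = "".join(rng.choice(list("G"), 400))
        utrs[f"t{i}"] = seq[:100] + site + seq[106:]
        regions[f"t{i}"] = [(80, 130)]
    pvals, kept = mre_enrichment_filter([MIR], utrs, regions, alpha=0.05)
    assert kept == {"mirX"} and pvals["mirX"] < 0.01


def test_enrichment_filter_null_rarely_keeps(rng):
    keep_count = 0
    runs = 20
    for r in range(runs):
        utrs = {f"t{i}": "".join(rng.choice(list("ACGT"), 600)) for i in range(5)}
        regions = {f"t{i}": [(100, 160), (400, 460)] for i in range(5)}
        mir = MiRna("m", "".join(rng.choice(list("ACGU"), 21)), 1)
        _, kept = mre_enrichment_filter([mir], utrs, regions, alpha=0.05)
        keep_count += bool(kept)
    assert keep_count <= 2  # proportional placement: keep rate ~ alpha


def test_fisher_p_equals_hypergeometric_tail():
    from scipy import stats as sps
    rng = np.random.default_rng(12)
    for _ in range(60):
        a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        got = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert got == pytest.approx(oracles.hypergeom_tail(a, b, c, d), abs=1e-10)


# ---------------------------------------------------------------------------
# MRE change calling
# ---------------------------------------------------------------------------

def match(mirna, typ, start):
    return MreMatch(mirna, typ, start, within_cluster=True, cluster_distance=0)


def test_disruption_creation_and_substitution():
    kept = {"mirA", "mirB"}
    ref = [match("mirA", "6MER", 100)]
    alt = [match("mirB", "6MER", 100)]
    res = classify_mre_change("rs1", "t1", 102, ref, alt, kept, kept)
    assert res.disrupted == {"mirA"} and res.created == {"mirB"}
    assert res.substitution
    res2 = classify_mre_change("rs1", "t1", 102, ref, [], kept, kept)
    assert res2.disrupted == {"mirA"} and not res2.created and not res2.substitution


def test_enhancement_counts_as_creation():
    kept = {"mirA"}
    ref = [match("mirA", "6MER", 100)]
    alt = [match("mirA", "8MER", 99)]
    res = classify_mre_change("rs1", "t1", 102, ref, alt, kept, kept)
    assert res.created == {"mirA"} and not res.disrupted


def test_pool_membership_gates_calls():
    ref = [match("mirA", "6MER", 100)]
    res = classify_mre_change("rs1", "t1", 102, ref, [], set(), {"mirA"})
    assert not res.disrupted


def test_snp_outside_site_yields_empty():
    ref = [match("mirA", "6MER", 100)]
    res = classify_mre_change("rs1", "t1", 300, ref, [], {"mirA"}, {"mirA"})
    assert not res.disrupted and not res.created


def test_allele_swap_duality(rng):
    """classify(ref->alt).disrupted == classify(alt->ref).created under
    symmetric pools, for random site configurations."""
    kept = {f"m{i}" for i in range(4)}
    types = ("6MER", "7MER_A1", "7MER_M8", "8MER")
    for _ in range(50):
        snp_pos = 100
        def random_side():
            out = []
            for i in range(4):
                if rng.random() < 0.5:
                    typ = str(rng.choice(types))
                    start = snp_pos - int(rng.integers(0, 6))
                    out.append(match(f"m{i}", typ, start))
            return out
        ref, alt = random_side(), random_side()
        fwd = classify_mre_change("rs", "t", snp_pos, ref, alt, kept, kept)
        rev = classify_mre_change("rs", "t", snp_pos, alt, ref, kept, kept)
        assert fwd.disrupted == rev.created
        assert fwd.created == rev.disrupted


def test_conservation_flag_strict_cutoff():
    assert conservation_flag(0.57) is False
    assert conservation_flag(0.58) is True
    assert conservation_flag(None) is None
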