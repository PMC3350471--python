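"""Localization classes, odds-ratio machinery, resampled null, small stats."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.integrate import quad

from conftest import make_panel
from mirsnpmech import enrichment
from mirsnpmech.enrichment import (ContingencyTable2x2, LocationClass,
                                   classify_snp_location, contingency_chi2,
                                   empirical_p, fisher_combined_p,
                                   maf_binned_or, odds_ratio_ci,
                                   rough_fdr_level)
from mirsnpmech.io_core import SnpRecord, TranscriptModel


def snp(pos, chrom="chr1"):
    return SnpRecord(f"rs{pos}", chrom, pos, "A", "G", 0.2)


PLUS_TX = TranscriptModel("tp", "GP", "chr1", "+", ((0, 100), (200, 400)), 20, 300)


def test_five_class_labels():
    assert classify_snp_location(snp(5000), [PLUS_TX]) == LocationClass.INTERGENIC
    assert classify_snp_location(snp(150), [PLUS_TX]) == LocationClass.INTRONIC
    assert classify_snp_location(snp(10), [PLUS_TX]) == LocationClass.UTR5
    assert classify_snp_location(snp(250), [PLUS_TX]) == LocationClass.CDS
    assert classify_snp_location(snp(350), [PLUS_TX]) == LocationClass.UTR3


def test_precedence_cds_over_intron():
    # SNP in the CDS of A and the intron of B: precedence gives CDS
    other = TranscriptModel("tq", "GQ", "chr1", "+", ((200, 240), (280, 400)), 210, 390)
    assert classify_snp_location(snp(250), [PLUS_TX, other]) == LocationClass.CDS
    assert classify_snp_location(snp(250), [other]) == LocationClass.INTRONIC


def test_classify_locations_bulk_matches_single():
    snps = [snp(p) for p in (10, 150, 250, 350, 5000)]
    bulk = enrichment.classify_locations(snps, [PLUS_TX])
    for s in snps:
        assert bulk[s.snp_id] == classify_snp_location(s, [PLUS_TX])


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def test_or_hand_evaluated_woolf():
    res = odds_ratio_ci(ContingencyTable2x2(10, 90, 5, 95))
    assert res.or_estimate == pytest.approx(950 / 450, abs=1e-12)
    # independent evaluation of the Woolf formula
    se = math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95)
    z = stats.norm.ppf(0.975)
    assert res.ci_low == pytest.approx(math.exp(math.log(950 / 450) - z * se))
    assert res.ci_high == pytest.approx(math.exp(math.log(950 / 450) + z * se))
    assert not res.corrected


def test_or_symmetric_table():
    res = odds_ratio_ci(ContingencyTable2x2(50, 50, 50, 50))
    assert res.or_estimate == 1.0
    assert res.ci_low == pytest.approx(1 / res.ci_high)


def test_or_haldane_correction_path():
    res = odds_ratio_ci(ContingencyTable2x2(0, 50, 10, 40))
    assert res.corrected and math.isfinite(res.or_estimate) and res.or_estimate > 0


def test_or_empty_margin_raises():
    with pytest.raises(ValueError, match="margin"):
        odds_ratio_ci(ContingencyTable2x2(0, 0, 5, 5))


@given(st.tuples(st.integers(1, 400), st.integers(1, 400),
                 st.integers(1, 400), st.integers(1, 400)))
def test_or_column_swap_reciprocal(cells):
    t = ContingencyTable2x2(*cells)
    r1 = odds_ratio_ci(t).or_estimate
    r2 = odds_ratio_ci(t.column_swapped()).or_estimate
    assert r1 * r2 == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# resampled null and empirical p
# ---------------------------------------------------------------------------

def _panel_and_classes(rng, n=40):
    cols = rng.integers(0, 2, size=(n, 30)).tolist()
    panel = make_panel(cols)
    classes = {sid: (LocationClass.UTR3 if i % 4 == 0 else LocationClass.INTRONIC)
               for i, sid in enumerate(panel.snp_ids)}
    return panel, classes


def test_null_distribution_deterministic(rng):
    panel, classes = _panel_and_classes(rng)
    a = enrichment.null_enrichment_distribution(panel, classes, 5, reps=5, seed=3)
    b = enrichment.null_enrichment_distribution(panel, classes, 5, reps=5, seed=3)
    assert (a == b).all() and len(a) == 5


def test_null_degenerate_all_snps_gives_or_one(rng):
    panel, classes = _panel_and_classes(rng)
    vals = enrichment.null_enrichment_distribution(panel, classes, panel.n_snps,
                                                   reps=4, seed=0)
    assert np.allclose(vals, 0.0)


def test_null_mean_near_zero_under_self_sampling(rng):
    # large enough per-replicate counts that the Haldane correction bias is
    # negligible relative to the sampling error
    panel, classes = _panel_and_classes(rng, n=240)
    vals = enrichment.null_enrichment_distribution(panel, classes, 80, reps=150,
                                                   seed=1)
    se = vals.std(ddof=1) / math.sqrt(len(vals))
    assert abs(vals.mean()) < 2 * se + 0.05


def test_empirical_p_rank_component():
    null = list(np.random.default_rng(0).normal(size=999))
    assert empirical_p(max(null) + 1e-9, null) == pytest.approx(2 / 1000, abs=5e-3)
    assert empirical_p(np.median(null) - 1.0, null) > 0.5


def test_empirical_p_normal_fit_agrees_on_gaussian_null(rng):
    null = rng.normal(size=10_000)
    for obs in (0.5, 1.0, 1.5):
        emp = (np.count_nonzero(null >= obs) + 1) / (len(null) + 1)
        fit = stats.norm.sf(obs, loc=null.mean(), scale=null.std(ddof=1))
        assert abs(emp - fit) < 0.01
        assert empirical_p(obs, null) == pytest.approx(max(emp, fit))


# ---------------------------------------------------------------------------
# MAF bins and r2 sweep
# ---------------------------------------------------------------------------

def _snps_with_mafs(mafs, prefix):
    return [SnpRecord(f"{prefix}{i}", "chr1", i, "A", "G", m)
            for i, m in enumerate(mafs)]


def test_maf_binned_or_self_comparison_is_one(rng):
    mafs = rng.uniform(0, 0.5, 200)
    snps = _snps_with_mafs(mafs, "x")
    classes = {s.snp_id: (LocationClass.UTR3 if i % 3 == 0 else LocationClass.CDS)
               for i, s in enumerate(snps)}
    res = maf_binned_or(snps, snps, classes)
    for key, r in res.items():
        if r is not None:
            assert r.or_estimate == pytest.approx(1.0)


def test_maf_bin_without_test_snps_is_undefined():
    test = _snps_with_mafs([0.05, 0.07], "t")
    bg = _snps_with_mafs([0.05, 0.15, 0.25, 0.35, 0.45], "b")
    classes = {s.snp_id: LocationClass.UTR3 for s in test + bg}
    res = maf_binned_or(test, bg, classes)
    assert res[(0.1, 0.2)] is None  # no test SNPs there: undefined, not zero


def test_r2_sweep_monotone_and_matches_independent_runs(rng):
    from mirsnpmech import ld_toolkit
    cols = rng.integers(0, 2, size=(20, 60)).tolist()
    panel = make_panel(cols)
    classes = {sid: (LocationClass.UTR3 if i % 5 == 0 else LocationClass.INTRONIC)
               for i, sid in enumerate(panel.snp_ids)}
    sent = ["s2", "s9", "s33"]
    sweep = enrichment.r2_sweep_or(sent, panel, classes)
    thresholds = sorted(sweep)
    sizes = [sweep[t][1] for t in thresholds]
    assert sizes == sorted(sizes, reverse=True)  # lower threshold: superset
    for thr in (0.5, 0.8, 1.0):
        assert sweep[round(thr, 6)][1] == len(
            ld_toolkit.extend_sentinels(sent, panel, r2_min=thr))


# ---------------------------------------------------------------------------
# small statistics
# ---------------------------------------------------------------------------

def test_fisher_combined_identity_and_quadrature():
    assert fisher_combined_p([0.2]) == pytest.approx(0.2, abs=1e-12)
    statistic = -2 * (math.log(0.05) + math.log(0.05))
    assert statistic == pytest.approx(11.9829, abs=1e-3)
    oracle, _ = quad(lambda x: stats.chi2.pdf(x, df=4), statistic, np.inf)
    assert fisher_combined_p([0.05, 0.05]) == pytest.approx(oracle, abs=1e-9)


def test_fisher_combined_monotone_with_p_one():
    base = [0.03, 0.2]
    assert fisher_combined_p(base + [1.0]) >= fisher_combined_p(base)


def test_rough_fdr_values():
    assert rough_fdr_level(0.05, 1) == pytest.approx(0.05)
    assert rough_fdr_level(0.05, 10) == pytest.approx(0.0275)
    assert rough_fdr_level(0.05, 10**9) == pytest.approx(0.025, abs=1e-6)


def test_chi2_homogeneous_and_hand_formula():
    res = contingency_chi2([[30, 30], [30, 30]])
    assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)
    # textbook evaluation for (20,80 / 10,90)
    obs = np.array([[20, 80], [10, 90]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    by_hand = ((obs - exp) ** 2 / exp).sum()
    res = contingency_chi2(obs)
    assert res.statistic == pytest.approx(by_hand, abs=1e-12)
    assert not res.low_expected
    assert contingency_chi2([[3, 1], [1, 3]]).low_expected


def test_chi2_direction_agrees_with_fisher():
    table = [[30, 70], [10, 90]]
    chi = contingency_chi2(table)
    fisher_p = stats.fisher_exact(table)[1]
    assert (chi.p_value < 0.05) == (fisher_p < 0.05)
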