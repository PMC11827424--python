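"""Spearman machinery, correlation suites, rankings and their comparison."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import permutation_p_value
from tlsquant.metrics import SectionAreas, summarize_section
from tlsquant.qualification import DomainComposition, TLSDomain
from tlsquant.stats import (
    compare_rankings,
    filter_domains_for_correlation,
    ki67_correlation_suite,
    rank_patients,
    spearman,
    treg_presence_analysis,
)
from tlsquant.synthetic import (
    CohortConfig,
    domains_from_composition_table,
    sample_cohort_compositions,
)


def domain(counts, did="d", sid="s"):
    comp = DomainComposition(counts)
    return TLSDomain(did, sid, comp, 1000.0, None)


def summaries_from_table(table):
    out = []
    for (sid, pid), grp in table.groupby(["section_id", "patient_id"], sort=True):
        doms = domains_from_composition_table(grp)
        out.append(summarize_section(sid, pid, doms, SectionAreas(0.0, float("nan"), 0.0)))
    return out


def test_perfect_concordance_and_reversal():
    x = np.arange(10.0)
    assert spearman(x, x).rho == pytest.approx(1.0)
    assert spearman(x, -x).rho == pytest.approx(-1.0)


def test_matches_scipy_spearman_on_random_data():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(10, 200))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        got = spearman(x, y)
        want_rho, want_p = sps.spearmanr(x, y)
        assert got.rho == pytest.approx(want_rho, abs=1e-12)
        assert got.p_value == pytest.approx(want_p, rel=1e-6)


def test_rho_equals_pearson_on_average_ranks_with_ties():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 5, 50).astype(float)  # heavy ties
    y = rng.integers(0, 5, 50).astype(float)
    got = spearman(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    assert got.rho == pytest.approx(sps.pearsonr(rx, ry)[0], abs=1e-12)


def test_p_value_matches_permutation_oracle():
    rng = np.random.default_rng(11)
    x = rng.uniform(size=100)
    y = rng.uniform(size=100)
    got = spearman(x, y)
    oracle = permutation_p_value(x, y, 10_000, np.random.default_rng(0))
    se = math.sqrt(oracle * (1 - oracle) / 10_000)
    assert abs(got.p_value - oracle) < max(5 * se, 0.01)


def test_small_n_uses_exact_permutation_enumeration():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 5.0])
    got = spearman(x, y)
    # brute force over all 720 permutations
    import itertools

    rhos = []
    for perm in itertools.permutations(y):
        rhos.append(sps.spearmanr(x, perm)[0])
    expected = np.mean([abs(r) >= abs(got.rho) - 1e-12 for r in rhos])
    assert got.p_value == pytest.approx(expected)


def test_rho_invariant_under_monotone_transforms():
    rng = np.random.default_rng(4)
    x = rng.uniform(0.01, 1, 60)
    y = rng.uniform(0.01, 1, 60)
    base = spearman(x, y).rho
    assert spearman(np.log10(x), y).rho == pytest.approx(base, abs=1e-12)
    assert spearman(x, np.exp(3 * y)).rho == pytest.approx(base, abs=1e-12)


def test_nan_pairs_dropped_and_counted():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6, 7, 8, 9, 10, 11, 12])
    y = np.array([2.0, 1.0, 3.0, np.nan, 5.0, 6, 7, 8, 9, 10, 11, 12])
    res = spearman(x, y)
    assert res.n_points == 10


def test_insufficient_and_constant_inputs():
    assert spearman([1.0, 2.0], [1.0, 2.0]).insufficient
    res = spearman([1.0] * 20, np.arange(20.0))
    assert res.insufficient and math.isnan(res.rho)


def test_correlation_filter_boundary_and_scope():
    small = domain({"B_Ki67neg": 49})
    exact = domain({"B_Ki67neg": 50})
    kept = filter_domains_for_correlation([small, exact], min_cells=50)
    assert kept == [exact]


def test_treg_presence_x_values_lie_in_unit_interval():
    rng = np.random.default_rng(8)
    doms = []
    for i in range(40):
        n = int(rng.integers(60, 200))
        treg_neg = int(rng.integers(0, n // 4))
        doms.append(
            domain(
                {
                    "B_Ki67pos": 5,
                    "B_Ki67neg": n - treg_neg - 15,
                    "CD8T_Ki67neg": 5,
                    "CD4Tconv_Ki67neg": 5,
                    "CD4Treg_Ki67neg": treg_neg,
                },
                did=f"d{i}",
            )
        )
    results = treg_presence_analysis(doms)
    assert len(results) == 3
    table_x = [
        d.composition.counts["CD4Treg_Ki67neg"] / d.composition.n_lymph for d in doms
    ]
    assert all(0 <= v <= 1 for v in table_x)


def test_section_level_correlation_beats_domain_level_on_shared_latent():
    """Pooling domains within a section averages out within-patient noise."""
    diffs = []
    for seed in range(15):
        cfg = CohortConfig(n_patients=14, domain_count_range=(10, 30), seed=seed)
        table, _ = sample_cohort_compositions(cfg)
        doms = domains_from_composition_table(table)
        dom_res = ki67_correlation_suite(domains=doms, level="domain")
        sec_res = ki67_correlation_suite(summaries=summaries_from_table(table), level="section")
        diffs.append(
            np.mean([r.rho for r in sec_res]) - np.mean([r.rho for r in dom_res])
        )
    assert np.mean(diffs) > 0


def test_rankings_agree_when_patients_are_internally_homogeneous():
    rows = []
    for pid, frac in [("P1", 0.6), ("P2", 0.2), ("P3", 0.9)]:
        for d in range(3):
            rows.append(
                summarize_section(
                    f"{pid}_s{d}",
                    pid,
                    [
                        domain(
                            {"B_Ki67pos": int(frac * 100), "B_Ki67neg": 100 - int(frac * 100)},
                            did=f"{pid}_{d}",
                            sid=f"{pid}_s{d}",
                        )
                    ],
                    SectionAreas(0.0, float("nan"), 0.0),
                )
            )
    a = rank_patients(rows, "per_domain_mean")
    b = rank_patients(rows, "pooled")
    assert a.patient_ids == b.patient_ids == ["P3", "P1", "P2"]


def test_methods_diverge_on_unbalanced_domains():
    doms = [
        domain({"B_Ki67pos": 100, "B_Ki67neg": 900}, did="big"),
        domain({"B_Ki67pos": 9, "B_Ki67neg": 1}, did="small"),
    ]
    summary = summarize_section("s1", "P1", doms, SectionAreas(0.0, float("nan"), 0.0))
    per_dom = rank_patients([summary], "per_domain_mean").measure["P1"]
    pooled = rank_patients([summary], "pooled").measure["P1"]
    assert per_dom == pytest.approx(0.5)
    assert pooled == pytest.approx(109 / 1010)


def test_compare_rankings_identity_reversal_and_mismatch():
    from tlsquant.stats import RankingResult

    ids = [f"P{i}" for i in range(12)]
    m = {p: 1.0 - i / 12 for i, p in enumerate(ids)}
    a = RankingResult("per_domain_mean", ids, m)
    same = compare_rankings(a, RankingResult("pooled", list(ids), m), k=8)
    assert same["rank_rho"] == pytest.approx(1.0)
    assert same["top_k_overlap"] == 8
    rev = compare_rankings(a, RankingResult("pooled", ids[::-1], m))
    assert rev["rank_rho"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="P99"):
        compare_rankings(a, RankingResult("pooled", ids[:-1] + ["P99"], m))


def test_correlation_results_invariant_to_domain_order():
    cfg = CohortConfig(n_patients=6, domain_count_range=(5, 10), seed=2)
    table, _ = sample_cohort_compositions(cfg)
    doms = domains_from_composition_table(table)
    fwd = ki67_correlation_suite(domains=doms, level="domain")
    rev = ki67_correlation_suite(domains=doms[::-1], level="domain")
    for r1, r2 in zip(fwd, rev):
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
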