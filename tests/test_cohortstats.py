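import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mitorea.arraydata import SubjectMeta
from mitorea.calling import call_subject
from mitorea.cohortstats import (
    base_prevalence,
    burden_table,
    cohort_sizes,
    compare_burden_groups,
    copy_number,
    correlate,
    fisher_simulated,
    haplogroup_assign,
    kruskal_dunn,
    load_marker_table,
    mann_whitney,
    mean_cq,
    onset_contrast,
)
from mitorea.synthetic import SimConfig, simulate_cohort


# ---------------------------------------------------------------------------
# study bookkeeping

def test_unique_subject_arithmetic():
    sizes = cohort_sizes()
    assert sizes["cohort1"] == 48
    assert sizes["cohort2"] == 22
    assert sizes["total_unique"] == 55


# ---------------------------------------------------------------------------
# Mann-Whitney

def _enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (no ties)."""
    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for comb in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n + m) if i not in comb]
        us.append(sum(1 for a in xs for b in ys if a > b))
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_le, p_ge))


def test_mann_whitney_textbook_case():
    rep = mann_whitney([1, 2, 3], [4, 5, 6])
    assert rep.statistic == 0.0
    assert rep.p == pytest.approx(0.1)  # 2/20 rank arrangements


def test_mann_whitney_all_identical_degenerates_to_p_one():
    rep = mann_whitney([2, 2, 2], [2, 2, 2])
    assert rep.p == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    x=st.lists(st.integers(0, 1000), min_size=2, max_size=7, unique=True),
    y=st.lists(st.integers(1001, 2000), min_size=2, max_size=7, unique=True),
    shift=st.integers(-1500, 0),
)
def test_mann_whitney_matches_enumeration_for_small_untied_samples(x, y, shift):
    y = [v + shift for v in y]
    if set(x) & set(y):
        return
    rep = mann_whitney(x, y)
    assert rep.p == pytest.approx(_enumeration_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def test_kruskal_identical_groups():
    rep = kruskal_dunn({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
    assert rep.statistic == 0.0
    assert rep.p == 1.0


def test_dunn_adjustment_properties():
    rng = np.random.default_rng(5)
    rep = kruskal_dunn({
        "a": rng.normal(0, 1, 10),
        "b": rng.normal(1, 1, 10),
        "c": rng.normal(2, 1, 10),
    })
    pw = rep.pairwise
    assert len(pw) == 3
    assert (pw["p_adjusted"] >= pw["p_unadjusted"] - 1e-15).all()
    assert (pw["p_adjusted"] <= 1.0).all()
    # the extreme contrast a-vs-c should be the smallest adjusted p
    idx = pw.set_index(["group1", "group2"])["p_adjusted"]
    assert idx[("a", "c")] == pw["p_adjusted"].min()


# ---------------------------------------------------------------------------
# burden tables

@pytest.fixture(scope="module")
def called_cohort(genome):
    config = SimConfig(
        groups={"non-maternal": 5, "maternal": 5},
        structure_seed=42,
        noise_seed=43,
        hom_gene_multipliers={"maternal": {"ND5": 4.0}},
    )
    cohort = simulate_cohort(config, genome)
    callsets = [call_subject(cohort.intensities[m.subject_id], genome)
                for m in cohort.meta]
    return cohort, callsets


def test_burden_table_totals_match_callset_counts(genome, called_cohort):
    cohort, callsets = called_cohort
    table = burden_table(callsets, genome, "homoplasmic")
    for cs in callsets:
        assert table.loc[cs.subject_id, "total"] == cs.n_homoplasmic
    truth = cohort.truth.by_subject()
    for sid in table.index:
        nd5_truth = sum(
            1 for v in truth[sid].variants
            if v.mutation_class == "homoplasmic" and 12_337 <= v.position <= 14_148
        )
        assert table.loc[sid, "ND5"] == nd5_truth


def test_burden_table_attributes_known_nd5_positions(genome, called_cohort):
    """A subject carrying the J-haplogroup backbone has its 12,612 and
    13,708 variants attributed to ND5."""
    cohort, callsets = called_cohort
    j_subjects = [s.subject_id for s in cohort.truth.subjects
                  if s.haplogroup == "J"]
    assert j_subjects  # seeded cohort contains at least one J carrier
    table = burden_table(callsets, genome, "homoplasmic")
    by_id = {cs.subject_id: cs for cs in callsets}
    for sid in j_subjects:
        hom_pos = {c.position for c in by_id[sid].variants("homoplasmic")}
        assert {12_612, 13_708} <= hom_pos
        assert table.loc[sid, "ND5"] >= 2


def test_zero_class_subject_gives_zero_row(genome):
    config = SimConfig(groups={"CTRL": 3}, het_rate_per_kb=0.0,
                       lowlevel_rate=0.0, structure_seed=1, noise_seed=2)
    cohort = simulate_cohort(config, genome)
    callsets = [call_subject(s, genome) for s in cohort.intensities.values()]
    table = burden_table(callsets, genome, "heteroplasmic")
    assert (table.to_numpy() == 0).all()


def test_planted_nd5_enrichment_has_smallest_per_gene_p(genome, called_cohort):
    cohort, callsets = called_cohort
    table = burden_table(callsets, genome, "homoplasmic")
    reports = compare_burden_groups(table.drop(columns="total"),
                                    cohort.grouping())
    pvals = {gene: rep.p for gene, rep in reports.items()}
    assert min(pvals, key=pvals.get) == "ND5"


def test_onset_contrast_excludes_unknown_and_detects_shift():
    rng = np.random.default_rng(8)
    subjects = [f"s{i}" for i in range(21)]
    counts = rng.poisson(2, 21).astype(float)
    meta = []
    for i, sid in enumerate(subjects):
        onset = "bulbar" if i < 10 else ("spinal" if i < 20 else "unknown")
        if onset == "bulbar":
            counts[i] += 2  # planted bulbar enrichment
        meta.append(SubjectMeta(sid, "maternal", "WB", onset_site=onset))
    table = pd.DataFrame({"ND5": counts}, index=subjects)
    rep = onset_contrast(table, meta, "ND5")
    assert rep.n == (10, 10)  # unknown-onset subject dropped
    assert rep.p <= 0.05


def test_onset_contrast_identical_distributions():
    meta = [SubjectMeta(f"s{i}", "maternal", "WB",
                        onset_site="bulbar" if i % 2 else "spinal")
            for i in range(10)]
    table = pd.DataFrame({"ND5": [3.0] * 10}, index=[f"s{i}" for i in range(10)])
    rep = onset_contrast(table, meta, "ND5")
    assert rep.p == pytest.approx(1.0)


def test_onset_contrast_refuses_tiny_classes():
    meta = [SubjectMeta(f"s{i}", "maternal", "WB", onset_site="spinal")
            for i in range(6)]
    table = pd.DataFrame({"ND5": np.arange(6.0)}, index=[f"s{i}" for i in range(6)])
    with pytest.raises(ValueError, match="3 subjects"):
        onset_contrast(table, meta, "ND5")


# ---------------------------------------------------------------------------
# base prevalence

def test_base_prevalence_chi2_matches_hand_computation(genome, called_cohort):
    cohort, callsets = called_cohort
    half = len(callsets) // 2
    groups = {"g1": callsets[:half], "g2": callsets[half:]}
    res = base_prevalence(groups, genome)
    tab = res.counts.loc[res.counts.sum(axis=1) > 0,
                         res.counts.sum(axis=0) > 0].to_numpy()
    # hand-computed Pearson chi-squared
    rows, cols = tab.sum(1, keepdims=True), tab.sum(0, keepdims=True)
    expected = rows @ cols / tab.sum()
    chi2 = ((tab - expected) ** 2 / expected).sum()
    assert res.chi2 == pytest.approx(chi2)
    # counts per base sum to the groups' total mutation counts
    total = sum(cs.n_homoplasmic + cs.n_heteroplasmic for cs in callsets)
    assert res.counts.to_numpy().sum() == total


def test_base_prevalence_mutation_free_groups_skipped(genome):
    config = SimConfig(groups={"CTRL": 3}, hom_rate_per_kb=0.0,
                       het_rate_per_kb=0.0, lowlevel_rate=0.0,
                       haplogroup_probs={"rCRS": 1.0}, sigma=0.0)
    cohort = simulate_cohort(config, genome)
    callsets = [call_subject(s, genome) for s in cohort.intensities.values()]
    res = base_prevalence({"a": callsets[:1], "b": callsets[1:]}, genome)
    assert res.skipped
    assert (res.percentages.to_numpy() == 0).all()


# ---------------------------------------------------------------------------
# copy number

def test_copy_number_printed_formula():
    assert copy_number((25, 25, 25), (17, 17, 17)) == pytest.approx(256.0)
    assert copy_number((24, 24), (24, 24)) == pytest.approx(1.0)


def test_copy_number_shift_invariance():
    a = copy_number((25.1, 24.9, 25.0), (18.0, 18.2, 17.8))
    b = copy_number((28.1, 27.9, 28.0), (21.0, 21.2, 20.8))
    assert a == pytest.approx(b)


def test_copy_number_missing_replicates_give_missing_value():
    assert copy_number((25.0,), (17.0, 17.1)) is None
    assert copy_number(None, (17.0, 17.1)) is None
    # platelets: report the mean mitochondrial Cq instead
    assert mean_cq((17.0, 17.2, 17.1)) == pytest.approx(17.1)


def test_simulated_ct_recovers_planted_copy_factor(genome):
    config = SimConfig(groups={"CTRL": 12}, structure_seed=3, noise_seed=4,
                       cn_factor=150.0)
    cohort = simulate_cohort(config, genome)
    cns = [copy_number(m.ct_b2m, m.ct_dloop) for m in cohort.meta]
    assert np.mean(cns) == pytest.approx(150.0, rel=0.05)


# ---------------------------------------------------------------------------
# haplogroups

def test_j_markers_outscore_h():
    call = haplogroup_assign([(12_612, "G"), (13_708, "A")])
    assert call.scores["J"] > call.scores["H"]
    assert call.best_haplogroup == "J"


def test_full_marker_set_scores_one():
    markers = load_marker_table()
    call = haplogroup_assign(markers["J"])
    assert call.score == pytest.approx(1.0)
    assert call.label == "J"
    assert set(call.matched_positions) == {p for p, _ in markers["J"]}


def test_empty_variant_set_reference_like():
    call = haplogroup_assign([])
    assert call.label == "rCRS-like"
    assert call.scores["J"] == 0.0


def test_simulated_backbone_recovered(genome, called_cohort):
    cohort, callsets = called_cohort
    truth = cohort.truth.by_subject()
    for cs in callsets:
        variants = [(c.position, c.called_alleles[0])
                    for c in cs.variants("homoplasmic")]
        call = haplogroup_assign(variants)
        assert call.best_haplogroup == truth[cs.subject_id].haplogroup


# ---------------------------------------------------------------------------
# Fisher simulated

def test_fisher_simulated_converges_to_exact():
    exact = 2 / 252  # hypergeometric enumeration for [[5,0],[0,5]]
    for n_sim, tol in ((1_000, 0.01), (100_000, 0.001)):
        res = fisher_simulated([[5, 0], [0, 5]], n_sim=n_sim, seed=7)
        assert res.p == pytest.approx(exact, abs=tol)


def test_fisher_simulated_agrees_with_scipy_exact_2x2():
    table = [[8, 2], [3, 9]]
    exact = stats.fisher_exact(table).pvalue
    res = fisher_simulated(table, n_sim=100_000, seed=11)
    assert res.p == pytest.approx(exact, abs=0.005)


def test_fisher_identical_columns_and_determinism():
    res1 = fisher_simulated([[5, 5], [5, 5]], n_sim=2_000, seed=3)
    res2 = fisher_simulated([[5, 5], [5, 5]], n_sim=2_000, seed=3)
    assert res1.p == res2.p
    assert res1.p > 0.9


def test_fisher_degenerate_margins():
    res = fisher_simulated([[0, 0], [3, 4]], n_sim=100, seed=0)
    assert res.p == 1.0
    assert res.degenerate


# ---------------------------------------------------------------------------
# correlation

def test_correlate_linear_normal_uses_pearson():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 40)
    res = correlate(x, 2 * x + 1)
    assert res.method == "pearson"
    assert res.coefficient == pytest.approx(1.0)


def test_correlate_heavy_tailed_monotone_uses_spearman():
    rng = np.random.default_rng(2)
    x = rng.standard_t(1, 50)
    res = correlate(x, x**3)
    assert res.method == "spearman"
    assert res.coefficient == pytest.approx(1.0)


def test_correlate_matches_direct_formula_on_toy_set():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.1, 3.9, 6.2, 8.1, 9.8, 12.3]
    res = correlate(x, y)
    mx, my = np.mean(x), np.mean(y)
    r = (sum((a - mx) * (b - my) for a, b in zip(x, y))
         / math.sqrt(sum((a - mx) ** 2 for a in x)
                     * sum((b - my) ** 2 for b in y)))
    assert res.coefficient == pytest.approx(r, abs=1e-12)


def test_correlate_drops_missing_pairs_and_needs_four():
    res = correlate([1, 2, None, 4, 5, 6], [2, 4, 5, 8, None, 12])
    assert res.n == 4
    with pytest.raises(ValueError):
        correlate([1, 2, None, 4], [1, 2, 3, None])
    with pytest.raises(ValueError):
        correlate([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
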