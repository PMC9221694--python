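"""AUC, DeLong intervals, and detection rates at fixed false-positive rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import momscreen as ms
from momscreen.performance import auc_mann_whitney, dr_at_fixed_fpr, evaluate_model
from momscreen.risk import RiskModel, Term, published_equation
from conftest import make_subject


def _brute_force_auc(cases, controls):
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def test_perfectly_separated_scores():
    auc, (lo, hi) = auc_mann_whitney([5, 6, 7], [1, 2, 3])
    assert auc == 1.0
    assert lo <= auc <= hi <= 1.0


@pytest.mark.parametrize("seed", [2, 3, 5])
def test_auc_equals_exhaustive_pair_count(seed):
    rng = np.random.default_rng(seed)
    cases = rng.choice(np.arange(20) / 4.0, size=60)  # ties guaranteed
    controls = rng.choice(np.arange(20) / 4.0, size=100)
    auc, _ = auc_mann_whitney(cases, controls)
    assert auc == pytest.approx(_brute_force_auc(cases, controls), abs=1e-14)


def test_null_scores_near_half():
    rng = np.random.default_rng(7)
    aucs = [
        auc_mann_whitney(rng.normal(size=50), rng.normal(size=80))[0]
        for _ in range(50)
    ]
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


def test_ci_methods_sane_and_similar():
    rng = np.random.default_rng(13)
    cases = rng.normal(1.0, 1, size=40)
    controls = rng.normal(0.0, 1, size=120)
    auc_d, ci_d = auc_mann_whitney(cases, controls, ci_method="delong")
    auc_h, ci_h = auc_mann_whitney(cases, controls, ci_method="hanley-mcneil")
    assert auc_d == auc_h
    assert ci_d[0] <= auc_d <= ci_d[1]
    assert ci_h[0] == pytest.approx(ci_d[0], abs=0.05)
    with pytest.raises(ValueError):
        auc_mann_whitney(cases, controls, ci_method="bogus")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_auc_invariant_under_increasing_transform(seed):
    """AUC on the linear predictor x equals AUC on the probability p."""
    rng = np.random.default_rng(seed)
    x_cases = rng.normal(1, 1, size=12)
    x_controls = rng.normal(0, 1, size=20)
    auc_x, _ = auc_mann_whitney(x_cases, x_controls)
    p = lambda x: 1 / (1 + np.exp(-x))
    auc_p, _ = auc_mann_whitney(p(x_cases), p(x_controls))
    assert auc_p == pytest.approx(auc_x, abs=1e-14)


def test_thresholds_on_integer_grid():
    """Controls 1..100 at FPR 10% → exactly 10 controls above the cutoff."""
    controls = np.arange(1.0, 101.0)
    thresholds, drs, exceed = dr_at_fixed_fpr([50.0], controls, fprs=(0.10,))
    assert np.sum(controls > thresholds[0.10]) == 10
    assert exceed[0.10] == pytest.approx(0.10)


def test_dr_monotone_and_exceedance_bounded():
    rng = np.random.default_rng(23)
    for _ in range(20):
        cases = rng.normal(0.5, 1, size=rng.integers(5, 40))
        controls = rng.normal(0, 1, size=rng.integers(15, 200))
        thresholds, drs, exceed = dr_at_fixed_fpr(cases, controls)
        fprs = sorted(drs)
        assert all(drs[a] <= drs[b] for a, b in zip(fprs, fprs[1:]))
        assert all(
            thresholds[a] >= thresholds[b] for a, b in zip(fprs, fprs[1:])
        )
        for f in fprs:
            assert exceed[f] <= f + 1.0 / len(controls) + 1e-12


def test_identical_distributions_dr_tracks_fpr():
    rng = np.random.default_rng(29)
    drs_acc = {0.10: [], 0.20: [], 0.30: []}
    for _ in range(100):
        cases = rng.normal(size=60)
        controls = rng.normal(size=60)
        _, drs, _ = dr_at_fixed_fpr(cases, controls)
        for f, dr in drs.items():
            drs_acc[f].append(dr)
    for f, acc in drs_acc.items():
        assert np.mean(acc) == pytest.approx(f, abs=0.03)


def test_constant_control_scores_warn():
    with pytest.warns(UserWarning):
        _, drs, _ = dr_at_fixed_fpr([0.2, 0.8], [0.5] * 12)
    assert drs[0.10] == pytest.approx(0.5)  # one case above the constant


def test_evaluate_model_deterministic(study_cohort, study_profiles):
    eq = published_equation("SPTB_LE32")
    a = evaluate_model(eq, study_profiles, study_cohort)
    b = evaluate_model(eq, study_profiles, study_cohort)
    assert a == b
    assert a.n_cases > 0 and a.n_controls > 0


def test_zero_slope_model_chance_level(study_cohort, study_profiles):
    flat = RiskModel(
        outcome="SPTB_LE32",
        intercept=-2.0,
        terms=(Term("PSME2", "log10_mom", 0.0),),
    )
    with pytest.warns(UserWarning):  # constant scores
        res = evaluate_model(flat, study_profiles, study_cohort)
    assert res.auc == pytest.approx(0.5, abs=1e-12)  # all scores tie


def test_variant_scoring_consistent_for_complete_subjects():
    """Complete-data subjects score identically with and without variants."""
    from momscreen.risk import fit_missingness_variants, score
    from conftest import simulate_from_equation

    eq = RiskModel(
        outcome="EOP_LT34",
        intercept=-1.0,
        terms=(
            Term("NAMPT", "log10_mom", 2.0),
            Term("APOA1", "log10_mom", 0.8),
            Term("nulliparous", "indicator", 0.9),
            Term("parity_1_2", "indicator", -1.2),
        ),
    )
    rng = np.random.default_rng(37)
    profiles, records = simulate_from_equation(eq, 800, rng)
    model = fit_missingness_variants(
        profiles, records, "EOP_LT34", ["NAMPT", "APOA1", "nulliparous", "parity_1_2"]
    )
    full = model.variants[frozenset({"NAMPT", "APOA1"})]
    bare = RiskModel(outcome=full.outcome, intercept=full.intercept, terms=full.terms)
    for prof, rec in list(zip(profiles, records))[:50]:
        assert score(model, prof, rec).x == pytest.approx(score(bare, prof, rec).x)


def test_large_sample_self_consistency_of_dr():
    """DR at fixed FPR at cohort scale matches a large-sample evaluation of
    the same generative model (scores from the published ≤32 w equation at
    the study's group median MoMs)."""
    def draw_scores(rng, n_case, n_control):
        # two-marker linear predictor at the generator's group medians
        b1, b2 = 0.5732, 0.8268
        def group(mu1, mu2, n):
            return b1 * rng.normal(mu1, 0.35, n) + b2 * rng.normal(mu2, 0.35, n)
        cases = group(np.log10(4.09), np.log10(8.84), n_case)
        controls = group(0.0, np.log10(1.03), n_control)
        return cases, controls

    rng = np.random.default_rng(41)
    big_cases, big_controls = draw_scores(rng, 50000, 50000)
    _, dr_big, _ = dr_at_fixed_fpr(big_cases, big_controls)
    small_cases, small_controls = draw_scores(rng, 300, 1900)
    _, dr_small, _ = dr_at_fixed_fpr(small_cases, small_controls)
    for f in dr_big:
        assert dr_small[f] == pytest.approx(dr_big[f], abs=0.05)
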