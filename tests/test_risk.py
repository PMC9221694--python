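"""Risk models: published equations, ML fitting, missingness variants."""

import math

import numpy as np
import pytest
from scipy.special import expit

import momscreen as ms
from momscreen.risk import (
    MissingPredictorError,
    RiskModel,
    Term,
    fit_logistic,
    fit_missingness_variants,
    load_models,
    published_equation,
    save_models,
    score,
)
from conftest import make_subject, simulate_from_equation


def _profile(sid="P0", **log10_moms):
    return ms.MoMProfile(
        sid, {k: 10.0 ** v for k, v in log10_moms.items()}, dict(log10_moms)
    )


class TestPublishedEquations:
    def test_sptb_le32_baseline(self):
        """All MoM 1, non-Hispanic Black, no prior PTB → x = 1.4677 − 0.1119·40."""
        eq = published_equation("SPTB_LE32")
        rec = make_subject(race_nhb=True, prior_ptb=False)
        sc = score(eq, _profile(PSME2=0.0, LET7G=0.0), rec)
        assert sc.x == pytest.approx(-3.0083, abs=1e-10)
        assert sc.p == pytest.approx(0.047, abs=5e-4)

    def test_ptb_lt37_baseline(self):
        eq = published_equation("PTB_LT37")
        rec = make_subject(race_nhb=True, smoker=False, prior_ptb=False)
        sc = score(eq, _profile(PSME2=0.0), rec)
        assert sc.x == pytest.approx(2.9733 - 0.1111 * 40, abs=1e-10)
        assert sc.p == pytest.approx(0.187, abs=5e-4)

    def test_eop_lt34_nulliparous(self):
        eq = published_equation("EOP_LT34")
        rec = make_subject(parity=0)
        sc = score(eq, _profile(NAMPT=0.0, APOA1=0.0), rec)
        assert sc.x == pytest.approx(-7.900 + 3.6091, abs=1e-10)
        assert sc.p == pytest.approx(0.0135, abs=5e-4)

    def test_pe_all_nulliparous(self):
        eq = published_equation("PE_ALL")
        rec = make_subject(parity=0)
        sc = score(eq, _profile(NAMPT=0.0, MAP_MMHG=0.0), rec)
        assert sc.x == pytest.approx(-2.1134 + 0.8873, abs=1e-10)
        assert sc.p == pytest.approx(0.227, abs=5e-4)

    def test_doubling_psme2_shifts_x_by_coefficient(self):
        eq = published_equation("SPTB_LE32")
        rec = make_subject()
        base = score(eq, _profile(PSME2=0.0, LET7G=0.0), rec).x
        doubled = score(eq, _profile(PSME2=math.log10(2.0), LET7G=0.0), rec).x
        assert doubled - base == pytest.approx(0.5732 * math.log10(2.0), abs=1e-12)

    def test_unknown_equation_rejected(self):
        with pytest.raises(KeyError):
            published_equation("NOT_A_MODEL")


def test_zero_linear_predictor_gives_half():
    model = RiskModel(outcome="SPTB_LE32", intercept=0.0, terms=())
    sc = score(model, _profile(), make_subject())
    assert sc.x == 0.0
    assert sc.p == 0.5
    assert sc.y == 1.0


def test_probability_monotone_in_positive_coefficient_marker():
    eq = published_equation("SPTB_LE32")
    rec = make_subject()
    ps = [
        score(eq, _profile(PSME2=v, LET7G=0.0), rec).p
        for v in np.linspace(-2, 2, 9)
    ]
    assert all(b > a for a, b in zip(ps, ps[1:]))
    assert all(0.0 < p < 1.0 for p in ps)


def _irls_oracle(X, y, tol=1e-12, maxiter=200):
    """Textbook unpenalized IRLS, independent of the package implementation."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(maxiter):
        eta = Xc @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = Xc.T * w
        new = np.linalg.solve(XtW @ Xc, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            break
        beta = new
    return beta


def test_single_predictor_fit_matches_irls_oracle():
    """20-row fixture: the ML fit equals textbook IRLS to 6 decimals."""
    rng = np.random.default_rng(31)
    log_moms = rng.normal(0, 0.5, size=20)
    y = np.array([0, 1] * 10, float)
    profiles, records = [], []
    for i, (l, yi) in enumerate(zip(log_moms, y)):
        profiles.append(_profile(sid=f"F{i}", PSME2=l))
        records.append(
            make_subject(
                subject_id=f"F{i}",
                outcome=ms.Outcome.SPTB_LE32 if yi else ms.Outcome.NONCASE,
            )
        )
    model = fit_logistic(profiles, records, "SPTB_LE32", ["PSME2"])
    beta = _irls_oracle(log_moms.reshape(-1, 1), y)
    assert model.intercept == pytest.approx(beta[0], abs=1e-6)
    assert model.terms[0].coef == pytest.approx(beta[1], abs=1e-6)


def test_refit_recovers_published_equation_coefficients():
    """Simulating outcomes from the ≤32 w equation and refitting recovers it."""
    eq = published_equation("SPTB_LE32")
    rng = np.random.default_rng(47)
    profiles, records = simulate_from_equation(eq, 5000, rng)
    model = fit_logistic(
        profiles, records, "SPTB_LE32",
        ["PSME2", "LET7G", "other_race", "earliest_prior_ptb_weeks"],
    )
    fitted = {t.name: t.coef for t in model.terms}
    expected = {t.name: t.coef for t in eq.terms}
    assert model.intercept == pytest.approx(eq.intercept, rel=0.15)
    for name, coef in expected.items():
        assert fitted[name] == pytest.approx(coef, rel=0.15), name


def test_null_fit_has_small_slopes():
    """Outcome independent of the predictors → slope coefficients near zero."""
    rng = np.random.default_rng(53)
    profiles, records = [], []
    for i in range(2000):
        profiles.append(_profile(sid=f"N{i}", PSME2=rng.normal(0, 0.5)))
        records.append(
            make_subject(
                subject_id=f"N{i}",
                outcome=ms.Outcome.SPTB_LE32 if rng.random() < 0.2
                else ms.Outcome.NONCASE,
            )
        )
    model = fit_logistic(profiles, records, "SPTB_LE32", ["PSME2"])
    assert abs(model.terms[0].coef) < 0.35
    assert not model.separation


def test_separation_detected_and_ridge_applied():
    """A predictor level with zero events drives the MLE to ±∞; ridge caps it."""
    rng = np.random.default_rng(59)
    profiles, records = [], []
    for i in range(120):
        case = i < 30
        # every case is parity 3+; parity 1-2 occurs only among controls
        parity = 3 if case else int(rng.choice([1, 2, 3]))
        profiles.append(_profile(sid=f"S{i}", NAMPT=rng.normal(0.3 if case else 0, 0.4)))
        records.append(
            make_subject(
                subject_id=f"S{i}",
                parity=parity,
                outcome=ms.Outcome.EOP_LT34 if case else ms.Outcome.NONCASE,
            )
        )
    model = fit_logistic(profiles, records, "EOP_LT34", ["NAMPT", "parity_1_2"])
    assert model.separation
    assert model.ridge_used
    assert all(math.isfinite(t.coef) for t in model.terms)


def test_too_few_cases_rejected():
    profiles = [_profile(sid=f"X{i}", PSME2=0.1 * i) for i in range(12)]
    records = [
        make_subject(
            subject_id=f"X{i}",
            outcome=ms.Outcome.SPTB_LE32 if i < 2 else ms.Outcome.NONCASE,
        )
        for i in range(12)
    ]
    with pytest.raises(ValueError):
        fit_logistic(profiles, records, "SPTB_LE32", ["PSME2"])


class TestMissingnessVariants:
    def _training_data(self, nampt_missing_frac=0.05, n=400, seed=61):
        rng = np.random.default_rng(seed)
        profiles, records = [], []
        for i in range(n):
            case = i < n // 4
            moms = {"APOA1": rng.normal(0.4 if case else 0.0, 0.4)}
            if rng.random() >= nampt_missing_frac:
                moms["NAMPT"] = rng.normal(0.5 if case else 0.0, 0.4)
            profiles.append(_profile(sid=f"M{i}", **moms))
            records.append(
                make_subject(
                    subject_id=f"M{i}",
                    outcome=ms.Outcome.EOP_LT34 if case else ms.Outcome.NONCASE,
                )
            )
        return profiles, records

    def test_observed_patterns_get_variants(self):
        profiles, records = self._training_data()
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1"]
        )
        assert set(model.variants) == {
            frozenset({"NAMPT", "APOA1"}),
            frozenset({"APOA1"}),
        }

    def test_no_missingness_single_variant(self):
        profiles, records = self._training_data(nampt_missing_frac=0.0)
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1"]
        )
        assert set(model.variants) == {frozenset({"NAMPT", "APOA1"})}

    def test_dispatch_on_missing_marker(self):
        profiles, records = self._training_data()
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1"]
        )
        rec = make_subject()
        full = score(model, _profile(NAMPT=0.2, APOA1=0.1), rec)
        sub = score(model, _profile(APOA1=0.1), rec)
        reduced = model.variants[frozenset({"APOA1"})]
        assert sub.x == pytest.approx(
            reduced.intercept + reduced.terms[0].coef * 0.1
        )
        assert full.x != sub.x

    def test_subject_missing_all_markers_uses_covariate_variant(self):
        profiles, records = self._training_data()
        # one training subject with no markers at all makes the empty pattern
        # observable, so a covariates-only sub-equation is fit
        profiles.append(_profile(sid="EMPTY"))
        records.append(make_subject(subject_id="EMPTY", outcome=ms.Outcome.NONCASE))
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1", "nulliparous"]
        )
        assert frozenset() in model.variants
        sc = score(model, _profile(), make_subject(parity=0))
        assert 0.0 < sc.p < 1.0

    def test_no_variant_for_pattern_raises(self):
        profiles, records = self._training_data(nampt_missing_frac=0.0)
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1"]
        )
        with pytest.raises(MissingPredictorError):
            score(model, _profile(APOA1=0.1), make_subject())

    def test_serialization_round_trip(self, tmp_path):
        profiles, records = self._training_data()
        model = fit_missingness_variants(
            profiles, records, "EOP_LT34", ["NAMPT", "APOA1"]
        )
        path = tmp_path / "models.yaml"
        save_models({"EOP_LT34": model}, path)
        loaded = load_models(path)["EOP_LT34"]
        assert loaded.intercept == pytest.approx(model.intercept)
        assert set(loaded.variants) == set(model.variants)
        rec = make_subject()
        prof = _profile(NAMPT=0.2, APOA1=-0.3)
        assert score(loaded, prof, rec).x == pytest.approx(score(model, prof, rec).x)
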