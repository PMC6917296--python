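"""The score itself: exposure c, posterior means, monotonicity, updating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from bfhs import (
    BetaPrior,
    Family,
    RelativeRecord,
    age_specific_risk,
    bfhs,
    constant_hazard_table,
    family_exposure,
    family_hazard_multiplier,
    posterior_mean_closed_form,
    posterior_mean_quadrature,
    read_families,
    score_families,
    three_level_score,
)
from bfhs.score import ScoreError

P0 = 0.197


def literal_signed_posterior_mean(alpha, b, m):
    """Oracle: the (0, 1)-scale integrals with the literal signed
    (log(1-p))^m factor, kept independent of the production path."""

    def integrand(p, a):
        return p ** (a - 1) * (1 - p) ** (b - 1) * math.log1p(-p) ** m

    num, _ = quad(integrand, 0, 1, args=(alpha + 1,), limit=200)
    den, _ = quad(integrand, 0, 1, args=(alpha,), limit=200)
    return num / den


class TestFamilyExposure:
    def test_empty_family_has_zero_exposure(self, disease):
        assert family_exposure(Family("e"), disease, P0) == 0.0

    def test_hand_arithmetic(self):
        # constant 0.002/yr: Lambda(50) = 0.10, Lambda(25) = 0.05
        table = constant_hazard_table(0.002)
        fam = Family("f", [RelativeRecord(50, 0), RelativeRecord(25, 1)])
        assert family_exposure(fam, table, P0) == pytest.approx(
            0.15 / math.log(1 - P0), abs=1e-10
        )
        assert family_exposure(fam, table, P0) == pytest.approx(-0.6839, abs=1e-3)

    def test_relatives_before_hazard_onset_contribute_nothing(self, disease):
        fam = Family("f", [RelativeRecord(15, 0), RelativeRecord(19.5, 0)])
        assert family_exposure(fam, disease, P0) == 0.0

    def test_out_of_span_age_names_the_relative(self, disease):
        fam = Family("f", [RelativeRecord(120, 0, relation="mother")])
        with pytest.raises(ScoreError, match="mother"):
            family_exposure(fam, disease, P0)


class TestPosteriorMean:
    def test_no_information_returns_prior_mean(self, prior):
        assert posterior_mean_quadrature(prior, 0.0, 0) == pytest.approx(
            prior.mean, abs=1e-10
        )

    def test_m0_is_shifted_beta_mean(self, prior):
        # Beta(alpha, beta - c) closed form
        assert posterior_mean_quadrature(prior, -0.6837, 0) == pytest.approx(
            1.184 / (1.184 + 4.828 + 0.6837), abs=1e-8
        )

    def test_one_case_frozen_oracle_value(self, prior):
        # frozen from an independent Riemann-sum evaluation of the
        # (0, 1)-scale integrals at 4e6 grid points
        expected = 0.3016895259
        assert posterior_mean_closed_form(prior, -0.6837, 1) == pytest.approx(
            expected, abs=1e-8
        )
        assert posterior_mean_quadrature(prior, -0.6837, 1) == pytest.approx(
            expected, abs=1e-8
        )

    @pytest.mark.parametrize("m", [1, 2])  # odd and even parity
    def test_sign_cancellation_matches_literal_formula(self, prior, m):
        literal = literal_signed_posterior_mean(prior.alpha, prior.beta + 0.5, m)
        assert posterior_mean_quadrature(prior, -0.5, m) == pytest.approx(
            literal, abs=1e-8
        )

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        alpha=st.floats(0.5, 5.0),
        b=st.floats(1.0, 30.0),
        m=st.integers(0, 5),
    )
    def test_closed_form_agrees_with_quadrature(self, alpha, b, m):
        prior = BetaPrior(alpha, b)
        cf = posterior_mean_closed_form(prior, 0.0, m)
        qd = posterior_mean_quadrature(prior, 0.0, m)
        assert cf == pytest.approx(qd, abs=1e-6)

    def test_strictly_increasing_in_case_count(self, prior):
        values = [posterior_mean_closed_form(prior, -1.0, m) for m in range(6)]
        assert np.all(np.diff(values) > 0)

    def test_strictly_decreasing_in_cancer_free_exposure(self, prior):
        values = [
            posterior_mean_closed_form(prior, c, 1)
            for c in (0.0, -0.5, -1.0, -2.0, -4.0)
        ]
        assert np.all(np.diff(values) < 0)

    def test_large_m_defers_to_quadrature(self, prior, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="bfhs.score"):
            value = posterior_mean_closed_form(prior, -20.0, 13)
        assert value == pytest.approx(
            posterior_mean_quadrature(prior, -20.0, 13), abs=1e-8
        )
        assert "quadrature" in caplog.text

    @pytest.mark.parametrize("bad_m", [-1, 1.5])
    def test_invalid_case_counts_rejected(self, prior, bad_m):
        with pytest.raises(ScoreError):
            posterior_mean_closed_form(prior, 0.0, bad_m)

    def test_nonpositive_posterior_shape_rejected(self, prior):
        with pytest.raises(ScoreError, match="beta - c"):
            posterior_mean_quadrature(prior, 5.0, 0)


class TestBFHS:
    def test_zero_information_family(self, disease, prior):
        res = bfhs(Family("none"), disease, prior, P0)
        assert res.p_hat == prior.mean
        assert res.c == 0.0 and res.m == 0

    def test_worked_misreporting_example_qualitative(self, disease, prior):
        """Three relatives (cancer-free at 78 and 53, diagnosed at 55) give a
        score near 0.28 on a SEER-like table; misreporting the diagnosis age
        as 52, then a censoring age as 76, nudges the score upward — the
        published ordering under age misreporting."""
        correct = Family("w", [RelativeRecord(78, 0), RelativeRecord(53, 0),
                               RelativeRecord(55, 1)])
        mis1 = Family("w", [RelativeRecord(78, 0), RelativeRecord(53, 0),
                            RelativeRecord(52, 1)])
        mis2 = Family("w", [RelativeRecord(76, 0), RelativeRecord(53, 0),
                            RelativeRecord(52, 1)])
        r0 = bfhs(correct, disease, prior, P0).p_hat
        r1 = bfhs(mis1, disease, prior, P0).p_hat
        r2 = bfhs(mis2, disease, prior, P0).p_hat
        assert r0 == pytest.approx(0.28, abs=0.02)
        assert r0 < r1 < r2
        assert abs(r1 - r0) < 0.01 and abs(r2 - r0) < 0.01  # impact is minor

    def test_worked_example_regression_on_bundled_table(self, disease, prior):
        # frozen from the quadrature oracle on the bundled synthetic table
        fam = Family("w", [RelativeRecord(78, 0), RelativeRecord(53, 0),
                           RelativeRecord(55, 1)])
        assert bfhs(fam, disease, prior, P0).p_hat == pytest.approx(
            0.2828967663, abs=1e-8
        )

    def test_updating_with_longer_cancer_free_followup_never_raises_score(
        self, disease, prior
    ):
        base = bfhs(
            Family("f", [RelativeRecord(50, 0)]), disease, prior, P0
        ).p_hat
        older = bfhs(
            Family("f", [RelativeRecord(60, 0)]), disease, prior, P0
        ).p_hat
        flipped = bfhs(
            Family("f", [RelativeRecord(50, 1)]), disease, prior, P0
        ).p_hat
        assert older <= base
        assert flipped > base

    def test_result_invariants(self, disease, prior):
        fam = Family("f", [RelativeRecord(70, 1), RelativeRecord(60, 0)])
        res = bfhs(fam, disease, prior, P0)
        assert res.c <= 0
        assert res.b >= prior.beta
        assert 0 < res.p_hat < 1
        assert res.total_hazard == pytest.approx(
            res.c * math.log(1 - P0), abs=1e-12
        )


class TestHazardMultiplier:
    def test_identity_at_population_risk(self):
        assert family_hazard_multiplier(P0, P0) == pytest.approx(1.0, abs=1e-12)

    def test_doubling_log_arithmetic(self):
        p = 1 - (1 - P0) ** 2
        assert family_hazard_multiplier(p, P0) == pytest.approx(2.0, abs=1e-12)

    def test_direct_value(self):
        assert family_hazard_multiplier(0.394, P0) == pytest.approx(
            math.log(0.606) / math.log(0.803), abs=1e-12
        )

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_domain_errors(self, p):
        with pytest.raises(ScoreError):
            family_hazard_multiplier(p, P0)


class TestAgeSpecificRisk:
    def test_population_risk_matches_baseline_interval(self, disease):
        expected = 1 - math.exp(
            -(disease.cumulative_hazard(55) - disease.cumulative_hazard(50))
        )
        assert age_specific_risk(P0, disease, 50, 55, P0) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("p", [0.05, 0.197, 0.5, 0.9])
    def test_full_lifespan_risk_recovers_p(self, disease, p):
        # the defining property of f(p): lifetime pure risk equals p
        assert age_specific_risk(p, disease, 0, 90, P0) == pytest.approx(
            p, abs=1e-12
        )

    def test_higher_family_risk_gives_higher_interval_risk(self, disease):
        low = age_specific_risk(P0, disease, 50, 55, P0)
        high = age_specific_risk(0.3017, disease, 50, 55, P0)
        assert high > low

    def test_reversed_interval_rejected(self, disease):
        with pytest.raises(ScoreError):
            age_specific_risk(0.2, disease, 55, 50, P0)


class TestThreeLevelScore:
    @pytest.mark.parametrize("n_affected, expected", [(0, "0"), (1, "1"), (3, "2+")])
    def test_categories(self, n_affected, expected):
        rels = [RelativeRecord(60, 1)] * n_affected + [RelativeRecord(50, 0)]
        assert three_level_score(Family("f", rels)) == expected


class TestFamilyIO:
    def test_read_and_score_families(self, tmp_path, disease, prior):
        path = tmp_path / "fam.csv"
        path.write_text(
            "family_id,relative_id,relation,age,event\n"
            "a,a1,mother,78,0\n"
            "a,a2,sister,53,0\n"
            "a,a3,sister,55,1\n"
            "b,b1,sister,45,0\n"
        )
        families = read_families(path)
        assert [f.n for f in families] == [3, 1]
        scores = score_families(families, disease, prior, P0)
        assert list(scores.columns) == ["family_id", "n", "m", "c", "bfhs"]
        assert scores.loc[0, "m"] == 1
        assert scores.loc[0, "bfhs"] > scores.loc[1, "bfhs"]

    def test_missing_age_excluded_with_warning(self, tmp_path, caplog):
        import logging

        path = tmp_path / "fam.csv"
        path.write_text(
            "family_id,relative_id,relation,age,event\na,a1,sister,,0\na,a2,sister,50,1\n"
        )
        with caplog.at_level(logging.WARNING, logger="bfhs.score"):
            families = read_families(path)
        assert families[0].n == 1
        assert "missing age" in caplog.text
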