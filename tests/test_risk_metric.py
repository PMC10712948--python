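import numpy as np
import pytest

from arraxis.axis_model import PUBLISHED_AXIS, AxisModel
from arraxis.population import NATURAL_MU, NATURAL_SIGMA
from arraxis.risk_metric import (
    classify_drug,
    evaluate,
    lump_classes,
    optimize_threshold,
    population_centre_logit,
    risk_score,
    susceptible_fraction,
)

A_AJMALINE = np.array([-0.425, -2.32, 0.0, 0.0])
A_LINEZOLID = np.array([-2.71, -0.828, 0.0, 0.0])


def mc_susceptible_fraction(score, axis, n, seed, mu=NATURAL_MU, sigma=NATURAL_SIGMA):
    """Monte-Carlo oracle: sample the projected population directly."""
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, sigma, size=n)
    p = 1.0 / (1.0 + np.exp(-(population_centre_logit(axis, mu) + axis.norm * (s + score))))
    return p.mean(), p.std(ddof=1) / np.sqrt(n)


class TestRiskScore:
    def test_ajmaline_25x(self):
        assert risk_score(A_AJMALINE, PUBLISHED_AXIS) == pytest.approx(1.16, abs=0.005)

    def test_linezolid_25x(self):
        assert risk_score(A_LINEZOLID, PUBLISHED_AXIS) == pytest.approx(-1.18, abs=0.006)

    def test_drug_free_zero(self):
        assert risk_score(np.zeros(4), PUBLISHED_AXIS) == 0.0

    def test_linear_in_action(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a1, a2 = -rng.random(4), -rng.random(4)
            s = risk_score(a1 + a2, PUBLISHED_AXIS)
            assert s == pytest.approx(
                risk_score(a1, PUBLISHED_AXIS) + risk_score(a2, PUBLISHED_AXIS),
                rel=1e-12,
            )

    def test_pure_channel_blocks_have_known_sign(self):
        # IKr block is pro-arrhythmic, ICaL block protective
        assert risk_score([0.0, np.log(0.5), 0.0, 0.0], PUBLISHED_AXIS) > 0
        assert risk_score([np.log(0.5), 0.0, 0.0, 0.0], PUBLISHED_AXIS) < 0


class TestSusceptibleFraction:
    # printed values carry the 3-dp rounding of the regression coefficients,
    # so agreement is asserted to the looser of the printed half-ulp and 2%
    @pytest.mark.parametrize(
        "r,printed,ulp",
        [
            (0.0, 0.93, 0.005),       # drug-free baseline
            (1.44, 41.5, 0.05),       # 10x Ibutilide displacement
            (1.16, 26.0, 0.5),        # 25x Ajmaline displacement
            (-1.18, 0.0095, 5e-5),    # 25x Linezolid displacement
        ],
    )
    def test_reproduces_printed_population_fractions(self, r, printed, ulp):
        pct = 100.0 * susceptible_fraction(r, PUBLISHED_AXIS)
        assert abs(pct - printed) <= max(ulp, 0.02 * printed)

    @pytest.mark.parametrize("r", [-2.0, -1.0, 0.0, 1.0, 2.0])
    def test_quadrature_matches_monte_carlo(self, r):
        quad = susceptible_fraction(r, PUBLISHED_AXIS)
        mc, se = mc_susceptible_fraction(r, PUBLISHED_AXIS, n=1_000_000, seed=17)
        assert abs(quad - mc) < 3 * se

    def test_matches_full_4d_view(self):
        # rotational-symmetry reduction: shifting every channel by the drug
        # action and averaging the 4-D a-priori probability gives the same P
        rng = np.random.default_rng(5)
        n = 400_000
        X = rng.normal(NATURAL_MU, NATURAL_SIGMA, size=(n, 4))
        for A in (A_AJMALINE, A_LINEZOLID, np.zeros(4)):
            p4 = PUBLISHED_AXIS.predict_probability(X + A)
            se = p4.std(ddof=1) / np.sqrt(n)
            p1 = susceptible_fraction(risk_score(A, PUBLISHED_AXIS), PUBLISHED_AXIS)
            assert abs(p1 - p4.mean()) < 4 * se

    def test_monotone_continuous_with_saturating_limits(self):
        rs = np.linspace(-6, 6, 61)
        ps = np.array([susceptible_fraction(r, PUBLISHED_AXIS) for r in rs])
        assert np.all(np.diff(ps) > 0)
        # continuity: steps bounded by max slope ~ ||B||/4 per unit r
        assert np.all(np.diff(ps) < 0.25)
        assert susceptible_fraction(-30.0, PUBLISHED_AXIS) < 1e-12
        assert susceptible_fraction(30.0, PUBLISHED_AXIS) > 1.0 - 1e-9

    def test_sigma_zero_reduces_to_logistic(self):
        p = susceptible_fraction(0.0, PUBLISHED_AXIS, sigma=0.0)
        assert p == pytest.approx(
            PUBLISHED_AXIS.predict_probability([NATURAL_MU] * 4), rel=1e-12
        )


class TestClassification:
    def test_threshold_is_strict(self):
        assert classify_drug(1.16, 0.195) == "unsafe"
        assert classify_drug(-1.18, 0.195) == "safe"
        assert classify_drug(0.195, 0.195) == "safe"

    def test_lumping(self):
        assert lump_classes([1, 2, 3, 4]).tolist() == [True, True, False, False]
        with pytest.raises(ValueError):
            lump_classes([0])


class TestEvaluate:
    def test_perfect_separation(self):
        scores = [2.0, 1.5, 1.0, -1.0, -1.5, -2.0]
        classes = [1, 1, 2, 3, 4, 4]
        rep = evaluate(scores, classes)
        assert rep.auroc == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(1.0)
        assert 1.0 > rep.theta > -1.0

    def test_chance_level_auroc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=2000)
        classes = rng.integers(1, 5, size=2000)
        rep = evaluate(scores, classes, theta=0.0)
        assert rep.auroc == pytest.approx(0.5, abs=0.05)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=300)
        classes = np.where(scores + rng.normal(size=300) > 0, 1, 4)
        r1 = evaluate(scores, classes)
        r2 = evaluate(np.exp(scores / 2.0), classes)
        assert r1.auroc == pytest.approx(r2.auroc, rel=1e-12)

    def test_tie_break_toward_larger_theta(self):
        # any theta in (-1, 1) is equally accurate; the largest midpoint wins
        theta = optimize_threshold([1.0, -1.0], [1, 4])
        assert theta == pytest.approx(0.0)
        theta = optimize_threshold([2.0, 1.0, -1.0], [1, 1, 4])
        assert theta == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1, 2])

    def test_roc_monotone(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=100)
        classes = np.where(scores + rng.normal(size=100) > 0, 1, 3)
        rep = evaluate(scores, classes)
        fprs = [p[0] for p in rep.roc]
        tprs = [p[1] for p in rep.roc]
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert 0.0 <= rep.auroc <= 1.0
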