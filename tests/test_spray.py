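"""GES1 spray exposure: BBA algebra, greenhouse vapour term, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from owbscreen import (
    DomainError,
    GreenhouseParams,
    Protection,
    SprayScenario,
    application_spray_exposure,
    crrm_twa,
    ges1_enumerate,
    ml_spray_exposure,
)
from owbscreen.core import round_display

from conftest import PRINTED_APP_ROWS, PRINTED_ML_ROWS, RATE_HANDHELD, RATE_TRACTOR


def _decimals(x: float) -> int:
    return len(str(x).split(".")[1])


class TestMixingLoading:
    @pytest.mark.parametrize("technique, formulation", sorted(PRINTED_ML_ROWS))
    def test_reproduces_reference_rows(self, registry, ref_substance, technique, formulation):
        dermal, inhalation, rcr = PRINTED_ML_ROWS[(technique, formulation)]
        rate = RATE_TRACTOR if registry.technique(technique).group == "tractor" else RATE_HANDHELD
        est = ml_spray_exposure(
            SprayScenario(technique=technique, formulation=formulation, application_rate=rate),
            ref_substance, registry,
        )
        assert round_display(est.dermal, _decimals(dermal)) == dermal
        assert round_display(est.inhalation, _decimals(inhalation)) == inhalation
        assert round_display(est.rcr_total, 3) == rcr

    def test_zero_rate_gives_zero(self, registry, ref_substance):
        est = ml_spray_exposure(
            SprayScenario(technique="boom", formulation="WP", application_rate=0.0),
            ref_substance, registry,
        )
        assert est.dermal == est.inhalation == est.rcr_total == 0.0

    def test_unknown_technique_rejected(self, registry, ref_substance):
        with pytest.raises(Exception, match="technique"):
            ml_spray_exposure(
                SprayScenario(technique="drone", formulation="WP", application_rate=1.0),
                ref_substance, registry,
            )


class TestApplication:
    @pytest.mark.parametrize("technique, environment", sorted(PRINTED_APP_ROWS))
    def test_reproduces_reference_rows(self, registry, ref_substance, technique, environment):
        dermal, inhalation, rcr = PRINTED_APP_ROWS[(technique, environment)]
        rate = RATE_TRACTOR if registry.technique(technique).group == "tractor" else RATE_HANDHELD
        est = application_spray_exposure(
            SprayScenario(technique=technique, environment=environment, application_rate=rate),
            ref_substance, registry,
        )
        assert round_display(est.dermal, _decimals(dermal)) == dermal
        assert round_display(est.inhalation, _decimals(inhalation)) == inhalation
        assert round_display(est.rcr_total, 3) == rcr

    def test_formulation_independent(self, registry, ref_substance):
        estimates = [
            application_spray_exposure(
                SprayScenario(technique="boom", formulation=f, application_rate=1.0),
                ref_substance, registry,
            )
            for f in ("liquid", "WP", "WG")
        ]
        assert len({(e.dermal, e.inhalation) for e in estimates}) == 1

    def test_indoor_nonvolatile_equals_outdoor(self, registry, ref_substance):
        outdoor = application_spray_exposure(
            SprayScenario(technique="handheld", environment="outdoor",
                          application_rate=RATE_HANDHELD),
            ref_substance, registry,
        )
        indoor = application_spray_exposure(
            SprayScenario(technique="handheld", environment="indoor",
                          application_rate=RATE_HANDHELD),
            ref_substance, registry,
        )
        assert indoor.dermal == outdoor.dermal
        assert indoor.inhalation == outdoor.inhalation

    def test_indoor_volatile_adds_vapour(self, registry, volatile_substance):
        outdoor = application_spray_exposure(
            SprayScenario(technique="handheld", environment="outdoor",
                          application_rate=RATE_HANDHELD),
            volatile_substance, registry,
        )
        indoor = application_spray_exposure(
            SprayScenario(technique="handheld", environment="indoor",
                          application_rate=RATE_HANDHELD),
            volatile_substance, registry,
        )
        assert indoor.inhalation > outdoor.inhalation
        assert indoor.dermal == outdoor.dermal

    def test_indoor_tractor_rejected(self, registry, ref_substance):
        with pytest.raises(DomainError, match="hand-held"):
            application_spray_exposure(
                SprayScenario(technique="boom", environment="indoor", application_rate=1.0),
                ref_substance, registry,
            )

    @settings(derandomize=True, max_examples=30)
    @given(rate=st.floats(1e-3, 10), scale=st.floats(0.1, 10))
    def test_homogeneous_in_rate(self, registry, volatile_substance, rate, scale):
        """Exposure (including the vapour term) scales linearly with rate."""
        def run(r):
            return application_spray_exposure(
                SprayScenario(technique="handheld", environment="indoor", application_rate=r),
                volatile_substance, registry,
            )
        base, scaled = run(rate), run(rate * scale)
        assert scaled.dermal == pytest.approx(base.dermal * scale, rel=1e-9)
        assert scaled.inhalation == pytest.approx(base.inhalation * scale, rel=1e-9)


def _ode_twa(ar, gp):
    """Independent oracle: integrate dC/dt = S - q*C numerically and average.

    S = 100*AR/(h*tr) mg/m^3/h while the release lasts; the running integral
    of C is carried as a second state so the T-hour TWA is I(t)/T.
    """
    source = 100.0 * ar / (gp.h * gp.tr)

    def rhs(_t, y):
        c, _ = y
        return [source - gp.q * c, c]

    sol = solve_ivp(rhs, (0.0, gp.t), [0.0, 0.0], rtol=1e-10, atol=1e-14)
    return sol.y[1, -1] / gp.T


class TestCrrm:
    def test_zero_rate(self):
        gp = GreenhouseParams(q=1, h=4, tr=8, t=8, T=8)
        assert crrm_twa(0.0, gp) == 0.0

    def test_reference_point_against_ode(self):
        gp = GreenhouseParams(q=1, h=4, tr=8, t=8, T=8)
        value = crrm_twa(1.0, gp)
        assert value == pytest.approx(2.7345, abs=5e-5)
        assert value == pytest.approx(_ode_twa(1.0, gp), rel=1e-6)

    def test_no_ventilation_limit(self):
        """As q -> 0 the TWA tends to 100*AR*t / (2*h*tr) for t = T."""
        ar, h, tr = 2.0, 4.0, 8.0
        limit = 100.0 * ar * 8.0 / (2.0 * h * tr)
        value = crrm_twa(ar, GreenhouseParams(q=1e-7, h=h, tr=tr, t=8, T=8))
        assert value == pytest.approx(limit, rel=1e-5)

    def test_exposure_beyond_release_rejected(self):
        with pytest.raises(ValueError, match="release"):
            GreenhouseParams(q=1, h=4, tr=4, t=8, T=8)

    @settings(derandomize=True, max_examples=100)
    @given(
        ar=st.floats(0.01, 10), q=st.floats(0.05, 10), h=st.floats(1, 10),
        tr=st.floats(0.5, 12), t_frac=st.floats(0.05, 1), T=st.floats(0.5, 24),
    )
    def test_matches_ode_oracle(self, ar, q, h, tr, t_frac, T):
        gp = GreenhouseParams(q=q, h=h, tr=tr, t=t_frac * tr, T=T)
        assert crrm_twa(ar, gp) == pytest.approx(_ode_twa(ar, gp), rel=1e-6)

    def test_monotone_in_ventilation_and_time(self):
        qs = [0.2, 0.5, 1.0, 2.0, 5.0]
        values = [crrm_twa(1.0, GreenhouseParams(q=q, h=4, tr=8, t=8, T=8)) for q in qs]
        assert values == sorted(values, reverse=True)
        ts = [1.0, 2.0, 4.0, 8.0]
        values = [crrm_twa(1.0, GreenhouseParams(q=1, h=4, tr=8, t=t, T=8)) for t in ts]
        assert values == sorted(values)


class TestGes1Enumerate:
    def test_worst_cases_match_reference(self, registry, ref_substance):
        ml, app = ges1_enumerate(
            ref_substance, RATE_TRACTOR, RATE_HANDHELD, Protection(), registry
        )
        worst_tractor = ml.worst("tractor")
        assert worst_tractor.formulation == "WP"
        assert "boom" in worst_tractor.equipment
        assert round_display(worst_tractor.estimate.rcr_total, 3) == 0.675
        worst_hand = ml.worst("hand_held")
        assert worst_hand.formulation == "liquid"
        assert round_display(worst_hand.estimate.rcr_total, 3) == 0.750
        worst_app = app.worst("tractor")
        assert "air-assisted" in worst_app.equipment
        assert round_display(worst_app.estimate.rcr_total, 3) == 0.508

    def test_zero_rates_tie_break_is_first_in_canonical_order(self, registry, ref_substance):
        ml, app = ges1_enumerate(ref_substance, 0.0, 0.0, Protection(), registry)
        assert all(row.estimate.rcr_total == 0.0 for row in ml.rows)
        for group in ("tractor", "hand_held"):
            flagged = [r for r in ml.rows if r.group == group and r.worst_case]
            first = next(r for r in ml.rows if r.group == group)
            assert flagged == [first]

    def test_permutation_table_shape(self, registry, ref_substance):
        ml, app = ges1_enumerate(ref_substance, 1.0, 1.0, Protection(), registry)
        assert len(ml.rows) == 9   # 3 techniques x 3 formulations
        assert len(app.rows) == 4  # boom, air-blast, hand-held outdoor + indoor
        frame = ml.to_frame()
        assert list(frame["ppe"].unique()) == ["No PPE"]
        assert frame["worst_case"].sum() == 2
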