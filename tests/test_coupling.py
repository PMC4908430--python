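"""Energy-coupling, hinge and information-activity regressions."""

import math

import numpy as np
import pytest

from ribopinch import (
    Condition,
    ConstructRecord,
    PinchParams,
    apparent_Ea,
    gen_construct_ladder,
    hinge_fit,
    info_activity_fit,
    linear_coupling_fit,
    simulate_panel,
)
from ribopinch.constants import rt
from ribopinch.errors import GroupingError, InsufficientDataError
from ribopinch.synthetic import NoiseSpec

K_UNCAT = 2e-10


def make_records(stab_mags, ea_fn, linker="L1", cond=None, k_obs=1e-3):
    cond = cond or Condition()
    return [
        ConstructRecord(
            construct_id=f"{linker}-{i}",
            k_obs=k_obs,
            stability=-s,
            linker_class=linker,
            condition=cond,
            E_a_apparent=ea_fn(s),
        )
        for i, s in enumerate(stab_mags)
    ]


class TestLinearCoupling:
    def test_exact_slope_recovery(self):
        """E_a = E0 - 0.38 x (x = stability magnitude) gives the
        dEa/ddG slope +0.38 with r^2 = 1."""
        recs = make_records(np.linspace(0, 3.5, 8), lambda s: 12.0 - 0.38 * s)
        fit = linear_coupling_fit(recs)
        assert fit.slope == pytest.approx(0.38, abs=1e-12)
        assert fit.slope_vs_magnitude == pytest.approx(-0.38, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_no_coupling_zero_slope(self):
        recs = make_records(np.linspace(0, 3.0, 6), lambda s: 10.0)
        assert linear_coupling_fit(recs).slope == pytest.approx(0.0, abs=1e-12)

    def test_grouped_vs_pooled(self):
        """Two linker families with slopes 0.38 and 0.20: grouped fits
        recover each; the pooled slope lies between (closed-form OLS on
        the constructed points)."""
        xs = np.linspace(0, 3.0, 6)
        a = make_records(xs, lambda s: 12.0 - 0.38 * s, linker="A")
        b = make_records(xs, lambda s: 14.0 - 0.20 * s, linker="B")
        grouped = linear_coupling_fit(a + b, group_by_linker=True)
        assert grouped["A"].slope == pytest.approx(0.38, abs=1e-9)
        assert grouped["B"].slope == pytest.approx(0.20, abs=1e-9)
        pooled = linear_coupling_fit(a + b)
        assert 0.20 < pooled.slope < 0.38

    def test_mixed_conditions_in_group_rejected(self):
        xs = np.linspace(0, 3.0, 6)
        a = make_records(xs[:3], lambda s: 12 - 0.3 * s, cond=Condition(mg_mM=1.0))
        b = make_records(xs[3:], lambda s: 12 - 0.3 * s, cond=Condition(mg_mM=0.3))
        with pytest.raises(GroupingError):
            linear_coupling_fit(a + b, group_by_linker=True)

    def test_pooled_mixed_conditions_warns(self):
        xs = np.linspace(0, 3.0, 6)
        a = make_records(xs[:3], lambda s: 12 - 0.3 * s, cond=Condition(mg_mM=1.0))
        b = make_records(xs[3:], lambda s: 12 - 0.3 * s, cond=Condition(mg_mM=0.3))
        with pytest.warns(UserWarning, match="mixes"):
            linear_coupling_fit(a + b)

    def test_wildtype_excluded_by_default(self):
        recs = make_records(np.linspace(0, 3.0, 6), lambda s: 12.0 - 0.38 * s)
        wt = ConstructRecord(
            construct_id="WT", k_obs=1e-3, stability=-2.0,
            E_a_apparent=50.0, is_wildtype=True, condition=Condition(),
        )
        fit = linear_coupling_fit(recs + [wt])
        assert fit.n_points == 6
        assert fit.slope == pytest.approx(0.38, abs=1e-9)

    def test_equivariance_under_ea_offset(self):
        recs = make_records(np.linspace(0, 3.0, 7), lambda s: 9.0 - 0.31 * s)
        shifted = make_records(np.linspace(0, 3.0, 7), lambda s: 14.0 - 0.31 * s)
        f1, f2 = linear_coupling_fit(recs), linear_coupling_fit(shifted)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)
        assert f2.intercept - f1.intercept == pytest.approx(5.0, abs=1e-9)

    def test_too_few_records(self):
        recs = make_records([0.0, 1.0], lambda s: 10 - s)
        with pytest.raises(InsufficientDataError):
            linear_coupling_fit(recs)


class TestHinge:
    def ea_hinge(self, s, slope=0.38, bp=4.0, e0=12.0):
        return e0 - slope * min(s, bp)

    def test_recovers_synthetic_breakpoint(self):
        """Noiseless rise-then-flat data: breakpoint 4.0, slope 0.38."""
        xs = np.linspace(0, 7, 15)
        recs = make_records(xs, self.ea_hinge)
        fit = hinge_fit(recs)
        assert fit.model == "hinge"
        assert fit.breakpoint == pytest.approx(4.0, abs=0.1)
        assert fit.slope == pytest.approx(0.38, abs=0.005)

    def test_pure_linear_falls_back(self):
        xs = np.linspace(0, 6, 10)
        recs = make_records(xs, lambda s: 12.0 - 0.38 * s)
        fit = hinge_fit(recs)
        assert fit.model == "linear"
        assert fit.breakpoint is None

    def test_flat_data_selects_linear_zero_slope(self):
        recs = make_records(np.linspace(0, 6, 8), lambda s: 10.0)
        fit = hinge_fit(recs)
        assert fit.model == "linear"
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_hinge_rss_never_exceeds_linear(self):
        """The hinge family nests the line, so its profiled rss can
        never be worse."""
        rng = np.random.default_rng(42)
        xs = np.linspace(0, 7, 12)
        for _ in range(5):
            noise = rng.normal(0, 0.3, len(xs))
            recs = make_records(
                xs, lambda s: 12 - 0.3 * min(s, 4.2)
            )
            for r, dn in zip(recs, noise):
                r.E_a_apparent += dn
            lin = linear_coupling_fit(recs)
            xs_m = np.array([-r.stability for r in recs])
            ys = np.array([r.E_a_apparent for r in recs])
            # profile rss at the best grid breakpoint, by hand
            best_rss = min(
                _rss_hinge(xs_m, ys, bp)
                for bp in np.arange(xs_m.min() + 0.1, xs_m.max(), 0.1)
            )
            assert best_rss <= lin.rss + 1e-9

    def test_short_span_warns_and_falls_back(self):
        recs = make_records([0.0, 0.05, 0.1, 0.12, 0.15][:4], lambda s: 10 - s)
        with pytest.warns(UserWarning, match="hinge"):
            fit = hinge_fit(recs)
        assert fit.model == "linear"

    def test_noisy_recovery_within_tolerance(self):
        """With sd 0.3 kcal/mol noise on E_a and 12-construct panels,
        the linear slope estimator centers on the generating coupling
        within 0.05 (single-panel scatter at this noise level is ~0.08,
        so the invariant is about the estimator, not one draw)."""
        from ribopinch.constants import rt

        p = PinchParams(c=0.38, k_chem=1e9)
        slopes = []
        for seed in range(40):
            panel = simulate_panel(
                p, np.linspace(0, 3.5, 12),
                noise_sd_logk=0.3 / rt(p.temperature), seed=seed,
            )
            for r in panel:
                r.E_a_apparent = apparent_Ea(r.k_obs, K_UNCAT, r.condition)
            slopes.append(linear_coupling_fit(panel).slope)
        assert np.mean(slopes) == pytest.approx(0.38, abs=0.05)


def _rss_hinge(x, y, bp):
    z = np.minimum(x, bp)
    zm, ym = z.mean(), y.mean()
    sxx = np.sum((z - zm) ** 2)
    slope = np.sum((z - zm) * (y - ym)) / sxx
    resid = y - (ym + slope * (z - zm))
    return float(np.sum(resid**2))


class TestInfoActivity:
    def _bits_records(self, k_fn):
        recs = []
        for bp in range(8):
            recs.append(
                ConstructRecord(
                    construct_id=f"bp{bp}", k_obs=k_fn(bp),
                    p12_bp=bp, p12_bits=2.0 * bp, condition=Condition(),
                )
            )
        return recs

    def test_constructed_decade_slope(self):
        """k = c*10^(bits/10) is exactly 10-fold per 10 bits."""
        recs = self._bits_records(lambda bp: 1e-4 * 10 ** (2 * bp / 10))
        fit = info_activity_fit(recs)
        assert fit.fold_per_10bits == pytest.approx(10.0, rel=1e-9)

    def test_constant_rate_fold_one(self):
        recs = self._bits_records(lambda bp: 3e-3)
        assert info_activity_fit(recs).fold_per_10bits == pytest.approx(1.0)

    def test_pinch_ladder_gives_about_twelvefold(self):
        """A ladder through the full pinch model (c = 0.38, mean stack
        0.81 kcal/mol/bp, below the cap) shows the closed-form
        exp(0.38 * 5 * 0.81 / RT) ~ 12-fold per 10 bits."""
        p = PinchParams(k_chem=1e9, E_cap=100.0)  # stay on the rising limb
        recs = gen_construct_ladder(range(5), 0.81, p)
        fit = info_activity_fit(recs)
        expected = math.exp(0.38 * 5 * 0.81 / rt(p.temperature))
        assert expected == pytest.approx(12.15, abs=0.01)
        assert fit.fold_per_10bits == pytest.approx(expected, rel=1e-6)


class TestPinchClosure:
    def test_panel_to_coupling_recovers_c(self, conf_limited_pinch):
        """Central pipeline closure: simulate under the pinch model,
        convert to E_a, refit -- the coupling fraction comes back."""
        panel = simulate_panel(conf_limited_pinch, np.linspace(0, 3.5, 10))
        for r in panel:
            r.E_a_apparent = apparent_Ea(r.k_obs, K_UNCAT, r.condition)
        fit = linear_coupling_fit(panel)
        assert fit.slope == pytest.approx(conf_limited_pinch.c, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_panel_hinge_recovers_cap(self, conf_limited_pinch):
        panel = simulate_panel(conf_limited_pinch, np.linspace(0, 7, 15))
        for r in panel:
            r.E_a_apparent = apparent_Ea(r.k_obs, K_UNCAT, r.condition)
        fit = hinge_fit(panel)
        assert fit.model == "hinge"
        assert fit.breakpoint == pytest.approx(conf_limited_pinch.E_cap, abs=0.1)
        assert fit.slope == pytest.approx(conf_limited_pinch.c, abs=0.005)

    def test_noisy_panels_center_on_c(self, conf_limited_pinch):
        """Monte-Carlo: slope estimates over noisy panels center on the
        generating coupling."""
        slopes = []
        for seed in range(60):
            panel = simulate_panel(
                conf_limited_pinch, np.linspace(0, 3.5, 12),
                noise_sd_logk=0.15, seed=seed,
            )
            for r in panel:
                r.E_a_apparent = apparent_Ea(r.k_obs, K_UNCAT, r.condition)
            slopes.append(linear_coupling_fit(panel).slope)
        assert np.mean(slopes) == pytest.approx(0.38, abs=0.02)
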