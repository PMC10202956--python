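"""Closed-form eigenvalues, regime classification, and the phase diagram."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podowave import ModelParams, classify_regime, eigenvalues, phase_diagram
from podowave.params import characteristic_quantities, treatment_preset
from podowave.stability import OSCILLATORY_LABELS, treatment_arrows


class TestEigenvalues:
    def test_sustained_boundary_gives_400s_period(self):
        # Gamma=2, ratio=1: purely imaginary pair +-i/tau_m
        res = eigenvalues(2.0, 1.0, 63.66)
        assert res.omega1.real == pytest.approx(0.0, abs=1e-15)
        assert abs(res.omega1.imag) == pytest.approx(1 / 63.66, rel=1e-12)
        assert res.period_exact == pytest.approx(2 * math.pi * 63.66, rel=1e-9)
        assert res.regime == "oscillatory_sustained_boundary"

    def test_zero_feedback_critical_damping(self):
        res = eigenvalues(0.0, 1.0, 100.0)
        assert res.omega1 == res.omega2 == pytest.approx(-0.01)
        assert res.regime == "monotonic_stable"
        assert res.period_exact is None

    def test_damped_oscillation_roots(self):
        res = eigenvalues(1.5, 1.0, 100.0)
        assert res.omega1.real == pytest.approx(-0.0025, rel=1e-9)
        assert abs(res.omega1.imag) == pytest.approx(0.009682458, rel=1e-6)
        assert res.period_exact == pytest.approx(648.9, rel=1e-3)
        assert res.regime == "oscillatory_damped"

    def test_conjugate_pair(self):
        res = eigenvalues(1.8, 0.9, 64.0)
        assert res.omega1 == res.omega2.conjugate()

    @given(
        gamma=st.floats(0.0, 6.0),
        ratio=st.floats(0.01, 100.0),
        tau_m=st.floats(1.0, 1000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_roots_satisfy_characteristic_quadratic(self, gamma, ratio, tau_m):
        res = eigenvalues(gamma, ratio, tau_m)
        b = gamma - 1.0 - ratio
        for w in (res.omega1, res.omega2):
            residual = w * w - (b / tau_m) * w + ratio / tau_m**2
            assert abs(residual) < 1e-10 / tau_m**2 + 1e-14

    def test_boundary_real_part_is_zero(self):
        # on tau_m/tau_p = Gamma - 1 the real part vanishes
        res = eigenvalues(1.7, 0.7, 50.0)
        assert abs(res.omega1.real) < 1e-9

    def test_preconditions(self):
        with pytest.raises(ValueError):
            eigenvalues(1.0, -1.0, 10.0)
        with pytest.raises(ValueError):
            eigenvalues(1.0, 1.0, 0.0)


class TestClassifyRegime:
    def test_defaults_are_oscillatory_regime_I(self):
        assert classify_regime(ModelParams()) == "oscillatory_damped"

    def test_cytochalasinD_is_non_oscillatory(self):
        # tau_m/tau_p << 1 with Gamma ~ 2 gives real positive eigenvalues:
        # monotonic (regime II) growth in the linearized model
        treated = treatment_preset("cytochalasinD", ModelParams())
        assert classify_regime(treated) not in OSCILLATORY_LABELS

    def test_blebbistatin_is_monotonic(self):
        treated = treatment_preset("blebbistatin", ModelParams())
        assert classify_regime(treated) == "monotonic_stable"

    def test_y27632_is_effectively_non_oscillatory(self):
        # at tau_m = tau_p any Gamma > 0 is formally inside the oscillatory
        # wedge, but with Gamma -> 0 the mode is overdamped: its quality
        # factor Im/(2|Re|) collapses far below one (no visible cycle)
        treated = treatment_preset("Y27632", ModelParams())
        ch = characteristic_quantities(treated)
        res = eigenvalues(ch.Gamma, treated.tau_m / ch.tau_p, treated.tau_m)
        if res.regime not in ("monotonic_stable",):
            q_factor = abs(res.omega1.imag) / (2 * abs(res.omega1.real))
            assert q_factor < 0.5
        q_ctrl = None
        ch0 = characteristic_quantities(ModelParams())
        res0 = eigenvalues(ch0.Gamma, 1.0, ModelParams().tau_m)
        q_ctrl = abs(res0.omega1.imag) / (2 * abs(res0.omega1.real))
        assert q_ctrl > 2.0  # the control, by contrast, rings for cycles

    def test_strong_feedback_is_unstable(self):
        p = ModelParams()
        ch = characteristic_quantities(p)
        ratio = p.tau_m / ch.tau_p
        # choose alpha so that Gamma = 1 + ratio + 0.5
        target = 1.0 + ratio + 0.5
        scale = target / ch.Gamma
        res = eigenvalues(target, ratio, p.tau_m)
        assert res.omega1.real > 0
        assert classify_regime(p.replace(alpha=p.alpha * scale)) in (
            "unstable",
            "oscillatory_unstable",
        )


class TestPhaseDiagram:
    def test_single_cell_boundary(self):
        pd = phase_diagram((2.0, 2.0), (1.0, 1.0), resolution=1)
        assert pd.labels.shape == (1, 1)
        assert pd.labels[0, 0] == "oscillatory_sustained_boundary"

    def test_labels_match_pointwise_eigenvalues(self):
        pd = phase_diagram((0.0, 4.0), (0.01, 100.0), resolution=21)
        for i, g in enumerate(pd.Gamma):
            for j, r in enumerate(pd.tau_ratio):
                assert pd.labels[i, j] == eigenvalues(g, r, 64.0).regime

    def test_treatment_arrows_leave_regime_I(self):
        """Each preset moves the control point out of the sustained-
        oscillation region: either to a non-oscillatory label or to an
        overdamped mode with quality factor below one."""
        arrows = treatment_arrows(ModelParams()).set_index("treatment")
        assert arrows.loc["control", "regime"] in OSCILLATORY_LABELS
        for name in ("cytochalasinD", "blebbistatin", "Y27632"):
            p = treatment_preset(name, ModelParams())
            ch = characteristic_quantities(p)
            res = eigenvalues(ch.Gamma, p.tau_m / ch.tau_p, p.tau_m)
            if res.regime in OSCILLATORY_LABELS:
                q_factor = abs(res.omega1.imag) / (2 * abs(res.omega1.real))
                assert q_factor < 0.5
            else:
                assert res.regime in ("monotonic_stable", "unstable")

    def test_csv_export(self, tmp_path):
        pd_res = phase_diagram(resolution=5)
        out = tmp_path / "pd.csv"
        pd_res.to_csv(out)
        assert out.exists()
        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) == {"Gamma", "tau_ratio", "label"}
        assert len(df) == 25
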