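"""Zwanzig/BAR estimators, replica statistics, energy CSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepkit import (ReplicaSeries, ValidationError, WindowSamples,
                    bar_window, generate_gaussian_samples, kt,
                    leg_free_energy, read_energy_csv, write_energy_csv,
                    zwanzig_window)

KT298 = kt(298.0)


class TestZwanzigWindow:
    def test_zero_samples_give_zero(self):
        assert zwanzig_window(np.zeros(100), 298.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [-3.7, 0.2, 12.0])
    @pytest.mark.parametrize("T", [200.0, 298.0, 400.0])
    def test_constant_samples_return_the_constant(self, c, T):
        assert zwanzig_window(np.full(50, c), T) == pytest.approx(c)

    def test_gaussian_closed_form(self):
        # dU ~ N(2, 1) at 298 K: true dG = mu - sigma^2/(2 kT)
        w = generate_gaussian_samples(2.0, 1.0, 100_000, 298.0, seed=3)
        true = 2.0 - 1.0 / (2.0 * KT298)
        se = np.sqrt(2.0) / (KT298 * np.sqrt(100_000))  # delta-method scale
        est = zwanzig_window(w.dU_forward, 298.0)
        assert abs(est - true) < 4 * se

    def test_huge_samples_do_not_overflow(self):
        dU = np.array([1e5, 1e5, -1e5])
        assert np.isfinite(zwanzig_window(dU, 298.0))

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            zwanzig_window([], 298.0)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            zwanzig_window([0.0, np.nan, 1.0], 298.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40),
           st.floats(100, 500))
    def test_jensen_bound_and_order_invariance(self, dU, T):
        est = zwanzig_window(dU, T)
        assert est <= np.mean(dU) + 1e-9
        assert est == pytest.approx(zwanzig_window(sorted(dU), T))


def _window(fwd, bwd, lf=0.0, lt=1.0, stage="all"):
    return WindowSamples(lambda_from=lf, lambda_to=lt,
                         dU_forward=np.asarray(fwd, float),
                         dU_backward=np.asarray(bwd, float),
                         temperature=298.0, stage=stage)


class TestLegFreeEnergy:
    def test_all_zero_leg(self):
        rep = ReplicaSeries(0, [_window([0.0] * 5, [0.0] * 5)])
        leg = leg_free_energy([rep])
        assert leg.dG == leg.hysteresis == leg.sem == 0.0
        assert leg.n_replicas == 1

    def test_two_constant_windows(self):
        windows = [_window([1.0], [-1.0], 0.0, 0.5),
                   _window([1.0], [-1.0], 0.5, 1.0)]
        leg = leg_free_energy([ReplicaSeries(0, windows)])
        assert leg.dG_forward == pytest.approx(2.0)
        assert leg.dG_backward == pytest.approx(-2.0)
        assert leg.dG == pytest.approx(2.0)
        assert leg.hysteresis == pytest.approx(0.0)

    def test_planted_gaussian_leg_recovers_sum(self):
        kT = KT298
        planted = [0.7, -0.3, 1.1, 0.2]  # per-window true dG
        sigma = 0.6
        reps = []
        for r in range(10):
            windows = []
            for i, dg in enumerate(planted):
                w = generate_gaussian_samples(
                    dg + sigma ** 2 / (2 * kT), sigma, 4000, 298.0,
                    seed=97 * r + i)
                windows.append(_window(w.dU_forward, w.dU_backward,
                                       i / len(planted),
                                       (i + 1) / len(planted)))
            reps.append(ReplicaSeries(r, windows))
        leg = leg_free_energy(reps)
        assert leg.n_replicas == 10
        assert abs(leg.dG - sum(planted)) < 3 * max(leg.sem, 1e-4)

    def test_sem_scales_as_inverse_sqrt_n(self):
        def sem_with(n_reps):
            reps = [ReplicaSeries(r, [_window(
                generate_gaussian_samples(1.0, 0.8, 200, 298.0,
                                          seed=500 + r).dU_forward,
                generate_gaussian_samples(1.0, 0.8, 200, 298.0,
                                          seed=900 + r).dU_backward)])
                for r in range(n_reps)]
            return leg_free_energy(reps).sem
        # population sem halves when replica count quadruples (statistically)
        assert sem_with(40) < sem_with(10)

    def test_mismatched_schedules_rejected(self):
        r0 = ReplicaSeries(0, [_window([0.1], [0.1], 0.0, 1.0)])
        r1 = ReplicaSeries(1, [_window([0.1], [0.1], 0.0, 0.5),
                               _window([0.1], [0.1], 0.5, 1.0)])
        with pytest.raises(ValidationError, match="schedule"):
            leg_free_energy([r0, r1])


class TestBarWindow:
    def test_symmetric_samples_give_zero(self):
        f = np.array([0.8, -0.8, 0.3, -0.3])
        assert bar_window(f, -f, 298.0) == pytest.approx(0.0, abs=1e-8)

    def test_constant_offset_recovered(self):
        c = 2.5
        assert bar_window(np.full(10, c), np.full(10, -c),
                          298.0) == pytest.approx(c, abs=1e-7)

    def test_gaussian_fixture_matches_analytic(self):
        w = generate_gaussian_samples(2.0, 1.0, 50_000, 298.0, seed=8)
        true = 2.0 - 1.0 / (2.0 * KT298)
        est = bar_window(w.dU_forward, w.dU_backward, 298.0)
        assert est == pytest.approx(true, abs=0.02)

    def test_bar_agrees_with_zwanzig_on_gaussian_grid(self):
        for mu, sigma, T, seed in [(0.5, 0.3, 298.0, 1), (2.0, 1.0, 298.0, 2),
                                   (-1.0, 0.7, 350.0, 3)]:
            w = generate_gaussian_samples(mu, sigma, 30_000, T, seed=seed)
            z = zwanzig_window(w.dU_forward, T)
            b = bar_window(w.dU_forward, w.dU_backward, T)
            se = 3 * sigma / np.sqrt(30_000) + 3 * sigma ** 2 / (
                kt(T) * np.sqrt(30_000))
            assert abs(z - b) < 3 * max(se, 0.01)


class TestEnergyCsv:
    def _replicas(self):
        reps = []
        for r in range(2):
            windows = [_window([0.1, 0.2], [-0.1], 0.0, 0.5, "decharge"),
                       _window([0.3], [-0.3, -0.2], 0.5, 1.0, "decharge")]
            reps.append(ReplicaSeries(r, windows))
        return reps

    def test_roundtrip_preserves_samples(self, tmp_path):
        path = tmp_path / "leg.csv"
        write_energy_csv(self._replicas(), path)
        back = read_energy_csv(path)
        assert len(back) == 2
        for orig, rec in zip(self._replicas(), back):
            assert rec.schedule_key() == orig.schedule_key()
            for wo, wr in zip(orig.windows, rec.windows):
                np.testing.assert_allclose(wr.dU_forward, wo.dU_forward)
                np.testing.assert_allclose(wr.dU_backward, wo.dU_backward)

    def test_minimal_file_parses(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text(
            "replica,stage,window_index,lambda_from,lambda_to,direction,"
            "dU_kcal_mol,temperature_K\n"
            "0,all,0,0.0,0.5,fwd,0.1,298\n"
            "0,all,1,0.5,1.0,fwd,0.2,298\n")
        (rep,) = read_energy_csv(path)
        assert len(rep.windows) == 2

    def test_lambda_gap_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "replica,stage,window_index,lambda_from,lambda_to,direction,"
            "dU_kcal_mol,temperature_K\n"
            "0,all,0,0.0,0.5,fwd,0.1,298\n"
            "0,all,1,0.6,1.0,fwd,0.2,298\n")
        with pytest.raises(ValidationError, match="tiling gap"):
            read_energy_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("replica,stage,window_index\n0,all,0\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_energy_csv(path)

    def test_mixed_temperature_rejected(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text(
            "replica,stage,window_index,lambda_from,lambda_to,direction,"
            "dU_kcal_mol,temperature_K\n"
            "0,all,0,0.0,1.0,fwd,0.1,298\n"
            "0,all,0,0.0,1.0,fwd,0.2,300\n")
        with pytest.raises(ValidationError, match="temperature"):
            read_energy_csv(path)
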