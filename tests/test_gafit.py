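import numpy as np
import pytest

from vcdfit import (
    Ensemble,
    ConformerRecord,
    GAConfig,
    SynthConfig,
    boltzmann_weights,
    fit_energies,
    fit_free,
    generate_ensemble,
    generate_experiment,
    overlap_vs_window,
    sim_overlap,
)
from vcdfit.gafit import FitnessEvaluator, _boltzmann_rows
from vcdfit.weighting import ThermoConfig, composite_spectrum

FAST_GA = GAConfig(population_size=64, generations=150, seed=0)


def _two_conformer_problem(seed):
    cfg = SynthConfig(n_conformers=2, energy_error_sigma=0.5, seed=seed)
    ensemble, truth = generate_ensemble(cfg)
    _, exp_vcd = generate_experiment(truth, cfg)
    return ensemble, exp_vcd


def _grid_scan_best(ensemble, exp_vcd, demax, step=0.001):
    """Independent oracle: exhaustive scan of the single free direction
    delta_2 - delta_1 of a 2-conformer problem."""
    ev = FitnessEvaluator(ensemble, exp_vcd)
    diffs = np.arange(-2 * demax, 2 * demax + step / 2, step)
    deltas = np.zeros((len(diffs), 2))
    deltas[:, 1] = diffs
    W = _boltzmann_rows(ensemble.energies, deltas, ThermoConfig().kt)
    return float(ev.sim_vcd(W).max())


class TestFitEnergies:
    def test_single_conformer_has_no_freedom(self, broadening):
        cfg = SynthConfig(n_conformers=1, seed=5)
        ensemble, truth = generate_ensemble(cfg)
        _, exp_vcd = generate_experiment(truth, cfg)
        res = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=FAST_GA)
        assert np.allclose(res.weights, [1.0])
        comp = composite_spectrum(ensemble, [1.0], "VCD", broadening)
        assert res.sim_vcd == pytest.approx(sim_overlap(comp, exp_vcd), abs=1e-12)

    def test_recovers_known_two_conformer_weights(self, broadening):
        # experiment built at weights [0.7, 0.3] from the fit ensemble itself
        cfg = SynthConfig(n_conformers=2, baseline_noise=0.0, freq_perturbation_sigma=0.0, seed=9)
        ensemble, truth = generate_ensemble(cfg, true_energies=[0.0, 0.8])
        exp_vcd = composite_spectrum(ensemble, [0.7, 0.3], "VCD", broadening)
        res = fit_energies(ensemble, exp_vcd, demax=2.0, ga_cfg=FAST_GA)
        assert res.sim_vcd >= 0.999
        assert np.allclose(res.weights, [0.7, 0.3], atol=0.02)

    def test_vanishing_demax_reproduces_boltzmann(self):
        ensemble, exp_vcd = _two_conformer_problem(33)
        res = fit_energies(ensemble, exp_vcd, demax=1e-9, ga_cfg=FAST_GA)
        bw = boltzmann_weights(ensemble.energies)
        assert np.allclose(res.weights, bw, atol=1e-6)
        ev = FitnessEvaluator(ensemble, exp_vcd)
        assert res.sim_vcd == pytest.approx(float(ev.sim_vcd(bw[None, :])[0]), abs=1e-6)

    def test_matches_exhaustive_oracle(self):
        ensemble, exp_vcd = _two_conformer_problem(101)
        res = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=GAConfig(seed=1))
        assert res.sim_vcd >= _grid_scan_best(ensemble, exp_vcd, 1.0) - 0.005

    def test_never_below_boltzmann_start(self):
        ensemble, exp_vcd = _two_conformer_problem(55)
        bw = boltzmann_weights(ensemble.energies)
        ev = FitnessEvaluator(ensemble, exp_vcd)
        bw_overlap = float(ev.sim_vcd(bw[None, :])[0])
        res = fit_energies(ensemble, exp_vcd, demax=0.5, ga_cfg=FAST_GA)
        assert res.sim_vcd >= bw_overlap - 1e-12

    def test_history_non_decreasing(self):
        ensemble, exp_vcd = _two_conformer_problem(56)
        res = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=FAST_GA)
        assert np.all(np.diff(res.history) >= -1e-15)

    def test_seed_reproducibility(self):
        ensemble, exp_vcd = _two_conformer_problem(57)
        a = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=GAConfig(seed=11))
        b = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=GAConfig(seed=11))
        assert np.array_equal(a.deltas, b.deltas)
        assert a.sim_vcd == b.sim_vcd
        assert np.array_equal(a.history, b.history)

    def test_demax_monotonicity_with_warm_start(self):
        ensemble, exp_vcd = _two_conformer_problem(58)
        best, warm = -2.0, ()
        for demax in (0.25, 0.5, 1.0, 2.0, 4.0):
            res = fit_energies(ensemble, exp_vcd, demax=demax, ga_cfg=FAST_GA, init_deltas=warm)
            assert res.sim_vcd >= best - 1e-12
            best, warm = res.sim_vcd, (res.deltas,)

    def test_deltas_respect_bound(self):
        ensemble, exp_vcd = _two_conformer_problem(59)
        res = fit_energies(ensemble, exp_vcd, demax=0.3, ga_cfg=FAST_GA)
        assert np.all(np.abs(res.deltas) <= 0.3 + 1e-12)
        assert res.adjusted_energies.min() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_demax_rejected(self):
        ensemble, exp_vcd = _two_conformer_problem(60)
        with pytest.raises(ValueError):
            fit_energies(ensemble, exp_vcd, demax=-1.0)

    def test_summary_contains_key_quantities(self):
        ensemble, exp_vcd = _two_conformer_problem(61)
        res = fit_energies(ensemble, exp_vcd, demax=1.0, ga_cfg=FAST_GA)
        text = res.summary()
        assert "SimVCD" in text and f"{res.sim_vcd:.4f}" in text
        frame = res.to_frame()
        assert set(ensemble.ids) == set(frame["id"])
        assert frame["fitted_weight"].sum() == pytest.approx(1.0, abs=1e-9)


class TestFitFree:
    def test_independent_of_starting_energies(self):
        cfg = SynthConfig(n_conformers=3, baseline_noise=0.0, freq_perturbation_sigma=0.0, seed=21)
        ensemble, truth = generate_ensemble(cfg)
        _, exp_vcd = generate_experiment(truth, cfg)
        shifted = Ensemble(
            [ConformerRecord(c.id, c.energy * 3.0 + 2.0, c.sticks) for c in ensemble]
        )
        a = fit_free(ensemble, exp_vcd, ga_cfg=GAConfig(seed=3))
        b = fit_free(shifted, exp_vcd, ga_cfg=GAConfig(seed=3))
        assert np.allclose(a.weights, b.weights, atol=0.01)

    def test_recovers_single_generating_conformer(self, broadening):
        cfg = SynthConfig(n_conformers=3, baseline_noise=0.0, freq_perturbation_sigma=0.0, seed=21)
        ensemble, truth = generate_ensemble(cfg)
        exp = composite_spectrum(truth.true_ensemble, [0.0, 0.0, 1.0], "VCD", broadening)
        res = fit_free(ensemble, exp, ga_cfg=GAConfig(seed=3))
        assert res.weights[2] >= 0.98

    def test_requires_two_conformers(self):
        cfg = SynthConfig(n_conformers=1, seed=5)
        ensemble, truth = generate_ensemble(cfg)
        _, exp_vcd = generate_experiment(truth, cfg)
        with pytest.raises(ValueError):
            fit_free(ensemble, exp_vcd)

    def test_identical_spectra_split_is_a_flat_direction(self, broadening):
        sticks = generate_ensemble(SynthConfig(n_conformers=1, seed=8))[0][0].sticks
        twins = Ensemble(
            [ConformerRecord("t1", 0.0, sticks), ConformerRecord("t2", 0.5, sticks)]
        )
        exp = composite_spectrum(twins, [0.5, 0.5], "VCD", broadening)
        res = fit_free(twins, exp, ga_cfg=GAConfig(seed=4))
        # any split between identical twins fits perfectly
        assert res.sim_vcd == pytest.approx(1.0, abs=1e-9)


class TestOverlapVsWindow:
    def test_single_conformer_window_forces_agreement(self, noisy_synth):
        ensemble, truth, _, exp_vcd = noisy_synth
        second = np.sort(ensemble.energies)[1]
        window = [second / 2.0]
        vals = [
            overlap_vs_window(ensemble, exp_vcd, window, m, ga_cfg=FAST_GA)["overlap"].iloc[0]
            for m in ("mean", "bw", "fitted")
        ]
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)
        assert vals[0] == pytest.approx(vals[2], abs=1e-12)

    def test_fitted_dominates_boltzmann_at_every_window(self, noisy_synth):
        ensemble, truth, _, exp_vcd = noisy_synth
        windows = [0.5, 1.0, 2.0, 4.0]
        bw = overlap_vs_window(ensemble, exp_vcd, windows, "bw")
        fit = overlap_vs_window(ensemble, exp_vcd, windows, "fitted", demax=1.0, ga_cfg=FAST_GA)
        assert np.all(fit["overlap"].to_numpy() >= bw["overlap"].to_numpy() - 1e-12)

    def test_window_grid_validated(self, noisy_synth):
        ensemble, _, _, exp_vcd = noisy_synth
        with pytest.raises(ValueError):
            overlap_vs_window(ensemble, exp_vcd, [], "bw")
        with pytest.raises(ValueError):
            overlap_vs_window(ensemble, exp_vcd, [2.0, 1.0], "bw")
        with pytest.raises(ValueError):
            overlap_vs_window(ensemble, exp_vcd, [1.0], "nonsense")
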