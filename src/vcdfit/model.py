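"""Model facade: one object tying ensemble, experiment and settings.

``ConformerWeightModel`` follows the model/results convention of the
statistical-modelling ecosystem: the model is constructed from data
(a conformer ensemble plus experimental spectra) and configuration;
``fit()`` runs the genetic algorithm and returns a ``FitResult``
carrying estimates, diagnostics and a ``summary()`` table.  The
validation procedures (cross-validation, enantiomer discrimination,
energy-uncertainty estimation, conformer necessity) hang off the model
so they always see the same data and settings as the fit.
"""

from __future__ import annotations

import numpy as np

from . import validation
from .gafit import FitnessEvaluator, FitResult, GAConfig, fit_energies, fit_free, overlap_vs_window
from .similarity import SimilarityConfig
from .spectra import (
    VA,
    VCD,
    BroadeningConfig,
    ContinuousSpectrum,
    Ensemble,
    RegionMask,
    optimize_scaling,
    read_conformer_ensemble,
    read_experimental_spectrum,
)
from .weighting import ThermoConfig, arithmetic_weights, boltzmann_weights

__all__ = ["ConformerWeightModel"]


class ConformerWeightModel:
    """Conformer-population model for a VCD (and optionally VA) experiment.

    Parameters
    ----------
    ensemble
        Conformer ensemble with relative energies (kcal/mol) and stick
        spectra.
    exp_vcd, exp_va
        Experimental spectra on the comparison grid (as produced by
        :func:`vcdfit.spectra.read_experimental_spectrum` with the same
        broadening configuration).
    thermo, broadening, similarity
        Temperature, lineshape/grid and overlap settings.
    mask
        Region mask of wavenumber intervals included in the comparison.
    """

    def __init__(
        self,
        ensemble: Ensemble,
        exp_vcd: ContinuousSpectrum,
        exp_va: ContinuousSpectrum | None = None,
        thermo: ThermoConfig | None = None,
        broadening: BroadeningConfig | None = None,
        similarity: SimilarityConfig | None = None,
        mask: RegionMask | None = None,
    ):
        self.ensemble = ensemble
        self.exp_vcd = exp_vcd
        self.exp_va = exp_va
        self.thermo = thermo or ThermoConfig()
        self.broadening = broadening or BroadeningConfig()
        sim = similarity or SimilarityConfig()
        if mask is not None:
            sim = SimilarityConfig(sim.variant, mask)
        self.similarity = sim

    @classmethod
    def from_files(
        cls,
        manifest,
        exp_vcd_path,
        exp_va_path=None,
        broadening: BroadeningConfig | None = None,
        **kwargs,
    ) -> "ConformerWeightModel":
        """Build the model from a manifest and spectrum files on disk."""
        broadening = broadening or BroadeningConfig()
        ensemble = read_conformer_ensemble(manifest)
        exp_vcd = read_experimental_spectrum(exp_vcd_path, VCD, broadening)
        exp_va = read_experimental_spectrum(exp_va_path, VA, broadening) if exp_va_path else None
        return cls(ensemble, exp_vcd, exp_va, broadening=broadening, **kwargs)

    # -- weighting baselines ------------------------------------------------

    def boltzmann_weights(self) -> np.ndarray:
        return boltzmann_weights(self.ensemble.energies, self.thermo)

    def _overlap_at(self, weights) -> float:
        ev = FitnessEvaluator(self.ensemble, self.exp_vcd, None, self.similarity, self.broadening)
        return float(ev.sim_vcd(np.asarray(weights)[None, :])[0])

    def boltzmann_overlap(self) -> float:
        """SimVCD at the plain Boltzmann weights (no fitting)."""
        return self._overlap_at(self.boltzmann_weights())

    def mean_overlap(self) -> float:
        """SimVCD at equal weights (the arithmetic-mean baseline)."""
        return self._overlap_at(arithmetic_weights(len(self.ensemble)))

    # -- fitting ------------------------------------------------------------

    def fit(self, demax: float = 1.0, ga: GAConfig | None = None, alpha: float = 0.0) -> FitResult:
        """GA fit with energy modulations bounded by ±``demax`` (kcal/mol)."""
        return fit_energies(
            self.ensemble, self.exp_vcd, self.exp_va, demax, self.thermo, ga,
            self.similarity, self.broadening, alpha,
        )

    def fit_unconstrained(self, ga: GAConfig | None = None, alpha: float = 0.0) -> FitResult:
        """GA fit of weights on the simplex, ignoring computed energies."""
        return fit_free(
            self.ensemble, self.exp_vcd, self.exp_va, self.thermo, ga,
            self.similarity, self.broadening, alpha,
        )

    def optimize_frequency_scaling(self, bounds=(0.95, 1.05), step=0.001) -> float:
        """Grid-search the global frequency-scaling factor on the VA data
        at Boltzmann weights; returns the factor (apply with
        ``self.ensemble.scaled(factor)``)."""
        if self.exp_va is None:
            raise ValueError("frequency scaling requires an experimental VA spectrum")
        return optimize_scaling(
            self.ensemble, self.boltzmann_weights(), self.exp_va, bounds, step, self.broadening
        )

    # -- validation ---------------------------------------------------------

    def cross_validate(self, k: int = 5, demax: float = 1.0, ga: GAConfig | None = None,
                       seed: int | None = None, pooled: bool = False) -> validation.CVResult:
        return validation.kfold_cv(
            self.ensemble, self.exp_vcd, k, demax, self.thermo, ga,
            self.similarity, self.broadening, seed, pooled,
        )

    def cv_vs_nconf(self, n_grid, k: int = 5, demax: float = 1.0, ga: GAConfig | None = None,
                    seed: int | None = None):
        return validation.cv_vs_nconf(
            self.ensemble, self.exp_vcd, n_grid, k, demax, self.thermo, ga,
            self.similarity, self.broadening, seed,
        )

    def cv_vs_demax(self, demax_grid, k: int = 5, ga: GAConfig | None = None,
                    seed: int | None = None):
        return validation.cv_vs_demax(
            self.ensemble, self.exp_vcd, demax_grid, k, self.thermo, ga,
            self.similarity, self.broadening, seed,
        )

    def enantiomer_test(self, demax: float = 1.0, ga: GAConfig | None = None,
                        threshold: float = validation.CONFIDENCE_THRESHOLD):
        return validation.enantiomer_test(
            self.ensemble, self.exp_vcd, demax, self.thermo, ga,
            self.similarity, self.broadening, threshold,
        )

    def energy_uncertainty(self, window_grid=None):
        return validation.estimate_energy_uncertainty(
            self.ensemble, self.exp_vcd, window_grid, self.thermo,
            self.similarity, self.broadening,
        )

    def conformer_necessity(self, conformer_id: str, demax: float = 1.0, ga: GAConfig | None = None):
        return validation.conformer_necessity(
            self.ensemble, self.exp_vcd, conformer_id, demax, self.thermo, ga,
            self.similarity, self.broadening,
        )

    def window_scan(self, window_grid, method: str = "bw", demax: float = 1.0,
                    ga: GAConfig | None = None):
        return overlap_vs_window(
            self.ensemble, self.exp_vcd, window_grid, method, demax, self.thermo, ga,
            self.similarity, self.broadening,
        )

    # -- plotting -----------------------------------------------------------

    def plot_fit(self, result: FitResult, ax=None):
        """Overlay the fitted composite VCD spectrum on the experiment."""
        import matplotlib.pyplot as plt

        from .weighting import composite_spectrum

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        comp = composite_spectrum(self.ensemble, result.weights, VCD, self.broadening)
        ax.plot(self.exp_vcd.grid, self.exp_vcd.values, "k-", lw=1, label="experiment")
        ax.plot(comp.grid, comp.values, "r-", lw=1,
                label=f"fit (SimVCD = {result.sim_vcd:.4f})")
        ax.set_xlabel(r"wavenumber / cm$^{-1}$")
        ax.set_ylabel(r"$\Delta A$ (arb. u.)")
        ax.invert_xaxis()
        ax.legend(frameon=False)
        return ax
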