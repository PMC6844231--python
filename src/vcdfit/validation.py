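"""Confidence machinery for population fits.

Fitting dozens of conformer weights to one spectrum invites
overfitting: with enough conformers carrying partially opposing bands,
almost any spectrum — including that of the wrong enantiomer — can be
matched.  This module provides the diagnostics that keep an assignment
honest:

* k-fold cross-validation over spectral blocks, which exposes
  overfitting as a gap between training and held-out overlap;
* a two-enantiomer discrimination test: fit both mirror images and
  require the overlap difference to clear a confidence threshold (0.4
  by default, in line with the threshold commonly used for unfitted
  Boltzmann-weighted comparisons);
* an energy-uncertainty estimator: the energy-window size at which the
  Boltzmann-weighted composite starts to beat the arithmetic mean
  tracks the error in the computed conformer energies;
* a conformer-necessity test: refit without one conformer and measure
  the overlap drop it causes.

Cross-validation folds are built from contiguous blocks of width twice
the linewidth (2·FWHM), not from single grid points: adjacent points
within a linewidth are almost perfectly correlated, and point-wise
folds would leak the test data into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from io import StringIO

import numpy as np
import pandas as pd

from .gafit import FitnessEvaluator, FitResult, GAConfig, fit_energies
from .similarity import SimilarityConfig
from .spectra import BroadeningConfig, ContinuousSpectrum, Ensemble
from .weighting import ThermoConfig, arithmetic_weights, boltzmann_weights
from .gafit import overlap_vs_window

__all__ = [
    "CVResult",
    "DiscriminationResult",
    "UncertaintyEstimate",
    "spectral_folds",
    "kfold_cv",
    "cv_vs_nconf",
    "cv_vs_demax",
    "enantiomer_test",
    "estimate_energy_uncertainty",
    "conformer_necessity",
]

CONFIDENCE_THRESHOLD = 0.4


@dataclass
class CVResult:
    k: int
    train_overlaps: np.ndarray
    test_overlaps: np.ndarray
    demax: float
    seed: int
    pooled_test_overlap: float | None = None

    @property
    def mean_train_overlap(self) -> float:
        return float(np.mean(self.train_overlaps))

    @property
    def mean_test_overlap(self) -> float:
        return float(np.mean(self.test_overlaps))

    def summary(self) -> str:
        buf = StringIO()
        buf.write(f"{self.k}-fold cross-validation (dE_max = {self.demax:g} kcal/mol, seed {self.seed})\n")
        buf.write(f"{'fold':<6}{'train':>9}{'test':>9}\n")
        for i, (tr, te) in enumerate(zip(self.train_overlaps, self.test_overlaps)):
            buf.write(f"{i:<6}{tr:>9.4f}{te:>9.4f}\n")
        buf.write(f"{'mean':<6}{self.mean_train_overlap:>9.4f}{self.mean_test_overlap:>9.4f}\n")
        if self.pooled_test_overlap is not None:
            buf.write(f"pooled test overlap: {self.pooled_test_overlap:.4f}\n")
        return buf.getvalue()


@dataclass
class DiscriminationResult:
    """Outcome of fitting both enantiomers to the same experiment."""

    sim_correct: float
    sim_mirror: float
    threshold: float = CONFIDENCE_THRESHOLD
    fit_correct: FitResult | None = None
    fit_mirror: FitResult | None = None

    @property
    def delta(self) -> float:
        return self.sim_correct - self.sim_mirror

    @property
    def verdict(self) -> str:
        return "assigned" if self.delta >= self.threshold else "inconclusive"

    def summary(self) -> str:
        return (
            "Enantiomer discrimination\n"
            f"  fit to as-given enantiomer : SimVCD = {self.sim_correct:.4f}\n"
            f"  fit to mirrored enantiomer : SimVCD = {self.sim_mirror:.4f}\n"
            f"  difference                 : {self.delta:.4f} (threshold {self.threshold:g})\n"
            f"  verdict                    : {self.verdict}\n"
        )


@dataclass
class UncertaintyEstimate:
    """Energy-window crossover between Boltzmann and arithmetic weighting."""

    value: float
    lower_bound_only: bool
    table: pd.DataFrame = field(repr=False, default=None)

    def __str__(self):
        ge = ">= " if self.lower_bound_only else ""
        return f"{ge}{self.value:g} kcal/mol"


def _comparison_indices(
    exp_vcd: ContinuousSpectrum, sim_cfg: SimilarityConfig | None, broadening: BroadeningConfig
) -> np.ndarray:
    grid = broadening.grid()
    keep = np.ones(len(grid), dtype=bool)
    if sim_cfg is not None and sim_cfg.mask is not None:
        keep &= sim_cfg.mask.indicator(grid)
    if exp_vcd.measured is not None:
        keep &= exp_vcd.measured
    return np.flatnonzero(keep)


def spectral_folds(
    indices: np.ndarray, k: int, block_points: int, seed: int
) -> list[np.ndarray]:
    """Partition comparison indices into k folds of spectral blocks.

    Contiguous runs of indices are chopped into blocks of
    ``block_points`` points; blocks are shuffled (seeded) and dealt
    round-robin to the folds.  The folds partition the indices exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    indices = np.asarray(indices, dtype=int)
    runs = np.split(indices, np.flatnonzero(np.diff(indices) > 1) + 1)
    blocks = []
    for run in runs:
        for start in range(0, len(run), block_points):
            blocks.append(run[start : start + block_points])
    if len(blocks) < 2 * k:
        raise ValueError(f"only {len(blocks)} spectral blocks for {k} folds; need >= {2 * k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for pos, bi in enumerate(order):
        folds[pos % k].append(blocks[bi])
    return [np.sort(np.concatenate(f)) for f in folds]


def kfold_cv(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    k: int = 5,
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    seed: int | None = None,
    pooled: bool = False,
) -> CVResult:
    """k-fold cross-validation of the energy-modulation fit.

    For each fold the modulations are fitted on the training blocks and
    the overlap is evaluated on the held-out blocks.  ``pooled=True``
    additionally reports one overlap over all held-out points, each
    predicted by the fold that held it out.
    """
    broadening = broadening or BroadeningConfig()
    ga_cfg = ga_cfg or GAConfig()
    seed = ga_cfg.seed if seed is None else seed
    block = max(2, int(round(2 * broadening.fwhm / broadening.grid_step)))
    idx = _comparison_indices(exp_vcd, sim_cfg, broadening)
    folds = spectral_folds(idx, k, block, seed)
    train_overlaps, test_overlaps = [], []
    pooled_pred = np.zeros(len(broadening.grid())) if pooled else None
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, test_idx)
        fold_ga = dc_replace(ga_cfg, seed=seed + 1 + fi)
        res = fit_energies(
            ensemble, exp_vcd, None, demax, thermo, fold_ga, sim_cfg, broadening,
            grid_indices=train_idx,
        )
        train_overlaps.append(res.sim_vcd)
        test_ev = FitnessEvaluator(
            ensemble, exp_vcd, None, sim_cfg, broadening, grid_indices=test_idx
        )
        test_overlaps.append(float(test_ev.sim_vcd(res.weights[None, :])[0]))
        if pooled:
            comp = res.weights @ ensemble.broadened_matrix("VCD", broadening)
            pooled_pred[test_idx] = comp[test_idx]
    pooled_overlap = None
    if pooled:
        ev = FitnessEvaluator(ensemble, exp_vcd, None, sim_cfg, broadening, grid_indices=idx)
        # overlap of the concatenated held-out predictions with experiment
        from .similarity import trapezoid_weights

        grid = broadening.grid()
        w = trapezoid_weights(grid[idx])
        f, g = pooled_pred[idx], exp_vcd.values[idx]
        pooled_overlap = float(
            np.clip(np.sum(w * f * g) / np.sqrt(np.sum(w * f * f) * np.sum(w * g * g)), -1, 1)
        )
    return CVResult(k, np.asarray(train_overlaps), np.asarray(test_overlaps), demax, seed, pooled_overlap)


def cv_vs_nconf(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    n_grid,
    k: int = 5,
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated overlap as a function of ensemble size.

    For each n the n lowest-energy conformers are used; the table also
    reports the plain Boltzmann-weight overlap and the fully fitted
    overlap on the same subset.  A test-overlap column that peaks at
    small n and then sinks below the Boltzmann column is the signature
    of overfitting.
    """
    order = np.argsort(ensemble.energies, kind="stable")
    rows = []
    for n in n_grid:
        n = int(n)
        if not 1 <= n <= len(ensemble):
            raise ValueError(f"n={n} outside ensemble size {len(ensemble)}")
        sub = ensemble.subset(order[:n])
        bw = boltzmann_weights(sub.energies, thermo)
        ev = FitnessEvaluator(sub, exp_vcd, None, sim_cfg, broadening)
        bw_overlap = float(ev.sim_vcd(bw[None, :])[0])
        fit = fit_energies(sub, exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening)
        if n == 1:
            test = train = bw_overlap
        else:
            cv = kfold_cv(sub, exp_vcd, k, demax, thermo, ga_cfg, sim_cfg, broadening, seed)
            test, train = cv.mean_test_overlap, cv.mean_train_overlap
        rows.append(
            {
                "n_conformers": n,
                "test_overlap": test,
                "train_overlap": train,
                "bw_overlap": bw_overlap,
                "fitted_overlap": fit.sim_vcd,
            }
        )
    return pd.DataFrame(rows)


def cv_vs_demax(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    demax_grid,
    k: int = 5,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-validated overlap as a function of the modulation bound."""
    demax_grid = np.asarray(demax_grid, dtype=float)
    if np.any(demax_grid <= 0) or np.any(np.diff(demax_grid) <= 0):
        raise ValueError("dE_max grid must be positive and ascending")
    rows = []
    warm: tuple = ()
    for demax in demax_grid:
        cv = kfold_cv(ensemble, exp_vcd, k, demax, thermo, ga_cfg, sim_cfg, broadening, seed)
        fit = fit_energies(
            ensemble, exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening,
            init_deltas=warm,
        )
        warm = (fit.deltas,)  # nested bounds: warm-start the next, larger dE_max
        rows.append(
            {
                "demax_kcal": demax,
                "test_overlap": cv.mean_test_overlap,
                "train_overlap": cv.mean_train_overlap,
                "fitted_overlap": fit.sim_vcd,
            }
        )
    return pd.DataFrame(rows)


def enantiomer_test(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    threshold: float = CONFIDENCE_THRESHOLD,
) -> DiscriminationResult:
    """Fit the experiment with both enantiomers and compare the overlaps.

    The mirror ensemble has every rotational strength negated (VA is
    unchanged).  The assignment is accepted only when the overlap of
    the as-given enantiomer exceeds the mirror fit by at least the
    threshold — fitted overlaps alone are inflated by the fitting
    freedom and cannot be trusted against a fixed absolute cutoff.
    """
    fit_c = fit_energies(ensemble, exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening)
    fit_m = fit_energies(ensemble.mirrored(), exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening)
    return DiscriminationResult(fit_c.sim_vcd, fit_m.sim_vcd, threshold, fit_c, fit_m)


def estimate_energy_uncertainty(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    window_grid=None,
    thermo: ThermoConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
) -> UncertaintyEstimate:
    """Estimate the uncertainty of the computed energies (kcal/mol).

    Computes the overlap-versus-energy-window curves for equal weights
    and Boltzmann weights.  If the energies were exact, Boltzmann
    weighting would win everywhere (estimate 0).  Energy errors of size
    sigma scramble the weighting of conformers within ~sigma of the
    floor, so the window size at which Boltzmann weighting starts to
    win — and keeps winning — estimates sigma.  If equal weights win
    through the top of the grid, the estimate is reported as a lower
    bound at the grid maximum.
    """
    if window_grid is None:
        window_grid = np.arange(0.25, 3.0 + 1e-9, 0.25)
    windows = np.asarray(window_grid, dtype=float)
    if windows.size == 0:
        raise ValueError("empty window grid")
    mean_curve = overlap_vs_window(ensemble, exp_vcd, windows, "mean", 1.0, thermo, None, sim_cfg, broadening)
    bw_curve = overlap_vs_window(ensemble, exp_vcd, windows, "bw", 1.0, thermo, None, sim_cfg, broadening)
    table = pd.DataFrame(
        {
            "window_kcal": windows,
            "n_conformers": mean_curve["n_conformers"],
            "mean_overlap": mean_curve["overlap"],
            "bw_overlap": bw_curve["overlap"],
        }
    )
    bw_wins = (table["bw_overlap"].to_numpy() >= table["mean_overlap"].to_numpy() - 1e-12)
    strict = table["bw_overlap"].to_numpy() > table["mean_overlap"].to_numpy() + 1e-12
    if bw_wins.all():
        return UncertaintyEstimate(0.0, False, table)
    # smallest window from which bw dominates for all larger windows
    suffix_ok = np.logical_and.accumulate(bw_wins[::-1])[::-1]
    for i in range(len(windows)):
        if suffix_ok[i] and strict[i:].any():
            return UncertaintyEstimate(float(windows[i]), False, table)
    return UncertaintyEstimate(float(windows[-1]), True, table)


def conformer_necessity(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    conformer_id: str,
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
) -> tuple[float, float, float]:
    """Overlap with and without one conformer, each from a fresh fit.

    A positive drop means the conformer is needed to explain the
    experiment — evidence that it is populated in solution.
    Returns (overlap_with, overlap_without, difference).
    """
    if len(ensemble) < 2:
        raise ValueError("necessity test needs at least 2 conformers")
    full = fit_energies(ensemble, exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening)
    reduced = fit_energies(
        ensemble.without(conformer_id), exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening
    )
    return full.sim_vcd, reduced.sim_vcd, full.sim_vcd - reduced.sim_vcd
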