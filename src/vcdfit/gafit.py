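"""Genetic-algorithm fitting of conformer populations to experiment.

The experimental VCD spectrum is fitted by a Boltzmann-weighted sum of
computed conformer spectra in which each conformer's energy may deviate
from its computed value by a per-conformer modulation δ_i bounded by
±ΔE^max.  The bound encodes the assumed uncertainty of the quantum-
chemistry energies (of order 1-2 kcal/mol for routine DFT).  The genome
is the modulation vector; fitness is the VCD overlap (optionally mixed
with the VA overlap).  The all-zero genome — the plain Boltzmann-weight
solution — is always seeded into the initial population, so the fitted
overlap can never fall below the unfitted one.

``fit_free`` drops the energy constraint entirely and optimises weights
directly on the probability simplex through softmax-parameterised
genes; its result is independent of the starting energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .similarity import SimilarityConfig, trapezoid_weights
from .spectra import BroadeningConfig, ContinuousSpectrum, Ensemble
from .weighting import ThermoConfig, arithmetic_weights, boltzmann_weights

__all__ = ["GAConfig", "FitResult", "FitnessEvaluator", "fit_energies", "fit_free", "overlap_vs_window"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults are sized for up to ~200 genes: tournament selection,
    uniform crossover, per-gene Gaussian mutation clipped to bounds,
    elitism, and a stagnation-based stop.  ``mutation_sigma=None`` uses
    ΔE^max/10 for bounded fits and 0.5 for free (softmax) fits.
    """

    population_size: int = 128
    generations: int = 300
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    mutation_sigma: float | None = None
    elitism: int = 2
    convergence_tol: float = 1e-6
    convergence_window: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.elitism < 1 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [1, population_size)")


class FitnessEvaluator:
    """Vectorised overlap evaluation for whole GA populations.

    Broadened conformer spectra are collapsed to a matrix restricted to
    the comparison points (region mask ∩ measured range ∩ an optional
    explicit grid-index subset, as used by cross-validation), so one
    generation costs a single matrix product.
    """

    def __init__(
        self,
        ensemble: Ensemble,
        exp_vcd: ContinuousSpectrum,
        exp_va: ContinuousSpectrum | None = None,
        sim_cfg: SimilarityConfig | None = None,
        broadening: BroadeningConfig | None = None,
        alpha: float = 0.0,
        grid_indices: np.ndarray | None = None,
    ):
        self.sim_cfg = sim_cfg or SimilarityConfig()
        self.broadening = broadening or BroadeningConfig()
        self.alpha = float(alpha)
        grid = self.broadening.grid()
        self.keep = self._keep_mask(grid, exp_vcd, grid_indices)
        if self.keep.sum() < 2:
            raise ValueError("fewer than 2 comparison points remain after masking")
        self._w = trapezoid_weights(grid[self.keep])
        self._vcd = self._channel(ensemble.broadened_matrix("VCD", self.broadening), exp_vcd)
        self._va = None
        if self.alpha > 0.0:
            if exp_va is None:
                raise ValueError("alpha > 0 requires an experimental VA spectrum")
            self._va = self._channel(ensemble.broadened_matrix("VA", self.broadening), exp_va)
        elif exp_va is not None:
            self._va = self._channel(ensemble.broadened_matrix("VA", self.broadening), exp_va)

    def _keep_mask(self, grid, exp, grid_indices):
        keep = np.ones(len(grid), dtype=bool)
        if self.sim_cfg.mask is not None:
            keep &= self.sim_cfg.mask.indicator(grid)
        if exp.measured is not None:
            keep &= exp.measured
        if grid_indices is not None:
            sel = np.zeros(len(grid), dtype=bool)
            sel[np.asarray(grid_indices, dtype=int)] = True
            keep &= sel
        return keep

    def _channel(self, matrix, exp):
        if len(exp.grid) != matrix.shape[1]:
            raise ValueError("experimental spectrum is not on the comparison grid")
        M = matrix[:, self.keep]
        g = exp.values[self.keep]
        gg = float(np.sum(self._w * g * g))
        if gg <= 0:
            raise ValueError("zero-norm experimental spectrum: overlap undefined")
        return {"M": M, "wg": self._w * g, "gg": gg}

    def _sims(self, W: np.ndarray, ch) -> np.ndarray:
        S = W @ ch["M"]
        num = S @ ch["wg"]
        ss = (S * S) @ self._w
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.sim_cfg.variant == "cosine":
                s = num / np.sqrt(ss * ch["gg"])
            else:
                s = num / (ss + ch["gg"] - num)
        s = np.where(ss > 0, s, -np.inf)  # zero-norm composite cannot win
        return np.clip(s, -1.0, 1.0)

    def sim_vcd(self, W: np.ndarray) -> np.ndarray:
        return self._sims(np.atleast_2d(W), self._vcd)

    def sim_va(self, W: np.ndarray) -> np.ndarray:
        if self._va is None:
            raise ValueError("no experimental VA spectrum supplied")
        return self._sims(np.atleast_2d(W), self._va)

    def fitness(self, W: np.ndarray) -> np.ndarray:
        s = self._sims(np.atleast_2d(W), self._vcd)
        if self.alpha > 0.0:
            s = self.alpha * self._sims(np.atleast_2d(W), self._va) + (1.0 - self.alpha) * s
        return s


@dataclass
class FitResult:
    """Outcome of a population fit.

    ``deltas`` are the raw bounded energy modulations (kcal/mol);
    ``adjusted_energies`` re-centres E+δ so the minimum is zero — a pure
    reporting convention, since Boltzmann weights are invariant under a
    uniform energy shift.
    """

    ids: list
    energies: np.ndarray
    deltas: np.ndarray
    weights: np.ndarray
    sim_vcd: float
    sim_va: float | None
    history: np.ndarray
    seed: int
    demax: float | None
    method: str = "bounded"
    converged: bool = False
    thermo: ThermoConfig = field(default_factory=ThermoConfig)

    @property
    def adjusted_energies(self) -> np.ndarray:
        e = self.energies + self.deltas
        return e - e.min()

    @property
    def n_generations(self) -> int:
        return len(self.history)

    def to_frame(self) -> pd.DataFrame:
        bw = boltzmann_weights(self.energies, self.thermo)
        return pd.DataFrame(
            {
                "id": self.ids,
                "energy_kcal": self.energies,
                "delta_kcal": self.deltas,
                "adjusted_energy_kcal": self.adjusted_energies,
                "bw_weight": bw,
                "fitted_weight": self.weights,
            }
        ).sort_values("fitted_weight", ascending=False, ignore_index=True)

    def summary(self) -> str:
        buf = StringIO()
        demax = "unbounded" if self.demax is None else f"{self.demax:g} kcal/mol"
        buf.write("Conformer population fit\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"conformers: {len(self.ids):<6d} method: {self.method} (dE_max {demax})\n")
        buf.write(f"T = {self.thermo.temperature:g} K   seed = {self.seed}   ")
        buf.write(f"generations = {self.n_generations}{' (converged)' if self.converged else ''}\n")
        buf.write(f"SimVCD = {self.sim_vcd:.4f}")
        if self.sim_va is not None:
            buf.write(f"   SimVA = {self.sim_va:.4f}")
        buf.write("\n" + "-" * 64 + "\n")
        frame = self.to_frame()
        head = frame.head(15)
        buf.write(f"{'id':<12}{'E (kcal/mol)':>13}{'delta':>9}{'BW':>9}{'fitted':>9}\n")
        for _, row in head.iterrows():
            buf.write(
                f"{str(row['id']):<12}{row['energy_kcal']:>13.3f}{row['delta_kcal']:>9.3f}"
                f"{row['bw_weight']:>9.4f}{row['fitted_weight']:>9.4f}\n"
            )
        if len(frame) > len(head):
            buf.write(f"... {len(frame) - len(head)} more conformers\n")
        return buf.getvalue()


def _select_best(pop, fits, norms):
    """Best-by-fitness; exact ties broken toward the smallest ||genome||
    (maximum parsimony: stay closest to the computed energies)."""
    order = np.lexsort((norms, -fits))
    return order[0]


def _ga_loop(n_genes, bounds, decode, evaluator, cfg: GAConfig, sigma, rng, seed_zero=True,
             seed_genomes=()):
    lo, hi = bounds
    P = cfg.population_size
    pop = rng.uniform(lo, hi, size=(P, n_genes))
    if seed_zero:
        pop[0] = 0.0
    for k, genome in enumerate(seed_genomes, start=1):
        if k < P:
            pop[k] = np.clip(np.asarray(genome, dtype=float), lo, hi)
    fits = evaluator.fitness(decode(pop))
    norms = np.linalg.norm(pop, axis=1)
    history = []
    best_i = _select_best(pop, fits, norms)
    best = (fits[best_i], norms[best_i], pop[best_i].copy())
    history.append(best[0])
    converged = False
    n_elite = min(cfg.elitism, P)
    for _gen in range(1, cfg.generations):
        order = np.lexsort((norms, -fits))
        elites = pop[order[:n_elite]].copy()
        elite_fits = fits[order[:n_elite]].copy()
        n_off = P - n_elite
        # tournament selection of parents
        cand = rng.integers(0, P, size=(2 * n_off, cfg.tournament_size))
        cand_key = fits[cand] - 1e-12 * norms[cand]  # tiny norm penalty breaks ties
        parents = pop[cand[np.arange(2 * n_off), np.argmax(cand_key, axis=1)]]
        a, b = parents[:n_off].copy(), parents[n_off:].copy()
        # uniform crossover
        do_x = rng.random(n_off) < cfg.crossover_rate
        swap = (rng.random((n_off, n_genes)) < 0.5) & do_x[:, None]
        a[swap], b[swap] = b[swap], a[swap].copy()
        offspring = a
        # per-gene Gaussian mutation, clipped to bounds
        mut = rng.random((n_off, n_genes)) < cfg.mutation_rate
        offspring = offspring + mut * rng.normal(0.0, sigma, size=(n_off, n_genes))
        np.clip(offspring, lo, hi, out=offspring)
        off_fits = evaluator.fitness(decode(offspring))
        pop = np.vstack([elites, offspring])
        fits = np.concatenate([elite_fits, off_fits])
        norms = np.linalg.norm(pop, axis=1)
        i = _select_best(pop, fits, norms)
        if fits[i] > best[0] or (fits[i] == best[0] and norms[i] < best[1]):
            best = (fits[i], norms[i], pop[i].copy())
        history.append(best[0])
        w = cfg.convergence_window
        if len(history) > w and history[-1] - history[-1 - w] < cfg.convergence_tol:
            converged = True
            break
    return best[2], np.asarray(history), converged


def _boltzmann_rows(energies, deltas, kt):
    x = -(energies[None, :] + np.atleast_2d(deltas)) / kt
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


def _softmax_rows(genes):
    x = np.atleast_2d(genes)
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


def fit_energies(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    exp_va: ContinuousSpectrum | None = None,
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    alpha: float = 0.0,
    grid_indices: np.ndarray | None = None,
    init_deltas=(),
) -> FitResult:
    """Fit conformer populations with energy modulations bounded by ±ΔE^max.

    ``grid_indices`` restricts the fitness evaluation to an explicit
    subset of grid points (used by cross-validation); the reported
    overlaps then refer to that subset.  ``init_deltas`` seeds extra
    genomes (clipped to the bounds) into the initial population — used
    to warm-start a fit from the optimum of a smaller ΔE^max, which
    makes the best overlap provably non-decreasing along a ΔE^max scan
    (the feasible sets are nested).
    """
    if demax <= 0:
        raise ValueError("dE_max must be positive")
    thermo = thermo or ThermoConfig()
    ga_cfg = ga_cfg or GAConfig()
    evaluator = FitnessEvaluator(ensemble, exp_vcd, exp_va, sim_cfg, broadening, alpha, grid_indices)
    energies = ensemble.energies
    n = len(ensemble)
    if n == 1:
        w = np.array([1.0])
        sv = float(evaluator.sim_vcd(w[None, :])[0])
        sa = float(evaluator.sim_va(w[None, :])[0]) if exp_va is not None else None
        return FitResult(
            ensemble.ids, energies, np.zeros(1), w, sv, sa, np.array([sv]), ga_cfg.seed, demax,
            "bounded", True, thermo,
        )
    sigma = ga_cfg.mutation_sigma if ga_cfg.mutation_sigma is not None else demax / 10.0
    rng = np.random.default_rng(ga_cfg.seed)
    decode = lambda pop: _boltzmann_rows(energies, pop, thermo.kt)
    deltas, history, converged = _ga_loop(
        n, (-demax, demax), decode, evaluator, ga_cfg, sigma, rng, seed_zero=True,
        seed_genomes=init_deltas,
    )
    weights = _boltzmann_rows(energies, deltas, thermo.kt)[0]
    sim_vcd = float(evaluator.sim_vcd(weights[None, :])[0])
    sim_va = float(evaluator.sim_va(weights[None, :])[0]) if exp_va is not None else None
    return FitResult(
        ensemble.ids, energies, deltas, weights, sim_vcd, sim_va, history, ga_cfg.seed, demax,
        "bounded", converged, thermo,
    )


def fit_free(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    exp_va: ContinuousSpectrum | None = None,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
    alpha: float = 0.0,
    grid_indices: np.ndarray | None = None,
) -> FitResult:
    """Fit weights directly on the probability simplex (energies free).

    Genes are softmax-parameterised, so the result does not depend on
    the computed energies at all; reported deltas are the effective
    energies -kT ln(w) (re-centred) minus the computed ones.
    """
    if len(ensemble) < 2:
        raise ValueError("free fitting needs at least 2 conformers")
    thermo = thermo or ThermoConfig()
    ga_cfg = ga_cfg or GAConfig()
    evaluator = FitnessEvaluator(ensemble, exp_vcd, exp_va, sim_cfg, broadening, alpha, grid_indices)
    energies = ensemble.energies
    n = len(ensemble)
    sigma = ga_cfg.mutation_sigma if ga_cfg.mutation_sigma is not None else 0.5
    rng = np.random.default_rng(ga_cfg.seed)
    bound = 20.0  # softmax genes: exp(±20) spans any realistic weight ratio
    genes, history, converged = _ga_loop(
        n, (-bound, bound), _softmax_rows, evaluator, ga_cfg, sigma, rng, seed_zero=True
    )
    weights = _softmax_rows(genes)[0]
    sim_vcd = float(evaluator.sim_vcd(weights[None, :])[0])
    sim_va = float(evaluator.sim_va(weights[None, :])[0]) if exp_va is not None else None
    eff = -thermo.kt * np.log(np.maximum(weights, 1e-300))
    deltas = (eff - eff.min()) - energies
    return FitResult(
        ensemble.ids, energies, deltas, weights, sim_vcd, sim_va, history, ga_cfg.seed, None,
        "free", converged, thermo,
    )


def overlap_vs_window(
    ensemble: Ensemble,
    exp_vcd: ContinuousSpectrum,
    window_grid,
    method: str = "bw",
    demax: float = 1.0,
    thermo: ThermoConfig | None = None,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
) -> pd.DataFrame:
    """Overlap with experiment as a function of the energy-window size.

    For each window E_w the ensemble is restricted to conformers with
    relative energy <= E_w and the VCD overlap is computed with equal
    weights (``mean``), Boltzmann weights (``bw``) or GA-fitted weights
    (``fitted``).  Comparing the mean and bw curves locates the point
    where the computed energies start carrying information — an
    empirical estimate of their uncertainty.
    """
    if method not in ("mean", "bw", "fitted"):
        raise ValueError("method must be 'mean', 'bw' or 'fitted'")
    thermo = thermo or ThermoConfig()
    windows = np.asarray(window_grid, dtype=float)
    if windows.size == 0:
        raise ValueError("empty window grid")
    if np.any(np.diff(windows) <= 0):
        raise ValueError("window grid must be strictly ascending")
    rows = []
    for ew in windows:
        sub = ensemble.within_window(ew)
        if method == "fitted":
            res = fit_energies(sub, exp_vcd, None, demax, thermo, ga_cfg, sim_cfg, broadening)
            s = res.sim_vcd
        else:
            ev = FitnessEvaluator(sub, exp_vcd, None, sim_cfg, broadening)
            w = arithmetic_weights(len(sub)) if method == "mean" else boltzmann_weights(sub.energies, thermo)
            s = float(ev.sim_vcd(w[None, :])[0])
        rows.append({"window_kcal": ew, "n_conformers": len(sub), "overlap": s})
    return pd.DataFrame(rows)
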