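"""Conformer population weights and composite ensemble spectra.

Thermal populations follow the Boltzmann distribution over relative
energies, w_i ∝ exp(-E_i / k_B T).  The arithmetic mean (equal weights)
is the zero-information baseline; modulated weights are Boltzmann
weights of energies shifted by per-conformer modulations δ_i, the
mechanism by which fitting absorbs the uncertainty of computed DFT
energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import BroadeningConfig, ContinuousSpectrum, Ensemble

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "ThermoConfig",
    "boltzmann_weights",
    "arithmetic_weights",
    "modulated_weights",
    "composite_spectrum",
    "write_weights",
]

# Boltzmann constant, kcal mol^-1 K^-1, pinned to 7 significant digits
# so outputs are bit-reproducible across platforms.
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature for Boltzmann weighting; room temperature by default."""

    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def kt(self) -> float:
        """k_B T in kcal/mol."""
        return KB_KCAL_PER_MOL_K * self.temperature


def boltzmann_weights(energies, thermo: ThermoConfig | None = None) -> np.ndarray:
    """Normalized thermal populations from relative energies (kcal/mol).

    Computed shift-stably: the minimum energy is subtracted before
    exponentiation, which leaves the weights unchanged (the distribution
    is invariant under a uniform energy shift) but avoids underflow.
    """
    thermo = thermo or ThermoConfig()
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    x = np.exp(-(e - e.min()) / thermo.kt)
    return x / x.sum()


def arithmetic_weights(n: int) -> np.ndarray:
    """Equal weights 1/n — the 'wisdom of the crowd' baseline."""
    if n < 1:
        raise ValueError("need at least one conformer")
    return np.full(n, 1.0 / n)


def modulated_weights(
    energies, deltas, demax: float | None, thermo: ThermoConfig | None = None
) -> np.ndarray:
    """Boltzmann weights of energies E_i + δ_i with |δ_i| <= ΔE^max.

    ``demax=None`` means unbounded modulations (free fitting).
    """
    e = np.asarray(energies, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if e.shape != d.shape:
        raise ValueError("energies and deltas must have the same length")
    if demax is not None and np.any(np.abs(d) > demax + 1e-12):
        raise ValueError(f"|delta| exceeds the {demax} kcal/mol bound")
    return boltzmann_weights(e + d, thermo)


def composite_spectrum(
    ensemble: Ensemble, weights, which: str, cfg: BroadeningConfig | None = None
) -> ContinuousSpectrum:
    """Weighted sum of broadened conformer spectra.

    Conformer spectra are broadened once per (mode, grid) and cached on
    the ensemble, so re-weighting costs one matrix-vector product.
    """
    cfg = cfg or BroadeningConfig()
    w = np.asarray(weights, dtype=float)
    if len(w) != len(ensemble):
        raise ValueError(f"got {len(w)} weights for {len(ensemble)} conformers")
    matrix = ensemble.broadened_matrix(which, cfg)
    return ContinuousSpectrum(cfg.grid(), w @ matrix, mode=which)


def write_weights(ids, weights, path) -> None:
    """Write ``id,weight`` rows sorted by descending weight."""
    order = np.argsort(-np.asarray(weights, dtype=float), kind="stable")
    with open(path, "w") as fh:
        fh.write("id,weight\n")
        for i in order:
            fh.write(f"{ids[i]},{weights[i]:.6f}\n")
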