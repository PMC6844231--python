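"""Normalized overlap between calculated and experimental spectra.

The overlap (SimVA for absorption, SimVCD for circular dichroism) maps a
pair of spectra to [-1, +1]: +1 for a perfectly matching spectrum, -1
for an exactly opposite one.  The default variant is the cosine of the
two spectra under a trapezoid-weighted inner product, which is
scale-invariant — only band shapes and signs matter, not absolute
intensity units.  A Tanimoto-style variant is provided as an option; it
is not scale-invariant and rewards matching absolute magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import BroadeningConfig, ContinuousSpectrum, Ensemble, RegionMask, apply_mask

__all__ = ["SimilarityConfig", "sim_overlap", "sim_pair"]


@dataclass(frozen=True)
class SimilarityConfig:
    variant: str = "cosine"
    mask: RegionMask | None = None

    def __post_init__(self):
        if self.variant not in ("cosine", "tanimoto"):
            raise ValueError(f"variant must be 'cosine' or 'tanimoto', got {self.variant!r}")


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Composite-trapezoid quadrature weights, segment-aware.

    Masked grids may contain gaps; each contiguous run of points is
    treated as its own trapezoid panel so excluded regions contribute
    nothing to the inner product.
    """
    grid = np.asarray(grid, dtype=float)
    n = len(grid)
    if n == 1:
        return np.ones(1)
    steps = np.diff(grid)
    gap = steps > 1.5 * steps.min()
    w = np.zeros(n)
    seg_start = 0
    for i in range(n - 1):
        if gap[i]:
            _accumulate_segment(w, grid, seg_start, i)
            seg_start = i + 1
    _accumulate_segment(w, grid, seg_start, n - 1)
    return w


def _accumulate_segment(w: np.ndarray, grid: np.ndarray, a: int, b: int) -> None:
    if a == b:  # isolated point: give it one nominal step of weight
        w[a] += 1.0
        return
    h = np.diff(grid[a : b + 1])
    w[a] += h[0] / 2
    w[b] += h[-1] / 2
    w[a + 1 : b] += (h[:-1] + h[1:]) / 2


def _inner(f: np.ndarray, g: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * f * g))


def sim_overlap(
    calc: ContinuousSpectrum, exp: ContinuousSpectrum, cfg: SimilarityConfig | None = None
) -> float:
    """Overlap between a calculated and an experimental spectrum.

    Both spectra must live on the same grid.  Points outside the
    experiment's measured range and outside the configured region mask
    are excluded.  Raises on zero-norm input (e.g. an all-zero VCD
    spectrum), which signals an undefined comparison rather than a zero
    overlap.
    """
    cfg = cfg or SimilarityConfig()
    if len(calc.grid) != len(exp.grid) or not np.array_equal(calc.grid, exp.grid):
        raise ValueError("spectra must share the same wavenumber grid")
    if cfg.mask is not None:
        calc = apply_mask(calc, cfg.mask)
        exp = apply_mask(exp, cfg.mask)
    keep = exp.measured if exp.measured is not None else np.ones(len(exp), dtype=bool)
    if calc.measured is not None:
        keep = keep & calc.measured
    if keep.sum() < 2:
        raise ValueError("fewer than 2 grid points remain after masking")
    grid = exp.grid[keep]
    f = calc.values[keep]
    g = exp.values[keep]
    w = trapezoid_weights(grid)
    ff, gg, fg = _inner(f, f, w), _inner(g, g, w), _inner(f, g, w)
    if ff <= 0 or gg <= 0:
        raise ValueError("zero-norm spectrum: overlap undefined")
    if cfg.variant == "cosine":
        s = fg / np.sqrt(ff * gg)
    else:  # tanimoto
        s = fg / (ff + gg - fg)
    return float(np.clip(s, -1.0, 1.0))


def sim_pair(
    ensemble: Ensemble,
    weights,
    exp_va: ContinuousSpectrum,
    exp_vcd: ContinuousSpectrum,
    cfg: SimilarityConfig | None = None,
    broadening: BroadeningConfig | None = None,
) -> tuple[float, float]:
    """(SimVA, SimVCD) of the weighted ensemble against experiment."""
    from .weighting import composite_spectrum

    broadening = broadening or BroadeningConfig()
    calc_va = composite_spectrum(ensemble, weights, "VA", broadening)
    calc_vcd = composite_spectrum(ensemble, weights, "VCD", broadening)
    return sim_overlap(calc_va, exp_va, cfg), sim_overlap(calc_vcd, exp_vcd, cfg)
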