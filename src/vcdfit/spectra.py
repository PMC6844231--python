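"""Stick and continuous vibrational spectra.

A conformer's quantum-chemistry output is a *stick spectrum*: a list of
normal-mode wavenumbers with a dipole strength (IR absorption, VA) and a
rotational strength (circular dichroism, VCD) per mode.  Comparison with
experiment happens after Lorentzian line broadening onto a uniform
wavenumber grid, optionally after a global frequency scaling that
compensates the systematic error of harmonic DFT frequencies, and
optionally restricted to a set of wavenumber intervals (a region mask).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StickSpectrum",
    "ConformerRecord",
    "Ensemble",
    "ContinuousSpectrum",
    "RegionMask",
    "BroadeningConfig",
    "SpectrumFormatError",
    "read_experimental_spectrum",
    "read_conformer_ensemble",
    "write_spectrum",
    "write_ensemble",
    "broaden",
    "scale_frequencies",
    "optimize_scaling",
    "apply_mask",
]

VA = "VA"
VCD = "VCD"


class SpectrumFormatError(ValueError):
    """Raised for unparseable or contract-violating spectral input."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class StickSpectrum:
    """Mode frequencies (cm^-1) with dipole and rotational strengths.

    Strengths are in arbitrary but mutually consistent units: the
    similarity measure used downstream is scale-invariant, so no
    conversion to molar absorptivity is required.
    """

    frequencies: np.ndarray
    dipole_strengths: np.ndarray
    rotational_strengths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "frequencies", _as_float_array(self.frequencies, "frequencies"))
        object.__setattr__(self, "dipole_strengths", _as_float_array(self.dipole_strengths, "dipole_strengths"))
        object.__setattr__(
            self, "rotational_strengths", _as_float_array(self.rotational_strengths, "rotational_strengths")
        )
        n = len(self.frequencies)
        if len(self.dipole_strengths) != n or len(self.rotational_strengths) != n:
            raise ValueError("frequencies, dipole and rotational strengths must have equal length")
        if n and np.any(self.frequencies <= 0):
            raise ValueError("mode frequencies must be strictly positive")
        if n and np.any(self.dipole_strengths < 0):
            raise ValueError("dipole strengths must be non-negative")

    def __len__(self) -> int:
        return len(self.frequencies)

    def strengths(self, which: str) -> np.ndarray:
        if which == VA:
            return self.dipole_strengths
        if which == VCD:
            return self.rotational_strengths
        raise ValueError(f"mode must be 'VA' or 'VCD', got {which!r}")


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer: a label, a relative energy (kcal/mol) and its sticks."""

    id: str
    energy: float
    sticks: StickSpectrum

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ValueError(f"conformer {self.id!r}: energy must be finite")


class Ensemble:
    """Ordered collection of conformers with relative energies.

    Energies are shifted on construction so the lowest conformer sits at
    zero.  Broadened per-conformer spectra are cached per (mode, grid)
    so that re-weighting during fitting costs a single matrix product.
    """

    def __init__(self, conformers: Sequence[ConformerRecord]):
        conformers = list(conformers)
        if not conformers:
            raise ValueError("an ensemble needs at least one conformer")
        ids = [c.id for c in conformers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate conformer id(s): {dup}")
        e0 = min(c.energy for c in conformers)
        self.conformers: list[ConformerRecord] = [replace(c, energy=c.energy - e0) for c in conformers]
        self._broadened: dict = {}

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i) -> ConformerRecord:
        return self.conformers[i]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conformers]

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def subset(self, indices: Iterable[int]) -> "Ensemble":
        indices = list(indices)
        sub = Ensemble([self.conformers[i] for i in indices])
        for key, matrix in self._broadened.items():  # reuse broadened rows
            sub._broadened[key] = matrix[indices]
        return sub

    def within_window(self, window: float) -> "Ensemble":
        """Conformers with relative energy <= window (kcal/mol)."""
        keep = [i for i, c in enumerate(self.conformers) if c.energy <= window]
        if not keep:
            raise ValueError(f"no conformer within the {window} kcal/mol window")
        return self.subset(keep)

    def without(self, conformer_id: str) -> "Ensemble":
        keep = [i for i, c in enumerate(self.conformers) if c.id != conformer_id]
        if len(keep) == len(self.conformers):
            raise KeyError(f"unknown conformer id {conformer_id!r}")
        if not keep:
            raise ValueError("cannot remove the only conformer")
        return self.subset(keep)

    def mirrored(self) -> "Ensemble":
        """The opposite enantiomer: rotational strengths negated, VA unchanged."""
        out = Ensemble(
            [
                ConformerRecord(
                    c.id,
                    c.energy,
                    StickSpectrum(
                        c.sticks.frequencies, c.sticks.dipole_strengths, -c.sticks.rotational_strengths
                    ),
                )
                for c in self.conformers
            ]
        )
        for (which, key), matrix in self._broadened.items():
            out._broadened[(which, key)] = -matrix if which == VCD else matrix
        return out

    def scaled(self, factor: float) -> "Ensemble":
        return Ensemble(
            [ConformerRecord(c.id, c.energy, scale_frequencies(c.sticks, factor)) for c in self.conformers]
        )

    def broadened_matrix(self, which: str, cfg: "BroadeningConfig") -> np.ndarray:
        """(n_conformers, n_grid) matrix of broadened spectra; cached."""
        key = (which, cfg.key())
        if key not in self._broadened:
            grid = cfg.grid()
            self._broadened[key] = np.vstack(
                [_lorentzian_sum(c.sticks.frequencies, c.sticks.strengths(which), grid, cfg.fwhm) for c in self]
            )
        return self._broadened[key]


@dataclass(frozen=True)
class ContinuousSpectrum:
    """Intensities on an ascending wavenumber grid.

    ``measured`` flags grid points that were actually covered by the
    experimental data (points outside the measured range are stored as
    zero and excluded from similarity evaluation).
    """

    grid: np.ndarray
    values: np.ndarray
    mode: str = VCD
    measured: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "grid", _as_float_array(self.grid, "grid"))
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must have the same length")
        if len(self.grid) == 0:
            raise ValueError("empty grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if self.mode not in (VA, VCD):
            raise ValueError(f"mode must be 'VA' or 'VCD', got {self.mode!r}")
        if self.measured is not None:
            m = np.asarray(self.measured, dtype=bool)
            if len(m) != len(self.grid):
                raise ValueError("measured flags must match the grid length")
            object.__setattr__(self, "measured", m)

    def __len__(self) -> int:
        return len(self.grid)

    def negated(self) -> "ContinuousSpectrum":
        return ContinuousSpectrum(self.grid, -self.values, self.mode, self.measured)


@dataclass(frozen=True)
class RegionMask:
    """Wavenumber intervals [lo, hi) that are INCLUDED in comparisons."""

    intervals: tuple

    def __init__(self, intervals: Iterable[Sequence[float]]):
        ivs = sorted((float(lo), float(hi)) for lo, hi in intervals)
        for lo, hi in ivs:
            if not lo < hi:
                raise ValueError(f"interval [{lo}, {hi}) requires lo < hi")
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                raise ValueError(f"overlapping intervals [{lo1},{hi1}) and [{lo2},{hi2})")
        object.__setattr__(self, "intervals", tuple(ivs))

    @classmethod
    def excluding(cls, excluded: Iterable[Sequence[float]], span: Sequence[float]) -> "RegionMask":
        """Mask including everything in ``span`` except the given intervals."""
        lo, hi = float(span[0]), float(span[1])
        cuts = sorted((float(a), float(b)) for a, b in excluded)
        included = []
        cursor = lo
        for a, b in cuts:
            if a > cursor:
                included.append((cursor, min(a, hi)))
            cursor = max(cursor, b)
        if cursor < hi:
            included.append((cursor, hi))
        # [lo, hi) excluded regions leave the point at hi itself included:
        # use a half-open interval ending just past the span end.
        return cls([(a, b) for a, b in included if a < b])

    def indicator(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        keep = np.zeros(len(grid), dtype=bool)
        for lo, hi in self.intervals:
            keep |= (grid >= lo) & (grid < hi)
        return keep

    @classmethod
    def parse(cls, text: str) -> "RegionMask":
        """Parse ``lo:hi[,lo:hi...]`` (cm^-1, included intervals)."""
        ivs = []
        for part in text.split(","):
            lo, hi = part.split(":")
            ivs.append((float(lo), float(hi)))
        return cls(ivs)


@dataclass(frozen=True)
class BroadeningConfig:
    """Lorentzian broadening and comparison-grid settings.

    The default grid, 900-1700 cm^-1 at 1 cm^-1, covers the mid-IR
    fingerprint region in which VA/VCD assignment work is done.  The
    step must resolve the lineshape (step <= FWHM/4).
    """

    fwhm: float = 8.0
    grid_lo: float = 900.0
    grid_hi: float = 1700.0
    grid_step: float = 1.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.grid_step <= 0 or self.grid_hi <= self.grid_lo:
            raise ValueError("grid bounds/step invalid")
        if self.grid_step > self.fwhm / 4:
            raise ValueError("grid step must be <= FWHM/4 to sample the lineshape")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def key(self) -> tuple:
        return (self.fwhm, self.grid_lo, self.grid_hi, self.grid_step)


def _lorentzian_sum(freqs: np.ndarray, strengths: np.ndarray, grid: np.ndarray, fwhm: float) -> np.ndarray:
    """Area-normalised Lorentzian broadening: each mode contributes its
    strength to the integral of the band."""
    if len(freqs) == 0:
        return np.zeros_like(grid)
    half = fwhm / 2.0
    # (n_modes, n_grid) kernel; fine at the mode counts of conformer spectra
    d = grid[None, :] - freqs[:, None]
    kern = (fwhm / (2.0 * np.pi)) / (d * d + half * half)
    return strengths @ kern


def broaden(sticks: StickSpectrum, which: str, cfg: BroadeningConfig) -> ContinuousSpectrum:
    """Convolve a stick spectrum with a unit-area Lorentzian lineshape."""
    grid = cfg.grid()
    if len(grid) == 0:
        raise ValueError("empty grid")
    vals = _lorentzian_sum(sticks.frequencies, sticks.strengths(which), grid, cfg.fwhm)
    return ContinuousSpectrum(grid, vals, mode=which)


def scale_frequencies(sticks: StickSpectrum, factor: float) -> StickSpectrum:
    """Multiply all mode frequencies by a global scaling factor."""
    if not 0.9 <= factor <= 1.1:
        raise ValueError(f"scaling factor {factor} outside [0.9, 1.1]")
    return StickSpectrum(sticks.frequencies * factor, sticks.dipole_strengths, sticks.rotational_strengths)


def apply_mask(spectrum: ContinuousSpectrum, mask: RegionMask) -> ContinuousSpectrum:
    """Restrict a spectrum to the grid points inside the included intervals."""
    keep = mask.indicator(spectrum.grid)
    if not keep.any():
        raise ValueError("region mask covers no grid point")
    measured = spectrum.measured[keep] if spectrum.measured is not None else None
    return ContinuousSpectrum(spectrum.grid[keep], spectrum.values[keep], spectrum.mode, measured)


# ---------------------------------------------------------------------------
# file I/O


def _read_two_column(path: Path) -> np.ndarray:
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}: expected two columns, got {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}: non-numeric data in {raw!r}") from exc
    return np.array(rows, dtype=float)


def _read_jcamp(path: Path) -> np.ndarray:
    """Minimal JCAMP-DX reader: XYDATA=(X++(Y..Y)) and XYPOINTS dialects."""
    text = path.read_text()
    fields: dict[str, str] = {}
    data_label = None
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$", 1)[0].rstrip()
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label in ("XYDATA", "XYPOINTS"):
                data_label, in_data = label, True
                continue
            if label == "END":
                in_data = False
            fields[label] = value
            continue
        if in_data and line.strip():
            data_lines.append(line.strip())
    if data_label is None:
        raise SpectrumFormatError(f"{path}: no XYDATA/XYPOINTS block found")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    pts: list[tuple[float, float]] = []
    if data_label == "XYPOINTS":
        for line in data_lines:
            for pair in re.split(r";", line):
                pair = pair.strip()
                if not pair:
                    continue
                xy = re.split(r"[,\s]+", pair)
                pts.append((float(xy[0]) * xfac, float(xy[1]) * yfac))
    else:  # XYDATA (X++(Y..Y)): first number is X of the first Y on the line
        npoints = int(float(fields["NPOINTS"])) if "NPOINTS" in fields else None
        firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else None
        lastx = float(fields["LASTX"]) if "LASTX" in fields else None
        if "DELTAX" in fields:
            dx = float(fields["DELTAX"])
        elif npoints and npoints > 1 and firstx is not None and lastx is not None:
            dx = (lastx - firstx) / (npoints - 1)
        else:
            raise SpectrumFormatError(f"{path}: cannot determine DELTAX")
        for line in data_lines:
            nums = [float(t) for t in re.split(r"[,\s]+", line) if t]
            x = nums[0] * xfac
            for y in nums[1:]:
                pts.append((x, y * yfac))
                x += dx * xfac
    return np.array(pts, dtype=float)


def read_experimental_spectrum(
    path, mode: str = VCD, cfg: BroadeningConfig | None = None
) -> ContinuousSpectrum:
    """Load a measured spectrum and resample it onto the comparison grid.

    Accepts two-column delimited text (wavenumber, intensity) or simple
    JCAMP-DX.  Values are linearly interpolated onto the uniform grid of
    ``cfg``; grid points outside the measured wavenumber range are set
    to zero and flagged unmeasured so that similarity evaluation skips
    them.
    """
    cfg = cfg or BroadeningConfig()
    path = Path(path)
    head = path.read_text()[:200].lstrip()
    data = _read_jcamp(path) if head.startswith("##") else _read_two_column(path)
    if len(data) < 2:
        raise SpectrumFormatError(f"{path}: need at least 2 data points")
    order = np.argsort(data[:, 0], kind="stable")
    x, y = data[order, 0], data[order, 1]
    if np.any(np.diff(x) <= 0):
        raise SpectrumFormatError(f"{path}: duplicate wavenumbers after sorting")
    grid = cfg.grid()
    vals = np.interp(grid, x, y, left=0.0, right=0.0)
    measured = (grid >= x[0]) & (grid <= x[-1])
    vals[~measured] = 0.0
    return ContinuousSpectrum(grid, vals, mode=mode, measured=measured)


def write_spectrum(spectrum: ContinuousSpectrum, path) -> None:
    """Write a spectrum as two-column text (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write(f"# wavenumber_cm-1 intensity ({spectrum.mode})\n")
        for x, y in zip(spectrum.grid, spectrum.values):
            fh.write(f"{x:.12g} {y:.12g}\n")


def read_conformer_ensemble(path) -> Ensemble:
    """Read an ensemble from a manifest ``id,energy_kcal,sticks_path``.

    Stick files are 3-column text: wavenumber (cm^-1), dipole strength,
    rotational strength.  Relative paths are resolved against the
    manifest location.  Energies are shifted so the minimum is zero.
    """
    path = Path(path)
    base = path.parent
    conformers = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "energy_kcal", "sticks_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SpectrumFormatError(f"{path}: manifest must have columns {sorted(required)}")
        for row in reader:
            sticks_path = base / row["sticks_path"]
            if not sticks_path.exists():
                raise SpectrumFormatError(f"missing stick file {sticks_path}")
            table = np.atleast_2d(np.loadtxt(sticks_path, comments="#", ndmin=2))
            if table.size and table.shape[1] != 3:
                raise SpectrumFormatError(f"{sticks_path}: expected 3 columns, got {table.shape[1]}")
            sticks = StickSpectrum(table[:, 0], table[:, 1], table[:, 2])
            conformers.append(ConformerRecord(row["id"], float(row["energy_kcal"]), sticks))
    return Ensemble(conformers)


def write_ensemble(ensemble: Ensemble, out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write manifest + per-conformer stick files; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "energy_kcal", "sticks_path"])
        for c in ensemble:
            fname = f"{c.id}.sticks"
            writer.writerow([c.id, f"{c.energy:.12g}", fname])
            with open(out_dir / fname, "w") as sf:
                sf.write("# wavenumber_cm-1 dipole_strength rotational_strength\n")
                for f0, d, r in zip(c.sticks.frequencies, c.sticks.dipole_strengths, c.sticks.rotational_strengths):
                    sf.write(f"{f0:.12g} {d:.12g} {r:.12g}\n")
    return manifest


def optimize_scaling(
    ensemble: Ensemble,
    weights,
    exp_va: ContinuousSpectrum,
    bounds: tuple[float, float] = (0.95, 1.05),
    step: float = 0.001,
    cfg: BroadeningConfig | None = None,
) -> float:
    """Grid-search the global frequency-scaling factor on the VA spectrum.

    Returns the factor maximising the VA overlap between the weighted
    broadened ensemble and experiment; ties break toward the factor
    nearest 1 (no scaling preferred when the data cannot decide).
    """
    from .similarity import sim_overlap  # local import avoids a cycle

    cfg = cfg or BroadeningConfig()
    lo, hi = bounds
    if not (0.9 <= lo < hi <= 1.1):
        raise ValueError("scaling bounds must satisfy 0.9 <= lo < hi <= 1.1")
    if exp_va.mode != VA:
        raise ValueError("optimize_scaling requires a VA experimental spectrum")
    weights = np.asarray(weights, dtype=float)
    factors = np.arange(lo, hi + step / 2, step)
    grid = cfg.grid()
    best: tuple | None = None
    for f in factors:
        vals = np.zeros_like(grid)
        for w, c in zip(weights, ensemble):
            if w == 0.0:
                continue
            vals += w * _lorentzian_sum(c.sticks.frequencies * f, c.sticks.dipole_strengths, grid, cfg.fwhm)
        if not np.any(vals):
            raise ValueError("ensemble VA spectrum is identically zero")
        s = sim_overlap(ContinuousSpectrum(grid, vals, mode=VA), exp_va)
        cand = (s, -abs(f - 1.0), f)
        if best is None or cand[:2] > best[:2]:
            best = cand
    return float(best[2])
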