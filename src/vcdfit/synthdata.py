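"""Synthetic conformer ensembles with known ground truth.

Real inputs to population fitting are DFT stick spectra with energies
that carry an error of order 1-2 kcal/mol, and a measured spectrum that
reflects the *true* thermal populations plus baseline noise.  The
generator reproduces that statistical structure:

* all conformers of one molecule share a common set of normal modes: a
  mode template (frequencies, log-normal dipole strengths, rotational
  strength magnitudes) is drawn once, and each conformer perturbs it —
  small frequency shifts, multiplicative intensity jitter.  A
  configurable fraction of modes is *sign-opposing*: their VCD sign is
  drawn per conformer, giving the partially opposing band patterns
  that make conformer weighting matter and enantiomer discrimination
  non-trivial.  The remaining modes keep the template sign in every
  conformer, which is why even a badly weighted composite retains some
  resemblance to the experiment, as observed with real ensembles;
* true energies are drawn from an exponential distribution (many
  low-lying conformers, few high ones); the ensemble handed to fitting
  carries *reported* energies corrupted by Gaussian error of width
  sigma_E, mimicking DFT energy uncertainty;
* the pseudo-experiment is built from the TRUE stick frequencies and
  TRUE Boltzmann weights, plus Gaussian baseline noise, while the
  fitting ensemble carries frequencies perturbed by a few cm^-1 —
  so recovering the truth is exactly as hard as with real data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import (
    VA,
    VCD,
    BroadeningConfig,
    ConformerRecord,
    ContinuousSpectrum,
    Ensemble,
    StickSpectrum,
    write_ensemble,
    write_spectrum,
)
from .weighting import ThermoConfig, boltzmann_weights, composite_spectrum

__all__ = ["SynthConfig", "GroundTruth", "generate_ensemble", "generate_experiment", "make_fixture_suite"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults mimic routine mid-IR DFT output."""

    n_conformers: int = 10
    n_modes: int = 30
    freq_lo: float = 950.0
    freq_hi: float = 1650.0
    dipole_lognorm_mu: float = 0.0
    dipole_lognorm_sigma: float = 0.8
    rotational_scale: float = 0.05  # |R| ~ this fraction of the dipole scale
    opposing_mode_fraction: float = 0.3  # modes whose VCD sign is per-conformer
    mode_freq_jitter: float = 5.0  # cm^-1 conformer-to-conformer frequency spread
    dipole_jitter_sigma: float = 0.3  # lognormal intensity jitter per conformer
    rot_jitter_sigma: float = 1.0  # lognormal |R| jitter (R is very conformation-sensitive)
    energy_mean: float = 1.0  # exponential law for true energies (kcal/mol)
    energy_error_sigma: float = 0.0  # Gaussian error on reported energies
    # None: errors i.i.d. per conformer.  An integer g assigns conformers
    # at random to g families whose errors share a common component —
    # emulating DFT errors that are systematic within conformer
    # families rather than independent per conformer.  The family
    # component carries a fraction rho of the error variance.
    energy_error_groups: int | None = None
    energy_error_rho: float = 1.0
    # None: opposing-mode VCD signs are independent across conformers.
    # A float lambda (kcal/mol) makes sign patterns evolve along the
    # energy axis instead: the global minimum carries the template
    # pattern and each opposing mode of conformer i is flipped with
    # probability saturation*(1 - exp(-E_i/lambda)).  Near-degenerate
    # conformers then share most of their VCD signature (variants of
    # one structural motif) while high-energy ones progressively show
    # opposing band signs — as if the region were compared between the
    # two enantiomers (saturation near 1 makes them quasi-mirrors).
    sign_flip_energy_scale: float | None = None
    sign_flip_saturation: float = 0.5
    baseline_noise: float = 0.02  # fraction of max |signal| per channel
    freq_perturbation_sigma: float = 3.0  # cm^-1 between true and reported sticks
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self):
        if self.n_conformers < 1:
            raise ValueError("need at least one conformer")
        if self.n_modes < 1:
            raise ValueError("need at least one mode")
        for name in ("energy_error_sigma", "baseline_noise", "freq_perturbation_sigma",
                     "dipole_lognorm_sigma", "rotational_scale", "mode_freq_jitter",
                     "dipole_jitter_sigma", "rot_jitter_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.opposing_mode_fraction <= 1.0:
            raise ValueError("opposing_mode_fraction must lie in [0, 1]")
        if not 0.0 <= self.energy_error_rho <= 1.0:
            raise ValueError("energy_error_rho must lie in [0, 1]")
        if not 0.0 <= self.sign_flip_saturation <= 1.0:
            raise ValueError("sign_flip_saturation must lie in [0, 1]")
        if self.freq_hi <= self.freq_lo:
            raise ValueError("frequency range invalid")


@dataclass
class GroundTruth:
    """What the generator knows and the fitter must recover."""

    true_energies: np.ndarray
    true_weights: np.ndarray
    reported_energies: np.ndarray
    true_ensemble: Ensemble = field(repr=False)
    seed: int = 0


def _draw_template(rng, cfg: SynthConfig):
    """One molecule's normal-mode template shared by all conformers."""
    freqs = np.sort(rng.uniform(cfg.freq_lo, cfg.freq_hi, cfg.n_modes))
    dip = rng.lognormal(cfg.dipole_lognorm_mu, cfg.dipole_lognorm_sigma, cfg.n_modes)
    rot_mag = cfg.rotational_scale * dip * np.abs(rng.normal(0.0, 1.0, cfg.n_modes))
    rot_sign = rng.choice([-1.0, 1.0], cfg.n_modes)
    n_opp = int(round(cfg.opposing_mode_fraction * cfg.n_modes))
    opposing = np.zeros(cfg.n_modes, dtype=bool)
    opposing[rng.choice(cfg.n_modes, n_opp, replace=False)] = True
    return freqs, dip, rot_mag, rot_sign, opposing


def draw_true_energies(rng, cfg: SynthConfig) -> np.ndarray:
    e = np.sort(rng.exponential(cfg.energy_mean, cfg.n_conformers))
    return e - e[0]


def generate_ensemble(cfg: SynthConfig, true_energies=None) -> tuple[Ensemble, GroundTruth]:
    """Draw an ensemble; returns (ensemble as handed to fitting, truth).

    The returned ensemble carries the *reported* (corrupted) energies
    and the frequency-perturbed stick spectra; the GroundTruth carries
    the true energies, true Boltzmann weights and the true-stick
    ensemble from which experiments are synthesised.  ``true_energies``
    overrides the default exponential energy law (fixtures use this to
    impose specific energy ladders).
    """
    rng = np.random.default_rng(cfg.seed)
    tf, td, tmag, tsign, opposing = _draw_template(rng, cfg)
    true_conformers, reported_conformers = [], []
    if true_energies is None:
        true_energies = draw_true_energies(rng, cfg)
    else:
        true_energies = np.asarray(true_energies, dtype=float)
        if len(true_energies) != cfg.n_conformers:
            raise ValueError("true_energies length must equal n_conformers")
        true_energies = true_energies - true_energies.min()
    if cfg.energy_error_groups:
        gids = rng.integers(0, cfg.energy_error_groups, cfg.n_conformers)
        shared = rng.normal(0.0, 1.0, cfg.energy_error_groups)[gids]
        own = rng.normal(0.0, 1.0, cfg.n_conformers)
        rho = cfg.energy_error_rho
        err = cfg.energy_error_sigma * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
    else:
        err = rng.normal(0.0, cfg.energy_error_sigma, cfg.n_conformers)
    reported = true_energies + err
    for i in range(cfg.n_conformers):
        f = np.abs(tf + rng.normal(0.0, cfg.mode_freq_jitter, cfg.n_modes))
        d = td * rng.lognormal(0.0, cfg.dipole_jitter_sigma, cfg.n_modes)
        if cfg.sign_flip_energy_scale is not None:
            p_flip = cfg.sign_flip_saturation * (
                1.0 - np.exp(-true_energies[i] / cfg.sign_flip_energy_scale)
            )
            flips = np.where(rng.random(cfg.n_modes) < p_flip, -1.0, 1.0)
            signs = np.where(opposing, tsign * flips, tsign)
        else:
            signs = np.where(opposing, rng.choice([-1.0, 1.0], cfg.n_modes), tsign)
        r = signs * tmag * rng.lognormal(0.0, cfg.rot_jitter_sigma, cfg.n_modes)
        cid = f"c{i:03d}"
        true_conformers.append(ConformerRecord(cid, float(true_energies[i]), StickSpectrum(f, d, r)))
        fp = np.abs(f + rng.normal(0.0, cfg.freq_perturbation_sigma, cfg.n_modes))
        reported_conformers.append(ConformerRecord(cid, float(reported[i]), StickSpectrum(fp, d, r)))
    true_ens = Ensemble(true_conformers)
    thermo = ThermoConfig(cfg.temperature)
    truth = GroundTruth(
        true_energies=true_energies,
        true_weights=boltzmann_weights(true_energies, thermo),
        reported_energies=reported - reported.min(),
        true_ensemble=true_ens,
        seed=cfg.seed,
    )
    return Ensemble(reported_conformers), truth


def generate_experiment(
    truth: GroundTruth,
    cfg: SynthConfig,
    broadening: BroadeningConfig | None = None,
) -> tuple[ContinuousSpectrum, ContinuousSpectrum]:
    """Pseudo-experimental (VA, VCD) spectra from the ground truth.

    Built from the true sticks and true Boltzmann weights, then
    degraded with Gaussian baseline noise scaled to the largest
    absolute intensity of each channel.
    """
    broadening = broadening or BroadeningConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    out = []
    for which in (VA, VCD):
        spec = composite_spectrum(truth.true_ensemble, truth.true_weights, which, broadening)
        scale = np.max(np.abs(spec.values))
        noise = rng.normal(0.0, cfg.baseline_noise * scale, len(spec.grid)) if cfg.baseline_noise else 0.0
        out.append(ContinuousSpectrum(spec.grid, spec.values + noise, mode=which))
    return out[0], out[1]


def make_overfit_ensemble(
    n_informative: int = 5,
    n_redundant: int = 55,
    energy_error_sigma: float = 1.0,
    baseline_noise: float = 0.05,
    seed: int = 0,
    broadening: BroadeningConfig | None = None,
):
    """The overfitting test bed: an experiment generated by a few
    conformers, fitted with many.

    The informative conformers carry true energies within ~1 kcal/mol
    of the floor (real thermal population); the redundant ones sit
    2.5-4 kcal/mol up, so their true weights are negligible and every
    bit of weight the fit puts on them is overfitting.  Their
    *reported* energies, however, are drawn low (0-2.5 kcal/mol) — the
    quantum chemistry has wrongly stabilised them — which is exactly
    what hands the fit the freedom to abuse them.
    Returns (ensemble, truth, exp_va, exp_vcd).
    """
    rng = np.random.default_rng(seed + 77003)
    low = np.sort(rng.uniform(0.0, 1.0, n_informative))
    low[0] = 0.0
    cfg = SynthConfig(
        n_conformers=n_informative,
        opposing_mode_fraction=1.0,  # every conformer its own VCD signature
        energy_error_sigma=0.0,
        freq_perturbation_sigma=1.0,
        baseline_noise=baseline_noise,
        seed=seed,
    )
    ens0, truth = generate_ensemble(cfg, true_energies=low)
    # informative conformers carry accurate-ish reported energies, so
    # the low-n subsets are the well-posed reference
    rep_low = low + rng.normal(0.0, energy_error_sigma / 2.0, n_informative)
    conformers = [
        ConformerRecord(c.id, float(e), c.sticks) for c, e in zip(ens0, rep_low)
    ]
    # redundant conformers: random spectra (their own mode positions),
    # truly unpopulated (2.5-4 kcal/mol) but wrongly stabilised into
    # the apparent 1-3 kcal/mol range, where a generous energy
    # modulation can reach them and fit experimental noise
    high = np.sort(rng.uniform(2.5, 4.0, n_redundant))
    rep_high = rng.uniform(1.0, 3.0, n_redundant)
    true_conformers = list(truth.true_ensemble.conformers)
    for j in range(n_redundant):
        f = np.sort(rng.uniform(cfg.freq_lo, cfg.freq_hi, cfg.n_modes))
        d = rng.lognormal(cfg.dipole_lognorm_mu, cfg.dipole_lognorm_sigma, cfg.n_modes)
        r = cfg.rotational_scale * d * rng.normal(0.0, 1.0, cfg.n_modes)
        cid = f"r{j:03d}"
        sticks = StickSpectrum(f, d, r)
        conformers.append(ConformerRecord(cid, float(rep_high[j]), sticks))
        true_conformers.append(ConformerRecord(cid, float(high[j]), sticks))
    ensemble = Ensemble(conformers)
    true_e = np.concatenate([low, high])
    thermo = ThermoConfig(cfg.temperature)
    truth = GroundTruth(
        true_energies=true_e,
        true_weights=boltzmann_weights(true_e, thermo),
        reported_energies=np.concatenate([rep_low, rep_high]),
        true_ensemble=Ensemble(true_conformers),
        seed=seed,
    )
    truth.reported_energies -= truth.reported_energies.min()
    exp_va, exp_vcd = generate_experiment(truth, cfg, broadening)
    return ensemble, truth, exp_va, exp_vcd


def make_enantiomer_ensemble(seed: int = 203, broadening: BroadeningConfig | None = None):
    """Study conditions for enantiomer discrimination with opposing bands.

    A large ensemble (162 conformers) in which 80% of the modes carry
    per-conformer VCD signs: enough opposing-sign structure that the
    *wrong* enantiomer can be fitted above the conventional 0.4
    overlap threshold, while the correct enantiomer still fits better
    by a clear margin — the situation in which only the overlap
    difference, not the absolute overlap, is meaningful.
    Returns (ensemble, truth, exp_va, exp_vcd).
    """
    cfg = SynthConfig(
        n_conformers=162, opposing_mode_fraction=0.8,
        energy_error_sigma=1.0, baseline_noise=0.05, seed=seed,
    )
    ensemble, truth = generate_ensemble(cfg)
    exp_va, exp_vcd = generate_experiment(truth, cfg, broadening)
    return ensemble, truth, exp_va, exp_vcd


def make_uncertainty_ensemble(
    energy_error_sigma: float,
    replicate: int = 0,
    broadening: BroadeningConfig | None = None,
):
    """One replicate of the energy-uncertainty study conditions.

    Mirrors the structure of a large solution-phase conformer search:
    162 conformers on a dense energy ladder (uniform over 0-3
    kcal/mol), VCD signatures that decorrelate along the energy axis
    (lambda = 0.75 kcal/mol) until high-energy conformers show
    enantiomer-like opposing band signs, and reported energies
    corrupted by i.i.d. Gaussian error of the given sigma.
    Returns (ensemble, truth, exp_va, exp_vcd).
    """
    rng = np.random.default_rng(50000 + replicate)
    ladder = np.sort(rng.uniform(0.0, 3.0, 162))
    cfg = SynthConfig(
        n_conformers=162,
        opposing_mode_fraction=1.0,
        sign_flip_energy_scale=0.75,
        sign_flip_saturation=1.0,
        mode_freq_jitter=2.0,
        rot_jitter_sigma=0.5,
        energy_error_sigma=energy_error_sigma,
        seed=700 + replicate,
    )
    ensemble, truth = generate_ensemble(cfg, true_energies=ladder)
    exp_va, exp_vcd = generate_experiment(truth, cfg, broadening)
    return ensemble, truth, exp_va, exp_vcd


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir) -> dict:
    """Write the canonical fixture families used by the test suite.

    Everything is derived from pinned seeds, so two runs produce
    byte-identical files; a ``checksums.json`` records SHA-256 digests.
    Returns a mapping from fixture name to its directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, ensemble, truth, exp_va, exp_vcd):
        d = out_dir / name
        d.mkdir(exist_ok=True)
        write_ensemble(ensemble, d)
        write_spectrum(exp_va, d / "exp_va.dat")
        write_spectrum(exp_vcd, d / "exp_vcd.dat")
        sidecar = {
            "seed": int(truth.seed),
            "true_energies": [float(x) for x in truth.true_energies],
            "true_weights": [float(x) for x in truth.true_weights],
            "reported_energies": [float(x) for x in truth.reported_energies],
        }
        (d / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
        written[name] = d

    # 2-conformer oracle set (GA vs exhaustive 1-D scan)
    cfg2 = SynthConfig(n_conformers=2, energy_error_sigma=0.5, seed=201)
    ens, truth = generate_ensemble(cfg2)
    exp_va, exp_vcd = generate_experiment(truth, cfg2)
    emit("two_conformer", ens, truth, exp_va, exp_vcd)

    # 5-informative / 55-redundant overfitting set
    ens, truth, exp_va, exp_vcd = make_overfit_ensemble(seed=202)
    emit("overfit_60", ens, truth, exp_va, exp_vcd)

    # opposing-sign enantiomer set: the mirror enantiomer fits above
    # the naive 0.4 threshold, yet the overlap difference discriminates
    ens, truth, exp_va, exp_vcd = make_enantiomer_ensemble(seed=203)
    emit("enantiomer_opposing", ens, truth, exp_va, exp_vcd)

    # energy-uncertainty sets at sigma_E in {0, 1, 2.5} (first replicate each)
    for sig in (0.0, 1.0, 2.5):
        ens, truth, exp_va, exp_vcd = make_uncertainty_ensemble(sig, replicate=0)
        emit(f"uncertainty_sigma_{sig:g}".replace(".", "p"), ens, truth, exp_va, exp_vcd)

    checksums = {}
    for name, d in written.items():
        checksums[name] = {p.name: _sha256(p) for p in sorted(d.iterdir())}
    (out_dir / "checksums.json").write_text(json.dumps(checksums, indent=1))
    return written
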