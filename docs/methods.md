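# Methods

## Model

A flexible chiral molecule at temperature T populates conformers
i = 1…N with thermal weights w_i ∝ exp(−E_i/k_B T).  Its VA/VCD
spectrum is modelled as the weighted sum of per-conformer spectra,
each obtained by convolving the conformer's stick spectrum (mode
wavenumbers ν_k with dipole strengths D_k for VA and rotational
strengths R_k for VCD) with a unit-area Lorentzian,

    L(ν; ν_k, Γ) = (Γ/2π) / ((ν − ν_k)² + (Γ/2)²),

so every mode contributes exactly its strength to the band integral.
The default linewidth is Γ = 8 cm⁻¹ FWHM, typical of solution-phase
mid-IR spectra, on a 900–1700 cm⁻¹ grid at 1 cm⁻¹ (the grid step must
satisfy step ≤ Γ/4 to resolve the lineshape).

Computed harmonic frequencies carry a systematic error; a single
global multiplicative scaling factor is fitted by grid search (default
step 0.001 within [0.95, 1.05]) maximizing the VA overlap.  The VA
channel is used because it is insensitive to the sign errors that make
VCD fragile.  A per-interval (piecewise) scaling would be a natural
extension but is deliberately not the default: with one factor the
procedure cannot absorb band-shape misfit into frequency distortion.

### Energy modulations

Relative DFT conformer energies have errors of order 1–2 kcal/mol
while k_B T at 298.15 K is only 0.5925 kcal/mol (k_B = 0.0019872041
kcal mol⁻¹ K⁻¹, pinned to 7 digits for bit-reproducible output), so
computed Boltzmann weights can be qualitatively wrong.  The fit
replaces E_i by E_i + δ_i with |δ_i| ≤ ΔE^max and optimizes the δ
vector.  ΔE^max encodes the trusted accuracy of the quantum chemistry:
1 kcal/mol is a sensible default for good DFT; a scan over ΔE^max is
cheap and more informative than any single value.  Since Boltzmann
weights are invariant under a uniform energy shift, the δ vector has a
gauge freedom; fitted results keep the raw bounded deltas and report
re-centred adjusted energies with min(E+δ) = 0.

### Similarity

Spectra are compared with the cosine of a trapezoid-weighted inner
product over the comparison points,

    Sim = ⟨f, g⟩ / (‖f‖ ‖g‖) ∈ [−1, +1],

which is scale-invariant (no intensity-unit conventions needed),
antisymmetric under negation (−1 for the mirror enantiomer), and +1
only for proportional spectra.  A Tanimoto variant
⟨f,g⟩/(‖f‖²+‖g‖²−⟨f,g⟩) is available for workflows that calibrate
absolute intensities.  Comparison points are the grid points inside
the region mask, inside the experiment's measured range; masked grids
may contain gaps, and the quadrature weights are computed per
contiguous segment so excluded regions contribute nothing.

### Genetic algorithm

The genome is the modulation vector δ ∈ [−ΔE^max, +ΔE^max]^N.
Defaults: population 128, up to 300 generations, tournament selection
(size 3) with an infinitesimal parsimony bias toward smaller ‖δ‖₂ on
fitness ties, uniform crossover (rate 0.7), per-gene Gaussian mutation
(rate 0.2, σ = ΔE^max/10) clipped to bounds, elitism 2, and a
stagnation stop (improvement < 1e−6 over 50 generations).  Fitness is
the VCD overlap; an α-mixed α·SimVA + (1−α)·SimVCD fitness is
available (α = 0 by default, since the VA spectrum constrains weights
only weakly and the VCD overlap is the quantity of interest).  Two
structural guarantees matter more than the operator details:

- the all-zero genome (the plain Boltzmann solution) is seeded into
  every initial population, so the fitted overlap can never fall below
  the unfitted one;
- a ΔE^max scan warm-starts each fit with the optimum of the previous,
  smaller bound, making the fitted-overlap curve provably
  non-decreasing (the feasible sets are nested).

Fitness evaluation is vectorized: broadened conformer spectra are
cached as an N×G matrix, so one generation costs a single matrix
product; a full fit of a 162-conformer ensemble takes on the order of
a second.  All randomness flows from one integer seed; identical seeds
give bit-identical results.

`fit_free` removes the energy constraint entirely by optimizing
softmax-parameterized genes on the probability simplex; its result is
independent of the starting energies (verified by a shift test) and is
the right tool for asking "what populations does the spectrum alone
support?".  With it, reported deltas are −k_B T ln w re-centred minus
the computed energies.  Two conformers with identical spectra leave
the split between them undetermined; this flat direction is reported,
not treated as an error.

### Cross-validation

Point-wise folds would leak: adjacent grid points within a linewidth
are almost perfectly correlated.  The masked grid is therefore cut
into contiguous blocks of width 2Γ (16 points by default), blocks are
shuffled with a seeded permutation and dealt round-robin into k = 5
folds; fits run on the training blocks and are scored on the held-out
blocks.  The mean of per-fold test overlaps is reported; an
alternative pooled mode scores one overlap over all held-out points,
each predicted by the fold that held it out.  Overfitting shows up as
(a) test overlap falling below training overlap, and (b) the test
overlap versus ensemble-size curve peaking at small ensembles and then
declining — at that point adding conformers adds fitting freedom, not
information.  Restricting ΔE^max can also suppress overfitting, but
then fitted energies pile up at the bounds and the weights are not
truly optimized, so a tight ΔE^max is supported but discouraged as an
overfitting control.

### Enantiomer discrimination

The mirror ensemble negates every rotational strength (VA unchanged).
Both enantiomers are fitted with the same protocol; the verdict is
"assigned" only if SimVCD(correct) − SimVCD(mirror) ≥ 0.4.  The
difference, not the absolute overlap, is thresholded: with a hundred
or more conformers carrying partially opposing band signs, the wrong
enantiomer alone routinely fits above 0.4.  The 0.4 value mirrors the
threshold in common use for unfitted comparisons and is configurable.

### Energy-uncertainty estimator

For energy windows E_w on a grid (default 0.25–3 kcal/mol, step 0.25),
the overlap of the equal-weight (arithmetic-mean) composite and of the
Boltzmann composite over conformers with E ≤ E_w are compared.  If the
energies were exact, Boltzmann weighting would win everywhere
(estimate 0).  Errors of size σ scramble the ranking of conformers
within ~σ of the floor, so the two methods perform similarly up to a
window ≈ σ; beyond it the Boltzmann composite's suppression of
genuinely high-energy conformers wins while the mean dilutes.  The
estimator returns the smallest window from which the Boltzmann curve
dominates for all larger windows on the grid; if the mean wins through
the top of the grid the value is flagged as a lower bound.

## Synthetic data

The generator emulates the statistical structure of real inputs
rather than any specific molecule:

- **Mode template.** All conformers of one molecule share a set of
  normal modes.  A template (30 modes uniform over 950–1650 cm⁻¹,
  log-normal dipole strengths with σ = 0.8, rotational-strength
  magnitudes at 5% of the dipole scale) is drawn once; each conformer
  perturbs it with frequency shifts (σ = 5 cm⁻¹) and multiplicative
  intensity jitter (log-normal σ = 0.3 for D, 1.0 for R — rotational
  strengths are far more conformation-sensitive than dipole
  strengths).
- **Sign opposition.** A fraction of modes (default 0.3) carries a
  per-conformer VCD sign; the rest keep the template sign in every
  conformer.  Optionally the sign pattern decorrelates along the
  energy axis (flip probability saturating with E), so near-degenerate
  conformers look like variants of one motif while high-energy ones
  progressively show enantiomer-like opposing bands.
- **Energies.** True energies follow an exponential law (mean 1
  kcal/mol) unless an explicit ladder is imposed; reported energies
  add Gaussian error of width σ_E, either i.i.d. per conformer or with
  a family-correlated component (errors shared within random groups),
  emulating DFT errors that are systematic within conformer families.
- **Experiment.** Pseudo-experimental spectra are built from the
  *true* stick frequencies and *true* Boltzmann weights, plus Gaussian
  baseline noise (2% of the peak intensity by default), while the
  ensemble handed to fitting carries the perturbed frequencies
  (σ = 3 cm⁻¹) and corrupted energies — recovery is therefore exactly
  as hard as with real data.

What the generator does **not** emulate: solvent-induced band-shape
changes, baseline drift and artefacts of real VCD measurements,
anharmonic couplings, or mode-by-mode resemblance to any real
molecule.  Passing tests demonstrate that the machinery behaves
correctly under the stated statistical conditions, not that any
particular real assignment is right.

### Canonical fixtures

- *Two-conformer problems* (σ_E = 0.5): the single free direction
  δ₂ − δ₁ admits an exhaustive scan at 0.001 kcal/mol, the independent
  oracle against which the GA is verified.
- *Overfit set*: 5 informative conformers (true energies within 1
  kcal/mol, accurate-ish reported energies) plus 55 redundant ones
  with their own random mode positions, truly unpopulated (2.5–4
  kcal/mol) but wrongly stabilised into an apparent 1–3 kcal/mol
  range.  Junk bands at foreign frequencies fit training noise and
  actively damage held-out blocks — the ingredient that produces the
  test-overlap decline and the interior maximum of the test overlap
  along a ΔE^max scan.
- *Enantiomer set*: 162 conformers with 80% opposing modes and σ_E = 1;
  the mirror enantiomer fits to ≈ 0.47–0.50 (above the naive 0.4
  threshold) while the correct one fits to ≈ 0.94, so only the
  difference criterion discriminates.
- *Uncertainty sets*: 162 conformers on a dense uniform ladder
  (0–3 kcal/mol), fully opposing modes whose signs decorrelate with
  energy (λ = 0.75 kcal/mol, saturating at full inversion), i.i.d.
  energy errors σ_E ∈ {0, 1, 2.5}.  This structure is essential: with
  independent conformer spectra and i.i.d. errors larger than k_B T,
  the corrupted Boltzmann composite collapses onto near-arbitrary
  single conformers and the arithmetic mean wins at *every* window, so
  no crossover exists to read.  High-energy conformers with
  enantiomer-like opposing bands make the mean degrade as the window
  grows, restoring the crossover that real ensembles show.

## Numerical choices and edge cases

- Overlaps are clipped to [−1, 1] after rounding error; zero-norm
  spectra raise instead of returning 0, because an all-zero VCD
  comparison is undefined, not "orthogonal".
- Energies are min-shifted to 0 on ensemble construction; Boltzmann
  weights are computed shift-stably (max subtraction before
  exponentiation).
- Degenerate GA fitness ties break toward the smallest ‖δ‖₂ (stay
  closest to the computed energies).
- Single-conformer ensembles short-circuit the GA: the weight vector
  is [1] for every δ, so the fit is the plain overlap.
- Experimental points outside the measured wavenumber range are stored
  as zeros and excluded from every comparison via a measured-point
  mask; masks given by the user compose with it.

## Problem sizes

The shipped tests and the acceptance checks run ensembles up to 162
conformers, grids of 801 points, GA populations of 64–128 over up to
300 generations, and 5-fold cross-validation scans over 8 ensemble
sizes and 5 modulation bounds — sizes chosen so the full suite
completes in well under a minute while exercising every code path at
realistic conformer counts.

## Known limitations

- The global frequency-scaling surrogate cannot reproduce
  interval-dependent scaling schemes; strongly anharmonic regions
  should instead be excluded with a region mask.
- The uncertainty estimator reads a crossover on a finite window grid;
  when the Boltzmann composite never dominates it can only report a
  lower bound, and its calibration depends on the ensemble showing the
  energy-decorrelated spectral structure described above.
- Fitted weights are point estimates; their spread across
  cross-validation folds is the only uncertainty measure provided.
- JCAMP-DX support covers the two plain-text dialects named above; no
  compressed (DIF/DUP/SQZ) forms.
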