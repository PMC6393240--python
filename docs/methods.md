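# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## CSP mapping

Each backbone amide reports a weighted combined shift change between the
apo reference spectrum and a titration endpoint:

    CSP = sqrt( 1/2 [ Δδ_H² + (w·Δδ_N)² ] ),   w = 0.14 by default.

The ¹⁵N weight compensates the wider ¹⁵N ppm scale. As commonly printed,
this equation is typographically ambiguous
between `(w·Δδ_N)²` and `w·Δδ_N²`; the squared-weight convention is the
field standard and is the default (`scaled_squared`), the literal reading
is available (`literal`), and every profile records which was used. The
two coincide when w = 1 or Δδ_N = 0, which the tests exploit.

Significance is judged against μ + σ and μ + 2σ of the CSP distribution of
all residues observed at both endpoints. Choices:

* σ is the population standard deviation (divides by n) by default; the
  sample estimator is a flag, and the choice is recorded in the profile
  metadata.
* "above" means strictly greater than the threshold.
* Residues lost at the endpoint (broadened beyond detection or overlapped)
  are excluded from μ/σ with a recorded reason, never imputed. A
  user-supplied exclusion list handles overlapped peaks.
* The endpoint defaults to the final molar ratio; per-point profiles feed
  the isotherm fits.

Line broadening is treated descriptively as intensity ratios I/I₀ against
the reference point; residues undetectable at a point get ratio 0, and
residues with zero or missing reference intensity are flagged rather than
failing the whole profile. No exchange-regime lineshape modelling is
attempted.

## Binding isotherms

With total labelled-protein concentration P (μM) and total ligand
L = molar_ratio × P, the bound fraction of the depletion-corrected
single-site model is

    f_b = [ (P+L+K_D) − sqrt((P+L+K_D)² − 4PL) ] / (2P),

evaluated in the cancellation-safe form 2L / (s + sqrt(s²−4PL)) so that
the weak-binding limit (K_D ≫ P, L) stays accurate to machine precision.
CSP(L) = CSP_max·f_b. Depletion correction matters here because P = 100 μM
is not negligible against K_D of a few hundred μM; the hyperbolic model
CSP_max·L/(L+K_D) is available and agrees to < 0.1% once P ≪ K_D and
P ≪ L.

Fitting: per-residue least squares (via lmfit) with K_D started at the
ligand-schedule midpoint, CSP_max at 1.2× the largest observed CSP, and
K_D bounded in (0, 10⁵ μM]. At least four points including L = 0 are
required; an all-zero CSP series is rejected as "no binding signal".

Two statistical refinements:

* **Shared-reference covariance.** Every CSP in a titration is measured
  against the same noisy apo spectrum, so the errors are correlated: an
  independent per-point part plus a component common to all non-zero-L
  points. Reported standard errors therefore use a sandwich covariance
  with Σ = σ̂²(I + 𝟙𝟙ᵀ) over the non-zero-L points (the L = 0 point is
  exact by construction). In simulation, 95% Wald intervals built from
  these errors cover the truth in ≈ 92% of replicates, versus ≈ 76% for
  the plain independent-residual errors.
* **Well-resolved criterion.** A fit counts as converged only if the K_D
  standard error is finite and no larger than the estimate itself.
  Weakly saturating data occasionally produce runaway K_D estimates with
  huge uncertainties; flagging them keeps the averaged K_D meaningful.

The headline K_D is the unweighted mean ± sample (n−1) standard deviation
over a named set of well-resolved reporter residues; inverse-variance
weighting and the population estimator are options. The mean of the
per-fit standard errors is reported alongside, since literature ± values
may be either across-residue scatter or propagated fit error.

## Restraint generation

Relative solvent accessibility is computed with the Shrake–Rupley
algorithm (Bio.PDB, probe 1.4 Å, 960 sphere points) on heavy atoms of the
first model, normalised by the Miller et al. (1987) Gly-X-Gly maximum
areas and clipped to [0, 1]. That table matches a hydrogen-free
Shrake–Rupley computation on an ideal extended tripeptide to ≈ 0.1%
(verified in the tests), which is why it is preferred over tables derived
with other radii/conformer conventions. Residues with missing atoms are
flagged and scored from the atoms present.

Active residues = significant CSP (μ+σ tier by default) AND relative
accessibility ≥ 0.40; passive residues = accessible residues with any
heavy atom within 6.5 Å of any active heavy atom, minus the actives. Both
cutoffs are conventional docking practice and configurable. Residue
numbering between profile and structure is reconciled by a constant
offset or an explicit map; a significant residue that cannot be located in
the structure is an error, not a silent drop.

Restraints are emitted as CNS/HADDOCK-dialect `assign` statements, one per
active residue, listing the partner's active+passive residues, with
distance bounds `2.0 0.0 0.0`. Output is byte-stable, and a parser for
the emitted dialect recovers the restraint set exactly (round-trip
tested). Seeded variant files omitting a fraction of restraints (the
random-deletion behaviour of docking engines) can be emitted but are off
by default. Cluster z-scores are (score − mean)/sd over all clusters,
population sd by default.

## smFRET burst analysis

Photons are labelled by (excitation slot, detection channel) assuming the
alternation starts in the green slot at t = phase_offset, each slot being
half the 50 μs period (20 kHz alternation). Red-slot donor-channel
photons carry no ALEX information and are ignored; an optional
dead-fraction blanks slot edges.

Burst search is the all-photon sliding window: a photon is in a burst if
it lies inside any window of m = 10 consecutive photons whose local rate
m/span exceeds the threshold; maximal runs merge, and bursts under 30
photons are discarded. The default threshold is 50× the per-channel
background rate (50 kHz at the default 1 kHz/channel background), which
the default burst brightness (100 photons/ms) clears with a factor-two
margin. The implementation is vectorised but provably identical to the
exhaustive O(n·m) scan (tested on 10⁴-photon streams).

Stoichiometry filtering keeps S ∈ [0.3, 0.8]; donor-only (S → 1) and
acceptor-only (S → 0) species fall outside. The residual contaminant is
the coincident transit of a donor-only and an acceptor-only molecule,
which no stoichiometry filter can remove; simulations put the retained
dual-labelled fraction above 95%.

E\* = DA/(DD+DA) is deliberately uncorrected (no γ, leakage or
direct-excitation corrections — hooks exist but default to identity),
matching the *apparent* efficiency convention. The per-condition fit is
an unbinned maximum-likelihood single Gaussian over the E\* values inside
the fit window [0.2, 1.0]: the ML estimates are the sample mean and the
population sd of the windowed values; no truncation correction is
applied, and the 0.025-wide histogram bins are display-only. Fitting a
single Gaussian to a genuinely bimodal population returns the grand mean
with a large sd — documented behaviour, not a failure. The window default
excludes the donor-leakage/zero-peak region; whether low-E\* shoulders
should enter the fit is a judgement call left to the user via the window.

## Filament forward model

Subunit k of an ideal helix carries its label site at frame
(rotation k·twist about z) ∘ (translation k·rise) applied to a fixed
offset vector. Pairwise label distances obey the chord identity
d² = (Δk·rise)² + 2ρ²(1 − cos(Δk·twist)) for radial offset ρ, which the
tests verify to 10⁻⁹ Å. Label states are drawn per subunit at
donor:acceptor:unlabelled = 1:1:2 (two labels per four subunits on
average); configurations without a donor–acceptor pair are recorded as
FRET-incapable and model the no-FRET burst population. E uses the
nearest-pair approximation by default; a rate-additive multi-acceptor
option exists.

R₀ for the Cy3B/Atto647N pair is not published in this context; the
default 60 Å (with κ² = 2/3 implied by using a fixed R₀) is a documented
assumption. The true filament rise/twist and label-site positions are
unknown, so defaults are placeholders chosen rise-dominated — rise 45 Å,
twist 65°, radial offset 18 Å — putting adjacent labels ≈ 49 Å apart
(E ≈ 0.75), near the unperturbed-filament regime.

A geometric subtlety: because 1 − cos(Δk·twist) decreases when twist
(< 180°) decreases, *pure* untwisting always shortens the azimuthal part
of the chord and can raise E when ρ is large. Only the physically
observed coupled stretch+untwist deformation is guaranteed to move
labels apart in a rise-dominated geometry; the monotone E decrease is
therefore asserted along coupled remodelling paths, not for arbitrary
(stretch, untwist) pairs.

## Synthetic data

**Titrations** follow the standard schedule: 100 μM labelled protein, molar
ratios 0:1 → 8:1 in 0.5 steps (17 points). Each residue's shifts are
reference + f_b·Δδ_max + N(0, 0.002 ppm) in both dimensions; the noise sd
was chosen so significance calls are non-trivial. The planted interface
(by default the nine-residue patch K17/S20/S23/F49/A50/D52/W53/E55/H60;
the reverse preset plants L129/Y130/I132/F133/E134/E135/K164/E169/V171)
carries saturating shifts of 0.15–0.28 ppm (¹H) and 0.6–1.1 ppm (¹⁵N),
calibrated once so the endpoint profile mean (≈ 0.016 ppm) matches the
order of the published endpoint statistics (μ ≈ 0.014 ppm); background
residues get small (< 0.01 ppm combined) secondary shifts emulating
allosteric ripple. Optional geometric intensity attenuation
(I/I₀ = f^ratio) emulates intermediate-exchange broadening. The generator
does **not** emulate peak overlap, assignment errors, exchange-regime
lineshapes or temperature/pH drift — passing tests show the estimators
work under the stated noise model, not that real spectra are this clean.

**Photon streams**: bursts arrive as a Poisson process (40 s⁻¹ over
150 s in the presets), with exponential 1 ms durations and Poisson photon
counts at 100 photons/ms brightness — typical confocal magnitudes,
documented as assumptions. Burst counts are multinomial over DD/DA/AA
with p = (S(1−E), S·E, 1−S), so E[DA/(DD+DA)] → E_true and
E[(DD+DA)/total] → S_true; photon times are placed uniformly inside the
correct ALEX half-slots. Presets place the dual species (60%, S = 0.55)
at E\* = 0.70 (filament alone), 0.50 (+DnaD) and 0.60 (+DDBH2), alongside
20% donor-only and 20% acceptor-only, over 1 kHz/channel background. The
model is shot-noise only: no γ factor, spectral leakage, direct
excitation, blinking or bleaching, and no diffusion kinetics within a
burst. The 150 s preset duration yields ≳ 2000 filtered bursts, the scale
at which the Gaussian means are reproducible to ± 0.02.

All generators validate their outputs against the consuming types'
invariants and are byte-deterministic given a seed.

## Problem sizes and determinism

Recovery studies use 50 seeds × 17-point titrations for K_D (median
relative error ≤ 15% at K_D ∈ {500, 768, 1500} μM; exact to 10⁻⁶
noiseless), 20 seeds for planted-interface recovery, 200 replicates for
CI coverage, and one 150 s photon stream per FRET regime. Every
stochastic stage takes an explicit seed; CLI result files embed the
package version, stage configuration and input digests, and identical
config + inputs give bitwise-identical outputs (timestamps go to the
stderr log only).
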