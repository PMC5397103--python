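# Methods

## Model and procedure

`fretkappa` analyses conformational ensembles of a donor–linker–acceptor
construct at the level of per-frame dipole geometry. Each frame carries a
donor and an acceptor transition-dipole unit vector (µ̂_D, µ̂_A) and the two
chromophore reference points whose difference is the separation vector
R_DA. Three quantities are then chained:

1. **Orientation factor.** κ = µ̂_D·µ̂_A − 3(µ̂_D·R̂)(µ̂_A·R̂), squared.
   This vector form is the primary path because it is defined for every
   configuration. The equivalent angular form
   κ = sin θ_D sin θ_A cos φ − 2 cos θ_D cos θ_A is provided for reporting
   the angles and as an independent cross-check; the dihedral φ (unsigned,
   in [0, π], since κ² depends only on cos φ) is undefined whenever a
   dipole is collinear with R̂, which is flagged at sin θ < 1e-9 and makes
   the angle-form evaluator raise rather than guess.

2. **Förster radius and efficiency.**
   R₀⁶ = 9000 ln10 · κ² Q_D J / (128 π⁵ N_A n⁴). With J in M⁻¹ cm⁻¹ nm⁴
   and R₀ in Å this reduces to R₀⁶ = C κ² n⁻⁴ Q_D J with C ≈ 8.785×10⁻⁵.
   C is computed at import from Avogadro's number and the explicit unit
   conversions (the litre→cm³ factor lives inside the 9000; nm⁴→cm⁴ is
   10⁻²⁸; cm⁶→Å⁶ is 10⁴⁸) and is unit-tested against an independent
   re-derivation, not copied from a table. The overlap integral is
   trapezoidal quadrature of f_D(λ) ε_A(λ) λ⁴ on the union grid of the two
   spectra with linear interpolation, after area-normalizing the donor
   emission and rescaling the acceptor extinction to a stated peak value;
   trapezoidal quadrature was chosen because it is deterministic and
   testable against closed forms. Efficiencies follow
   E = 1/(1 + (R_DA/R₀)⁶). Per-frame ("instantaneous") efficiencies
   rescale the Förster radius with the frame's orientation factor,
   R₀(t)⁶ = R₀_ref⁶ · κ²(t)/κ²_ref, holding Q_D, n and J fixed. κ²_ref
   defaults to the isotropic 2/3; setting κ²_ref to a trajectory-averaged
   value (e.g. 0.69) with the same R₀_ref expresses the alternative
   convention in which the ensemble mean defines the unique radius.

3. **Apparent vs true distance distributions.** The unique-R₀ inversion
   R_app = R₀ (1/E − 1)^{1/6} is applied elementwise to an efficiency
   collection; frames with E outside the open interval (0, 1) — notably
   κ² = 0 frames, where transfer is orientation-forbidden and E = 0 — have
   no finite inverse and are excluded with a reported count. The apparent
   histogram is compared to the histogram of the geometric R_DA values via
   full width at half height (FWHH), and the headline diagnostic is
   width_ratio = FWHH(apparent)/FWHH(true).

The closed-form density of κ² for isotropic, independently re-orienting
dipoles,

    p(κ²) = ln(2+√3) / (2√(3κ²))                                0 < κ² ≤ 1
    p(κ²) = ln[(2+√3)/(√κ² + √(κ²−1))] / (2√(3κ²))              1 < κ² ≤ 4

serves as the theoretical reference curve. It has an integrable
κ⁻¹-singularity at 0, integrates to 1 and has mean 2/3; both facts are
verified by quadrature (with the substitution κ² = u² to tame the
singularity) rather than assumed, and the density is cross-validated
against large Monte-Carlo histograms.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `r0_ref` | 48 | Å | Förster radius at the reference κ² (CFP/YFP pair) |
| `kappa2_ref` | 2/3 | – | κ² convention to which `r0_ref` refers |
| `quantum_yield_donor` | 0.4 | – | donor fluorescence quantum yield Q_D |
| `refractive_index` | 1.4 | – | medium refractive index n |
| distance bin width | 1 | Å | histogram resolution for R_DA and R_app |
| efficiency bin width | 0.02 | – | ≥10 bins across a peak of FWHH ≈ 0.25 |
| κ² bin width | 0.05 | – | resolves the density's low-κ² rise |

Bin widths are conventions (all overridable), chosen so the distributions
of interest are resolved without dominating sampling noise at the default
sample sizes (10⁵–10⁶ frames).

Chromophore dipole axes: the true S₀→S₁ transition dipoles of
fluorescent-protein chromophores come from quantum chemistry and cannot be
recovered from coordinates. The shipped defaults span a long-axis atom
pair across the chromophore's conjugated ring system (CA2→CZ for CRO,
CA2→CZ2 for CRF) and are documented approximations; κ² is invariant under
a sign flip of either dipole, so only the axis matters, and both the atom
pair and the center definition (midpoint of the pair, or a named atom) are
configurable.

PDB handling: multi-model files are delimited by MODEL/ENDMDL; a file
without MODEL records is one frame; ATOM and HETATM are both kept;
alternate locations other than blank/'A' are skipped. Coordinates are Å
throughout. Binary trajectory formats are out of scope — convert to
multi-model PDB or the vector-table format.

## Synthetic generator

The generator (`fretkappa.synthetic`) emulates the statistical structure
an equilibrated flexible construct presents to this analysis: a stationary
distance distribution (fixed, or Gaussian with negative draws rejected)
and dipoles re-drawn independently each frame, either isotropically
(uniform directions via normalized 3-D Gaussian draws, which are exactly
rotation-invariant) or restricted to a cone about the separation or a lab
axis. The `paper-like` preset uses Gaussian distances 44 ± 1.5 Å with
isotropic orientations — a stationary stand-in for a flexibly linked
CFP/YFP pair whose donor–acceptor distance has plateaued in the
low-to-mid-40-Å range. A separate fixture generator produces an
exponentially relaxing distance series (default-style usage: start ≈ 90 Å,
plateau ≈ 44 Å) for the running-mean convergence diagnostic, whose
"plateau" is operationalized as the mean over a configurable final
fraction (default one third) of frames.

What the generator does **not** emulate — and hence what passing tests do
not show about real data:

- **No temporal correlation.** Frames are independent draws; the analysis
  implemented here is equilibrium-ensemble, so autocorrelation is not
  needed for any computed statistic, but dynamic-averaging regimes (κ²
  averaging within a donor lifetime) cannot be studied with it.
- **Distance–orientation independence.** In a real linker the dipole
  orientations and the separation are coupled through the chain; the
  generator draws them independently. The observed deviation of real
  ensembles from perfect isotropy is therefore only generically
  represented by the cone model, which is a stand-in, not a fit.
- **Spiky low-E behaviour.** Because κ² is redrawn per frame from a
  density singular at 0, the per-frame efficiency histogram has a sharp
  spike near E = 0 (and the apparent-distance distribution a long right
  tail). Photon-averaged single-molecule histograms smooth this spike, so
  the synthetic efficiency FWHH is not comparable to measured ones —
  width comparisons in this package are therefore made on *distance*
  distributions.

Consequently, ensemble-specific numbers from any particular MD study
(⟨κ²⟩ slightly above 2/3, a specific mean efficiency or efficiency FWHH)
are context for direction-of-effect checks here, not quantities this
package claims to reproduce.

## Numerical choices

- κ² is clipped nowhere: the vector form is algebraically confined to
  [0, 4] up to rounding, and tests assert the range on 10⁵ random frames.
- Histogram edges align to integer multiples of the bin width; density
  normalizes to unit area. FWHH takes the leftmost maximal bin as the
  peak (deterministic tie-break), measures between the outermost half-max
  crossings with linear interpolation between bin centers, returns the
  bin width when all mass sits in one bin, and raises on a flat
  multi-bin histogram (no defined peak).
- Comparisons between the κ² density and Monte-Carlo histograms exclude
  the first bin (the singularity is represented by counts, not by
  evaluating the density at 0) and use the bin-averaged density, since
  the density varies strongly within 0.05-wide bins near zero.
- The width ratio is reported as +∞ when the true distances occupy a
  single histogram bin (degenerate true distribution).
- Efficiency/distance inversion is exact analytically; in floating point
  the round trip holds to ~1e-12 relative over the practically relevant
  range (distance within roughly a factor 2 of R₀) and degrades by
  cancellation as E approaches 0 or 1.
- Determinism: every stochastic routine takes an explicit seed
  (numpy `default_rng`); pipeline runs with identical config and seed
  write identical outputs (TSV floats printed at fixed precision).

## Problem sizes

Monte-Carlo checks use 10⁶ samples for mean-κ² statistics (standard error
≈ 7×10⁻⁴) and 10⁷ for density-shape comparison; synthetic trajectory
analyses use 10⁵ frames. These sizes put sampling noise well below the
tested tolerances while keeping the full suite and the acceptance script
fast on a single CPU.

## Known limitations

- Dipole axes from atom pairs are geometric approximations (see above).
- The reported φ convention (unsigned inter-plane angle) may differ from
  other tools' signed dihedral conventions; κ² is unaffected.
- No kernel-density estimation: all widths are histogram FWHH values and
  inherit bin-width sensitivity of order one bin.
- No lifetime, anisotropy or photon-level modelling; efficiencies are
  ideal per-frame quantities.
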