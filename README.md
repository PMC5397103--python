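# fretkappa

Orientation-factor-aware FRET trajectory analysis.

Single-molecule and ensemble FRET experiments routinely convert a measured
transfer efficiency into a donor–acceptor distance through the Förster
relation with a single, fixed Förster radius R₀. That shortcut assumes the
orientation factor κ² is a constant (usually its isotropic dynamic average
2/3), while in a real flexibly linked construct — e.g. a CFP donor and YFP
acceptor joined by a Gly/Ser linker — κ² fluctuates over the full range
[0, 4] from frame to frame. `fretkappa` is a library and CLI for
quantifying what that assumption does to distance distributions. From
conformational frames of a two-fluorophore construct (multi-model PDB,
tabulated dipole vectors, or a built-in synthetic generator) it computes:

- per-frame dipole geometry θ_D, θ_A, φ, R_DA and the orientation factor
  κ² = (sin θ_D sin θ_A cos φ − 2 cos θ_D cos θ_A)², evaluated in the
  degeneracy-free vector form κ = µ̂_D·µ̂_A − 3(µ̂_D·R̂)(µ̂_A·R̂);
- the Förster radius from photophysics,
  R₀⁶ = 9000 ln10 · κ² Q_D J(λ) / (128 π⁵ N_A n⁴), with the spectral
  overlap J(λ) = ∫ f_D(λ) ε_A(λ) λ⁴ dλ computed from two-column spectra;
- instantaneous efficiencies E(t) = 1/(1 + (R_DA/R₀(t))⁶) with
  R₀(t)⁶ ∝ κ²(t), and their histograms;
- the **apparent** distance distribution R_app = R₀ (1/E − 1)^{1/6}
  reconstructed under a unique R₀, compared against the **true** R_DA
  distribution — including the full-width-at-half-height (FWHH) ratio that
  measures how orientational fluctuations inflate the apparent width;
- the closed-form probability density of κ² for isotropic, independently
  re-orienting dipoles (mean 2/3), as the theoretical reference curve.

It is aimed at structural-bioinformatics and single-molecule-biophysics
users who have conformational ensembles (e.g. from MD) or want controlled
synthetic ensembles to test FRET-inference procedures.

## Worked example

Simulate a stationary flexible-linker ensemble (Gaussian distances
44 ± 1.5 Å, dipoles re-drawn isotropically every frame), then analyze it
under R₀ = 48 Å with per-frame κ²:

```sh
fretkappa simulate --preset paper-like --n-frames 100000 --seed 7 --out demo/sim
cat > demo/run.yaml <<'EOF'
input_mode: table
input_path: demo/sim/trajectory.tsv
output_directory: demo/run
fret_params:
  r0_ref: 48.0
  kappa2_ref: 0.6666666666666666
  quantum_yield_donor: 0.4
  refractive_index: 1.4
efficiency_mode: instantaneous_kappa2
EOF
fretkappa analyze --config demo/run.yaml
```

Key numbers from the printed `report.json` (also written to `demo/run/`):

```
kappa2_summary     {"mean": 0.6651, "sd": 0.7185}
r_da_summary       {"mean": 43.998, "sd": 1.497, "fwhh": 3.772, ...}
efficiency_summary {"mean": 0.4688, "sd": 0.2801, ...}
apparent_summary   {"mean": 56.151, "sd": 34.442, "fwhh": 14.877, ...}
width_ratio        3.944
```

Reading: the sampled ⟨κ²⟩ sits at the isotropic limit 2/3; the true
distance distribution is 44 Å wide ±1.5 Å (FWHH ≈ 3.8 Å, as expected for a
Gaussian, 2.355 σ); but the distance distribution *reconstructed from the
efficiencies under a unique R₀* has FWHH ≈ 15 Å — a width ratio of ~3.9.
Orientational fluctuations alone, with no extra distance heterogeneity,
systematically broaden the apparent distance distribution.

The run directory also contains TSV histograms (`kappa2_histogram.tsv`
includes the closed-form isotropic density for overlay), the per-frame
`kappa2_series.tsv`, and the apparent-distance histogram.

The same analysis runs on real conformational ensembles: point
`input_mode: pdb` at a multi-model PDB file and give donor/acceptor
`ChromophoreSpec` entries (residue name plus the two atoms spanning the
transition-dipole axis; defaults for the CRO/CRF fluorescent-protein
chromophores ship with the package as documented approximations). The
vector-table format is tab-separated with the exact header
`frame dx dy dz ax ay az mux_d muy_d muz_d mux_a muy_a muz_a`
(donor center, acceptor center, donor dipole, acceptor dipole).

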