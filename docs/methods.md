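# Methods

This note records the model, the numerical choices, and the design of the
synthetic validation systems — what the implementation computes, under
which assumptions, and what the passing tests do and do not establish.

## Model and assumptions

The VCD intensity is obtained from the classical time-correlation function
of the electric and magnetic dipole derivatives,
`C(τ) = ⟨μ̇(0)·ṁ(τ)⟩`, with `μ̇ = P·v` and `ṁ = M·a` expanded over
per-atom Atomic Polar and Atomic Axial tensor blocks.  Assumptions
inherited from this formulation:

* **Classical nuclei.**  Trajectories are classical; a frequency-dependent
  quantum correction factor repairs detailed balance of the lineshape but
  not nuclear quantum effects in the dynamics.
* **`Ṁ·v` neglected.**  `ṁ` keeps only the `M·a` term; on the constant-
  tensor harmonic oracle the neglected term is identically zero, and it is
  second-order in the tensor evolution rate otherwise.
* **Tensor slowness.**  `P(t)` and `M(t)` vary one to two orders of
  magnitude more slowly than atomic velocities, so they are interpolated
  from reference structures instead of being recomputed per frame.
* **Fluctuation convention.**  Time means of `μ̇` and `ṁ` are subtracted
  before correlating.

The AAT is stored *real-valued* in the distributed-origin (atom-centered)
gauge: the imaginary unit of the quantum-mechanical tensor is absorbed
into the sine-transform convention of the spectra module, keeping all
arrays real.  The overall spectral sign is pinned by the requirement that
a mode with positive analytic rotational strength
`R_k ∝ (P·ℓ_k)·(M_lab·ℓ_k)` yields a positive band; this is asserted by
the end-to-end harmonic test rather than transcribed from a typeset
formula.

### Gauge transfer

Local-gauge AAT blocks are moved to a common laboratory origin per frame:

```
M_lab[i]_αβ = M_local[i]_αβ + κ · ε_αγδ · r[i]_γ · P[i]_δβ
```

with `r` the atom position relative to the origin (converted Å → bohr) and
`κ = 1/(4c)` in atomic units (`c` ≈ 137.036), the standard
distributed-origin convention.  Two facts make the spectra robust to this
choice: the mode-diagonal rotational strength is *exactly*
origin-independent (the shift adds a term orthogonal to `P·ℓ_k`), and for
an isotropic ensemble the origin-shift contribution to `⟨μ̇·ṁ⟩` averages
to zero, which is what the 64-orientation invariance test measures.

### Weights and metric

`w_j ∝ Π_x exp(−(d_j^x)²/(2σ_x²))`, normalized.  `d_j^x` is the root of
the **mean** squared coordinate difference over family *x* (so `σ_x` is
scale-free with respect to family size); angular coordinates are
differenced on the circle, and the continuous coordination number
`(1−(r/R₀)ⁿ)/(1−(r/R₀)ᵐ)` (default exponents (6, 12), the common
collective-variable convention) is available for environment counting.
Weights are evaluated in log space with a shift by the nearest reference,
so frames far from every reference still produce a defined weight vector
that concentrates on the nearest reference (ties → lowest index).  The
denominator convention is `2σ²`; σ defaults (half the minimal nonzero
inter-reference family distance) are defined relative to that choice, so
consistent configs are insensitive to the convention.

### Superposition

Rotations are mass-weighted quaternion fits (Horn's closed-form eigenvalue
method), which satisfy the Eckart conditions to first order in the
displacement and never return reflections.  The residual angular momentum
after rotation removal therefore scales with the square of the vibration
amplitude: suppression reaches 10⁻⁶ only in the small-amplitude limit
(verified at 1 K in the tests; at 300 K the suppression is ~10⁻³,
i.e. second order, which is the theoretically expected behaviour, not an
implementation deficiency).

### Transforms

The two-sided correlation function is antisymmetrized,
`C_a(τ) = [C(τ) − C(−τ)]/2` (only this part carries chirality; an even
correlation transforms to exactly zero and a time-reversed trajectory
flips the spectrum's sign), Hann-windowed over `[0, t_max]` (default
2 ps — the `Pv`/`Ma` correlations decay fast), zero-padded 4×, and
sine-transformed.  The IR channel uses the cosine transform of the
symmetric part of the `μ̇` autocorrelation.  The default quantum
correction is the dimensionless harmonic factor `βħω/(1−e^{−βħω})`
(→ 1 at ω → 0, → βħω in the deep quantum limit); the variant
`βħ/(1−e^{−βħω})` is selectable as `printed_qcf`.  Within a narrow band
the two differ only by a smooth envelope, which is why relative band
shapes are insensitive to the choice.  Absolute prefactors (volume,
isotropic 1/3, ω powers) are deliberately omitted: spectra are in
arbitrary units and only positions, signs, and ratios are certified.

### Finite differences

First derivatives use the five-point central stencil
`(1, −8, 0, 8, −1)/(12·dt)`, exact for polynomials of degree ≤ 4 with
O(dt⁴) truncation error (verified by a log–log convergence slope of
4.0 ± 0.2).  Two frames are dropped at each end per differentiation pass
rather than switching to one-sided stencils, keeping a uniform error
order.  File-provided velocities take precedence over differentiated
positions; accelerations are always differentiated from the velocities so
`v` and `a` stay mutually consistent.

## Synthetic ground truth

### Harmonic oracle

`generate_harmonic_trajectory` evolves
`x(t) = x_eq + Σ_k (A_k/√m_i)·l_k·cos(ω_k t + φ_k)` with classical
equipartition amplitudes `A_k = √(2k_BT)/ω_k` (mean mode energy `k_BT`,
time-averaged kinetic energy `k_BT/2`) and seeded uniform phases; exact
velocities are emitted alongside.  Mode vectors are random orthonormal
vectors orthogonal to rigid translations and rotations.  For this system
the double-harmonic band integrals of the pipeline are
`∝ ω_k·Q(ω_k)·R_k` (VCD) and `∝ Q(ω_k)·|P·ℓ_k|²` (IR) — the extra ω in
the VCD channel comes from `ṁ` being one time-derivative higher than
`μ̇`.  The end-to-end test checks band centers to one FFT bin, all band
signs, and integral ratios to 5% on 2·10⁵ steps of 0.5 fs.

What this does *not* establish: anharmonic couplings, Fermi resonances,
mode mixing, or solvent effects — the oracle is exactly the regime the
double-harmonic approximation describes, and real-data performance beyond
it is not certified by these tests.

### Methyl-rotor fixture

The rotor toy exercises the chemically-equivalent-minima machinery: a
3-fold torsional potential `V(θ) = (V₃/2)(1−cos 3θ)` integrated by BAOAB
Langevin dynamics, mapped onto a planar 5-atom geometry (central C, light
off-axis anchor, 3 ring hydrogens).  Conditions: barrier
7·10⁻⁴ amu·Å²/fs² (≈ 1.7 kcal/mol, methyl-like), 600 K (the regime where
methyl large-amplitude motions are well activated), friction 5·10⁻³ fs⁻¹,
dt 1 fs, 12 000 steps — a few tens of hops per run.

Design choices that make the fixture informative rather than decorative:

* **Ring-covariant hydrogen tensors.**  The three H blocks are one base
  block conjugated by each hydrogen's ring position — chemically
  equivalent atoms carry identical local tensors.  The permuted reference
  tensors then coincide exactly with this covariant construction at the
  other minima, as they must for genuinely equivalent wells.
* **Dominantly axisymmetric blocks** (`diag(d, d, d′) + λ·ε_z` plus a
  random anisotropic part), reflecting the approximate local symmetry of
  X–H moieties.
* **A light off-axis anchor.**  It breaks the ring symmetry for the
  anchor–H distance metric (resolving the three wells) and — the key
  point — gives the mass-weighted superposition a *competing 180°-flip
  branch*.  A generic axial rotor has no such branch: every fit quantity
  is then a continuous function of the geometry and single-reference
  evolution never jumps.  With the flip branch present, single-reference
  evolution shows a genuine frame-to-frame discontinuity when the global
  optimum of the fit switches branch, while the 3-member reducible set
  hands the frame over smoothly between references (jumps stay within
  3× the intra-well 95th-percentile jump; the single-reference maximum
  exceeds it by more than an order of magnitude).
* **Metric width σ = 0.5 Å**, between the thermal intra-well spread of
  the metric (~0.2 Å) and half the inter-well separation (~0.7 Å): narrow
  enough to suppress weight leakage onto a reference near its flip point,
  wide enough to blend the handover over many frames.

The fixture's behaviour was verified across 32 seeds beyond the one used
in the test suite.

## Numerical and interface choices

* Units: Å, fs, amu externally; frequency axis in cm⁻¹; tensors in
  arbitrary consistent units.  Angles are degrees in configs and radians
  internally.
* Reference sets are exchanged as versioned JSON (`awv-refset-v1`) with
  metric values frozen at creation time; the permutation expansion
  re-evaluates metric values from the permuted geometry when a metric
  specification is supplied, and leaves them for on-demand evaluation
  otherwise.
* Atom index maps between references and trajectory are explicit
  (`ref_atoms`); there is no geometric auto-matching — silent
  mis-assignment is the dominant failure mode this avoids.
* Weights and rotations are evaluated every frame by default; an optional
  stride holds them between evaluations, exploiting the tensors' slow
  variation.
* Degenerate (collinear) geometries make the fitted rotation
  ill-defined and raise explicitly; torsions over collinear atoms are
  flagged and skipped with a warning.
* PBC handling makes each molecule whole by minimum-image shifts about
  its first atom and refuses molecules spanning half the box.
* Cross channels below 10⁻⁶ of the total band-integrated magnitude are
  not written to per-channel files but always enter the decomposition
  identity, which holds pointwise to 10⁻¹⁰ (relative) by linearity of the
  transform.
* Determinism: identical configs and seeds produce byte-identical TSV
  outputs.

## Known limitations

* Absolute intensities are not produced (arbitrary units by design;
  medium refractive-index corrections are out of scope).
* Binary MD formats (DCD/XTC/TRR) are not read; convert to extended XYZ.
* Reference-structure *selection* (which minima to include) is the user's
  responsibility; the library only validates, expands, and evolves a
  given set.
* Conformer-resolved spectral separation is not implemented.
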