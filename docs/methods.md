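# Methods

## Model

Each electronic state (neutral, anion or cation) of a molecule with n
atoms is described harmonically: equilibrium Cartesian geometry x(0),
harmonic wavenumbers ω_j and a mass-weighted normal-mode matrix L
(3n × n_v, orthonormal columns; n_v = 3n−6, or 3n−5 for linear
molecules). The geometry change between the two states' minima is
projected onto the modes of one state (the *basis*):

    ΔQ = Lᵀ M^(1/2) (x_other(0) − x_basis(0)),

with M the diagonal 3n matrix of atomic masses. The neutral-basis
convention takes x_charged − x_neutral; the charged basis the reverse.
Downstream quantities depend only on |ΔQ|, so the sign convention does
not propagate. From ΔQ_j:

* Huang–Rhys factor S_j = ω_j ΔQ_j²/(2ħ) (ω_j as angular frequency);
* per-mode reorganization energy λ_j = ħω_j S_j;
* surface totals λ_N = Σ λ_j^(N), λ_C = Σ λ_j^(C), λ_i = λ_N + λ_C,
  which on exactly quadratic surfaces equal the adiabatic four-point
  relaxation energies E(rel) − E(min) computed per surface;
* activation energy E_A = ħω(υ−S)²/(4S), zero at the activationless
  point υ = S; the integer phonon estimate rounds S half-away-from-zero
  (both HCN stretch factors, 1.978 and 1.594, round to two phonons).

Franck–Condon factors of the displaced equal-frequency oscillator use the
generalized-Laguerre closed form

    FCF(μ,υ) = e^(−S) S^(υ−μ) (μ!/υ!) [L_μ^(υ−μ)(S)]²   (υ ≥ μ),

with indices swapped for υ < μ (the squared overlap is symmetric; the
swap also resolves an ambiguity in how the closed form is sometimes
printed). For μ = 0 this is the Poisson distribution e^(−S)Sᵘ/u!. Only
μ = 0 progressions feed spectra; finite-μ factors exist for testing and
the activation analysis. An independent quadrature oracle integrates the
Hermite-function overlap |⟨χ_μ(q−d)|χ_υ(q)⟩|² with d = √(2S) on a
±(12+d) grid (≥2000 points, convergence checked by grid halving) and is
the primary correctness surface for the closed forms.

ET spectra place, per mode, sticks at E₀ + υω_j weighted by the mode's
Poisson factors (υ = 1..υ_max, default 10; a "fundamentals" mode keeps
υ = 1 only), plus one 0–0 stick at E₀ weighted by Π_j e^(−S_j).
Cross-mode combination sticks (two modes simultaneously excited) are not
generated: the multimode intensity is treated as a sum of independent
single-mode progressions, a deliberate and documented simplification.
Duschinsky mixing is likewise neglected inside FCFs (J = 1); J is
computed only as a diagnostic. Absorption spectra use the neutral-basis
(ω, S) table, emission the charged-basis table — the charged surface's
frequencies set the emission band positions, which is why emission bands
sit left of absorption bands.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| σ (Gaussian s.d.) | 100 | cm⁻¹ | quarter of the ~400 cm⁻¹ resolution attributed to the biological detector; merges sub-resolution sticks |
| grid | 0–4000 step 1 | cm⁻¹ | covers all fundamental + low-overtone positions of organic molecules |
| υ_max | 10 | — | Poisson weights beyond υ=10 are negligible for S ≲ 3 |
| E₀ | 0 | cm⁻¹ | spectra plotted against vibrational wavenumber relative to the 0–0 line; configurable offset |
| normalization | max1 | — | cross-molecule comparability of band shapes |
| peak prominence | 0.05 of max | — | suppresses ripple while keeping minor bands |
| peak-match tolerance | 250 | cm⁻¹ | about half the detector resolution |
| λ-consistency tolerance | 5e-4 | eV | half a unit in the last digit of three-decimal tables |

Internal units are fixed (masses amu, lengths Å, frequencies cm⁻¹,
energies eV); all conversions go through one constants object
(ħ = h/2π with the SI-defined h, amu = 1.66053906892e-27 kg — CODATA
2022, 1 cm⁻¹ = 1.2398419843e-4 eV), so the Huang–Rhys coefficient
S/(ω·ΔQ²) = 1.48302e-2 per (cm⁻¹·amu·Å²) is exact with respect to those
constants.

## Alignment and frame conventions

The two states' geometries carry arbitrary relative orientation, so the
moving geometry is superimposed on the basis geometry by mass-weighted
Kabsch alignment (the Eckart-condition resolution of the frame
ambiguity), proper rotations only. A reflection is rejected only when
the improper fit is drastically better than the best proper rotation
(weighted squared residual below a quarter of the proper one) — the
signature of a genuine mirror-image mismatch; for planar or linear
geometries the proper optimum is degenerate with the reflected one and
alignment proceeds. After projection, the component of M^(1/2)Δx outside
the mode span (rotational contamination or missing modes) is reported as
a residual fraction and warned about above 1%, never silently dropped.

For the Duschinsky matrix J = (L′)ᵀL the initial state's mode matrix is
rotated into the final state's frame along with its geometry. The
displacement vector attached to a DuschinskyResult is expressed in the
final-state basis, L_finalᵀ M^(1/2)(x_initial(0) − x_final(0)) — the
value of the final state's normal coordinates at the initial minimum.

Rectilinear modes only: curvilinear-coordinate transforms (used by some
normal-mode-projection programs to soften large-amplitude-motion
artifacts) are out of scope, a documented deviation; for the small
displacements typical of neutral↔charged relaxations the rectilinear
projection is the standard first-order treatment.

## Synthetic data

Generators provide ground-truth fixtures in place of quantum-chemistry
inputs:

* **displaced diatomic** — both states share the COM-preserving stretch
  mode; bond lengths differ by Δr, so S = k·ω·μ·Δr² exactly (μ the
  reduced mass). Isotope studies rescale ω by √(μ_H/μ_D).
* **random polyatomic** — seeded orthonormal mode matrix drawn inside the
  translation/rotation complement, frequencies ascending in
  [300, 3500] cm⁻¹, and the charged geometry displaced by M^(−1/2)LΔQ
  with ΔQ chosen to invert the pipeline: projection must recover the
  prescribed per-mode S exactly. Optionally a seeded rigid motion is
  applied to exercise alignment.
* **published HCN table** and a partial acetophenone/acetophenone-d8
  pair (built from the few published dominant emission modes; the ring
  C–H stretch band's coupling is not published and is set to a common
  nominal S = 0.2 for both isotopologues — a synthetic stand-in, flagged
  as such in the API).

These fixtures emulate harmonic, contamination-free inputs. They do not
emulate DFT-level realism: anharmonicity, genuine Duschinsky mixing
magnitudes, mode-count and density-of-states of real odorants, or IR
intensities. Passing tests therefore demonstrate the correctness of the
vibronic machinery given harmonic inputs, not the accuracy of any
electronic-structure method.

## Numerical choices

* Factorials and factorial ratios via log-gamma (no overflow for large υ).
* Quadrature oracle: trapezoidal rule, 4001 points, convergence verified
  by comparing against a half-density grid; non-convergence raises with
  the estimated error.
* Mode tables are sorted by frequency ascending (stable sort).
* The λ = ħωS consistency check on externally supplied tables warns
  rather than fails: published tables round to three decimals and one
  published HCN row (3446 cm⁻¹, S = 0.029, λ = 0.013 eV) recomputes to
  0.0124 eV — the printed value is preserved and flagged.
* Band overlap: both spectra are linearly interpolated onto the coarser
  grid (spectra are σ = 100 cm⁻¹ smooth, so interpolation error at
  1 cm⁻¹ steps is negligible), area-normalized over the window, then
  ∫min is taken. An all-zero window yields 0 with a warning. Cosine
  similarity over the common grid is offered as a window-free second
  opinion. The choice of a bounded, shape-based overlap fraction follows
  the "percent band overlap" language used in comparative odorant
  studies, which never pin down a formal metric; numbers from this
  module are therefore comparable with such statements only
  qualitatively.
* Degenerate bend pairs of linear molecules are stored as the input
  provides them (never merged); the packaged linear-triatomic fixture
  carries 3n−5 = 4 modes with an explicitly degenerate bend pair.

## Limitations

* No electronic-structure computation: geometries, frequencies and modes
  are inputs (JSON schema), and partial charges for IETS are a required
  user input (charge-model choice left to the user).
* No multidimensional FCFs with Duschinsky mixing; no combination bands.
* No external (solvent/protein) reorganization energy and no absolute ET
  rates — prefactors, couplings and ΔG⁰ are outside the model.
* Spectral overlap is a geometric statement about curves, not a
  perceptual claim about odor similarity.
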