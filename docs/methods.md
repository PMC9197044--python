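# Methods

## Model

The package models a spin-correlated radical pair [FADH• … O₂•⁻].
Electron A sits on the flavin semiquinone, electron B on superoxide.
The spin Hamiltonian contains only the electronic Zeeman interaction
with a static field and isotropic Fermi-contact hyperfine couplings:

    H = ω S_Az + ω S_Bz + Σ_i a_i S_(e_i)·I_i,    ω = γₑ B.

Assumptions inherited by every downstream computation:

- **Isotropic couplings only.** Molecular orientations are assumed
  randomized, so anisotropic hyperfine components, exchange and dipolar
  electron–electron couplings, and g-anisotropy are all neglected. With
  everything isotropic only |B| matters and the field is placed along z.
- **One flavin nucleus.** Electron A couples only to the H5 proton
  (I = 1/2, a₁ = −802.9 μT), its dominant isotropic coupling. Additional
  nuclei can be added freely (`RadicalPairSystem.with_nucleus`), and the
  test suite verifies that each extra coupled spin damps the
  field-ratio response.
- **Oxygen isotopes.** ¹⁶O has zero nuclear spin, so the bare pair has
  no hyperfine term on electron B. The ¹⁷O scenario adds a single
  I = 5/2 nucleus with a₂ = 1886.8 μT — a DFT-derived value treated
  here as an input constant. Only one ¹⁷O is modelled even though
  superoxide has two oxygens; at realistic enrichment a single
  substitution dominates.
- **Symmetric kinetics.** Singlet and triplet channels react with the
  same rate k, so the chemistry weights time with k·e^(−kt) regardless
  of spin state. Spin relaxation is phenomenological: the deviation of
  the triplet probability from the statistical 3/4 decays as e^(−rt).
  This is a scalar-decay model, not a Lindblad treatment; it has no
  preferred relaxation axis.
- **Initial states.** Singlet-born pairs start in |S⟩⟨S|/M ⊗ 1_M-mixed
  nuclei; triplet-born pairs in the equal mixture of the three triplet
  states. The singlet is (|↑↓⟩ − |↓↑⟩)/√2 in the A⊗B product basis.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| B_GMF | geomagnetic (control) field | 55.26 | μT |
| B_HMF | hypomagnetic (shielded) field | 0.29 | μT |
| a₁ | H5 proton HFCC, electron A | −802.9 | μT |
| a₂ | ¹⁷O HFCC, electron B | 1886.8 | μT |
| k | spin-selective reaction rate | 2×10⁶ | s⁻¹ |
| r | spin-relaxation rate | 2×10⁵ | s⁻¹ |
| γₑ | electron gyromagnetic ratio | 1.76085963×10¹¹ | rad s⁻¹ T⁻¹ |

Field uncertainty bands (±0.01 / ±0.05 μT on the two fields) are
ignored; central values reproduce the reference yields to ≲10⁻⁶. The
gyromagnetic ratio is the free-electron value (g = 2.00231930436),
identical for both electrons; this convention reproduces the reference
yield table to better than 10⁻⁴, which settles the otherwise
unconstrained choice of g-factor.

All internal energies are angular frequencies (rad/s); μT inputs are
converted by ω = γₑB·10⁻⁶, including the HFCCs.

## Yield computation

Diagonalizing H (numpy `eigh`) gives eigenfrequencies ω_m and the
overlap weights W[m,n] = |⟨m|P̂_S|n⟩|². The closed-form ultimate yields
are Lorentzian-weighted double sums over all 4M×4M eigenstate pairs,
including m = n, where the Lorentzian reduces smoothly to k/(k+r) —
degeneracies need no special casing, and the within-block sums of W are
unitary-invariant, so eigenvector arbitrariness in degenerate subspaces
cannot move a yield. Yields within 10⁻¹⁰ of [0, 1] are clipped to the
interval; larger excursions raise.

The independent time-domain route expands the coherent triplet
probability in cosines of the beat frequencies, applies the relaxation
envelope, and integrates k·p_T(t)·e^(−kt) by composite Simpson. The
horizon T is chosen so the neglected tail (bounded by e^(−kT), since
p_T ≤ 1) is below 10⁻⁹, and the step resolves the fastest beat with 48
samples per period: at 20 samples per period the Simpson error can
reach ~10⁻⁶ on strongly coupled systems, while 48 keeps the worst
deviation from the closed form near 3×10⁻⁸ over randomized sweeps at
modest cost. A guard raises if the two requirements would need more
than 2×10⁶ grid points. A second cross-check propagates ρ(0) unitarily
in the eigenbasis and traces against the triplet projector; it agrees
with the spectral trace to 10⁻¹⁰.

## Parameter scans

The k–r ratio maps exploit the fact that the eigensystem depends only
on the field: W and Δω are computed once per field and the Lorentzian
sum is broadcast over the whole grid, so a 60×60 map costs milliseconds.

Default grids are logarithmic, 10³–10⁷ s⁻¹ with 60 points per axis, for
both k and r. The upper end is deliberately an order of magnitude below
the hyperfine frequency scale of the default pair (|a₁|γₑ ≈ 1.4×10⁸
rad/s). Beyond k ≈ 10⁷·⁷ s⁻¹ the pair reacts faster than a single
coherent singlet–triplet oscillation and the clean sign structure of
the field response (singlet-born GMF/HMF ratio ≥ 1, triplet-born ≤ 1)
develops genuine sub-10⁻⁴ inversions — confirmed by the time-domain
oracle, so they are physics, not numerics. That regime is outside what
the model is meant to describe, and the defaults exclude it; grids are
overridable everywhere and recorded in the map metadata.

The field sweep defaults to 0–1000 μT in 201 points at the reference
kinetics, wide enough to show that the response to shielding (0.29 μT)
far exceeds the response to a 500 μT applied field — the classic
low-field effect.

Agreement regions are extracted by thresholding the map against a
band (center ± half-width) and tracing band-edge contours by marching
squares on log(ratio) over the log-log grid.

## Experiment-side analysis

The experimental readout is the GMF-to-HMF ratio of mean BrdU⁺
proliferating-cell counts after 8 weeks (means 1826.20 vs 1363.51, SDs
174.55 vs 131.34). The ratio uncertainty is first-order (delta-method)
propagation of the two group SDs treated as independent:
se = ratio·√((sd_G/μ_G)² + (sd_H/μ_H)²). This choice is validated two
ways: it reproduces the published 1.34 ± 0.18 after two-decimal
rounding, and a parametric bootstrap at n = 8/group lands within 15% of
it. The published source reports a 25.37% decrease while the rounded
table means give 25.34%; the package recomputes from the table values
and does not force a match to the unrounded source.

The model-to-experiment comparison equates the triplet-yield ratio with
the cell-count ratio directly, with no intermediate dose–response
model. This is deliberately conservative: redox signaling can amplify
upstream ROS changes, so a smaller yield change could produce the
observed neurogenesis change. Only the ratio-band overlap is a tested
claim; the full causal chain (field → yield → superoxide →
neurogenesis) is not asserted by any test.

### Synthetic cohorts

Per-animal counts are not published, so the generator draws them from
normal distributions with the published group means/SDs, truncated at
zero by redrawing (negligible at the defaults, where mean/sd ≈ 10).
Group size is not published either; the default is n = 12 per group, a
typical cohort for rodent neurogenesis studies, and is an explicit
assumption. The generator emulates only the summary statistics — it
cannot reproduce inter-animal correlation structure, non-normal count
dispersion, or litter effects, so passing recovery tests show
consistency with the published summaries, not with the raw data.

The recovery check picks a reference kinetics point (k*, r*) inside the
published band's agreement region — specifically the in-band grid cell
whose ratio is closest to the band center, i.e. where the model best
matches the experimental point estimate (a point near a band edge
would, by construction, fall outside roughly half of the resampled
bands). Across seeded 12-animal cohorts, the model ratio at (k*, r*)
stays inside the band recomputed from each cohort in ≥ 90% of
replicates, and the recomputed agreement regions overlap the published
one in ≥ 95%.

## Numerical conventions

- Tensor order: electron A ⊗ electron B ⊗ nuclei in list order; yields
  are invariant under nuclear reordering (tested at 10⁻¹⁰).
- Hermiticity tolerance: 10⁻¹² relative to the largest entry; a
  violating matrix is rejected with the measured deviation.
- Hilbert-space guard: dimensions above 4096 are refused.
- Determinism: identical inputs give bitwise-identical maps; all
  stochastic components take explicit seeds or Generators.

## Known limitations

- No exchange or dipolar inter-radical coupling, no anisotropic
  hyperfine tensors, no radio-frequency fields, no Liouville-space
  spin-selective reaction operators (the closed forms assume equal
  channel rates).
- Relaxation is a single scalar rate; realistic superoxide relaxation
  may be orders of magnitude faster than the values the agreement
  region prefers, a known open question for this class of model.
- The ¹⁷O coupling is a fixed input; no electronic-structure
  calculation is performed.
- The experiment-side model treats group summaries as exact normal
  parameters and animals as independent.
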