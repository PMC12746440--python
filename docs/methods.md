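# Methods

## Model and conventions

All tensors are stored in Hartree atomic units with c = 137.035999084 a.u.
and 1 nm = 18.897261246 Bohr; the angular frequency is ω = 2πc/λ (a.u.).
Keeping one internal unit system makes the CID prefactor unambiguous:
conversions live only at I/O.

The observable is the degree of circular polarization of right-angle
Rayleigh scattered light in the depolarized geometry,

    Δ = (1/c) (24 β(G′)² − 8 β(A)²) / (12 β²),

with the invariants defined in `rayoa.invariants`:

    β²     = ½ (3 α_ij α_ij − α_ii α_jj)
    β(G′)² = ½ (3 α_ij G′_ij − α_ii G′_jj)
    β(A)²  = (ω/2) α_ij ε_ikl A_klj .

Literature normalizations of β(A)² differ by factors of 2 and by where the
frequency factor sits; the convention here places ω inside β(A)² so that
β(G′)² and β(A)² carry identical units and enter Δ through the single 1/c
prefactor. The minus sign on the quadrupole term is part of the contract;
tabulations with the opposite sign differ by an A-tensor sign convention.
Likewise the global sign of G′ differs between electronic-structure codes,
so the tensor-file reader exposes a `gprime_sign` switch (default +1); a
wrong choice flips every predicted Δ, which is why it is surfaced rather
than guessed.

Tensor character: α and A are polar tensors (rank 2 and 3), G′ is axial
and acquires a det(R) factor under improper operations. Consequently β² is
a true scalar while β(G′)² and β(A)² are pseudoscalars — improper
operations (the enantiomer map) flip their signs exactly, and any tensor
set invariant under a reflection has both identically zero. These exact
group-theoretic facts are the backbone of the test suite.

Origin translation (used as a test oracle only): for a shift O → O + d,

    G′_ij → G′_ij − (ω/2) ε_jkl d_k α_il
    A_ijk → A_ijk − (3/2)(d_j α_ik + d_k α_ij) + d_l α_il δ_jk ,

with α unchanged. For symmetric α every correction term is annihilated in
the β(G′)² and β(A)² contractions (each reduces to a symmetric object
contracted against an antisymmetric one), so both invariants are origin
independent; `shift_origin` therefore demands a symmetric α strictly.

Only the 90° depolarized SCP geometry is implemented; the geometry tag on
predictions exists so other CIDs (e.g. backscattering DCP strategies) can
be added without breaking the API. The 1/λ wavelength rescaling is valid
far off resonance only; the package has no excitation-energy data to check
this, so rescaling by more than a factor of 2 in wavelength logs a caution
instead.

## Numerical choices

- β² is evaluated in the algebraically identical sum-of-squares form
  ½Σ_{i<j}(α_ii−α_jj)² + 3Σ_{i<j}(s_ij² + w_ij²), which is manifestly
  non-negative and avoids the catastrophic cancellation of the raw double
  contraction near isotropy.
- Incoming tensors are validated to a relative Frobenius tolerance of 1e-6
  (finite-precision quantum-chemistry output); the file reader symmetrizes
  α and projects A onto its symmetric-traceless quadrupole form with a
  logged report when the violation exceeds that tolerance, but leaves
  tensors already clean to the 1e-14 level untouched so files round-trip
  bit-for-bit.
- |Δ| ≤ 1 is enforced on predictions (a normalized intensity difference);
  Δ is undefined for an isotropic scatterer (β² = 0) and that case raises
  rather than returning 0.
- Orthogonality of transforms is checked to 1e-12 absolute.

## Measurement model

The two circular channels are modelled as independent Poisson counters:
the total count N is Poisson with mean (count rate × exposure), and the
channels are Poisson draws with means N(1 ± Δ)/2. This is the standard
photon-counting model; it differs from multinomial thinning only at count
levels far below those of interest. The estimator Δ_raw = (n_R − n_L)/N has
standard error √((1−Δ²)/N) ≈ 1/√N: resolving |Δ| ~ 3.6 × 10⁻⁴ at the
~10⁻⁵ level needs ~10¹⁰ counts.

The detected count rate is a direct input rather than being derived from
laser power, solid angle and a scattering cross-section: cross-sections and
detector efficiencies vary over orders of magnitude and only the total
count matters statistically. The default, 2 × 10⁵ counts/s, is calibrated
so that a 15 h exposure accumulates ~10¹⁰ counts, i.e. reaches the ~10⁻⁵
precision floor quoted for real neat-liquid instruments at 30 mW; power
and solid angle are carried as exposure metadata.

Corrections are applied in a fixed order as the minimal faithful forms of
the three physical effects:

1. **Enantiomer-independent instrumental offset** — removable only by
   measuring both enantiomers: the symmetric part ½(Δ_A + Δ_B) is the
   offset, the antisymmetric part ±½(Δ_A − Δ_B) the physical signal.
2. **Enantiomeric excess** — dilutes Δ linearly, corrected by 1/ee.
3. **Incident-beam polarization rotation** — the optically active sample
   rotates the incident linear polarization along the path, degrading the
   geometry; modelled as a single multiplicative factor supplied by the
   caller (default 1, flagged in the output notes).

Uncertainties propagate in quadrature through these linear steps. The
interfaces accept a drop-in replacement if exact instrument-specific
correction formulas become available.

## Synthetic data

The fixture generator draws tensor sets with the exact structural
properties of molecular data: symmetric positive-definite α with entries of
order 100 a.u. (the polarizability scale of a small terpene), generic G′,
and A projected symmetric-traceless. For chiral fixtures, G′ and A are then
jointly rescaled — Δ is exactly linear in that pair — so |Δ| lands in the
10⁻⁴–10⁻³ regime of real small molecules (or exactly on a requested
target). Mirror-symmetric fixtures are built to commute with the reflection
z → −z (α block-diagonal, G′ restricted to single-z-index components, A to
even-z-count components), which forces the pseudoscalar invariants to
vanish by symmetry rather than by tuning. Everything is deterministic in
the seed.

What the fixtures do **not** emulate: real electronic structure. The
component-level correlations of a genuine molecule's α, G′ and A (and hence
realistic ratios β(G′)²/β(A)², dispersion near resonance, conformational
averaging) are absent, so passing tests demonstrate the correctness of the
tensor algebra, symmetry behaviour, statistics and pipeline logic — not the
accuracy of any particular quantum-chemistry prediction. To exercise the
pipeline on a real molecule, compute α, G′ and A with an electronic-
structure program (e.g. several hybrid/range-separated density functionals
with a large augmented basis at the wavelengths of interest), export each
run to the JSON tensor file format of `rayoa.tensor_core` (row-major, in
atomic units, minding `gprime_sign`), and feed the files to `rayoa predict`.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make the
statistical assertions sharp but cheap: 100 random tensor sets for oracle
equivalence, 100–200 rotations for invariance, 100–1000 measurement
replicates at 10⁴–10¹⁰ expected counts (Poisson sampling is O(1) in the
mean, so large counts cost nothing). The full suite runs in about a second;
the acceptance script in well under a minute.

## Known limitations

- One scattering geometry; no resonance effects, no polarized (isotropic)
  90° CID, no backscattering strategies.
- The beam-rotation correction is a user-supplied scalar, not a model of
  the polarization evolution along the path.
- No parsing of electronic-structure log files; ingestion is via the JSON
  tensor format only.
- The assignment logic is single-wavelength, single-observable by design;
  consensus across observables (OR, CD, ROA) is out of scope.
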