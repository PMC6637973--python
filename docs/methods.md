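# Methods

## The charge-density model

Atomic partial charges taken from a PSF are point values fitted to a force
field; using them as literal point charges makes any local density estimate
ill-defined.  The package models each atom's charge as an isotropic
Gaussian centred on the atom,

ρ(**r**) = C(a) Σᵢ qᵢ exp(−(|**r** − **r**ᵢ| / 2a)²),   C(a) = (4πa²)^(−3/2),

so ρ is smooth everywhere and ∫ρ d³r = Σ qᵢ holds identically.  The
exponent convention means the Gaussian's standard deviation is σ = a√2;
the normalisation C(a) is the unique prefactor with the correct e·Å⁻³
units that makes each atom's cloud integrate to its own charge.  A variant
of this prefactor with `a` in place of `a²` circulates in the literature;
it is dimensionally inconsistent (and coincides numerically only at
a = 1 Å), so this package uses C(a) = (4πa²)^(−3/2) throughout and
enforces the choice with conservation tests at widths ≠ 1 Å.

### Radial integrals in closed form

All radial quantities are measured from the capsid centre.  For a unit
Gaussian of width *a* centred at distance *d* from the origin, the charge
inside radius *R* is

F(R; d, a) = (a / d√π) [exp(−((R+d)/2a)²) − exp(−((R−d)/2a)²)]
           + ½ [erf((R−d)/2a) + erf((R+d)/2a)],

obtained by integrating the angular part of the off-centre Gaussian
analytically.  For d → 0 this reduces to
erf(R/2a) − (R/a√π)·exp(−R²/4a²); the implementation switches to that
centred limit below d/a = 10⁻⁶, where the general expression loses
precision to cancellation.  Shell charges are then
Q(r₁, r₂) = Σᵢ qᵢ [F(r₂; dᵢ, aᵢ) − F(r₁; dᵢ, aᵢ)], and the surface charge
density σ(r) = dQ(0, r)/dr has the matching closed form.  Both are exact
(to floating point) and cost O(N) per query; adaptive quadrature and
Monte-Carlo integration exist only as independent oracles in the test
suite, never as the production path.

Because Q is computed from a cumulative function, shell additivity
Q(r₁, r₃) = Q(r₁, r₂) + Q(r₂, r₃) and histogram-refinement consistency
hold to rounding error by construction.

### Numerical choices

- **Effective infinity.**  "All space" integrals are truncated at
  R_max = maxᵢ(dᵢ + 12aᵢ); the neglected tail of each Gaussian is below
  10⁻¹² of its charge.
- **Mode of the radial density.**  The surface-charge kernel of an atom at
  distance d peaks at d + 2a²/d, not exactly at d — the r² solid-angle
  factor shifts the mode outward.  The shift is 0.4 Å at d = 5 Å and
  negligible at capsid radii (0.02 Å at d = 100 Å, a = 1 Å).
- **Degenerate inputs.**  σ(0) = 0 exactly (the r² factor); zero-width or
  unset-charge models are rejected at construction; a single-atom
  structure has a histogram but no defined R_in/R_out (reported as NaN).

## Centre and capsid radii

The capsid centre is the unweighted centroid of atom positions
(charge-weighted centres are undefined for net-neutral shells); a
mass-weighted option uses PSF masses.  R_in/R_out are the 1st/99th
percentiles of atomic radial distances, widened by 2a on each side —
percentiles are robust to stray tails such as disordered termini.  The ±2a
margin keeps ~92% of an edge atom's Gaussian inside the band (each side
leaks ½·erfc(1) ≈ 7.6% of the atoms exactly at the percentile radius);
callers needing essentially-complete capture (≲10⁻³ of an edge atom's
charge per side) should widen to ±6a.  The histogram bars are integrated
shell charge per bin (e), not mean density, so they sum to the total
charge whenever the last edge reaches R_max.

## Widths

The default global width is a = 1.0 Å.  An optional per-element table maps
the leading letter of the atom name to a van der Waals radius
(H 1.20, C 1.70, N 1.55, O 1.52, S/P 1.80 Å); when active, every formula
uses aᵢ inside the atom sum.  As a → 0 the model reproduces plain charge
counting per shell, which the tests verify at a = 0.01 Å.

## Symmetry expansion

Expansion applies x′ = R·x + t per operator, transform-major, recording
each copy's operator serial as provenance; charges replicate unchanged, so
the expanded total is exactly T× the unit's.  Improper operators
(det R = −1) are rejected.  Deposited BIOMT operators take priority; the
built-in icosahedral set — the 60 proper rotations of I, generated by
closure from a 5-fold rotation about a vertex axis (0, 1, φ) and the
2-fold about z, in the orientation with 2-fold axes along the coordinate
axes — must be requested explicitly, never assumed.  No coordinate-
proximity deduplication is performed: silently collapsing duplicate copies
would corrupt charge totals.

## File handling

PDB parsing uses the fixed columns of the standard (coordinates in columns
31–54); only altloc ' '/'A' atoms are kept, HETATM is excluded by default,
and hydrogens are never stripped (PSF charge sets balance only with
hydrogens present).  PDB↔PSF pairing is strictly positional — PSFs
produced alongside a PDB share its ordering, and name-based matching is
ambiguous across naming schemes — with any count mismatch a hard error.
PSF atom lines are whitespace-tokenised, which accepts the X-PLOR, CHARMM
and EXT dialects uniformly; the NATOM header count is enforced against the
parsed row count.  On write, serials are renumbered 1..N with hybrid-36
encoding above 99999 so complete capsids stay writable, and coordinates
that cannot fit the 8.3 column raise an error rather than corrupt the
field.  All writers are atomic (temp file + rename).

## Synthetic fixtures

The generators emulate the geometry and charge layout of a capsid — thin
concentric atom shells at 10–100 Å radii, partial charges in [−1, 1] e,
optionally balanced to a target net charge, and an asymmetric-unit wedge
whose 60-fold expansion has its centroid at the symmetry centre — using
Fibonacci-sphere placement for reproducible near-uniform coverage and a
seeded generator for jitter and charges.  Random charges are drawn on the
PSF's 6-decimal grid so written fixtures round-trip exactly.  Fixtures do
**not** model protein chemistry: no residue topology, bonds, or realistic
charge correlations.  Passing tests therefore demonstrate the correctness
of the integrals, parsers and symmetry algebra on capsid-scale geometry,
not force-field realism on real capsids, where charge patterns are set by
the PSF and the same code paths apply unchanged.

## Problem sizes and test design

Tests run on fixtures of 10–5000 atoms (expansion tests use 60×100-atom
units; conservation checks sweep 50 seeded fixtures up to 5000 atoms),
chosen so the whole suite exercises every code path in a few seconds while
the quadrature and Monte-Carlo oracles stay accurate.  The Monte-Carlo
agreement check is statistical (3 standard errors, ~0.3% false-alarm rate
per comparison); a fixture exceeding it is re-checked once at 10× the
samples, which suppresses sampling noise while amplifying any real bias.
`scripts/acceptance.py` repeats the headline computations at the same
scales and reports every measured number; nothing in this document states
a result those scripts and tests do not themselves compute.

## Known limitations

- Charge distributions only: no electrostatic potential, field, or
  Poisson–Boltzmann solving.
- PSFs are read, never generated; charge parameterisation is upstream.
- No mmCIF input; no helical/prolate capsid symmetry; no per-chain or
  per-residue charge decomposition.
- The "full capsid" PSF pairing granularity (asymmetric unit vs expanded
  capsid) is the caller's choice; pairing works at either, but the counts
  must match the PDB being paired.
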