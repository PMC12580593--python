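# Methods

## Scope and model

The package rebuilds a segmented, scalar-relativistically contracted
Gaussian basis for titanium and the statistical calibration of Ti-49
chemical shifts computed with it. Everything runs on a single atomic
center: molecular geometry optimization, GIAO shielding calculations and
continuum solvation belong to external quantum-chemistry engines, for
which the package only emits input decks and consumes shielding/shift
tables.

## Well-tempered exponent ladders

Each angular-momentum channel carries a geometric ladder
ζ_j = α_l χ^(−j), j = 0 … n−1, so the largest generated exponent equals
α_l. The index convention is forced by α_l's role as the *maximum*
exponent: starting the ladder below α_l would leave the printed channel
maxima out of the basis. The packaged Ti constants (α_s, α_p, α_d at 14
significant figures; χ = 2.50, 2.75, 3.00; 18s/11p/6d) are treated as
canonical inputs; the multiconfigurational Dirac–Fock radii they derive
from are not recomputed. Exponents are kept at full double precision and
only rounded in text writers (14 significant digits).

## One-center integrals

Basis functions are normalized real spherical Gaussians
N r^l e^(−ζr²) S_lm. On a single center every operator factorizes into a
closed-form radial integral and an angular factor:

- overlap, kinetic, nuclear attraction and pVp are diagonal in (l, m)
  with elementary radial forms;
- the axial dipole couples Δl = ±1 at equal real-m;
- the electron repulsion integral is the finite multipole series
  (ab|cd) = Σ_L (4π/(2L+1)) ⟨S_a S_b S_LM⟩⟨S_c S_d S_LM⟩ R^L with real
  Gaunt coefficients and radial Slater integrals R^L.

R^L for Gaussian pair densities reduces to elementary functions. Two
numerical regimes are distinguished: the complementary closed form (an
erfc moment with a stabilized tail series) when the two pair exponents
are comparable, and a power-series expansion of the inner integral when
they are strongly separated; the kernel's symmetry always places the
tighter pair outside. This keeps relative accuracy near 1e−12 over the
ten decades an 18s ladder spans — verified against 30-digit mpmath
quadrature. Real Gaunt coefficients are obtained by Gauss–Legendre ×
trapezoidal spherical quadrature (exact for band-limited integrands, and
matching sympy's `real_gaunt` to machine precision) and cached.

The full ERI tensor is materialized per basis (≈ 0.35 GB for the
81-function primitive set), which keeps each SCF iteration at a few
matrix–vector products; a guard refuses > 400 functions.

## Atomic UHF

Spin-unrestricted SCF with per-shell fractional occupations. The Ti
ground configuration [Ar]4s²3d² (³F) is spherically averaged: the two
parallel-spin d electrons occupy the five α d spin-orbitals at 0.4 each.
This keeps the zero-field density totally symmetric, so each channel's
contraction coefficients are rotationally well defined. Orbitals are
obtained per symmetry block — (l, m) blocks at zero field, real-m blocks
with a field on, since an axial field preserves m and the axial
reflection symmetry. With the field on, occupations follow aufbau
ordering of the perturbed orbital energies per spin while keeping the
zero-field fractional weights, which makes the optimizer's objective
smooth.

Convergence machinery: core-Hamiltonian guess, DIIS with an 8-vector
window and 0.7/0.3 damping fallback, thresholds ΔE < 1e−10 hartree and
max orbital-gradient element < 1e−7. Everything is deterministic given
the inputs. The field enters as +F·z; atomic parity makes the energy even
in F (asserted by a test), so the sign convention is immaterial.

Anchors: hydrogen gives −0.5 hartree to 1e−4 on a 20-term ladder; helium
and neon reproduce their Hartree–Fock limits (−2.86168, −128.5471) to
basis accuracy; the converged nonrelativistic Ti atom satisfies the
virial ratio to 4e−5.

## DKH2 Hamiltonian

The scalar second-order Douglas–Kroll–Hess one-electron Hamiltonian is
built per l channel in the kinetic-energy eigenbasis from the V and pVp
matrices: free-particle Foldy–Wouthuysen kinematic factors
A_p, K_p = c/(E_p + c²) give the first-order even term
AVA + (AK) pVp (KA); the second-order even term is assembled from the odd
(large–small) block B_ik = A_i A_k (K_i pVp_ik/p_k − V_ik p_k K_k) via
E2 = ½(W Bᵀ + B Wᵀ), W_ik = B_ik/(E_i + E_k) — algebraically identical to
the standard matrix-DKH2 expression Σ_k w_ik w_jk [(E_i+E_j)/2 + E_k].
c = 137.035999084 a.u. (CODATA), point nucleus.

Limits verified: c → ∞ recovers T + V elementwise below 1e−6 hartree; the
hydrogen 1s DKH2 eigenvalue reproduces the exact Dirac value −0.5000067
hartree to 2e−6 (DKH2 is complete at this order in (Zα)²); heavy
one-electron ions are stabilized relative to the nonrelativistic level
and approach it monotonically as c grows. At very high Z the DKH order
expansion converges slowly for deep s levels (a known property of the
method, irrelevant at Z = 22): the basis-converged Z = 90 1s eigenvalue
sits between the nonrelativistic and Dirac values.

## f-polarization optimization

The three f exponents minimize the field-perturbed (F = 0.01 a.u.)
UHF-DKH2 total energy of the atom on the contracted [12s6p3d] stage,
optimized independently (unconstrained, not even-tempered) by
Nelder–Mead in log-exponent space from a (3.0, 1.0, 0.3) start. The
occupied 3d shell is what couples the f functions to the field response
at second order; with no field and no occupied f character the objective
is flat, which the optimizer detects and flags. The optimization is
local by design: an aufbau occupation in a finite field always has a
runaway basin toward extremely diffuse functions (field-tilted orbitals),
and the physically meaningful optimum is the interior one near the 3d
length scale. For Ti the optimizer lands at ≈ 3.52, 1.11, 0.36 (ratios
≈ 3.1), and a scaled-down grid-search oracle on a reduced Ti-like atom
confirms the optimizer to better than 1 %. Near-collapsing exponents
(ratio < 1.2) trigger a warning.

## Contraction

Strictly segmented: per channel one contracted segment of the innermost
primitives plus free primitives, with segment sizes forced by the counts
(18−11 = 7 s, 11−5 = 6 p, 6−2 = 4 d, 3−1 = 2 f). Coefficient sources are
the deepest orbital of each symmetry (1s, 2p, 3d) from the zero-field
UHF-DKH2 run; the f segment takes the f-channel components of the lowest
field-perturbed m = 0 orbital with Mulliken f weight ≥ 0.2, restricted to
the two tightest f primitives. Every contracted column is renormalized
under the radial overlap metric and signed so its innermost coefficient
is positive. Function counting uses spherical multiplicities (1, 3, 5, 7),
giving the 102 GTO / 59 CGTO totals; Cartesian counting (1, 3, 6, 10)
would give 117/68 and is provided for contrast.

The f-segment recipe is the one genuinely open design point (the original
construction cites an external method without equations); comparisons of
f coefficients against a published reference file are therefore reported
by the diff tool rather than asserted by tests.

## Shift calibration and statistics

δ = σ_ref − σ_calc (direct) and δ = a σ_calc + b (calibration; the
packaged line is a = −1.0027, b = −1000.0, which reduces to the direct
model at a = −1, b = σ_ref). Statistics per protocol: AD_i =
|δ_expt,i − δ_calc,i|, MAD = mean, SD_AD = sample (n−1) standard
deviation — the convention is recorded in the output because the source
tables do not define it and both conventions agree at printed precision —
RD_i = 100·AD_i/|δ_expt,i| (experimental magnitude in the denominator, as
the geometry table confirms), MRD = mean, plus slope and R² of calc vs
expt. Relative deviations are refused when an experimental value is zero.

The packaged fixtures store calculated shifts as printed (integer ppm)
and experimental values as printed (up to one decimal). Recomputed
summary statistics therefore differ from the published summaries by up to
the rounding of the underlying table: most reproduce exactly at printed
precision; the τHCTH MAD recomputes to 45.6 ppm against a printed 45
(inside the ±1 ppm rounding band), and two geometry rows print relative
deviations inconsistent with their own quoted lengths. Where only shift
columns exist, the shielding predictor is reconstructed as σ = K − δ_calc
with arbitrary K: ordinary least squares is affine equivariant, so slope
and R² are exact and only the intercept moves with K. The reference
shielding is recovered by jointly inverting the direct and calibration
columns of the external set (least squares over the nine row pairs,
residuals < 2 ppm).

## Problem sizes

The test suite runs the full primitive-basis Ti SCF (81 functions, both
Hamiltonians, shared across tests), small-model SCFs for the optimizer
oracle, and the complete statistics suite; the acceptance script
additionally runs the end-to-end rebuild with the f optimization capped
at 150 objective evaluations (fatol 1e−7), which reaches the same
exponents as the uncapped run to the reported precision.

## Limitations

- One center only; no electron correlation; no spin–orbit coupling; no
  four-component Hamiltonians (published four-component deviations are
  not recomputed here).
- Shieldings are consumed, never computed: protocol quality statements
  are conditional on externally supplied σ/δ tables.
- The synthetic regression-recovery check models calibration noise as
  i.i.d. Gaussian (30 ppm) over the experimental shift range; real
  protocol errors are structured (e.g. heavy-halide complexes), so that
  check validates the estimator, not the chemistry.
- DKH2 accuracy degrades for deep s levels at Z well beyond titanium.
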