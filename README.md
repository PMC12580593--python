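# nmrdkh

Construction toolkit for the **NMR-DKH basis set for titanium** and the
**Ti-49 NMR chemical-shift calibration** built on it.

Ti(IV) complexes — catalysts, and candidate anticancer metallodrugs — are
routinely characterized by ⁴⁹Ti NMR, whose chemical shifts span almost
3000 ppm (from −1389 ppm for [Ti(CO)₆]²⁻ to +1375 ppm for the neophyl
complex). Predicting δ⁴⁹Ti from first principles needs an all-electron
basis set whose core is contracted with scalar-relativistic weights, plus
a statistical calibration of computed shieldings against experiment. This
package rebuilds both ingredients and the benchmark statistics used to
validate them.

## What it computes

**Basis construction** (`nmrdkh.welltempered`, `atomic_scf`, `contraction`,
`basis_io`):

- well-tempered primitive ladders ζ_j = α_l χ^(−j) per channel, with
  α_l = k_l² f_l²/(π r_l²) from the innermost radial extent of the atomic
  density; for Ti: α_s = 131685.903249881, α_p = 1375.44747973736,
  α_d = 24.0073133461147 with χ = 2.50/2.75/3.00 and 18s/11p/6d primitives;
- a one-center unrestricted Hartree–Fock engine over real spherical
  Gaussians (analytic one-electron, dipole, pVp and two-electron
  integrals via the one-center multipole expansion), with an optional
  second-order Douglas–Kroll–Hess (DKH2) scalar-relativistic one-electron
  Hamiltonian and an optional axial finite field;
- three f-polarization exponents optimized to minimize the UHF-DKH2
  energy in a field of 0.01 a.u.;
- the strictly segmented contraction (18s11p6d3f) → [12s6p3d2f] — 102
  primitive and 59 contracted spherical functions — with segment
  coefficients taken from the deepest converged orbital of each symmetry;
- writers/readers/diffing for Gaussian "gen", NWChem and JSON dialects,
  and protocol input decks for external engines.

**Shift calibration** (`nmrdkh.shiftlab`, `fixtures`): the direct shift
model δ = σ_ref − σ_calc, the fitted calibration δ = a·σ_calc + b
(published line: δ = −1.0027 σ_calc − 1000.0), and the benchmark
statistics (MAD, SD, RD, MRD, slope, R²) over the packaged 41-complex
calibration set, 9-complex external set and 7-bond geometry table.

## Worked example

Benchmark statistics of the recommended GIAO-OLYP protocol over the
41-complex calibration set:

```sh
$ shift eval --table table3 --functional OLYP
```

(`shift` is also a POSIX shell builtin; in interactive bash invoke it as
`env shift ...`.)

prints (abridged) `"mad": 48.18, "sd_ad": 58.48, "mrd": 9.48, "r2": 0.9888`
— a mean absolute deviation of 48 ppm and mean relative deviation of 9.5 %
against experiment, with the per-complex deviation list following (the
[TiI₄] outlier contributes 209 ppm).

The calibration line and the external validation:

```sh
$ shift fit --table table3 --functional OLYP
{"a": -1.0027, "r2": 0.9888, "n": 41, ...}
$ shift external
{"direct": {"mad": 40.3, ...}, "model": {"mad": 48.1, ...},
 "sigma_ref": -1026.0, ...}
```

The slope of −1.0027 (R² = 0.9888) means the computed shielding tracks the
experimental shift almost exactly with the physical −1 proportionality;
the recovered σ_ref ≈ −1026 ppm is the implied shielding of the TiCl₄
reference, consistent across all nine external complexes to better than
2 ppm.

Rebuilding the basis end to end (atomic DKH2 SCF, f optimization,
contraction, export — a few minutes):

```sh
$ rebuild all -o ti_nmr_dkh.gbs --report report.json
```

The report records the converged UHF-DKH2 energy (−852.3599 hartree on
the primitive set), the optimized f exponents (≈ 3.52, 1.11, 0.36) and
the 102 GTO / 59 CGTO counts; the exported file carries 12 s, 6 p, 3 d
and 2 f shells.

## Layout

| module | contents |
| --- | --- |
| `nmrdkh.welltempered` | channel parameters, exponent ladders |
| `nmrdkh.atomic_scf` | integrals, DKH2, UHF, f-exponent optimization |
| `nmrdkh.contraction` | scheme parsing, segments, coefficient extraction |
| `nmrdkh.basis_io` | dialects, comparison, protocol decks |
| `nmrdkh.shiftlab` | shift models, regression, deviation statistics |
| `nmrdkh.fixtures` | packaged benchmark tables with integrity checks |
| `nmrdkh.pipeline` / `nmrdkh.cli` | end-to-end driver and the `forge`/`shift`/`rebuild` commands |

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
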