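# Methods

## The sensor model

`sprsim` models a prism-coupled surface-plasmon-resonance (SPR)
refractometer in the Kretschmann geometry: a BK7 prism, a thin silver
film, a 20 nm sensing film, and air, illuminated with p-polarized
632.8 nm light from the prism side.  Beyond the critical angle the
prism-side evanescent wave can phase-match the surface plasmon of the
silver/sensing-film interface; the transfer of energy into the plasmon
appears as a sharp minimum (the *dip*) in the reflectivity-versus-angle
curve.  The dip angle shifts when the refractive index of the sensing
film changes, which is the transduction mechanism.

The sensing film is itself a composite: magnetite-core/gold-shell
nanoparticles (Fe₃O₄@Au), each wrapped in a biomolecular shell (blood
plasma, haemoglobin cytoplasm, or lecithin), suspended in water.  Its
optical response is reduced to a single complex permittivity by three
nested quasi-static homogenizations, and that permittivity feeds the
multilayer reflectivity calculation.

All quantities are single-wavelength; dispersion models are out of
scope.  The magnetic response of the magnetite core is not modelled
(no external field is applied); only its permittivity enters.

## Homogenization chain

**Core-shell grain.**  A core of permittivity εc and radius b inside a
shell of permittivity εs and outer radius a is replaced by

    εeff = εs · [(εc + 2εs) + 2f(εc − εs)] / [(εc + 2εs) − f(εc − εs)],
    f = (b/a)³,

the internal-homogenization (equivalent-sphere) result.  εeff depends
on the radii only through the fill fraction f; f is always computed
from the exact radii, never from rounded display values.  The limits
f→0 ⇒ εs and εc=εs ⇒ εs are exact (the first is short-circuited so the
identity holds bit-for-bit).

**Complex particle.**  The grain (ε₂ = εeff) wrapped in a biomaterial
shell (ε₁) to outer radius R is reduced with the same coated-sphere
algebra,

    εn = ε₁ · [(2ε₁ + ε₂) + 2α(ε₂ − ε₁)] / [(2ε₁ + ε₂) − α(ε₂ − ε₁)],
    α = (a/R)³.

At α = 1 the expression reduces exactly to ε₂ (numerator 3ε₁ε₂ over
denominator 3ε₁), which the code short-circuits.  The formula is
verified in the tests against an independent route: the classical
coated-sphere polarizability in an arbitrary auxiliary host, inverted
through the Clausius–Mossotti relation.

**Composite film.**  Complex particles at volume fraction F in water
(εm) are mixed with a Maxwell-Garnett-type relation,

    (1−F)(ε − εm)/(2ε + εm) + F(ε − εn)/(ε + εn) = 0,

solved as a quadratic in ε.  Note the second denominator: the textbook
Maxwell-Garnett form would read (εn + 2ε).  Both variants are
implemented (`variant="paper" | "standard"`, default `"paper"`); they
give genuinely different mixtures and are never asserted equal — each
solver is checked only against its own relation's residual (< 1e-10).

*Root selection.*  The quadratic has two roots.  The physical one is
chosen by continuity in F: F is marched from 0 (where the solution is
exactly εm) to its target in steps ≤ 0.02, keeping at each step the
root nearest the previous one.  The selected root must be passive
(Im ≥ −1e-12); if the tracked root fails passivity but the other
passes, the passive root wins; if both fail, an error carrying both
roots is raised.  The endpoints F = 0 and F = 1 short-circuit to εm
and εn exactly.

## Constituent calibration

The core (Fe₃O₄) and shell (Au) permittivities at 632.8 nm are not
hard-coded.  They are recovered by root finding from two rows of the
core-shell characterization grid — the extreme fill fractions
f = (10/11)³ ≈ 0.751 and f = (10/100)³ = 0.001 — which maximizes the
conditioning of the 2-complex-unknown system.  Initialization follows
the physics: εs starts at the effective permittivity of the smallest-f
row (a nearly solid shell sphere) and εc at that of the largest-f row.
Every *other* row of the three characterization grids is held out and
reproduced by forward evaluation to well under 1 % relative error,
which validates the calibration.

The recovered values are

    εc = 3.28647 + 3.14599i   (magnetite-like, lossy dielectric)
    εs = −10.5616 + 1.27695i  (gold-like noble metal at 632.8 nm)

both regenerated at run time, flagged `calibrated` in the registry,
and overridable with literature constants.

Two structural caveats, established during development and enforced by
the tests:

* **Two-branch ambiguity.**  Two rows determine (εc, εs) only up to a
  quadratic two-branch ambiguity; a second exact solution generally
  exists.  A well-posed calibration therefore anchors the shell with a
  near-zero-f row (as the built-in pair does).  The round-trip property
  test draws its small-f row in (0.002, 0.08) accordingly.
* **Lossless degeneracies.**  For strictly lossless constituents the
  forward map has real poles (quasi-static coated-sphere resonances)
  and non-injective combinations (εc + 2εs = 0 makes εeff constant in
  f).  The physical target — a lossy metal shell — is free of these;
  the property tests require Im(εs) > 0.
* **Homogeneous convention.**  If every calibration row carries the
  same effective permittivity, the system is underdetermined in εc; by
  construction of the initialization the solver returns εc = εs = εeff.

## Reflectivity

The stack is prism half-space / films / exit half-space.  The
transverse wavevector in layer j is kz = √(εj k0² − kx²) with
kx = k0·np·sinθ set in the prism; the square-root branch is fixed by
Im(kz) ≥ 0 (fields decay away from interfaces), with Re(kz) ≥ 0 when
Im(kz) = 0.  Angles are degrees at every interface, radians internally.

Two independent formulations are implemented and cross-checked to
1e-10 on random passive stacks up to six layers:

* the recursive two-interface Fresnel combination
  r = (r_ij + r_sub·e^{2i kz d}) / (1 + r_ij·r_sub·e^{2i kz d}),
  folded from the exit side inward (this generalizes the three-medium
  formula to N media);
* the 2×2 characteristic (Abeles) transfer matrix with tilted
  admittances q = kz/ε (p) or q = kz (s).

s-polarization is implemented for testing symmetry (the polarizations
must coincide at normal incidence) but the sensor path uses p only.
Energy conservation (R ∈ [0, 1]) and the zero-thickness-layer deletion
identity are property-tested.

## Dip localization and metrics

The angular scan default is 40–60° at 0.005° (dip positions are quoted
to 0.01°, so the grid oversamples by 2×).  The dip is the global grid
minimum refined by a parabola through the minimum and its two
neighbours — exact for locally quadratic minima, reproducible without
derivatives, and invariant to halving the grid step within 0.01°.
When the generating stack is attached to the spectrum, the reflectivity
at the refined angle is re-evaluated exactly rather than interpolated.
A minimum on the scan boundary is reported unrefined with a warning.

The analytic resonance condition
θ = arcsin(√(εm nd²/(εm + nd²))/np), with εm the real part of the metal
permittivity, serves as an oracle for the three-layer limit: its angle
must sit within 0.3° of the numeric dip of an optically thick (100 nm)
silver film.  Thicker films (≥150 nm) were found to flatten the
minimum onto the scan boundary — the metal becomes a mirror — so
100 nm is the thickest film with a resolvable, position-converged dip.

Sensitivity is S = Δθ/Δn (deg/RIU), with Δn the analyte index minus
the water reference; the enhancement of a core-shell sensor over a
baseline is (S_with − S_without)/S_without × 100 %.  The "with" label
is deliberately assigned to the core-shell-bearing system so that an
improved sensor reports a positive percentage.

## Scenario grid and its defaults

`make_fixtures()` enumerates 34 deterministic scenarios: two pure-film
references (water; the Hb film at n = 1.3871 whose dip is the 45.44°
four-layer benchmark), one no-core-shell mixture per biomaterial at
F = 0.1, the with-core-shell grid (3 biomaterials × a ∈ {2.5, 5, 7.5,
10} nm × F ∈ {0.1, 0.8}) at f = 0.73, and a silver-thickness sweep
{20, 30, 40, 50, 60} nm.  f = 0.73 is the moderate characterization
value chosen for reflectivity work (the f = 0.85 alternative leaves a
sub-nanometre shell); F = 0.1 and 0.8 bracket dilute and crowded
suspensions; 40 nm silver is the optimum of the sweep.

**α is an assumption, not a datum.**  The complex-particle radius R is
never fixed by the source scenarios, so α = (a/R)³ is a free parameter;
fixtures default to α = 0.73, mirroring f, and every interface exposes
an override.  Two consequences, stated plainly:

* the composite dip angles are only qualitatively comparable to the
  reference scenario values (ordering and rightward shift are checked;
  absolute composite dip angles are not);
* at fixed f and fixed α the homogenization chain depends on no radius
  at all, so the dip is *exactly flat* in a — the "non-decreasing in a"
  trend holds degenerately.  A strictly increasing trend would require
  an a-dependent α (e.g. a fixed biomaterial shell thickness R − a).

## What the scenario generator does and does not emulate

The generator reproduces idealized model conditions: perfectly smooth
layers, a single wavelength, quasi-static (dipolar) particles, no
particle-particle correlation (dilute Maxwell-Garnett), no roughness,
no size-dependent damping of the metal shell, no beam divergence.
Passing tests therefore demonstrate internal consistency of the model
chain and fidelity to its reference values — not agreement with a
physical instrument, where finite spot size, roughness and dispersion
broaden and shift real dips.

## Numerical choices

* Calibration: scipy `root` (hybr, lm fallback) on the 4-real-unknown
  system; square-system residual must be < 1e-6 absolute.
* Mixing quadratic: citardauq pairing (larger-magnitude root first,
  companion from the product) to avoid cancellation; residual < 1e-10.
* Pole detection: a homogenization denominator is declared vanishing
  when |den| ≤ 1e-30·max(1, |num|); an error is raised rather than a
  number returned.
* Known turnover: Im(εeff) of the core-shell is *not* monotone in f up
  to f → 1 (the limit is Im(εc), below the mid-grid maximum); the
  monotonicity test asserts Im growth only below f = 0.75.
* Everything is deterministic; CSV output is full double precision
  (`%.17g`), LF line endings, so repeated runs are byte-identical.

## Known limitations

Single wavelength; quasi-static homogenization only (no Mie/multipole
corrections, invalid for particles approaching the wavelength); the
non-standard mixing denominator is retained by default for fidelity to
the reference relation with the textbook form behind a switch; α must
be supplied by the user for quantitative composite work.
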