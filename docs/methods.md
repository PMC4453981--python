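# Methods

This note documents the models implemented in `beadsas`, the conventions
chosen where more than one reading was defensible, and what the test
fixtures do and do not establish about real data.

## Units

All lengths are nm, all scattering vectors Q are nm⁻¹, intensities are in
arbitrary units. PDB files store Angstrom; conversion happens once, in
`io_formats`, on read and write.

## Sequence-derived properties

The dry (unhydrated) volume of a macromolecule is the sum of per-residue
unhydrated crystal-structure volumes over its composition; the packaged
table (`data/residue_volumes.yml`, label `consensus_crystal`) covers the
20 amino acids and 7 monosaccharides and is the only set wired into
modelling, though further sets can be loaded under new labels. Table
values are stored in 10⁻³ nm³ (the Å³ scale natural for single residues).

The hydration monolayer is parameterized by two constants: 0.3 g of bound
water per gram of macromolecule, and 0.0245 nm³ per bound water molecule
(vs 0.0299 nm³ in bulk water — shell water is more tightly packed). The
hydrated volume is therefore

    V_hyd = V_dry + (0.3 M / 18.015) × 0.0245 nm³.

Molecular weights use standard average residue masses (free monomer minus
one water; anhydro masses for glycosidically linked sugars) plus one water
per chain for the termini. The partial specific volume is v̄ = N_A V/M.
The 280 nm absorption coefficient uses the standard molar extinctions
5500 (Trp), 1490 (Tyr) and 125 (cystine) M⁻¹cm⁻¹ with all cysteines
assumed paired; it and v̄ are reported for convenience (AUC work) and play
no role in modelling. With the consensus volume table, v̄ comes out at
0.76–0.79 cm³/g for typical protein compositions (0.763 for lysozyme's),
at the high end of experimental values — a property of this volume set,
not an implementation artefact. Neutron/X-ray scattering densities and
matchpoints are not computed: they would need per-residue atomic
compositions that are outside this package's data.

## Grid transformation

The counting grid is anchored at the per-axis minimum coordinate of the
input (an optional fixed origin is available for strict comparability
across models). A box spawns a sphere at its centre, radius = boxside/2,
when it holds **at least** `cutoff` points; the inclusive threshold
matches the way the published cutoff value of 4 is used in practice, and a
`strict` flag provides the strictly-greater-than reading. Every run logs
the threshold semantics. An empty result (all boxes under the cutoff) is
returned with a warning rather than raised, so directory-scale runs can
record the failure and continue.

Model volume defaults to the **box convention** n·boxside³, which is
self-consistent with grid occupancy (each sphere stands for one full box);
the literal sphere convention n·(4/3)πr³ is available via a parameter.
The box convention is what the volume optimizers target.

## Hydration (four steps)

1. Every dry sphere is surrounded by 26 candidate water spheres on the
   corners, edge mid-points and face centres of a cube of side 4r — the
   offsets {−2r, 0, +2r}³ minus the origin.
2. The expanded set (dry + candidates) is grid-filtered on the dry model's
   box side with a user-set cutoff (spheres per box; the optimum is
   typically 10–12).
3. The original dry spheres are added back: extended, thin structures can
   lose spheres in step 2.
4. A final grid pass with cutoff 1 removes overlaps: one sphere per box,
   keeping the first with dry spheres ordered first. Keep-first (rather
   than keep-nearest-box-centre) guarantees every dry centre survives,
   which is the property downstream code relies on; the choice only
   affects which of several near-coincident hydration spheres represents
   a box.

Raising the step-2 cutoff filters more candidates, so the hydrated sphere
count and volume are non-increasing in the cutoff — this monotonicity is
what makes the cutoff table of `optimize_hydration_cutoff` interpretable.

## Parameter optimization

`optimize_box_side` scans the box side over [0.1, 1.5] nm at 10⁻³ nm
resolution and returns the grid point whose box-convention volume is
closest to the sequence-derived dry volume. The objective is
piecewise-constant in the side with many small jumps, so an exhaustive
scan (≈1400 grid transforms, well under a second for 10⁴ atoms) is both
simpler and more robust than a line search; if the best relative error
exceeds a configurable threshold (default 2 %) a warning is issued and
the best side still returned. `optimize_hydration_cutoff` hydrates at each
candidate cutoff (default 1–14) and returns the argmin plus the full
(cutoff, volume) table for the user's judgement.

## Debye curve

Pair distances are histogrammed either in *classic* mode (400 bins from
zero, user-set width; an out-of-range distance is an error, never a silent
truncation) or *modern* mode (user-set bin count spanning the observed
[min, max] pair distance). The curve on the q grid (npoints equally spaced
values on (0, qmax], Q = 0 excluded) is

    I(Q)/I(0) = g(Q) [ 1/n + (2/n²) Σ_j A_j sinc(Q d_j) ],

where the 1/n term is the self-contribution of the n spheres and
Σ A_j = n(n−1)/2 forces I → 1 as Q → 0. sinc is evaluated through its
series limit at small argument, and the sphere amplitude is
series-expanded below Qr = 10⁻³. With ≥ 2000 bins the histogrammed curve
agrees with the exact all-pairs sum to well under 1 % over Q ≤ 2 nm⁻¹ for
models up to a few hundred spheres (measured ≈ 0.1 %); accuracy improves
with bin count, and pair distances are accumulated in row blocks above
6000 spheres to bound memory.

## Smearing

SANS instrumental resolution is modelled as convolution with a unit-area
Gaussian whose width combines beam divergence and wavelength spread. The
width relation is a documented **convention of this package**: both inputs
are treated as FWHM contributions added in quadrature,

    FWHM(Q) = sqrt[ ((4π/λ)·Δθ)² + (Q·Δλ/λ)² ],   σ(Q) = FWHM/2.3548,

and an injectable `sigma_func` supports instrument-exact forms. The
discrete convolution runs on the curve's uniform q grid with reflective
edge handling, which preserves constant curves exactly; a curve shorter
than the kernel support is rejected, as is re-smearing an already smeared
curve. The flat incoherent baseline (a fraction of I(0), typically
0.5–1.5 %) is added only after curve fitting; the R factor refuses a
baseline-corrected theoretical curve to enforce that ordering.

## Guinier fits

Rg comes from an unweighted least-squares fit of ln I vs Q²
(Rg² = −3·slope, I(0) = exp(intercept)); Rxs from ln(IQ) vs Q²
(Rxs² = −2·slope) in a window that must lie above the Rg window.
Experimental error columns are read but not used as weights. Fits need at
least three points with positive intensity and a negative slope; a
positive slope is an error, not a NaN. The recommended Q·Rg range is
0.5–1.5 and leaving it triggers a warning. For a globular body the
Guinier approximation itself is biased high within that band (+1.3 % for
a uniform sphere fitted over Q·Rg 0.5–0.9, +2.4 % over 0.5–1.3, measured
on the analytic sphere form factor), so recovery tests fit at the low end
of the band; users comparing theoretical and experimental Rg values
should use the same window for both, where this bias cancels.

## R factor

Theoretical points are matched to each experimental Q by nearest
theoretical Q (equidistant ties resolve to the lower Q). The objective
R(η) = 100·Σ||I_e| − η|I_t||/Σ|I_e| is piecewise linear and convex in η,
so the minimizing scale is computed exactly as the weighted median of the
ratios |I_e|/|I_t| (weights |I_t|), rather than by iterative search; a
dense grid scan confirms the minimum in the tests. η scales the
theoretical curve (not the experimental one).

## Workflow

`analyse_directory` processes models in sorted name order. The X-ray
branch hydrates before computing the curve; the neutron branch always
uses the dry model (the hydration shell is invisible to SANS in ²H₂O) and
smears only when enabled. Outputs are two tab-separated tables — the
experimental Guinier summary (file, Rg, Rxs1, Rxs2) and the per-model
comparison (model, branch, model/curve Rg, Rxs, volume, then R % and η
per experimental curve) — plus sphere models and curves under
`<branch>/models` and `<branch>/curves`, and a timestamp-free JSON run
manifest recording the box side, cutoffs, binning, smearing and threshold
semantics. There is no randomness anywhere in the pipeline, so repeated
runs are byte-identical. A model that yields fewer than two spheres is
recorded as a failed row and the run continues.

## Synthetic fixtures

The fixture generator samples uniform atom clouds in balls, rods,
dumbbells and cubic lattices, with analytic Rg and envelope volume
attached (ball √(3/5)R; rod √(L²/12 + a²/2); dumbbell by the
parallel-axis theorem). Default sizes (R ≈ 2–3 nm, 10³–10⁴ points) sit in
the range of small globular proteins, and test "experimental" curves add
1–5 % multiplicative Gaussian noise, typical of well-measured solution
data. Workflow tests use 3–5 models of ~1200 atoms and 100-point curves
so the whole suite runs in seconds; the algorithms are size-independent
and the Debye cost grows as histogram bins × q points.

What the fixtures do **not** emulate: real atomic packing density and
chemistry (clouds are uniform, one pseudo-residue per atom), sequence
inhomogeneity, inter-particle interference, aggregation, buffer
subtraction artefacts, or realistic counting-statistics error models.
Passing tests establish the correctness of the geometry, the curve
mathematics and the fitting machinery — not that a particular biological
model is right.

## Known limitations

- Gaussian smearing only; triangular/trapezoidal resolution profiles and
  desmearing of slit-geometry laboratory SAXS data are out of scope.
- No χ² goodness-of-fit alternative; scoring is the R factor.
- Uniform sphere radii and unweighted atom counting (no mass/electron
  weighting, no solvent-accessibility-aware hydration).
- Single-model PDB files only; no mmCIF, no multi-model NMR ensembles.
- Experimental error columns are carried but never propagated.
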