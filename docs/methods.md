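# Methods

## Conventions

Images are 2-D integer arrays with the origin at the upper-left corner,
`x` rightward (columns) and `y` downward (rows); `pixels[y, x]` holds the
intensity. A displacement `d = (Δx, Δy)` pairs the reference pixel `(x, y)`
with the target `(x+Δx, y+Δy)`. Co-occurrence counting is ordered and
non-symmetric by default — `P(0,1)` and `P(1,0)` are distinct entries —
with an opt-in `symmetric` flag that adds the transpose. Gray levels are
used natively: no rescaling or requantization is applied to inputs (an
explicit `requantize` helper with uniform bins on `[0, max+1)` is provided
for high-bit-depth real images, whose dense `Ng × Ng` matrix would
otherwise be impractical).

Two pairing conventions are implemented. *Non-cyclic* drops pairs whose
target leaves the image (`(Nx−1)·Ny` horizontal unit pairs, `(Ny−1)·Nx`
vertical ones). *Cyclic* wraps target coordinates modulo the image size, so
every pixel contributes one pair. Cyclic pairing is not part of the
classical GLCM definition; it is included because on a sawtooth gradient
spanning a whole number of periods it eliminates boundary effects entirely
and turns the feature laws into machine-precision identities, giving the
package an exact test surface. Non-cyclic mode is the convention real
pipelines use and is what the full-scale validation sweep exercises.

## The gradient model

The synthetic input class is the one-dimensional sawtooth gradient:
`pixels(x, y) = ∇ · ((sign·y + phase) mod Ñg)` for a vertical gradient,
with `Ñg = 1 + ⌊(Ng−1)/∇⌋`. The wrap happens on the *lattice* of `Ñg`
levels, not modulo `Ng`: taking intensities mod `Ng` would visit
off-lattice levels whenever `Ng−1` is not divisible by `∇` and would
destroy the sub-diagonal structure (`m2` entries at offset `−m1∇`) that the
analysis relies on. `phase` (default 0) sets the starting lattice position;
no published convention fixes the starting level of a descending ramp, so
it is a parameter rather than a guess. The generator produces exact lattice
values — no noise, dithering, or 2-D/nonlinear gradients; those are out of
scope.

What passing tests on this generator do and do not show: the laws are
*exact* for this input class, and real textures contain gradients only as a
local component. Agreement here validates the arithmetic of a GLCM
pipeline and the derived normalization factors; it does not by itself
predict feature values of natural textures, where gradients mix with noise
and curvature.

## Features and numerics

Energy, Contrast, Correlation and Homogeneity are computed from the
normalized matrix exactly as stored. Contrast is accumulated over an
integer histogram of absolute level differences and divided by the pair
total once at the end; this keeps whole-period cyclic measurements exactly
equal to the closed form `∇²d(Ñg−d)` (a float accumulation leaves a
one-ulp residue at magnitudes of a few thousand). Correlation returns `nan`
with a `RuntimeWarning` for constant images (zero marginal variance)
rather than raising. Homogeneity is exposed in two variants, because the
literature uses both weights: `1/(1+|i−j|)` (the common library
"homogeneity", and the variant with the simple closed form) and Haralick's
original `1/(1+(i−j)²)`. The squared-weight law follows from the same
diagonal-splitting argument with `1+m` replaced by `1+m²`. The squared
variant never exceeds the absolute one.

Degenerate displacements — `d` a whole number of periods, `d_eff = d mod
Ñg = 0` — put all mass on the principal diagonal (`f2 = 0`, `f3 = 1`,
`f5 = 1`, `f1 = 1/Ñg`). They are flagged, not errors: `diagonal_split`
returns a `degenerate` field and sweep rows carry a `degenerate` column.
Displacements beyond one period reduce via `d_eff`, and a general vector
displacement on a vertical gradient acts only through `|Δy|`, since
intensity is independent of `x`. Negative gradients transpose the matrix
and change no feature, so gradient magnitudes are taken as `|∇|`
throughout.

## Normalization schemes

The scaling laws give `f1 ∝ 1/Ng` and `f2 ∝ Ng` at fixed `∇`, so the
factors `f1·Ng` and `f2/Ng` render them asymptotically bit-depth
invariant; `f3` and the absolute-weight `f5` need no factor. For the unit
gradient probed at `d = 1`, `f1·Ng` is *exactly* constant in `Ng` while
raw `f1` spans a 16-fold range over `Ng ∈ {16, 64, 256}`; `f5`, with no
correction at all, drifts by 5.1% over the same span (from
`((Ñg−1)/2 + 1/Ñg)/Ñg` at `Ñg=16` toward its limit 1/2) — its exact drift
is asserted in the unit tests. The empirical Löfstedt scheme (`f1·Ng²`,
`f2/Ng²`, homogeneity weight `1/(1+((i−j)/Ng)²)`) is implemented as a
comparison variant; note the rescaled homogeneity weight is strictly below
1 off the diagonal, so that feature approaches 1 from below as `Ng` grows
rather than equalling 1 identically.

## Gradient estimation

`estimate_gradient` inverts the Energy law: `Ñg ≈ round(1/f1)`, then all
`∇ ∈ [1, Ng−1]` with `1+⌊(Ng−1)/∇⌋ = Ñg`. The floor makes the preimage a
set (e.g. `{3, 4}` for a 9-level image with `f1 = 1/3`); `refine_gradient`
filters the set with a measured Contrast value, which separates candidates
through its `∇²` factor. The refinement tolerance (relative `1e-6` on
Contrast) suits exact synthetic measurements; noisy estimates need a looser
one.

## Validation sweep

`run_sweep` measures and predicts all four features over a gradient ×
displacement grid; defaults are 8-bit 1024 × 1024 images, vertical
gradients 1–7, vertical displacements 1–8. In cyclic mode the image height
is snapped to the nearest multiple of `Ñg` so the exactness regime applies;
agreement is then at the `1e-12` level across the entire grid (the
acceptance tests use bit depths 4–256). In non-cyclic mode the tolerance
story is subtler than an `O(d/Ny)` edge effect: Contrast (and to a lesser
degree Correlation) is *dominated* by the `m2` wrapped pairs, whose level
offset `m1·∇ ≈ Ng−1` enters squared. Dropping the last partial period
therefore perturbs `f2` by a relative `O(Ñg/Ny)`, not `O(1/Ny)`: at
`Ng=256`, `∇=1`, `Ny=1024` the deficit is three wrap pairs per 1023
transitions against four per 1024 cyclically — a 24.8% shortfall in `f2`,
reproduced digit-for-digit by scikit-image's `graycomatrix`/`graycoprops`
on the same image. Energy and Homogeneity, which weight all entries within
a factor of `Ñg` of each other, stay within 0.2% and 0.8% respectively,
and the qualitative shapes (`f1` flat in `d`; `f2` and `1−f3` proportional
to `d(Ñg−d)`; `f5` decreasing) hold throughout. Non-cyclic error shrinks
as the height grows at fixed parameters, and vanishes when `Ny − d` is a
multiple of `Ñg`. Relative error is reported as `|measured−predicted| /
|predicted|` (zero predicted with zero error reports 0, else ∞).

## Problem sizes

The acceptance-level checks run the full-scale grid: four 1024 × 1024
images and 32 co-occurrence matrices for the non-cyclic sweep, the
exactness grid over `Ng ∈ {4,7,8,16,256}`, `∇ ∈ 1..7`, `d ∈ 1..8` on
two-period images, and 200 random small images against an independent
double-loop counter. The whole suite completes in a few seconds on one
CPU; nothing is scaled down relative to the conditions described above.

## Known limitations

- Laws hold for one-dimensional linear gradients only; 2-D or nonlinear
  ramps, noise robustness, and the remaining ten Haralick features are out
  of scope.
- Dense `Ng × Ng` matrix storage: 16-bit images should be requantized
  before computing a GLCM.
- The non-cyclic sweep's Contrast/Correlation deviations described above
  are a property of boundary truncation itself, not of this
  implementation; cyclic whole-period pairing is the regime in which the
  laws are exact.
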