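# Methods

## The descriptor

A β-barrel (or open β-sheet) with n strands is reduced to the 2n joint
points P₁…P₂ₙ — the Cα coordinates of each strand's first and last
residue, in chain order — and the 2n − 3 torsion angles over consecutive
joint quadruples (P_k, P_{k+1}, P_{k+2}, P_{k+3}). Odd windows are
centred on a strand (β-type, n − 1 angles), even windows on a loop
(γ-type, n − 2 angles); the series alternates β₁, γ₁, β₂, γ₂, …, βₙ₋₁.
Loops influence nothing beyond providing the chain connectivity: the
descriptor reads only strand termini.

The torsion is the standard right-handed convention
(`atan2(|b₂|·b₁·(b₂×b₃), (b₁×b₂)·(b₂×b₃))` over the three bond vectors),
with the domain pinned to (−180°, +180°] by normalising −180° to +180°
so that sign classification is total. Positive angles correspond to the
clockwise rotation of P₄ against P₁ seen along the central bond. Because
projection drawings in the literature do not fix the viewing direction
algebraically, `compute_descriptor(..., flip_sign=True)` (CLI
`--flip-sign`) negates the whole series for comparison against data
produced under the opposite convention.

Exact semantics, pinned by coplanar fixtures the generator produces:

| geometry | angle |
| --- | --- |
| flat antiparallel strand pair | β = 0 |
| flat parallel strand pair | β = +180 |
| S_{i+2} folded back to S_i's side of S_{i+1} | γ = 0 |
| S_{i+2} extending opposite to S_i (flat antiparallel sheet) | γ = +180 |

Note the flat antiparallel sheet is the *opposite-side* γ geometry: its
γ angles are exactly +180°, not 0°. Real antiparallel barrels sit between
the two extremes (γ ≈ 90–150° for typical strand counts) because barrel
curvature rotates consecutive chords by the polygon's exterior angle.

### Degeneracy and numerics

A torsion quadruple is rejected (`DegenerateGeometryError`, naming the
angle index) when any bond vector is zero or a bond-vector pair is
collinear, with collinearity defined as a cross-product norm below 1e-9
after normalising the bonds to unit length. Rigid motions leave every
angle unchanged to ≤ 1e-9°; reflections negate every angle (+180° maps
to itself); the torsion is invariant under reversal of its four points.
An independently coded projection-based oracle (in the test suite and
the acceptance script) agrees with the implementation to ≤ 1e-6° — in
practice ~1e-13° — on 10,000 random quadruples.

## Boundary handling

Strand annotations are external (SHEET records, STRIDE `E` runs, or a
user table); the package never re-assigns secondary structure from
coordinates. Validation maps strand termini onto the Cα trace, sorts by
chain position, and derives loops as the residue complement between
consecutive strands. Specific choices:

- **Strand order is chain order.** Joints follow the chain, so spatial
  adjacency never reorders strands.
- **Merging.** `merge_gap ≥ 1` merges strands separated by at most that
  many residues (SHEET strands additionally only within one sheet id),
  because SHEET records routinely split a physical strand at a β-bulge.
  `merge_gap = 0` (the default for STRIDE and user tables; SHEET input
  defaults to 1) disables merging entirely: directly adjacent strands
  are a legal alternation with a zero-length loop, and rebuilding an
  annotation from its own strands at `merge_gap=0` is the identity.
- **Unresolved termini.** A strand terminus without a Cα is a hard error
  by default; `trim_to_resolved` shrinks the strand inward to the
  nearest resolved residue and logs the adjustment. Joint positions
  define everything downstream, so silent shifts are never applied.
- **Residue identity** is (author number, insertion code); ordering is
  file order, never a numeric sort. Alternate locations resolve to the
  highest-occupancy Cα, ties broken by altloc identifier.
- **TM ranges** (OPM-style) intersect exactly one strand each and replace
  it by the intersection, restricting full strands to their
  membrane-embedded portion; loops are re-derived.

## Pattern statistics

Signs: '+' covers [0°, +180°] (zero inclusive), '−' covers (−180°, 0°).
Dyads and triads are sliding windows of width 2 and 3 over consecutive
same-type angles of a single structure; group aggregation sums counts
and never concatenates sign strings across structures. Quadrants split
the domain at ±90°: ⁺A = [0°, 90°), ⁺B = [90°, 180°], ⁻A = [−90°, 0°),
⁻B = (−180°, −90°); interval closures are pinned left-closed (top closed
at +180°) as a package convention since verbal interval descriptions
leave them open. Histograms use left-closed bins over [−180°, 180°) with
+180° folded into the top bin; the default 10° width is the finest
granularity at which the distributions are usually discussed, and any
divisor of 360° is accepted.

Default size-grouping schemes follow the usual survey splits:
transmembrane 4–10 / 12–16 / 18–26 strands, cytoplasmic 4–6 / 7–8 /
10–14; custom schemes are JSON-definable.

## The synthetic generator

`generate_barrel` places strand k on a cylinder at azimuth k·360°/n,
as a straight row of `strand_length` residues (default 10, a typical
membrane-strand length) with axial spacing `rise` (default 3.3 Å, the
Cα rise of an extended strand). Two parameters control the regime:

- `twist` — the azimuthal slant of each strand: its top end is rotated
  by `twist` degrees (right-handed sense positive) relative to its
  bottom end. This is the strand tilt of real barrels, and its sign is
  the barrel's handedness.
- `stagger` — vertical offset per strand step (Å), the idealized
  analogue of the shear register offset between adjacent strands.

Chain direction per strand is settable (`direction_pattern`); default is
alternating (antiparallel). Loops are minimal straight-line
interpolations — loop geometry never affects the descriptor. Optional
uniform jitter (±0.05 Å, seed-controlled, off by default) supports
robustness checks without disturbing sign classifications.

`membrane_barrel_spec(n)` fixes twist = 95° and stagger = 3.3 Å. In an
untwisted prism the γ series alternates sign (±(180° − 360°/n)) because
the central bond of consecutive γ windows alternates direction; a
sufficiently slanted, staggered barrel — the regime real membrane
barrels occupy, with strand tilts of ~40° — breaks that parity. The
default was chosen once as the smallest round slant for which every β
and γ angle shares the twist's sign for all n from 4 to 26 (the n = 4
window is the narrowest); it yields β ≈ 8–11° and γ ≈ 60–175°, inside
the ranges observed for real membrane barrels. The left-handed
counterpart negates both parameters and equals the mirror image in its
sign tables.

What the generator does *not* emulate: hydrogen-bond registry and shear
numbers, elliptic cross-sections, strand-length variation, β-bulges,
unresolved residues, and loop conformations. Tests passing on these
fixtures therefore validate the descriptor's geometry and bookkeeping —
torsion correctness, counting laws, sign/mirror behaviour, limiting
cases — not its robustness to crystallographic artefacts, which enters
only through the boundary-handling options above.

## Counting identities

`expected_counts(n) = (n−1, n−2)` is exercised against the reference
survey cohorts in `barreljoint.cohorts`: per group, per-structure counts
times the number of structures must reproduce the reported angle
tallies (they do for every cytoplasmic group, with cohort totals 312 β
and 261 γ over 51 structures, and for the 10/12/16-strand TM groups).
The 8-strand TM row is reported as 30 β / 24 γ for 6 structures — 5 and
4 per structure, inconsistent with the 7 and 6 that eight strands force;
the row is kept verbatim, flagged inconsistent, and the formula is never
special-cased. The reported TM γ grand total (329) likewise differs from
the column sum of its own rows (303); neither is asserted.

## Problem sizes

The test suite and acceptance script run entirely on synthetic input:
barrels of n ∈ {2, 4, 8, 12, 16, 22, 26} strands for property checks,
one barrel per surveyed structure (51 + 11) for the counting identities,
and 10,000 random quadruples for the torsion cross-check. The whole
suite completes in well under a minute on one CPU.
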