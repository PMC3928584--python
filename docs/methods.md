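# Methods

This note documents the models and procedures implemented in
`morphotree`, the choices made where the conventions of the field leave
room, and what the synthetic test data does and does not establish.

## Reconstructions, segments, branches

An SWC reconstruction is an ordered list of 7-field records; any record
with a negative parent index is a root (normalized to −1).  Validation
reports duplicate indices, parents that do not appear earlier in the
file, zero-length segments (child coordinates equal to the parent's),
negative radii and non-standard structure flags (the last as a warning
only).  Indices may be arbitrary positive integers; `renumber` produces
the contiguous 1-based numbering used when files are emitted.  Column 6
is treated as a radius, the standard SWC convention; every
diameter-based formula uses 2r.  Files are written with 6 significant
digits, which exceeds the precision of the public archives the format
comes from.

Two connected segments belong to the same branch only if they chain
head-to-tail, share a structure flag, and no third segment shares the
parent index — so branches end exactly at bifurcations, flag changes and
tips.  Soma (flag 1) segments never join branches; a dendrite or axon
attached to a soma point roots its own tree there, and multi-point soma
contours are therefore handled without special cases.  A branch's
polyline includes its attachment point P₀, which is owned by the parent
branch (or the soma); its *own* records are P₁…P_m.  First-names are
assigned depth-first in file order — arbitrary but deterministic.
Strahler ordering is purely topological and generalizes verbatim to
trifurcations ("two **or more** daughters attaining the maximum order").

## Per-branch measurements

* **Length**: sum of 3D segment lengths.
* **Tapering**: OLS slope of diameter against cumulative 3D arc length
  over *all* polyline points, per the accumulative definition of the
  branch.  Because P₀ carries the parent's (or soma's) radius, root
  branches attached to a large soma inherit a soma-sized first diameter;
  this is a property of the definition and of SWC itself, and is most
  visible on synthetic trees with an oversized soma point.
* **DM tortuosity**: path / chord; undefined (NaN with a warning) when
  the endpoints coincide.
* **SOAM tortuosity**: the per-point total angle CP_k = √(IP_k² + TP_k²)
  summed over the n − 3 complete vector triples, divided by path length.
  The Euclidean combination of in-plane and torsional angles follows the
  sum-of-angles literature; an arithmetic-sum variant is switchable
  (`combine="sum"`) for sensitivity checks.  Branches with fewer than 4
  points have an empty angle sum (SOAM = 0, flagged "too short").
  *Numerical choice*: the torsional angle is ill-conditioned where
  consecutive chords are nearly parallel — the cross products' directions
  are then set by round-off, not geometry — so triples whose in-plane
  turn is below 10⁻⁴ rad contribute no torsion.  Without this guard, a
  perfectly straight branch written at 6-digit precision and re-read
  acquires an SOAM of order 0.1 rad/µm from noise alone; with it, the
  same branch measures < 10⁻⁶ rad/µm.
* **Soma distances**: Euclidean from the tree's root point to the branch
  start, and the path sum of all full-name ancestors' lengths.

## Directional vectors, angles, Rall exponents

Directional vectors are total-least-squares line fits (first principal
axis via SVD) over the first or last min(m, available) segments of a
branch, oriented along growth; m defaults to 5 segments, and the right
value genuinely depends on branch tortuosity, so it is exposed
everywhere.  TLS is used rather than coordinate-wise OLS because no
axis is privileged in 3D.  A bifurcation angle is the angle between the
parent's finish vector and a daughter's start vector, both pointing away
from the soma, so a straight continuation scores 0.

At a branch point X_j the parent diameter d_eq is taken at the parent's
final record and each daughter diameter dᵢ at the daughter's first own
record — the values adjacent to X_j.  The Rall exponent solves
d_eq^E = Σ dᵢ^E by Brent root finding on f(E) = (Σ dᵢ^E)^{1/E} − d_eq,
which is the E-norm of the daughter vector and hence strictly
decreasing, over E ∈ [0.05, 20] at relative tolerance 10⁻⁸ (evaluated in
the log domain for robustness).  No root exists when
d_eq ≤ max dᵢ or when d_eq exceeds the norm at the lower bracket edge;
both cases return a missing value with the reason attached rather than a
number.

## z-smoothing

Archive reconstructions often zig-zag along the optical axis.  Each
branch's z series is filtered with a moving average whose neighborhood
is defined on the cumulative xy-projected arc length (the point spacing
is not uniform, so a point-count window would weight space unevenly).
The window is a half-width in µm, default 5 µm — about one to two traced
points at archive sampling densities; 0 is the identity.  Ties in the
predictor from vertical segments are broken by 10⁻⁶ µm increments.

Filtering branches independently would create z-jumps at bifurcations,
so two synthetic boundary points are concatenated before filtering: one
prepended at −d̄ (d̄ = mean xy spacing) whose z averages the parent's
already-smoothed final z with the branch's own first z, and one appended
at L + d̄ averaging the initial z of all daughters; either is omitted
for root/terminal branches.  Placing them one mean spacing outside the
branch keeps their filter weight comparable to an interior point's.
Branches are processed root-to-tip so daughters see smoothed parents,
and the attachment record P₀ is never rewritten by the daughter — the
genealogy therefore stays exactly continuous.  Only z changes; x, y,
radii, indices and record order are bit-identical.

## Distributions and group summaries

The per-branch table ("vertical compression") joins topology, metrics
and distal-bifurcation fields, one row per branch, with missing values
kept as NaN.  Histograms use Sturges' rule k = ⌈1 + log₂ n⌉ on the
pooled finite values (a degenerate all-equal sample gets one bin widened
by ±0.5); the rightmost bin is closed, so counts always conserve the
number of finite values.  Group comparisons can share bin edges across
groups; values outside shared edges are clipped into the extreme bins
rather than dropped.  The across-cell SEM uses the n − 1 standard
deviation; a single-cell group reports a missing SEM rather than 0.

## Virtual neurons

The growth algorithm is this package's design.  A fitted
`MorphometryModel` stores, per centrifugal order (Strahler conditioning
is available as an option), the raw observed values of branch length,
taper slope, mean diameter, SOAM and bifurcation angle, plus the
fraction of branches at that order that have daughters.  Growth draws
from these lists by empirical resampling: each branch takes a length,
diameter, taper and SOAM target for its order; the polyline is a random
walk of ~2 µm steps whose per-step bend is the SOAM target × step, about
a uniformly random azimuth, so the realized length is exact and the
realized tortuosity approximates the drawn one; diameters taper linearly
about the drawn mean, clipped at 0.1 µm.  With the order's branching
probability the branch spawns two daughters at drawn angles on opposite
sides of a random azimuthal plane; orders beyond the deepest observed
clamp to it, whose branching probability is 0 in any finite sample, so
growth terminates; a 10⁴-branch safety cap truncates runaways with a
warning.  All randomness flows through one `numpy` generator seeded from
the config, so identical (model, seed) pairs give byte-identical SWC.

Because lengths and diameters are resampled verbatim, the generated
per-order distributions reproduce the model inputs (two-sample KS below
the α = 0.01 critical value at 100 neurons); SOAM and angles are
realized geometrically and match only approximately.

## Synthetic fixtures

`make_fixture` builds deterministic chains, Y-trees and complete binary
trees with exactly planned topology, branch lengths (optionally
jittered by a seeded uniform factor), taper, ±angle planar bifurcations,
and diameters stepped across branch points by 2^(−1/E) so every
bifurcation realizes the planned Rall exponent.  The noise-free geometry
is planar (z = 0), so the z_noise = 0 twin of a spec is an exact ground
truth for the smoothing tests, and added z-noise is i.i.d.
uniform(−a, +a).  These fixtures emulate the *measured* structure of
archive cells (branch-chained SWC, realistic magnitudes, z digitization
noise) but not their biology: no spatial polarity, no order-dependent
length gradients, no correlated noise, and soma contours reduced to one
point.  Passing tests therefore establish the correctness of the
algorithms on known ground truth, not morphological claims about real
cell classes, whose group distributions must be computed from real
archives.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200 random trees of up to
100 nodes for the topology and segment-count checks, fixture populations
of 6 cells for model fitting, and 100 virtual neurons for the closure
checks — sizes at which every stochastic criterion is stable across
seeds while the whole suite runs in well under a minute of CPU.
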