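# Methods

## The identifier and its encoding

A CandyCode is the random planar arrangement of small colored particles
(nonpareils) on a pill face. The raw observable is a list of
`(x, y, color)` records in image coordinates (y grows downward, units are
arbitrary — typically pixels). A pattern of *n* particles with *c*
distinguishable colors could in principle encode `n·log2(c)` bits (93
particles × 8 colors ≈ 279 bits), but reading those bits verbatim would
require globally consistent orientation and a perfectly repeatable
segmentation. Instead, each particle's *local neighborhood* is turned
into a short string, and the pill is represented by the multiset of those
strings:

1. **Neighbors.** The Delaunay triangulation of the particle centers
   defines adjacency. Delaunay edges are invariant to translation,
   rotation and uniform scaling of the photograph, which is exactly the
   invariance a hand-held re-photograph needs.
2. **Reading order.** A neighborhood is read clockwise (as displayed; in
   the y-down frame this is increasing `atan2(y−y_c, x−x_c)`). The
   cyclic sequence is made canonical by rotating it to its
   lexicographically smallest linearization. This generalizes the rule
   "start at the alphabetically first neighbor; if several qualify,
   compare the letters that follow" to ties of any depth, and is
   start-independent by construction. The center's letter is prepended.
3. **Discard filters** (defaults, all configurable): strings whose center
   lies on the convex hull (edge neighborhoods are truncated and their
   short strings repeat across pills); strings with fewer than 4 distinct
   letters (low-diversity neighborhoods, common when one color is in
   excess, collide often); strings with fewer than 2 neighbors. With 94
   particles roughly 52–56 strings survive, matching the ~53 retained on
   the real pills the model emulates.

Duplicate strings within one pill are kept (multiset semantics) and
matching uses the multiset intersection `Σ_s min(c_a(s), c_b(s))`, so a
duplicated neighborhood string can contribute at most its multiplicity.

Reflection is *not* an invariance: mirroring a photograph reverses every
reading cycle and generally changes the string set. The verification
workflow assumes photographs are not mirrored.

Cocircular degeneracies (4+ points on one circle) admit more than one
Delaunay triangulation; whichever qhull returns is used. Real coordinates
from photographs or the simulator are almost surely in general position.

## Matching and the verdict

The database stores each pill's string multiset plus an inverted index
(string → {pill: multiplicity}), so a query touches only pills sharing at
least one string. The verdict is `authentic` iff the best shared count
reaches a threshold, default **10**: between photographs of the same
physical pill the observed minimum was 21 shared strings, between
different pills the observed maximum was 2, and 10 sits between those
with a wide margin on both sides. Ties for best match are broken by
lexicographic id and reported.

## The simulator

`simulate_candycode` places `n_particles` (default 94, the median count
of the 120-pill reference library) non-overlapping disks on a circular
pill face by random sequential adsorption: positions proposed uniformly
on the disk of radius `pill_radius − particle_radius` (rejection from the
bounding square, exactly uniform), rejected when closer than
`2·particle_radius` to an accepted particle, up to `max_attempts = 10⁴`
proposals per particle. The default particle radius is
`sqrt(0.45/n)·pill_radius`, i.e. an area fraction of 0.45 — visually
realistic coverage, comfortably below the ~0.547 RSA jamming limit. At
this density a packing still jams occasionally (roughly once per 10⁵
codes); a jammed configuration is discarded and regenerated from a fresh
deterministic substream, keeping codes i.i.d. conditional on
packability. Colors are drawn independently from the alphabet's
probabilities; alphabet A idealizes the measured color frequencies of
commercial chocolate nonpareils (41.5% white, 7.3–8.1% each other color)
as white = 5/12 and 1/12 each — the same "white five times more frequent"
model used in the original simulations.

Per-code random substreams are derived with `SeedSequence((seed, index))`
so libraries are reproducible and order-independent; `library_member`
re-materializes any member from its index.

**Re-photograph model.** `perturb_candycode` displaces every particle by
isotropic Gaussian noise and optionally flips colors or drops particles.
The default `jitter_sigma = 0.25 × particle radius` was calibrated so
that a perturbed copy retains on average roughly half of its strings
(measured ≈ 0.55–0.6, within the 0.30–0.70 acceptance band), bracketing
the 40–61% retention observed between repeat photographs of real pills.
The mechanism matches the physical explanation: Delaunay adjacency is
sensitive to near-degenerate angles, so small viewpoint changes flip a
subset of edges while most neighborhoods survive.

What the generator does *not* emulate: perspective and pill curvature,
lighting/color-calibration error (color misreads are available but off by
default), particle size variation, and touching/occluded particles.
Passing tests therefore demonstrate the correctness and statistics of the
encoding/matching pipeline, not the robustness of a production imaging
stack.

## Library statistics and the scaling law

The uniqueness statistic is the **largest shared-string count between any
two different codes in a library**. For large libraries it is computed by
flattening all string occurrences into tokens (within-code duplicates get
an occurrence index, which realizes multiset-intersection semantics with
exact matching), grouping equal tokens, emitting one code-pair per
co-occurrence, and taking the deepest pair. This exactly equals the naive
all-pairs multiset count (property-tested) and handles 10⁵-code libraries
in well under a minute.

Sweeps simulate fresh libraries at sizes {10, 10², 10³, 10⁴} with 20
replicates per size (the original protocol went to 10⁵ with 100
replicates; the desk-scale default keeps a full three-alphabet run around
ten minutes on one core, and flags expose the full protocol). The
per-size mean of the per-library maximum is fitted by unweighted ordinary
least squares against log10(size). Size-1 libraries have no pairs; their
defined maximum of 0 is excluded from fits. Extrapolation evaluates the
fitted line at the target size (e.g. 10¹⁷, the library size at which
version-4 UUIDs reach 1% collision probability). Observed slopes are
≈1.2 (alphabet A), ≈0.9 (B), ≈0.6 (C) strings per decade, reproducing the
reference values, with 1e17 predictions near 21/15/10: only the unbiased
8-color and 15-color designs stay below the 21-string worst-case
true-match level at universally-unique scale.

A note on interpretation: "mean max shared ≈ 2.26" for 120-code
libraries is read as the per-library maximum averaged over 100
independent library simulations.

## Imaging

Rendering rasterizes the pill and each particle directly (a pixel is
filled iff its center lies inside the disk, no anti-aliasing), which
keeps component centroids within a small fraction of a pixel of the true
centers; particles are drawn at 90% of their physical radius so tangent
same-colored particles remain separate 4-connected components. Detection
classifies every pixel to its nearest palette entry (particle colors +
pill + background; default palettes keep all entries ≥ 40 RGB units
apart), labels 4-connected components per color, drops components smaller
than 4 pixels, and reports centroids (+0.5 px pixel-center convention).
On clean renders the detect→encode round trip reproduces the original
string set exactly; with additive Gaussian pixel noise (σ = 8/255) at
least 95% of particles are still recovered with the correct color.

## Numerical and performance choices

- Delaunay/convex hull via `scipy.spatial` (qhull); the RSA packer, color
  sampler and post-triangulation encoding (clockwise ordering, canonical
  rotation, filters) are numba kernels operating on numeric arrays, since
  the sweeps encode ~10⁵–10⁶ codes. The kernel path is property-tested
  against a pure-Python composition of the public single-neighborhood
  operations.
- Coordinates are serialized with 6 fractional digits; duplicate
  detection uses exact equality after parsing.
- Canonical rotation is brute force over all rotations (neighborhoods
  have ≤ ~12 neighbors, so O(g²) is negligible).
- All randomness flows through numpy `SeedSequence`/`Generator` (numba
  kernels receive derived integer seeds); identical seeds give
  byte-identical serialized libraries.

## Known limitations

- Geometry is strictly planar; strongly curved pill faces would need a
  spherical triangulation.
- The authenticity threshold is a fixed count, not a likelihood; for
  libraries far beyond ~10⁵ codes the impostor ceiling rises along the
  scaling law and the threshold should be re-derived from it.
- The detector assumes render-like contrast and the rendering palette;
  it is a functional stand-in for a real segmentation pipeline, not a
  replication of one.
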