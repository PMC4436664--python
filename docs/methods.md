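# Methods

## Model

`helixcg` represents an RNA tertiary structure at the level of its
secondary-structure elements.  A pseudoknot-free secondary structure is
decomposed into stems (maximal runs of stacked canonical pairs,
identified by their corner nucleotides c1 < c2 < c3 < c4), hairpins,
interior loops, multiloop segments and the 5'/3' unpaired regions; the
connectivity of these elements is the *skeleton graph*.  Pseudoknots in
the input pairing are eliminated first by keeping a maximum-cardinality
crossing-free subset of the pairs (interval dynamic programming, ties
broken toward the 5'-most pair).  Isolated base pairs are rejected: a
1-bp stem has no defined helix axis, so structures should be folded
with lonely pairs disallowed.

Each stem is a cylinder: an axis segment `(a_s, a_e)`, unit twist
vectors `(t_s, t_e)` perpendicular to the axis at its ends, and its
base-pair count.  One *virtual residue* per base pair sits equally
spaced on the axis with a twist interpolated through the *accumulated*
helical rotation (the base signed angle lifted by whole turns to the
branch nearest `(n_bp - 1)` times the configured per-bp twist; shortest-
arc interpolation would mistrack the groove for stems longer than about
5 bp).  A small virtual-atom set per nucleotide (P, O3', C1', base
centroid) is placed from fixed cylindrical offsets in the local (axis,
twist, axis x twist) frame.

### The stylised A-form template

Template constants are standard fibre-diffraction A-form values: rise
2.81 Å/bp, twist 32.7°/bp, C1' radius 9.4 Å; all configurable through
the stats file.  Two deliberate stylisations:

* The two C1' atoms of a pair are placed antipodally, so base-pair
  midpoints lie exactly on the axis.  A total-least-squares line
  through the midpoints then recovers the axis of a noiseless helix to
  machine precision, which anchors the geometry test suite.  Because an
  on-axis midpoint cannot define a twist direction, the twist reference
  is the perpendicular component of the vector to the *first-strand*
  C1' atom (for real threaded helices the C1'-C1' midpoint is off-axis
  and either convention differs only by a fixed rotation).
* P and O3' offsets are calibrated so that the O3'(k) to P(k+1)
  backbone linkage along either strand of an ideal helix has a fixed
  length (1.6 Å, the `linkage` constant).  The template is symmetric
  under flipping the helix end-for-end, which the placement frames
  exploit (below).

### Inter-helical parameters

The position of one stem relative to its predecessor is six numbers:
separation `r` between the connecting axis endpoints; polar/azimuth
`(u, v)` of the separation vector in the predecessor's connection
frame; polar/azimuth `(u_p, v_p)` of the new stem's inward axis in the
same frame; and `t`, the rotation of the new stem's connecting twist
about its own axis relative to a reference twist transported from the
predecessor.  `extract` and `place` are exact inverses (the round trip
is verified to 1e-9 over random draws, which is the correctness
criterion for this parameterization — no external software shares it).

The connection frame is anchored at the *corner pattern*, not just the
stem end: frames at corners on the second strand (c3/c4) negate the
twist axis.  Since the atom template is flip-symmetric, one stored
tuple then realizes the geometrically analogous arrangement for every
multiloop connection pattern (c2→c1, c4→c1, c4→c3) — a coaxial-stack
tuple continues whichever strand the connector follows, leaving exactly
the 1.6 Å linkage gap in all three patterns.  Statistics are always
expressed as "later stem relative to earlier stem"; when the build
traversal crosses a connector backwards, the pair is realized at a
canonical origin and rigidly transported onto the placed stem.

### Building and resampling

Models are built by walking the traversal order (5'-most stem first,
every stem after an already-placed neighbour).  Hairpins and the 5'/3'
regions are straight segments (direction in the stem-end frame plus a
length).  In every multiloop junction the segment with the most
nucleotides (5'-most at ties) is the *break*: it receives no
parameters, and its feasibility is judged by the junction-closure rule.

Resampling replaces one element's stored parameters and re-runs the
deterministic realization from the parameter set.  Upstream geometry is
recomputed through the identical floating-point operations (hence
bit-identical), and each downstream placement is a fixed function of
its parent frame, so the downstream subtree moves rigidly — this
rebuild is equivalent by construction to transporting a cached subtree
and was chosen for being considerably less error-prone; the measured
cost (~1 ms per rebuild on the test fixtures) is negligible next to the
energy evaluation.

## Energies

Two constraint terms take only values in {0, 10,000 × violations}; the
penalty constant is far above the knowledge terms' range, so a single
violation guarantees Metropolis rejection:

* **Clash** — any two virtual atoms closer than 1.8 Å clash, provided
  they belong to different stems that do not share a connector element.
  Only stems carry virtual atoms (loop nucleotide positions are too
  variable to track at this resolution), and stems are never directly
  adjacent in the skeleton graph, so the exclusion is applied to stem
  pairs joined through one connector — otherwise perfect coaxial stacks
  at junctions would self-clash.  A k-d-tree accelerates the search and
  agrees exactly with the all-pairs count.
* **Junction closure** — a break segment of n nucleotides must bridge
  the O3'→P gap between the capping corner nucleotides of its two
  stems.  The allowed distance is `g0 + g1·n` with defaults g0 = 3.0 Å
  (one phosphodiester linkage with slack) and g1 = 6.5 Å per nucleotide
  (near-maximal backbone extension); the boundary is closed (a gap
  exactly at the limit is feasible).  The rule is an explicit,
  configurable stand-in — no published functional form exists for it.

Three knowledge-based terms use the reference-ratio form
`E(x) = −c·log(p_t(x)/p_r(x))` with Gaussian KDEs (Scott's-rule
bandwidths, sample standard deviation with ddof = 1, zero-variance
floor 1e-3) and densities floored at 1e-12 of the KDE's approximate
mode (max density over its own sample points), keeping tail energies
finite.  `c` defaults to 1 per term:

* **Radius of gyration** over stem virtual residues (loops excluded).
* **Loop–loop distance** — one term per hairpin, its anchor-to-anchor
  distance to the nearest other hairpin; omitted entirely (not zero)
  for single-hairpin structures.
* **A-minor** — one term per qualifying hairpin/interior loop.  A
  loop–stem pair is parameterized by (d, φ, ψ): closest distance
  between the loop segment and the stem axis, angle between the element
  directions, and angle between the interaction vector and the
  minor-groove direction.  The interaction probability is Bayes' rule
  `P(I)·p(d,φ,ψ|I)/p(d,φ,ψ)` with 3-D product-kernel KDEs (per-
  dimension Scott bandwidths; angles treated as plain values in [0, π],
  no circular kernel) clamped to [0, 1], and a loop's expected
  interaction count sums this over non-adjacent stems within 30 Å
  (beyond which the probability is negligible).  The prior defaults to
  0.2 per loop kind and lives in the stats file.  The minor-groove
  direction is the interpolated twist rotated half a turn about the
  axis — opposite the C1' direction, an explicit approximation.  With a
  sequence supplied, only adenine-containing loops qualify as donors;
  without one every hairpin/interior loop does.

Target distributions are built by collecting corpus measures whose
structure length lies within 1% of the target length, widening the
window symmetrically (factor 1.5 per step) until at least 500 measures
are available; an exhausted corpus yields all records plus a warning.

## Sampling

Metropolis–Hastings with kT = 1 (energies are already log density
ratios).  Each step redraws one uniformly chosen element's parameters
— fragment replacement from the same size bucket is symmetric, so the
acceptance probability is `min(1, exp(−ΔE))`.  The secondary structure
never changes.  Every tenth step the current structure's measure values
are appended to each term's reference distribution and the current
energy is re-evaluated under the moved landscape; reference updates use
the current structure regardless of acceptance, but clash- or closure-
violating structures are neither stored as samples nor used for
updates.  Burn-in is not discarded by default (the `fold` command has a
`--burn-in` fraction flag).  The Jensen–Shannon divergence between
KDE-smoothed sampled and target measures, computed on a shared grid
spanning both supports, serves as the convergence diagnostic: when its
running value levels off the target has been adequately sampled.

## Synthetic statistics

Full-scale mined statistics corpora (e.g. ribosome subgraphs or large
predicted-decoy sets) are not bundled; the generator emulates them and
defines the default study conditions.  Per bucket it perturbs a coaxial/ideal
arrangement: separations grow linearly with the connector's nucleotide
count (so multiloop `r` is monotone in segment size), orientations get
configurable angular dispersion (default 0.35 rad), stem rise/twist
jitter around the A-form values, and loop lengths scale with nucleotide
count.  Two rejection filters emulate the pruning of impossible
fragments: multiloop tuples must leave a bridgeable O3'→P gap (≤ 0.85
of the closure limit) under *all three* connection patterns, and
interior-loop tuples must place two canonical 8-bp stems without atom
contact below 2.0 Å (interface base pairs excluded).  Defaults are 40
tuples per bucket, interior-loop strands to 6 nt, multiloop segments to
8 nt, hairpins 3–10 nt.

What the generator does not emulate: sequence-dependent geometry,
correlations between neighbouring placements, non-canonical pairs, and
the heavy multimodality of real junction statistics.  Passing tests
therefore demonstrate the correctness of the machinery (decomposition,
geometry, energies, sampling) and the *mechanism* of distribution
matching — not prediction accuracy on real RNAs, which requires mined
statistics supplied through the documented stats-file format.

## Problem sizes and numerical choices

The shipped experiments use two-stem and three-stem fixtures (27–50
nt), 10,000-iteration chains, 500–1,000 direct builds for proposal
distributions, and 1,000-sample Gaussian targets; the convergence
experiment shifts the target one proposal-sd below the proposal mean
with 0.75× its width — far enough to measure steering, near enough to
remain reachable under the fixed secondary structure.  Chain samples
are thinned to every tenth step before two-sample testing against
independent builds (a few steps decorrelate the handful of degrees of
freedom in these fixtures).  Degenerate inputs are handled explicitly:
zero-length separation leaves (u, v) = 0, a zero-length loop reports
φ = 0, coincident midpoints raise a degenerate-axis error, and
single-entry stats buckets make resampling a no-op.

## Known limitations

* Pseudoknotted tertiary folds are out of scope; the representation
  assumes a nested secondary structure.
* Loops are straight segments; no all-atom reconstruction is provided.
* The A-minor minor-groove vector and virtual-atom offsets are
  template-level approximations, versioned in the stats file
  (`aform-1`).
* Thread mode reads PDB model 1 only, first-come altlocs, and requires
  a supplied canonical pair list (the geometric detector bundled with
  `thread` is a labelled heuristic, not an annotation tool).
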