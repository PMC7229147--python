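# Methods

## 1. Ancestral state reconstruction under the Mk model

### Model

A discrete foot-morphology character with k states (k = 5 for the standard
coding: 0 non-webbed, 1 palmate, 2 semipalmate, 3 totipalmate, 4 lobate)
evolves along a rooted phylogeny as a continuous-time Markov chain with the
symmetric one-parameter ("Mk1") rate matrix: every off-diagonal entry is r,
every diagonal −(k−1)r. This admits the closed-form transition probabilities

    P_ii(t) = 1/k + (k−1)/k · e^{−k r t}
    P_ij(t) = 1/k −   1/k  · e^{−k r t},   i ≠ j,

which the implementation uses directly (no matrix exponentiation at run
time; agreement with `expm(Qt)` is asserted in tests to 1e−10). The chain's
stationary distribution is uniform, and the root prior is taken to be that
stationary 1/k. The "unscaled tree" convention sets every branch length to
1, so r is measured in expected changes per branch segment; trees with
explicit lengths are accepted unchanged so that reruns on alternative
published topologies need no special handling.

Assumptions worth stating: a single rate shared by all state pairs and all
branches (no asymmetry, no rate variation), independence of the character
from the tree, and a known, correctly rooted topology. Polytomies are
evaluated natively by the pruning recursion — composite family-level trees
contain them, and arbitrary resolution would add fictitious edges.

### Likelihood and reconstruction

Felsenstein's pruning recursion computes P(tip data | r) in one postorder
pass. Conditional-likelihood vectors are rescaled to a maximum of 1 at every
internal node, with the log-scalers accumulated, so likelihoods of large
trees cannot underflow. A tip with missing data (`?`; e.g. a taxon whose
foot type the literature does not record) contributes an all-ones vector —
exactly the likelihood obtained by pruning that tip from the tree, a
neutrality the tests assert.

Marginal (per-node) posterior probabilities combine the downward pass with
an upward pass: for child c of node u, `up[c] = P(t_c)ᵀ(up[u] ⊙ ∏_{siblings}
P(t_b)·down[b])`, and the marginal at any node is `up ⊙ down` renormalised.
This equals re-rooting at each node, and — under the uniform prior — also
equals the "proportional likelihoods" convention of classic Mk software.
Both passes are checked against brute-force enumeration over all
internal-state assignments on small trees (1e−10).

### Rate estimation

The single rate is estimated by bounded 1-D maximisation of the
log-likelihood (summed over characters when several are given) on
[1e−8, 100], tolerance 1e−8 on r. The likelihood surface flattens into a
plateau at large r (the stationary limit), which can stall a linear
golden-section search far from an interior optimum; the optimiser therefore
first locates the peak on a log-rate scale, then polishes linearly around
it. The boundary r = 0 is evaluated explicitly so constant characters return
exactly 0. On simulated data (16 tips, 500 characters, true r = 0.3) the
median estimate over 20 seeds lands within a few percent of truth; a
single character — the realistic use case — identifies r far more loosely,
which is why the reconstruction object reports r̂ and the log-likelihood
alongside the node vectors.

Most-probable (MAP) states take the per-node argmax, breaking ties towards
the lowest state index and flagging them explicitly — determinism over
silence. Independent origins of a set of target states (e.g. all four
webbed types) are counted as edges whose child state is in the target set
while the parent state is not, tips included as children; observed tip
states always override reconstructed ones.

## 2. The section-entropy statistic

### Definition and conventions

For a binarised image Z of proliferating cells, with foreground pixel set F
and section width W_max,

    S = Σ_{(p,q) ∈ F×F, p≠q} ln( ‖p − q‖ / W_max ).

Conventions fixed here because the bare quadruple sum leaves them open:

* **Self-pairs are excluded.** The literal sum includes p = q, whose
  ln 0 = −∞ makes every image's S undefined; dropping zero-distance
  self-pairs is the only reading that yields a finite statistic.
* **Ordered pairs are retained** (each unordered pair counts twice),
  matching the literal quadruple sum. Because S therefore scales like
  N(N−1) in the foreground count, the per-pair mean S/(N(N−1)) is always
  reported alongside as a size-free companion.
* **Channel roles.** S is computed on the PHH3 (proliferating-cell) mask;
  W_max is the maximum row-wise extent of the Hoechst (all-nuclei) mask,
  serving as a tissue-size proxy. Images must be oriented with the
  medio-lateral axis horizontal.
* Coordinates are 0-based pixel centres, distances Euclidean in pixel
  units; larger-than-memory pair sets are handled by blocking the distance
  computation (the naive double loop is the test oracle, to 1e−9).

S is exactly translation-invariant and invariant to transposition (with
W_max held fixed), and invariant to a common rescaling of coordinates and
W_max — properties the test suite asserts. Clustering shortens pairwise
distances, so at fixed N and W_max clustered patterns score lower than
uniform-random ones; this ordering is asserted over 50 seeded pattern
pairs. For strict lattices vs uniform patterns the sign of the difference
depends on geometry, so no grid-vs-random claim is made.

### Binarisation

Otsu's threshold is computed on the full 256-bin 8-bit histogram as the
first argmax of the between-class variance; foreground is *strictly above*
the threshold. Constant images are rejected rather than silently returning
an arbitrary cut. An optional connected-component centroid mode collapses
each stained blob to a single point before the pair sum; it is off by
default (the statistic is defined over raw pixels) but is what makes the
rendered-image pipeline directly comparable to ground-truth cell
coordinates in tests.

### Aggregation

Three section replicates per individual and position (second joint of toe
III; centre of its second phalanx) are averaged per individual; three
individuals are averaged per species; the species-level comparison is the
joint/phalanx ratio of mean S. `summarize` is permutation-invariant within
groups and linear in the section values.

## 3. Synthetic data

The generator emulates the *structure* of the study's inputs, not their
content, and every generator is a pure function of (parameters, seed).

**Characters.** Random rooted binary topologies by uniform sequential
pairing (unit branch lengths); forward Mk simulation draws the root state
uniformly and transitions each edge with the closed-form probabilities —
the same matrices the likelihood uses, so simulation and inference are
mutually consistent by construction and rate recovery is a real end-to-end
check.

**Section images.** Proliferating cells are planted as a planar point
process in a w × h region — uniform ("poisson"), centred square lattice
("grid"), or Thomas cluster (uniform parents, Gaussian offspring of sd =
radius, resampled into the region; two parameters controlling disorder
monotonically). Rendering places Gaussian blobs (default σ = 2 px, peak 220)
on Gaussian background noise (mean 10, sd 5) for the PHH3 channel, and a
filled ellipse covering the region (intensity 110) plus a denser nucleus
blob field for the Hoechst channel; defaults are 512×512 8-bit images.
The ground truth (continuous centres, continuous tissue width 2·(w/2)√2)
feeds the oracle tests.

**The nested paper-like dataset** mirrors the study design: 3 species-like
series × 2 positions × 3 individuals × 3 sections = 54 image pairs. The
planted joint/phalanx expected-S ratios are ~5 (moorhen-like), ~2
(grebe-like) and 0.95 (coot-like, phalanx very slightly higher). Both
positions share one tall, thin section geometry (40 × 340 px region,
W_max ≈ 57 px), so typical pair distances exceed W_max and S is robustly
positive; the ratios are planted through the proliferating-cell *counts*
(S grows ≈ quadratically in N), echoing the interpretation that joints
carry more proliferating dense connective tissue. The exact counts
(moorhen-like 189/80, grebe-like 163/110, coot-like 107/110) were fixed
once by a pilot run of the full render→Otsu→S pipeline over seeds
1000–1004 (`scripts/calibrate_synthetic.py`) and are stored with the pilot
curve in `src/webfoot/calibration.json`; the dataset manifest records them
per section.

What the synthetic images deliberately do **not** emulate: histological
texture, staining gradients and artefacts, section-shape differences
between joints and phalanges, cell-size variation, or any real
interspecific difference beyond the planted ratios. Passing tests
therefore certify the *statistic and pipeline* — binarisation, width
normalisation, pair summation, nested averaging, and recovery of a planted
effect through the full imaging path — not any biological claim about real
sections.

## 4. Numerical choices and edge cases

* Transition probabilities: closed form; t < 0 rejected; rows sum to 1 to
  1e−12 by construction.
* Likelihood scaling: per-node max-normalisation with accumulated
  log-scalers; characters with zero likelihood at r = 0 (non-constant data)
  return −∞ cleanly rather than NaN.
* Rate optimisation: log-scale coarse pass (xatol 1e−6) then linear polish
  (xatol 1e−8) within a ×4 window, boundary r = 0 checked explicitly.
* MAP ties: lowest index, flagged (tolerance 1e−12 on vector entries).
* Otsu ties: first argmax; thresholds compared on the full 0–255 histogram
  regardless of the image's observed range.
* S requires ≥ 2 foreground pixels and W_max ≥ 1; coincident continuous
  points (possible only in centroid/point mode) raise rather than silently
  dropping −∞ terms.
* Pair sums above 8000 points are computed in blocks to bound memory; both
  paths are tested against each other.
* All output tables use fixed float formatting, so identical runs are
  byte-identical.

## 5. Problem sizes used by the test suite and acceptance script

Enumeration cross-checks use trees of ≤ 5 tips with k ≤ 3 (200 random
draws); rate recovery uses 20 replicates of 500 characters on 16-tip trees;
the planted-ratio check runs the full 54-section dataset across 20 seeds;
the acceptance script averages ratios over 5 dataset replicates. These
sizes make every check exhaustive or well-powered while keeping a full run
in minutes on one CPU.

## 6. Known limitations

* One symmetric rate: no directional (gain ≠ loss) or hidden-rate models,
  by design; the single-character rate estimate is accordingly diffuse.
* Marginal, not joint, reconstruction: per-node vectors can be individually
  optimal yet jointly inconsistent on adjacent nodes.
* The origin-counting rule operates on MAP states and inherits their
  tie-breaking; near-ties at deep nodes can move the count by one.
* W_max is measured along raster rows only; rotated sections must be
  re-oriented upstream.
* S compares sections meaningfully only under the study's own averaging
  design; it is not normalised for foreground count (use the per-pair
  output when N varies strongly).
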