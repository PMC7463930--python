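# Methods

## Scope and model

The package operates on curated peptides: standard 20-letter sequences of
12–100 residues (shorter ones cannot carry the 9-residue helix window plus
lag-4 covariances meaningfully; longer ones are full proteins, not targeting
or antimicrobial peptides). Group labels (TP with mTP/cTP, SP with
eSP/bSP/tSP, HA-RAMP families, globular AMPs, random) ride in a sidecar TSV.

### Z-scales and ACC terms

Residues are encoded with the three Hellberg z-scales, shipped as a packaged
TSV (`data/zscales_hellberg.tsv`, values as distributed via AAindex/protr);
any 20×3 table can be substituted. The ACC descriptor of a peptide of length
N is

    ACC(i,j,l) = sum_{n=1}^{N-l} z_i[n] * z_j[n+l] / (N - l),   l = 1..4,

for all nine ordered scale pairs: 36 terms. Two deliberate choices:

* **No within-peptide centering.** The formula averages raw products. A
  `centered=True` variant (per-peptide mean subtraction before the products)
  exists but is off by default; the two differ by composition-driven offsets
  and should not be mixed in one analysis.
* **Ordered pairs are kept distinct** (ACC(1,2,l) pairs z1 at position n with
  z2 at n+l; ACC(2,1,l) the reverse). Collapsing them would discard
  directional information along the chain.

Standardization (column mean 0, sample variance 1) is computed over whichever
peptide collection is passed — the analysis set as a whole, matching the
convention that clustering, trees and PCA all operate in the same
standardized space — and the fitted means/scales are returned so held-out
peptides can be projected consistently. Zero-variance columns raise an error
rather than being silently dropped.

### Physico-chemical features

* **Hydrophobicity**: maximum over all 9-residue sliding windows of the mean
  octanol/water hydrophobicity (packaged Fauchère–Pliska-type scale,
  kcal/mol-ish units; overridable). Nine residues is 2.5 helix turns, long
  enough to mean something structurally and short enough to exist in every
  curated peptide.
* **Net charge**: (#K + #R) − (#D + #E), i.e. charge at pH 7.4 with histidine
  and the termini taken as neutral. Integer by construction.
* **Amphiphilic helix**: the longest contiguous segment of ≥ 9 residues whose
  Eisenberg mean hydrophobic moment — |Σ h_n (cos nδ, sin nδ)| / m at
  δ = 100°/residue — reaches `moment_threshold`. The search is an exhaustive
  O(N²) scan over windows (N ≤ 100 makes this trivial); ties in length go to
  the most N-terminal window; one helix is reported per peptide. Reported
  coordinates are 1-based inclusive; internally 0-based half-open.

The amphiphilicity threshold is the load-bearing free parameter. Helical-wheel
screening tools do not share a single published cutoff, so the default
(0.36 on the packaged scale) is a package choice, configurable in
`HelixCriterion`; helix-dependent results (helix length, helix net charge,
amphiphilic fraction, the null-model percentages below) must be read as
criterion-dependent. The mean moment is *not* invariant to adding a constant
to the hydrophobicity scale — swapping scales changes moments and hence
detections.

### Clustering, trees, ordination, statistics

* **K-means** (scikit-learn) with k-means++ and the best inertia of
  `n_init=100` restarts, deterministic per seed; k selected in 2..10 by the
  best mean silhouette (Euclidean, computed in the same standardized space as
  the clustering; coincident-point silhouettes are 0 by convention, ties in k
  go to the smallest). Group-vs-cluster composition is tested with Pearson
  chi² without continuity correction.
* **Neighbor joining** is implemented in-package (classical Saitou–Nei
  Q-matrix joins with the standard branch-length formulas) because the
  support pipeline needs a fixed negative-length policy: negative branch
  lengths are clamped to zero with the deficit moved to the sibling edge,
  preserving the path length through the join. Ties in the Q matrix break
  toward the smallest index pair, so trees are reproducible. scikit-bio's
  independent NJ serves as a cross-check in the test suite. On additive
  distances the implementation is exact.
* **Bootstrap support** resamples the 36 descriptor dimensions with
  replacement — the descriptor-space analogue of resampling alignment
  columns. Resampling peptides instead would change the leaf set and cannot
  yield per-edge support. **Internode certainty** uses the two-way variant:
  for each internal split of the main tree with bootstrap frequency f1 and
  most prevalent conflicting split frequency f2, with p = f1/(f1+f2),
  IC = 1 + p log2 p + (1−p) log2 (1−p), IC = 1 when no conflict is observed;
  TC is the sum over the n−3 internal edges. IC is in [0,1] under this
  renormalization; conflicts beyond the single most prevalent one are not
  aggregated.
* **PCA** via full SVD on the standardized table, with a deterministic sign
  convention (largest-magnitude loading positive per component) so score
  tables are reproducible across runs and platforms. Correlation circles are
  plain Pearson correlations of each descriptor with each PC score. The
  per-group "central area" is the convex hull of the ⌈n/2⌉ points nearest the
  group mean *in the displayed PC plane* (not in full 36-D — the quantity
  annotates a 2-D plot); mean rather than median or density was chosen for
  centrality and is the main open choice here.
* **Group statistics**: two-sided Mann–Whitney rank-sum tests for all group
  pairs with Holm step-down correction (statsmodels). scipy's `method="auto"`
  picks the exact distribution for small tie-free samples and the
  tie-corrected normal approximation otherwise. Peptides with no detected
  helix are excluded from helix-feature summaries and tests (their n is
  reported accordingly). Significance threshold 0.05 throughout.

### Motif rules

FGLK and Hsp70-binding motifs are expressed as window-composition rules
(window length, named residue classes, min/max counts per class, optional
N-terminal search region). The packaged defaults — FGLK: 10-residue window
with ≥1 aromatic {F,W,Y}, ≥1 helix-breaker {G,P}, ≥1 small hydrophobic
{L,V,I,A}, ≥1 basic {K,R}; Hsp70: 7-residue window within the first 10
residues with ≥4 of {L,I,V,F,M} and ≤1 acidic — are explicit heuristics
encoding the motifs' composition glosses, not any specific published scoring
scheme; counts from them are not comparable to counts produced under other
rule sets. Users can encode a published rule exactly via the YAML rule file.
Overlapping qualifying windows shifted by one position are merged into a
single hit so that one motif in a permissive context counts once.

## Synthetic data

The generators emulate the structure of curated peptide collections without
any database access:

* `random_peptides`: residues i.i.d. from a packaged Swiss-Prot-style
  background composition; lengths from a normal(45, 15) truncated to
  [12, 100] (45 residues is the mean targeting-peptide length; the spread is
  an assumption covering short AMPs to long plant TPs) or resampled from a
  user-supplied length set. This is the null model: real composition, no
  selected structure.
* `designed_amphiphilic`: a fully deterministic positive control. Wheel
  positions within a 180° arc alternate Met/Ala; the polar side carries
  `n_basic` lysines at the angles most opposite the face centre, plus Gly/Ser
  filler. Met/Ala rather than an all-Leu face is deliberate: the moment of
  the *arranged* face must clear the detection threshold while the *multiset*
  of residues must not — an all-leucine composition is so hydrophobic that a
  sizeable fraction of its random permutations still forms a full-length
  amphiphilic window, defeating the scramble control. With the Met/Ala face
  the design is detected down to the 9-residue minimum and ~95% of scrambles
  lose (or shorten) the helix.
* `scramble`: uniform residue permutation — identical composition and net
  charge, destroyed periodicity.
* `two_class_dataset`: clustering ground truth from two composition profiles
  (defaults: background boosted 8× on {L,I,V,F,M} vs on {K,R,S,T,N},
  renormalized). The contrast is set so the planted structure is
  unambiguous: silhouette selection returns k = 2 with adjusted Rand ≥ 0.9
  against truth across seeds.

**What passing tests on synthetic data do and do not show.** They show the
pipeline recovers planted compositional structure and that the feature
definitions behave as specified. They do not show that real TPs and HA-RAMPs
cluster together: real peptide groups differ in subtler, correlated ways
(shared evolutionary history, cleavage-site context, species composition)
that i.i.d. composition sampling cannot emulate, and dataset curation choices
move real-data results more than any parameter here.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere randomness exists (generators, k-means
restarts, bootstrap) and outputs are byte-reproducible per seed. Distances
use `scipy.spatial.distance.pdist` so identical peptides sit at exactly 0.
ACC agrees with a brute-force double loop to 1e-12 relative tolerance.
Degenerate cases: peptides shorter than the helix minimum yield "no helix"
(fraction 0); a motif window longer than the peptide yields no hits, not an
error; collinear point selections yield a segment instead of a hull;
singleton-only clusterings and zero-variance descriptor columns raise errors.

## Analysis problem sizes

The shipped drivers use a 120-peptide study set, 200 bootstrap replicates and
a 200-peptide null set — sizes at which every stage runs in seconds while
leaving bootstrap frequencies stable to a few points; full-size analyses
(hundreds of peptides, B = 1000) use the same code paths unchanged.

## Known limitations

* The amphiphilicity criterion (threshold, single-moment rule) is one
  defensible reading of helical-wheel screening; tools differ, and absolute
  helix counts move with the criterion.
* IC uses only the most prevalent conflicting bipartition (no aggregation
  over all conflicts, no partial-tree corrections).
* The motif defaults are composition heuristics; per-peptide counts under
  them must not be quoted as reproducing counts obtained with the original
  published rules.
* Wilcoxon p-values for very small groups (n < 8) come from the exact
  distribution only when the pooled sample is tie-free; heavy ties at tiny n
  make the normal approximation rough.
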