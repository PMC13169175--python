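# Methods

This note documents the models implemented in `colonytrack`, the
assumptions behind them, the synthetic data they are validated on, and
the numerical choices a user may want to audit.

## Problem setting

Input is a time-ordered stack of 2-D integer label images (0 =
background), one per timepoint, from any segmentation tool. Two tasks
are addressed:

1. **Tracking** — give each cell a consistent label across frames, with
   new cells (buds or fission daughters) receiving fresh labels.
2. **Lineage tracing** — for each new bud, identify its mother among
   nearby cells.

Both tasks operate on masks only, never on the underlying microscopy
images, so the methods are insensitive to imaging conditions. Tracking
errors compound exponentially over a recording (a frame-to-frame error
rate of 1−c leaves only ~cⁿ of cells correctly tracked after n frames),
which is why the design aims at very low per-transition error.

## Area normalization

Before feature extraction, all frames of a movie are rescaled by one
global factor s = sqrt(target / observed mean cell area) using
nearest-neighbor interpolation (any smoother scheme corrupts labels).
The default target is 625 px² (≈ a 28-px-diameter yeast cell at 60×
with ~0.11 µm pixels). One factor per movie — not per frame — preserves
growth dynamics within the movie. This makes a trained model transfer
across magnifications without metadata.

## Geometric features

Per cell (from the pixel-coordinate PCA, equivalent-ellipse convention):
area; major and minor full axis lengths 4·sqrt(eigenvalue); their
geometric mean; axial orientation in [−π/2, π/2), encoded for the
network as (cos 2θ, sin 2θ) so that the undirected axis has no wrap
discontinuity; eccentricity. Ten Fourier contour descriptors
(translation-, rotation- and scale-invariant magnitudes) are available
but excluded from the default tracking vector — they did not help
tracking.

Per within-frame cell pair: CoM-to-CoM column/row offsets, Euclidean
length, directed angle encoded as (cos φ, sin φ), and the closest
distance between contours. Contours are sub-pixel `find_contours`
polylines at level 0.5, so cells sharing a pixel edge have distance
exactly 0; 8-connected diagonal contact (distance ≈ 0.7 between
polylines) is snapped to 0, and the first genuinely separated
configuration (a one-pixel gap) has distance 1.

## Assignment graph

For a frame transition, every cross-frame cell pair (x in frame t, y in
frame t+1) becomes a node carrying both cells' feature vectors. Nodes
(x, y) and (x′, y′) are joined by an edge — carrying the x–x′ and y–y′
pair features — iff max(d(x,x′), d(y,y′)) < 8 px (closest contour
points, strict inequality) and x ≠ x′, y ≠ y′. Message passing along
these edges lets the network compare the relative geometry of a cell's
neighborhood in both frames, which is the information that
distinguishes visually identical cells in a crowded colony.

Cross-frame pairs whose CoM distance exceeds 60 px (after
normalization) are pruned to keep the graph near-linear in cell count;
at realistic growth rates the true correspondence moves far less than
this gate between consecutive frames, and `label_nodes` records any
ground-truth pair the gate would drop (zero in all experiments at
strides 1–2; isolated single pairs can occur at stride 3 when the
colony recenters).

## Assignment-scoring network

Node and edge features are z-scored (statistics frozen at training) and
embedded by two separate two-layer MLPs (ReLU) into 64 channels. Four
residual blocks follow; each applies layer norm → ReLU → dropout (0.1)
→ a softmax-aggregation convolution → residual add. The convolution
computes, for node j with neighbors i,

    out_j = MLP( y_j + Σ_i softmax_i(m_ij) ⊙ m_ij ),
    m_ij = ReLU(y_i + e_ij) + ε,

with the softmax per feature channel across neighbors (temperature 1)
and ε a small learnable constant (init 10⁻⁷). Isolated nodes aggregate
zero. A final affine map to two logits and a softmax gives each node a
correct-assignment score. Since sign-sensitive pair features are
direction-dependent, each undirected edge is expanded into two directed
messages with the appropriate sign flips.

Training minimizes per-node two-class cross-entropy with
inverse-frequency class weighting (correct nodes are ~1/n of the
graph), Adam at 10⁻³, full-batch per transition graph, 10–60 epochs.
Transitions where either frame has fewer than 20 cells are excluded
(sparse early frames hurt training; the trained model still tracks
them). Training sets may include stride-subsampled transitions to teach
longer frame intervals. Width, depth, dropout, optimizer and epochs are
exposed in `GNNConfig`; the defaults (64 channels, 4 layers) train on a
laptop CPU in minutes.

Implementation: a small in-package reverse-mode autodiff engine on
numpy. The network runs in float32 with sparse-CSR segment sums and a
single global shift inside the message softmax (messages are bounded
because inputs are layer-normed, so per-neighborhood maxima are not
needed for stability). The vectorized forward is verified against an
independent loop-based dense re-implementation in the test suite.
Everything is seeded and single-threaded: two runs with the same seed
are bit-identical.

## Global assignment

Node scores are reshaped to an n₁×n₂ score matrix (pruned pairs scored
0). Budding mode maximizes total matched score with the Jonker–Volgenant
linear sum assignment (scipy); matches scoring below 0.5 are then
severed into a lost + new pair, so genuinely new cells in dense regions
are not force-matched. Fission mode adds the division constraint: with
m < n cells, at most n−m cells divided, so at most 2m−n cells may be
tracked through; the resulting binary program (row/column sums ≤ 1,
total matches ≤ 2m−n) is solved exactly with scipy's HiGHS-backed MILP.
Fission daughters are attributed to a vanished parent by maximal overlap
with its last footprint, ties by closest CoM.

`track_movie` propagates labels transition by transition (fresh labels
are monotone and never reused), computes features on the normalized
copy, and writes the relabeling onto the original-scale masks, so the
output movie is footprint-identical to the input.

## Lineage tracing

Candidate mothers for a new bud are the closest ≤ 4 cells within 12 px
contour-to-contour distance. For each (bud, candidate) pair, 15
features are computed over the N = 8 frames after budding (~half a cell
cycle at 5-min intervals): contour-distance statistics (value at
budding, std, min, max, range); recession speeds of the bud's CoM and
of its farthest point from the candidate (regression slopes, px/frame);
bud orientation — the acute angle between the bud's major axis and the
line from the candidate's CoM to its contour point nearest the bud —
(value at the last frame, change, min, slope); and the position angle —
same line vs the *candidate's* major axis — (change, std, min, max).
Angles are unsigned in [0, π/2] (an axis is undirected; the range
convention is ours). Shorter windows are allowed down to 2 frames when
the track ends.

The classifier scores each candidate independently (binary
mother/non-mother), which handles variable candidate counts; the
predicted mother is the argmax of the mother-class confidence, with
exact ties resolved to the closest candidate. The network is a stack of
affine → batch norm → ELU → dropout layers and a 2-class softmax head;
the default depth is two hidden layers (the evaluated configuration),
with one and three available. Features are z-scored with statistics
frozen at training. Implementation is hand-derived numpy backprop — the
net is tiny and is retrained thousands of times during feature
elimination, where per-call overhead dominates.

The fluorescence variant needs no training: per post-budding frame, the
image is Gaussian-blurred (σ = 1 px), the brightest point along the
bud's contour is found, and the nearest other cell (within a 20 px
sanity gate) gets a vote; the majority over 8 frames wins, ties go to
the earliest-seen candidate, and a winning share below 0.6 flags the
call low-confidence.

The nearest-cell baseline assigns the cell with minimal contour
distance (ties to the lowest label). In crowded colonies several cells
touch a new bud (distance 0 for all of them), so this baseline
degenerates; the geometric classifier's advantage comes mostly from bud
orientation and growth direction, which are biased toward the true
mother by budding biology.

## Backward feature elimination

A wrapper protocol over the classifier: data are split 80/20 by budding
event (the 20% test portion is never used for selection); within the
80%, 5-fold cross-validation evaluates every single-feature-removal
candidate at each step, and the feature whose removal gives the highest
mean validation accuracy is eliminated, from the full set down to one
feature. Exact accuracy ties (the metric is quantized at 1/|fold|) are
broken toward lower mean validation loss. The reported per-size curve
is the direct CV accuracy of each surviving set.

A caveat established during validation: with mutually redundant
informative features, removing one informative feature is often as
harmless as removing an injected pure-noise feature, so the greedy
order among near-tied candidates is effectively random unless the
evaluation network is in an overfitting regime where noise actively
costs validation accuracy. With two informative features plus one noise
feature the protocol removes the noise first essentially always; with
15 redundant features plus five noise features, noise leaves early on
average but not always first. The elimination default
(`epochs=60, hidden_dim=8, lr=5·10⁻³, dropout=0`) was chosen from
those diagnostics as the best-separating configuration that keeps a
full elimination run fast; pushing the evaluator far deeper into the
overfitting regime (hundreds of epochs, wider layers) sharpens the
noise signal but multiplies the cost of the thousands of retrainings a
full elimination requires.

## Synthetic colonies

The simulator provides the training data and exact ground truth.
Budding cells are mildly elongated ellipses (aspect 1.05–1.35); a
mother past a stochastic maturity area (~600 px², 8% CV) buds every
cell cycle (mean 18 frames ≈ 90 min at 5-min intervals, 15% CV). Buds
nucleate touching the mother, keep their own label forever (the mother
keeps hers), start at 18% of the mother's area, grow to maturity within
about one cycle, and point radially away from the mother. Bud placement
is polar: with probability `bud_site_bias` (default 0.8) the bud
appears near one of the mother's axis poles (±15° Gaussian spread),
otherwise uniformly — this biological bias is what makes geometry-based
lineage tracing learnable beyond the nearest cell. Fission cells are
capsules (width ~9 px) that grow exponentially in length and split
medially at a stochastic division length into two fresh labels,
retiring the parent.

Crowding is resolved by damped Jacobi repulsion (displacements
accumulated per sweep and capped at 1.5 px per cell per iteration), so
colony expansion and passive displacement emerge without a physics
engine; attached buds are re-glued to their mothers each sweep.
Rasterization assigns contested pixels to the cell with the smallest
normalized shape function, making masks disjoint and touching; stray
pixels (rare) are removed by keeping each label's largest 4-connected
component. The optional fluorescence channel renders a Gaussian spot
(σ = 2 px, amplitude 3000 on a noisy ~200-count background) at each
bud–mother junction for the first 8 frames after budding.

What the simulator does **not** model: segmentation errors (masks are
perfect), cell death, cells entering or leaving the field of view,
photobleaching or uneven illumination in the fluorescence channel,
brightfield appearance, and z-structure. Passing the synthetic
benchmarks therefore demonstrates that the algorithms recover known
ground truth under realistic geometry, growth and crowding — not that
they are robust to segmentation noise; on real data the upstream
segmentation quality bounds what tracking can achieve.

## Benchmark scales and defaults

The built-in experiments (test suite and `scripts/acceptance.py`) use:
three training colonies plus one held-out colony per mode — budding
colonies grown 100 frames from 2 cells to ~55–75 cells, fission
colonies 80 frames from 4 cells to ~60 rods; tracker training for 10
epochs on stride-1 and stride-2 transitions (~200 graphs); evaluation
at strides 1–3. At these scales the full budding benchmark runs in
about six minutes on one CPU core and reaches mean tracklet F1 ≈ 0.99
at stride 1; fission tracking is near-perfect (F1 > 0.999), consistent
with the distinctive length scales of rods. Lineage training uses 200
epochs on ~250 pooled budding events.

## Degenerate inputs and edge cases

One-pixel cells get both axes floored at 1 px and zero eccentricity.
Fragmented labels use the largest component's contour and emit a
warning. Empty frames yield empty graphs; the caller treats all cells
as new/lost. Buds lost before their second frame raise an
insufficient-history error and are excluded from lineage training;
unassignable buds (no candidate within the gate) are logged and counted
as incorrect by the accuracy metric unless configured otherwise.
Checkpoints embed a hash of the feature schema and refuse to score
graphs built with a different layout.
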