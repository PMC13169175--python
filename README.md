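# colonytrack

Cell tracking and lineage tracing for growing yeast colonies, operating
purely on labeled segmentation masks.

Time-lapse recordings of budding yeast are hard to track: cells are
densely packed, nearly identical in appearance, change in number and
size, and drift as the colony expands. Because frame-to-frame errors
compound exponentially over a recording (after *n* frames only ~*cⁿ*
of cells remain correctly tracked if 1−*c* is the per-transition error
rate), the per-transition error rate has to be very low for the output
to be usable. `colonytrack` addresses this with:

* **a graph neural network tracker** — every cross-frame cell pair
  (x, y) is a node carrying both cells' geometric features (area, PCA
  axes, orientation, eccentricity); nodes whose same-frame cells lie
  within 8 px of each other (closest contour points) are joined by
  edges carrying relative-position pair features. Residual
  message-passing layers with per-channel softmax aggregation,
  x′ⱼ = MLP(yⱼ + Σᵢ softmaxᵢ(ReLU(yᵢ + eᵢⱼ) + ε) ⊙ (ReLU(yᵢ + eᵢⱼ) + ε)),
  score each pair as a correct/incorrect assignment; the global
  matching is solved by Jonker–Volgenant linear sum assignment. For
  rod-shaped fission yeast, which divides symmetrically and retires the
  parent label, the solve adds the division constraint that with m
  cells before and n > m after, at most 2m−n cells may be tracked
  through (exact MILP, HiGHS);
* **a feed-forward lineage classifier** — for each new bud, up to four
  candidate mothers within 12 px are scored from 15 dynamic geometric
  features (contour-distance statistics, recession speeds, bud
  orientation and position angles over the 8 frames after budding),
  exploiting the biological bias of where buds appear and how they
  grow; plus a fluorescence variant (bud-neck marker majority vote) and
  the classical nearest-cell baseline;
* **a colony simulator** — growing, touching, crowding colonies with
  biased polar budding or medial fission and exact ground-truth tracks
  and lineages, used for training, validation, and all built-in
  benchmarks;
* **metrics** — tracklet F1 (mean ± SEM over transitions, restricted to
  cells with a ground-truth correspondence) and lineage assignment
  accuracy.

The neural networks are implemented in-package on a small numpy
autodiff engine; there is no deep-learning framework dependency, and
every seeded pipeline is bit-reproducible single-threaded.

## Worked example

Train the tracker on two small simulated colonies and track a third
(`examples/track_colony.py`, ~2 minutes):

```
$ python examples/track_colony.py
trained on 74 frame transitions; loss 1.263 -> 0.050
tracklet F1 = 0.9730 +- 0.0050 (SEM over 49 transitions)
events: 51 new cells, 21 lost
```

The F1 is the fraction of frame-to-frame cell correspondences the
tracker recovered, scored against the simulator's exact ground truth; a
lightly trained model severs low-confidence matches into lost + new
pairs, hence the inflated event counts. Full-scale training (three
100-frame colonies, see `scripts/acceptance.py`) reaches F1 ≈ 0.99 at
the base frame interval and degrades gracefully as frames are skipped.

Mother assignment (`examples/trace_lineage.py`):

```
$ python examples/trace_lineage.py
117 budding events with ground-truth mothers
classifier accuracy: 0.958
nearest-cell accuracy: 0.708
```

In a crowded colony several cells touch each new bud, so the
nearest-cell rule degenerates to a tie-break; the classifier recovers
most of those cases from bud orientation and growth geometry.

The other examples: `simulate_colony.py` (ground-truth guarantees of
the simulator) and `eliminate_features.py` (greedy backward feature
elimination with injected noise features).

## Command line

A thin CLI wraps the library for shell use:

```sh
colonytrack simulate out/ --mode budding --n-frames 60 --seed 1
colonytrack train-track out/masks.tif --out tracker.npz
colonytrack track out/masks.tif tracker.npz tracked/
colonytrack evaluate tracked/tracked.tif out/masks.tif eval/
```

Every run writes a `manifest.json` (resolved parameters, seed, output
checksums) next to its artifacts.

## Data formats

Label movies are multi-page TIFF (one integer-labeled page per frame)
or directories of `t0000.tif`-style frames; fluorescence channels are
parallel 16-bit stacks; lineage tables are CSV with columns
`bud_id,mother_id,budding_frame`. Simulated and real data use the same
formats and are interchangeable everywhere.
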