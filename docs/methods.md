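# Methods

## Scope and model of the data

The package analyses high-speed bright-field video of red blood cells
(RBCs) driven through a shallow microfluidic channel with a 5 µm
constriction. The full-scale recording geometry is 800 × 150 px, 8-bit,
500 fps, with a throughput of about 2 cells/s; these are the defaults of
`SceneParams`. Fetal RBCs are modelled as 21% larger by volume than adult
RBCs; since the camera sees a 2-D projection, the class size contrast is
implemented as a projected-area ratio of 1.21^(2/3) ≈ 1.136 under
isotropic scaling (configurable). Fetal RBCs are also softer, which the
generator expresses as a larger elongation factor in the constriction
(defaults: adult 1.25, fetal 1.75) with exponential shape relaxation after
exit (time constant 10 frames). The amplitude defaults are chosen so the
two donor-level distributions stay separated even at extreme donor draws
(the 5% log-normal donor perturbation moves a donor's amplitude by a few
percent, far less than the 40% class gap): the generated cohorts are
strongly separated by construction, in size and in deformation jointly.

## Synthetic recordings

Cells are anti-aliased ellipses of signed contrast (default −40 intensity
units, i.e. darker than the 180-level background) on a static background of
channel walls; sensor noise is i.i.d. Gaussian (sd 2). Arrivals follow
exponential inter-arrival times at the configured throughput; each cell
translates at constant speed (default 6 px/frame), elongates by the
donor-perturbed amplitude while its centre is inside the constriction
(area-preserving: flow axis × e, cross axis ÷ e), and relaxes afterwards.
Donor effect: one log-normal factor per donor (sd 5%) multiplies the mean
area and the amplitude, creating within-donor correlation across that
donor's cells.

What the generator does **not** emulate: hydrodynamics (no lubrication
flow, no speed-up in the constriction), optics (no point-spread function,
no defocus), illumination drift, cell-cell interactions, and the biconcave
RBC geometry. Passing tests therefore demonstrate that the pipeline's
machinery — detection, tracking, donor-disjoint learning, statistics — is
correct and recovers planted structure; they do not certify performance on
real recordings.

## Detection

Per recording, the background is the per-pixel median of 100 frames
sampled uniformly without replacement (all frames if fewer), each smoothed
with a Gaussian kernel first. The kernel width is nowhere fixed by the
design being reproduced; σ = 1 px is the default (removes single-pixel
noise without eroding 50 px² cells). Each frame is smoothed the same way,
the background subtracted, and pixels with |difference| > 5 (strict) are
foreground — the absolute value makes detection symmetric in contrast
sign. Connected components (8-connectivity by default, 4 available) with
area strictly greater than 50 px are reported with centroid and half-open
bounding box, sorted by (min_col, min_row). Coordinates are (row, col),
0-based, everywhere.

## Tracking and clips

Regions in consecutive frames are paired by largest shared pixel area,
computed on exact pixel sets. Assignment is greedy in descending overlap;
ties break toward the next-frame region with the smaller
(min_row, min_col) corner, then the earlier previous region — cells are
sparse, so optimal assignment would change almost nothing, and determinism
matters more. Chains of pairings form tracks (strictly consecutive
frames); tracks shorter than a minimum length are dropped (library default
8 frames, the slow pathway's minimum).

Each track yields a clip: a 50 × 50 px window centred on the rounded
region centroid, cut from the raw (unsmoothed) frames, zero-filled outside
the frame. Clips are standardized to a fixed temporal length for batching
(default 64 frames; uniform nearest-frame resampling for longer tracks,
last-frame replication for shorter). Clips come from raw rather than
background-subtracted frames (a config switch exists).

## Two-pathway classifier

The classifier follows the slow/fast two-pathway design for video
recognition with τ = 8 (slow temporal stride), α = 8 (fast/slow frame-rate
ratio) and β = 1/8 (fast/slow channel widths). Both pathways are residual
3-D CNNs; fast features are fused into the slow pathway after the stem and
after each stage but the last through a time-strided convolution (kernel
5×1×1, stride α, output 2·βC channels, concatenated channel-wise). The
head pools each pathway spatially, then takes both the temporal mean and
the temporal max of the pooled features — constriction deformation is a
transient event, and a pure space-time average dilutes it while the max
preserves it — and feeds the concatenation through dropout into a linear
softmax. Input is 1-channel grayscale;
the stems are adapted accordingly (slow stem kernel 1×5×5 — no temporal
mixing; fast stem 3×5×5; both spatial stride 2).

Depth presets: `tiny` (two stages, slow widths 32/64, one basic block
each) for CPU-scale work; `50`/`101` keep the standard four-stage layouts
(widths 64–512, blocks 3-4-6-3 / 3-4-23-3) built from the same basic
block. Parameter counts per pathway are exposed; the fast pathway costs
≈ β² of the slow one.

All layers — im2col 3-D convolution, batch normalisation (momentum 0.9,
eps 1e-5), ReLU, dropout (inverted, seeded), linear — are numpy with
hand-derived backward passes, verified against central finite differences
in the test suite. An optional input average-pooling factor
(`spatial_pool`) downscales clips before the stems; the desk-scale preset
uses 2 (50→25 px), which preserves the size/aspect contrast while cutting
compute ≈ 4×.

## Training and evaluation

Donors are partitioned into k = 5 splits by greedy balancing: donors
shuffled (seeded), stably sorted by descending cell count, each assigned
to the currently smallest split; every donor lands in exactly one split,
and each split ends up with ≈ 20% of cells. A stratified variant runs the
same greedy pass within each class, guaranteeing both classes in every
split — with 164 donors both variants behave alike; with 12 donors only
the stratified one keeps the test split two-class, so small cohorts use
it. One split is the test set; the other four are cross-validation folds
(train on 3, validate on the 4th).

Optimisation: SGD with momentum 0.9, batch 8, cross-entropy, cosine
warm-restart schedule (initial period 10 epochs, doubling; initial lr
0.01, floor 1e-4 — the restart constants are not fixed by the reference
design and are config), at most 250 epochs, validation every 2 epochs,
early stop after 10 evaluations without improvement in validation macro
sensitivity. Train-time augmentation: random spatial jitter ±4 px with
edge-replicated fill (zero fill would put an out-of-distribution black
border on every training clip), random leading-frame drop up to 4 frames,
random vertical flip (the channel is mirror-symmetric across the flow
axis); horizontal flip is off by default because flow direction is
physically meaningful, and intensity and scale jitter exist but default
off because both corrupt the integrated-contrast size cue. Two options
matter specifically when very few donors are available: mixup
(Beta-distributed clip interpolation with soft labels), which fills the
feature space between the handful of donor exemplars each class provides
and stops the network carving decision islands around them, and
stochastic weight averaging over the later checkpoints (with a batch-norm
statistics refresh), which removes the donor-level lottery of selecting a
single best-validation checkpoint against a two-donor validation set.
Both default off at full scale and on in the desk-scale preset.

Metrics: AUC (fetal-score ranking), macro sensitivity (unweighted mean of
per-class recalls — the aggregate the per-class recalls imply), accuracy,
precision and F1 for the fetal class, each in % with a Wald 95% CI
(p ± 1.96·√(p(1−p)/n)); AUC uses the Hanley–McNeil variance. Fold
aggregation defaults to the entry-wise fold mean (confusion matrices are
averaged); pooled-score metrics are reported alongside. Per-donor
accuracies are averaged across fold models with donors weighted equally.
Ramping: 10% of the total data is allocated donor-disjointly for early
stopping, then one model per fraction {10%, …, 100%} of the remaining
training clips (≈ {7%, …, 70%} of the total) is trained and scored by test
macro sensitivity.

## Donor statistics

The per-donor per-fold accuracy grid A (D × F, balanced) is modelled as
A_df = μ + α_d + a_f + ε with donor effects fixed (sum-to-zero; the model
assigns no distribution to them) and the fold effect random,
a_f ~ N(0, σ²_A). The error contrasts orthogonal to the donor design split
into F−1 fold-mean contrasts with variance σ² + Dσ²_A and (D−1)(F−1)
interaction contrasts with variance σ², so REML has a closed form: the
method-of-moments solution when MS_fold ≥ MS_resid, the pooled variance at
the σ²_A = 0 boundary otherwise. The LRT against σ²_A = 0 is referred to
half a χ²₁ tail (its null distribution is an equal mixture of a point mass
at 0 and χ²₁ because 0 is on the parameter-space edge), so p ≤ 0.5 always.
The restricted log-likelihood is defined through orthonormal contrasts;
the LRT is invariant to that convention but the absolute log-likelihood
(and hence AIC, reported as −2·logLik + 2·(D+1) for the reduced model) can
differ from other software by a data-independent constant. The
implementation matches lmerTest's variance estimates and LRT to seven
digits on test grids.

The donor ANOVA is one-way over donors with folds as replicates
(df D−1, D(F−1)); the class comparison is a one-factor ANOVA on the D
donor-mean accuracies (df 1, D−2), equivalent to the squared pooled-t —
its two-level factor is why a "two-way" label sometimes attaches to it;
the degrees of freedom fix the analysis actually meant. Degenerate inputs
(zero residual variance) report F = ∞, p = 0, flagged; unbalanced grids
are refused rather than approximated.

## Desk-scale problem sizes

Full-scale recordings are large (a faithful 50-cell donor at 2 cells/s is
≈ 12 000 frames of 800 × 150 px), so tests and the acceptance run use a
scaled scene chosen once: 256 × 80 px frames, 20 cells/s, 12 donors × 30
cells, clips of 32 frames (slow pathway: 4), tiny depth preset with input
pooling 2, minimum track length 24 frames so every clip spans the
constriction passage (shorter fragments carry no deformation signal),
training ≤ 30 epochs at lr 0.02 with dropout 0.1, weight decay 1e-4,
mixup 0.3 and weight averaging — the donor-robustness choices discussed
above. The synthetic cohort at these settings is strongly separated:
donor-level size and deformation distributions overlap only in the
extreme tails, and a donor-disjoint test split is recovered at macro
sensitivity well above 0.9 in the typical seed (an occasional extreme
donor draw still lands near the clip-level class boundary).

## Known limitations

- The numpy network trains at CPU scale only; the deep presets are
  buildable and correct but not desk-trainable.
- Track identity switches are possible when cells touch; no occlusion
  reasoning or motion model is attempted.
- The boundary-LRT asymptotics (50:50 mixture) are exact only for the
  balanced design; unbalanced grids are out of scope by construction.
- Wald CIs can overshoot [0, 100]% near the boundaries; they are reported
  as computed.
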