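# Methods

## Model

Each taxon contributes one aligned nucleotide sequence of length L,
one-hot encoded as a 4×L matrix (rows A, C, G, T; U read as T; N and gaps
as all-zero columns).  The encoder h_θ is a small convolutional network:

    conv (30 filters, kernel 10, stride 1, no padding)
    → average pooling (width 5, non-overlapping)
    → dropout 20% (training only)
    → flatten → dense (360, ReLU) → dense (s = 30, ReLU)

For L = 350 the convolution yields 341 positions, pooled to 68; for the
simulator's L = 35, 26 positions pooled to 5.  The final ReLU is
deliberate: it lets latent dimensions switch off exactly, which is what
makes "root features" (below) identifiable, and it gives the collapse
failure mode a clean signature (exact zeros).  The fully connected stack
is one 360-unit hidden layer followed by the 30-unit output; a variant
with a second 360-unit layer is available (`extra_hidden=True` /
`--fc-layers 2`) since the hidden-layer count is a genuinely open design
choice.  Weights use uniform fan-in initialization under the run seed.
Dropout is placed directly after pooling, before flattening.

Latent distances are plain Euclidean norms between feature vectors;
together they form D_θ, compared against the reference tree T.

## Losses

Let Σ_T be the set of quartet splits of T (one per 4-subset; |Σ_T| =
C(n,4)) and D_T the patristic metric.  With the closed form
e = (D(i,l) + D(j,k) − D(i,k) − D(j,l)) / 2 for a split ij|kl:

* siamese: mean over unordered pairs of |D_θ − D_T|;
* quartet: mean over S ∈ Σ_T of e_θ(S)²;
* combined: quartet + σ · mean over S ∈ Σ_T of the mean |D_θ − D_T| over
  the six within-quartet pairs of S.

All reductions are means, so gradients are comparable across n.  In the
combined loss each pair is implicitly reweighted by the number of quartets
containing it; this follows the per-quartet indexing of the objective and
is documented rather than corrected.  σ defaults to 0.1 — large enough to
anchor the embedding scale against collapse, small enough that topology
(not branch-length fit) dominates; it is exposed in the config and the
behaviour is qualitatively stable over σ ∈ [0.01, 1].

The quartet score is the fraction of S ∈ Σ_T whose diagram is S or S′
with |e| < f, where f = (min(s₂, s₃) − s₁)/2 is the isolation index of
the reference split.  Comparisons are exact float comparisons — near
collapse an epsilon would silently inflate the score — and the inequality
is strict so that f = 0 (e.g. the all-zero matrix) never counts.  Ties
s₂ = s₃ classify as S and s₁ = min(s₂, s₃) as S/S′; exact ties occur on
perfect tree metrics, and float rounding may land them a hair on either
side, which does not affect correctness (both S and S′ reconstruct the
split).

## Training

Data are presented quartet-wise: one epoch is one pass over Σ_T in
shuffled minibatches (default 64 quartets per Adam step; the pure siamese
loss passes over the n(n−1)/2 taxon pairs instead).  Every step embeds
all taxa — the batch only selects which quartets contribute to the loss.
This epoch semantics, rather than one full-batch step per epoch, is what
reproduces the characteristic dynamics at a 100-epoch budget: the
combined loss reaches quartet score 1.0 within the first tens of epochs,
training against a taxa-shuffled tree converges at a comparable rate, and
the pure quartet loss collapses.  Gradients flow analytically from the
loss through the distance matrix into the encoder; the backward pass is
verified against finite differences in the test suite.

Optimizer: Adam with lr 7e−3 (β₁ = 0.9, β₂ = 0.999), chosen so that the
fixed 100-epoch protocol converges for the regularized losses while the
unregularized quartet loss exhibits its collapse mode within the run; at
much smaller rates the collapse drift is too slow to manifest, at much
larger rates the σ = 0.01 setting destabilizes.  Both lr and batch size
are config.  Training runs a fixed number of epochs (no early stopping,
no model selection); validation is delegated to the interpretability
statistics.  Collapse is flagged when the mean latent norm drops below
1e−3, far below the patristic scale of any tree with branch lengths
≥ 0.1.  With minibatch noise the evaluation-mode loss is not monotone
epoch-to-epoch (roughly 60% of successive epochs decrease); over a run it
decreases by an order of magnitude or more.

Replicates run with seeds base_seed + 0..n−1; each run's seed feeds
separate generators for initialization, dropout and batch order, making
runs bit-reproducible.

## Simulator

The generator emulates a minimal three-segment evolution process along a
guide tree: a stable prefix (8 nt, drawn once, shared by all taxa), an
evolving core (20 nt, drawn at the displayed root, then re-drawn toward
the leaves with exactly 3 substitutions — distinct positions, forced base
change — on entry to every node, leaves included), and a random tail
(7 nt i.i.d. per taxon).  Branch lengths are ignored: divergence accrues
per node.  Applying mutations at leaves too keeps sister taxa distinct in
the evolving segment; both root children receive their 3 substitutions
independently.  Segment positions (1-based) are S1 = 1..8, S2 = 9..28,
S3 = 29..35.

What the simulator does **not** emulate: indels, rate heterogeneity,
substitution-model structure (no transition/transversion bias), or
alignment uncertainty.  Passing tests on simulated data therefore show
that the losses and the interpretability pipeline behave as designed on
clean tree signal; they do not establish performance on real marker genes,
where signal strength and alignment quality vary.

Random reference trees are generated by uniform sequential leaf addition
(2k−3 attachment choices for the k-th leaf) with i.i.d. uniform [0.1, 1.0]
branch lengths.  The displayed root is placed on the most balanced edge,
mirroring how reference trees of two sister clades are displayed; the
root bipartition anchors both the simulator's evolving segment and the
root-feature definition.

## Interpretability

A latent feature is a *root feature* when every taxon on one side of the
root bipartition activates it (> 1e−6) and no taxon on the other side
does.  For each root feature, in-silico mutagenesis substitutes all four
bases at every position (the present base included), evaluates the model,
and normalizes the four outputs per position as P/Σ|P| − 0.25, so an
uninformative position scores four zeros.  Maps are averaged over the
feature-positive taxa, then collapsed to a per-position relevance by
summing absolute values over bases and normalizing across positions —
absolute values because the four per-position scores of a ReLU model sum
to exactly zero, so signed accumulation would erase the signal.  The
localization statistic Δf is the mean relevance over S2 minus the mean
over S3; its extreme values are +1/20 (all relevance on one S2 position)
and −1/7.

The null comparison trains models against taxa-shuffled copies of the
guide tree (same shape and lengths, permuted labels) on the same
alignment, and compares pooled root-feature Δf values with a one-sided
Mann-Whitney U test (exact for group sizes ≤ 8, tie-corrected normal
approximation otherwise).  On average, correct-tree models localize more
relevance on the evolving segment than shuffled-tree models, but the gap
is modest and varies across experiment realizations: any
taxon-discriminating feature leans on S2, which holds 20 of the 27
variable positions, and the valid-convolution geometry further favors
central positions over the 7-nt tail.  Small experiments (5 models per
group) therefore reject the null only in a minority-to-half of runs;
larger pooled comparisons (10 models per group) reject more often.  An
external attribution backend (e.g. a DeepLIFT implementation) can be
substituted for mutagenesis via `model_root_deltas(...,
attribution_backend=...)`; everything downstream of the L×4 score matrix
is backend-agnostic.

## Numerical and interface choices

* Leaf indices are assigned by sorted label order and used by every
  matrix and table; FASTA IDs must match tree leaves exactly.
* Rooted Newick inputs are accepted; a degree-2 root is treated as an
  edge subdivision (it changes neither patristic distances nor induced
  quartet splits).  Polytomies, duplicate labels, and partial branch
  lengths are rejected up front.
* Quartet splits are stored canonically (i < j, k < l, i < k), one per
  4-subset; the induced pairing is found as the unique pair-sum minimizer
  under the hop-count metric.
* Zero-length branches are allowed; quartets across a zero-length edge
  have f = 0 and simply never count as correct.
* Distance matrices export to relaxed PHYLIP and to NEXUS with a
  DISTANCES block (triangle=both), the format SplitsTree reads for
  NeighborNet; taxon labels are sanitized for these dialects with a
  warning and a mapping table.
* Problem sizes throughout the tests and the reproduction script are the
  study conditions themselves (13 taxa, 35-nt simulated alignments,
  100-epoch runs, 10 replicates), chosen because the method targets small
  curated taxon sets; nothing is scaled down from them.

## Known limitations

* A tree metric is not exactly Euclidean-embeddable, so with a large
  siamese weight (σ ≈ 1) the optimum retains small distortion and the
  quartet score touches 1.0 only transiently through minibatch noise.
* The interpretability separation (Δf, correct vs shuffled trees) is a
  weak effect at 13 taxa × 35 nt; see above.
* Training cost grows with C(n, 4); for much larger taxon sets quartet
  subsampling would be needed, which is not implemented.
* The attribution tools assume alignable, equal-length sequences.
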