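# Methods

## Model

`spin` classifies protein sequences into functional classes within a family
of homologs by (i) locating a domain span from per-token embeddings and
(ii) classifying the mean-pooled span representation.

A sequence of `n` residues is tokenized to `N = n + 1` tokens (one prepended
classification token, CLS). Sequences longer than `max_length − 1 = 1023`
residues are excluded, never truncated, and the exclusion is reported with
the record id; attention-based encoders scale quadratically in sequence
length, so a hard cap is the standard operating regime. An encoder
satisfying `EncoderContract` maps tokens to an `N × d` matrix. The CLS row
is removed before all downstream processing and never contributes to
pooling.

**Span predictor.** A single dense layer maps each residue-token vector to a
(start, end) logit pair, giving an `L × 2` matrix over the `L = n` residue
tokens — the extractive question-answering construction. At inference the
span is `(argmax start column, argmax end column)`, ties to the lowest
index; when a domain occurs more than once only this single best-scoring
span is reported. If the selected end does not lie strictly after the
selected start, the model falls back to the full residue range and flags the
prediction; no other length or ordering check is applied. Coordinates:
files carry 1-based inclusive residue positions (the UniProt convention);
internally spans are 0-based token indices over residues, conversion
`start − 1` / `end − 1`; the pooled region is `[t_start, t_end]` inclusive.

**Classifier.** The embedding rows in the span are averaged into one `1 × d`
vector and passed through Dropout → Dense → Tanh → Dropout → Dense with a
softmax over the `|C|` classes. With the span module disabled (or when a
training set carries no annotations) the mean runs over all residue rows.

## Objective and optimisation

```
L = w_class · L_class + w_span · L_span,   w_class = 0.7, w_span = 0.3
```

`L_class` is the batch mean of `−log ŷ(true class) · W(true class)` with
inverse-frequency weights `W_c = N / (|C| · s_c)` computed from the training
supports; balanced data gives every class weight exactly 1. `L_span` is the
mean of the start- and end-position cross-entropies, averaged over the
annotated samples of the batch; unannotated samples contribute only the
class term, and a fully unannotated dataset drops the span term entirely.
Batch reduction is the mean (not the sum) so the learning rate is
batch-size independent. Probabilities are clamped at 1e-12 before logs.
Class weights multiply only the classification term.

Optimisation is AdamW (decoupled weight decay) with a cosine-annealed
learning rate and linear warmup over the first 10% of steps
(`warmup = round(0.1 · total steps)`). Parameters declared frozen by the
encoder contract are never updated — the tests assert bit-identity across
steps. Defaults in `TrainConfig` describe the fine-tuning regime of a
pretrained encoder: learning rate 1e-4, weight decay 0.01, dropout 0.1,
10 epochs, batch 8 (train) / 32 (eval), three seeds for the repetition
driver (`train_multi_seed`, reporting mean ± sd of the best validation
macro-weighted F1).

**Checkpoint selection.** After each epoch the validation macro-weighted F1
is computed through the *inference* path (predicted spans, no dropout); the
snapshot with the highest value is kept. Ties keep the **latest** epoch: the
classification metric saturates within a few epochs on separable families
while the span head — 30% of the objective — is still improving, so keeping
the earliest tied epoch would freeze a half-trained span predictor. This is
the one place the implementation prefers late over early; overfitting is
still bounded by selection on validation F1 itself.

**Splits.** `split_dataset` partitions 80/10/10 by default:
`floor(0.8 n)` train, `floor(0.1 n)` validation, remainder test (28,151
records → 22,520 / 2,815 / 2,816). Stratified mode (the default) applies
the same rule within each class, requiring ≥ 3 members per class.

## Evaluation

Per class, one-vs-rest counts (TP, FP, TN, FN) give

- macro-weighted F1 `Σ W_c F1_c / Σ W_c` with
  `F1_c = 2TP_c / (2TP_c + FP_c + FN_c)` and `F1_c = 0` on an empty
  denominator (conservative 0/0 rule);
- weighted accuracy: the `W_c`-weighted mean of per-class one-vs-rest
  accuracies. Normalisation divides by `Σ W_c` by default, which keeps the
  score in [0, 1] under imbalance; a `1/|C|` prefactor instead (identical
  for balanced classes, where every `W_c = 1`) would exceed 1 on perfect
  imbalanced predictions, so it is exposed only as the
  `normalization="n_classes"` switch.

Weights at evaluation come from the *training* supports, so validation and
test scores are comparable across splits.

Span quality is the fraction of boundaries within a ±3-residue tolerance,
start and end separately; tolerance 0 reduces to exact match. Uncertainty is
a percentile bootstrap: the paired test set is resampled with replacement
(default 1000 replicates) and the 2.5/97.5 percentiles bracket the
replicate mean. The percentile method was chosen over normal-approximation
intervals because span accuracies sit near 1, where symmetric intervals
leak outside [0, 1].

## Calibration and abstention

Temperature scaling divides logits by a scalar `T > 0` fitted on validation
data by bounded 1-D NLL minimisation (`T ∈ [0.05, 20]`, tolerance 1e-4).
Scaling by a positive scalar is monotone per sample, so predicted classes
never change. Degenerate case: when the validation set is perfectly
classified, the NLL decreases monotonically as `T → 0` and the optimum
saturates at the bound, collapsing every confidence to 1; `T` is then
unidentified and the fit returns `T = 1` with a warning. Calibration quality
is the Expected Calibration Error over 10 equal-width bins on (0, 1]
(bin count exposed as a flag): the occupancy-weighted mean absolute gap
between bin accuracy and bin mean confidence, empty bins contributing 0.

Abstention: a prediction whose (calibrated) top confidence falls below a
threshold is labelled UNKNOWN; threshold 0 never abstains. A data-driven
threshold is suggested as the lowest crossing of the binned confidence
densities of an in-family set and an out-of-family set (midpoint of the two
bin centres where the density difference flips sign, carrying the last
non-zero sign across empty bins); identical distributions produce a warning
and no threshold.

## Synthetic families and the toy encoder

The generator builds `flank | domain-background · MOTIF · domain-background
| flank` sequences:

- flanks: i.i.d. uniform over the 20 canonical amino acids, lengths 10–40;
- domain background: uniform over a 4-letter hydrophobic core alphabet
  (I, L, V, M), domain lengths 20–32 — the composition step at the domain
  boundary is the learnable boundary signal, as for a globular domain
  against disordered linkers;
- motif: one 12-residue motif per class, planted ≥ 3 residues interior to
  the domain, each position substituted by a uniform random letter with
  probability 0.05; 200 sequences per class.

Default motifs are **composition-matched**: each is a random permutation of
the same balanced multiset over the domain alphabet, with pairwise-disjoint
3-mer sets. Classes therefore differ only in residue *arrangement*, never in
letter counts — which is exactly why composition-preserving reshuffles work
as out-of-family nulls, and why the null experiments measure loss of
sequence structure rather than a trivial composition shift.

The `ToyEncoder` represents residue `i` by its one-hot identity, the letter
compositions of the 6 residues to its left and right, a constant, and a
one-hot hash (256 buckets) of the gapped context pattern
`(i−3, i−1, i, i+1, i+3)` — dimension 320, deterministic, zero trainable
layers. Two design constraints fix the context feature: its receptive field
(7 residues) must exceed the 5-residue blocks of the chunk-reshuffle null,
so that chunked sequences lose their context features the way they lose
long-range structure under a full transformer encoder; and it must tolerate
sparse substitution noise, which the dilation provides (a single substitution
corrupts fewer gapped patterns than contiguous 7-mers, whose complete loss
under 5% noise is common enough to cap classification accuracy). A plain
3-residue window satisfies neither: it is statistically too weak to localise
a boundary against uniform flanks, and chunk reshuffling leaves 3-mers
mostly intact.

Null generators: `chunk_shuffle` permutes contiguous 5-residue blocks within
the sequence (a trailing short block travels as one unit); `full_shuffle`
permutes residues uniformly. Both preserve the amino-acid multiset exactly.

## Canonical studies

`spin.studies` fixes one configuration used by the test suite, the
acceptance script and the README example: a 3-class family (seed 11,
600 sequences, 80/10/10 split) and head training at learning rate 0.1,
150 epochs, weight decay 0.05, dropout 0.2, hidden width 64. These differ
from `TrainConfig`'s defaults because the task differs: the fine-tuning
defaults assume a pretrained encoder whose parameters need gentle updates,
whereas here small heads are trained from random initialisation over a
frozen encoder — a regime that needs a larger step size and more epochs
(AdamW steps are scale-adaptive, so total parameter movement is roughly
learning rate × steps). The stronger regularisation keeps the classifier's
confidence moderate off the training manifold, which the abstention
experiment measures.

Problem sizes in the studies (600 sequences, 1000 bootstrap replicates,
200 coverage repetitions, 1000 oracle instances, batches up to 2000
sequences for the scaling fit) were chosen so the full acceptance run
completes in about a minute on a single CPU while keeping sampling error
well below the margins being tested.

## What the synthetic results do and do not show

Passing synthetic studies demonstrate that the pipeline is *correct*: the
losses implement their formulas, the span head can localise a boundary
marked by a composition step, pooling and fallback behave as specified,
weighting neutralises imbalance, the bootstrap has nominal coverage, and
calibrated confidence separates structured from reshuffled input. They do
not show that real protein families are classified at any particular
accuracy: real homologs share phylogenetic covariance, motifs degrade
non-uniformly, domain boundaries are softer than a composition step, and a
pretrained language-model encoder behaves differently from the toy encoder.
Real-data performance must be established with a real encoder and labels.

Known limitations:

- The toy encoder is strictly local; it cannot express long-range residue
  interactions, and classification evidence is bounded by exact k-mer
  survival under noise.
- Abstention margins vary with the family realisation (some random families
  are easier to reject nulls for than others), and binary families saturate
  softmax confidence, weakening separation; the canonical abstention study
  therefore uses ≥ 3 classes.
- Temperature scaling on small, nearly-perfect validation sets is weakly
  identified (see the degenerate-case guard above); ECE estimates on
  60-sample sets are coarse (bin occupancy is low).
- The NumPy training loop holds all embeddings in memory; for datasets
  beyond ~10⁴ sequences × 1024 tokens a streaming encoder cache would be
  needed.
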