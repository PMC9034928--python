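# Methods

## Overview

`drugner` is a joint sequence-labeling system for drug named-entity
recognition (DNER, BIO tags over entity types) and drug named-entity
normalization (DNEN, per-token identifiers from a controlled vocabulary).
A shared BiLSTM encoder over concatenated word, character-CNN and
(optionally) contextual embeddings feeds two task heads coupled by
explicit feedback; the DNER head is a linear-chain CRF, the DNEN head a
per-token softmax. Everything — embeddings, recurrences, CRF, training —
is implemented in NumPy with hand-written reverse-mode gradients that the
test suite validates against central differences and exact enumeration.

## Preprocessing

Corpora arrive either as DDI-challenge-style XML (sentences with
character-offset entity annotations, offsets 0-based and inclusive on
both ends) or as CoNLL-style token-per-line files. Tokenization is
whitespace splitting with leading/trailing punctuation peeled into
separate tokens; any entity boundary falling inside a token forces an
additional split, so entity spans always align with token boundaries and
BIO conversion is lossless. Discontinuous mentions (semicolon-separated
offset fragments) are annotated fragment by fragment. Ill-formed BIO
output is repaired by promoting a stray `I-X` to `B-X`, which preserves
the entity content and keeps recall measurable.

Four alphabets (word, character, label, feature) are built over the
training corpus in first-occurrence order, plus a normalization-label
alphabet for the second task. Every alphabet reserves index 0 for padding
and 1 for unknown; frozen alphabets map unseen instances to the unknown
index. A corpus encodes into two parallel lists — surface columns
`[words, chars, labels, features]` and index columns mirroring them — and
decoding the index columns reproduces the corpus exactly. The feature
column has no prescribed content; it defaults to a single constant symbol
and accepts a user extractor `f(sentence, i) -> str` (e.g. capitalization
shape), preserving the four-column contract without inventing features.

## Embeddings

* **Word**: trainable table, dim 100 by default; rows can be initialized
  from a plain-text vector file, remaining rows drawn uniformly from
  ±√(3/dim). The padding row is pinned at zero. The literal ±3/dim
  reading of the initialization bound is available (`init_bound:
  "linear"`); the variance-preserving √ form is the default, which is the
  convention of the character-CNN tagging lineage.
* **Character CNN**: char embeddings (dim 30) are convolved with 30
  filters of window 3 and max-pooled over time into one vector per word.
  Words are padded symmetrically so a single-character word still yields
  a window; trailing padding beyond that requirement is stripped, making
  the encoding invariant to it. Dropout (rate 0.5) is applied to the
  character embeddings before convolution, in training mode only — this
  is the one dropout site in the network; placing it here follows the
  published architecture's description of dropout as part of the CNN.
* **Contextual**: a small bidirectional language model (L layers, state
  s, trained by next-token prediction forward and previous-token
  prediction backward) yields 2L+1 representations per token: the input
  vector plus forward/backward states per layer, where the forward state
  at position k conditions only on tokens ≤ k. For mixing these regroup
  into L+1 layers of width 2s (layer 0 is the input duplicated), combined
  as ELMo_k = γ·Σ_j softmax(w)_j·h_{k,j}. The mixing formula carries no
  task scale as printed, so the scalar γ defaults to 1 and is trainable.
  During downstream training the biLM is frozen; only w and γ receive
  gradient. The configured `elmo_dim` is the mixed width 2s (1024 in the
  reference configuration; test fixtures use 8–16).

Channels concatenate in the fixed order (word, char, contextual)
regardless of how the configuration lists them, e.g. 100+30+1024 = 1154
at reference dimensions.

## Encoder

The shared encoder is a BiLSTM (state size 200 default, zero initial
states). Two cell variants sit behind `lstm_variant`:

* `standard` (default, matching the reference hyperparameter table's "no
  peepholes"): independent input/forget/output gates, no peepholes.
* `paper`: a coupled input–forget cell with peephole weights,
  i = σ(W_xi x + W_hi h' + w_ci∗c' + b_i),
  c = (1−i)∗c' + i∗tanh(W_xc x + W_hc h' + b_c),
  o = σ(W_xo x + W_ho h' + w_co∗c + b_o), h = o∗tanh(c).

The two variants exist because the published recurrence equations and the
published hyperparameter table disagree; the table governs training, the
equations are honored verbatim behind the switch and verified by a scalar
hand oracle. Both variants have full backward passes and are
gradient-checked.

## CRF

Emissions P (n×k) come from the DNER head; transitions A ((k+2)×(k+2))
carry distinguished START/STOP indices, with transitions into START and
out of STOP pinned at a −10⁴ sentinel (kept finite so gradients never
produce NaN). Start/stop transitions are learned. The partition function
uses the forward recursion in log space; the NLL gradient is
expected-minus-observed feature counts from forward–backward; decoding is
exact Viterbi with ties broken toward the lowest label index. A hard BIO
transition mask (forbidding `I-X` after anything but `B-X`/`I-X`) is
available but off by default — the CRF is left to learn the constraints,
and decoded output is repaired instead. Batch loss is the mean
per-sentence NLL, keeping the learning-rate scale independent of batch
size.

## Multitask coupling and training

Both heads read the shared state v_i through

    input = v_i ∘ (v_i + y_other M),

so the head always sees the uncorrected representation alongside the
feedback-corrected one (the bare `v + yM` reading is available via
`feedback_concat: false`). U maps DNEN labels into the feedback space and
V maps DNER labels — the published equations print U in both places while
the accompanying text names V for the DNER→DNEN direction; the text's
reading is implemented. y_other is the current model's own prediction
(one-hot by default, the softmax distribution optionally), never the gold
labels of the other task — instances arrive with only one task's labels —
and no gradient flows through it. At inference one alternation round is
used: DNEN without feedback → DNER with that feedback → DNEN with the
decoded DNER labels.

Training samples a task per step (proportional to dataset sizes by
default, uniform or explicit probabilities optional), draws the next
minibatch from that task's reshuffling pool, and updates the shared
parameters plus that task's head only. One epoch is one expected pass
over the union of task instances. The optimizer menu covers SGD (default:
lr 0.015, per-epoch decay lr/(1+0.05e), global gradient-norm clip 5.0),
AdaGrad, Adadelta, RMSProp and Adam. Single-task training is the same
loop with a degenerate schedule and feedback off, which makes the
"zeroed feedback reduces to single-task" property hold by construction.
All randomness (initialization, dropout, task sampling, shuffling) flows
from independent streams spawned from one seed; repeated runs are
bit-identical.

## Evaluation

Span-level precision/recall/F1 under two criteria: **strict** (exact
boundaries and type) and **type** (≥1 token overlap with a same-type gold
span). Credit is one-to-one with greedy left-to-right pairing — the
matching multiplicity is not prescribed anywhere authoritative, and
greedy pairing prevents one long prediction from matching several golds;
on non-overlapping span sets it coincides with maximum bipartite
matching, which the tests verify against an independent matcher.
Micro-averages sum TP/FP/FN across types. Degenerate conventions: P=0
with no predictions, R=0 with no gold, F1=0 when P+R=0. Normalization
output is scored by token accuracy and mention accuracy (all tokens of a
gold mention correct); no authoritative DNEN metric exists, so both are
reported.

## Synthetic corpora

Real drug-interaction corpora are licensed; the generator produces
structurally equivalent material with known ground truth. Sentences are
drawn over a closed context vocabulary; a lexicon of multi-token surface
forms (types in the DDI2013 training proportions Drug 63% / Brand 10% /
Group 23% / Drug_n 4%, assigned by largest-remainder quota; `synonymy`
surface forms per normalization ID) is sampled at `entity_rate` per slot.
The default entity rate (0.30, ≈2 entities per sentence of 6–14 tokens)
mirrors the density of the real corpora. Every entity is preceded by a
fixed trigger token and every entity token carries its normalization ID,
so the two labelings are consistent by construction. Two regimes:

* **separable** (`ambiguity_rate = 0`): entity words never occur as
  context, so token identity suffices and a correct implementation can
  approach perfect F1 — the convergence fixture.
* **correlated** (`ambiguity_rate > 0`): entity words also appear as
  plain context words, making entity-hood context-dependent (the trigger
  resolves it) while the normalization ID stays a deterministic function
  of (surface form, type) — the regime in which the two tasks carry
  mutually useful signal.

What the generator does *not* emulate: real drug morphology, annotation
noise, document structure, long-range discourse, class imbalance beyond
type proportions. Passing tests on it demonstrate correctness of the
machinery and the direction of the multitask effect at desk scale, not
clinical-corpus performance.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on one CPU in minutes;
sizes were chosen as the smallest at which each effect is stable:
convergence uses 2000 separable sentences at state size 50 (stopping once
strict F1 ≥ 0.95, typically epoch 5–7); the multitask comparison uses 360
correlated sentences × 5 seeds at state 30; the feedback-gain measurement
uses 200 dense-entity sentences × 5 seeds with a 12-ID vocabulary, where
normalization learns past the all-NIL baseline within 12 epochs. CRF
oracles enumerate all k^n paths for n ≤ 6, k ≤ 5. Gradient checks use
central differences at ε = 10⁻⁶ with relative tolerance 10⁻⁴. Tie-breaks:
Viterbi and all argmax decisions resolve toward the lowest index.
Degenerate inputs: empty sequences are rejected; single-label CRFs have
zero loss; one-character words convolve via symmetric padding.

## Known limitations

* No batching across sentences inside the recurrences (minibatches are
  accumulated sentence by sentence); throughput is desk-scale.
* The biLM is a toy: training it on the task corpus cannot reproduce
  large-scale contextual pretraining; the contextual channel mainly
  serves the architecture contract, and precomputed vectors can be
  substituted.
* DNEN is per-token with a NIL class; mention-level normalization against
  an external terminology (dictionary lookup, candidate generation) is
  out of scope.
* No nested or overlapping entities (rejected at ingestion); no sentence
  splitting of raw documents.
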