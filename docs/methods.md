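# Methods

## The task and the model

`sdpre` classifies the relation between two clinical entity mentions
(problems, treatments, tests) that co-occur in one sentence of a
discharge summary.  Candidate pairs follow the i2b2-2010 schema —
test–problem pairs may be TeCP or TeRP, problem–problem pairs PIP, and
treatment–problem pairs TrCP, TrAP, TrWP, TrNAP or TrIP — and every
candidate may also be None (no relation); in real corpora of this kind
roughly two thirds of candidates are None.

The classifier combines two views of each candidate:

**Sentence-sequence branch.** Every mention is collapsed to a single
placeholder token carrying its semantic type and role: `tar_<type>` for
the two entities under consideration, `ent_<type>` for all others.  Each
token of the masked sentence S = {w1, …, wn} is represented by the
concatenation of its word embedding and two position embeddings — learned
vectors indexed by the token's signed distance to each target (for
"She … tar_treatment … tar_problem" the distances of "She" are −4 and
−8).  A Bi-LSTM reads this sequence; its per-step output is
h(t) = [hf(t), hb(t)].

**Shortest-dependency-path (SDP) branch.** From a dependency parse of
the sentence, the minimal-edge path P = {p1, …, pm} between the two
target tokens is extracted by breadth-first search over the undirected
view of the edge set.  Neighboring path words are merged by a shared
convolutional transform, ConP_i = flatten([P_i; P_{i+1}] · M) with
M ∈ R^{n1×n2}, giving one 2·n2-dimensional local feature per path edge.
Each ConP_i is concatenated with the embedding of that edge's dependency
relation type d_i, and a second Bi-LSTM reads the m−1 steps.

**Classification head.** Both branches are pooled (element-wise max over
steps by default), concatenated, passed through a fully-connected tanh
layer with dropout on its input, and classified with
p(i|s) = softmax(Wo·s + bo).  Training minimizes cross-entropy with
Adam.

Ablation flags reproduce three configurations: sentence-only, +SDP word
sequence, and +SDP word sequence with relation types.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `word_dim` | 100 | word-embedding dimension (n1 of the SDP transform) |
| `position_dim` | 50 | per-target position-embedding dimension |
| `deprel_dim` | 50 | dependency-relation-type embedding dimension |
| `hidden` | 200 | Bi-LSTM hidden units per direction and n2 of the transform |
| `dropout_rate` | 0.5 | dropout on the fully-connected layer's input |
| `max_dist` | 60 | distance range of the position vocabulary |
| `learning_rate` | 1e-5 | Adam step size |
| `batch_size` | 32 | mini-batch size |

The deprel dimension, the FC layer width (set to `hidden`), and the
pooling rule are choices of this package; word/position dimensions, the
hidden size, the optimizer and batch size are the reference regime the
architecture was designed around.  Position and relation-type embeddings
are initialized uniformly in [−0.05, 0.05], out-of-vocabulary word
vectors in [−0.25, 0.25], all seeded.  Distances are stored raw and
bucketed at lookup: {−60…60} individually, with one shared bucket for
|d| > 60.

## Numerical and structural choices

* **Engine.** The network runs on a small in-repo reverse-mode
  automatic-differentiation engine (`sdpre._autodiff`) over float64 numpy
  arrays.  Gradients are exact; the test-suite audits them against
  central finite differences at 1e-4 relative error (with a 1e-6
  absolute floor for entries at the roundoff noise level).
* **Padding.** Variable-length sentences and paths are padded; padding
  is masked out of recurrent updates and pooling, so encodings are
  invariant to batch composition (asserted in tests).
* **SDP ties and failures.** Among equal-length paths (possible only in
  non-tree parses) the lexicographically smallest node sequence is
  returned.  When the two targets are disconnected, the SDP branch
  receives a learned no-path placeholder vector and the sentence branch
  carries the instance.
* **Convolution shape.** Stacking P_i and P_{i+1} row-wise into a 2×n1
  block and right-multiplying by M (n1×n2) yields 2×n2; its row-major
  flattening — the concatenation of P_i·M and P_{i+1}·M — is the step
  feature.
* **Graph projection after masking.** Parses cover the original tokens
  (parse-then-collapse, the default; parses of pre-masked sentences are
  also accepted).  A collapsed span keeps its outgoing edges and exactly
  one incoming edge: the head edge of its *shallowest* token, the span's
  local syntactic root.  This keeps trees trees; attaching at the last
  token instead can create cycles when a span is not a constituent.
* **Direction annotations.** Each SDP step records whether it traverses
  its edge head-ward or dependent-ward; the channel is kept as an
  annotation only and is not fed to the model by default.
* **Evaluation.** Micro P/R/F pools TP/FP/FN over the eight positive
  classes; None is excluded by default (a flag includes it).
  Cross-validation splits by document so no document contributes to both
  training and test material of a fold; pooled metrics come from the
  union of fold predictions.

## The synthetic corpus generator

Real i2b2 data is access-restricted, so all tests and the acceptance
script run on generated corpora that emulate its structure: documents of
8–16-token sentences, 1–5 typed mentions per sentence (multi-token with
probability 0.3, capped so at least two non-entity tokens remain),
random projective dependency trees built by recursive splitting, and
candidate labels drawn from the reference class proportions (about 68 %
None, TeRP/TrAP/PIP dominating the positives).  At most one positive
relation is sampled per sentence.

The syntactic signal is explicit and controllable: each positive pair
gets a class-specific trigger token placed on the tree path between the
targets with probability `sdp_signal_strength` (default 0.8; the retry
loop falls back to a deterministic projective tree routed through a free
token when random trees leave no interior slot), and off the path
otherwise.  Two off-path distractor triggers of other classes are added
to every positive sentence, so a sentence-sequence reader faces
competing cues that the pruned dependency path removes.  This is the
mechanism the SDP branch is supposed to exploit; the generator makes it
true by construction, which is what the ablation checks measure.

What the generator does **not** emulate: clinical vocabulary and word
statistics, parse errors of a real parser, cross-sentence discourse,
assertion/negation phenomena, annotation noise, and document-level label
correlations.  Passing tests therefore demonstrate that the
implementation is correct and that the architecture can exploit
path-localized evidence — not that it reaches any particular accuracy on
real clinical text, which additionally requires the restricted corpus
and domain-trained embeddings.

## Problem sizes used by the checks

Unit and property tests run on corpora of a few hundred instances with
scaled-down dimensions (word 8–16, hidden 6–16).  The ablation check
uses five paired seeds, each with ≈2,000 instances (100 documents × 10
sentences), trigger always on the path, 5-fold document-level
cross-validation, and a toy regime (word 16 / position 8 / hidden 16,
Adam at 0.01, 8 epochs) — sizes chosen so the paired comparison is
decisive while the whole suite stays desk-scale.  The overfitting check
trains the toy model on 20 instances for 200 epochs.  These reduced
dimensions are the package's own test conditions; the model defaults
remain the full-scale regime above.

## Known limitations

* No attention, no pretrained transformer encoders, no multi-task heads.
* Relation direction beyond what entity types imply is not modeled.
* The pure-numpy engine is single-threaded and unsuited to corpus-scale
  training at the full 100/50/200 dimensions; it is meant for method
  study and desk-scale experiments.
* The optional live-parser hook accepts any callable producing a
  dependency graph from tokens, but no parser ships with the package;
  CoNLL-U files are the supported input.
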