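# sdpre — shortest-dependency-path relation extraction for clinical text

`sdpre` is a library and command-line tool for classifying relations
between clinical entities — medical problems, treatments and tests —
that co-occur in a sentence of a clinical note.  It targets the
i2b2-2010 relation schema: eight positive classes (TeCP, TeRP, PIP,
TrCP, TrAP, TrWP, TrNAP, TrIP) plus None for the many unrelated
candidate pairs.  It is written for NLP researchers and engineers who
want a transparent, fully-tested reference implementation of a
syntax-aware neural relation classifier that runs anywhere numpy runs.

## The model

Two branches encode each candidate pair:

* **Sentence sequence.**  Entity mentions are collapsed to typed
  placeholders (`tar_treatment`, `ent_treatment`, `tar_problem` … —
  `tar_` marks the two targets).  Each token of the masked sentence
  S = {w1, …, wn} is the concatenation of its word embedding and two
  position embeddings indexed by the signed distance to each target.  A
  Bi-LSTM reads the sequence; per-step output h(t) = [hf(t), hb(t)].
* **Shortest dependency path (SDP).**  From a dependency parse
  (CoNLL-U), the minimal path P = {p1, …, pm} between the targets is
  extracted by BFS.  Neighboring path words are merged by a shared
  convolution, ConP_i = flatten([P_i; P_{i+1}] · M), concatenated with a
  dependency-relation-type embedding d_i, and read by a second Bi-LSTM.
* **Head.**  Pooled branch vectors are concatenated, passed through a
  fully-connected layer with dropout, and classified with
  p(i|s) = softmax(Wo·s + bo); training is cross-entropy with Adam.

Evaluation is micro-averaged P/R/F over the positive classes with
document-level k-fold cross-validation.  Because the real i2b2 corpus is
access-restricted, the package ships a synthetic-corpus generator that
emulates its structure (typed mentions, class imbalance, dependency
trees) with a controllable amount of signal planted on the dependency
path, so the whole pipeline is testable without any download.

## Worked example

```python
from sdpre import example_sentence, prepare_instances

sentence, graph = example_sentence()
inst = prepare_instances([sentence], [graph])[0]
print("masked :", " ".join(inst.masked_tokens))
print("pos1   :", inst.pos1)
print("pos2   :", inst.pos2)
print("sdp    :", inst.sdp.arrow_notation(inst.masked_tokens))
print("label  :", inst.label.value)
```

prints

```
masked : She was maintained on tar_treatment and ent_treatment for tar_problem
pos1   : [-4, -3, -2, -1, 0, 1, 2, 3, 4]
pos2   : [-8, -7, -6, -5, -4, -3, -2, -1, 0]
sdp    : tar_treatment –nmod→ maintained –nmod→ tar_problem
label  : TrAP
```

The sentence "She was maintained on an epidural and pca for pain
control" has three mentions; with *an epidural* and *pain control* as
the target pair, both collapse to `tar_` tokens and *pca* to `ent_`.
"She" sits 4 tokens left of the first target and 8 left of the second —
those signed distances index the position embeddings.  The dependency
path prunes the sentence to `tar_treatment –nmod→ maintained –nmod→
tar_problem`: the word "maintained" and the two nmod relations are
exactly the evidence the SDP branch feeds the classifier, here for a
TrAP (treatment administered for problem) relation.

### Pipeline from the shell

```bash
sdpre run config.yaml
```

with a toy configuration (synthetic corpus of 60 documents, trigger
always on the dependency path, scaled-down dimensions, 5-fold CV over
three feature configurations) prints a report in the usual ablation
layout:

```
Features                                     P (%)   R (%)   F (%)   Δ (%)
Sentence Sequence only                        0.00    0.00    0.00    0.00
+SDP (Word Sequence)                         42.19   25.00   31.40   31.40
+SDP (Word Sequence + Relation Type)         44.12   27.78   34.09   34.09
pipeline complete; manifest with 5 artifacts written
```

On this corpus the class label is recoverable only from a trigger word
on the dependency path, surrounded by off-path distractors — so the
sentence-only model fails while both SDP configurations recover a large
share of the relations, and relation-type embeddings add a further gain.
Individual stages are available as `sdpre simulate / prepare / train /
evaluate / crossval`; every run writes a manifest tying artifacts to the
config hash and seed.

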