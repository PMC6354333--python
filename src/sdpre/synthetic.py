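"""Self-contained synthetic corpora for developing and testing the pipeline.

The real i2b2-2010 relation corpus is access-restricted, so this module
generates toy corpora with the same *shape*: documents of pre-tokenized
sentences, 1–5 typed entity mentions per sentence, intra-sentence
candidate pairs with eight positive relation classes plus a dominant
None class, and a projective dependency tree per sentence.

The syntactic signal is controllable: each positively-labeled pair gets a
class-specific trigger token that is placed *on* the dependency-tree path
between the two entities with probability ``sdp_signal_strength`` and off
the path otherwise.  Positive sentences additionally carry off-path
distractor triggers of other classes, so a model that prunes the sentence
down to the dependency path has a genuine advantage over one that reads
the whole sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (AnnotatedSentence, EmbeddingTable, EntityMention,
                        EntityType, RelationLabel, write_conllu,
                        write_i2b2_corpus, write_word2vec_text)
from .depgraph import DependencyGraph
from .preprocess import DEFAULT_SCHEMA, PairSchema

#: Class frequencies of the reference corpus (counts out of 29,282
#: candidate instances), normalized to probabilities.
REFERENCE_CLASS_COUNTS: dict[RelationLabel, int] = {
    RelationLabel.TeCP: 504,
    RelationLabel.TeRP: 3052,
    RelationLabel.PIP: 2203,
    RelationLabel.TrCP: 526,
    RelationLabel.TrAP: 2617,
    RelationLabel.TrWP: 133,
    RelationLabel.TrNAP: 174,
    RelationLabel.TrIP: 203,
    RelationLabel.NONE: 19870,
}

_DEPRELS = ("nsubj", "obj", "nmod", "amod", "advmod", "conj", "case", "det")
_ENTITY_TYPES = (EntityType.PROBLEM, EntityType.TREATMENT, EntityType.TEST)
_TYPE_WEIGHTS = (0.45, 0.30, 0.25)


def default_class_proportions() -> dict[RelationLabel, float]:
    total = sum(REFERENCE_CLASS_COUNTS.values())
    return {k: v / total for k, v in REFERENCE_CLASS_COUNTS.items()}


@dataclass
class SynthConfig:
    """Conditions of the generated corpus.

    ``sdp_signal_strength`` is the probability that a positive pair's
    trigger token lies on the dependency path between the targets;
    ``n_distractors`` off-path triggers of other classes are added to
    every positive sentence.
    """

    n_documents: int = 20
    sentences_per_doc: int = 10
    vocab_size: int = 300
    entity_density: float = 2.5  # mean mentions per sentence, clipped to 1..5
    class_proportions: dict[RelationLabel, float] = field(
        default_factory=default_class_proportions)
    sdp_signal_strength: float = 0.8
    n_distractors: int = 2
    multi_token_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        if not 0.0 <= self.sdp_signal_strength <= 1.0:
            raise ValueError("sdp_signal_strength must be in [0, 1]")


def sample_label(rng: np.random.Generator,
                 proportions: dict[RelationLabel, float],
                 admissible: frozenset[RelationLabel] | None = None) -> RelationLabel:
    """Draw a label from ``proportions``, optionally renormalized to an
    admissible subset."""
    labels = [l for l in proportions if admissible is None or l in admissible]
    probs = np.array([proportions[l] for l in labels])
    probs = probs / probs.sum()
    return labels[int(rng.choice(len(labels), p=probs))]


def random_projective_tree(n: int, rng: np.random.Generator) -> list[int]:
    """Random projective dependency tree as a head list (root head = -1).

    Built by recursive splitting: a segment's head is drawn uniformly,
    and the sub-segments to its left and right attach their own
    recursively-drawn heads to it.  The result is connected, acyclic and
    single-rooted for every seed.
    """
    heads = [-1] * n

    def build(lo: int, hi: int) -> int | None:
        if lo > hi:
            return None
        r = int(rng.integers(lo, hi + 1))
        left = build(lo, r - 1)
        right = build(r + 1, hi)
        if left is not None:
            heads[left] = r
        if right is not None:
            heads[right] = r
        return r

    build(0, n - 1)
    return heads


def heads_to_graph(heads: list[int], rng: np.random.Generator) -> DependencyGraph:
    edges = set()
    root = 0
    for dep, head in enumerate(heads):
        if head < 0:
            root = dep
        else:
            edges.add((head, dep, _DEPRELS[int(rng.integers(len(_DEPRELS)))]))
    return DependencyGraph(n_tokens=len(heads), edges=frozenset(edges), root=root)


def _span_head(heads: list[int], start: int, end: int) -> int:
    """The shallowest token of a span — where the collapsed mention attaches."""
    def depth(x: int) -> int:
        d = 0
        while heads[x] >= 0:
            x = heads[x]
            d += 1
        return d
    return min(range(start, end + 1), key=lambda o: (depth(o), -o))


def _routed_tree(n: int, a: int, b: int, f: int) -> list[int]:
    """A deterministic projective tree whose a–b path is exactly a→f→b.

    ``f`` becomes the root with ``a`` and ``b`` as direct children; every
    other token chains inward to the nearest of the three anchors, which
    keeps all edges nested.
    """
    lo, mid, hi = sorted((a, b, f))
    heads = [0] * n
    heads[f] = -1
    heads[a] = heads[b] = f
    for i in range(n):
        if i in (a, b, f):
            continue
        if i < lo:
            heads[i] = i + 1  # chain rightward into lo
        elif i > hi:
            heads[i] = i - 1  # chain leftward into hi
        elif lo < i < mid:
            heads[i] = i - 1  # chain into lo, nested inside the lo–f edge
        else:
            heads[i] = i + 1  # chain into hi, nested inside the f–hi edge
    return heads


def _tree_path(heads: list[int], a: int, b: int) -> list[int]:
    """Node sequence of the unique tree path from a to b."""
    def ancestors(x: int) -> list[int]:
        chain = [x]
        while heads[x] >= 0:
            x = heads[x]
            chain.append(x)
        return chain

    anc_a, anc_b = ancestors(a), ancestors(b)
    set_a = set(anc_a)
    lca = next(x for x in anc_b if x in set_a)
    up = anc_a[:anc_a.index(lca) + 1]
    down = anc_b[:anc_b.index(lca)][::-1]
    return up + down


def _sample_mentions(n_tokens: int, rng: np.random.Generator,
                     config: SynthConfig, doc_id: str,
                     sent_idx: int) -> list[EntityMention]:
    k = int(np.clip(rng.poisson(config.entity_density), 1, 5))
    spans: list[tuple[int, int]] = []
    used = 0
    for _ in range(40):
        if len(spans) == k:
            break
        length = 2 if rng.random() < config.multi_token_prob else 1
        if used + length > n_tokens - 2:  # keep free tokens for triggers
            continue
        start = int(rng.integers(0, n_tokens - length + 1))
        span = (start, start + length - 1)
        if all(span[1] < s or e < span[0] for s, e in spans):
            spans.append(span)
            used += length
    mentions = []
    for start, end in sorted(spans):
        etype = _ENTITY_TYPES[int(rng.choice(len(_ENTITY_TYPES), p=_TYPE_WEIGHTS))]
        mentions.append(EntityMention(
            id=f"{doc_id}:{sent_idx}:{start}-{end}",
            sentence_index=sent_idx,
            token_start=start,
            token_end=end,
            entity_type=etype,
            surface="",  # filled in once tokens are final
        ))
    return mentions


def _generate_sentence(doc_id: str, sent_idx: int, rng: np.random.Generator,
                       config: SynthConfig, schema: PairSchema
                       ) -> tuple[AnnotatedSentence, DependencyGraph]:
    n = int(rng.integers(8, 17))
    tokens = [f"w{int(rng.integers(config.vocab_size)):04d}" for _ in range(n)]
    mentions = _sample_mentions(n, rng, config, doc_id, sent_idx)
    entity_tokens = {i for m in mentions for i in range(m.token_start, m.token_end + 1)}

    # candidate pairs in random order; at most one positive per sentence so
    # the on-path trigger slot is unambiguous
    pairs = []
    for i, m1 in enumerate(mentions):
        for m2 in mentions[i + 1:]:
            if schema.admissible(m1.entity_type, m2.entity_type) is not None:
                pairs.append((m1, m2))
    relations: list[tuple[str, str, RelationLabel]] = []
    positive: tuple[EntityMention, EntityMention, RelationLabel] | None = None
    for pi in rng.permutation(len(pairs)):
        m1, m2 = pairs[int(pi)]
        admissible = schema.admissible(m1.entity_type, m2.entity_type)
        label = sample_label(rng, config.class_proportions, admissible)
        if label is not RelationLabel.NONE:
            positive = (m1, m2, label)
            relations.append((m1.id, m2.id, label))
            break  # remaining pairs stay None

    # tree: for a positive pair, retry until the path between the entity
    # head tokens has an interior non-entity token to carry the trigger
    heads = random_projective_tree(n, rng)
    path_interior: list[int] = []
    if positive is not None:
        m1, m2, _ = positive
        for _ in range(50):
            path = _tree_path(heads,
                              _span_head(heads, *m1.span),
                              _span_head(heads, *m2.span))
            path_interior = [p for p in path[1:-1] if p not in entity_tokens]
            if path_interior:
                break
            heads = random_projective_tree(n, rng)
        else:
            # deterministic fallback: route the path through a free token
            free = sorted(set(range(n)) - entity_tokens)
            a, b = m1.token_end, m2.token_end
            between = [x for x in free if min(a, b) < x < max(a, b)]
            f = between[0] if between else free[0]
            heads = _routed_tree(n, a, b, f)
            path = _tree_path(heads,
                              _span_head(heads, *m1.span),
                              _span_head(heads, *m2.span))
            path_interior = [p for p in path[1:-1] if p not in entity_tokens]
            assert path_interior, "routed tree must expose a free path slot"
    graph = heads_to_graph(heads, rng)

    if positive is not None:
        m1, m2, label = positive
        path = set(_tree_path(heads,
                              _span_head(heads, *m1.span),
                              _span_head(heads, *m2.span)))
        on_path = rng.random() < config.sdp_signal_strength
        if on_path:
            slot = path_interior[int(rng.integers(len(path_interior)))]
        else:
            off = [i for i in range(n)
                   if i not in path and i not in entity_tokens]
            slot = off[int(rng.integers(len(off)))] if off else path_interior[0]
        tokens[slot] = f"trig_{label.value}"
        # off-path distractor triggers of other classes
        other = [l for l in RelationLabel
                 if l not in (label, RelationLabel.NONE)]
        free = [i for i in range(n)
                if i not in path and i not in entity_tokens and i != slot]
        rng.shuffle(free)
        for d in range(min(config.n_distractors, len(free))):
            distractor = other[int(rng.integers(len(other)))]
            tokens[free[d]] = f"trig_{distractor.value}"

    mentions = [EntityMention(m.id, m.sentence_index, m.token_start, m.token_end,
                              m.entity_type,
                              " ".join(tokens[m.token_start:m.token_end + 1]))
                for m in mentions]
    sentence = AnnotatedSentence(doc_id=doc_id, sentence_index=sent_idx,
                                 tokens=tokens, mentions=mentions,
                                 relations=relations)
    return sentence, graph


def generate_corpus(config: SynthConfig, schema: PairSchema = DEFAULT_SCHEMA
                    ) -> tuple[list[AnnotatedSentence], list[DependencyGraph]]:
    """Generate a corpus; deterministic under ``config.seed``.

    Returns sentences and their dependency graphs, aligned by position.
    """
    rng = np.random.default_rng(config.seed)
    sentences, graphs = [], []
    for d in range(config.n_documents):
        doc_id = f"doc{d:03d}"
        for s in range(config.sentences_per_doc):
            sentence, graph = _generate_sentence(doc_id, s, rng, config, schema)
            sentences.append(sentence)
            graphs.append(graph)
    return sentences, graphs


# ---------------------------------------------------------------------------
# The worked example sentence and its parse
# ---------------------------------------------------------------------------

def example_sentence() -> tuple[AnnotatedSentence, DependencyGraph]:
    """The canonical worked example with its two-nmod parse.

    "She was maintained on an epidural and pca for pain control", with
    mentions [an epidural]/treatment, [pca]/treatment and
    [pain control]/problem, and a tree in which "maintained" heads both
    "epidural" and "control" via nmod — so the dependency path between
    the two target entities is epidural –nmod→ maintained –nmod→ control.
    """
    tokens = "She was maintained on an epidural and pca for pain control".split()
    doc_id = "example"
    mentions = [
        EntityMention(f"{doc_id}:0:4-5", 0, 4, 5, EntityType.TREATMENT, "an epidural"),
        EntityMention(f"{doc_id}:0:7-7", 0, 7, 7, EntityType.TREATMENT, "pca"),
        EntityMention(f"{doc_id}:0:9-10", 0, 9, 10, EntityType.PROBLEM, "pain control"),
    ]
    relations = [(mentions[0].id, mentions[2].id, RelationLabel.TrAP)]
    sentence = AnnotatedSentence(doc_id, 0, tokens, mentions, relations)
    edges = frozenset({
        (2, 0, "nsubj"),     # She <- maintained
        (2, 1, "aux"),       # was <- maintained
        (5, 3, "case"),      # on <- epidural
        (5, 4, "det"),       # an <- epidural
        (2, 5, "nmod"),      # epidural <- maintained
        (7, 6, "cc"),        # and <- pca
        (5, 7, "conj"),      # pca <- epidural
        (10, 8, "case"),     # for <- control
        (10, 9, "compound"), # pain <- control
        (2, 10, "nmod"),     # control <- maintained
    })
    graph = DependencyGraph(n_tokens=11, edges=edges, root=2)
    return sentence, graph


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def write_fixture_suite(out_dir: str | Path, config: SynthConfig | None = None,
                        embedding_dim: int = 10,
                        include_example: bool = True) -> dict[str, Path]:
    """Write a small fixed-seed corpus to disk in every supported format.

    Emits ``txt/ concepts/ relations/`` in the i2b2 dialect, one CoNLL-U
    file of parses, and a toy word2vec text file.  The corpus always
    includes the worked example sentence with its two-nmod parse.  Output
    is byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    if config is None:
        config = SynthConfig(n_documents=3, sentences_per_doc=4, seed=7)
    sentences, graphs = generate_corpus(config)
    if include_example:
        ex_sentence, ex_graph = example_sentence()
        sentences = sentences + [ex_sentence]
        graphs = graphs + [ex_graph]

    paths = {
        "text": out_dir / "txt",
        "concepts": out_dir / "concepts",
        "relations": out_dir / "relations",
        "parses": out_dir / "parses.conllu",
        "embeddings": out_dir / "embeddings.txt",
    }
    write_i2b2_corpus(sentences, paths["text"], paths["concepts"], paths["relations"])
    write_conllu(graphs, [s.tokens for s in sentences], paths["parses"])

    vocab_tokens = sorted({t for s in sentences for t in s.tokens})
    rng = np.random.default_rng(config.seed + 1)
    table = EmbeddingTable(
        vocabulary={t: i for i, t in enumerate(vocab_tokens)},
        vectors=np.round(rng.uniform(-0.5, 0.5, size=(len(vocab_tokens), embedding_dim)), 6),
        dimension=embedding_dim,
    )
    write_word2vec_text(table, paths["embeddings"])
    return paths
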