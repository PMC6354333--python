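"""From annotated sentences to classifier-ready relation instances.

For every intra-sentence candidate entity pair whose types admit a
relation, the sentence is converted the way the classifier sees it:

* each mention's token span collapses to one placeholder token encoding
  its semantic type and role — ``tar_<type>`` for the two target entities,
  ``ent_<type>`` for every other mention ("She was maintained on
  tar_treatment and ent_treatment for tar_problem");
* every token gets two signed relative distances, one to each target
  (e.g. "She" is at −4 from the first target and −8 from the second);
* the shortest dependency path between the two targets is extracted from
  the parse, re-indexed onto the masked token sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .corpus_io import (AnnotatedSentence, ConfigError, EntityMention,
                        EntityType, IntegrityError, RelationLabel)
from .depgraph import DependencyGraph, SDPath, shortest_dependency_path

logger = logging.getLogger(__name__)

INSTANCE_SCHEMA_VERSION = 1

TARGET_PREFIX = "tar_"
NONTARGET_PREFIX = "ent_"
_MASK_TOKENS = {f"{p}{t.value}" for p in (TARGET_PREFIX, NONTARGET_PREFIX) for t in EntityType}


@dataclass(frozen=True)
class PairSchema:
    """Which unordered entity-type pairs admit which relation labels."""

    allowed_type_pairs: dict[frozenset[EntityType], frozenset[RelationLabel]]

    def admissible(self, a: EntityType, b: EntityType) -> frozenset[RelationLabel] | None:
        return self.allowed_type_pairs.get(frozenset((a, b)))


#: The i2b2-2010 task schema: test–problem, problem–problem and
#: treatment–problem pairs are candidates; every candidate may be None.
DEFAULT_SCHEMA = PairSchema({
    frozenset((EntityType.TEST, EntityType.PROBLEM)):
        frozenset((RelationLabel.TeCP, RelationLabel.TeRP, RelationLabel.NONE)),
    frozenset((EntityType.PROBLEM,)):
        frozenset((RelationLabel.PIP, RelationLabel.NONE)),
    frozenset((EntityType.TREATMENT, EntityType.PROBLEM)):
        frozenset((RelationLabel.TrCP, RelationLabel.TrAP, RelationLabel.TrWP,
                   RelationLabel.TrNAP, RelationLabel.TrIP, RelationLabel.NONE)),
})


@dataclass
class RelationInstance:
    """One masked candidate pair with position features and (optionally) its SDP."""

    doc_id: str
    sentence_index: int
    instance_id: str
    masked_tokens: list[str]
    e1_index: int
    e2_index: int
    pos1: list[int]
    pos2: list[int]
    label: RelationLabel
    sdp: SDPath | None = None

    def __post_init__(self) -> None:
        n = len(self.masked_tokens)
        if not (len(self.pos1) == len(self.pos2) == n):
            raise ValueError("position sequences must cover every masked token")
        if not self.masked_tokens[self.e1_index].startswith(TARGET_PREFIX):
            raise ValueError("e1_index does not point at a tar_ token")
        if not self.masked_tokens[self.e2_index].startswith(TARGET_PREFIX):
            raise ValueError("e2_index does not point at a tar_ token")
        if self.pos1[self.e1_index] != 0 or self.pos2[self.e2_index] != 0:
            raise ValueError("distance of a target to itself must be 0")

    @property
    def sdp_tokens(self) -> list[str] | None:
        if self.sdp is None:
            return None
        return [self.masked_tokens[i] for i in self.sdp.nodes]


def generate_candidates(
    sentence: AnnotatedSentence, schema: PairSchema = DEFAULT_SCHEMA
) -> list[tuple[EntityMention, EntityMention, RelationLabel]]:
    """All unordered in-sentence mention pairs admitted by the schema.

    ``(e1, e2)`` follows sentence order.  The gold label is attached when
    annotated, else ``None`` — unrelated candidates dominate real corpora.
    """
    gold: dict[frozenset[str], RelationLabel] = {}
    for a, b, label in sentence.relations:
        gold[frozenset((a, b))] = label

    mentions = sorted(sentence.mentions, key=lambda m: (m.span, m.id))
    out = []
    for i, m1 in enumerate(mentions):
        for m2 in mentions[i + 1:]:
            admissible = schema.admissible(m1.entity_type, m2.entity_type)
            if admissible is None:
                continue
            label = gold.get(frozenset((m1.id, m2.id)), RelationLabel.NONE)
            if label not in admissible:
                raise IntegrityError(
                    f"{sentence.doc_id}:{sentence.sentence_index}: gold label "
                    f"{label.value} not admissible for types "
                    f"({m1.entity_type.value}, {m2.entity_type.value})"
                )
            out.append((m1, m2, label))
    return out


def _resolve_overlaps(mentions: list[EntityMention],
                      where: str) -> list[EntityMention]:
    """Overlapping spans: the longer one wins, losers dropped with a warning."""
    kept: list[EntityMention] = []
    for m in sorted(mentions, key=lambda m: (-(m.token_end - m.token_start), m.token_start, m.id)):
        if any(m.token_start <= k.token_end and k.token_start <= m.token_end for k in kept):
            logger.warning("%s: mention %s overlaps a longer mention, dropped", where, m.id)
            continue
        kept.append(m)
    return sorted(kept, key=lambda m: m.token_start)


def mask_entities(
    sentence: AnnotatedSentence, target_pair: tuple[EntityMention, EntityMention]
) -> tuple[list[str], int, int, dict[int, int]]:
    """Collapse every mention to a single typed placeholder token.

    Returns the masked token sequence, the indices of the two ``tar_``
    tokens, and the old-token→new-token index map (used to project the
    dependency parse onto the masked sentence).
    """
    t1, t2 = target_pair
    ids = {m.id for m in sentence.mentions}
    if t1.id not in ids or t2.id not in ids:
        raise ValueError("target mentions must belong to the sentence")
    where = f"{sentence.doc_id}:{sentence.sentence_index}"
    kept = _resolve_overlaps(sentence.mentions, where)
    target_ids = {t1.id, t2.id}

    masked: list[str] = []
    index_map: dict[int, int] = {}
    spans = {m.token_start: m for m in kept}
    i = 0
    while i < len(sentence.tokens):
        m = spans.get(i)
        if m is not None:
            prefix = TARGET_PREFIX if m.id in target_ids else NONTARGET_PREFIX
            new_idx = len(masked)
            masked.append(f"{prefix}{m.entity_type.value}")
            for j in range(m.token_start, m.token_end + 1):
                index_map[j] = new_idx
            i = m.token_end + 1
        else:
            index_map[i] = len(masked)
            masked.append(sentence.tokens[i])
            i += 1

    e1 = index_map[t1.token_start]
    e2 = index_map[t2.token_start]
    if e1 == e2:
        raise IntegrityError(f"{where}: the two targets collapse to one token")
    return masked, e1, e2, index_map


def masked_sentence(
    sentence: AnnotatedSentence, target_pair: tuple[EntityMention, EntityMention]
) -> tuple[AnnotatedSentence, tuple[EntityMention, EntityMention]]:
    """The masked sentence as a new :class:`AnnotatedSentence` (masking is
    idempotent: re-masking the result is a no-op)."""
    masked, e1, e2, index_map = mask_entities(sentence, target_pair)
    new_mentions = []
    new_targets = {}
    for m in sentence.mentions:
        if m.token_start not in index_map:
            continue
        new_idx = index_map[m.token_start]
        if not masked[new_idx] in _MASK_TOKENS:
            continue  # dropped by overlap resolution
        nm = EntityMention(m.id, sentence.sentence_index, new_idx, new_idx,
                           m.entity_type, masked[new_idx])
        if new_idx in (e1, e2) and m.id in (target_pair[0].id, target_pair[1].id):
            new_targets[m.id] = nm
        if nm.span not in {x.span for x in new_mentions}:
            new_mentions.append(nm)
    out = AnnotatedSentence(sentence.doc_id, sentence.sentence_index, masked,
                            new_mentions, list(sentence.relations))
    return out, (new_targets[target_pair[0].id], new_targets[target_pair[1].id])


def position_features(masked_tokens: list[str], e1_index: int,
                      e2_index: int) -> tuple[list[int], list[int]]:
    """Signed relative distances of every token to each target.

    ``pos1[i] = i − e1_index`` and ``pos2[i] = i − e2_index``; distances are
    stored raw and bucketed only at embedding lookup.
    """
    n = len(masked_tokens)
    for idx in (e1_index, e2_index):
        if not 0 <= idx < n:
            raise ValueError(f"target index {idx} outside sentence")
    pos1 = [i - e1_index for i in range(n)]
    pos2 = [i - e2_index for i in range(n)]
    return pos1, pos2


def project_graph(graph: DependencyGraph, index_map: dict[int, int],
                  n_masked: int) -> DependencyGraph:
    """Contract the parse onto the masked tokens.

    All tokens of a collapsed span merge into one node.  The merged node
    keeps the span's outgoing edges (children of any span token) and
    exactly one incoming edge: the head edge of the span's shallowest
    token — the span's local syntactic root, which for constituent-like
    mentions is the head word ("epidural" in "an epidural").  A tree
    therefore stays a tree: every other node keeps its single head, and
    the merged node's parent chain cannot re-enter the span because no
    span token is shallower than its designated head.
    """
    if graph.n_tokens != len(index_map):
        raise IntegrityError(
            f"parse has {graph.n_tokens} tokens but sentence has {len(index_map)}"
        )
    head_of = {d: h for h, d, _rel in graph.edges}

    def depth(node: int) -> int:
        d, seen = 0, set()
        while node in head_of and node not in seen:
            seen.add(node)
            node = head_of[node]
            d += 1
        return d

    members: dict[int, list[int]] = {}
    for old, new in index_map.items():
        members.setdefault(new, []).append(old)
    designated = {new: min(olds, key=lambda o: (depth(o), -o))
                  for new, olds in members.items()}
    edges = set()
    for h, d, rel in graph.edges:
        nh, nd = index_map[h], index_map[d]
        if nh == nd:
            continue  # internal to a span
        if d != designated[nd]:
            logger.debug("dropping head edge of non-head span token %d", d)
            continue
        edges.add((nh, nd, rel))
    return DependencyGraph(n_tokens=n_masked, edges=frozenset(edges),
                           root=index_map[graph.root])


def prepare_instances(
    sentences: list[AnnotatedSentence],
    graphs: list[DependencyGraph] | None,
    schema: PairSchema = DEFAULT_SCHEMA,
    graphs_are_masked: bool = False,
    parser: "Callable[[list[str]], DependencyGraph] | None" = None,
) -> list[RelationInstance]:
    """Build every candidate instance for a parsed corpus.

    ``graphs`` aligns with ``sentences`` by position; pass ``None`` to build
    sentence-only instances (no SDP).  By default parses cover the original
    tokens and are contracted after masking (parse-then-collapse); set
    ``graphs_are_masked`` when parses were produced on masked sentences.
    When ``graphs`` is ``None`` a live ``parser`` callable (tokens → graph)
    may supply parses instead; none ships with the package.
    """
    if graphs is not None and len(graphs) != len(sentences):
        raise IntegrityError("need exactly one dependency graph per sentence")
    instances: list[RelationInstance] = []
    for si, sentence in enumerate(sentences):
        if graphs is not None:
            graph = graphs[si]
        elif parser is not None:
            graph = parser(sentence.tokens)
        else:
            graph = None
        for m1, m2, label in generate_candidates(sentence, schema):
            masked, e1, e2, index_map = mask_entities(sentence, (m1, m2))
            pos1, pos2 = position_features(masked, e1, e2)
            sdp = None
            if graph is not None:
                g = graph if graphs_are_masked else project_graph(graph, index_map, len(masked))
                sdp = shortest_dependency_path(g, e1, e2)
                if sdp is None:
                    logger.warning(
                        "%s:%d: no dependency path between targets, "
                        "falling back to sentence features",
                        sentence.doc_id, sentence.sentence_index,
                    )
            instances.append(RelationInstance(
                doc_id=sentence.doc_id,
                sentence_index=sentence.sentence_index,
                instance_id=(f"{sentence.doc_id}:{sentence.sentence_index}:"
                             f"{m1.token_start}-{m1.token_end}_{m2.token_start}-{m2.token_end}"),
                masked_tokens=masked,
                e1_index=e1,
                e2_index=e2,
                pos1=pos1,
                pos2=pos2,
                label=label,
                sdp=sdp,
            ))
    return instances


# ---------------------------------------------------------------------------
# JSON-lines (de)serialization of prepared instances
# ---------------------------------------------------------------------------

def save_instances(instances: list[RelationInstance], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(json.dumps({"schema_version": INSTANCE_SCHEMA_VERSION}) + "\n")
        for inst in instances:
            rec = {
                "doc_id": inst.doc_id,
                "sentence_index": inst.sentence_index,
                "instance_id": inst.instance_id,
                "masked_tokens": inst.masked_tokens,
                "e1_index": inst.e1_index,
                "e2_index": inst.e2_index,
                "label": inst.label.value,
            }
            if inst.sdp is not None:
                rec["sdp"] = {
                    "nodes": list(inst.sdp.nodes),
                    "relations": list(inst.sdp.relations),
                    "directions": list(inst.sdp.directions),
                }
            fh.write(json.dumps(rec) + "\n")


def load_instances(path: str | Path) -> list[RelationInstance]:
    instances = []
    with Path(path).open() as fh:
        header = json.loads(fh.readline())
        if header.get("schema_version") != INSTANCE_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported instance schema version "
                f"{header.get('schema_version')!r}, expected {INSTANCE_SCHEMA_VERSION}"
            )
        for line in fh:
            rec = json.loads(line)
            sdp = None
            if "sdp" in rec:
                sdp = SDPath(tuple(rec["sdp"]["nodes"]),
                             tuple(rec["sdp"]["relations"]),
                             tuple(rec["sdp"]["directions"]))
            pos1, pos2 = position_features(rec["masked_tokens"], rec["e1_index"], rec["e2_index"])
            instances.append(RelationInstance(
                doc_id=rec["doc_id"],
                sentence_index=rec["sentence_index"],
                instance_id=rec["instance_id"],
                masked_tokens=rec["masked_tokens"],
                e1_index=rec["e1_index"],
                e2_index=rec["e2_index"],
                pos1=pos1,
                pos2=pos2,
                label=RelationLabel(rec["label"]),
                sdp=sdp,
            ))
    return instances
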