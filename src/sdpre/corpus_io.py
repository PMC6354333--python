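"""Readers and writers for the corpus formats consumed by the pipeline.

Three formats are supported:

* the i2b2-2010 concept/relation annotation dialect: per-document plain
  text (one pre-tokenized sentence per line) plus ``.con`` / ``.rel``
  annotation files with 1-based ``line:token`` coordinates,
* CoNLL-U dependency parses (10 tab-separated columns, ``HEAD`` 0 = root),
* word2vec text embeddings (optional ``V D`` header, one token + floats
  per line).

All coordinates are converted at this boundary to the internal convention:
0-based token-level inclusive spans within a 0-based sentence index.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depgraph import DependencyGraph

logger = logging.getLogger(__name__)


class CorpusParseError(ValueError):
    """A malformed annotation or parse line; message names file and line."""


class IntegrityError(ValueError):
    """Annotations that are individually well-formed but mutually inconsistent."""


class ConfigError(ValueError):
    """Inputs that contradict the declared configuration (e.g. embedding dim)."""


class EntityType(str, enum.Enum):
    PROBLEM = "problem"
    TREATMENT = "treatment"
    TEST = "test"


class RelationLabel(str, enum.Enum):
    """The eight i2b2-2010 relation classes plus None (no relation)."""

    TeCP = "TeCP"
    TeRP = "TeRP"
    PIP = "PIP"
    TrCP = "TrCP"
    TrAP = "TrAP"
    TrWP = "TrWP"
    TrNAP = "TrNAP"
    TrIP = "TrIP"
    NONE = "None"


# Fixed label order used for class indices, confusion matrices, reports.
LABEL_ORDER: tuple[RelationLabel, ...] = tuple(RelationLabel)
POSITIVE_LABELS: frozenset[RelationLabel] = frozenset(
    l for l in RelationLabel if l is not RelationLabel.NONE
)


@dataclass(frozen=True)
class EntityMention:
    """A typed entity span, 0-based inclusive token offsets within a sentence."""

    id: str
    sentence_index: int
    token_start: int
    token_end: int
    entity_type: EntityType
    surface: str

    def __post_init__(self) -> None:
        if self.token_start > self.token_end:
            raise ValueError(f"mention {self.id}: start > end")
        if self.token_start < 0:
            raise ValueError(f"mention {self.id}: negative offset")

    @property
    def span(self) -> tuple[int, int]:
        return (self.token_start, self.token_end)


@dataclass
class AnnotatedSentence:
    """One sentence with its typed mentions and gold intra-sentence relations."""

    doc_id: str
    sentence_index: int
    tokens: list[str]
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[tuple[str, str, RelationLabel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {m.id for m in self.mentions}
        for m in self.mentions:
            if m.token_end >= len(self.tokens):
                raise ValueError(
                    f"{self.doc_id}:{self.sentence_index}: mention {m.id} "
                    f"ends at {m.token_end} beyond sentence length {len(self.tokens)}"
                )
        for a, b, _lab in self.relations:
            if a not in ids or b not in ids:
                raise IntegrityError(
                    f"{self.doc_id}:{self.sentence_index}: relation references "
                    f"unknown mention ({a}, {b})"
                )

    def mention_by_id(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise KeyError(mention_id)


# ---------------------------------------------------------------------------
# i2b2-2010 annotation dialect
# ---------------------------------------------------------------------------

_CONCEPT_RE = re.compile(
    r'^c="(?P<text>[^"]*)" (?P<l1>\d+):(?P<t1>\d+) (?P<l2>\d+):(?P<t2>\d+)'
    r'\|\|t="(?P<type>[^"]+)"\s*$'
)
_SPAN_RE = re.compile(r'^c="(?P<text>[^"]*)" (?P<l1>\d+):(?P<t1>\d+) (?P<l2>\d+):(?P<t2>\d+)$')
_REL_RE = re.compile(r'^(?P<c1>c=".*?" \d+:\d+ \d+:\d+)\|\|r="(?P<rel>[^"]+)"\|\|(?P<c2>c=".*?" \d+:\d+ \d+:\d+)\s*$')


def _parse_span(part: str, where: str) -> tuple[str, int, int, int]:
    m = _SPAN_RE.match(part)
    if m is None:
        raise CorpusParseError(f"{where}: malformed concept span {part!r}")
    l1, t1, l2, t2 = (int(m.group(k)) for k in ("l1", "t1", "l2", "t2"))
    if l1 != l2:
        raise CorpusParseError(f"{where}: concept spans multiple lines ({l1} vs {l2})")
    # 1-based line and token coordinates -> 0-based
    return m.group("text"), l1 - 1, t1 - 1, t2 - 1


def read_i2b2_corpus(text_dir: str | Path, concept_dir: str | Path,
                     relation_dir: str | Path) -> list[AnnotatedSentence]:
    """Load an i2b2-2010-style corpus into the internal data model.

    Each ``<doc>.txt`` holds one whitespace-tokenized sentence per line;
    ``<doc>.con`` holds concept lines ``c="…" L:T L:T||t="type"``;
    ``<doc>.rel`` holds relation lines ``c="…" L:T L:T||r="REL"||c="…" L:T L:T``.
    Only sentences containing at least one mention are returned.  Relation
    lines whose endpoints lie in different sentences are dropped with a
    warning (the task is intra-sentence by construction).
    """
    text_dir, concept_dir, relation_dir = Path(text_dir), Path(concept_dir), Path(relation_dir)
    sentences: list[AnnotatedSentence] = []
    for txt_path in sorted(text_dir.glob("*.txt")):
        doc_id = txt_path.stem
        lines = txt_path.read_text().splitlines()
        doc_tokens = [line.split() for line in lines]

        mentions_per_line: dict[int, list[EntityMention]] = {}
        con_path = concept_dir / f"{doc_id}.con"
        if con_path.exists():
            for lineno, raw in enumerate(con_path.read_text().splitlines(), start=1):
                if not raw.strip():
                    continue
                where = f"{con_path}:{lineno}"
                m = _CONCEPT_RE.match(raw)
                if m is None:
                    raise CorpusParseError(f"{where}: malformed concept line {raw!r}")
                text, sent_i, t1, t2 = _parse_span(raw.split("||")[0], where)
                try:
                    etype = EntityType(m.group("type"))
                except ValueError as exc:
                    raise CorpusParseError(f"{where}: unknown entity type {m.group('type')!r}") from exc
                if sent_i >= len(doc_tokens) or t2 >= len(doc_tokens[sent_i]):
                    raise CorpusParseError(f"{where}: span outside document text")
                mention = EntityMention(
                    id=f"{doc_id}:{sent_i}:{t1}-{t2}",
                    sentence_index=sent_i,
                    token_start=t1,
                    token_end=t2,
                    entity_type=etype,
                    surface=text,
                )
                mentions_per_line.setdefault(sent_i, []).append(mention)

        relations_per_line: dict[int, list[tuple[str, str, RelationLabel]]] = {}
        rel_path = relation_dir / f"{doc_id}.rel"
        if rel_path.exists():
            by_span = {
                (m.sentence_index, m.token_start, m.token_end): m
                for ms in mentions_per_line.values() for m in ms
            }
            for lineno, raw in enumerate(rel_path.read_text().splitlines(), start=1):
                if not raw.strip():
                    continue
                where = f"{rel_path}:{lineno}"
                m = _REL_RE.match(raw)
                if m is None:
                    raise CorpusParseError(f"{where}: malformed relation line {raw!r}")
                try:
                    label = RelationLabel(m.group("rel"))
                except ValueError as exc:
                    raise CorpusParseError(f"{where}: unknown relation type {m.group('rel')!r}") from exc
                _, s1, a1, b1 = _parse_span(m.group("c1"), where)
                _, s2, a2, b2 = _parse_span(m.group("c2"), where)
                if s1 != s2:
                    logger.warning("%s: cross-sentence relation dropped", where)
                    continue
                for key in ((s1, a1, b1), (s2, a2, b2)):
                    if key not in by_span:
                        raise IntegrityError(f"{where}: relation references unknown concept span {key}")
                m1, m2 = by_span[(s1, a1, b1)], by_span[(s2, a2, b2)]
                relations_per_line.setdefault(s1, []).append((m1.id, m2.id, label))

        for sent_i, mentions in sorted(mentions_per_line.items()):
            sentences.append(AnnotatedSentence(
                doc_id=doc_id,
                sentence_index=sent_i,
                tokens=doc_tokens[sent_i],
                mentions=sorted(mentions, key=lambda m: m.span),
                relations=relations_per_line.get(sent_i, []),
            ))
    return sentences


def write_i2b2_corpus(sentences: list[AnnotatedSentence], text_dir: str | Path,
                      concept_dir: str | Path, relation_dir: str | Path) -> None:
    """Serialize sentences back to the i2b2 dialect (inverse of the reader)."""
    text_dir, concept_dir, relation_dir = Path(text_dir), Path(concept_dir), Path(relation_dir)
    for d in (text_dir, concept_dir, relation_dir):
        d.mkdir(parents=True, exist_ok=True)

    docs: dict[str, list[AnnotatedSentence]] = {}
    for s in sentences:
        docs.setdefault(s.doc_id, []).append(s)
    for doc_id, sents in sorted(docs.items()):
        sents = sorted(sents, key=lambda s: s.sentence_index)
        n_lines = max(s.sentence_index for s in sents) + 1
        lines = [""] * n_lines
        con_lines: list[str] = []
        rel_lines: list[str] = []
        for s in sents:
            lines[s.sentence_index] = " ".join(s.tokens)
            li = s.sentence_index + 1  # back to 1-based
            for m in sorted(s.mentions, key=lambda m: m.span):
                con_lines.append(
                    f'c="{m.surface}" {li}:{m.token_start + 1} {li}:{m.token_end + 1}'
                    f'||t="{m.entity_type.value}"'
                )
            for a_id, b_id, label in s.relations:
                a, b = s.mention_by_id(a_id), s.mention_by_id(b_id)
                rel_lines.append(
                    f'c="{a.surface}" {li}:{a.token_start + 1} {li}:{a.token_end + 1}'
                    f'||r="{label.value}"'
                    f'||c="{b.surface}" {li}:{b.token_start + 1} {li}:{b.token_end + 1}'
                )
        (text_dir / f"{doc_id}.txt").write_text("\n".join(lines) + "\n")
        (concept_dir / f"{doc_id}.con").write_text("".join(l + "\n" for l in con_lines))
        (relation_dir / f"{doc_id}.rel").write_text("".join(l + "\n" for l in rel_lines))


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

def read_conllu(path: str | Path) -> list[DependencyGraph]:
    """Read dependency parses, one :class:`DependencyGraph` per sentence block.

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are skipped.
    A head index beyond the block is a parse error; zero or multiple roots
    produce a warning but the graph is still returned.
    """
    path = Path(path)
    graphs: list[DependencyGraph] = []
    block: list[tuple[int, int, str]] = []  # (id, head, deprel), 1-based

    def flush(where: str) -> None:
        if not block:
            return
        n = len(block)
        edges = set()
        roots = []
        for tok_id, head, deprel in block:
            if head < 0 or head > n:
                raise CorpusParseError(f"{where}: head index {head} out of range for {n} tokens")
            if head == 0:
                roots.append(tok_id - 1)
            else:
                edges.add((head - 1, tok_id - 1, deprel))
        if len(roots) != 1:
            logger.warning("%s: expected exactly one root, found %d", where, len(roots))
        root = roots[0] if roots else 0
        graphs.append(DependencyGraph(n_tokens=n, edges=frozenset(edges), root=root))
        block.clear()

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            where = f"{path}:{lineno}"
            if not line.strip():
                flush(where)
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise CorpusParseError(f"{where}: expected 10 columns, got {len(cols)}")
            tok_id = cols[0]
            if "-" in tok_id or "." in tok_id:
                continue  # multiword range / empty node
            try:
                block.append((int(tok_id), int(cols[6]), cols[7]))
            except ValueError as exc:
                raise CorpusParseError(f"{where}: non-integer ID or HEAD") from exc
    flush(str(path))
    return graphs


def write_conllu(graphs: list[DependencyGraph], tokens: list[list[str]],
                 path: str | Path) -> None:
    """Write parses as CoNLL-U blocks (inverse of :func:`read_conllu`)."""
    if len(graphs) != len(tokens):
        raise ValueError("one token list required per graph")
    out_lines: list[str] = []
    for g, toks in zip(graphs, tokens):
        if g.n_tokens != len(toks):
            raise ValueError("token count does not match graph")
        head = {d: (h + 1, rel) for h, d, rel in g.edges}
        for i, form in enumerate(toks):
            h, rel = head.get(i, (0, "root"))
            out_lines.append("\t".join(
                [str(i + 1), form, "_", "_", "_", "_", str(h), rel, "_", "_"]
            ))
        out_lines.append("")
    Path(path).write_text("".join(l + "\n" for l in out_lines))


# ---------------------------------------------------------------------------
# word2vec text embeddings
# ---------------------------------------------------------------------------

class OOVPolicy(str, enum.Enum):
    RANDOM_INIT = "random_init"
    ZERO = "zero"


@dataclass
class EmbeddingTable:
    """Dense token→vector table with a declared out-of-vocabulary policy.

    Out-of-vocabulary vectors are materialized lazily and cached, so the
    same unseen token always maps to the same vector within a table.  The
    random policy draws uniformly from [-0.25, 0.25].
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    dimension: int
    oov_policy: OOVPolicy = OOVPolicy.RANDOM_INIT
    _oov_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.dimension:
            raise ValueError("vectors must be (V, dimension)")
        if sorted(self.vocabulary.values()) != list(range(len(self.vocabulary))):
            raise ValueError("vocabulary indices must be dense 0..V-1")

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def lookup(self, token: str, rng: np.random.Generator | None = None) -> np.ndarray:
        if token in self.vocabulary:
            return self.vectors[self.vocabulary[token]]
        if token not in self._oov_cache:
            if self.oov_policy is OOVPolicy.ZERO:
                vec = np.zeros(self.dimension)
            else:
                if rng is None:
                    rng = np.random.default_rng(abs(hash(token)) % (2**31))
                vec = rng.uniform(-0.25, 0.25, size=self.dimension)
            self._oov_cache[token] = vec
        return self._oov_cache[token]


def load_word2vec_text(path: str | Path, expected_dim: int) -> EmbeddingTable:
    """Load a word2vec text file (optional ``V D`` header line)."""
    path = Path(path)
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        first = fh.readline()
        parts = first.split()
        header = len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts)
        if header:
            _, dim = int(parts[0]), int(parts[1])
            if dim != expected_dim:
                raise ConfigError(f"{path}: header declares dimension {dim}, expected {expected_dim}")
        else:
            fh.seek(0)
        for lineno, raw in enumerate(fh, start=2 if header else 1):
            parts = raw.split()
            if not parts:
                continue
            token, vals = parts[0], parts[1:]
            if len(vals) != expected_dim:
                raise ConfigError(
                    f"{path}:{lineno}: vector of length {len(vals)}, expected {expected_dim}"
                )
            if token in vocab:
                continue
            vocab[token] = len(rows)
            rows.append(np.array([float(v) for v in vals]))
    vectors = np.vstack(rows) if rows else np.zeros((0, expected_dim))
    return EmbeddingTable(vocabulary=vocab, vectors=vectors, dimension=expected_dim)


def write_word2vec_text(table: EmbeddingTable, path: str | Path, header: bool = True) -> None:
    tokens = sorted(table.vocabulary, key=table.vocabulary.__getitem__)
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"{len(tokens)} {table.dimension}\n")
        for tok in tokens:
            vec = table.vectors[table.vocabulary[tok]]
            fh.write(tok + " " + " ".join(format(v, ".6g") for v in vec) + "\n")
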