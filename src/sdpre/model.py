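"""The dual-branch relation classifier.

Branch one encodes the whole masked sentence: each token is the
concatenation of its word embedding and two position embeddings (signed
distance to each target entity), fed to a Bi-LSTM whose per-step output is
h(t) = [hf(t), hb(t)].  Branch two encodes the shortest dependency path:
neighboring path words P_i, P_{i+1} are merged by a shared convolutional
transform, ConP_i = flatten([P_i; P_{i+1}] · M), concatenated with the
embedding of the dependency relation of that step, and fed to a second
Bi-LSTM.  Both branches are pooled, concatenated, passed through a
fully-connected layer with dropout, and classified with softmax:
p(i|s) = softmax(Wo·s + bo).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .corpus_io import EmbeddingTable, LABEL_ORDER, RelationLabel
from .preprocess import RelationInstance

CHECKPOINT_SCHEMA_VERSION = 1

PAD = "<pad>"
UNK = "<unk>"


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults follow the reference regime: 100-dim word embeddings, 50-dim
    position embeddings, 200 hidden units in every Bi-LSTM and in the SDP
    convolution output (n2), nine classes, dropout on the fully-connected
    layer.  The two ablation flags reproduce the three studied
    configurations: sentence-only; +SDP word sequence; +SDP word sequence
    and relation types.
    """

    word_dim: int = 100
    position_dim: int = 50
    deprel_dim: int = 50
    hidden: int = 200
    n_classes: int = 9
    dropout_rate: float = 0.5
    use_sdp_words: bool = True
    use_sdp_relations: bool = True
    max_dist: int = 60
    pooling: str = "max"  # or "final"
    fc_dim: int | None = None  # defaults to `hidden`

    def __post_init__(self) -> None:
        for name in ("word_dim", "position_dim", "deprel_dim", "hidden", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.use_sdp_relations and not self.use_sdp_words:
            raise ValueError("relation-type features require the SDP word branch")
        if self.pooling not in ("max", "final"):
            raise ValueError("pooling must be 'max' or 'final'")

    @property
    def fc_size(self) -> int:
        return self.fc_dim if self.fc_dim is not None else self.hidden

    @property
    def n_position_buckets(self) -> int:
        # −max_dist..+max_dist plus one shared out-of-range bucket
        return 2 * self.max_dist + 2


def position_bucket(distance: int, max_dist: int) -> int:
    """Map a signed distance to its embedding row; |d|>max_dist shares one bucket."""
    if -max_dist <= distance <= max_dist:
        return distance + max_dist
    return 2 * max_dist + 1


@dataclass
class Vocabulary:
    """Dense word and dependency-relation vocabularies with PAD/UNK rows."""

    words: dict[str, int]
    deprels: dict[str, int]

    @classmethod
    def build(cls, instances: list[RelationInstance]) -> "Vocabulary":
        words = {PAD: 0, UNK: 1}
        deprels = {PAD: 0, UNK: 1}
        for inst in instances:
            for tok in inst.masked_tokens:
                words.setdefault(tok, len(words))
            if inst.sdp is not None:
                for rel in inst.sdp.relations:
                    deprels.setdefault(rel, len(deprels))
        return cls(words=words, deprels=deprels)

    def word_index(self, token: str) -> int:
        return self.words.get(token, self.words[UNK])

    def deprel_index(self, rel: str) -> int:
        return self.deprels.get(rel, self.deprels[UNK])


LABEL_TO_INDEX = {label: i for i, label in enumerate(LABEL_ORDER)}


def make_batch(instances: list[RelationInstance], vocab: Vocabulary,
               config: ModelConfig) -> dict[str, np.ndarray]:
    """Pad a group of instances into index/mask arrays.

    Padding is masked out of both the recurrent updates and the pooling,
    so encodings are invariant to the amount of padding.
    """
    B = len(instances)
    T = max(len(i.masked_tokens) for i in instances)
    S = max([len(i.sdp) for i in instances if i.sdp is not None] or [2])

    words = np.zeros((B, T), dtype=np.int64)
    p1 = np.zeros((B, T), dtype=np.int64)
    p2 = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T))
    sdp_words = np.zeros((B, S), dtype=np.int64)
    deprels = np.zeros((B, S - 1), dtype=np.int64)
    sdp_mask = np.zeros((B, S - 1))
    has_sdp = np.zeros((B, 1))
    labels = np.zeros(B, dtype=np.int64)

    for b, inst in enumerate(instances):
        n = len(inst.masked_tokens)
        words[b, :n] = [vocab.word_index(t) for t in inst.masked_tokens]
        p1[b, :n] = [position_bucket(d, config.max_dist) for d in inst.pos1]
        p2[b, :n] = [position_bucket(d, config.max_dist) for d in inst.pos2]
        mask[b, :n] = 1.0
        labels[b] = LABEL_TO_INDEX[inst.label]
        if inst.sdp is not None:
            m = len(inst.sdp)
            sdp_words[b, :m] = [vocab.word_index(inst.masked_tokens[i])
                                for i in inst.sdp.nodes]
            deprels[b, :m - 1] = [vocab.deprel_index(r) for r in inst.sdp.relations]
            sdp_mask[b, :m - 1] = 1.0
            has_sdp[b, 0] = 1.0
    return {"words": words, "p1": p1, "p2": p2, "mask": mask,
            "sdp_words": sdp_words, "deprels": deprels, "sdp_mask": sdp_mask,
            "has_sdp": has_sdp, "labels": labels}


def sdp_convolution(path_word_vectors: np.ndarray, M: np.ndarray) -> np.ndarray:
    """ConP_i = flatten([P_i; P_{i+1}] · M) for i = 1..m−1.

    ``path_word_vectors`` is (m, n1); ``M`` is the shared (n1, n2)
    transform.  Stacking the two word vectors row-wise and
    right-multiplying gives a 2×n2 block whose row-major flattening is
    the concatenation of P_i·M and P_{i+1}·M.  Returns (m−1, 2·n2).
    """
    P = np.asarray(path_word_vectors, dtype=np.float64)
    if P.ndim != 2:
        raise ValueError("path word vectors must be a (m, n1) array")
    if P.shape[0] < 2:
        raise ValueError("a path of length < 2 has no neighboring pairs")
    if P.shape[1] != M.shape[0]:
        raise ValueError("word dimension does not match the transform")
    out = np.empty((P.shape[0] - 1, 2 * M.shape[1]))
    for i in range(P.shape[0] - 1):
        block = np.vstack([P[i], P[i + 1]]) @ M  # 2 × n2
        out[i] = block.reshape(-1)
    return out


_NEG = -1.0e9  # pooling mask value; finite to keep gradients clean


class RelationClassifier:
    """Trainable dual-branch network over prepared relation instances."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary,
                 seed: int = 0, pretrained: EmbeddingTable | None = None) -> None:
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        c = config

        self._add_embedding("word_emb", len(vocab.words), c.word_dim, rng,
                            scale=0.25, pretrained=pretrained)
        self._add_embedding("pos1_emb", c.n_position_buckets, c.position_dim, rng, 0.05)
        self._add_embedding("pos2_emb", c.n_position_buckets, c.position_dim, rng, 0.05)

        sent_in = c.word_dim + 2 * c.position_dim
        self._add_lstm("sent_f", sent_in, c.hidden, rng)
        self._add_lstm("sent_b", sent_in, c.hidden, rng)

        if c.use_sdp_words:
            k = np.sqrt(6.0 / (c.word_dim + c.hidden))
            self.params["conv_M"] = ad.parameter(
                rng.uniform(-k, k, size=(c.word_dim, c.hidden)), "conv_M")
            sdp_in = 2 * c.hidden
            if c.use_sdp_relations:
                self._add_embedding("deprel_emb", len(vocab.deprels), c.deprel_dim, rng, 0.05)
                sdp_in += c.deprel_dim
            self._add_lstm("sdp_f", sdp_in, c.hidden, rng)
            self._add_lstm("sdp_b", sdp_in, c.hidden, rng)
            self.params["no_path"] = ad.parameter(
                rng.uniform(-0.05, 0.05, size=(1, 2 * c.hidden)), "no_path")

        feat = 2 * c.hidden + (2 * c.hidden if c.use_sdp_words else 0)
        k = np.sqrt(6.0 / (feat + c.fc_size))
        self.params["fc_W"] = ad.parameter(rng.uniform(-k, k, size=(feat, c.fc_size)), "fc_W")
        self.params["fc_b"] = ad.parameter(np.zeros(c.fc_size), "fc_b")
        k = np.sqrt(6.0 / (c.fc_size + c.n_classes))
        self.params["out_W"] = ad.parameter(rng.uniform(-k, k, size=(c.fc_size, c.n_classes)), "out_W")
        self.params["out_b"] = ad.parameter(np.zeros(c.n_classes), "out_b")

    # -- parameter construction -------------------------------------------

    def _add_embedding(self, name: str, rows: int, dim: int,
                       rng: np.random.Generator, scale: float,
                       pretrained: EmbeddingTable | None = None) -> None:
        table = rng.uniform(-scale, scale, size=(rows, dim))
        if pretrained is not None:
            if pretrained.dimension != dim:
                raise ValueError(
                    f"pretrained embeddings have dimension {pretrained.dimension}, "
                    f"model expects {dim}")
            for tok, idx in self.vocab.words.items():
                if tok in pretrained:
                    table[idx] = pretrained.lookup(tok)
        table[0] = 0.0  # PAD row
        self.params[name] = ad.parameter(table, name)

    def _add_lstm(self, prefix: str, in_dim: int, hidden: int,
                  rng: np.random.Generator) -> None:
        k = 1.0 / np.sqrt(hidden)
        self.params[f"{prefix}_Wx"] = ad.parameter(
            rng.uniform(-k, k, size=(in_dim, 4 * hidden)), f"{prefix}_Wx")
        self.params[f"{prefix}_Wh"] = ad.parameter(
            rng.uniform(-k, k, size=(hidden, 4 * hidden)), f"{prefix}_Wh")
        self.params[f"{prefix}_b"] = ad.parameter(np.zeros(4 * hidden), f"{prefix}_b")

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward pieces ----------------------------------------------------

    def _lstm_pass(self, xs: list[Tensor], mask: np.ndarray, prefix: str,
                   reverse: bool) -> tuple[list[Tensor], Tensor]:
        """One LSTM direction with masked state updates.

        Returns per-step hidden states (aligned to input order) and the
        final state after the last *valid* step of each sequence.
        """
        H = self.config.hidden
        Wx, Wh, b = (self.params[f"{prefix}_{s}"] for s in ("Wx", "Wh", "b"))
        B, T = mask.shape
        h = Tensor(np.zeros((B, H)))
        cell = Tensor(np.zeros((B, H)))
        hs: list[Tensor | None] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            gates = ad.add(ad.add(ad.matmul(xs[t], Wx), ad.matmul(h, Wh)), b)
            i_g = ad.sigmoid(ad.slice_cols(gates, 0, H))
            f_g = ad.sigmoid(ad.slice_cols(gates, H, 2 * H))
            g_g = ad.tanh(ad.slice_cols(gates, 2 * H, 3 * H))
            o_g = ad.sigmoid(ad.slice_cols(gates, 3 * H, 4 * H))
            c_new = ad.add(ad.mul(f_g, cell), ad.mul(i_g, g_g))
            h_new = ad.mul(o_g, ad.tanh(c_new))
            m = mask[:, t:t + 1]
            cell = ad.add(ad.mul(c_new, m), ad.mul(cell, 1.0 - m))
            h = ad.add(ad.mul(h_new, m), ad.mul(h, 1.0 - m))
            hs[t] = h
        return hs, h  # type: ignore[return-value]

    def _bilstm(self, xs: list[Tensor], mask: np.ndarray, prefix: str) -> Tensor:
        """Bi-LSTM + pooling; h(t) = [hf(t), hb(t)], pooled per config."""
        hf, hf_last = self._lstm_pass(xs, mask, f"{prefix}_f", reverse=False)
        hb, hb_last = self._lstm_pass(xs, mask, f"{prefix}_b", reverse=True)
        if self.config.pooling == "final":
            return ad.concat([hf_last, hb_last])
        pooled: Tensor | None = None
        for t in range(mask.shape[1]):
            h_t = ad.concat([hf[t], hb[t]])
            m = mask[:, t:t + 1]
            masked = ad.add(ad.mul(h_t, m), (1.0 - m) * _NEG)
            pooled = masked if pooled is None else ad.maximum(pooled, masked)
        assert pooled is not None
        return pooled

    def _encode_sentence(self, batch: dict[str, np.ndarray]) -> Tensor:
        xs = []
        for t in range(batch["words"].shape[1]):
            xs.append(ad.concat([
                ad.gather_rows(self.params["word_emb"], batch["words"][:, t]),
                ad.gather_rows(self.params["pos1_emb"], batch["p1"][:, t]),
                ad.gather_rows(self.params["pos2_emb"], batch["p2"][:, t]),
            ]))
        return self._bilstm(xs, batch["mask"], "sent")

    def _encode_sdp(self, batch: dict[str, np.ndarray]) -> Tensor:
        c = self.config
        S = batch["sdp_words"].shape[1]
        projected = [ad.matmul(ad.gather_rows(self.params["word_emb"],
                                              batch["sdp_words"][:, s]),
                               self.params["conv_M"])
                     for s in range(S)]
        xs = []
        for i in range(S - 1):
            conp = ad.concat([projected[i], projected[i + 1]])
            if c.use_sdp_relations:
                conp = ad.concat([conp, ad.gather_rows(self.params["deprel_emb"],
                                                       batch["deprels"][:, i])])
            xs.append(conp)
        pooled = self._bilstm(xs, batch["sdp_mask"], "sdp")
        # instances without a dependency path get the learned placeholder
        has = batch["has_sdp"]
        return ad.add(ad.mul(pooled, has), ad.mul(self.params["no_path"], 1.0 - has))

    def forward(self, batch: dict[str, np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        parts = [self._encode_sentence(batch)]
        if self.config.use_sdp_words:
            parts.append(self._encode_sdp(batch))
        feats = ad.concat(parts) if len(parts) > 1 else parts[0]
        if train and self.config.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            feats = ad.dropout(feats, self.config.dropout_rate, rng, train=True)
        fc = ad.tanh(ad.add(ad.matmul(feats, self.params["fc_W"]), self.params["fc_b"]))
        return ad.add(ad.matmul(fc, self.params["out_W"]), self.params["out_b"])

    def loss(self, batch: dict[str, np.ndarray], train: bool = True,
             rng: np.random.Generator | None = None,
             sample_weights: np.ndarray | None = None) -> Tensor:
        logits = self.forward(batch, train=train, rng=rng)
        return ad.softmax_cross_entropy(logits, batch["labels"], sample_weights)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, instances: list[RelationInstance],
                      batch_size: int = 64) -> np.ndarray:
        probs = []
        for lo in range(0, len(instances), batch_size):
            batch = make_batch(instances[lo:lo + batch_size], self.vocab, self.config)
            logits = self.forward(batch, train=False)
            probs.append(ad.softmax(logits.value))
        return np.vstack(probs)

    def predict(self, instances: list[RelationInstance],
                batch_size: int = 64) -> list[RelationLabel]:
        probs = self.predict_proba(instances, batch_size)
        return [LABEL_ORDER[i] for i in probs.argmax(axis=1)]

    def classify(self, sentence_vec: np.ndarray,
                 sdp_vec: np.ndarray | None = None) -> np.ndarray:
        """Probabilities from already-pooled branch vectors (Eq.-2 head)."""
        parts = [np.atleast_2d(sentence_vec)]
        if self.config.use_sdp_words:
            if sdp_vec is None:
                sdp_vec = self.params["no_path"].value
            parts.append(np.atleast_2d(sdp_vec))
        s = np.concatenate(parts, axis=1)
        fc = np.tanh(s @ self.params["fc_W"].value + self.params["fc_b"].value)
        logits = fc @ self.params["out_W"].value + self.params["out_b"].value
        return ad.softmax(logits)[0]

    def embed_sentence(self, instance: RelationInstance) -> np.ndarray:
        """Per-token input vectors: concat(word, pos1, pos2) embeddings."""
        c = self.config
        rows = []
        for tok, d1, d2 in zip(instance.masked_tokens, instance.pos1, instance.pos2):
            rows.append(np.concatenate([
                self.params["word_emb"].value[self.vocab.word_index(tok)],
                self.params["pos1_emb"].value[position_bucket(d1, c.max_dist)],
                self.params["pos2_emb"].value[position_bucket(d2, c.max_dist)],
            ]))
        return np.vstack(rows)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "config": asdict(self.config),
            "words": sorted(self.vocab.words, key=self.vocab.words.__getitem__),
            "deprels": sorted(self.vocab.deprels, key=self.vocab.deprels.__getitem__),
        }
        arrays = {f"param_{k}": v.value for k, v in self.params.items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "RelationClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["schema_version"] != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
            config = ModelConfig(**meta["config"])
            vocab = Vocabulary(
                words={w: i for i, w in enumerate(meta["words"])},
                deprels={r: i for i, r in enumerate(meta["deprels"])},
            )
            model = cls(config, vocab, seed=0)
            for k in model.params:
                model.params[k].value = np.array(data[f"param_{k}"])
        return model
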