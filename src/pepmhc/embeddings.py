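"""Sub-word embedding table and skip-gram pre-training.

The embedding of a word is the sum of the embeddings of its sub-word
multiset (fastText scheme).  Pre-training learns sub-word vectors by
classifying word pairs as context vs non-context: the dot product of the two
word vectors is passed through a sigmoid and scored with binary
cross-entropy.  Negatives are sampled uniformly from the vocabulary,
excluding each center's true context words, at a fixed ratio per positive.
A single table serves both the center and context roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .context import ContextPairSet, sequence_context_pairs
from .tokenizer import TokenizedSequence, enumerate_subwords


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class EmbeddingTable:
    """Growable map from sub-word string to a d-dimensional vector.

    Looking up an unseen sub-word creates it on the fly from a uniform
    distribution on [-0.5/dim, 0.5/dim] (seeded), so models can encode
    words never observed during pre-training.
    """

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self._index: dict[str, int] = {}
        self._matrix = np.zeros((0, dim), dtype=float)
        self._rng = np.random.default_rng(seed)
        self._init_seed = seed
        self._word_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, subword: str) -> bool:
        return subword in self._index

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def _grow(self, n_new: int) -> None:
        extra = self._rng.uniform(-0.5 / self.dim, 0.5 / self.dim, (n_new, self.dim))
        self._matrix = np.vstack([self._matrix, extra])

    def index(self, subword: str) -> int:
        """Row index of a sub-word, creating it if unseen."""
        i = self._index.get(subword)
        if i is None:
            i = len(self._index)
            self._index[subword] = i
            self._grow(1)
        return i

    def vector(self, subword: str) -> np.ndarray:
        i = self.index(subword)  # may grow the matrix; resolve index first
        return self._matrix[i]

    def subword_indices(self, word: str) -> np.ndarray:
        """Row indices of the word's sub-word multiset (repeats kept)."""
        cached = self._word_cache.get(word)
        if cached is None:
            cached = np.asarray(
                [self.index(s) for s in enumerate_subwords(word)], dtype=int
            )
            self._word_cache[word] = cached
        return cached

    def word_vector(self, word: str) -> np.ndarray:
        """Sum of the vectors of the word's sub-word multiset."""
        idx = self.subword_indices(word)
        return self._matrix[idx].sum(axis=0)

    def set_vector(self, subword: str, vec: Sequence[float]) -> None:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.dim,):
            raise ValueError(f"vector must have length {self.dim}")
        i = self.index(subword)
        self._matrix[i] = vec

    def copy(self) -> "EmbeddingTable":
        out = EmbeddingTable(self.dim, seed=self._init_seed)
        out._index = dict(self._index)
        out._matrix = self._matrix.copy()
        out._rng = np.random.default_rng(self._rng.bit_generator.state["state"]["state"] % (2**31))
        return out

    def as_dict(self) -> dict[str, np.ndarray]:
        return {s: self._matrix[i].copy() for s, i in self._index.items()}

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subword\t" + "\t".join(f"d{i}" for i in range(self.dim)) + "\n")
            for s, i in self._index.items():
                fh.write(s + "\t" + "\t".join(repr(float(v)) for v in self._matrix[i]) + "\n")

    @classmethod
    def load_tsv(cls, path: str | Path, seed: int = 0) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            dim = len(header) - 1
            table = cls(dim=dim, seed=seed)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                table.set_vector(parts[0], [float(x) for x in parts[1:]])
        return table


def word_vector(word: str, table: EmbeddingTable) -> np.ndarray:
    """Module-level convenience wrapper for :meth:`EmbeddingTable.word_vector`."""
    return table.word_vector(word)


def pair_probability(u: np.ndarray, v: np.ndarray) -> float:
    """sigmoid(u . v): probability that two word vectors are in context."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(sigmoid(float(u @ v)))


@dataclass(frozen=True)
class PretrainConfig:
    """Skip-gram pre-training hyperparameters.

    negatives_per_positive : uniform random negatives sampled per positive
        pair each epoch (default 5, standard skip-gram practice).
    """

    negatives_per_positive: int = 5
    epochs: int = 30
    learning_rate: float = 0.5
    batch_size: int = 128
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


def _context_map(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    ctx: dict[str, set[str]] = {}
    for a, b in pairs:
        ctx.setdefault(a, set()).add(b)
        ctx.setdefault(b, set()).add(a)
    return ctx


def sample_negative_pairs(
    vocab: Sequence[str],
    positives: ContextPairSet | Iterable[tuple[str, str]],
    k: int,
    seed: int,
) -> list[tuple[str, str]]:
    """For each positive (center, _), draw k (center, random word) negatives.

    The random word is uniform over the vocabulary excluding the center
    itself and all of the center's true context words.  Reproducible under
    the seed.
    """
    pos_list = list(positives.pairs) if isinstance(positives, ContextPairSet) else list(positives)
    ctx = _context_map(pos_list)
    vocab = list(vocab)
    vocab_set = set(vocab)
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for center, _ in pos_list:
        forbidden = ctx.get(center, set()) | {center}
        eligible = vocab_set - forbidden
        if not eligible:
            raise ValueError(
                f"vocabulary too small: no eligible negatives for center {center!r}"
            )
        for _ in range(k):
            while True:
                cand = vocab[int(rng.integers(len(vocab)))]
                if cand not in forbidden:
                    out.append((center, cand))
                    break
    return out


def _collect_pairs(
    corpus: ContextPairSet | Iterable[ContextPairSet] | Iterable[TokenizedSequence],
) -> list[tuple[str, str]]:
    if isinstance(corpus, ContextPairSet):
        return sorted(corpus.pairs)
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if isinstance(corpus[0], ContextPairSet):
        merged: set[tuple[str, str]] = set()
        for ps in corpus:
            merged |= ps.pairs
        return sorted(merged)
    merged = set()
    for tokens in corpus:
        merged |= sequence_context_pairs(tokens).pairs
    return sorted(merged)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def pretrain(
    corpus: ContextPairSet | Iterable[ContextPairSet] | Iterable[TokenizedSequence],
    cfg: PretrainConfig = PretrainConfig(),
    table: EmbeddingTable | None = None,
) -> tuple[EmbeddingTable, list[dict[str, float]]]:
    """Train sub-word vectors on context-pair classification.

    Returns the trained table and a loss trace (one row per epoch with
    train/held-out binary cross-entropy; epoch 0 is the pre-update loss).
    Gradients flow to the sub-word vectors of both words of every pair.
    """
    positives = _collect_pairs(corpus)
    if not positives:
        raise ValueError("no context pairs to train on")
    if table is None:
        table = EmbeddingTable(seed=cfg.seed)
    if cfg.epochs == 0:
        return table, []

    rng = np.random.default_rng(cfg.seed)
    vocab = sorted({w for pair in positives for w in pair})
    sub_idx = np.asarray([table.subword_indices(w) for w in vocab], dtype=int)
    word_id = {w: i for i, w in enumerate(vocab)}
    ctx = _context_map(positives)
    ctx_ids = {
        word_id[w]: np.asarray(sorted(word_id[c] for c in cs), dtype=int)
        for w, cs in ctx.items()
    }

    pos_ids = np.asarray([(word_id[a], word_id[b]) for a, b in positives], dtype=int)
    n_holdout = int(len(pos_ids) * cfg.holdout_fraction) if len(pos_ids) >= 20 else 0
    perm = rng.permutation(len(pos_ids))
    val_ids = pos_ids[perm[:n_holdout]]
    train_ids = pos_ids[perm[n_holdout:]]

    k = cfg.negatives_per_positive
    S = sub_idx.shape[1]
    M = table.matrix  # updated in place

    def word_vecs(ids: np.ndarray) -> np.ndarray:
        return M[sub_idx[ids]].sum(axis=1)

    def sample_negs(centers: np.ndarray, gen: np.random.Generator) -> np.ndarray:
        negs = gen.integers(len(vocab), size=len(centers))
        for _ in range(100):
            bad = np.asarray(
                [n == c or (c in ctx_ids and n in ctx_ids[c]) for c, n in zip(centers, negs)]
            )
            if not bad.any():
                break
            negs[bad] = gen.integers(len(vocab), size=int(bad.sum()))
        return negs

    # fixed validation batch (positives + k negatives each)
    if len(val_ids):
        val_gen = np.random.default_rng(int(rng.integers(2**31)))
        val_centers = np.repeat(val_ids[:, 0], k)
        val_negs = sample_negs(val_centers, val_gen)
        val_u = np.concatenate([val_ids[:, 0], val_centers])
        val_v = np.concatenate([val_ids[:, 1], val_negs])
        val_y = np.concatenate([np.ones(len(val_ids)), np.zeros(len(val_negs))])

    def eval_loss(u_ids: np.ndarray, v_ids: np.ndarray, y: np.ndarray) -> float:
        p = sigmoid((word_vecs(u_ids) * word_vecs(v_ids)).sum(axis=1))
        return _bce(p, y)

    trace: list[dict[str, float]] = []
    lr = cfg.learning_rate
    for epoch in range(cfg.epochs + 1):
        # loss bookkeeping on a fixed subset, before this epoch's updates
        row = {"epoch": float(epoch)}
        probe = train_ids[: min(len(train_ids), 2048)]
        probe_negs = sample_negs(
            np.repeat(probe[:, 0], k), np.random.default_rng(cfg.seed + 7)
        )
        row["train_loss"] = eval_loss(
            np.concatenate([probe[:, 0], np.repeat(probe[:, 0], k)]),
            np.concatenate([probe[:, 1], probe_negs]),
            np.concatenate([np.ones(len(probe)), np.zeros(len(probe_negs))]),
        )
        if len(val_ids):
            row["val_loss"] = eval_loss(val_u, val_v, val_y)
        trace.append(row)
        if epoch == cfg.epochs:
            break

        order = rng.permutation(len(train_ids))
        flip = rng.integers(2, size=len(train_ids)).astype(bool)
        epoch_pairs = train_ids[order]
        epoch_pairs = np.where(flip[:, None], epoch_pairs[:, ::-1], epoch_pairs)
        for start in range(0, len(epoch_pairs), cfg.batch_size):
            batch = epoch_pairs[start : start + cfg.batch_size]
            centers = np.repeat(batch[:, 0], k)
            negs = sample_negs(centers, rng)
            u_ids = np.concatenate([batch[:, 0], centers])
            v_ids = np.concatenate([batch[:, 1], negs])
            y = np.concatenate([np.ones(len(batch)), np.zeros(len(negs))])
            U = word_vecs(u_ids)
            V = word_vecs(v_ids)
            p = sigmoid((U * V).sum(axis=1))
            g = ((p - y) / len(y))[:, None]  # d(mean BCE)/d(dot)
            grad_u = g * V
            grad_v = g * U
            np.subtract.at(
                M, sub_idx[u_ids].ravel(), lr * np.repeat(grad_u, S, axis=0)
            )
            np.subtract.at(
                M, sub_idx[v_ids].ravel(), lr * np.repeat(grad_v, S, axis=0)
            )
    return table, trace


# ---------------- high-level pre-training entry points ----------------

def pretrain_peptide_table(
    peptides: Iterable[str],
    cfg: PretrainConfig = PretrainConfig(),
    table: EmbeddingTable | None = None,
) -> tuple[EmbeddingTable, list[dict[str, float]]]:
    """Pre-train a peptide table on sequence-window context pairs."""
    from .tokenizer import tokenize

    tokens = [tokenize(p) for p in peptides]
    if not tokens:
        raise ValueError("empty peptide corpus")
    return pretrain(tokens, cfg, table)


def pretrain_allele_table(
    aligned: Mapping[str, str],
    context_matrix,
    cfg: PretrainConfig = PretrainConfig(),
    context_cfg=None,
    table: EmbeddingTable | None = None,
) -> tuple[EmbeddingTable, list[dict[str, float]]]:
    """Pre-train an allele table on structural context pairs.

    ``context_matrix`` is the allele-averaged Cα distance matrix; pairs are
    built per aligned allele sequence against this single matrix and merged.
    """
    from .context import ContextConfig, structural_context_pairs
    from .tokenizer import aligned_config, tokenize

    if context_cfg is None:
        context_cfg = ContextConfig()
    tok_cfg = aligned_config()
    pair_sets = [
        structural_context_pairs(tokenize(seq, tok_cfg), context_matrix, context_cfg)
        for seq in aligned.values()
    ]
    if not pair_sets:
        raise ValueError("no aligned allele sequences")
    return pretrain(pair_sets, cfg, table)
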