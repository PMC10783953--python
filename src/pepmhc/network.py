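"""Binding-probability prediction head and affinity fine-tuning.

Architecture: the peptide and allele are tokenized into fixed-width words
whose embeddings (sums of sub-word vectors, trainable) are flattened and fed
through one 250-unit fully connected layer per branch (dropout 0.5), then
concatenated and passed through two 240-unit layers (dropout 0.4) to a
single sigmoid output.  ReLU activations elsewhere; plain SGD with learning
rate 0.01.  Peptides up to 45 residues (15 words) are accepted, shorter
peptides being left-padded with all-pad words.  Training pairs each batch of
observed positives with freshly regenerated random-peptide negatives, and
early-stops on validation AUC.

Implemented directly on NumPy arrays with explicit backpropagation; the
embedding tables receive gradients through the word-sum, so sub-word vectors
keep adapting during supervised training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import BindingRecord, NegativeSampler
from .embeddings import EmbeddingTable, sigmoid
from .tokenizer import TokenizerConfig, aligned_config, tokenize


@dataclass(frozen=True)
class NetConfig:
    """Prediction-head hyperparameters.

    Defaults follow the published architecture: 250-unit branch layers with
    dropout 0.5, a 240/240 trunk with dropout 0.4, sigmoid output, SGD with
    learning rate 0.01, embedding dimension 32 and a 45-residue peptide
    capacity (15 words at word size 3).
    """

    peptide_capacity: int = 45
    word_size: int = 3
    embedding_dim: int = 32
    branch_width: int = 250
    branch_dropout: float = 0.5
    trunk_widths: tuple[int, ...] = (240, 240)
    trunk_dropout: float = 0.4
    learning_rate: float = 0.01
    batch_size: int = 32
    neg_pos_ratio: float = 1.0
    max_epochs: int = 300
    patience: int = 60

    def __post_init__(self) -> None:
        if self.peptide_capacity % self.word_size != 0:
            raise ValueError("peptide_capacity must be divisible by word_size")
        if not (0 <= self.branch_dropout < 1 and 0 <= self.trunk_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if any(w <= 0 for w in (self.branch_width, *self.trunk_widths)):
            raise ValueError("layer widths must be positive")

    @property
    def peptide_words(self) -> int:
        return self.peptide_capacity // self.word_size


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class BindingModel:
    """Peptide + allele branches feeding a fully connected trunk."""

    def __init__(
        self,
        pep_table: EmbeddingTable,
        allele_table: EmbeddingTable,
        allele_panel: Mapping[str, str],
        cfg: NetConfig = NetConfig(),
        seed: int = 0,
    ):
        if pep_table.dim != cfg.embedding_dim or allele_table.dim != cfg.embedding_dim:
            raise ValueError(
                f"embedding tables must have dim {cfg.embedding_dim}; got "
                f"{pep_table.dim} (peptide) and {allele_table.dim} (allele)"
            )
        if not allele_panel:
            raise ValueError("allele panel is empty")
        self.cfg = cfg
        self.pep_table = pep_table
        self.allele_table = allele_table
        self.pep_cfg = TokenizerConfig(word_size=cfg.word_size)
        self.allele_cfg = aligned_config(word_size=cfg.word_size)
        self.panel: dict[str, str] = {k: v.upper() for k, v in allele_panel.items()}

        # per-allele sub-word index block, built once
        self._allele_words: dict[str, tuple[str, ...]] = {}
        n_words = None
        for name, seq in self.panel.items():
            words = tokenize(seq, self.allele_cfg).words
            if n_words is None:
                n_words = len(words)
            elif len(words) != n_words:
                raise ValueError("allele sequences tokenized to differing word counts")
            self._allele_words[name] = words
        self.allele_word_count = int(n_words)
        self._allele_idx = {
            name: np.asarray(
                [self.allele_table.subword_indices(w) for w in words], dtype=int
            )
            for name, words in self._allele_words.items()
        }
        self._pad_word = self.pep_cfg.pad_char * cfg.word_size

        d = cfg.embedding_dim
        rng = np.random.default_rng(seed)
        self._init_seed = seed

        def dense(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
            scale = np.sqrt(2.0 / n_in)
            return rng.normal(0.0, scale, (n_in, n_out)), np.zeros(n_out)

        pep_in = cfg.peptide_words * d
        allele_in = self.allele_word_count * d
        self.W_p, self.b_p = dense(pep_in, cfg.branch_width)
        self.W_a, self.b_a = dense(allele_in, cfg.branch_width)
        self.trunk: list[tuple[np.ndarray, np.ndarray]] = []
        n_in = 2 * cfg.branch_width
        for width in cfg.trunk_widths:
            self.trunk.append(dense(n_in, width))
            n_in = width
        self.W_out, self.b_out = dense(n_in, 1)
        self.epoch = 0
        self.best_val_score: float | None = None

    # ---------------- featurization ----------------

    def peptide_indices(self, peptides: Sequence[str]) -> np.ndarray:
        """(B, peptide_words, n_subwords) sub-word index block; left-pads
        short peptides with all-pad words."""
        cap = self.cfg.peptide_words
        blocks = []
        for pep in peptides:
            tokens = tokenize(pep, self.pep_cfg)
            if len(tokens.words) > cap:
                raise ValueError(
                    f"peptide {pep!r} exceeds the {self.cfg.peptide_capacity}-residue capacity"
                )
            slots = (self._pad_word,) * (cap - len(tokens.words)) + tokens.words
            blocks.append([self.pep_table.subword_indices(w) for w in slots])
        return np.asarray(blocks, dtype=int)

    def allele_indices(self, alleles: Sequence[str]) -> np.ndarray:
        blocks = []
        for name in alleles:
            if name not in self._allele_idx:
                raise KeyError(
                    f"unknown allele {name!r}; available: {sorted(self._allele_idx)}"
                )
            blocks.append(self._allele_idx[name])
        return np.asarray(blocks, dtype=int)

    # ---------------- forward / backward ----------------

    def _forward(
        self,
        pidx: np.ndarray,
        aidx: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        cfg = self.cfg
        Mp = self.pep_table.matrix
        Ma = self.allele_table.matrix
        B = pidx.shape[0]
        X_p = Mp[pidx].sum(axis=2).reshape(B, -1)
        X_a = Ma[aidx].sum(axis=2).reshape(B, -1)

        def drop_mask(shape, rate):
            if not train or rate == 0.0:
                return None
            return (rng.random(shape) >= rate) / (1.0 - rate)

        cache = {"pidx": pidx, "aidx": aidx, "X_p": X_p, "X_a": X_a}
        h_p = _relu(X_p @ self.W_p + self.b_p)
        h_a = _relu(X_a @ self.W_a + self.b_a)
        m_p = drop_mask(h_p.shape, cfg.branch_dropout)
        m_a = drop_mask(h_a.shape, cfg.branch_dropout)
        cache.update(h_p=h_p, h_a=h_a, m_p=m_p, m_a=m_a)
        if m_p is not None:
            h_p, h_a = h_p * m_p, h_a * m_a
        h = np.concatenate([h_p, h_a], axis=1)
        cache["h"] = h
        acts, masks = [], []
        for W, b in self.trunk:
            z = _relu(h @ W + b)
            m = drop_mask(z.shape, cfg.trunk_dropout)
            acts.append(z)
            masks.append(m)
            h = z * m if m is not None else z
        cache.update(trunk_acts=acts, trunk_masks=masks, trunk_in=cache["h"])
        logits = (h @ self.W_out + self.b_out).ravel()
        p = sigmoid(logits)
        cache.update(last_h=h, p=p)
        return p, cache

    def _backward(self, cache, dlogit: np.ndarray) -> None:
        """SGD update from d(loss)/d(logit) (already includes 1/B)."""
        lr = self.cfg.learning_rate
        g = dlogit[:, None]
        dW_out = cache["last_h"].T @ g
        db_out = g.sum(axis=0)
        dh = g @ self.W_out.T
        self.W_out -= lr * dW_out
        self.b_out -= lr * db_out

        # trunk, in reverse
        for li in range(len(self.trunk) - 1, -1, -1):
            W, b = self.trunk[li]
            z, m = cache["trunk_acts"][li], cache["trunk_masks"][li]
            if m is not None:
                dh = dh * m
            dz = dh * (z > 0)
            prev = cache["trunk_acts"][li - 1] if li > 0 else cache["trunk_in"]
            if li > 0 and cache["trunk_masks"][li - 1] is not None:
                prev = prev * cache["trunk_masks"][li - 1]
            dW = prev.T @ dz
            db = dz.sum(axis=0)
            dh = dz @ W.T
            self.trunk[li] = (W - lr * dW, b - lr * db)

        w = self.cfg.branch_width
        dh_p, dh_a = dh[:, :w], dh[:, w:]
        for branch, dhb in (("p", dh_p), ("a", dh_a)):
            hb, mb = cache[f"h_{branch}"], cache[f"m_{branch}"]
            if mb is not None:
                dhb = dhb * mb
            dzb = dhb * (hb > 0)
            X = cache[f"X_{branch}"]
            W = self.W_p if branch == "p" else self.W_a
            dW = X.T @ dzb
            db = dzb.sum(axis=0)
            dX = dzb @ W.T
            if branch == "p":
                self.W_p -= lr * dW
                self.b_p -= lr * db
                self._scatter_embedding_grad(self.pep_table, cache["pidx"], dX)
            else:
                self.W_a -= lr * dW
                self.b_a -= lr * db
                self._scatter_embedding_grad(self.allele_table, cache["aidx"], dX)

    def _scatter_embedding_grad(
        self, table: EmbeddingTable, idx: np.ndarray, dX: np.ndarray
    ) -> None:
        B, n_words, n_sub = idx.shape
        d = table.dim
        M = table.matrix
        dword = dX.reshape(B, n_words, d)
        grads = np.repeat(dword.reshape(B * n_words, d), n_sub, axis=0)
        # bincount-based scatter-add (duplicate rows accumulate)
        flat = (idx.reshape(-1, 1) * d + np.arange(d)).ravel()
        acc = np.bincount(flat, weights=grads.ravel(), minlength=M.size).reshape(M.shape)
        M -= self.cfg.learning_rate * acc

    # ---------------- public API ----------------

    def predict(self, peptide: str, allele: str) -> float:
        """Deterministic (dropout-free) binding probability in (0, 1)."""
        return float(self.predict_batch([peptide], [allele])[0])

    def predict_batch(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        pidx = self.peptide_indices(peptides)
        aidx = self.allele_indices(alleles)
        p, _ = self._forward(pidx, aidx, train=False)
        return p

    def predict_records(self, records: Iterable[BindingRecord]) -> np.ndarray:
        records = list(records)
        return self.predict_batch([r.peptide for r in records], [r.allele for r in records])

    def allele_embedding(self, allele: str) -> np.ndarray:
        """Flattened word-embedding block of an allele (trained or not)."""
        aidx = self.allele_indices([allele])
        return self.allele_table.matrix[aidx[0]].sum(axis=1).ravel().copy()

    # ---------------- checkpointing ----------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "config": asdict(self.cfg),
            "panel": self.panel,
            "init_seed": self._init_seed,
            "epoch": self.epoch,
            "best_val_score": self.best_val_score,
        }
        meta["config"]["trunk_widths"] = list(self.cfg.trunk_widths)
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        self.pep_table.save_tsv(path / "pep_table.tsv")
        self.allele_table.save_tsv(path / "allele_table.tsv")
        arrays = {"W_p": self.W_p, "b_p": self.b_p, "W_a": self.W_a, "b_a": self.b_a,
                  "W_out": self.W_out, "b_out": self.b_out}
        for i, (W, b) in enumerate(self.trunk):
            arrays[f"trunk_W{i}"] = W
            arrays[f"trunk_b{i}"] = b
        np.savez(path / "weights.npz", **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BindingModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["trunk_widths"] = tuple(cfg_d["trunk_widths"])
        cfg = NetConfig(**cfg_d)
        pep_table = EmbeddingTable.load_tsv(path / "pep_table.tsv")
        allele_table = EmbeddingTable.load_tsv(path / "allele_table.tsv")
        model = cls(pep_table, allele_table, meta["panel"], cfg, seed=meta["init_seed"])
        with np.load(path / "weights.npz") as z:
            model.W_p, model.b_p = z["W_p"], z["b_p"]
            model.W_a, model.b_a = z["W_a"], z["b_a"]
            model.W_out, model.b_out = z["W_out"], z["b_out"]
            model.trunk = [
                (z[f"trunk_W{i}"], z[f"trunk_b{i}"]) for i in range(len(cfg.trunk_widths))
            ]
        model.epoch = meta["epoch"]
        model.best_val_score = meta["best_val_score"]
        return model

    def _snapshot(self):
        return (
            self.W_p.copy(), self.b_p.copy(), self.W_a.copy(), self.b_a.copy(),
            [(W.copy(), b.copy()) for W, b in self.trunk],
            self.W_out.copy(), self.b_out.copy(),
            self.pep_table.matrix.copy(), dict(self.pep_table._index),
            self.allele_table.matrix.copy(), dict(self.allele_table._index),
        )

    def _restore(self, snap) -> None:
        (self.W_p, self.b_p, self.W_a, self.b_a, trunk, self.W_out, self.b_out,
         pm, pi, am, ai) = snap
        self.trunk = [(W.copy(), b.copy()) for W, b in trunk]
        self.pep_table._matrix = pm.copy()
        self.pep_table._index = dict(pi)
        self.pep_table._word_cache = {}
        self.allele_table._matrix = am.copy()
        self.allele_table._index = dict(ai)
        self.allele_table._word_cache = {}


def build_model(
    pep_table: EmbeddingTable,
    allele_table: EmbeddingTable,
    allele_panel: Mapping[str, str],
    cfg: NetConfig = NetConfig(),
    seed: int = 0,
) -> BindingModel:
    return BindingModel(pep_table, allele_table, allele_panel, cfg, seed)


@dataclass
class TrainLog:
    rows: list[dict[str, float]] = field(default_factory=list)

    def append(self, **kw: float) -> None:
        self.rows.append(kw)

    def column(self, name: str) -> list[float]:
        return [r[name] for r in self.rows if name in r]


def _val_auc(model: BindingModel, records: Sequence[BindingRecord]) -> float:
    labels = np.asarray([r.label for r in records])
    scores = model.predict_records(records)
    return float(roc_auc_score(labels, scores))


def train_binding(
    model: BindingModel,
    positives: Sequence[BindingRecord],
    val_records: Sequence[BindingRecord],
    sampler: NegativeSampler,
    seed: int = 0,
    freeze_embeddings: bool = False,
) -> TrainLog:
    """Train on observed positives + per-batch regenerated negatives.

    ``val_records`` must contain both classes; early stopping monitors
    validation AUC with the configured patience and the best weights are
    restored at the end.
    """
    positives = [r for r in positives if r.label == 1]
    if not positives:
        raise ValueError("no positive training records")
    if len({r.label for r in val_records}) < 2:
        raise ValueError("validation records must contain both classes")
    cfg = model.cfg
    rng = np.random.default_rng(seed)
    log = TrainLog()
    best_auc, best_snap, stall = -np.inf, None, 0
    scatter = model._scatter_embedding_grad
    if freeze_embeddings:
        model._scatter_embedding_grad = lambda *a, **k: None

    # featurize the fixed records once; per-batch negatives are featurized fresh
    pos_pidx = model.peptide_indices([r.peptide for r in positives])
    pos_aidx = model.allele_indices([r.allele for r in positives])
    val_pidx = model.peptide_indices([r.peptide for r in val_records])
    val_aidx = model.allele_indices([r.allele for r in val_records])
    val_y = np.asarray([r.label for r in val_records])
    try:
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(positives))
            n_pos = max(1, int(cfg.batch_size / (1 + cfg.neg_pos_ratio)))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(positives), n_pos):
                take = order[start : start + n_pos]
                n_neg = max(1, int(round(len(take) * cfg.neg_pos_ratio)))
                negs = sampler.sample(n_neg)
                pidx = np.concatenate(
                    [pos_pidx[take], model.peptide_indices([r.peptide for r in negs])]
                )
                aidx = np.concatenate(
                    [pos_aidx[take], model.allele_indices([r.allele for r in negs])]
                )
                y = np.concatenate([np.ones(len(take)), np.zeros(n_neg)])
                p, cache = model._forward(pidx, aidx, train=True, rng=rng)
                eps = 1e-12
                loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
                model._backward(cache, (p - y) / len(y))
                epoch_loss += float(loss)
                n_batches += 1
            val_p, _ = model._forward(val_pidx, val_aidx, train=False)
            val_auc = float(roc_auc_score(val_y, val_p))
            log.append(epoch=epoch, train_loss=epoch_loss / n_batches, val_auc=val_auc)
            model.epoch = epoch + 1
            if val_auc > best_auc + 1e-6:
                best_auc, best_snap, stall = val_auc, model._snapshot(), 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    finally:
        model._scatter_embedding_grad = scatter
    if best_snap is not None:
        model._restore(best_snap)
        model.best_val_score = best_auc
    return log


def finetune_affinity(
    model: BindingModel,
    records: Sequence,
    val_records: Sequence,
    seed: int = 0,
    max_epochs: int | None = None,
) -> TrainLog:
    """Fine-tune on transformed binding affinity with mean-squared error.

    Targets must already be on the [0, 1] scale (1 - log_50000(IC50)); the
    sigmoid output doubles as the regression head.  Initialization can be a
    freshly built model (from scratch) or a binding-trained model (transfer).
    Early stopping monitors validation MSE.
    """
    if not records:
        raise ValueError("no affinity records")
    for r in list(records) + list(val_records):
        if not (0.0 <= r.target <= 1.0):
            raise ValueError(
                f"target {r.target} outside [0, 1]; pass transformed affinities, not raw IC50"
            )
    cfg = model.cfg
    records = list(records)
    rng = np.random.default_rng(seed)
    log = TrainLog()
    best_mse, best_snap, stall = np.inf, None, 0
    epochs = cfg.max_epochs if max_epochs is None else max_epochs
    all_pidx = model.peptide_indices([r.peptide for r in records])
    all_aidx = model.allele_indices([r.allele for r in records])
    all_y = np.asarray([r.target for r in records])
    val_pidx = model.peptide_indices([r.peptide for r in val_records])
    val_aidx = model.allele_indices([r.allele for r in val_records])
    val_y = np.asarray([r.target for r in val_records])
    for epoch in range(epochs):
        order = rng.permutation(len(records))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(records), cfg.batch_size):
            take = order[start : start + cfg.batch_size]
            y = all_y[take]
            p, cache = model._forward(all_pidx[take], all_aidx[take], train=True, rng=rng)
            loss = float(np.mean((p - y) ** 2))
            # d(MSE)/d(logit) = 2(p-y) * p(1-p) / B
            model._backward(cache, 2.0 * (p - y) * p * (1 - p) / len(y))
            epoch_loss += loss
            n_batches += 1
        val_p, _ = model._forward(val_pidx, val_aidx, train=False)
        val_mse = float(np.mean((val_p - val_y) ** 2))
        log.append(epoch=epoch, train_mse=epoch_loss / n_batches, val_mse=val_mse)
        model.epoch = epoch + 1
        if val_mse < best_mse - 1e-9:
            best_mse, best_snap, stall = val_mse, model._snapshot(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_snap is not None:
        model._restore(best_snap)
        model.best_val_score = best_mse
    return log
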