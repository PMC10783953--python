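"""Context-pair construction for skip-gram pre-training.

Two notions of context are supported.  Peptide words take their context from
the linear sequence: every word within a fixed window (default 3 words) of a
center word is a positive context.  Allele words take their context from
protein 3D structure: two words are in context when the minimum Cα–Cα
distance between any of their residues is below a threshold (default 45 Å).
Per-allele distance matrices are averaged into a single context matrix, and
only residue positions inside a usable window (default 24–301, the region
reliably present in structural models) contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .tokenizer import GAP_CHAR, TokenizedSequence


@dataclass(frozen=True)
class ContextConfig:
    """Context-definition parameters.

    seq_window : window half-width in words for sequence context (default 3).
    struct_threshold : Cα distance threshold in Å for structural context
        (default 45; a 5–65 Å grid in steps of 5 is the tuning range).
    residue_lo, residue_hi : 1-based inclusive residue positions bounding the
        usable part of the structural models (defaults 24 and 301).
    word_distance : how to reduce residue-level distances to a word-level
        distance; ``"min"`` (closest-contact, default) or ``"mean"``.
    """

    seq_window: int = 3
    struct_threshold: float = 45.0
    residue_lo: int = 24
    residue_hi: int = 301
    word_distance: Literal["min", "mean"] = "min"

    def __post_init__(self) -> None:
        if self.seq_window < 1:
            raise ValueError("seq_window must be >= 1")
        if self.struct_threshold <= 0:
            raise ValueError("struct_threshold must be positive")
        if self.residue_lo >= self.residue_hi:
            raise ValueError("residue_lo must be < residue_hi")


@dataclass
class DistanceMatrix:
    """Square symmetric Cα–Cα distance matrix with absent entries as NaN.

    ``positions`` are the 1-based residue numbers labelling rows/columns.
    """

    values: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        n = len(self.positions)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match positions")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("distances must be non-negative")

    def lookup(self, pos_a: int, pos_b: int) -> float:
        """Distance between two residue numbers; NaN if absent."""
        idx = {p: i for i, p in enumerate(self.positions)}
        if pos_a not in idx or pos_b not in idx:
            return float("nan")
        return float(self.values[idx[pos_a], idx[pos_b]])


@dataclass(frozen=True)
class ContextPairSet:
    """Deduplicated unordered positive (center, context) word pairs.

    Pairs are stored canonically (lexicographically ordered tuple) with no
    self-pairs; training expands each pair in both directions.
    """

    pairs: frozenset[tuple[str, str]]
    provenance: Literal["sequence", "structure"]

    @staticmethod
    def from_pairs(
        pairs: Iterable[tuple[str, str]],
        provenance: Literal["sequence", "structure"],
    ) -> "ContextPairSet":
        canon = {
            (a, b) if a < b else (b, a) for a, b in pairs if a != b
        }
        return ContextPairSet(pairs=frozenset(canon), provenance=provenance)

    def __len__(self) -> int:
        return len(self.pairs)


def sequence_context_pairs(
    tokens: TokenizedSequence, cfg: ContextConfig = ContextConfig()
) -> ContextPairSet:
    """Positive pairs from the linear sequence window.

    Word *i* is in context with word *j* when ``1 <= |i - j| <= seq_window``.
    """
    words = tokens.words
    if len(words) == 0:
        raise ValueError("tokenized sequence has no words")
    pairs = [
        (words[i], words[j])
        for i in range(len(words))
        for j in range(i + 1, min(i + cfg.seq_window, len(words) - 1) + 1)
    ]
    return ContextPairSet.from_pairs(pairs, "sequence")


def calpha_distance_matrix(
    coords: Mapping[int, Sequence[float]],
    cfg: ContextConfig = ContextConfig(),
) -> DistanceMatrix:
    """Pairwise Euclidean Cα–Cα distances for one structural model.

    ``coords`` maps 1-based residue numbers to (x, y, z) in Å.  Residues
    outside ``[residue_lo, residue_hi]`` are excluded; residues missing from
    the model simply have no row/column.
    """
    usable = sorted(p for p in coords if cfg.residue_lo <= p <= cfg.residue_hi)
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 usable residues in [{cfg.residue_lo}, "
            f"{cfg.residue_hi}]; got {len(usable)}"
        )
    xyz = np.asarray([coords[p] for p in usable], dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("coordinates must be finite")
    diff = xyz[:, None, :] - xyz[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(values=values, positions=np.asarray(usable))


def read_calpha_pdb(path: str | Path, chain: str | None = None) -> dict[int, tuple[float, float, float]]:
    """Extract Cα coordinates (residue number -> xyz) from a PDB file."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    coords: dict[int, tuple[float, float, float]] = {}
    model = next(structure.get_models())
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for residue in ch:
            if "CA" in residue:
                x, y, z = residue["CA"].coord
                coords[residue.id[1]] = (float(x), float(y), float(z))
    if not coords:
        raise ValueError(f"no CA atoms found in {path}" + (f" chain {chain}" if chain else ""))
    return coords


def read_distance_matrix_tsv(path: str | Path) -> DistanceMatrix:
    """Read a precomputed distance matrix (rows/columns = residue numbers)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    positions = df.index.to_numpy(dtype=int)
    if not np.array_equal(positions, df.columns.to_numpy(dtype=int)):
        raise ValueError("row and column residue numbers differ")
    return DistanceMatrix(values=df.to_numpy(dtype=float), positions=positions)


def write_distance_matrix_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(dm.values, index=dm.positions, columns=dm.positions).to_csv(
        path, sep="\t"
    )


def mean_distance_matrix(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise mean over matrices, averaging each entry over the models
    in which it is present (NaN-aware); entries present nowhere stay NaN."""
    if len(matrices) == 0:
        raise ValueError("need at least one distance matrix")
    all_pos = sorted({int(p) for dm in matrices for p in dm.positions})
    pos_index = {p: i for i, p in enumerate(all_pos)}
    n = len(all_pos)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for dm in matrices:
        rows = np.asarray([pos_index[int(p)] for p in dm.positions])
        present = np.isfinite(dm.values)
        sub = np.where(present, dm.values, 0.0)
        total[np.ix_(rows, rows)] += sub
        count[np.ix_(rows, rows)] += present
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    return DistanceMatrix(values=mean, positions=np.asarray(all_pos))


def word_residue_positions(
    tokens: TokenizedSequence, cfg: ContextConfig = ContextConfig()
) -> list[list[int]]:
    """Map each word to the structure residue numbers it covers.

    Aligned columns are mapped to residue numbers by ungapped residue count:
    gap columns consume no residue number.  Pad characters and residues
    outside ``[residue_lo, residue_hi]`` are dropped.
    """
    w = tokens.config.word_size
    residue_of_col: list[int | None] = []
    resnum = 0
    for ch in tokens.source:
        if ch == GAP_CHAR:
            residue_of_col.append(None)
        else:
            resnum += 1
            residue_of_col.append(resnum)
    out: list[list[int]] = []
    for i in range(len(tokens.words)):
        cols = range(i * w - tokens.pad_count, (i + 1) * w - tokens.pad_count)
        residues = [
            residue_of_col[c]
            for c in cols
            if 0 <= c < len(residue_of_col) and residue_of_col[c] is not None
        ]
        out.append([r for r in residues if cfg.residue_lo <= r <= cfg.residue_hi])
    return out


def structural_context_pairs(
    tokens: TokenizedSequence,
    dm: DistanceMatrix,
    cfg: ContextConfig = ContextConfig(),
) -> ContextPairSet:
    """Positive pairs from 3D structure.

    Two distinct words pair when the minimum (or mean, per config) present
    Cα distance between their residue sets is within ``struct_threshold``.
    Words with no residues in the usable window produce no pairs.
    """
    word_pos = word_residue_positions(tokens, cfg)
    if all(len(p) == 0 for p in word_pos):
        raise ValueError("no usable residues in the configured residue window")
    idx = {int(p): i for i, p in enumerate(dm.positions)}
    word_rows = [
        np.asarray([idx[p] for p in positions if p in idx], dtype=int)
        for positions in word_pos
    ]
    reduce = np.nanmin if cfg.word_distance == "min" else np.nanmean
    pairs: list[tuple[str, str]] = []
    n = len(tokens.words)
    for i in range(n):
        if word_rows[i].size == 0:
            continue
        for j in range(i + 1, n):
            if word_rows[j].size == 0:
                continue
            block = dm.values[np.ix_(word_rows[i], word_rows[j])]
            if np.all(np.isnan(block)):
                continue
            with np.errstate(invalid="ignore"):
                d = float(reduce(block))
            if d <= cfg.struct_threshold:
                pairs.append((tokens.words[i], tokens.words[j]))
    return ContextPairSet.from_pairs(pairs, "structure")
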