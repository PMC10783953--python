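"""Readers, cleaning rules, negative generation and the affinity transform.

Eluted-ligand (mass-spectrometry) data contain only positive peptide–HLA
pairs, so synthetic negatives are regenerated per training batch: a random
peptide is drawn by sampling its length from the empirical length
distribution of the bound peptides, sampling each residue uniformly over the
20 amino acids, and pairing it with a random allele from the panel.

Binding affinity (IC50, nM) is mapped to [0, 1] with 1 - log_50000(x),
clipped, so 1 nM -> 1.0 and 50000 nM -> 0.0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tokenizer import AMINO_ACIDS

IC50_MAX = 50000.0
EPITOPE_LENGTH_RANGE = (8, 15)

_ALLELE_RE = re.compile(
    r"^(?:HLA-?)?([A-Z]+[0-9]*)\*?(\d{2,3}):?(\d{2,3})", re.IGNORECASE
)


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    label: int
    source: str = "observed"  # observed | synthetic-negative


@dataclass(frozen=True)
class AffinityRecord:
    peptide: str
    allele: str
    ic50: float
    target: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive (nM)")
        if self.target is None:
            object.__setattr__(self, "target", transform_affinity(self.ic50))


@dataclass
class DatasetSplit:
    """Exact-peptide-disjoint train/validation/test partitions."""

    train: list
    validation: list
    test: list
    seed: int

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def normalize_allele(name: str) -> str:
    """Normalize HLA allele names to the two-field form, e.g. HLA-A*02:01.

    Raises ValueError for names without a full two-field specification
    (non-specific alleles such as "HLA class I" or "HLA-A2").
    """
    m = _ALLELE_RE.match(name.strip())
    if not m:
        raise ValueError(f"non-specific or malformed allele name: {name!r}")
    locus, f1, f2 = m.group(1).upper(), m.group(2), m.group(3)
    return f"HLA-{locus}*{int(f1):02d}:{int(f2):02d}"


def _check_peptide(pep: str) -> str:
    pep = pep.strip().upper()
    if not pep:
        raise ValueError("empty peptide")
    bad = [c for c in pep if c not in AMINO_ACIDS]
    if bad:
        raise ValueError(f"non-standard residue {bad[0]!r}")
    return pep


def read_pair_table(
    path: str | Path,
    kind: str = "binding",
    sep: str | None = None,
) -> tuple[list, pd.DataFrame]:
    """Read a peptide–HLA pair table (TSV/CSV).

    Requires columns ``peptide``, ``allele`` and ``label`` (binding) or
    ``ic50`` (affinity).  Returns (records, rejects) where rejects is a
    DataFrame of malformed rows with their 1-based line numbers and reasons.
    Duplicate (peptide, allele) rows collapse to one record.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    value_col = "label" if kind == "binding" else "ic50"
    missing = {"peptide", "allele", value_col} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    records: list = []
    rejects: list[dict] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            pep = _check_peptide(str(row["peptide"]))
            allele = normalize_allele(str(row["allele"]))
            if kind == "binding":
                label = int(row["label"])
                if label not in (0, 1):
                    raise ValueError(f"label must be 0 or 1, got {row['label']}")
                rec = BindingRecord(pep, allele, label)
            else:
                rec = AffinityRecord(pep, allele, float(row[value_col]))
        except (ValueError, TypeError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
            continue
        key = (pep, allele)
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)
    return records, pd.DataFrame(rejects, columns=["line", "reason"])


def clean_epitope_pairs(
    records: Iterable[BindingRecord],
    length_range: tuple[int, int] = EPITOPE_LENGTH_RANGE,
) -> tuple[list[BindingRecord], dict[str, int]]:
    """Apply epitope-data cleaning rules.

    Removes duplicate (peptide, allele) pairs, pairs carrying conflicting
    labels (both positive and negative observations), and peptides outside
    the 8–15 residue length range.  Returns the kept records and a manifest
    of counts removed per filter.  Idempotent.
    """
    records = list(records)
    labels: dict[tuple[str, str], set[int]] = {}
    for r in records:
        labels.setdefault((r.peptide, r.allele), set()).add(r.label)

    manifest = {"input": len(records), "duplicate": 0, "conflicting": 0, "length": 0}
    kept: list[BindingRecord] = []
    emitted: set[tuple[str, str]] = set()
    lo, hi = length_range
    for r in records:
        key = (r.peptide, r.allele)
        if key in emitted:
            manifest["duplicate"] += 1
            continue
        if len(labels[key]) > 1:
            manifest["conflicting"] += 1
            emitted.add(key)
            continue
        if not lo <= len(r.peptide) <= hi:
            manifest["length"] += 1
            emitted.add(key)
            continue
        emitted.add(key)
        kept.append(r)
    manifest["kept"] = len(kept)
    return kept, manifest


def transform_affinity(ic50: float | np.ndarray) -> float | np.ndarray:
    """Map IC50 in nM to [0, 1] via 1 - log_50000(ic50), clipped.

    Strictly decreasing on (0, 50000]; values above 50000 nM clip to 0.
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ic50 must be positive (nM)")
    out = np.clip(1.0 - np.log(arr) / math.log(IC50_MAX), 0.0, 1.0)
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def inverse_transform_affinity(target: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`transform_affinity` on [0, 1]: IC50 = 50000^(1-t)."""
    arr = np.asarray(target, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("target must be in [0, 1]")
    out = np.exp((1.0 - arr) * math.log(IC50_MAX))
    return float(out) if np.isscalar(target) or arr.ndim == 0 else out


def peptide_length_distribution(
    positives: Iterable[BindingRecord],
) -> dict[int, float]:
    """Empirical length distribution of bound peptides (sums to 1)."""
    lengths = [len(r.peptide) for r in positives]
    if not lengths:
        raise ValueError("no positive records")
    counts = pd.Series(lengths).value_counts().sort_index()
    freqs = counts / counts.sum()
    return {int(k): float(v) for k, v in freqs.items()}


class NegativeSampler:
    """Per-batch synthetic negative generator.

    Draws peptide length from the positives' length distribution, each
    residue uniformly over the 20 amino acids, and the allele uniformly over
    the panel.  Each call is a fresh draw.
    """

    def __init__(
        self,
        length_dist: dict[int, float],
        allele_panel: Sequence[str],
        seed: int = 0,
    ):
        if not length_dist:
            raise ValueError("empty length distribution")
        if not allele_panel:
            raise ValueError("empty allele panel")
        self._lengths = np.asarray(sorted(length_dist), dtype=int)
        probs = np.asarray([length_dist[int(l)] for l in self._lengths])
        self._probs = probs / probs.sum()
        self._panel = list(allele_panel)
        self._aa = np.asarray(sorted(AMINO_ACIDS))
        self._rng = np.random.default_rng(seed)

    def sample(self, n: int) -> list[BindingRecord]:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = self._rng
        lengths = rng.choice(self._lengths, size=n, p=self._probs)
        alleles = rng.choice(len(self._panel), size=n)
        out = []
        for length, ai in zip(lengths, alleles):
            pep = "".join(rng.choice(self._aa, size=int(length)))
            out.append(
                BindingRecord(pep, self._panel[int(ai)], 0, source="synthetic-negative")
            )
        return out


def sample_negative_batch(
    length_dist: dict[int, float],
    allele_panel: Sequence[str],
    n: int,
    seed: int,
) -> list[BindingRecord]:
    """One-shot form of :class:`NegativeSampler` (fresh draw per call)."""
    return NegativeSampler(length_dist, allele_panel, seed=seed).sample(n)


def split_dataset(
    records: Sequence,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Split records into peptide-disjoint train/validation/test partitions.

    All records sharing a peptide string land in the same partition, so no
    sequence leaks across partitions.  Peptide groups are shuffled (seeded)
    and assigned to fill the requested fractions of records.
    """
    if len(records) == 0:
        raise ValueError("no records to split")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(r.peptide, []).append(r)
    rng = np.random.default_rng(seed)
    peptides = sorted(groups)
    rng.shuffle(peptides)

    total = len(records)
    targets = [f * total for f in fractions]
    parts: list[list] = [[], [], []]
    counts = [0.0, 0.0, 0.0]
    for pep in peptides:
        # assign to the partition furthest below its target
        deficits = [targets[i] - counts[i] for i in range(3)]
        i = int(np.argmax(deficits))
        parts[i].extend(groups[pep])
        counts[i] += len(groups[pep])
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)


def read_aligned_fasta(path: str | Path) -> tuple[dict[str, str], int]:
    """Read a multiple-sequence-aligned FASTA of allele protein sequences.

    Returns (allele name -> uppercased aligned sequence, column count).
    All sequences must have the same length.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    n_cols: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if n_cols is None:
            n_cols = len(seq)
        elif len(seq) != n_cols:
            raise ValueError(
                f"ragged alignment: {rec.id} has {len(seq)} columns, expected {n_cols}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs, int(n_cols)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Tabular view of binding or affinity records."""
    return pd.DataFrame([r.__dict__ for r in records])


def write_pair_table(records: Iterable, path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
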