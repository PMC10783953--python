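"""Synthetic fixtures: pseudo-allele panels with planted binding motifs.

Generates everything the pipeline consumes without downloads: families of
aligned pseudo-allele sequences, helix-like Cα backbones (ideal α-helix
geometry, ~3.8 Å between consecutive Cα), position-specific binding motifs
with anchor positions, eluted-ligand-style positive/decoy pair tables,
affinity tables whose IC50 tracks motif match, and a random-protein 9-mer
corpus with overlapping windows (emulating permissive proteasomal cleavage,
which densely samples every protein region).

Every generator is a pure function of its parameters and seed.  A family's
alleles share a motif and a near-identical sequence/structure (<= 5% mutated
columns, small coordinate jitter); per family one allele is designated
"low-data" (a tenth of the positives) and one "zero-shot" (no positives) to
exercise the low-data and transfer evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import AffinityRecord, BindingRecord, inverse_transform_affinity
from .tokenizer import AMINO_ACIDS

AA_ORDER = sorted(AMINO_ACIDS)
DEFAULT_LENGTH_DIST = {8: 0.15, 9: 0.55, 10: 0.20, 11: 0.10}
MOTIF_LENGTH = 9
ANCHOR_POSITIONS = (1, 8)  # 0-based: position 2 and the C-terminus of a 9-mer


@dataclass
class Motif:
    """Per-position residue preference weights for a 9-mer binding motif.

    ``weights`` is (9, 20) over the alphabetically ordered amino acids; each
    row sums to 1.  Anchor positions carry most of their mass on two
    residues.  Peptides of length 8–11 map their first two and last position
    onto motif columns 1–2 and 9; interior positions spread over columns 3–8.
    """

    weights: np.ndarray
    anchors: tuple[int, ...] = ANCHOR_POSITIONS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (MOTIF_LENGTH, len(AA_ORDER)):
            raise ValueError(f"weights must be ({MOTIF_LENGTH}, {len(AA_ORDER)})")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("each position's weights must sum to 1")

    @staticmethod
    def column_map(length: int) -> list[int]:
        """Motif column for each position of a peptide of the given length."""
        if length < 8:
            raise ValueError("motif peptides are at least 8 residues")
        interior = length - 3
        cols = [0, 1]
        cols += [2 + min(5, (j * 6) // interior) for j in range(interior)]
        cols.append(8)
        return cols

    def sample_peptide(self, length: int, rng: np.random.Generator) -> str:
        cols = self.column_map(length)
        return "".join(
            AA_ORDER[int(rng.choice(len(AA_ORDER), p=self.weights[c]))] for c in cols
        )

    def score(self, peptide: str) -> float:
        """Log-likelihood ratio of the peptide under the motif vs uniform."""
        cols = self.column_map(len(peptide))
        uniform = 1.0 / len(AA_ORDER)
        eps = 1e-9
        return float(
            sum(
                math.log((self.weights[c][AA_ORDER.index(aa)] + eps) / uniform)
                for c, aa in zip(cols, peptide)
            )
        )


@dataclass(frozen=True)
class SyntheticAllele:
    name: str
    family: int
    aligned_seq: str
    coords: dict[int, tuple[float, float, float]]
    role: str  # full | low_data | zero_shot


@dataclass
class SyntheticPanel:
    alleles: list[SyntheticAllele]
    motifs: dict[int, Motif]  # family -> motif
    n_columns: int
    seed: int

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    @property
    def aligned(self) -> dict[str, str]:
        return {a.name: a.aligned_seq for a in self.alleles}

    def motif_of(self, allele_name: str) -> Motif:
        fam = next(a.family for a in self.alleles if a.name == allele_name)
        return self.motifs[fam]

    def family_of(self, allele_name: str) -> int:
        return next(a.family for a in self.alleles if a.name == allele_name)


def _helix_coords(
    n_residues: int, rng: np.random.Generator, jitter: float = 0.2
) -> dict[int, tuple[float, float, float]]:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å, 100° per residue."""
    radius, rise, turn = 2.3, 1.5, math.radians(100.0)
    out = {}
    noise = rng.normal(0.0, jitter, (n_residues, 3))
    for i in range(n_residues):
        x = radius * math.cos(i * turn) + noise[i, 0]
        y = radius * math.sin(i * turn) + noise[i, 1]
        z = rise * i + noise[i, 2]
        out[i + 1] = (float(x), float(y), float(z))
    return out


def _random_motif(rng: np.random.Generator) -> Motif:
    n_aa = len(AA_ORDER)
    weights = np.empty((MOTIF_LENGTH, n_aa))
    for pos in range(MOTIF_LENGTH):
        if pos in ANCHOR_POSITIONS:
            w = np.full(n_aa, 0.10 / (n_aa - 2))
            picks = rng.choice(n_aa, size=2, replace=False)
            w[picks] = 0.45
        else:
            w = rng.dirichlet(np.full(n_aa, 0.5))
        weights[pos] = w / w.sum()
    return Motif(weights=weights)


def gen_panel(
    n_families: int = 2,
    alleles_per_family: int = 3,
    n_columns: int = 72,
    seed: int = 0,
    mutation_fraction: float = 0.05,
) -> SyntheticPanel:
    """Generate families of aligned pseudo-alleles with helix-like backbones.

    Within a family, each allele mutates at most ``mutation_fraction`` of the
    base sequence's columns and jitters the base backbone slightly; families
    are independent draws, so between-family identity is at chance level.
    """
    if n_columns < 30:
        raise ValueError("n_columns must be >= 30")
    if n_families < 1 or alleles_per_family < 1:
        raise ValueError("need at least one family and one allele per family")
    rng = np.random.default_rng(seed)
    alleles: list[SyntheticAllele] = []
    motifs: dict[int, Motif] = {}
    n_mut = max(1, int(mutation_fraction * n_columns))
    for fam in range(n_families):
        base = "".join(rng.choice(AA_ORDER, size=n_columns))
        base_xyz = _helix_coords(n_columns, rng, jitter=0.0)
        motifs[fam] = _random_motif(rng)
        for ai in range(alleles_per_family):
            seq = list(base)
            for col in rng.choice(n_columns, size=n_mut, replace=False):
                seq[col] = str(rng.choice(AA_ORDER))
            # small enough that consecutive Ca spacing stays ~3.8 +/- 0.2 A
            jitter = rng.normal(0.0, 0.05, (n_columns, 3))
            coords = {
                p: (x + jitter[p - 1, 0], y + jitter[p - 1, 1], z + jitter[p - 1, 2])
                for p, (x, y, z) in base_xyz.items()
            }
            if alleles_per_family >= 3 and ai == alleles_per_family - 1:
                role = "zero_shot"
            elif alleles_per_family >= 3 and ai == alleles_per_family - 2:
                role = "low_data"
            else:
                role = "full"
            alleles.append(
                SyntheticAllele(
                    name=f"HLA-F{fam + 1}*{ai + 1:02d}:01",
                    family=fam,
                    aligned_seq="".join(seq),
                    coords=coords,
                    role=role,
                )
            )
    return SyntheticPanel(alleles=alleles, motifs=motifs, n_columns=n_columns, seed=seed)


def _sample_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    lengths = np.asarray(sorted(DEFAULT_LENGTH_DIST))
    probs = np.asarray([DEFAULT_LENGTH_DIST[int(l)] for l in lengths])
    return rng.choice(lengths, size=n, p=probs)


def gen_binding_data(
    panel: SyntheticPanel,
    n_pos_per_allele: int = 200,
    decoy_ratio: float = 1.0,
    seed: int = 0,
) -> list[BindingRecord]:
    """Planted-motif positives plus uniform-random labeled decoys.

    "full" alleles receive ``n_pos_per_allele`` positives, "low_data" alleles
    a tenth of that, "zero_shot" alleles none.  Each allele also receives
    ``decoy_ratio`` times its positive count of uniform decoys (label 0).
    """
    if not panel.alleles:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    records: list[BindingRecord] = []
    for allele in panel.alleles:
        n_pos = {
            "full": n_pos_per_allele,
            "low_data": max(1, n_pos_per_allele // 10),
            "zero_shot": 0,
        }[allele.role]
        motif = panel.motifs[allele.family]
        for length in _sample_lengths(rng, n_pos):
            records.append(
                BindingRecord(motif.sample_peptide(int(length), rng), allele.name, 1)
            )
        n_dec = int(round(n_pos * decoy_ratio))
        for length in _sample_lengths(rng, n_dec):
            pep = "".join(rng.choice(AA_ORDER, size=int(length)))
            records.append(
                BindingRecord(pep, allele.name, 0, source="synthetic-negative")
            )
    return records


def sample_allele_records(
    panel: SyntheticPanel,
    allele_name: str,
    n_pos: int,
    n_dec: int,
    seed: int = 0,
    exclude_peptides: Sequence[str] = (),
) -> list[BindingRecord]:
    """Fresh motif positives + uniform decoys for one allele (evaluation sets).

    Peptides in ``exclude_peptides`` (e.g. the training set) are rejected and
    resampled, so the result is disjoint from them.
    """
    motif = panel.motif_of(allele_name)
    rng = np.random.default_rng(seed)
    banned = set(exclude_peptides)
    out: list[BindingRecord] = []
    for label, n in ((1, n_pos), (0, n_dec)):
        made = 0
        while made < n:
            length = int(_sample_lengths(rng, 1)[0])
            if label == 1:
                pep = motif.sample_peptide(length, rng)
            else:
                pep = "".join(rng.choice(AA_ORDER, size=length))
            if pep in banned:
                continue
            banned.add(pep)
            src = "observed" if label == 1 else "synthetic-negative"
            out.append(BindingRecord(pep, allele_name, label, source=src))
            made += 1
    return out


def gen_affinity_data(
    panel: SyntheticPanel, n: int = 1000, seed: int = 0
) -> list[AffinityRecord]:
    """Affinity pairs whose IC50 tracks motif match.

    Half the peptides are motif-sampled, half uniform; the transformed
    target is centered on an affine function of the (squashed) motif score
    with uniform noise, then mapped back to IC50 in [1, 50000] nM.
    """
    if not panel.alleles:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    out: list[AffinityRecord] = []
    for _ in range(n):
        allele = panel.alleles[int(rng.integers(len(panel.alleles)))]
        motif = panel.motifs[allele.family]
        length = int(_sample_lengths(rng, 1)[0])
        if rng.random() < 0.5:
            pep = motif.sample_peptide(length, rng)
        else:
            pep = "".join(rng.choice(AA_ORDER, size=length))
        z = 1.0 / (1.0 + math.exp(-motif.score(pep) / 4.0))
        target = float(np.clip(0.15 + 0.7 * z + rng.uniform(-0.15, 0.15), 0.0, 1.0))
        ic50 = float(np.clip(inverse_transform_affinity(target), 1.0, 50000.0))
        out.append(AffinityRecord(pep, allele.name, ic50))
    return out


def gen_peptide_corpus(
    n_proteins: int = 50, protein_length: int = 50, seed: int = 0
) -> list[str]:
    """All overlapping 9-mers of random proteins (L - 8 windows each)."""
    if protein_length < 9:
        raise ValueError("protein_length must be >= 9")
    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    for _ in range(n_proteins):
        protein = "".join(rng.choice(AA_ORDER, size=protein_length))
        peptides.extend(
            protein[i : i + 9] for i in range(protein_length - 9 + 1)
        )
    return peptides


# ---------------- file writers (the formats the real pipeline reads) ----------------

def write_aligned_fasta(panel: SyntheticPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in panel.alleles:
            fh.write(f">{a.name}\n{a.aligned_seq}\n")


def write_calpha_pdb(
    coords: dict[int, tuple[float, float, float]], path: str | Path
) -> None:
    """Minimal PDB with one CA ATOM record per residue (chain A, ALA)."""
    with open(path, "w") as fh:
        for serial, (resnum, (x, y, z)) in enumerate(sorted(coords.items()), 1):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_panel_pdbs(panel: SyntheticPanel, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for a in panel.alleles:
        p = out_dir / (a.name.replace("*", "_").replace(":", "") + ".pdb")
        write_calpha_pdb(a.coords, p)
        paths.append(p)
    return paths


def write_corpus(peptides: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(peptides) + "\n")
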