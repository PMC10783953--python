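"""Metrics and stratified evaluation.

Reports ROC AUC, area under the precision–recall curve (average-precision,
step-wise convention) and the TPR/F1 reached at a false-discovery-rate
operating point (default 5%, optionally 1%): among score thresholds whose
precision is at least 1 - FDR, the one maximizing recall is chosen.  Two
stratifications probe generalization: alleles with fewer than 200 positive
training peptides ("low-data" alleles), and test peptides binned by their
minimum Levenshtein distance to any training peptide (<=2, 3, 4, >=5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import BindingRecord

EDIT_DISTANCE_BINS = ("<=2", "3", "4", ">=5")


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute this metric")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise area under the precision–recall curve)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def tpr_f1_at_fdr(
    scores: Sequence[float],
    labels: Sequence[int],
    fdr_level: float = 0.05,
) -> tuple[float, float, float, bool]:
    """TPR, F1 and threshold at the FDR operating point.

    Among all thresholds achieving precision >= 1 - fdr_level, pick the one
    maximizing recall (ties go to the lower threshold).  Returns
    (tpr, f1, threshold, achievable); if no threshold reaches the required
    precision, (0, 0, +inf, False) is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    n_pred = np.arange(1, len(y) + 1)
    precision = tp / n_pred
    n_pos = int((labels == 1).sum())
    recall = tp / n_pos
    # only threshold at distinct score cut-points (include all tied scores)
    cut = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    ok = cut[precision[cut] >= 1.0 - fdr_level]
    if ok.size == 0:
        return 0.0, 0.0, float("inf"), False
    best = ok[np.argmax(recall[ok])]
    if recall[ok].max() > 0:
        # lower threshold wins recall ties
        best = ok[np.nonzero(recall[ok] == recall[ok].max())[0][-1]]
    tpr = float(recall[best])
    prec = float(precision[best])
    f1 = 0.0 if tpr + prec == 0 else 2 * prec * tpr / (prec + tpr)
    return tpr, float(f1), float(s[best]), True


def low_data_allele_subset(
    test_records: Sequence[BindingRecord],
    train_records: Sequence[BindingRecord],
    min_positives: int = 200,
) -> tuple[list[BindingRecord], list[str]]:
    """Test records whose allele has < min_positives positive training peptides."""
    counts: dict[str, int] = {}
    for r in train_records:
        if r.label == 1:
            counts[r.allele] = counts.get(r.allele, 0) + 1
    alleles = sorted(
        {r.allele for r in test_records if counts.get(r.allele, 0) < min_positives}
    )
    subset = [r for r in test_records if r.allele in set(alleles)]
    return subset, alleles


def min_edit_distance(peptide: str, train_peptides: Sequence[str]) -> int:
    """Minimum Levenshtein distance from a peptide to any training peptide."""
    if not train_peptides:
        raise ValueError("empty training set")
    return min(
        edlib.align(peptide, t, task="distance", mode="NW")["editDistance"]
        for t in train_peptides
    )


def edit_distance_bin(d: int) -> str:
    if d <= 2:
        return "<=2"
    if d >= 5:
        return ">=5"
    return str(d)


def min_edit_distance_strata(
    test_peptides: Iterable[str],
    train_peptides: Sequence[str],
) -> dict[str, str]:
    """Bin each test peptide by minimum edit distance to the training set."""
    train_peptides = list(train_peptides)
    if not train_peptides:
        raise ValueError("empty training set")
    return {
        pep: edit_distance_bin(min_edit_distance(pep, train_peptides))
        for pep in set(test_peptides)
    }


@dataclass
class EvalReport:
    """Metrics over pooled scores plus per-stratum breakdowns."""

    auc: float
    auprc: float
    tpr_at_fdr: float
    f1_at_fdr: float
    fdr_level: float
    fdr_achievable: bool
    threshold: float
    n_records: int
    strata: dict[str, dict] = field(default_factory=dict)
    secondary_fdr: dict[str, float | bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "tpr_at_fdr": self.tpr_at_fdr,
            "f1_at_fdr": self.f1_at_fdr,
            "fdr_level": self.fdr_level,
            "fdr_achievable": self.fdr_achievable,
            "threshold": self.threshold,
            "n_records": self.n_records,
            "secondary_fdr": self.secondary_fdr,
            "strata": self.strata,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _metric_block(scores: np.ndarray, labels: np.ndarray, fdr_level: float) -> dict:
    if len(np.unique(labels)) < 2:
        return {"n": int(len(labels)), "auc": None, "auprc": None,
                "tpr_at_fdr": None, "f1_at_fdr": None}
    tpr, f1, _, ok = tpr_f1_at_fdr(scores, labels, fdr_level)
    return {
        "n": int(len(labels)),
        "auc": roc_auc(scores, labels),
        "auprc": auprc(scores, labels),
        "tpr_at_fdr": tpr,
        "f1_at_fdr": f1,
        "fdr_achievable": ok,
    }


def evaluate(
    scores: Sequence[float],
    test_records: Sequence[BindingRecord],
    train_records: Sequence[BindingRecord] | None = None,
    fdr_level: float = 0.05,
    low_data_min_positives: int = 200,
    secondary_fdr_level: float = 0.01,
) -> EvalReport:
    """Full evaluation: pooled metrics + low-data-allele and edit-distance strata.

    The FDR threshold is computed globally over pooled scores; the 5% point
    is primary and the 1% point is reported alongside.  Stratified
    breakdowns require ``train_records`` and are skipped otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([r.label for r in test_records])
    if len(scores) != len(labels):
        raise ValueError("scores and records length mismatch")
    tpr, f1, thr, ok = tpr_f1_at_fdr(scores, labels, fdr_level)
    report = EvalReport(
        auc=roc_auc(scores, labels),
        auprc=auprc(scores, labels),
        tpr_at_fdr=tpr,
        f1_at_fdr=f1,
        fdr_level=fdr_level,
        fdr_achievable=ok,
        threshold=thr,
        n_records=len(labels),
    )
    tpr2, f12, _, ok2 = tpr_f1_at_fdr(scores, labels, secondary_fdr_level)
    report.secondary_fdr = {
        "fdr_level": secondary_fdr_level,
        "tpr_at_fdr": tpr2,
        "f1_at_fdr": f12,
        "fdr_achievable": ok2,
    }
    if train_records is not None:
        subset, alleles = low_data_allele_subset(
            test_records, train_records, low_data_min_positives
        )
        mask = np.asarray([r.allele in set(alleles) for r in test_records])
        report.strata["low_data_alleles"] = {
            "alleles": alleles,
            **_metric_block(scores[mask], labels[mask], fdr_level),
        }
        train_peps = sorted({r.peptide for r in train_records})
        bins = min_edit_distance_strata(
            [r.peptide for r in test_records], train_peps
        )
        by_bin: dict[str, dict] = {}
        rec_bins = np.asarray([bins[r.peptide] for r in test_records])
        for b in EDIT_DISTANCE_BINS:
            m = rec_bins == b
            if m.any():
                by_bin[b] = _metric_block(scores[m], labels[m], fdr_level)
        report.strata["edit_distance"] = by_bin
    return report


def curve_frames(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC (fpr/tpr) and precision–recall (recall/precision) curve tables."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return (
        pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pd.DataFrame({"recall": rec, "precision": prec}),
    )


def export_allele_embeddings(model, alleles: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-allele flattened word-embedding blocks as a table.

    Covers every allele in the model's aligned panel, including alleles with
    no ligand training data (the aligned sequence suffices).
    """
    names = sorted(model.panel) if alleles is None else list(alleles)
    rows = [model.allele_embedding(a) for a in names]
    mat = np.asarray(rows)
    return pd.DataFrame(mat, index=names,
                        columns=[f"d{i}" for i in range(mat.shape[1])])
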