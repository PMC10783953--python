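import numpy as np
import pytest

import pepmhc as pm
from pepmhc.data import BindingRecord
from pepmhc.evaluation import EDIT_DISTANCE_BINS, edit_distance_bin


def pairwise_auc_oracle(scores, labels):
    """AUC as the probability a random positive outranks a random negative."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_oracle(scores, labels):
    """Step-wise AP: sum over distinct thresholds of (delta recall) x precision,
    treating tied scores as a single operating point."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(y.sum())
    total = 0.0
    prev_tp = 0
    for thr in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= thr
        tp = int((y[pred] == 1).sum())
        precision = tp / int(pred.sum())
        total += (tp - prev_tp) / n_pos * precision
        prev_tp = tp
    return total


def fdr_point_oracle(scores, labels, fdr):
    """Exhaustive search over all score cut-points."""
    best = (0.0, 0.0, float("inf"), False)
    n_pos = sum(labels)
    for thr in sorted(set(scores)):
        pred = [s >= thr for s in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        fp = sum(p and not l for p, l in zip(pred, labels))
        if tp + fp == 0:
            continue
        prec = tp / (tp + fp)
        rec = tp / n_pos
        if prec >= 1 - fdr and (rec, -thr) >= (best[0], -best[2]):
            f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            best = (rec, f1, thr, True)
    return best


def dp_edit_distance(a, b):
    m, n = len(a), len(b)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[m, n])


class TestRocAuc:
    def test_perfect_separation(self):
        assert pm.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example_two_thirds(self):
        assert pm.roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 1]) == pytest.approx(2 / 3)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert pm.roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pm.roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pairwise_oracle_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(10, 500))
        scores = rng.integers(0, 10, n) / 10.0  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert pm.roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels)
        )


class TestAuprc:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_average_precision_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 300))
        scores = rng.random(n)  # distinct scores: AP convention is exact
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert pm.auprc(scores, labels) == pytest.approx(
            average_precision_oracle(scores, labels)
        )


class TestTprF1AtFdr:
    def test_perfect_classifier(self):
        tpr, f1, thr, ok = pm.tpr_f1_at_fdr([0.9, 0.8, 0.1], [1, 1, 0], 0.05)
        assert (tpr, f1, ok) == (1.0, 1.0, True)

    def test_hand_worked_case(self):
        tpr, f1, thr, ok = pm.tpr_f1_at_fdr(
            [0.9, 0.8, 0.7, 0.6, 0.5], [1, 1, 0, 1, 0], 0.05
        )
        assert thr == pytest.approx(0.8)
        assert tpr == pytest.approx(2 / 3)
        assert f1 == pytest.approx(0.8)
        assert ok

    def test_inverted_classifier_flagged(self):
        tpr, f1, thr, ok = pm.tpr_f1_at_fdr([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.05)
        assert not ok and tpr == 0.0

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_threshold_search(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(8, 200))
        scores = (rng.integers(0, 20, n) / 20.0).tolist()
        labels = rng.integers(0, 2, n).tolist()
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        fdr = float(rng.choice([0.01, 0.05, 0.2]))
        tpr, f1, thr, ok = pm.tpr_f1_at_fdr(scores, labels, fdr)
        otpr, of1, othr, ook = fdr_point_oracle(scores, labels, fdr)
        assert ok == ook
        if ok:
            assert tpr == pytest.approx(otpr)
            assert f1 == pytest.approx(of1)
            assert thr == pytest.approx(othr)


class TestLowDataSubset:
    def _train(self, counts):
        out = []
        for allele, n in counts.items():
            for i in range(n):
                out.append(BindingRecord(f"ACDEFGHI{'K' * (i % 3 + 1)}", allele, 1))
        return out

    def test_threshold_is_strictly_less_than_200(self):
        train = []
        for allele, n in [("HLA-A*01:01", 199), ("HLA-A*02:01", 200)]:
            train += [
                BindingRecord("ACDEFGHIK", allele, 1, source=f"r{i}") for i in range(n)
            ]
        test = [
            BindingRecord("KLMNPQRST", "HLA-A*01:01", 1),
            BindingRecord("KLMNPQRST", "HLA-A*02:01", 1),
        ]
        subset, alleles = pm.low_data_allele_subset(test, train)
        assert alleles == ["HLA-A*01:01"]
        assert len(subset) == 1

    def test_empty_training_set_includes_everything(self):
        test = [BindingRecord("ACDEFGHIK", "HLA-A*01:01", 1)]
        subset, alleles = pm.low_data_allele_subset(test, [])
        assert subset == test

    def test_counts_match_groupby_oracle(self):
        rng = np.random.default_rng(9)
        aas = sorted(pm.tokenize("ACD").config.alphabet)
        alleles = [f"HLA-A*{i:02d}:01" for i in range(1, 6)]
        train = [
            BindingRecord(
                "".join(rng.choice(aas, 9)),
                alleles[int(rng.integers(5))],
                int(rng.integers(2)),
            )
            for _ in range(1000)
        ]
        test = [
            BindingRecord("".join(rng.choice(aas, 9)), alleles[int(rng.integers(5))], 1)
            for _ in range(200)
        ]
        min_pos = 100
        subset, low = pm.low_data_allele_subset(test, train, min_positives=min_pos)
        expected_low = {
            a
            for a in alleles
            if sum(r.allele == a and r.label == 1 for r in train) < min_pos
        }
        assert set(low) <= expected_low
        assert all(r.allele in expected_low for r in subset)


class TestEditDistance:
    def test_identical_peptide_distance_zero(self):
        assert pm.min_edit_distance("ACDEFGHIK", ["ACDEFGHIK", "KLMNPQRST"]) == 0

    def test_single_substitution(self):
        assert pm.min_edit_distance("AAAAAAAAA", ["AAAAAAAAT"]) == 1

    def test_kitten_sitting_classic(self):
        assert pm.min_edit_distance("kitten", ["sitting"]) == 3

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            pm.min_edit_distance("ACDEFGHIK", [])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dp_oracle_on_random_pairs(self, trial):
        rng = np.random.default_rng(300 + trial)
        aas = sorted(pm.tokenize("ACD").config.alphabet)
        for _ in range(20):
            a = "".join(rng.choice(aas, rng.integers(8, 16)))
            b = "".join(rng.choice(aas, rng.integers(8, 16)))
            assert pm.min_edit_distance(a, [b]) == dp_edit_distance(a, b)

    def test_binning_matches_convention(self):
        assert [edit_distance_bin(d) for d in [0, 2, 3, 4, 5, 9]] == [
            "<=2", "<=2", "3", "4", ">=5", ">=5",
        ]
        assert set(EDIT_DISTANCE_BINS) == {"<=2", "3", "4", ">=5"}

    def test_strata_minimize_over_training_set(self):
        strata = pm.min_edit_distance_strata(
            ["ACDEFGHIK"], ["ACDEFGHIV", "WWWWWWWWW"]
        )
        assert strata["ACDEFGHIK"] == "<=2"  # distance 1 to the near neighbour


class TestEvaluateReport:
    def _scored(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        records, scores = [], []
        aas = sorted(pm.tokenize("ACD").config.alphabet)
        for i in range(n):
            label = int(rng.integers(2))
            allele = f"HLA-A*{int(rng.integers(1, 4)):02d}:01"
            records.append(
                BindingRecord("".join(rng.choice(aas, 9)), allele, label)
            )
            scores.append(float(np.clip(0.5 * label + rng.normal(0.3, 0.2), 0, 1)))
        return scores, records

    def test_report_fields_and_ranges(self):
        scores, records = self._scored()
        train = records[:150]
        report = pm.evaluate(scores[150:], records[150:], train)
        d = report.to_dict()
        for key in ("auc", "auprc", "tpr_at_fdr", "f1_at_fdr"):
            assert 0.0 <= d[key] <= 1.0
        assert "low_data_alleles" in d["strata"]
        assert "edit_distance" in d["strata"]
        assert d["fdr_level"] == 0.05
        assert d["secondary_fdr"]["fdr_level"] == 0.01

    def test_stratum_sizes_sum_to_test_size(self):
        scores, records = self._scored(300, seed=2)
        report = pm.evaluate(scores[100:], records[100:], records[:100])
        ed = report.strata["edit_distance"]
        assert sum(block["n"] for block in ed.values()) == 200

    def test_one_percent_fdr_level_supported(self):
        scores, records = self._scored(200, seed=3)
        report = pm.evaluate(scores, records, fdr_level=0.01)
        assert report.fdr_level == 0.01

    def test_length_mismatch_rejected(self):
        scores, records = self._scored(50, seed=4)
        with pytest.raises(ValueError):
            pm.evaluate(scores[:-1], records)
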