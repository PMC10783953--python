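import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pepmhc as pm
from pepmhc.data import BindingRecord, records_to_frame


class TestReadPairTable:
    def _write(self, tmp_path, rows, header="peptide\tallele\tlabel"):
        path = tmp_path / "pairs.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_well_formed_rows_parsed(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ACDEFGHIK\tHLA-A*02:01\t1",
             "KLMNPQRST\thla-a0201\t0",
             "ACDEFGHIV\tHLA-B*57:01\t1"],
        )
        records, rejects = pm.read_pair_table(path)
        assert len(records) == 3 and len(rejects) == 0
        assert records[1].allele == "HLA-A*02:01"  # normalized

    def test_nonstandard_residue_rejected_with_line_number(self, tmp_path):
        path = self._write(tmp_path, ["ABCX*\tHLA-A*02:01\t1"])
        records, rejects = pm.read_pair_table(path)
        assert len(records) == 0
        assert rejects.iloc[0]["line"] == 2
        assert "non-standard residue" in rejects.iloc[0]["reason"]

    def test_duplicate_pairs_collapse(self, tmp_path):
        path = self._write(
            tmp_path,
            ["ACDEFGHIK\tHLA-A*02:01\t1", "ACDEFGHIK\tHLA-A*02:01\t1"],
        )
        records, _ = pm.read_pair_table(path)
        assert len(records) == 1

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, ["ACDEFGHIK\t1"], header="peptide\tlabel")
        with pytest.raises(ValueError, match="allele"):
            pm.read_pair_table(path)

    def test_affinity_kind_builds_transformed_targets(self, tmp_path):
        path = self._write(
            tmp_path, ["ACDEFGHIK\tHLA-A*02:01\t500"], header="peptide\tallele\tic50"
        )
        records, _ = pm.read_pair_table(path, kind="affinity")
        assert records[0].target == pytest.approx(0.4256, abs=1e-4)


class TestNormalizeAllele:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("HLA-A*02:01", "HLA-A*02:01"),
            ("hla-a0201", "HLA-A*02:01"),
            ("A*02:01", "HLA-A*02:01"),
            ("HLA-B5701", "HLA-B*57:01"),
        ],
    )
    def test_two_field_normalization(self, raw, expected):
        assert pm.normalize_allele(raw) == expected

    @pytest.mark.parametrize("raw", ["HLA class I", "HLA-A2", ""])
    def test_non_specific_names_rejected(self, raw):
        with pytest.raises(ValueError):
            pm.normalize_allele(raw)


class TestCleanEpitopePairs:
    def test_conflicting_labels_removed_entirely(self):
        recs = [
            BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1),
            BindingRecord("ACDEFGHIK", "HLA-A*02:01", 0),
            BindingRecord("KLMNPQRST", "HLA-A*02:01", 1),
        ]
        kept, manifest = pm.clean_epitope_pairs(recs)
        assert [r.peptide for r in kept] == ["KLMNPQRST"]
        assert manifest["conflicting"] == 1

    def test_length_rule_is_inclusive_8_to_15(self):
        recs = [
            BindingRecord("ACDEFGH", "HLA-A*02:01", 1),            # 7-mer: out
            BindingRecord("ACDEFGHI", "HLA-A*02:01", 1),           # 8-mer: in
            BindingRecord("ACDEFGHIKLMNPQR", "HLA-A*02:01", 1),    # 15-mer: in
            BindingRecord("ACDEFGHIKLMNPQRS", "HLA-A*02:01", 1),   # 16-mer: out
        ]
        kept, _ = pm.clean_epitope_pairs(recs)
        assert sorted(len(r.peptide) for r in kept) == [8, 15]

    def test_idempotent_and_never_grows(self):
        recs = [
            BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1),
            BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1),
            BindingRecord("KLMNPQRST", "HLA-B*07:02", 0),
        ]
        once, _ = pm.clean_epitope_pairs(recs)
        twice, _ = pm.clean_epitope_pairs(once)
        assert once == twice and len(once) <= len(recs)


class TestAffinityTransform:
    def test_closed_form_endpoints(self):
        assert pm.transform_affinity(50000.0) == 0.0
        assert pm.transform_affinity(1.0) == 1.0

    def test_500_nm(self):
        assert pm.transform_affinity(500.0) == pytest.approx(
            1 - math.log(500) / math.log(50000), abs=1e-12
        )

    def test_strictly_decreasing_on_grid(self):
        grid = np.logspace(0, math.log10(50000), 100)
        vals = pm.transform_affinity(grid)
        assert np.all(np.diff(vals) < 0)

    def test_values_above_50000_clip_to_zero(self):
        assert pm.transform_affinity(123456.0) == 0.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            pm.transform_affinity(0.0)

    @given(st.floats(min_value=1.0, max_value=50000.0))
    @settings(max_examples=100)
    def test_inverse_round_trip_to_six_significant_digits(self, ic50):
        back = pm.inverse_transform_affinity(pm.transform_affinity(ic50))
        assert back == pytest.approx(ic50, rel=1e-6)


class TestLengthDistribution:
    def test_point_mass(self):
        recs = [BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1)] * 5
        assert pm.peptide_length_distribution(recs) == {9: 1.0}

    def test_even_split(self):
        recs = [BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1)] * 50 + [
            BindingRecord("ACDEFGHIKL", "HLA-A*02:01", 1)
        ] * 50
        dist = pm.peptide_length_distribution(recs)
        assert dist == {9: 0.5, 10: 0.5}

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        aas = sorted(pm.tokenize("ACD").config.alphabet)
        recs = [
            BindingRecord(
                "".join(rng.choice(aas, rng.integers(8, 16))), "HLA-A*02:01", 1
            )
            for _ in range(1000)
        ]
        dist = pm.peptide_length_distribution(recs)
        for length, freq in dist.items():
            expected = sum(len(r.peptide) == length for r in recs) / 1000
            assert freq == pytest.approx(expected)
        assert sum(dist.values()) == pytest.approx(1.0)


class TestNegativeSampling:
    def test_point_mass_length(self):
        recs = pm.sample_negative_batch({9: 1.0}, ["HLA-A*02:01"], 50, seed=0)
        assert all(len(r.peptide) == 9 for r in recs)
        assert all(r.label == 0 and r.source == "synthetic-negative" for r in recs)

    def test_residues_uniform_over_20_amino_acids(self):
        recs = pm.sample_negative_batch({9: 1.0}, ["HLA-A*02:01"], 12000, seed=1)
        counts: dict[str, int] = {}
        for r in recs:
            for aa in r.peptide:
                counts[aa] = counts.get(aa, 0) + 1
        observed = [counts.get(aa, 0) for aa in sorted(pm.tokenize("ACD").config.alphabet)]
        assert stats.chisquare(observed).pvalue > 0.01

    def test_fresh_draw_per_call(self):
        a = pm.sample_negative_batch({9: 1.0}, ["HLA-A*02:01"], 30, seed=1)
        b = pm.sample_negative_batch({9: 1.0}, ["HLA-A*02:01"], 30, seed=2)
        assert {r.peptide for r in a} != {r.peptide for r in b}

    def test_sampler_object_advances_between_calls(self):
        sampler = pm.NegativeSampler({9: 1.0}, ["HLA-A*02:01"], seed=3)
        assert {r.peptide for r in sampler.sample(20)} != {
            r.peptide for r in sampler.sample(20)
        }

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            pm.sample_negative_batch({9: 1.0}, ["HLA-A*02:01"], 0, seed=0)


class TestSplitDataset:
    def _records(self, n, seed=0):
        rng = np.random.default_rng(seed)
        aas = sorted(pm.tokenize("ACD").config.alphabet)
        return [
            BindingRecord("".join(rng.choice(aas, 9)), f"HLA-A*{i % 3 + 1:02d}:01", 1)
            for i in range(n)
        ]

    def test_partition_sizes(self):
        split = pm.split_dataset(self._records(100), (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (80, 10, 10)

    def test_peptide_disjoint_even_across_alleles(self):
        recs = self._records(60)
        shared = recs[0].peptide
        recs.append(BindingRecord(shared, "HLA-B*07:02", 1))
        split = pm.split_dataset(recs, seed=1)
        for part in split:
            peps = {r.peptide for r in part}
            others = [
                {r.peptide for r in q} for q in split if q is not part
            ]
            for o in others:
                assert not (peps & o)

    def test_jointly_exhaustive(self):
        recs = self._records(57)
        split = pm.split_dataset(recs, seed=2)
        assert len(split.train) + len(split.validation) + len(split.test) == 57

    def test_same_seed_identical(self):
        recs = self._records(40)
        s1 = pm.split_dataset(recs, seed=5)
        s2 = pm.split_dataset(recs, seed=5)
        assert s1.train == s2.train and s1.test == s2.test

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            pm.split_dataset(self._records(10), (0.5, 0.2, 0.2), seed=0)


class TestAlignedFasta:
    def test_uniform_alignment_read_and_uppercased(self, tmp_path):
        path = tmp_path / "al.fasta"
        path.write_text(">a1\nacdef-hik\n>a2\nACDEFGHIK\n>a3\nACDWF-HIK\n")
        seqs, n_cols = pm.read_aligned_fasta(path)
        assert n_cols == 9 and len(seqs) == 3
        assert seqs["a1"] == "ACDEF-HIK"

    def test_ragged_alignment_names_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a1\nACDEF\n>a2\nACD\n")
        with pytest.raises(ValueError, match="a2"):
            pm.read_aligned_fasta(path)


def test_records_frame_round_trips_fields():
    recs = [BindingRecord("ACDEFGHIK", "HLA-A*02:01", 1)]
    df = records_to_frame(recs)
    assert list(df.columns) == ["peptide", "allele", "label", "source"]
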