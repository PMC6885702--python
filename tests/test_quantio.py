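"""Reporter-matrix parsing, filtering and normalization."""

import numpy as np
import pandas as pd
import pytest

from mstriad.errors import ConfigurationError, ValidationError
from mstriad.quantio import (
    FilterReport,
    ReporterMatrix,
    bridge_normalize,
    filter_quantifiable,
    normalize_to_reference,
    read_matrix,
    read_protein_groups,
    split_sets,
    validate_design,
    write_matrix,
)

from conftest import make_design, make_matrix
from _oracles import rowwise_filter_oracle


class TestReadProteinGroups:
    def test_parses_toy_table(self, toy_protein_groups):
        path, design, raw = toy_protein_groups
        m = read_protein_groups(path, design)
        assert m.n_proteins == 4
        assert m.abundances.shape == (4, 6)
        assert list(m.protein_ids) == [f"P{i}" for i in range(4)]
        assert list(m.meta["peptide_count"]) == [5, 3, 2, 8]
        # file order preserved, values parsed exactly
        col = "Reporter intensity corrected 127"
        np.testing.assert_array_equal(
            m.abundances["set1:127"].to_numpy(), raw[col].to_numpy()
        )

    def test_missing_channel_column_names_channel(self, toy_protein_groups, tmp_path):
        path, _, raw = toy_protein_groups
        design = make_design(["126", "131X"], ["a", "b"])
        with pytest.raises(ConfigurationError, match="131X"):
            read_protein_groups(path, design)

    def test_duplicate_protein_ids_rejected(self, toy_protein_groups, tmp_path):
        path, design, raw = toy_protein_groups
        dup = raw.copy()
        dup.loc[1, "Majority protein IDs"] = "P0"
        p = tmp_path / "dup.txt"
        dup.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValidationError, match="P0"):
            read_protein_groups(p, design)

    def test_zero_intensity_becomes_missing(self, toy_protein_groups, tmp_path):
        path, design, raw = toy_protein_groups
        raw = raw.copy()
        raw.loc[2, "Reporter intensity corrected 128"] = 0
        p = tmp_path / "zero.txt"
        raw.to_csv(p, sep="\t", index=False)
        m = read_protein_groups(p, design)
        assert np.isnan(m.abundances.loc["P2", "set1:128"])
        # round trip of the parsed matrix keeps the missing cell missing
        out = tmp_path / "roundtrip.tsv"
        write_matrix(m, out, sig_digits=None)
        back = read_matrix(out, design)
        assert np.isnan(back.abundances.loc["P2", "set1:128"])

    def test_round_trip_bit_for_bit(self, toy_protein_groups, tmp_path):
        path, design, _ = toy_protein_groups
        m = read_protein_groups(path, design)
        out = tmp_path / "full.tsv"
        write_matrix(m, out, sig_digits=None)
        back = read_matrix(out, design)
        np.testing.assert_array_equal(
            back.abundances.to_numpy(), m.abundances.to_numpy()
        )


class TestDesignValidation:
    def test_duplicate_channel_rejected(self):
        with pytest.raises(ValidationError, match="duplicate channel"):
            make_design(["126", "126"], ["a", "b"])

    def test_two_references_rejected(self):
        with pytest.raises(ValidationError, match="reference"):
            make_design(["126", "127"], ["a", "b"], roles=["reference", "reference"])

    def test_duplicate_sample_pair_rejected(self):
        with pytest.raises(ValidationError, match="pair"):
            make_design(["126", "127"], ["a", "a"], replicates=[1, 1])


class TestFilterQuantifiable:
    def test_hand_counted_toy(self):
        design = make_design(["126", "127"], ["a", "b"])
        m = make_matrix(np.ones((5, 2)), design)
        m.meta.loc["P0", "is_reverse"] = True
        m.meta.loc["P1", "is_contaminant"] = True
        m.meta.loc["P2", "peptide_count"] = 1
        out, report = filter_quantifiable(m, min_peptides=2)
        assert out.n_proteins == 2
        assert list(out.protein_ids) == ["P3", "P4"]
        assert report.removed_reverse == 1
        assert report.removed_contaminant == 1
        assert report.removed_low_peptides == 1

    def test_identity_on_clean_input(self):
        design = make_design(["126", "127"], ["a", "b"])
        m = make_matrix(np.ones((4, 2)), design, peptide_count=3)
        out, report = filter_quantifiable(m, min_peptides=1)
        assert out.n_proteins == 4
        pd.testing.assert_frame_equal(out.abundances, m.abundances)

    def test_matches_rowwise_oracle_on_random_rows(self):
        rng = np.random.default_rng(11)
        n = 1000
        design = make_design(["126", "127"], ["a", "b"])
        m = make_matrix(np.ones((n, 2)), design)
        m.meta["is_reverse"] = rng.random(n) < 0.05
        m.meta["is_contaminant"] = rng.random(n) < 0.1
        m.meta["peptide_count"] = rng.integers(0, 6, n)
        out, _ = filter_quantifiable(m, min_peptides=2)
        expected = rowwise_filter_oracle(
            m.meta["is_reverse"], m.meta["is_contaminant"], m.meta["peptide_count"], 2
        )
        assert list(out.protein_ids) == list(m.protein_ids[np.asarray(expected)])

    def test_min_peptides_below_one_rejected(self):
        design = make_design(["126"], ["a"])
        m = make_matrix(np.ones((2, 1)), design)
        with pytest.raises(ValueError):
            filter_quantifiable(m, min_peptides=0)


class TestNormalizeToReference:
    def _matrix(self, values, **kw):
        design = make_design(
            ["126", "127", "128"], ["ctl", "a", "b"],
            roles=["reference", "sample", "sample"],
        )
        return make_matrix(values, design, **kw)

    def test_row_ratio_arithmetic(self):
        m = self._matrix([[100.0, 200.0, 50.0]])
        out, _ = normalize_to_reference(m)
        np.testing.assert_allclose(out.abundances.to_numpy(), [[1.0, 2.0, 0.5]])
        assert out.normalized

    def test_scale_invariance(self):
        vals = np.array([[100.0, 200.0, 50.0], [10.0, 5.0, 20.0]])
        a, _ = normalize_to_reference(self._matrix(vals))
        b, _ = normalize_to_reference(self._matrix(vals * 7.3))
        np.testing.assert_allclose(a.abundances.to_numpy(), b.abundances.to_numpy())

    def test_zero_reference_row_dropped_and_reported(self):
        m = self._matrix([[100.0, 2.0, 3.0], [np.nan, 2.0, 3.0]])
        out, report = normalize_to_reference(m)
        assert out.n_proteins == 1
        assert report.dropped_missing_reference == 1

    def test_idempotent(self):
        m = self._matrix(np.random.default_rng(3).uniform(1, 100, (6, 3)))
        once, _ = normalize_to_reference(m)
        twice, _ = normalize_to_reference(once)
        np.testing.assert_array_equal(
            once.abundances.to_numpy(), twice.abundances.to_numpy()
        )

    def test_commutes_with_filtering(self):
        design = make_design(
            ["126", "127"], ["ctl", "a"], roles=["reference", "sample"]
        )
        rng = np.random.default_rng(4)
        m = make_matrix(rng.uniform(1, 100, (20, 2)), design)
        m.meta["peptide_count"] = rng.integers(0, 5, 20)
        a, _ = normalize_to_reference(filter_quantifiable(m, 2)[0])
        b, _ = filter_quantifiable(normalize_to_reference(m)[0], 2)
        pd.testing.assert_frame_equal(a.abundances, b.abundances)

    def test_no_reference_is_configuration_error(self):
        design = make_design(["126", "127"], ["a", "b"])
        m = make_matrix(np.ones((2, 2)), design)
        with pytest.raises(ConfigurationError):
            normalize_to_reference(m)


class TestBridgeNormalize:
    def _set(self, values, set_id, ids):
        design = make_design(
            ["126", "127", "131"], ["a", "b", "veh"],
            roles=["sample", "sample", "bridge"], set_id=set_id,
        )
        return make_matrix(values, design, ids=ids)

    def test_missing_bridge_drops_protein(self):
        s1 = self._set(np.ones((3, 3)), "s1", ["P0", "P1", "P2"])
        vals2 = np.ones((3, 3))
        vals2[1, 2] = np.nan
        s2 = self._set(vals2, "s2", ["P0", "P1", "P2"])
        joined, report = bridge_normalize([s1, s2])
        assert joined.n_proteins == 2
        assert report.dropped_missing_bridge == 1

    def test_unit_bridge_is_identity_on_samples(self):
        vals = np.column_stack([np.arange(1.0, 5.0), np.arange(2.0, 6.0), np.ones(4)])
        s = self._set(vals, "s1", [f"P{i}" for i in range(4)])
        joined, _ = bridge_normalize([s])
        np.testing.assert_allclose(
            joined.abundances[["s1:126", "s1:127"]].to_numpy(), vals[:, :2]
        )

    def test_recovers_cross_set_ratios_under_batch_factors(self):
        """Planting per-set multiplicative batch factors must leave
        bridge-normalized cross-set ratios equal to the true ones."""
        rng = np.random.default_rng(5)
        true = rng.uniform(1, 100, (10, 4))  # 2 sample channels per set
        bridge_true = rng.uniform(1, 100, 10)
        ids = [f"P{i}" for i in range(10)]
        sets = []
        for si, b in enumerate([1.0, 13.7]):
            vals = np.column_stack(
                [true[:, 2 * si] * b, true[:, 2 * si + 1] * b, bridge_true * b]
            )
            sets.append(self._set(vals, f"s{si}", ids))
        joined, _ = bridge_normalize(sets)
        got = joined.abundances["s1:126"] / joined.abundances["s0:126"]
        expect = true[:, 2] / true[:, 0]
        np.testing.assert_allclose(got.to_numpy(), expect, rtol=1e-12)

    def test_geometric_mean_of_two_bridges(self):
        design = make_design(
            ["126", "130", "131"], ["a", "veh", "veh"],
            roles=["sample", "bridge", "bridge"], replicates=[1, 1, 2],
        )
        m = make_matrix([[8.0, 2.0, 8.0]], design)  # geomean(2, 8) = 4
        joined, _ = bridge_normalize([m])
        assert joined.abundances.iloc[0, 0] == pytest.approx(2.0)

    def test_split_sets_partitions_columns(self):
        from mstriad.synthetic import simulate_expression

        m, _ = simulate_expression(30, n_specific=0, n_shared=0, seed=0)
        parts = split_sets(m)
        assert sum(p.abundances.shape[1] for p in parts) == m.abundances.shape[1]
        assert {c for p in parts for c in p.abundances.columns} == set(
            m.abundances.columns
        )
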