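"""Activity calls, profile partitioning, SAM-FDR, extrapolation, qPCR."""

import numpy as np
import pandas as pd
import pytest

from hervarray.transcriptome import (
    call_active_elements,
    extrapolate_repertoire,
    fc_u5_u3,
    partition_profiles,
    qpcr_relative_expression,
    relative_expression,
    sam_fdr,
    tissue_specific_sets,
)


class TestActivity:
    def _expr(self, rows):
        return pd.DataFrame(rows, index=[f"ps{i}" for i in range(len(rows))],
                            columns=["t1", "t2"])

    def test_exactly_100_is_inactive(self):
        expr = self._expr([[100.0, 100.0]])
        result = call_active_elements(expr, {"ps0": "L0"})
        assert not result.element_active["L0"]

    def test_barely_above_in_one_tissue_activates_element(self):
        expr = self._expr([[100.5, 10.0]])
        result = call_active_elements(expr, {"ps0": "L0"})
        assert result.element_active["L0"]

    def test_element_with_several_active_probesets_counts_once(self):
        expr = self._expr([[500.0, 10.0], [300.0, 10.0], [200.0, 10.0]])
        mapping = {"ps0": "L0", "ps1": "L0", "ps2": "L0"}
        result = call_active_elements(expr, mapping)
        assert int(result.element_active.sum()) == 1

    def test_unmapped_probeset_warned_and_excluded(self):
        expr = self._expr([[500.0, 10.0], [500.0, 10.0]])
        with pytest.warns(UserWarning, match="without element mapping"):
            result = call_active_elements(expr, {"ps0": "L0"})
        assert result.unmapped_probesets == ["ps1"]

    def test_counting_is_order_independent(self):
        expr = self._expr([[500.0, 10.0], [10.0, 500.0]])
        mapping = {"ps0": "L0", "ps1": "L1"}
        a = call_active_elements(expr, mapping).element_active
        b = call_active_elements(expr.iloc[::-1, ::-1], mapping).element_active
        assert a.sort_index().equals(b.sort_index())


class TestPartitionProfiles:
    def _implanted(self, seed=0, per_cluster=30):
        rng = np.random.default_rng(seed)
        tissues = [f"t{i}" for i in range(5)]
        rows, labels = [], []
        for k in range(3):
            for _ in range(per_cluster):
                base = rng.uniform(3, 5, size=5)
                base[k] += rng.uniform(4, 6)
                rows.append(base)
                labels.append(k)
        index = [f"ps{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=index, columns=tissues), np.array(labels)

    def test_recovers_implanted_single_tissue_profiles(self):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = self._implanted(seed=1)
        profiles, unclassified = partition_profiles(expr, random_state=0)
        assignment = np.full(len(expr), -1)
        for p in profiles:
            for m in p.members:
                assignment[expr.index.get_loc(m)] = p.profile_id
        assert adjusted_rand_score(truth, assignment) >= 0.9

    def test_signature_names_the_elevated_tissue(self):
        expr, _ = self._implanted(seed=2)
        profiles, _ = partition_profiles(expr, k=3, random_state=0)
        signatures = sorted(tuple(p.tissue_signature) for p in profiles)
        assert signatures == [("t0",), ("t1",), ("t2",)]

    def test_cluster_below_minimum_size_dissolves(self):
        rng = np.random.default_rng(3)
        big = rng.normal(0, 0.1, size=(30, 4))
        small = rng.normal(8, 0.1, size=(5, 4))
        expr = pd.DataFrame(np.vstack([big, small]),
                            index=[f"ps{i}" for i in range(35)],
                            columns=list("abcd"))
        profiles, unclassified = partition_profiles(expr, k=2, random_state=0)
        assert len(profiles) == 1
        assert set(unclassified) == {f"ps{i}" for i in range(30, 35)}

    def test_constant_matrix_yields_no_profiles(self):
        expr = pd.DataFrame(np.ones((20, 4)), columns=list("abcd"))
        profiles, unclassified = partition_profiles(expr, random_state=0)
        assert profiles == [] or all(len(p.members) >= 6 for p in profiles)
        # membership partitions either way
        sizes = sum(len(p.members) for p in profiles) + len(unclassified)
        assert sizes == 20

    def test_membership_is_a_partition(self):
        expr, _ = self._implanted(seed=4)
        profiles, unclassified = partition_profiles(expr, random_state=0)
        seen = [m for p in profiles for m in p.members] + list(unclassified)
        assert sorted(seen) == sorted(expr.index)


def _two_group_expr(rng, n_probesets=300, n_per_group=6, shift_idx=(), shift=0.0):
    """Comparison-scale matrix with optional log2 shifts in group B."""
    base = rng.uniform(7, 9, size=n_probesets)
    log2 = np.tile(base[:, None], (1, 2 * n_per_group)) + rng.normal(
        0, 1.0, size=(n_probesets, 2 * n_per_group)
    )
    for i in shift_idx:
        log2[i, n_per_group:] += shift
    cols = [f"n{i}" for i in range(n_per_group)] + [f"t{i}" for i in range(n_per_group)]
    expr = pd.DataFrame(2.0**log2, index=[f"ps{i}" for i in range(n_probesets)], columns=cols)
    groups = pd.Series(["normal"] * n_per_group + ["tumor"] * n_per_group, index=cols)
    pairs = pd.Series([f"p{i}" for i in range(n_per_group)] * 2, index=cols)
    return expr, groups, pairs


class TestSamFdr:
    def test_detection_filter_excludes_all_low_probesets(self):
        rng = np.random.default_rng(0)
        expr, groups, _ = _two_group_expr(rng, n_probesets=50)
        expr.iloc[0] = 63.0  # below 2^6 everywhere
        result = sam_fdr(expr, groups, n_permutations=50, seed=0)
        assert "ps0" in result.filtered_out
        assert "ps0" not in result.table.index

    def test_d_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        expr, groups, _ = _two_group_expr(rng, n_probesets=80)
        swapped = groups.map({"normal": "tumor", "tumor": "normal"})
        a = sam_fdr(expr, groups, n_permutations=50, seed=0)
        b = sam_fdr(expr, swapped, n_permutations=50, seed=0)
        assert np.allclose(a.table["d"], -b.table["d"])
        assert (a.table["called"] == b.table["called"]).all()

    def test_implanted_shifts_recovered(self):
        """4-SD shifts in 50 of 1000 probesets: recall >= 0.9 at FDR 20%."""
        rng = np.random.default_rng(2)
        shift_idx = range(50)
        expr, groups, pairs = _two_group_expr(
            rng, n_probesets=1000, shift_idx=shift_idx, shift=4.0
        )
        result = sam_fdr(expr, groups, paired=pairs, n_permutations=100, seed=0)
        called = set(result.table.index[result.table["called"]])
        truth = {f"ps{i}" for i in shift_idx}
        recall = len(called & truth) / len(truth)
        assert recall >= 0.9
        if called:
            fdp = len(called - truth) / len(called)
            se = np.sqrt(0.2 * 0.8 / len(called))
            assert fdp <= 0.2 + 3 * se

    def test_null_data_produces_almost_no_calls(self):
        """Complete-null simulations stay at the no-discovery baseline."""
        total_called = 0
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            expr, groups, pairs = _two_group_expr(rng, n_probesets=200)
            result = sam_fdr(expr, groups, paired=pairs, n_permutations=100, seed=seed)
            total_called += int(result.table["called"].sum())
            total += len(result.table)
        assert total_called / total <= 0.01

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(3)
        expr, groups, _ = _two_group_expr(rng, n_probesets=20, n_per_group=2)
        groups.iloc[:] = ["normal", "tumor", "tumor", "tumor"]
        with pytest.raises(ValueError, match=">= 2"):
            sam_fdr(expr.iloc[:, :4], groups, n_permutations=10, seed=0)


class TestTissueSpecificSets:
    def test_shared_members_removed(self):
        out = tissue_specific_sets({"T1": {"a", "b"}, "T2": {"b", "c"}})
        assert out == {"T1": {"a"}, "T2": {"c"}}

    def test_identical_lists_yield_empty_sets(self):
        out = tissue_specific_sets({"T1": {"a"}, "T2": {"a"}})
        assert out == {"T1": set(), "T2": set()}

    def test_single_tissue_keeps_everything(self):
        out = tissue_specific_sets({"T1": {"a", "b"}})
        assert out == {"T1": {"a", "b"}}


class TestExtrapolateRepertoire:
    def test_published_solo_ltr_cell(self):
        """100 transcribed of 432 on chip, 464 in genome -> 107.41 corrected."""
        t = pd.DataFrame({"HERV-W": [100]}, index=["solo_LTR"])
        c = pd.DataFrame({"HERV-W": [432]}, index=["solo_LTR"])
        g = pd.DataFrame({"HERV-W": [464]}, index=["solo_LTR"])
        corrected, _ = extrapolate_repertoire(t, c, g)
        assert corrected.iloc[0, 0] == pytest.approx(107.41, abs=0.005)

    def test_chip_equal_genome_is_identity(self):
        t = pd.DataFrame({"f": [10.0]})
        c = pd.DataFrame({"f": [50.0]})
        corrected, _ = extrapolate_repertoire(t, c, c)
        assert corrected.iloc[0, 0] == 10.0

    def test_zero_transcriptome_stays_zero(self):
        t = pd.DataFrame({"f": [0.0]})
        c = pd.DataFrame({"f": [50.0]})
        g = pd.DataFrame({"f": [80.0]})
        corrected, _ = extrapolate_repertoire(t, c, g)
        assert corrected.iloc[0, 0] == 0.0

    def test_zero_chip_with_signal_rejected(self):
        t = pd.DataFrame({"f": [5.0]})
        c = pd.DataFrame({"f": [0.0]})
        with pytest.raises(ValueError, match="chip count"):
            extrapolate_repertoire(t, c, t)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 50, size=(2, 6)).astype(float))
        c = pd.DataFrame(rng.integers(50, 100, size=(2, 6)).astype(float))
        g = pd.DataFrame(rng.integers(100, 200, size=(2, 6)).astype(float))
        _, proportions = extrapolate_repertoire(t, c, g)
        assert proportions.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)


class TestQpcr:
    def test_minimum_ct_gives_unit_rle(self):
        ct = pd.Series([25.0, 27.0, 30.0])
        rle = relative_expression(ct, 2.0)
        assert rle.iloc[0] == 1.0

    def test_unit_housekeeping_normalization_is_identity(self):
        ct = pd.DataFrame(
            {
                "s1": [20.0, 20.0, 20.0, 25.0],
                "s2": [20.0, 20.0, 20.0, 28.0],
            },
            index=["hk1", "hk2", "hk3", "target"],
        )
        eff = pd.Series(2.0, index=ct.index)
        out = qpcr_relative_expression(ct, eff, ["hk1", "hk2", "hk3"])
        # housekeeping RLEs are all 1, so the target keeps its raw RLE
        assert out.loc["target", "s1"] == pytest.approx(1.0)
        assert out.loc["target", "s2"] == pytest.approx(2.0**-3)

    def test_geometric_mean_identity(self):
        """Three housekeeping systems with equal RLE r divide by exactly r."""
        ct = pd.DataFrame(
            {"s1": [20.0, 20.0, 20.0, 22.0], "s2": [21.0, 21.0, 21.0, 22.0]},
            index=["hk1", "hk2", "hk3", "target"],
        )
        eff = pd.Series(2.0, index=ct.index)
        out = qpcr_relative_expression(ct, eff, ["hk1", "hk2", "hk3"])
        # in s2 every housekeeping RLE is 1/2 -> target divided by 1/2
        raw_target = 2.0 ** (22.0 - 22.0)
        assert out.loc["target", "s2"] == pytest.approx(raw_target / 0.5)

    def test_missing_housekeeping_rejected(self):
        ct = pd.DataFrame({"s1": [20.0]}, index=["target"])
        eff = pd.Series(2.0, index=ct.index)
        with pytest.raises(ValueError, match="housekeeping"):
            qpcr_relative_expression(ct, eff, ["hk1"])

    def test_fc_u5_u3_printed_example(self):
        """Eff 2/2, Ct_U3 25, Ct_U5 22 -> fold change 8, promoter."""
        ratio, promoter = fc_u5_u3(2.0, 25.0, 2.0, 22.0)
        assert ratio == pytest.approx(8.0)
        assert promoter

    def test_fc_below_one_is_not_promoter(self):
        ratio, promoter = fc_u5_u3(2.0, 22.0, 2.0, 25.0)
        assert ratio == pytest.approx(1 / 8)
        assert not promoter
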