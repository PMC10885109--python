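import numpy as np
import pandas as pd
import pytest

from clcrep import binning as bn
from clcrep import simulate as sim
from clcrep.errors import FormatError, ParameterError


def make_table(total, alone, refs=None, panel=None):
    total = np.asarray(total, dtype=float)
    refs = refs or [f"R{i}" for i in range(total.shape[0])]
    panel = panel or [f"P{i}" for i in range(total.shape[1])]
    return bn.BeadGeomeanTable(
        total_geomean=pd.DataFrame(total, index=refs, columns=panel),
        reference_alone=pd.Series(alone, index=refs, dtype=float),
    )


class TestNetGeomean:
    def test_formula(self):
        table = make_table([[1500.0]], [400.0])
        assert bn.net_geomean(table).iloc[0, 0] == pytest.approx(1100.0)

    def test_full_competition_zero(self):
        table = make_table([[400.0]], [400.0])
        assert bn.net_geomean(table).iloc[0, 0] == pytest.approx(0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(5)
        total = rng.uniform(100, 2000, size=(3, 4))
        alone = rng.uniform(50, 500, size=3)
        net = bn.net_geomean(make_table(total, alone))
        for i in range(3):
            for j in range(4):
                assert net.iloc[i, j] == pytest.approx(total[i, j] - alone[i])

    def test_negative_values_retained(self):
        table = make_table([[100.0]], [400.0])
        assert bn.net_geomean(table).iloc[0, 0] == pytest.approx(-300.0)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(6)
        total = rng.uniform(100, 2000, size=(3, 3))
        alone = rng.uniform(50, 500, size=3)
        net = bn.net_geomean(make_table(total, alone)).to_numpy()
        net_scaled = bn.net_geomean(make_table(total * 3.5, alone * 3.5)).to_numpy()
        assert np.allclose(net_scaled, 3.5 * net)

    def test_missing_reference_alone_named(self):
        with pytest.raises(FormatError, match="R1"):
            bn.BeadGeomeanTable(
                total_geomean=pd.DataFrame([[1.0], [2.0]], index=["R0", "R1"], columns=["P0"]),
                reference_alone=pd.Series({"R0": 1.0}),
            )

    def test_long_round_trip(self):
        config = sim.BinSimConfig(n_references=3, n_panel=4, seed=2)
        long_df, _ = sim.generate_binning_panel(config)
        table = bn.BeadGeomeanTable.from_long(long_df)
        back = table.to_long().sort_values(["reference_id", "panel_id"]).reset_index(drop=True)
        orig = long_df.sort_values(["reference_id", "panel_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, orig[back.columns], check_exact=False)


class TestCorrelateProfiles:
    def test_identical_columns_r_one(self):
        net = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        r, flagged = bn.correlate_profiles(net)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert flagged == []

    def test_anticorrelated_columns(self):
        net = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        r, _ = bn.correlate_profiles(net)
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(9)
        net = pd.DataFrame(rng.normal(size=(5, 6)), columns=list("abcdef"))
        r, _ = bn.correlate_profiles(net)
        for i in "abc":
            for j in "def":
                x, y = net[i].to_numpy(), net[j].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
                assert r.loc[i, j] == pytest.approx(expected)

    def test_zero_variance_profile_flagged_and_excluded(self):
        net = pd.DataFrame({"a": [1.0, 2, 3], "flat": [2.0, 2, 2]})
        r, flagged = bn.correlate_profiles(net)
        assert flagged == ["flat"]
        assert "flat" not in r.columns

    def test_single_reference_rejected(self):
        with pytest.raises(ParameterError):
            bn.correlate_profiles(pd.DataFrame({"a": [1.0]}))


def block_r_matrix(blocks, within=0.95, between=0.1):
    ids = [ab for block in blocks for ab in block]
    r = pd.DataFrame(between, index=ids, columns=ids, dtype=float)
    for block in blocks:
        for a in block:
            for b in block:
                r.loc[a, b] = within
    np.fill_diagonal(r.values, 1.0)
    return r


class TestAssignBins:
    def test_block_diagonal_recovered(self):
        r = block_r_matrix([["a1", "a2", "a3"], ["b1", "b2"]])
        assignment = bn.assign_bins(r, 0.8)
        members = assignment.bin_members()
        assert members == {"A": ["a1", "a2", "a3"], "B": ["b1", "b2"]}

    def test_all_below_threshold_singletons(self):
        r = block_r_matrix([["a"], ["b"], ["c"]], between=0.1)
        assignment = bn.assign_bins(r, 0.8)
        assert len(set(assignment.bins.values())) == 3

    def test_permutation_invariance_up_to_relabelling(self):
        r = block_r_matrix([["a1", "a2"], ["b1", "b2", "b3"], ["c1"]])
        perm = ["b2", "c1", "a1", "b1", "a2", "b3"]
        shuffled = r.loc[perm, perm]
        def parts(asg):
            return sorted(
                (frozenset(m) for m in asg.bin_members().values()),
                key=lambda s: sorted(s)[0],
            )
        assert parts(bn.assign_bins(r, 0.8)) == parts(bn.assign_bins(shuffled, 0.8))

    def test_raising_threshold_refines(self):
        rng = np.random.default_rng(3)
        config = sim.BinSimConfig(n_references=6, n_panel=12, n_bins=3, noise_cv=0.2, seed=4)
        long_df, _ = sim.generate_binning_panel(config)
        net = bn.net_geomean(bn.BeadGeomeanTable.from_long(long_df))
        r, _ = bn.correlate_profiles(net)
        low = bn.assign_bins(r, 0.6)
        high = bn.assign_bins(r, 0.9)
        # every high-threshold bin is contained in one low-threshold bin
        for members in high.bin_members().values():
            parents = {low.bins[ab] for ab in members}
            assert len(parents) == 1

    def test_bad_threshold_rejected(self):
        with pytest.raises(ParameterError):
            bn.assign_bins(block_r_matrix([["a", "b"]]), 0.0)

    def test_planted_bins_recovered_end_to_end(self):
        config = sim.BinSimConfig(n_references=6, n_panel=12, n_bins=3,
                                  noise_cv=0.05, seed=7)
        long_df, planted = sim.generate_binning_panel(config)
        net = bn.net_geomean(bn.BeadGeomeanTable.from_long(long_df))
        r, flagged = bn.correlate_profiles(net)
        assignment = bn.assign_bins(r, 0.8)
        assert flagged == []
        recovered = {}
        for ab, label in assignment.bins.items():
            recovered.setdefault(label, set()).add(ab)
        expected = {}
        for ab in assignment.bins:
            expected.setdefault(planted[ab], set()).add(ab)
        assert sorted(recovered.values(), key=sorted) == sorted(expected.values(), key=sorted)


class TestBenchmarkBinning:
    def _net_with_benchmarks(self, seed=0):
        """Panel of 6: 3 planted in benchmark bins, 3 in new bins."""
        bins = {"REF01": "A", "REF02": "B", "REF03": "C", "REF04": "A",
                "AB01": "A", "AB02": "B", "AB03": "C",
                "AB04": "X", "AB05": "Y", "AB06": "Z"}
        config = sim.BinSimConfig(n_references=4, n_panel=6, bin_assignment=bins,
                                  noise_cv=0.05, seed=seed)
        long_df, _ = sim.generate_binning_panel(config)
        table = bn.BeadGeomeanTable.from_long(long_df)
        return bn.net_geomean(table), bins

    def test_matched_and_novel_split_equals_planted(self):
        net, bins = self._net_with_benchmarks()
        # benchmark profiles: simulate the benchmarks as panel antibodies
        # against the same references by reusing their competition pattern
        bench_cfg = sim.BinSimConfig(
            n_references=4, n_panel=3,
            bin_assignment={"REF01": "A", "REF02": "B", "REF03": "C", "REF04": "A",
                            "AB01": "A", "AB02": "B", "AB03": "C"},
            noise_cv=0.05, seed=99,
        )
        bench_long, _ = sim.generate_binning_panel(bench_cfg)
        bench_net = bn.net_geomean(bn.BeadGeomeanTable.from_long(bench_long))
        bench_net.columns = ["BMA", "BMB", "BMC"]
        combined = pd.concat([net, bench_net], axis=1)
        result = bn.benchmark_binning(
            combined, panel_ids=list(net.columns),
            benchmark_bins={"BMA": "A", "BMB": "B", "BMC": "C"},
            threshold=0.8,
        )
        by_ab = result.set_index("panel_id")
        assert by_ab.loc["AB01", "bin"] == "A"
        assert by_ab.loc["AB02", "bin"] == "B"
        assert by_ab.loc["AB03", "bin"] == "C"
        assert by_ab.loc[["AB04", "AB05", "AB06"], "novel"].all()
        assert int(result["novel"].sum()) == 3

    def test_empty_benchmark_set_rejected(self):
        net, _ = self._net_with_benchmarks()
        with pytest.raises(ParameterError):
            bn.benchmark_binning(net, list(net.columns), {})
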