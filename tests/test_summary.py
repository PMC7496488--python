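"""Panel post-processing: site collapsing, densities, Poisson rate tests."""

import numpy as np
import pandas as pd
import pytest

from cnvsd.intervals import IntervalSet
from cnvsd.summary import (
    captured_length_per_chrom,
    collapse_to_sites,
    density_table,
    exact_poisson_two_sample,
    filter_rare_calls,
    frequency_spectrum,
    group_density,
    pairwise_poisson_tests,
    panel_stats,
)


def call_row(sample, chrom, start, end, type_, n_targets=3, conf=10.0):
    return {
        "sample": sample, "chrom": chrom, "start": start, "end": end,
        "type": type_, "n_targets": n_targets, "confidence": conf,
    }


class TestCollapse:
    def test_three_identical_calls_one_site(self):
        calls = pd.DataFrame([call_row(f"s{i}", "chr1", 0, 1000, "DEL") for i in range(3)])
        sites, ids = collapse_to_sites(calls, panel_size=100)
        assert len(sites) == 1
        assert sites.loc[0, "n_carriers"] == 3
        assert sites.loc[0, "frequency"] == pytest.approx(3.0)
        assert set(ids) == {0}

    def test_del_and_dup_stay_separate_sites(self):
        calls = pd.DataFrame(
            [call_row("a", "chr1", 0, 1000, "DEL"), call_row("b", "chr1", 0, 1000, "DUP")]
        )
        sites, _ = collapse_to_sites(calls, panel_size=10)
        assert len(sites) == 2
        assert set(sites["type"]) == {"DEL", "DUP"}

    def test_touching_calls_do_not_link(self):
        calls = pd.DataFrame(
            [call_row("a", "chr1", 0, 100, "DEL"), call_row("b", "chr1", 100, 200, "DEL")]
        )
        sites, _ = collapse_to_sites(calls, panel_size=10)
        assert len(sites) == 2

    def test_matches_connected_components_oracle(self, rng):
        """Site partition equals connected components of the same-type
        overlap graph (networkx oracle)."""
        import networkx as nx

        for _ in range(10):
            rows = []
            for i in range(50):
                s = int(rng.integers(0, 5000))
                rows.append(
                    call_row(
                        f"s{rng.integers(20)}",
                        f"chr{rng.integers(1, 3)}",
                        s,
                        s + int(rng.integers(50, 800)),
                        "DEL" if rng.random() < 0.7 else "DUP",
                    )
                )
            calls = pd.DataFrame(rows)
            sites, ids = collapse_to_sites(calls, panel_size=30)
            g = nx.Graph()
            g.add_nodes_from(range(len(calls)))
            for i in range(len(calls)):
                for j in range(i + 1, len(calls)):
                    a, b = calls.iloc[i], calls.iloc[j]
                    if (
                        a["chrom"] == b["chrom"]
                        and a["type"] == b["type"]
                        and a["start"] < b["end"]
                        and b["start"] < a["end"]
                    ):
                        g.add_edge(i, j)
            components = {frozenset(c) for c in nx.connected_components(g)}
            mine = {
                frozenset(np.flatnonzero(ids == sid))
                for sid in np.unique(ids)
            }
            assert mine == components

    def test_collapse_is_input_order_invariant(self, rng):
        rows = [
            call_row(f"s{i % 7}", "chr1", int(rng.integers(0, 3000)), 0, "DEL")
            for i in range(30)
        ]
        for r in rows:
            r["end"] = r["start"] + int(rng.integers(100, 900))
        calls = pd.DataFrame(rows)
        sites1, _ = collapse_to_sites(calls, 10)
        sites2, _ = collapse_to_sites(calls.sample(frac=1, random_state=3), 10)
        pd.testing.assert_frame_equal(sites1, sites2)

    def test_panel_smaller_than_carriers_rejected(self):
        calls = pd.DataFrame([call_row(f"s{i}", "chr1", 0, 100, "DEL") for i in range(5)])
        with pytest.raises(ValueError, match="panel_size"):
            collapse_to_sites(calls, panel_size=3)


class TestRareFilter:
    def test_two_carrier_site_removed_three_retained(self):
        calls = pd.DataFrame(
            [call_row(f"s{i}", "chr1", 0, 1000, "DEL") for i in range(2)]
            + [call_row(f"s{i}", "chr1", 5000, 6000, "DEL") for i in range(3)]
        )
        kept, sites = filter_rare_calls(calls, panel_size=10, min_accessions=3)
        assert len(kept) == 3
        assert len(sites) == 1
        assert sites.loc[0, "start"] == 5000

    def test_survivors_match_independent_tally(self, small_panel):
        _, truth = small_panel
        rows = []
        for r in truth.sites.itertuples():
            for s in r.carriers.split(","):
                rows.append(call_row(s, r.chrom, r.start, r.end, r.type))
        calls = pd.DataFrame(rows)
        kept, sites = filter_rare_calls(calls, panel_size=40)
        expected = truth.sites[truth.sites["n_carriers"] >= 3]
        assert len(sites) == len(expected)
        assert kept["sample"].count() == expected["n_carriers"].sum()


class TestPanelStats:
    def test_headline_mean_calls_per_sample(self):
        """197,407 calls over 397 accessions average to 497 per sample."""
        calls = pd.DataFrame({"n_targets": np.ones(197_407, dtype=int)})
        stats = panel_stats(calls, pd.DataFrame(), panel_size=397)
        assert stats["mean_calls_per_sample_display"] == 497

    def test_zero_calls(self):
        stats = panel_stats(pd.DataFrame(columns=["n_targets"]), pd.DataFrame(), 100)
        assert stats["mean_calls_per_sample"] == 0.0


TABLE1 = {  # per-chromosome deletion / duplication counts
    "1H": (1983, 575), "2H": (2355, 586), "3H": (2001, 495), "4H": (782, 186),
    "5H": (1973, 525), "6H": (1663, 441), "7H": (2393, 647),
}


class TestDensityTable:
    def _sites(self):
        rows = []
        for chrom, (n_del, n_dup) in TABLE1.items():
            for i in range(n_del):
                rows.append({"chrom": chrom, "type": "DEL"})
            for i in range(n_dup):
                rows.append({"chrom": chrom, "type": "DUP"})
        return pd.DataFrame(rows)

    def test_genome_wide_deletion_duplication_ratio(self):
        mb = pd.Series({c: 10.0 for c in TABLE1})
        table = density_table(self._sites(), mb).set_index("chrom")
        assert table.loc["all", "n_del"] == 13_150
        assert table.loc["all", "n_dup"] == 3_455
        assert table.loc["all", "del_dup_ratio"] == pytest.approx(3.81, abs=0.005)
        assert table.loc["1H", "del_dup_ratio"] == pytest.approx(3.45, abs=0.005)
        assert table.loc["4H", "del_dup_ratio"] == pytest.approx(4.20, abs=0.005)

    def test_deletion_density_cross_check(self):
        """1H captured length back-computed from its duplication density
        (575 / 74.24 Mb) reproduces the deletion density 256.04 /Mb."""
        mb_1h = 575 / 74.24
        table = density_table(
            self._sites(), pd.Series({c: mb_1h for c in TABLE1})
        ).set_index("chrom")
        assert table.loc["1H", "del_density"] == pytest.approx(256.04, abs=0.05)

    def test_counts_recoverable_from_density(self, rng):
        mb = pd.Series({c: float(rng.uniform(5, 12)) for c in TABLE1})
        table = density_table(self._sites(), mb).set_index("chrom")
        for chrom in TABLE1:
            back = table.loc[chrom, "del_density"] * table.loc[chrom, "captured_mb"]
            assert round(back) == TABLE1[chrom][0]

    def test_zero_captured_length_rejected(self):
        with pytest.raises(ValueError, match="4H"):
            density_table(self._sites(), pd.Series({c: (0.0 if c == "4H" else 1.0) for c in TABLE1}))


class TestExactPoisson:
    def test_symmetric_case_p_one(self):
        assert exact_poisson_two_sample(7, 7, 2.0, 2.0) == pytest.approx(1.0)

    def test_matches_binomial_tail_oracle(self):
        """Direct minlike summation over Binomial(12, 1/2)."""
        from math import comb

        n, p = 12, 0.5
        pmf = [comb(n, k) * p**n for k in range(n + 1)]
        obs = pmf[10]
        expected = sum(q for q in pmf if q <= obs + 1e-12)
        assert exact_poisson_two_sample(10, 2, 1.0, 1.0) == pytest.approx(expected, rel=1e-9)

    def test_exchange_symmetry_and_scale_invariance(self, rng):
        for _ in range(20):
            k1, k2 = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            e1, e2 = float(rng.uniform(0.5, 5)), float(rng.uniform(0.5, 5))
            p = exact_poisson_two_sample(k1, k2, e1, e2)
            assert p == pytest.approx(exact_poisson_two_sample(k2, k1, e2, e1), rel=1e-12)
            assert p == pytest.approx(
                exact_poisson_two_sample(k1, k2, 7 * e1, 7 * e2), rel=1e-12
            )

    def test_null_pvalues_roughly_uniform(self, rng):
        """Common-rate replicates: rejection rate at 0.05 within binomial CI."""
        rej = 0
        reps = 200
        for _ in range(reps):
            k1, k2 = rng.poisson(40), rng.poisson(40)
            if exact_poisson_two_sample(int(k1), int(k2), 1.0, 1.0) <= 0.05:
                rej += 1
        # 95% binomial CI around 0.05 for 200 draws (discrete conservatism
        # of the exact test pushes the rate below the nominal level)
        assert rej / reps <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)

    def test_pairwise_table_with_holm(self):
        counts = pd.Series({"1H": 100, "2H": 110, "3H": 40})
        exp = pd.Series({"1H": 1.0, "2H": 1.0, "3H": 1.0})
        df = pairwise_poisson_tests(counts, exp, adjust="holm")
        assert len(df) == 3
        assert (df["p_adj"] >= df["p"] - 1e-12).all()
        assert (df["p_adj"] <= 1.0).all()


class TestGroupDensity:
    def _calls(self, samples, n_per_sample):
        rows = []
        for s in samples:
            for i in range(n_per_sample[s]):
                rows.append(call_row(s, "chr1", i * 1000, i * 1000 + 500, "DEL"))
        return pd.DataFrame(rows)

    def test_identical_samples_give_equal_groups(self):
        samples = [f"s{i}" for i in range(6)]
        groups = pd.Series(["g1", "g1", "g2", "g2", "g3", "g3"], index=samples)
        calls = self._calls(samples, {s: 4 for s in samples})
        mb = pd.Series({"chr1": 2.0})
        out = group_density(calls, groups, mb, n_boot=50, seed=0)
        dels = out[(out["type"] == "DEL") & (out["chrom"] == "chr1")]
        assert dels["mean_density"].nunique() == 1

    def test_doubling_counts_doubles_density(self):
        samples = [f"s{i}" for i in range(4)]
        groups = pd.Series(["a", "a", "b", "b"], index=samples)
        calls = self._calls(samples, {"s0": 2, "s1": 2, "s2": 4, "s3": 4})
        out = group_density(calls, groups, pd.Series({"chr1": 1.0}), n_boot=10, seed=0)
        d = out[(out["type"] == "DEL")].set_index("group")["mean_density"]
        assert d["b"] == pytest.approx(2 * d["a"])

    def test_unlabelled_sample_rejected(self):
        calls = self._calls(["s0"], {"s0": 1})
        with pytest.raises(ValueError, match="without group"):
            group_density(calls, pd.Series(dtype=object), pd.Series({"chr1": 1.0}))


class TestFrequencySpectrum:
    def test_single_site_row(self):
        sites = pd.DataFrame(
            [{"site_id": 0, "chrom": "chr1", "start": 100, "end": 300,
              "type": "DEL", "n_carriers": 40, "frequency": 40.0, "carriers": ""}]
        )
        spec = frequency_spectrum(sites)
        assert len(spec) == 1
        assert spec.loc[0, "midpoint"] == 200
        assert spec.loc[0, "frequency"] == 40.0

    def test_empty_sites(self):
        assert len(frequency_spectrum(pd.DataFrame(columns=["chrom", "start", "end", "type", "frequency"]))) == 0

    def test_row_count_and_frequencies_match_truth(self, small_panel):
        _, truth = small_panel
        spec = frequency_spectrum(
            truth.sites.assign(frequency=100.0 * truth.sites["n_carriers"] / 40)
        )
        assert len(spec) == len(truth.sites)
        assert spec["frequency"].tolist() == (100.0 * truth.sites["n_carriers"] / 40).tolist()


def test_density_times_length_returns_counts(small_genome):
    mb = captured_length_per_chrom(small_genome.target_intervals())
    assert (mb > 0).all()
    sites = pd.DataFrame(
        [{"chrom": c, "type": "DEL"} for c in mb.index for _ in range(5)]
    )
    table = density_table(sites, mb).set_index("chrom")
    for c in mb.index:
        assert table.loc[c, "del_density"] * table.loc[c, "captured_mb"] == pytest.approx(5.0)
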