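"""Constrained relabeling: conservation, uniformity, determinism, boundaries."""

import numpy as np
import pandas as pd
import pytest

import lingcod_burden as lb
from conftest import make_null_config


def _hosts_with(n_males, n_females, male_colors=None):
    hosts = []
    for i in range(n_males):
        color = male_colors[i] if male_colors else "brown"
        hosts.append(
            lb.HostRecord(f"M{i}", "R1", "S1", 10.0, "male", color, 60.0, 2.0, 0.05)
        )
    for i in range(n_females):
        hosts.append(
            lb.HostRecord(f"W{i}", "R1", "S1", 10.0, "female", "blue" if i % 2 else "brown", 60.0, 2.0, 0.05)
        )
    return hosts


class TestPermuteColors:
    def test_males_only_conserves_counts_and_females(self):
        hosts = _hosts_with(63, 26)
        scheme = lb.PermutationScheme(mode="males_only", n_blue_males=4, seed=1)
        for rep in range(50):
            out = lb.permute_colors(hosts, scheme, rep)
            males = [h for h in out if h.sex == "male"]
            assert sum(h.color == "blue" for h in males) == 4
            # females retain their actual colors
            for orig, new in zip(hosts, out):
                if orig.sex == "female":
                    assert new.color == orig.color

    def test_both_sexes_conserves_both_counts(self):
        hosts = _hosts_with(63, 26)
        scheme = lb.PermutationScheme(mode="both_sexes", n_blue_males=4, n_blue_females=11, seed=1)
        for rep in range(50):
            out = lb.permute_colors(hosts, scheme, rep)
            assert sum(h.color == "blue" for h in out if h.sex == "male") == 4
            assert sum(h.color == "blue" for h in out if h.sex == "female") == 11

    def test_uniform_over_eligible_subsets(self):
        """3 males, choose 1: each assignment appears ~1/3 of the time."""
        hosts = _hosts_with(3, 2)
        scheme = lb.PermutationScheme(mode="males_only", n_blue_males=1, seed=3)
        freq = {"M0": 0, "M1": 0, "M2": 0}
        n = 3000
        for rep in range(n):
            out = lb.permute_colors(hosts, scheme, rep)
            chosen = [h.fish_id for h in out if h.sex == "male" and h.color == "blue"]
            freq[chosen[0]] += 1
        for fid in freq:
            assert abs(freq[fid] / n - 1 / 3) < 0.03

    def test_infeasible_constraint_raises(self):
        hosts = _hosts_with(2, 2)
        scheme = lb.PermutationScheme(mode="males_only", n_blue_males=4)
        with pytest.raises(ValueError, match="blue males"):
            lb.permute_colors(hosts, scheme, 0)

    def test_replicate_determinism(self):
        hosts = _hosts_with(20, 10)
        scheme = lb.PermutationScheme(mode="both_sexes", n_blue_males=4, n_blue_females=3, seed=9)
        a = [h.color for h in lb.permute_colors(hosts, scheme, 7)]
        b = [h.color for h in lb.permute_colors(hosts, scheme, 7)]
        assert a == b

    def test_zero_replicates_invalid(self):
        with pytest.raises(ValueError):
            lb.PermutationScheme(n_replicates=0)


class TestRunPermutationTest:
    def test_degenerate_exchangeable_males_give_proportion_one(self, fast_design):
        """If all males carry identical data, relabeling which of them are
        blue cannot change the fit: every replicate z ties the observed z and
        the two-sided extreme proportion is 1."""
        rng = np.random.default_rng(8)
        hosts, rows = [], []
        for i in range(8):  # identical males, 4 blue / 4 brown observed
            hosts.append(
                lb.HostRecord(f"M{i}", "R1", "S1", 20.0, "male",
                              "blue" if i < 4 else "brown", 60.0, 2.0, 0.05)
            )
            rows.append((f"M{i}", [7, 3]))
        for i in range(10):  # females vary
            hosts.append(
                lb.HostRecord(f"W{i}", "R1", "S1", 20.0, "female",
                              "blue" if i < 5 else "brown", 60.0, 2.0, 0.05)
            )
            rows.append((f"W{i}", list(rng.integers(0, 12, 2))))
        counts = lb.ParasiteCountTable(
            pd.DataFrame(
                [
                    {"fish_id": fid, "taxon_id": f"T{t}", "count": c}
                    for fid, cs in rows
                    for t, c in enumerate(cs)
                ]
            )
        )
        design = lb.ModelDesign(
            include_depth=False, nested_terms=(), taxon_structure="none",
            use_offset=False,
        )
        scheme = lb.PermutationScheme(
            mode="males_only", n_blue_males=4, n_replicates=20, seed=5
        )
        res = lb.run_permutation_test(hosts, counts, design, scheme)
        assert res.extreme_proportion == 1.0
        assert res.n_failed == 0

    def test_same_seed_same_replicate_vector(self, fast_design):
        ds = lb.generate_dataset(make_null_config(55))
        scheme = lb.PermutationScheme(mode="males_only", n_replicates=30, seed=11)
        r1 = lb.run_permutation_test(ds.hosts, ds.counts, fast_design, scheme)
        r2 = lb.run_permutation_test(ds.hosts, ds.counts, fast_design, scheme)
        np.testing.assert_array_equal(r1.replicate_z, r2.replicate_z)
        assert r1.extreme_proportion == r2.extreme_proportion

    def test_null_exchangeability_ks(self, fast_design):
        """Under the null generator, observed and replicate z share one
        distribution (two-sample KS not extreme at alpha = 0.01)."""
        from scipy.stats import ks_2samp

        observed, replicates = [], []
        for sim in range(30):
            ds = lb.generate_dataset(make_null_config(7000 + sim))
            scheme = lb.PermutationScheme(
                mode="males_only", n_replicates=39, seed=7000 + sim
            )
            res = lb.run_permutation_test(ds.hosts, ds.counts, fast_design, scheme)
            observed.append(res.observed_z)
            replicates.extend(res.replicate_z[res.replicate_converged])
        stat, p = ks_2samp(observed, replicates)
        assert p > 0.01

    def test_replicates_frame_layout(self, fast_design):
        from lingcod_burden.permutation import replicates_frame

        ds = lb.generate_dataset(make_null_config(91))
        scheme = lb.PermutationScheme(mode="males_only", n_replicates=12, seed=2)
        res = lb.run_permutation_test(ds.hosts, ds.counts, fast_design, scheme)
        frame = replicates_frame(res)
        assert list(frame.columns) == ["replicate_index", "z", "converged"]
        assert len(frame) == 12
        assert 0.0 <= res.extreme_proportion <= 1.0
        assert 0 < res.corrected_p <= 1.0
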