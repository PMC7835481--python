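import numpy as np
import pytest

from perfilt import (DegenerateDFLError, FilterResult, TaxaTable, dfl_sequence,
                     generate_mock, mbqc_design, order_taxa,
                     perfect_permutation_fast, perfect_permutation_full,
                     perfect_simultaneous, rule_of_thumb_filter)
from conftest import small_mock_design


@pytest.fixture(scope="module")
def mock_table():
    table, truth = generate_mock(mbqc_design(seed=3))
    return table, truth


class TestSimultaneous:
    def test_alpha_one_removes_nothing(self, mock_table):
        table, _ = mock_table
        res = perfect_simultaneous(table, alpha=1.0)
        assert res.removed == set()
        assert res.cutoff_position == 1

    def test_dominant_taxon_retained(self):
        # one taxon with ~all the squared Gram mass plus 30 sparse noise taxa
        rng = np.random.default_rng(5)
        n = 40
        dom = rng.poisson(1000, size=(n, 1))
        noise = (rng.random((n, 30)) < 0.08) * rng.poisson(3, size=(n, 30))
        t = TaxaTable(np.hstack([dom, noise]),
                      [f"s{i}" for i in range(n)],
                      ["dominant"] + [f"n{i:02d}" for i in range(30)])
        res = perfect_simultaneous(t, alpha=0.1)
        assert "dominant" in res.retained

    def test_degenerate_dfl_errors(self):
        t = TaxaTable(np.eye(4, dtype=int) * 3,
                      [f"s{i}" for i in range(4)], [f"t{i}" for i in range(4)])
        with pytest.raises(DegenerateDFLError, match="equal"):
            perfect_simultaneous(t)

    def test_nested_alpha_removal(self, mock_table):
        # a smaller alpha crosses the significance threshold later, so it
        # removes at least as many taxa
        table, _ = mock_table
        strict = perfect_simultaneous(table, alpha=0.02)
        lax = perfect_simultaneous(table, alpha=0.3)
        assert lax.removed <= strict.removed

    def test_monotonized_pvalues_non_increasing(self, mock_table):
        table, _ = mock_table
        res = perfect_simultaneous(table, alpha=0.1)
        vals = [res.pvalues[j] for j in sorted(res.pvalues)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_partition_invariant(self, mock_table):
        table, _ = mock_table
        res = perfect_simultaneous(table, alpha=0.1)
        assert res.retained | res.removed == set(table.taxon_ids)
        assert not res.retained & res.removed


class TestPermutationFull:
    def test_determinism(self, mock_table):
        table, _ = mock_table
        a = perfect_permutation_full(table, alpha=0.1, k=200, seed=7)
        b = perfect_permutation_full(table, alpha=0.1, k=200, seed=7)
        assert a.retained == b.retained
        assert a.pvalues == b.pvalues

    def test_k_minimum_enforced(self, mock_table):
        table, _ = mock_table
        with pytest.raises(ValueError, match=">= 100"):
            perfect_permutation_full(table, k=50)

    def test_two_taxon_enumeration(self):
        # p = 2: only j = 1 testable and only two orderings exist.  The
        # ordering whose first taxon has the larger loss attains the
        # smallest possible empirical tail value of the two.
        t = TaxaTable(np.array([[10, 1], [8, 2], [9, 1]]),
                      ["a", "b", "c"], ["big", "small"])
        from perfilt.filtering_loss import TaxaOrdering
        pvals = {}
        for name, order in (("big_first", [0, 1]), ("small_first", [1, 0])):
            o = TaxaOrdering(order=np.array(order), criterion="custom")
            res = perfect_permutation_full(t, alpha=0.5, k=200, ordering=o,
                                           seed=1, tail="empirical")
            pvals[name] = res.raw_pvalues[1]
        dfl_big = dfl_sequence(t, TaxaOrdering(order=np.array([0, 1]),
                                               criterion="custom")).dfl[0]
        dfl_small = dfl_sequence(t, TaxaOrdering(order=np.array([1, 0]),
                                                 criterion="custom")).dfl[0]
        assert dfl_big > dfl_small  # "big" really is the maximal observation
        assert pvals["big_first"] == min(pvals.values())
        assert pvals["small_first"] == 1.0

    def test_monotonized_pvalues_non_increasing(self, mock_table):
        table, _ = mock_table
        res = perfect_permutation_full(table, alpha=0.1, k=200, seed=1)
        vals = [res.pvalues[j] for j in sorted(res.pvalues)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestPermutationFast:
    def test_matches_full_on_mock(self, mock_table):
        table, _ = mock_table
        full = perfect_permutation_full(table, alpha=0.1, k=300, seed=11)
        fast = perfect_permutation_fast(table, alpha=0.1, k=300, seed=11)
        assert fast.cutoff_position == full.cutoff_position
        assert fast.retained == full.retained

    def test_shared_streams_give_identical_probed_pvalues(self, mock_table):
        table, _ = mock_table
        full = perfect_permutation_full(table, alpha=0.1, k=300, seed=11)
        fast = perfect_permutation_fast(table, alpha=0.1, k=300, seed=11)
        for j, p in fast.raw_pvalues.items():
            assert p == full.raw_pvalues[j]

    def test_no_cutoff_matches_full(self):
        # homogeneous Poisson table: no position is significant at a tiny alpha
        rng = np.random.default_rng(0)
        t = TaxaTable(rng.poisson(20, size=(15, 12)),
                      [f"s{i}" for i in range(15)],
                      [f"t{j:02d}" for j in range(12)])
        full = perfect_permutation_full(t, alpha=1e-4, k=200, seed=5)
        fast = perfect_permutation_fast(t, alpha=1e-4, k=200, seed=5)
        assert full.no_cutoff and fast.no_cutoff
        assert full.retained == fast.retained == set(t.taxon_ids)

    def test_probe_bound_large_p(self):
        # p = 1000: probes bounded by 2 ceil(log2 p) + 4 = 24
        rng = np.random.default_rng(2)
        n, p_sig, p_noise = 30, 20, 980
        sig = rng.poisson(rng.uniform(200, 2000, p_sig), size=(n, p_sig))
        noise = (rng.random((n, p_noise)) < 0.05) * rng.poisson(3, size=(n, p_noise))
        t = TaxaTable(np.hstack([sig, noise]),
                      [f"s{i}" for i in range(n)],
                      [f"t{j:04d}" for j in range(p_sig + p_noise)])
        fast = perfect_permutation_fast(t, alpha=0.1, k=100, seed=3)
        bound = 2 * int(np.ceil(np.log2(1000))) + 4
        assert len(fast.probes) <= bound
        assert fast.probes == sorted(set(fast.probes), key=fast.probes.index)

    def test_matches_full_on_seeded_synthetic_tables(self):
        for seed in range(5):  # broader sweep in the acceptance suite
            table, _ = generate_mock(small_mock_design(seed))
            full = perfect_permutation_full(table, alpha=0.1, k=200, seed=seed)
            fast = perfect_permutation_fast(table, alpha=0.1, k=200, seed=seed)
            assert fast.cutoff_position == full.cutoff_position
            assert fast.retained == full.retained


class TestRuleOfThumb:
    def test_any_positive_count_retained(self, tiny_table):
        res = rule_of_thumb_filter(tiny_table, min_count=0, min_samples=1)
        assert res.retained == {"tA", "tB", "tC", "tD"}

    def test_k5_removes_taxon_in_four_samples(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:, 0] = 3
        counts[:4, 1] = 2
        t = TaxaTable(counts, [f"s{i}" for i in range(10)], ["common", "A"])
        res = rule_of_thumb_filter(t, min_count=0, min_samples=5)
        assert "A" in res.removed
        assert "common" in res.retained

    def test_brute_force_count_threshold(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 6, size=(6, 4))
        t = TaxaTable(counts, [f"s{i}" for i in range(6)],
                      [f"t{j}" for j in range(4)])
        res = rule_of_thumb_filter(t, min_count=2, min_samples=2)
        expected = {t.taxon_ids[j] for j in range(4)
                    if (counts[:, j] > 2).sum() >= 2}
        assert res.retained == expected

    def test_prevalence_percent_variant(self, tiny_table):
        res = rule_of_thumb_filter(tiny_table, min_prevalence_pct=60)
        # tA in 3/3, tC in 2/3 (67%), tB and tD in 1/3
        assert res.retained == {"tA", "tC"}

    def test_excessive_min_samples_warns_but_returns(self, tiny_table, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="perfilt"):
            res = rule_of_thumb_filter(tiny_table, min_samples=99)
        assert res.retained == set()
        assert "exceeds" in caplog.text


class TestFilterResult:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FilterResult(method="x", retained={"a"}, removed={"a"})

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            FilterResult(method="x", retained={"a"}, removed=set(),
                         pvalues={1: 1.5})

    def test_json_round_trip(self, tmp_path, mock_table):
        import json
        table, _ = mock_table
        res = perfect_simultaneous(table, alpha=0.1)
        path = tmp_path / "r.json"
        res.to_json(path)
        doc = json.loads(path.read_text())
        assert set(doc["retained"]) == res.retained
        assert doc["method"] == "simultaneous"
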