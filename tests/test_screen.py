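"""Gene aggregation, fold changes, replicate correlation and enrichment
filtering."""

import numpy as np
import pandas as pd
import pytest

from threecs import (
    aggregate_genes,
    enrichment_filter,
    intersect_replicates,
    log2fc,
    replicate_correlation,
)


def guide_frame(data: dict, samples=("d0", "d21")) -> pd.DataFrame:
    return pd.DataFrame(data, index=list(samples)).T


class TestAggregation:
    ANNOTATION = {"g1": "USP7", "g2": "USP7", "g3": "USP7", "g4": "OTUB1"}

    def test_gene_sum(self):
        counts = pd.DataFrame(
            {"d0": [10, 20, 30, 5]}, index=["g1", "g2", "g3", "g4"]
        )
        table = aggregate_genes(counts, self.ANNOTATION)
        assert int(table.counts.loc["USP7", "d0"]) == 60
        assert int(table.counts.loc["OTUB1", "d0"]) == 5

    def test_single_gene_normalizes_to_one(self):
        counts = pd.DataFrame({"d0": [10, 20]}, index=["g1", "g2"])
        table = aggregate_genes(counts, {"g1": "USP7", "g2": "USP7"})
        assert table.normalized().loc["USP7", "d0"] == 1.0

    def test_unmapped_members_tracked_and_warned(self):
        counts = pd.DataFrame({"d0": [10, 5]}, index=["g1", "mystery"])
        with pytest.warns(UserWarning, match="no gene annotation"):
            table = aggregate_genes(counts, {"g1": "USP7"})
        assert list(table.unmapped.index) == ["mystery"]
        assert table.normalized().loc["USP7", "d0"] == 1.0

    def test_aggregate_then_normalize_equals_normalize_then_sum(self):
        rng = np.random.default_rng(0)
        members = [f"g{i}" for i in range(30)]
        annotation = {m: f"gene{i % 7}" for i, m in enumerate(members)}
        counts = pd.DataFrame(
            {"d0": rng.integers(0, 1000, 30)}, index=members
        )
        table = aggregate_genes(counts, annotation)
        norm_members = counts["d0"] / counts["d0"].sum()
        expected = norm_members.groupby(pd.Series(annotation)).sum()
        assert np.allclose(
            table.normalized()["d0"].sort_index(), expected.sort_index()
        )

    def test_duplicate_member_rows_rejected(self):
        counts = pd.DataFrame({"d0": [1, 2]}, index=["g1", "g1"])
        with pytest.raises(ValueError):
            aggregate_genes(counts, {"g1": "USP7"})


class TestLog2FC:
    def test_identical_samples_give_zero(self):
        counts = guide_frame({"a": (10, 10), "b": (20, 20)})
        fc = log2fc(counts, "d0", "d21")
        assert np.allclose(fc, 0.0)

    def test_norm_doubling_without_pseudocount(self):
        counts = guide_frame({"a": (10, 40), "b": (30, 30), "c": (20, 50)})
        fc = log2fc(counts, "d0", "d21", pseudocount=0)
        norm0 = counts["d0"] / counts["d0"].sum()
        norm21 = counts["d21"] / counts["d21"].sum()
        assert fc["a"] == pytest.approx(np.log2(norm21["a"] / norm0["a"]))

    def test_antisymmetry_under_sample_swap(self):
        counts = guide_frame({"a": (10, 40), "b": (0, 30), "c": (20, 5)})
        forward = log2fc(counts, "d0", "d21")
        backward = log2fc(counts, "d21", "d0")
        assert np.allclose(forward, -backward)

    def test_simulated_fourfold_depletion(self):
        rng = np.random.default_rng(1)
        n = 200
        base = rng.integers(5_000, 10_000, n).astype(float)
        depleted = base.copy()
        depleted[:20] /= 4
        counts = pd.DataFrame(
            {"d0": rng.poisson(base), "d21": rng.poisson(depleted)},
            index=[f"g{i}" for i in range(n)],
        )
        fc = log2fc(counts, "d0", "d21")
        # renormalization shifts everything by a small constant; compare
        # the depleted group against the unchanged bulk
        assert (fc[:20].mean() - fc[20:].mean()) == pytest.approx(-2.0, abs=0.15)

    def test_missing_sample_key_error(self):
        with pytest.raises(KeyError):
            log2fc(guide_frame({"a": (1, 1)}), "d0", "d99")


class TestCorrelation:
    def test_identical_tables_perfect(self):
        counts = pd.Series({"a": 10, "b": 20, "c": 5})
        r, r2, rho = replicate_correlation(counts, counts)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_anti_ranked_spearman(self):
        a = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        b = pd.Series({"a": 9, "b": 6, "c": 3, "d": 1})
        _, _, rho = replicate_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_intersection_of_members_used(self):
        a = pd.Series({"a": 1, "b": 2, "c": 3, "x": 99})
        b = pd.Series({"a": 1, "b": 2, "c": 3, "y": 99})
        r, _, _ = replicate_correlation(a, b)
        assert r == pytest.approx(1.0)

    def test_too_few_shared_members(self):
        with pytest.raises(ValueError):
            replicate_correlation(
                pd.Series({"a": 1, "b": 2}), pd.Series({"a": 1, "b": 2})
            )

    def test_noisy_replicates_high_r2(self):
        rng = np.random.default_rng(2)
        true = rng.integers(20_000, 60_000, 315)
        rep1 = pd.Series(rng.poisson(true), index=range(315))
        rep2 = pd.Series(rng.poisson(true), index=range(315))
        _, r2, rho = replicate_correlation(rep1, rep2)
        assert r2 > 0.9 and rho > 0.88


class TestEnrichment:
    def test_strict_twofold_boundary(self):
        counts = guide_frame(
            {"exact2": (10, 20), "above": (10, 21), "below": (10, 19)},
            samples=("ctrl", "trt"),
        )
        # equalize sample totals so normalized ratio == raw ratio
        counts.loc["filler"] = [70, 40]
        result = enrichment_filter(counts, "trt", "ctrl", min_fold=2)
        assert "above" in result.members
        assert "exact2" not in result.members
        assert "below" not in result.members

    def test_zero_control_flagged_and_included(self):
        counts = guide_frame({"a": (0, 10), "b": (10, 10)}, samples=("ctrl", "trt"))
        result = enrichment_filter(counts, "trt", "ctrl")
        assert "a" in result.members and "a" in result.flagged_infinite

    def test_monotone_in_min_fold(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            {"ctrl": rng.integers(1, 100, 200), "trt": rng.integers(1, 100, 200)},
            index=[f"g{i}" for i in range(200)],
        )
        sizes = [
            len(enrichment_filter(counts, "trt", "ctrl", f).members)
            for f in (1, 2, 4, 8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_spiked_enrichment_recovered(self):
        rng = np.random.default_rng(4)
        n = 5000
        base = np.full(n, 1000.0)
        treated = base.copy()
        treated[:50] *= 4
        counts = pd.DataFrame(
            {"ctrl": rng.poisson(base), "trt": rng.poisson(treated)},
            index=[f"g{i}" for i in range(n)],
        )
        result = enrichment_filter(counts, "trt", "ctrl", min_fold=2)
        spiked = {f"g{i}" for i in range(50)}
        assert spiked <= result.members
        # false positives are rare at this depth
        assert len(result.members - spiked) < 0.01 * n

    def test_invalid_min_fold(self):
        with pytest.raises(ValueError):
            enrichment_filter(guide_frame({"a": (1, 1)}), "d21", "d0", 0)


class TestIntersection:
    def test_three_way(self):
        common, sizes = intersect_replicates({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"})
        assert common == {"B", "C"}
        assert sizes == [3, 3, 2]

    def test_disjoint(self):
        common, _ = intersect_replicates({"A"}, {"B"})
        assert common == frozenset()

    def test_planted_resistant_subset_survives(self):
        rng = np.random.default_rng(5)
        n = 2000
        planted = {f"g{i}" for i in range(30)}
        sets = []
        for rep in range(3):
            base = np.full(n, 500.0)
            treated = base.copy()
            treated[:30] *= 6
            counts = pd.DataFrame(
                {"ctrl": rng.poisson(base), "trt": rng.poisson(treated)},
                index=[f"g{i}" for i in range(n)],
            )
            sets.append(enrichment_filter(counts, "trt", "ctrl").members)
        common, _ = intersect_replicates(*sets)
        assert planted <= common

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_replicates({"A"})
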