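"""Master lists, methylation matrices, clustering, concordance selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from methbin import (
    DmrMatrix,
    DmrSet,
    GenomicInterval,
    build_master_list,
    cluster_rows,
    filter_body_methylated,
    methylation_matrix,
    rank_by_mean_difference,
    select_concordant,
)
from methbin.conserved import _abs_corr_distance
from oracles import average_linkage_naive

GI = GenomicInterval


def win(start, ctx="CG"):
    return GI("chr1", start, start + 100, context=ctx, direction="hyper")


def matrix_from(values: dict, starts=None, ctx="CG"):
    vals = pd.DataFrame(values)
    starts = starts or [i * 100 for i in range(len(vals))]
    windows = [win(s, ctx) for s in starts]
    vals.index = [f"chr1:{s}-{s + 100}" for s in starts]
    return DmrMatrix(vals, windows, context=ctx)


class TestMasterList:
    def test_shared_window_deduplicated(self):
        a = DmrSet("c1", "CG", "hyper", [win(0), win(200)])
        b = DmrSet("c2", "CG", "hyper", [win(200), win(400)])
        master = build_master_list([a, b])
        assert [m.start for m in master] == [0, 200, 400]
        assert len(master) >= max(len(a), len(b))

    def test_mixed_context_rejected(self):
        a = DmrSet("c1", "CG", "hyper", [win(0)])
        b = DmrSet("c2", "CHH", "hyper", [win(0, "CHH")])
        with pytest.raises(ValueError):
            build_master_list([a, b])


class TestMethylationMatrix:
    def test_values_and_rounding(self, simulated_samples):
        from conftest import make_sample

        rows = [("chr1", 10, "+", "CG", 2, 4), ("chr1", 20, "+", "CG", 2, 4)]
        s1 = make_sample(rows, "s1")
        s2 = make_sample([("chr1", 10, "+", "CG", 4, 4), ("chr1", 20, "+", "CG", 4, 8)], "s2")
        m = methylation_matrix([win(0)], [s1, s2], "CG")
        assert m.values.loc["chr1:0-100", "s1"] == pytest.approx(0.5)
        # 8/12 = 0.6666... rounds to 3 decimals
        assert m.values.loc["chr1:0-100", "s2"] == pytest.approx(0.667)

    def test_missing_flagged_and_all_missing_dropped(self):
        from conftest import make_sample

        s1 = make_sample([("chr1", 10, "+", "CG", 2, 4)], "s1")
        s2 = make_sample([("chr1", 210, "+", "CG", 2, 4)], "s2")
        m = methylation_matrix([win(0), win(200), win(400)], [s1, s2], "CG")
        assert len(m.values) == 2  # win(400) dropped
        assert np.isnan(m.values.loc["chr1:0-100", "s2"])

    def test_agrees_with_region_quantification(self, simulated_samples):
        from methbin import QuantRegion, quantify_region

        sample = simulated_samples["mutA"]
        w = win(10_000)
        m = methylation_matrix([w], [sample], "CG")
        pct, _ = quantify_region(sample, QuantRegion("w", "chr1", w.start, w.end,
                                                     contexts=("CG",)),
                                 min_site_coverage=4)["CG"]
        v = m.values.iloc[0, 0]
        if pct is None:
            assert np.isnan(v)
        else:
            assert v == pytest.approx(pct / 100, abs=5e-4)  # 3-decimal rounding


class TestClusterRows:
    def test_identical_rows_merge_first_at_zero(self):
        m = matrix_from({
            "a": [0.1, 0.1, 0.9], "b": [0.2, 0.2, 0.8], "c": [0.3, 0.3, 0.1],
        })
        Z, order = cluster_rows(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_negated_row_has_zero_absolute_correlation_distance(self):
        X = np.array([[0.1, 0.5, 0.9], [0.9, 0.5, 0.1]])
        d = squareform(_abs_corr_distance(X))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_average_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(18, 8))
        D = squareform(_abs_corr_distance(X))
        Z = linkage(squareform(D, checks=False), method="average")
        got = squareform(cophenet(Z))
        expect = average_linkage_naive(D)
        assert np.allclose(got, expect, atol=1e-9)

    def test_constant_row_maximal_distance(self):
        m = matrix_from({"a": [0.5, 0.1], "b": [0.5, 0.9], "c": [0.5, 0.5]})
        d = squareform(_abs_corr_distance(m.values.to_numpy()))
        assert d[0, 1] == pytest.approx(1.0)


class TestSelectConcordant:
    MUT = ["m1", "m2", "m3", "m4", "m5"]
    CTL = ["c1", "c2", "c3"]

    def _matrix(self, rows):
        cols = self.MUT + self.CTL
        return matrix_from({c: [r[i] for r in rows] for i, c in enumerate(cols)})

    def test_all_mutants_above_controls_selected(self):
        m = self._matrix([[0.8, 0.7, 0.9, 0.75, 0.85, 0.2, 0.25, 0.2]])
        sel = select_concordant(m, self.MUT, self.CTL, "hyper")
        assert len(sel) == 1

    def test_single_discordant_mutant_excluded(self):
        m = self._matrix([[0.8, 0.7, 0.9, 0.75, 0.1, 0.2, 0.25, 0.2]])
        assert select_concordant(m, self.MUT, self.CTL, "hyper") == []

    def test_no_magnitude_cutoff(self):
        # tiny but uniformly positive differences still selected
        m = self._matrix([[0.21, 0.22, 0.21, 0.23, 0.22, 0.2, 0.2, 0.2]])
        assert len(select_concordant(m, self.MUT, self.CTL, "hyper")) == 1

    def test_hypo_direction(self):
        m = self._matrix([[0.1, 0.05, 0.1, 0.08, 0.06, 0.5, 0.55, 0.5]])
        assert len(select_concordant(m, self.MUT, self.CTL, "hypo")) == 1
        assert select_concordant(m, self.MUT, self.CTL, "hyper") == []

    def test_cluster_cut_mode_selects_concordant_cluster(self):
        rows = [
            [0.8, 0.7, 0.9, 0.75, 0.85, 0.2, 0.25, 0.2],
            [0.82, 0.72, 0.88, 0.7, 0.8, 0.22, 0.2, 0.24],
            [0.1, 0.9, 0.2, 0.8, 0.1, 0.5, 0.5, 0.5],
            [0.9, 0.1, 0.8, 0.2, 0.9, 0.5, 0.5, 0.5],
        ]
        m = self._matrix(rows)
        sel = select_concordant(m, self.MUT, self.CTL, "hyper",
                                mode="cluster-cut", n_clusters=2)
        assert {s.start for s in sel} == {0, 100}

    def test_incomplete_row_never_selected(self):
        m = self._matrix([[0.8, 0.7, 0.9, 0.75, np.nan, 0.2, 0.25, 0.2]])
        assert select_concordant(m, self.MUT, self.CTL, "hyper") == []


class TestBodyMethylationFilter:
    def test_cg_window_in_gene_removed_chh_untouched(self):
        genes = [GI("chr1", 50, 500)]
        windows = [win(0, "CG"), win(600, "CG"), win(100, "CHH")]
        kept = filter_body_methylated(windows, genes)
        keys = {(k.start, k.context) for k in kept}
        assert keys == {(600, "CG"), (100, "CHH")}  # 1-bp overlap removes win(0)


class TestRanking:
    def test_score_and_tie_order(self):
        m = matrix_from(
            {"m1": [0.9, 0.3, 0.9], "c1": [0.1, 0.1, 0.1]},
            starts=[200, 100, 0],
        )
        ranked = rank_by_mean_difference(m, ["m1"], ["c1"])
        assert list(ranked["score"].round(3)) == [0.8, 0.8, 0.2]
        # tied scores fall back to coordinate order
        assert list(ranked.index[:2]) == ["chr1:0-100", "chr1:200-300"]

    def test_rows_conserved_except_missing(self):
        m = matrix_from({"m1": [0.9, np.nan], "c1": [0.1, 0.1]})
        ranked = rank_by_mean_difference(m, ["m1"], ["c1"])
        assert len(ranked) == 1
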