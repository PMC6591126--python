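"""Alpha diversity, Bray-Curtis, PERMANOVA/PERMDISP, indicator species."""

import numpy as np
import pandas as pd
import pytest

from rhizonet import community


class TestAlphaDiversity:
    def test_uniform_four_otus(self):
        table = pd.DataFrame({"a": [25], "b": [25], "c": [25], "d": [25]})
        res = community.alpha_diversity(table)
        assert res["richness"].iloc[0] == 4
        assert res["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert res["sheldon_evenness"].iloc[0] == pytest.approx(1.0)

    def test_single_otu(self):
        table = pd.DataFrame({"a": [100], "b": [0]})
        res = community.alpha_diversity(table)
        assert res["richness"].iloc[0] == 1
        assert res["shannon"].iloc[0] == pytest.approx(0.0)
        assert res["sheldon_evenness"].iloc[0] == pytest.approx(1.0)

    def test_hand_summed_formula(self):
        table = pd.DataFrame({"a": [50], "b": [30], "c": [20]})
        res = community.alpha_diversity(table)
        p = np.array([0.5, 0.3, 0.2])
        h = -(p * np.log(p)).sum()
        assert res["shannon"].iloc[0] == pytest.approx(h)
        assert res["sheldon_evenness"].iloc[0] == pytest.approx(np.exp(h) / 3)

    def test_shannon_maximal_at_uniform(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 50, 6)
            table = pd.DataFrame([counts, [counts.sum() // 6] * 6])
            table.columns = [f"o{i}" for i in range(6)]
            res = community.alpha_diversity(table)
            assert res["shannon"].iloc[1] >= res["shannon"].iloc[0] - 1e-9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            community.alpha_diversity(pd.DataFrame({"a": [0]}))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        table = pd.DataFrame({"a": [3, 3], "b": [7, 7]})
        d = community.bray_curtis(table)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        table = pd.DataFrame({"a": [5, 0], "b": [0, 9]})
        assert community.bray_curtis(table).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        table = pd.DataFrame({"a": [6, 2], "b": [4, 8]})
        # sum|diff| = 4 + 4 = 8; sum(total) = 20 -> 0.4
        assert community.bray_curtis(table).iloc[0, 1] == pytest.approx(0.4)


def _permanova_oracle(D, codes):
    """From-scratch pseudo-F via the sum-of-squares identity."""
    n = D.shape[0]
    a = len(set(codes))
    ss_total = (D**2).sum() / (2 * n)
    ss_within = 0.0
    for g in set(codes):
        idx = np.flatnonzero(codes == g)
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_statistic_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        table = pd.DataFrame(np.abs(X) + 1)
        table.columns = [f"o{i}" for i in range(4)]
        d = community.bray_curtis(table)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = community.permanova(d, groups, n_perm=99, seed=0)
        codes = (groups == "b").astype(int)
        assert res.statistic == pytest.approx(
            _permanova_oracle(d.to_numpy(), codes)
        )

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        table = pd.DataFrame(rng.integers(1, 50, (8, 5)))
        table.index = [f"s{i}" for i in range(8)]
        table.columns = [f"o{i}" for i in range(5)]
        d = community.bray_curtis(table)
        groups = ["x"] * 4 + ["y"] * 4
        mine = community.permanova(d, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)), groups, permutations=0
        )
        assert mine.statistic == pytest.approx(theirs["test statistic"])

    def test_maximal_separation_minimal_p(self):
        block1 = np.tile([10, 0, 0, 0], (8, 1))
        block2 = np.tile([0, 0, 0, 10], (8, 1))
        table = pd.DataFrame(np.vstack([block1, block2]) + 0)
        table.columns = list("abcd")
        table.iloc[::2, 1] += 1  # break exact ties within groups
        d = community.bray_curtis(table)
        groups = ["g1"] * 8 + ["g2"] * 8
        res = community.permanova(d, groups, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.explained_variation > 50

    def test_permutation_invariant_to_sample_reordering(self, rng):
        table = pd.DataFrame(rng.integers(1, 40, (8, 6)))
        table.columns = [f"o{i}" for i in range(6)]
        groups = np.array(["a", "b"] * 4)
        d = community.bray_curtis(table)
        r1 = community.permanova(d, groups, n_perm=199, seed=5)
        perm = rng.permutation(8)
        d2 = d.iloc[perm, perm]
        r2 = community.permanova(d2, groups[perm], n_perm=199, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_degenerate_distances_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            community.permanova(d, ["a", "a", "b", "b"], n_perm=99, seed=0)


class TestPermdisp:
    def test_dispersion_difference_detected(self, rng):
        """Near-duplicated points vs a widely dispersed group."""
        tight = np.tile([10.0, 10, 10, 10], (8, 1)) + rng.normal(0, 0.05, (8, 4))
        loose = np.abs(rng.normal(10, 8, (8, 4))) + 1
        table = pd.DataFrame(np.vstack([tight, loose]))
        table.columns = list("abcd")
        d = community.bray_curtis(table)
        res = community.permdisp(d, ["t"] * 8 + ["l"] * 8, n_perm=999, seed=0)
        assert res.p_value <= 0.05

    def test_statistic_matches_vegan_betadisper(self, rng, tmp_path):
        """Cross-check the centroid-dispersion F against R's
        vegan::betadisper, which implements the same imaginary-part
        correction for negative PCoA eigenvalues."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = pd.DataFrame(rng.integers(1, 50, (10, 6)))
        table.index = [f"s{i}" for i in range(10)]
        table.columns = [f"o{i}" for i in range(6)]
        d = community.bray_curtis(table)
        groups = ["x"] * 5 + ["y"] * 5
        mine = community.permdisp(d, groups, n_perm=99, seed=0)
        mat = tmp_path / "dist.tsv"
        d.to_csv(mat, sep="\t")
        script = (
            "suppressMessages(library(vegan));"
            f"m <- as.matrix(read.table('{mat}', sep='\t', header=TRUE, row.names=1));"
            "g <- factor(rep(c('x','y'), each=5));"
            "bd <- betadisper(as.dist(m), g, type='centroid');"
            "cat(anova(bd)$'F value'[1])"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert mine.statistic == pytest.approx(float(out.stdout.strip()), rel=1e-5)

    def test_single_point_per_group_rejected(self):
        table = pd.DataFrame({"a": [1, 5], "b": [9, 2]})
        d = community.bray_curtis(table)
        with pytest.raises(ValueError):
            community.permdisp(d, ["x", "y"], n_perm=99, seed=0)


class TestIndicatorSpecies:
    def test_perfect_indicator_scores_one(self):
        table = pd.DataFrame(
            {"ind": [8, 9, 0, 0, 0, 0], "bg": [5, 5, 5, 5, 5, 5]}
        )
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        res = community.indicator_species(table, groups, n_perm=99, seed=0)
        assert res.loc["ind", "indval"] == pytest.approx(1.0)
        assert res.loc["ind", "group"] == "g1"

    def test_absent_species_scores_zero_for_its_group(self):
        table = pd.DataFrame({"x": [0, 0, 3, 4]})
        res = community.indicator_species(table, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.loc["x", "group"] == "b"
        assert res.loc["x", "indval"] == pytest.approx(1.0)

    def test_hand_evaluated_three_groups(self):
        # group means: g1 -> 6, g2 -> 2, g3 -> 0; A = 6/8; B = 1 in g1
        table = pd.DataFrame({"x": [6, 6, 2, 2, 0, 0]})
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        res = community.indicator_species(table, groups, n_perm=99, seed=0)
        assert res.loc["x", "indval"] == pytest.approx(np.sqrt(6 / 8 * 1.0))

    def test_indval_monotone_in_fidelity(self):
        # same specificity, higher fidelity -> higher IndVal
        lo = pd.DataFrame({"x": [10, 0, 0, 0, 0, 0]})
        hi = pd.DataFrame({"x": [5, 5, 0, 0, 0, 0]})
        groups = ["a", "a", "b", "b", "c", "c"]
        r_lo = community.indicator_species(lo, groups, n_perm=99, seed=0)
        r_hi = community.indicator_species(hi, groups, n_perm=99, seed=0)
        assert r_hi.loc["x", "indval"] > r_lo.loc["x", "indval"]

    def test_raw_variant_differs_under_unequal_sampling(self):
        table = pd.DataFrame({"x": [9, 1, 1, 1, 1, 1]})
        groups = ["a", "b", "b", "b", "b", "b"]
        g = community.indicator_species(table, groups, 99, 0, group_equalized=True)
        r = community.indicator_species(table, groups, 99, 0, group_equalized=False)
        assert g.loc["x", "indval"] != pytest.approx(r.loc["x", "indval"])
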