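"""UCell and ssGSEA scoring, GMT parsing and score comparisons."""

import numpy as np
import pandas as pd
import pytest

from immatlas import (GeneSet, compare_group_scores, read_gmt, ssgsea_score,
                      ssgsea_scores, ucell_score, write_gmt)

from conftest import make_bundle


def brute_force_ssgsea(profile, genes_in_set, alpha):
    """Oracle: explicit two-ECDF walk over the sorted profile."""
    order = sorted(profile.index, key=lambda g: -profile[g])
    ranks = profile.rank()  # 1 = lowest
    n = len(order)
    n_hit = sum(g in genes_in_set for g in order)
    wsum = sum(ranks[g] ** alpha for g in order if g in genes_in_set)
    cdf_in = cdf_out = score = 0.0
    for g in order:
        if g in genes_in_set:
            cdf_in += ranks[g] ** alpha / wsum
        else:
            cdf_out += 1.0 / (n - n_hit)
        score += cdf_in - cdf_out
    return score


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("alpha", ("g1", "g2", "g3")), GeneSet("beta", ("x",))]
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert back == sets

    def test_duplicates_dropped_and_malformed_rejected(self, tmp_path):
        (tmp_path / "s.gmt").write_text("dup\tna\tg1\tg2\tg1\n")
        assert read_gmt(tmp_path / "s.gmt")[0].genes == ("g1", "g2")
        (tmp_path / "bad.gmt").write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(tmp_path / "bad.gmt")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("nothing", ())


def rank_profile_bundle(values, genes=None):
    return make_bundle(np.asarray(values)[None, :], genes=genes)


class TestUCell:
    def test_top_ranked_set_scores_one(self):
        bundle = rank_profile_bundle([9, 8, 7, 1, 1, 0, 0, 0])
        s = ucell_score(bundle, GeneSet("top", ("g0", "g1", "g2")), max_rank=5)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_unexpressed_single_gene_scores_zero(self):
        values = list(range(20, 0, -1)) + [0]
        bundle = rank_profile_bundle(values)
        s = ucell_score(bundle, GeneSet("solo", ("g20",)), max_rank=10)
        assert s.iloc[0] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # 10 genes, max_rank 5, set at ranks 2 and 4:
        # R = 6, U' = 3, score = 1 - 3/(2*5) = 0.7
        bundle = rank_profile_bundle([10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        s = ucell_score(bundle, GeneSet("pair", ("g1", "g3")), max_rank=5)
        assert s.iloc[0] == pytest.approx(0.7)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(20, 40))
        bundle = make_bundle(counts)
        genes = tuple(f"g{j}" for j in (1, 5, 9, 22))
        s1 = ucell_score(bundle, GeneSet("s", genes), max_rank=30)
        transformed = make_bundle(counts ** 2)  # strictly monotone on counts >= 0
        s2 = ucell_score(transformed, GeneSet("s", genes), max_rank=30)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 8, size=(5, 30))
            bundle = make_bundle(counts)
            genes = tuple(f"g{j}" for j in rng.choice(30, 4, replace=False))
            s = ucell_score(bundle, GeneSet("s", genes), max_rank=rng.integers(3, 40))
            assert np.all((s >= 0) & (s <= 1))

    def test_missing_genes_logged_absent_set_rejected(self):
        bundle = rank_profile_bundle([3, 2, 1])
        s = ucell_score(bundle, GeneSet("partial", ("g0", "nope")), max_rank=2)
        assert 0 <= s.iloc[0] <= 1
        with pytest.raises(ValueError, match="no genes"):
            ucell_score(bundle, GeneSet("absent", ("nope",)))


class TestSsgsea:
    def _profile(self):
        rng = np.random.default_rng(2)
        return pd.Series(rng.permutation(np.arange(1.0, 21.0)),
                         index=[f"g{j}" for j in range(20)])

    def test_top_set_positive_bottom_set_negative(self):
        prof = self._profile()
        top = tuple(prof.sort_values(ascending=False).index[:4])
        bottom = tuple(prof.sort_values().index[:4])
        assert ssgsea_score(prof, GeneSet("top", top), alpha=0.0) > 0
        assert ssgsea_score(prof, GeneSet("bottom", bottom), alpha=0.0) < 0

    def test_top_set_is_maximal_for_its_size(self):
        prof = self._profile()
        rng = np.random.default_rng(3)
        top = tuple(prof.sort_values(ascending=False).index[:4])
        best = ssgsea_score(prof, GeneSet("top", top), alpha=0.0)
        for _ in range(30):
            other = tuple(rng.choice(prof.index, 4, replace=False))
            assert ssgsea_score(prof, GeneSet("other", other), alpha=0.0) <= best + 1e-12

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_walk(self, alpha):
        prof = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                         index=[f"g{j}" for j in range(1, 7)])
        genes = {"g1", "g4"}
        assert ssgsea_score(prof, GeneSet("s", tuple(genes)), alpha=alpha) == pytest.approx(
            brute_force_ssgsea(prof, genes, alpha), rel=1e-12)

    def test_constant_profile_is_undefined(self):
        prof = pd.Series(np.ones(6), index=[f"g{j}" for j in range(6)])
        assert np.isnan(ssgsea_score(prof, GeneSet("s", ("g1",)), alpha=0.25))

    def test_multi_sample_table_and_normalization(self):
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(rng.uniform(0, 10, (3, 20)),
                                index=["s1", "s2", "s3"],
                                columns=[f"g{j}" for j in range(20)])
        sets = [GeneSet("a", ("g0", "g1", "g2")), GeneSet("b", ("g5", "g6"))]
        raw = ssgsea_scores(profiles, sets)
        assert raw.shape == (3, 2)
        norm = ssgsea_scores(profiles, sets, normalize=True)
        span = np.nanmax(raw.to_numpy()) - np.nanmin(raw.to_numpy())
        np.testing.assert_allclose(norm.to_numpy(), raw.to_numpy() / span)


class TestCompareGroupScores:
    def _meta(self, groups):
        return pd.DataFrame({"grp": groups},
                            index=pd.Index([f"c{i}" for i in range(len(groups))],
                                           name="barcode"))

    def test_identical_distributions_give_p_one(self):
        scores = pd.Series([0.5] * 8, index=self._meta(["a"] * 4 + ["b"] * 4).index)
        comp = compare_group_scores(scores, self._meta(["a"] * 4 + ["b"] * 4), "grp")
        assert comp.pairwise["p_adjusted"].iloc[0] == 1.0
        assert comp.pairwise["winner"].iloc[0] == "tie"

    def test_shifted_group_wins(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.uniform(0.0, 0.3, 30), rng.uniform(0.5, 0.9, 30)]
        meta = self._meta(["lo"] * 30 + ["hi"] * 30)
        comp = compare_group_scores(pd.Series(vals, index=meta.index), meta, "grp")
        assert comp.pairwise["winner"].iloc[0] == "hi"
        assert comp.pairwise["p_adjusted"].iloc[0] < 1e-6

    def test_single_group_is_hard_error_and_small_groups_dropped(self):
        meta = self._meta(["a"] * 5 + ["b"])
        scores = pd.Series(np.linspace(0, 1, 6), index=meta.index)
        with pytest.raises(ValueError, match="2 groups"):
            compare_group_scores(scores, meta, "grp")
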