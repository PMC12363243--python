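"""Abundance normalisation, heteroscedastic statistics, overlay mapping."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from ecophase import gene_overlay as go
from ecophase.sequence_io import AnnotationCounts, EcosystemLabel, SampleMetadata

pingouin = pytest.importorskip("pingouin")


def meta(sample_id, bases):
    return SampleMetadata(
        sample_id=sample_id, label=EcosystemLabel(path=("Aquatic", "Marine")), assembled_bases=bases
    )


class TestNormalize:
    @pytest.mark.parametrize(
        "count, bases, expected", [(5, 10**9, 5.0), (2, 5 * 10**8, 4.0), (0, 10**9, 0.0)]
    )
    def test_arithmetic(self, count, bases, expected):
        assert go.normalize_abundance(count, bases) == expected

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = int(rng.integers(0, 1000))
            b = int(rng.integers(1, 10**6))
            s = int(rng.integers(1, 50))
            assert go.normalize_abundance(c * s, b * s) == pytest.approx(
                go.normalize_abundance(c, b), rel=1e-12
            )

    def test_nonpositive_bases_errors(self):
        with pytest.raises(ValueError):
            go.normalize_abundance(1, 0)


class TestAbundanceTable:
    def test_disjoint_identifiers(self):
        anns = [
            AnnotationCounts("s1", Counter({"COG1": 2})),
            AnnotationCounts("s2", Counter({"KO:K1": 4})),
        ]
        table = go.build_abundance_table(anns, [meta("s1", 10**9), meta("s2", 10**9)])
        assert table.shape == (2, 2)
        assert table.loc["s1", "COG1"] == 2.0
        assert table.loc["s1", "KO:K1"] == 0.0  # annotated sample, absent gene: true zero
        assert table.loc["s2", "COG1"] == 0.0

    def test_halved_bases_doubles_abundance(self):
        anns = [
            AnnotationCounts("s1", Counter({"COG1": 6})),
            AnnotationCounts("s2", Counter({"COG1": 6})),
        ]
        table = go.build_abundance_table(anns, [meta("s1", 10**9), meta("s2", 5 * 10**8)])
        assert table.loc["s2", "COG1"] == 2 * table.loc["s1", "COG1"]

    def test_unannotated_sample_is_missing_not_zero(self):
        anns = [AnnotationCounts("s1", Counter({"COG1": 1}))]
        table = go.build_abundance_table(anns, [meta("s1", 10**9), meta("s2", 10**9)])
        assert np.isnan(table.loc["s2", "COG1"])

    def test_no_annotations_empty_table(self):
        table = go.build_abundance_table([], [meta("s1", 10**9)])
        assert table.shape == (1, 0)

    def test_missing_assembled_bases_names_sample(self):
        anns = [AnnotationCounts("s1", Counter({"COG1": 1}))]
        bad = SampleMetadata("s1", EcosystemLabel(("A", "B")), assembled_bases=None)
        with pytest.raises(ValueError, match="s1"):
            go.build_abundance_table(anns, [bad])


class TestWelchGamesHowell:
    def test_identical_groups_null_result(self):
        cmp = go.welch_games_howell({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert cmp.welch_F == 0.0
        assert cmp.welch_p == 1.0

    def test_huge_offset_all_stars(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)  # 10 SD apart
        cmp = go.welch_games_howell({"a": a, "b": b})
        assert all(p.star == "***" for p in cmp.pairwise)

    def test_two_group_F_equals_squared_welch_t(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.5, 2, 17)
            F, _ = go.welch_anova_stat({"a": a, "b": b})
            t, _, _ = go.two_tailed_t(a, b)
            assert F == pytest.approx(t**2, abs=1e-9)

    def test_matches_pingouin_reference(self):
        """Welch ANOVA and Games-Howell agree with the independent
        reference implementation on a fixed fixture."""
        rng = np.random.default_rng(3)
        vals = {"A": rng.normal(0, 1, 12), "B": rng.normal(0.8, 2, 9), "C": rng.normal(-0.5, 0.5, 15)}
        df = pd.DataFrame([(k, v) for k, arr in vals.items() for v in arr], columns=["g", "y"])
        ref_anova = pingouin.welch_anova(dv="y", between="g", data=df)
        F, p = go.welch_anova_stat(vals)
        assert F == pytest.approx(float(ref_anova["F"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref_anova["p_unc"].iloc[0]), abs=1e-6)
        ref_gh = pingouin.pairwise_gameshowell(dv="y", between="g", data=df)
        ours = {(r.group_a, r.group_b): r.p for r in go.games_howell(vals)}
        for _, row in ref_gh.iterrows():
            assert ours[(row["A"], row["B"])] == pytest.approx(float(row["pval"]), abs=1e-6)

    def test_relabel_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        vals = {"A": rng.normal(0, 1, 10), "B": rng.normal(1, 2, 14), "C": rng.normal(2, 1, 8)}
        base = {(r.group_a, r.group_b): r.p for r in go.games_howell(vals)}
        shifted = {k: np.asarray(v) + 100.0 for k, v in vals.items()}
        for r in go.games_howell(shifted):
            assert r.p == pytest.approx(base[(r.group_a, r.group_b)], rel=1e-9)
        renamed = {"X" + k: v for k, v in vals.items()}
        for r in go.games_howell(renamed):
            assert r.p == pytest.approx(base[(r.group_a[1:], r.group_b[1:])], rel=1e-12)

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError, match="b"):
            go.welch_games_howell({"a": [1, 2, 3], "b": [5]})
        with pytest.raises(ValueError, match="zero variance"):
            go.welch_games_howell({"a": [1, 2, 3], "b": [4, 4, 4]})


class TestTwoTailedT:
    def test_identical_samples(self):
        t, p, star = go.two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0
        assert star == "ns"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 9)
        b = rng.normal(1, 2, 13)
        t1, p1, _ = go.two_tailed_t(a, b)
        t2, p2, _ = go.two_tailed_t(b, a)
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_pingouin_reference(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 11)
        b = rng.normal(0.7, 1.5, 16)
        t, p, _ = go.two_tailed_t(a, b)
        ref = pingouin.ttest(a, b, correction=True)
        assert t == pytest.approx(float(ref["T"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            go.two_tailed_t([1.0], [1.0, 2.0])


class TestOverlay:
    def make_table(self):
        return pd.DataFrame(
            {"COG1": [1.0, 3.0, 5.0, np.nan], "COG2": [2.0, 2.0, 2.0, 2.0]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )

    def test_endpoints_under_auto_range(self):
        ov = go.overlay_values(self.make_table(), "COG1")
        assert ov.positions["s1"] == 0.0
        assert ov.positions["s3"] == 1.0

    def test_missing_hidden(self):
        ov = go.overlay_values(self.make_table(), "COG1")
        assert bool(ov.hidden["s4"])
        assert np.isnan(ov.positions["s4"])

    def test_all_equal_single_position(self):
        ov = go.overlay_values(self.make_table(), "COG2")
        assert (ov.positions == 0.5).all()

    def test_heat_midpoint_recenters(self):
        ov = go.overlay_values(self.make_table(), "COG1", heat_midpoint=3.0)
        assert ov.positions["s2"] == pytest.approx(0.5)
        assert ov.positions["s1"] == 0.0
        assert ov.positions["s3"] == 1.0

    def test_unknown_gene_errors(self):
        with pytest.raises(KeyError):
            go.overlay_values(self.make_table(), "COG999")
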