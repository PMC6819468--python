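import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stemwall.expression import GeneScaledMatrix
from stemwall.patterns import (
    PatternTemplate,
    derive_templates,
    hcluster,
    match_genome,
    pca_covariance,
    slope_metric,
    templates_from_json,
    templates_to_json,
)
from stemwall.shapes import PATTERN_NAMES, archetype

INTERNODES = [9, 8, 7, 6, 5, 4, 3, 2]


def _scaled(rows: dict) -> GeneScaledMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=INTERNODES[: len(next(iter(rows.values())))])
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0, 1.0)
    return GeneScaledMatrix(values=df.sub(mean, axis=0).div(sd, axis=0))


class TestSlopeMetric:
    def test_identity_is_zero(self):
        a = [0.1, 0.5, 0.9, 0.3]
        assert slope_metric(a, a) == 0.0

    def test_constant_offset_is_zero(self):
        # dyadic values: the offset adds exactly, so the score is exactly 0
        a = np.array([0.0, 1.0, 0.5, 3.0])
        assert slope_metric(a, a + 2.0) == 0.0
        b = np.array([0.1, 0.5, 0.9, 0.3])
        assert slope_metric(b, b + 17.3) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # |1-0| + |-1-0| + |0-0| = 2
        assert slope_metric([0, 1, 0, 0], [0, 0, 0, 0]) == 2.0

    def test_constant_test_gene_scores_total_variation_of_bait(self):
        a = np.array([0.0, 2.0, 1.0, 4.0])
        tv = np.abs(np.diff(a)).sum()
        assert slope_metric(a, np.zeros(4)) == pytest.approx(tv)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            slope_metric([1, 2, 3], [1, 2])

    def test_pseudometric_over_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, 8))
            dab = slope_metric(a, b)
            assert dab >= 0
            assert dab == pytest.approx(slope_metric(b, a))
            assert dab <= slope_metric(a, c) + slope_metric(c, b) + 1e-12

    def test_offset_invariance_both_sides(self):
        rng = np.random.default_rng(43)
        a, x = rng.normal(size=(2, 6))
        base = slope_metric(a, x)
        assert slope_metric(a + 5, x) == pytest.approx(base)
        assert slope_metric(a, x - 3) == pytest.approx(base)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        profiles=hnp.arrays(
            float,
            (2, 8),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=32),
        ),
        offset=st.floats(-1e6, 1e6, allow_nan=False, width=32),
    )
    def test_property_symmetry_and_offset_invariance(self, profiles, offset):
        a, x = profiles
        d = slope_metric(a, x)
        assert d >= 0
        assert slope_metric(x, a) == pytest.approx(d, abs=1e-6)
        scale = max(1.0, np.abs(np.diff(a)).max(), np.abs(np.diff(x)).max())
        assert slope_metric(a + offset, x) == pytest.approx(
            d, abs=1e-6 * max(scale, abs(offset))
        )


class TestHCluster:
    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        up = {f"u{i}": archetype("Secondary", 8) * 100 + rng.normal(0, 1, 8)
              for i in range(6)}
        down = {f"d{i}": archetype("Elongation", 8) * 100 + rng.normal(0, 1, 8)
                for i in range(6)}
        m = _scaled({**up, **down})
        clades = hcluster(m, list(m.values.index), k=2)
        groups = {clades[g] for g in up}
        assert len(groups) == 1
        assert groups != {clades[g] for g in down}

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        m = _scaled({f"g{i}": rng.normal(size=8) for i in range(5)})
        clades = hcluster(m, list(m.values.index), k=5)
        assert clades.nunique() == 5

    def test_duplicated_profiles_share_a_clade(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        rows = {"a": base, "b": base}
        rows.update({f"g{i}": rng.normal(size=8) for i in range(6)})
        m = _scaled(rows)
        clades = hcluster(m, list(m.values.index), k=4)
        assert clades["a"] == clades["b"]

    def test_k_out_of_range_errors(self):
        m = _scaled({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="out of range"):
            hcluster(m, ["a", "b"], k=5)


class TestDeriveTemplates:
    def test_single_clade_of_identical_profiles(self):
        prof = archetype("Secondary", 8)
        m = _scaled({"a": prof, "b": prof})
        clades = pd.Series({"a": 1, "b": 1})
        tpl = derive_templates(m, clades, {1: "Secondary"})
        assert np.allclose(tpl["Secondary"].profile, m.values.loc["a"])

    def test_auto_grouping_on_noiseless_archetypes(self):
        rows, clade_map = {}, {}
        for cid, name in enumerate(PATTERN_NAMES, start=1):
            for j in range(4):
                rows[f"{name}{j}"] = archetype(name, 8) * (50 + 10 * j)
                clade_map[f"{name}{j}"] = cid
        m = _scaled(rows)
        tpl = derive_templates(m, pd.Series(clade_map), "auto")
        assert sorted(tpl) == sorted(PATTERN_NAMES)
        for name in PATTERN_NAMES:
            assert all(g.startswith(name) for g in tpl[name].member_genes)
            # noiseless members scale to the same z-profile, so the template
            # reproduces the scaled archetype
            assert np.allclose(
                tpl[name].profile, m.values.loc[f"{name}0"], atol=1e-9
            )

    def test_manual_map_missing_clade_errors(self):
        m = _scaled({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="lacks"):
            derive_templates(m, pd.Series({"a": 1, "b": 2}), {1: "x"})


class TestMatchGenome:
    def test_member_genes_within_sd_of_a_mixed_universe(self):
        # the one-score-SD threshold is meaningful on a heterogeneous
        # universe: template members score near zero, unrelated genes spread
        # the distribution, and every member falls below one SD
        rng = np.random.default_rng(3)
        members = {f"m{i}": archetype("Secondary", 8) * 100 + rng.normal(0, 0.5, 8)
                   for i in range(20)}
        others = {f"x{i}": rng.gamma(2, 30, 8) for i in range(100)}
        m = _scaled({**members, **others})
        profile = m.values.loc[list(members)].mean(axis=0).to_numpy()
        tpl = {"Secondary": PatternTemplate("Secondary", profile, list(members))}
        res = match_genome(m, tpl, list(members) + list(others))["Secondary"]
        assert res.loc[list(members), "within_sd"].all()
        # members out-rank the unrelated genes
        assert set(res.index[res["rank"] <= 20]) == set(members)

    def test_rank_order_invariant_to_universe_order(self):
        rng = np.random.default_rng(4)
        rows = {f"g{i}": rng.normal(size=8) for i in range(30)}
        m = _scaled(rows)
        tpl = {"t": PatternTemplate("t", archetype("Elongation", 8))}
        names = list(rows)
        r1 = match_genome(m, tpl, names)["t"]
        r2 = match_genome(m, tpl, names[::-1])["t"]
        assert list(r1.index) == list(r2.index)
        assert (r1["rank"] == r2["rank"]).all()

    def test_ranks_are_ascending_and_tie_broken_by_id(self):
        base = archetype("Flat", 8)
        m = _scaled({"b": [1, 2, 3, 4, 5, 6, 7, 8], "a": [1, 2, 3, 4, 5, 6, 7, 8],
                     "c": [5, 1, 5, 1, 5, 1, 5, 1]})
        tpl = {"t": PatternTemplate("t", np.zeros(8))}
        res = match_genome(m, tpl, ["c", "b", "a"])["t"]
        assert list(res.index[:2]) == ["a", "b"]  # tied scores, ID order
        assert list(res["rank"]) == [1, 2, 3]

    def test_empty_universe_errors(self):
        m = _scaled({"a": [1, 2, 3]})
        tpl = {"t": PatternTemplate("t", np.zeros(3))}
        with pytest.raises(ValueError, match="empty"):
            match_genome(m, tpl, [])


class TestPCACovariance:
    def test_rank_one_data_loads_on_first_component(self):
        prof = archetype("Secondary", 8)
        rows = {f"g{i}": prof * (i + 1) for i in range(5)}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=INTERNODES)
        m = GeneScaledMatrix(values=df)  # raw multiples: covariance is rank 1
        _, fractions = pca_covariance(m)
        assert fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = _scaled({f"g{i}": rng.normal(size=8) for i in range(40)})
        _, fractions = pca_covariance(m)
        assert fractions.sum() == pytest.approx(1.0)
        assert (np.diff(fractions) <= 1e-12).all()

    def test_five_pattern_data_concentrates_in_three_components(self, sim_default):
        from stemwall.expression import normalize_per20m, scale_genes

        norm = normalize_per20m(sim_default.counts["B73"])
        scaled = scale_genes(norm)
        truth = sim_default.truth
        genes = truth.index[truth["pattern"] != "Flat"]
        _, fractions = pca_covariance(scaled, list(genes))
        assert fractions[:3].sum() >= 0.8

    def test_too_few_genes_errors(self):
        m = _scaled({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="three"):
            pca_covariance(m)


def test_template_json_roundtrip():
    tpl = {"Secondary": PatternTemplate("Secondary", archetype("Secondary", 8), ["a"])}
    back = templates_from_json(templates_to_json(tpl))
    assert back["Secondary"].member_genes == ["a"]
    assert np.allclose(back["Secondary"].profile, tpl["Secondary"].profile)
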