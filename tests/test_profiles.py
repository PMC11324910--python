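import numpy as np
import pandas as pd
import pytest

from metaferm import profiles
from metaferm.profiles import (
    STARCH_SUCROSE,
    EcMatchParams,
    PathwayGeneSet,
    activity_vs_16s,
    ec_from_names,
    flag_upregulated_pathways,
    genus_activity,
    normalize_enzyme_name,
    organism_enzyme_matrix,
    pathway_fraction,
    rpkm,
)


class TestRpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        out = rpkm(counts, {"g": 1000}, {"s": 1e6})
        assert out.loc["g", "s"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        assert rpkm(counts, {"g": 500}, {"s": 1e6}).loc["g", "s"] == 0.0

    def test_doubling_total_halves_rpkm(self, rng):
        counts = pd.DataFrame({"s": rng.poisson(20, 50)}, index=[f"g{i}" for i in range(50)])
        lengths = {g: int(l) for g, l in zip(counts.index, rng.integers(200, 3000, 50))}
        a = rpkm(counts, lengths, {"s": 1e6})
        b = rpkm(counts, lengths, {"s": 2e6})
        assert np.allclose(b, a / 2)

    def test_round_trip_to_counts(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30, size=(20, 3)),
            index=[f"g{i}" for i in range(20)], columns=list("abc"),
        )
        lengths = {g: int(l) for g, l in zip(counts.index, rng.integers(200, 3000, 20))}
        totals = {c: float(counts[c].sum()) for c in counts.columns}
        r = rpkm(counts, lengths, totals)
        back = r.mul(pd.Series(lengths) / 1e3, axis=0).mul(
            pd.Series(totals) / 1e6, axis=1
        )
        assert np.allclose(back, counts, rtol=1e-9)

    def test_zero_total_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ValueError):
            rpkm(counts, {"g": 100}, {"s": 0})


class TestGenusActivity:
    def test_single_genus_has_share_one(self):
        counts = pd.DataFrame({"s": [5, 3]}, index=["a", "b"])
        act = genus_activity(counts, {"a": "G", "b": "G"})
        assert np.allclose(act.to_numpy(), 1.0)

    def test_shares_sum_to_one_including_other_pool(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(30, 4)),
            index=[f"g{i}" for i in range(30)], columns=list("abcd"),
        )
        counts.iloc[-1] = 1  # one vanishing genus -> pooled
        labels = {f"g{i}": f"Genus{i % 10}" for i in range(30)}
        act = genus_activity(counts, labels, min_display_share=0.05)
        assert np.allclose(act.sum(axis=0), 1.0, atol=1e-12)

    def test_minor_genera_pooled_into_other(self):
        counts = pd.DataFrame({"s": [990, 10]}, index=["a", "b"])
        act = genus_activity(counts, {"a": "Big", "b": "Small"}, min_display_share=0.05)
        assert profiles.OTHER_LABEL in act.index and "Small" not in act.index

    def test_unassigned_genes_excluded_from_denominator(self):
        counts = pd.DataFrame({"s": [50, 50]}, index=["a", "b"])
        act = genus_activity(counts, {"a": "G", "b": "Unassigned"})
        assert act.loc["G", "s"] == pytest.approx(1.0)

    def test_invariant_to_per_sample_rescaling(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(10, 3)) + 1,
            index=[f"g{i}" for i in range(10)], columns=list("abc"),
        )
        labels = {f"g{i}": f"G{i % 3}" for i in range(10)}
        a = genus_activity(counts, labels)
        b = genus_activity(counts * 7, labels)
        assert np.allclose(a, b)


class TestPathwayFraction:
    def test_all_member_reads_give_one(self):
        counts = pd.DataFrame({"s": [10, 20]}, index=["a", "b"])
        ann = {"a": ("3.2.1.1",), "b": ("3.2.1.10",)}
        assert pathway_fraction(counts, ann).loc["s"] == pytest.approx(1.0)

    def test_partial_ec_matches_nothing_by_default(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        ann = {"a": ("3.2.1.-",), "b": ("1.1.1.1",)}
        assert pathway_fraction(counts, ann).loc["s"] == 0.0

    def test_prefix_mode_matches_partial_ec(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        ann = {"a": ("3.2.1.-",), "b": ("1.1.1.1",)}
        frac = pathway_fraction(counts, ann, prefix_match=True)
        assert frac.loc["s"] == pytest.approx(0.5)

    def test_denominator_is_annotated_reads_only(self):
        counts = pd.DataFrame({"s": [10, 10, 80]}, index=["a", "b", "c"])
        ann = {"a": ("3.2.1.1",), "b": ("1.1.1.1",), "c": ()}
        assert pathway_fraction(counts, ann).loc["s"] == pytest.approx(0.5)

    def test_no_annotated_genes_is_an_error(self):
        counts = pd.DataFrame({"s": [10]}, index=["a"])
        with pytest.raises(ValueError):
            pathway_fraction(counts, {"a": ()})

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            PathwayGeneSet("empty", frozenset())


class TestOrganismEnzymeMatrix:
    def _fixture(self):
        r = pd.DataFrame(
            {"s1": [1.0, 2.0, 4.0], "s2": [3.0, 5.0, 6.0]},
            index=["a", "b", "c"],
        )
        labels = {"a": "Bacteroides", "b": "Bacteroides", "c": "Lactobacillus"}
        ecs = {"a": ("3.2.1.11",), "b": ("3.2.1.1", "3.2.1.11"), "c": ("3.2.1.10",)}
        return r, labels, ecs

    def test_single_gene_table_equals_its_rpkm(self):
        r = pd.DataFrame({"s": [2.5]}, index=["g"])
        out = organism_enzyme_matrix(r, {"g": "Bacteroides"}, {"g": ("3.2.1.11",)})
        assert out.loc["Bacteroides", "3.2.1.11"] == pytest.approx(2.5)

    def test_gene_order_permutation_invariance(self):
        r, labels, ecs = self._fixture()
        a = organism_enzyme_matrix(r, labels, ecs)
        b = organism_enzyme_matrix(r.iloc[::-1], labels, ecs)
        assert a.equals(b)

    def test_totals_conserve_member_gene_rpkm(self):
        r, labels, ecs = self._fixture()
        out = organism_enzyme_matrix(r, labels, ecs)
        expected = sum(
            r.loc[g].sum() * len(ecs[g]) for g in r.index
        )  # genes count once per EC they carry
        assert out.to_numpy().sum() == pytest.approx(expected)

    def test_planted_genus_dominates_its_enzyme_column(self):
        r, labels, ecs = self._fixture()
        out = organism_enzyme_matrix(r, labels, ecs)
        col = out["3.2.1.11"]
        assert col.idxmax() == "Bacteroides"
        assert col.get("Lactobacillus", 0.0) == 0.0


class TestEcFromNames:
    def test_domain_name_normalization_trace(self, enzyme_dictionary):
        out = ec_from_names(
            {"g": ["Oligo-1,6-glucosidase, C-terminal domain"]}, enzyme_dictionary
        )
        assert list(out["ec"]) == ["3.2.1.10"]
        assert normalize_enzyme_name(
            "Oligo-1,6-glucosidase, C-terminal domain"
        ) == "oligo 1 6 glucosidase"

    def test_case_insensitive_match(self, enzyme_dictionary):
        out = ec_from_names({"g": ["DEXTRANASE"]}, enzyme_dictionary)
        assert list(out["ec"]) == ["3.2.1.11"]

    def test_stoplist_only_name_matches_nothing(self, enzyme_dictionary):
        out = ec_from_names({"g": ["type domain enzyme-like"]}, enzyme_dictionary)
        assert out.empty

    def test_multiple_matches_are_flagged(self):
        lut = {"amylase alpha": "3.2.1.1", "alpha amylase": "3.2.1.98"}
        out = ec_from_names({"g": ["alpha amylase", "amylase, alpha"]}, lut)
        assert set(out["ec"]) == {"3.2.1.1", "3.2.1.98"}
        assert out["multiple"].all()

    def test_normalization_is_idempotent(self):
        params = EcMatchParams()
        for name in ("Oligo-1,6-glucosidase, C-terminal domain", "ALPHA-amylase!!"):
            once = normalize_enzyme_name(name, params)
            assert normalize_enzyme_name(once, params) == once


class TestActivityVs16s:
    def test_identical_tables_give_rho_one(self, rng):
        act = pd.DataFrame(rng.dirichlet(np.ones(4), size=10).T,
                           index=list("abcd"))
        corr = activity_vs_16s(act, act)
        assert corr.pooled_rho == pytest.approx(1.0)
        assert corr.per_genus["rho"].to_numpy() == pytest.approx(1.0)

    def test_rank_reversal_gives_rho_minus_one(self, rng):
        act = pd.DataFrame(rng.random((3, 8)), index=list("abc"))
        flipped = act.max(axis=1).to_numpy()[:, None] - act
        corr = activity_vs_16s(act, pd.DataFrame(flipped, index=act.index,
                                                 columns=act.columns))
        assert (corr.per_genus["rho"] == -1.0).all()

    def test_too_few_points_rejected(self):
        act = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            activity_vs_16s(act, act)


def test_flag_upregulated_pathways_uses_member_coverage():
    gene_ecs = {"g1": ("3.2.1.1",), "g2": ("3.2.1.10",)}
    out = flag_upregulated_pathways([STARCH_SUCROSE], ["g1", "g2"], gene_ecs)
    assert out.loc[0, "covered_fraction"] == pytest.approx(2 / 9)
    assert not out.loc[0, "flagged"]
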