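import numpy as np
import pytest

from meshsem import (
    FrequencyTable,
    SimilarityRequest,
    build_ic_table,
    mica,
    sim_jc,
    sim_lin,
    sim_rel,
    sim_resnik,
    sim_wang,
    similarity,
    wang_s_values,
)

from .conftest import build_manual
from .oracles import (
    jc_oracle,
    lin_oracle,
    mica_ic_oracle,
    rel_oracle,
    wang_oracle,
)

OMEGAS = [round(0.1 * k, 1) for k in range(1, 11)]


@pytest.fixture(scope="module")
def chain_ic(ds_chain):
    return build_ic_table(ds_chain, FrequencyTable.from_dataset(ds_chain))


@pytest.fixture(scope="module")
def two_cat_ic(ds_two_categories):
    ds = ds_two_categories
    return build_ic_table(ds, FrequencyTable.from_dataset(ds))


@pytest.fixture(scope="module")
def wang_ds():
    """The worked graph example: a three-level chain plus a sibling branch."""
    return build_manual(
        [
            ("D1", "root", ["C01"], 10),
            ("D2", "mid", ["C01.100"], 10),
            ("D3", "deep leaf", ["C01.100.500"], 10),
            ("D4", "side leaf", ["C01.200"], 10),
        ]
    )


class TestMICA:
    def test_cross_category_printed_tree_numbers(self, ds_two_categories, two_cat_ic):
        """Terms at C10.574.945 and F03.700.750 belong to different
        categories, so their MICA is designated 0."""
        result = mica(ds_two_categories, two_cat_ic, "D000202", "D000212")
        assert result.mica_ui is None
        assert result.mica_ic == 0.0

    def test_self_mica_is_self(self, ds_chain, chain_ic):
        result = mica(ds_chain, chain_ic, "D000101", "D000101")
        assert result.mica_ui == "D000101"
        assert result.mica_ic == chain_ic.ic["D000101"]

    def test_siblings_meet_at_parent(self, ds_chain, chain_ic):
        result = mica(ds_chain, chain_ic, "D000101", "D000102")
        assert result.mica_ui == "D000100"

    def test_matches_exhaustive_oracle_on_fixture(self, ds_small, ic_small):
        rng = np.random.default_rng(11)
        uis = sorted(t.ui for t in ds_small.main_headings)
        for _ in range(200):
            u1, u2 = rng.choice(uis, size=2)
            assert mica(ds_small, ic_small, u1, u2).mica_ic == pytest.approx(
                mica_ic_oracle(ds_small, ic_small, u1, u2), abs=1e-12
            )


class TestICMeasures:
    """Frozen expectations: IC(d1)=1.0, IC(d2)=0.69897, IC(MICA)=0.30103."""

    def test_chain_ic_inputs(self, chain_ic):
        assert chain_ic.ic["D000101"] == pytest.approx(1.0, abs=1e-5)
        assert chain_ic.ic["D000102"] == pytest.approx(0.69897, abs=1e-5)
        assert chain_ic.ic["D000100"] == pytest.approx(0.30103, abs=1e-5)

    def test_resnik_is_mica_ic(self, ds_chain, chain_ic):
        assert sim_resnik(ds_chain, chain_ic, "D000101", "D000102") == pytest.approx(
            0.30103, abs=1e-5
        )
        assert sim_resnik(ds_chain, chain_ic, "D000101", "D000101") == pytest.approx(
            chain_ic.ic["D000101"]
        )

    def test_lin_direct_evaluation(self, ds_chain, chain_ic):
        assert sim_lin(ds_chain, chain_ic, "D000101", "D000102") == pytest.approx(
            0.35436, abs=1e-5
        )
        assert sim_lin(ds_chain, chain_ic, "D000101", "D000101") == 1.0

    def test_jc_clamps_to_zero(self, ds_chain, chain_ic):
        # distance 1.0 + 0.69897 - 2*0.30103 = 1.09691 >= 1
        assert sim_jc(ds_chain, chain_ic, "D000101", "D000102") == 0.0
        assert sim_jc(ds_chain, chain_ic, "D000101", "D000101") == 1.0

    def test_rel_damps_lin_by_mica_probability(self, ds_chain, chain_ic):
        # 10^(-0.30103) = 0.5, so rel = 0.35436 * 0.5
        assert sim_rel(ds_chain, chain_ic, "D000101", "D000102") == pytest.approx(
            0.17718, abs=1e-5
        )

    def test_rel_identity_is_one_minus_probability(self, ds_chain, chain_ic):
        d = "D000101"
        expected = 1.0 - 10.0 ** (-chain_ic.ic[d])
        assert sim_rel(ds_chain, chain_ic, d, d) == pytest.approx(expected)

    def test_all_measures_zero_across_categories(self, ds_two_categories, two_cat_ic):
        ds, ic = ds_two_categories, two_cat_ic
        assert sim_resnik(ds, ic, "D000202", "D000212") == 0.0
        assert sim_lin(ds, ic, "D000202", "D000212") == 0.0
        assert sim_jc(ds, ic, "D000202", "D000212") == 0.0
        assert sim_rel(ds, ic, "D000202", "D000212") == 0.0
        assert sim_wang(ds, "D000202", "D000212") == 0.0

    def test_lin_zero_denominator_boundary(self):
        # both roots roll up to all of N (via the shared multi-address
        # child), so both have IC exactly 0
        ds = build_manual(
            [
                ("D1", "a", ["C01"], 0),
                ("D2", "b", ["C02"], 0),
                ("D3", "shared", ["C01.100", "C02.100"], 20),
            ],
            n_total=20,
        )
        ic = build_ic_table(ds, FrequencyTable.from_dataset(ds))
        assert ic.ic["D1"] == 0.0 == ic.ic["D2"]
        assert sim_lin(ds, ic, "D1", "D1") == 1.0
        assert sim_lin(ds, ic, "D1", "D2") == 0.0


class TestWang:
    def test_s_values_worked_example(self, wang_ds):
        s = wang_s_values(wang_ds, "D3", omega=0.6)
        assert s == pytest.approx({"D3": 1.0, "D2": 0.6, "D1": 0.36})
        assert sum(s.values()) == pytest.approx(1.96)

    def test_self_contribution_is_one_for_any_omega(self, wang_ds):
        for omega in (0.0, 0.3, 1.0):
            assert wang_s_values(wang_ds, "D3", omega)["D3"] == 1.0

    def test_worked_pair_value(self, wang_ds):
        # (0.36 + 0.6) / (1.96 + 1.6)
        assert sim_wang(wang_ds, "D3", "D4", omega=0.6) == pytest.approx(
            0.26966, abs=1e-5
        )

    def test_identity_is_one_for_all_omegas(self, wang_ds):
        for omega in OMEGAS:
            assert sim_wang(wang_ds, "D3", "D3", omega) == pytest.approx(1.0)

    def test_min_edge_count_over_multiple_paths(self):
        """An ancestor reachable along chains of lengths 1 and 3 contributes
        omega^1, the maximum over paths."""
        ds = build_manual(
            [
                ("D1", "root", ["C01"], 1),
                ("D2", "mid", ["C01.100"], 1),
                ("D3", "lower", ["C01.100.200"], 1),
                ("D4", "rewired", ["C01.100.200.300", "C01.300"], 1),
            ]
        )
        s = wang_s_values(ds, "D4", omega=0.6)
        assert s["D1"] == pytest.approx(0.6)
        assert s["D3"] == pytest.approx(0.6)

    def test_matches_brute_force_oracle(self, ds_large):
        rng = np.random.default_rng(23)
        uis = sorted(t.ui for t in ds_large.main_headings)
        for _ in range(100):
            u1, u2 = rng.choice(uis, size=2)
            for omega in (0.2, 0.6, 1.0):
                assert sim_wang(ds_large, u1, u2, omega) == pytest.approx(
                    wang_oracle(ds_large, u1, u2, omega), abs=1e-12
                )


class TestSimilarityDispatch:
    def test_scr_against_its_own_broader_mh_is_identity(self, ds_small, ic_small):
        scr = ds_small.scrs[0]
        (mh_ui,) = ds_small.scr_broader_mhs(scr.ui)
        for method in ("res", "lin", "jc", "rel", "wang"):
            assert similarity(ds_small, ic_small, ui1=scr.ui, ui2=mh_ui,
                              method=method) == 1.0

    def test_symmetric_on_random_pairs_all_methods(self, ds_small, ic_small):
        rng = np.random.default_rng(5)
        uis = sorted(t.ui for t in ds_small.terms())
        for _ in range(100):
            u1, u2 = rng.choice(uis, size=2)
            for method in ("res", "lin", "jc", "rel", "wang"):
                assert similarity(
                    ds_small, ic_small, ui1=u1, ui2=u2, method=method
                ) == similarity(ds_small, ic_small, ui1=u2, ui2=u1, method=method)

    def test_bounded_methods_stay_in_unit_interval(self, ds_small, ic_small):
        rng = np.random.default_rng(17)
        uis = sorted(t.ui for t in ds_small.main_headings)
        for _ in range(100):
            u1, u2 = rng.choice(uis, size=2)
            for method in ("lin", "jc", "rel", "wang"):
                v = similarity(ds_small, ic_small, ui1=u1, ui2=u2, method=method)
                assert 0.0 <= v <= 1.0

    def test_ic_methods_equal_per_tree_number_enumeration(self, ds_large, ic_large):
        """The global-MICA shortcut matches exhaustive enumeration over
        tree-number pairs for the IC measures."""
        multi = [t for t in ds_large.main_headings if len(t.tree_numbers) > 1]
        assert multi
        rng = np.random.default_rng(31)
        uis = sorted(t.ui for t in ds_large.main_headings)
        fns = {"lin": lin_oracle, "jc": jc_oracle, "rel": rel_oracle}
        for t in multi[:5]:
            for u2 in rng.choice(uis, size=20):
                for method, oracle in fns.items():
                    got = similarity(ds_large, ic_large, ui1=t.ui, ui2=str(u2),
                                     method=method)
                    if t.ui == u2:
                        assert got == 1.0
                    else:
                        assert got == pytest.approx(
                            oracle(ds_large, ic_large, t.ui, str(u2)), abs=1e-12
                        )

    def test_wang_dispatch_max_over_tree_number_pairs(self):
        """With one address per term, the per-pair maximum equals the plain
        Wang score; with two addresses it is the best pairing."""
        ds = build_manual(
            [
                ("D1", "root", ["C01"], 1),
                ("D2", "a", ["C01.100"], 1),
                ("D3", "b", ["C01.100.200", "C01.300"], 1),
                ("D4", "c", ["C01.100.400"], 1),
            ]
        )
        from itertools import product

        from meshsem.tree import TreeNumber

        best = max(
            sim_wang(ds, "D3", "D4", 0.6, (tn1,), (tn2,))
            for tn1, tn2 in product(
                ds.get_term("D3").tree_numbers, ds.get_term("D4").tree_numbers
            )
        )
        assert similarity(ds, None, ui1="D3", ui2="D4", method="wang") == pytest.approx(
            best
        )

    def test_sibling_never_less_similar_than_cousin(self, ds_chain, chain_ic):
        ds = build_manual(
            [
                ("D1", "root", ["C01"], 100),
                ("D2", "a", ["C01.100"], 40),
                ("D3", "b", ["C01.200"], 40),
                ("D4", "a child", ["C01.100.100"], 10),
                ("D5", "a child 2", ["C01.100.200"], 10),
                ("D6", "b child", ["C01.200.100"], 10),
            ],
            n_total=400,
        )
        ic = build_ic_table(ds, FrequencyTable.from_dataset(ds))
        for method in ("lin", "wang"):
            sibling = similarity(ds, ic, ui1="D4", ui2="D5", method=method)
            cousin = similarity(ds, ic, ui1="D4", ui2="D6", method=method)
            assert sibling >= cousin

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            SimilarityRequest(ui1="D1", ui2="D2", method="cosine")
        with pytest.raises(ValueError):
            SimilarityRequest(ui1="D1", ui2="D2", omega=1.5)

    def test_scr_vs_scr_uses_broader_cross_product(self, ds_small, ic_small):
        s1, s2 = ds_small.scrs[0], ds_small.scrs[1]
        expected = max(
            similarity(ds_small, ic_small, ui1=a, ui2=b, method="lin")
            for a in ds_small.scr_broader_mhs(s1.ui)
            for b in ds_small.scr_broader_mhs(s2.ui)
        )
        got = similarity(ds_small, ic_small, ui1=s1.ui, ui2=s2.ui, method="lin")
        assert got == pytest.approx(expected)
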