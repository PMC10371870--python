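import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cardioniche.interactions import (
    LRDatabase,
    expressed_fraction,
    load_lr_database,
    lr_mean,
    lr_permutation_p,
    niche_interaction_screen,
)
from cardioniche.io_core import NormMatrix, ValidationError

from conftest import make_annotation


def write_db(tmp_path, interactions, complexes, gene_map=None):
    ipath = tmp_path / "inter.csv"
    cpath = tmp_path / "comp.csv"
    pd.DataFrame(interactions).to_csv(ipath, index=False)
    pd.DataFrame(complexes).to_csv(cpath, index=False)
    gpath = None
    if gene_map is not None:
        gpath = tmp_path / "map.csv"
        pd.DataFrame(gene_map).to_csv(gpath, index=False)
    return ipath, cpath, gpath


def dense_norm(values, genes):
    values = np.asarray(values, dtype=float)
    return NormMatrix(sp.csr_matrix(values),
                      [f"c{i}" for i in range(values.shape[0])], genes)


class TestLoad:
    def test_small_database_loads(self, tmp_path):
        i, c, _ = write_db(
            tmp_path,
            [{"partner_a": "L1", "partner_b": "cplx"},
             {"partner_a": "L2", "partner_b": "R2"}],
            [{"complex_name": "cplx", "member_1": "R1a", "member_2": "R1b"}],
        )
        db = load_lr_database(i, c)
        assert len(db) == 2
        assert db.partner_genes("cplx") == ["R1a", "R1b"]
        assert db.partner_genes("L1") == ["L1"]

    def test_undefined_complex_named_in_error(self, tmp_path):
        i, c, g = write_db(
            tmp_path,
            [{"partner_a": "L1", "partner_b": "X"}],
            [{"complex_name": "cplx", "member_1": "R1a", "member_2": "R1b"}],
            gene_map=[{"protein": "L1", "gene": "L1"},
                      {"protein": "R1a", "gene": "R1a"},
                      {"protein": "R1b", "gene": "R1b"}],
        )
        with pytest.raises(ValidationError, match="X"):
            load_lr_database(i, c, g)

    def test_gene_map_translates_members(self, tmp_path):
        i, c, g = write_db(
            tmp_path,
            [{"partner_a": "P001", "partner_b": "cplx"}],
            [{"complex_name": "cplx", "member_1": "P002", "member_2": "P003"}],
            gene_map=[{"protein": "P001", "gene": "NPPB"},
                      {"protein": "P002", "gene": "NPR1"},
                      {"protein": "P003", "gene": "NPR2"}],
        )
        db = load_lr_database(i, c, g)
        assert db.partner_genes("cplx") == ["NPR1", "NPR2"]
        assert db.partner_genes("P001") == ["NPPB"]

    def test_module_scale_table_parses(self, tmp_path):
        """A module of several hundred interactions (incl. proxy ligands and
        complexes) loads intact — synthetic stand-in at realistic scale."""
        n = 850
        inter = [{"partner_a": f"LIG{i:03d}", "partner_b": f"REC{i:03d}",
                  "proxy_a": i % 7 == 0, "proxy_b": False}
                 for i in range(n)]
        comp = [{"complex_name": f"REC{i:03d}", "member_1": f"R{i}a",
                 "member_2": f"R{i}b"} for i in range(0, n, 10)]
        i, c, _ = write_db(tmp_path, inter, comp)
        db = load_lr_database(i, c)
        assert len(db) > 800
        assert db.interactions["proxy_a"].sum() > 0
        assert len(db.complexes) == 85


class TestExpressedFraction:
    def test_three_of_ten(self):
        col = np.zeros((10, 1))
        col[:3] = 2.0
        norm = dense_norm(col, ["gA"])
        ann = make_annotation(["s"] * 10, ids=norm.row_ids)
        assert expressed_fraction(norm, ann, "gA", "s") == pytest.approx(0.3)

    def test_absent_gene_is_zero_with_warning(self):
        norm = dense_norm(np.ones((4, 1)), ["gA"])
        ann = make_annotation(["s"] * 4, ids=norm.row_ids)
        with pytest.warns(UserWarning):
            assert expressed_fraction(norm, ann, "gZ", "s") == 0.0

    def test_depends_only_on_zero_pattern(self):
        rng = np.random.default_rng(0)
        raw = rng.poisson(0.7, size=(20, 3)).astype(float)
        ann = make_annotation(["s"] * 20, ids=[f"c{i}" for i in range(20)])
        a = expressed_fraction(dense_norm(raw, list("abc")), ann, "a", "s")
        b = expressed_fraction(dense_norm(np.log1p(raw * 13), list("abc")),
                               ann, "a", "s")
        assert a == b


def simple_db(partner_a="L", partner_b="R", complexes=None):
    inter = pd.DataFrame([{"partner_a": partner_a, "partner_b": partner_b,
                           "proxy_a": False, "proxy_b": False}])
    return LRDatabase(inter, complexes or {})


class TestLRMean:
    def test_average_of_partner_means(self):
        vals = np.array([[2.0, 0.0], [2.0, 0.0], [0.0, 4.0], [0.0, 4.0]])
        norm = dense_norm(vals, ["L", "R"])
        ann = make_annotation(["A", "A", "B", "B"], ids=norm.row_ids)
        db = simple_db()
        assert lr_mean(norm, ann, db, 0, "A", "B") == pytest.approx(3.0)

    def test_complex_partner_takes_minimum_member_mean(self):
        vals = np.array([[2.0, 1.0, 5.0]] * 4)
        norm = dense_norm(vals, ["L", "Ra", "Rb"])
        ann = make_annotation(["A", "A", "B", "B"], ids=norm.row_ids)
        db = simple_db("L", "cplx", {"cplx": ["Ra", "Rb"]})
        # receiver value = min(1, 5) = 1 -> (2 + 1)/2
        assert lr_mean(norm, ann, db, 0, "A", "B") == pytest.approx(1.5)

    def test_complex_mean_rule_option(self):
        vals = np.array([[2.0, 1.0, 5.0]] * 4)
        norm = dense_norm(vals, ["L", "Ra", "Rb"])
        ann = make_annotation(["A", "A", "B", "B"], ids=norm.row_ids)
        db = simple_db("L", "cplx", {"cplx": ["Ra", "Rb"]})
        assert lr_mean(norm, ann, db, 0, "A", "B",
                       complex_rule="mean") == pytest.approx(2.5)

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(1)
        vals = rng.random((100, 4))
        norm = dense_norm(vals, ["L", "Ra", "Rb", "x"])
        labels = rng.choice(["A", "B", "C"], size=100)
        ann = make_annotation(labels, ids=norm.row_ids)
        db = simple_db("L", "cplx", {"cplx": ["Ra", "Rb"]})
        got = lr_mean(norm, ann, db, 0, "A", "B")
        oracle = (
            vals[labels == "A", 0].mean()
            + min(vals[labels == "B", 1].mean(), vals[labels == "B", 2].mean())
        ) / 2
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_under_joint_swap(self):
        rng = np.random.default_rng(2)
        vals = rng.random((30, 2))
        norm = dense_norm(vals, ["L", "R"])
        labels = ["A"] * 15 + ["B"] * 15
        ann = make_annotation(labels, ids=norm.row_ids)
        fwd = lr_mean(norm, ann, simple_db("L", "R"), 0, "A", "B")
        rev = lr_mean(norm, ann, simple_db("R", "L"), 0, "B", "A")
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_unresolvable_member_rejected(self):
        norm = dense_norm(np.ones((4, 1)), ["L"])
        ann = make_annotation(["A", "A", "B", "B"], ids=norm.row_ids)
        with pytest.raises(ValidationError):
            lr_mean(norm, ann, simple_db("L", "missing"), 0, "A", "B")


class TestLRPermutation:
    def test_single_state_p_one(self):
        norm = dense_norm(np.ones((12, 2)), ["L", "R"])
        ann = make_annotation(["A"] * 12, ids=norm.row_ids)
        p = lr_permutation_p(norm, ann, simple_db(), 0, "A", "A")
        assert p == 1.0

    def test_undersized_state_p_one(self):
        norm = dense_norm(np.ones((12, 2)), ["L", "R"])
        ann = make_annotation(["A"] * 3 + ["B"] * 9, ids=norm.row_ids)
        p = lr_permutation_p(norm, ann, simple_db(), 0, "A", "B",
                             min_cells=10)
        assert p == 1.0

    def test_exhaustive_matches_label_enumeration(self):
        rng = np.random.default_rng(3)
        vals = rng.random((6, 2))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        norm = dense_norm(vals, ["L", "R"])
        ann = make_annotation(labels, ids=norm.row_ids)
        db = simple_db()
        p = lr_permutation_p(norm, ann, db, 0, "A", "B", min_cells=1,
                             exhaustive=True)
        # independent oracle: enumerate the C(6,3) distinct assignments
        def stat(a_idx):
            a = list(a_idx)
            b = [i for i in range(6) if i not in a]
            return (vals[a, 0].mean() + vals[b, 1].mean()) / 2
        obs = stat([0, 1, 2])
        stats = [stat(c) for c in itertools.combinations(range(6), 3)]
        assert p == pytest.approx(np.mean([s >= obs for s in stats]),
                                  abs=1e-12)

    def test_planted_pair_directional(self, spec, expression):
        from cardioniche.synthetic_data import gen_lr_tables

        _, ann, norm = expression
        inter, comp = gen_lr_tables(spec)
        comp_dict = {r.complex_name: [r.member_1, r.member_2]
                     for r in comp.itertuples(index=False)}
        db = LRDatabase(inter, comp_dict)
        states = list(spec.states)
        fwd = lr_permutation_p(norm, ann, db, 0, states[0], states[1],
                               n_perm=500, seed=0)
        rev = lr_permutation_p(norm, ann, db, 0, states[1], states[0],
                               n_perm=500, seed=0)
        assert fwd < 0.05
        assert rev >= 0.05


class TestScreen:
    def _fixture(self):
        rng = np.random.default_rng(4)
        n = 60
        labels = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        vals = rng.random((n, 4)) + 0.5   # broadly expressed background
        # ligand L high in A, receptor R high in B; S expressed in 5% of A
        vals[:, 0] = np.where(labels == "A", 3.0, 0.05 * rng.random(n))
        vals[:, 1] = np.where(labels == "B", 3.0, 0.05 * rng.random(n))
        vals[:, 2] = 0.0
        vals[labels == "A", 2] = 0.0
        vals[0, 2] = 2.0                  # 1/20 = 5% of A expresses S
        norm = dense_norm(vals, ["L", "R", "S", "bg"])
        ann = make_annotation(labels, ids=norm.row_ids)
        inter = pd.DataFrame([
            {"partner_a": "L", "partner_b": "R", "proxy_a": False,
             "proxy_b": False},
            {"partner_a": "S", "partner_b": "R", "proxy_a": False,
             "proxy_b": False},
        ])
        return norm, ann, LRDatabase(inter, {})

    def test_low_fraction_ligand_excluded_regardless_of_p(self):
        norm, ann, db = self._fixture()
        out = niche_interaction_screen(norm, ann, db, ["A", "B"],
                                       n_perm=100, seed=0)
        s_rows = out[(out["partner_a"] == "S") & (out["sender"] == "A")]
        assert not s_rows["passed_fraction"].any()
        assert not s_rows["passed"].any()

    def test_statistical_mode_calls_planted_direction(self):
        norm, ann, db = self._fixture()
        out = niche_interaction_screen(norm, ann, db, ["A", "B"],
                                       n_perm=200, seed=0)
        out = out.set_index(["partner_a", "sender", "receiver"])
        assert out.loc[("L", "A", "B"), "passed"]

    def test_deg_mode_requires_a_deg_member(self, spec, expression):
        from cardioniche.synthetic_data import gen_lr_tables

        _, ann, norm = expression
        inter, comp = gen_lr_tables(spec)
        comp_dict = {r.complex_name: [r.member_1, r.member_2]
                     for r in comp.itertuples(index=False)}
        db = LRDatabase(inter, comp_dict)
        states = list(spec.states)
        out = niche_interaction_screen(norm, ann, db, states, mode="deg")
        passed = out[out["passed"]]
        # only the planted interaction has DEG members
        assert set(passed["interaction"]) == {0}
        assert (0, states[0], states[1]) in set(
            zip(passed["interaction"], passed["sender"], passed["receiver"])
        )

    def test_screen_shrinks_with_fraction_threshold(self):
        norm, ann, db = self._fixture()
        lo = niche_interaction_screen(norm, ann, db, ["A", "B"],
                                      frac_min=0.0, n_perm=50, seed=0)
        hi = niche_interaction_screen(norm, ann, db, ["A", "B"],
                                      frac_min=0.5, n_perm=50, seed=0)
        assert hi["passed_fraction"].sum() <= lo["passed_fraction"].sum()

    def test_empty_niche_rejected(self):
        norm, ann, db = self._fixture()
        with pytest.raises(ValidationError):
            niche_interaction_screen(norm, ann, db, [])

    def test_unknown_state_rejected(self):
        norm, ann, db = self._fixture()
        with pytest.raises(ValidationError):
            niche_interaction_screen(norm, ann, db, ["A", "Z"])
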