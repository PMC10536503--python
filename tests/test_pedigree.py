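import numpy as np
import pandas as pd
import pytest

from carriergwas.pedigree import (
    PedigreeError,
    additive_relationship,
    build_pedigree,
    classify_cohort,
    common_ancestors,
    relation_category,
)


def ped_from(rows):
    return build_pedigree(pd.DataFrame(rows))


class TestBuildPedigree:
    def test_trio_child_is_non_founder(self, trio_pedigree):
        assert len(trio_pedigree) == 3
        assert trio_pedigree.is_founder("sire")
        assert not trio_pedigree.is_founder("child")
        assert trio_pedigree.parents("child") == ("sire", "dam")

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            ped_from(
                [
                    {"id": "a", "sire": "b", "dam": None, "sex": "M"},
                    {"id": "b", "sire": "a", "dam": None, "sex": "M"},
                ]
            )

    def test_sex_conflict_rejected(self):
        with pytest.raises(PedigreeError, match="sex conflict"):
            ped_from(
                [
                    {"id": "x", "sire": None, "dam": None, "sex": "F"},
                    {"id": "c", "sire": "x", "dam": None, "sex": "M"},
                ]
            )

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            ped_from([{"id": "a"}, {"id": "a"}])

    def test_unlisted_parents_become_founders(self):
        ped = ped_from([{"id": "c", "sire": "s", "dam": "d", "sex": "M"}])
        assert "s" in ped and ped.sex("s") == "M"
        assert "d" in ped and ped.sex("d") == "F"


FULL_SIB_ROWS = [
    {"id": "s", "sire": None, "dam": None, "sex": "M"},
    {"id": "d", "sire": None, "dam": None, "sex": "F"},
    {"id": "c1", "sire": "s", "dam": "d", "sex": "M"},
    {"id": "c2", "sire": "s", "dam": "d", "sex": "F"},
]


class TestAdditiveRelationship:
    def test_parent_offspring_half(self, trio_pedigree):
        a = additive_relationship(trio_pedigree)
        assert a.loc["sire", "child"] == pytest.approx(0.5)
        assert a.loc["child", "child"] == pytest.approx(1.0)

    def test_full_sibs_and_inbred_offspring(self):
        ped = ped_from(
            FULL_SIB_ROWS + [{"id": "inbred", "sire": "c1", "dam": "c2", "sex": "M"}]
        )
        a = additive_relationship(ped)
        assert a.loc["c1", "c2"] == pytest.approx(0.5)
        # Offspring of a full-sib mating: F = 0.25.
        assert a.loc["inbred", "inbred"] == pytest.approx(1.25)

    def test_matrix_invariants(self, small_dataset):
        ped = small_dataset.pedigree
        subset = ped.ids[:40]
        a = additive_relationship(ped, subset).to_numpy()
        assert np.allclose(a, a.T)
        assert (np.diag(a) >= 1.0 - 1e-12).all()
        assert (a >= -1e-12).all()

    def test_truncation_never_increases_entries(self, small_dataset):
        ped = small_dataset.pedigree
        subset = ped.ids[-15:]
        a2 = additive_relationship(ped, subset, max_generations=2).to_numpy()
        a3 = additive_relationship(ped, subset, max_generations=3).to_numpy()
        assert (a2 <= a3 + 1e-12).all()

    def test_unknown_id_errors(self, trio_pedigree):
        with pytest.raises(KeyError):
            additive_relationship(trio_pedigree, ["nope"])

    def test_gene_dropping_oracle(self):
        """A entries match single-locus gene-dropping IBD sharing (MC oracle)."""
        rng = np.random.default_rng(42)
        rows = [
            {"id": f"f{i}", "sire": None, "dam": None, "sex": "M" if i % 2 == 0 else "F"}
            for i in range(10)
        ]
        ids = [r["id"] for r in rows]
        males = [i for i in ids if ids.index(i) % 2 == 0]
        females = [i for i in ids if ids.index(i) % 2 == 1]
        for g in range(2):
            new_m, new_f = [], []
            for k in range(10):
                iid = f"g{g}_{k}"
                sex = "M" if k % 2 == 0 else "F"
                rows.append(
                    {
                        "id": iid,
                        "sire": str(rng.choice(males)),
                        "dam": str(rng.choice(females)),
                        "sex": sex,
                    }
                )
                (new_m if sex == "M" else new_f).append(iid)
            males, females = new_m, new_f
        ped = ped_from(rows)
        all_ids = [r["id"] for r in rows]
        a = additive_relationship(ped, all_ids)

        # Oracle: drop unique founder alleles down the pedigree 10^4 times;
        # kinship(i,j) = P(random allele of i IBD to random allele of j).
        n_rep = 10_000
        founders = [i for i in all_ids if ped.is_founder(i)]
        alleles: dict[str, np.ndarray] = {}
        for k, f in enumerate(founders):
            alleles[f] = np.tile([2 * k, 2 * k + 1], (n_rep, 1))
        order = [i for i in all_ids if i not in alleles]
        while order:
            nxt = []
            for iid in order:
                s, d = ped.parents(iid)
                if s in alleles and d in alleles:
                    pick_s = rng.integers(2, size=n_rep)
                    pick_d = rng.integers(2, size=n_rep)
                    alleles[iid] = np.column_stack(
                        [
                            alleles[s][np.arange(n_rep), pick_s],
                            alleles[d][np.arange(n_rep), pick_d],
                        ]
                    )
                else:
                    nxt.append(iid)
            order = nxt
        check_pairs = [(all_ids[i], all_ids[j]) for i in range(0, 30, 7) for j in range(i, 30, 5)]
        for x, y in check_pairs:
            ax, ay = alleles[x], alleles[y]
            share = np.zeros(n_rep)
            for u in range(2):
                for v in range(2):
                    share += (ax[:, u] == ay[:, v]).astype(float)
            kin = share.mean() / 4.0
            if x == y:
                kin = 0.5 * (1.0 + (ax[:, 0] == ax[:, 1]).mean())
            expected = a.loc[x, y] / 2.0
            se = np.sqrt(max(expected * (1 - expected), 1e-4) / n_rep)
            assert abs(kin - expected) < 5 * se + 5e-3


class TestRelationCategory:
    def test_parent_offspring_views(self, trio_pedigree):
        assert relation_category(trio_pedigree, "sire", "child") == {"parent"}
        assert relation_category(trio_pedigree, "child", "sire") == {"offspring"}

    def test_half_sibs(self):
        ped = ped_from(
            [
                {"id": "d", "sire": None, "dam": None, "sex": "F"},
                {"id": "s1", "sire": None, "dam": None, "sex": "M"},
                {"id": "s2", "sire": None, "dam": None, "sex": "M"},
                {"id": "a", "sire": "s1", "dam": "d", "sex": "M"},
                {"id": "b", "sire": "s2", "dam": "d", "sex": "F"},
            ]
        )
        assert "half-sib" in relation_category(ped, "a", "b")

    def test_grandparent(self):
        ped = ped_from(
            [
                {"id": "gm", "sire": None, "dam": None, "sex": "F"},
                {"id": "m", "sire": None, "dam": "gm", "sex": "F"},
                {"id": "c", "sire": None, "dam": "m", "sex": "M"},
            ]
        )
        assert "grandparent" in relation_category(ped, "gm", "c")
        assert "grandchild" in relation_category(ped, "c", "gm")

    def test_avuncular(self):
        ped = ped_from(
            FULL_SIB_ROWS + [{"id": "niece", "sire": None, "dam": "c2", "sex": "F"}]
        )
        assert "avuncular" in relation_category(ped, "c1", "niece")

    def test_same_id_rejected(self, trio_pedigree):
        with pytest.raises(ValueError):
            relation_category(trio_pedigree, "sire", "sire")


def toy_classification_pedigree():
    """Case X with relatives covering each carrier/exclusion rule."""
    rows = [
        {"id": "gs", "sire": None, "dam": None, "sex": "M"},   # grandsire of X and Y
        {"id": "gd", "sire": None, "dam": None, "sex": "F"},
        {"id": "sireX", "sire": "gs", "dam": "gd", "sex": "M"},
        {"id": "damX", "sire": None, "dam": None, "sex": "F"},
        {"id": "X", "sire": "sireX", "dam": "damX", "sex": "F"},      # case
        {"id": "sibX", "sire": "sireX", "dam": "damX", "sex": "M"},   # full sib of X
        {"id": "childX", "sire": None, "dam": "X", "sex": "M"},       # offspring of X
        {"id": "damY", "sire": "gs", "dam": "gd", "sex": "F"},
        {"id": "Y", "sire": None, "dam": "damY", "sex": "M"},         # second case
        {"id": "gOnly", "sire": None, "dam": None, "sex": "F"},
        {"id": "damZ", "sire": None, "dam": "gOnly", "sex": "F"},
        {"id": "Z", "sire": None, "dam": "damZ", "sex": "F"},         # third case
        {"id": "loner", "sire": None, "dam": None, "sex": "M"},       # unrelated
    ]
    return ped_from(rows)


class TestClassifyCohort:
    def test_rule_application(self):
        ped = toy_classification_pedigree()
        genotyped = ["sireX", "childX", "sibX", "gOnly", "gs", "loner", "X", "Y", "Z"]
        st = classify_cohort(ped, ["X", "Y", "Z"], genotyped)
        assert st.status["X"] == "case"
        assert st.status["sireX"] == "carrier"        # parent of a case
        assert st.status["childX"] == "carrier"       # offspring of a case
        assert st.status["gs"] == "carrier"           # grandparent of two cases
        assert st.status["sibX"] == "excluded_relative"
        assert st.status["gOnly"] == "excluded_relative"  # grandparent of one case
        assert st.status["loner"] == "control"
        assert st.y["X"] == 2 and st.y["sireX"] == 1 and st.y["loner"] == 0
        assert "sibX" not in st.binary and st.binary["X"] == 1

    def test_pihat_rule(self):
        ped = toy_classification_pedigree()
        pihat = pd.DataFrame([{"ID1": "loner", "ID2": "X", "PI_HAT": 0.3}])
        st = classify_cohort(ped, ["X"], ["X", "loner"], pihat=pihat)
        assert st.status["loner"] == "excluded_relative"
        assert "pihat" in st.reason["loner"]

    def test_ambiguous_and_tcell_exclusions(self):
        ped = toy_classification_pedigree()
        st = classify_cohort(
            ped, ["X", "Y"], ["X", "Y"],
            diagnoses={"X": "ambiguous", "Y": "T"},
        )
        assert st.status["X"] == "excluded_diagnosis"
        assert st.status["Y"] == "excluded_diagnosis"
        assert not st.binary

    def test_order_independence(self):
        ped = toy_classification_pedigree()
        genotyped = ["sireX", "childX", "sibX", "gOnly", "gs", "loner", "X"]
        a = classify_cohort(ped, ["X", "Y", "Z"], genotyped)
        b = classify_cohort(ped, ["Z", "X", "Y"], list(reversed(genotyped)))
        assert a.status == b.status

    def test_carrier_beats_exclusion(self):
        # sireX is both parent of X (carrier rule) and, via gs/gd, could hit
        # relative rules; carrier must win.
        ped = toy_classification_pedigree()
        st = classify_cohort(ped, ["X", "Y"], ["sireX"])
        assert st.status["sireX"] == "carrier"

    def test_simulated_parent_carriers(self, small_dataset):
        """Every genotyped parent of a case is labelled carrier (recall 1)."""
        ds = small_dataset
        cases = ds.case_ids
        if len(cases) < 1:
            pytest.skip("no cases in this simulation seed")
        st = classify_cohort(ds.pedigree, cases, ds.pedigree.ids)
        for c in cases:
            for p in ds.pedigree.parents(c):
                if p is not None and p not in cases:
                    assert st.status[p] == "carrier"


class TestCommonAncestors:
    def test_full_sibs_parents_head_list(self):
        ped = ped_from(FULL_SIB_ROWS)
        out = common_ancestors(ped, ["c1", "c2"])
        assert set(out["id"][:2]) == {"s", "d"}

    def test_disjoint_families_empty(self):
        ped = ped_from(
            [
                {"id": "a", "sire": None, "dam": None, "sex": "M"},
                {"id": "b", "sire": None, "dam": None, "sex": "M"},
            ]
        )
        assert len(common_ancestors(ped, ["a", "b"])) == 0

    def test_ranked_by_year_then_path(self):
        rows = FULL_SIB_ROWS + [
            {"id": "gs", "sire": None, "dam": None, "sex": "M", "year": 1970},
        ]
        rows = [dict(r) for r in rows]
        for r in rows:
            if r["id"] == "s":
                r["sire"] = "gs"
                r["year"] = 1980
            if r["id"] == "d":
                r["year"] = 1981
        ped = ped_from(rows)
        out = common_ancestors(ped, ["c1", "c2"])
        assert list(out["id"]) == ["gs", "s", "d"]
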