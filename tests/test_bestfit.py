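import numpy as np
import pytest

from fossilfit import datasets
from fossilfit.bestfit import (
    FossilObservation,
    GroupProfile,
    ReferenceTraitTable,
    TraitRange,
    comparison_table,
    fit_report,
    hierarchical_assign,
    overlaps,
    read_reference_table,
    write_reference_table,
)
from fossilfit.synthetic_data import SimulationConfig, gen_fossil, gen_reference_system


@pytest.fixture
def tribe_table():
    return ReferenceTraitTable(
        level="tribe",
        groups=[
            GroupProfile("Oreochromini", 100, {
                "#Lt": TraitRange.int_set({4, 5}),
                "Vt": TraitRange.interval(26, 33),
            }),
            GroupProfile("Coptodonini", 30, {
                "#Lt": TraitRange.int_set({5}),
                "Vt": TraitRange.interval(26, 30),
            }),
            GroupProfile("Etiini", 5, {}),  # nothing recorded
        ],
    )


class TestOverlaps:
    @pytest.mark.parametrize(
        "obs,ref,expected",
        [
            (4, TraitRange.int_set({4, 5}), "fit"),  # tubule count in pooled set
            ((28, 30), TraitRange.interval(31, 36), "no-fit"),  # disjoint intervals
            ((28, 30), TraitRange.interval(30, 34), "fit"),  # single-point boundary
            ("cycloid", TraitRange.cat_set({"cycloid", "ctenoid"}), "fit"),
            ("ctenoid", TraitRange.cat_set({"cycloid"}), "no-fit"),
            (5, TraitRange.interval(4, 6, partial=True), "partial"),
        ],
    )
    def test_verdicts(self, obs, ref, expected):
        assert overlaps(obs, ref) == expected

    def test_interval_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = sorted(rng.integers(0, 20, 2))
            b = sorted(rng.integers(0, 20, 2))
            ra = TraitRange.interval(a[0], a[1])
            rb = TraitRange.interval(b[0], b[1])
            assert overlaps((b[0], b[1]), ra) == overlaps((a[0], a[1]), rb)

    def test_kind_mismatch_raises(self):
        with pytest.raises(TypeError, match="scale_type"):
            overlaps(4, TraitRange.cat_set({"cycloid"}), trait="scale_type")


class TestFitReport:
    def test_tubule_count_discriminates_tribes(self, tribe_table):
        rep = fit_report(FossilObservation({"#Lt": 4}), tribe_table)
        assert rep.candidates == ["Oreochromini"]
        assert rep.verdict("Coptodonini").per_trait["#Lt"] == "no-fit"

    def test_empty_observation_all_indeterminate(self, tribe_table):
        rep = fit_report(FossilObservation({}), tribe_table)
        assert rep.candidates == []
        assert all(v.indeterminate for v in rep.verdicts)

    def test_unrecorded_traits_excluded_from_both_sides(self, tribe_table):
        rep = fit_report(FossilObservation({"#Lt": 4, "Vt": (28, 30)}), tribe_table)
        etiini = rep.verdict("Etiini")
        assert etiini.indeterminate and not etiini.is_candidate

    def test_fit_fraction_one_iff_candidate(self, tribe_table):
        rep = fit_report(FossilObservation({"#Lt": 5, "Vt": (34, 35)}), tribe_table)
        for v in rep.verdicts:
            if v.n_observed_compared:
                assert (v.fit_fraction == 1.0) == v.is_candidate

    def test_monotone_under_trait_removal(self):
        """Dropping an observed trait can only grow the candidate set."""
        cfg = SimulationConfig(seed=11, n_clades=4)
        system = gen_reference_system(cfg)
        rng = np.random.default_rng(5)
        for i in range(100):
            clade = system.tribe_table.groups[int(rng.integers(4))].name
            fossil, _ = gen_fossil(system, clade, mask_fraction=0.2, seed=2000 + i)
            if not fossil.traits:
                continue
            full = set(fit_report(fossil, system.tribe_table).candidates)
            drop = list(fossil.traits)[int(rng.integers(len(fossil.traits)))]
            reduced = FossilObservation(
                {k: v for k, v in fossil.traits.items() if k != drop}
            )
            less = set(fit_report(reduced, system.tribe_table).candidates) if reduced.traits else set()
            if reduced.traits:
                assert full <= less


class TestHierarchicalAssign:
    def test_single_tribe_single_genus(self):
        tribe = ReferenceTraitTable("tribe", [GroupProfile("T", 1, {"Vt": TraitRange.interval(20, 30)})])
        genus = ReferenceTraitTable("genus", [GroupProfile("G", 1, {"Vt": TraitRange.interval(22, 28)})])
        res = hierarchical_assign(FossilObservation({"Vt": 25}), tribe, {"T": genus})
        assert res.tribe_candidates == ["T"]
        assert res.genus_candidates == {"T": ["G"]}

    def test_missing_genus_table_reports_unresolved(self):
        tribe = ReferenceTraitTable("tribe", [GroupProfile("T", 1, {"Vt": TraitRange.interval(20, 30)})])
        res = hierarchical_assign(FossilObservation({"Vt": 25}), tribe, {})
        assert res.unresolved_tribes == ["T"]

    def test_synthetic_two_level_recovery(self):
        """True tribe among candidates for >=95% of 200 masked fossils."""
        cfg = SimulationConfig(seed=42)
        system = gen_reference_system(cfg)
        hits = 0
        for i in range(200):
            clade = system.tribe_table.groups[i % cfg.n_clades].name
            fossil, truth = gen_fossil(system, clade, mask_fraction=0.3, seed=42_000 + i)
            res = hierarchical_assign(fossil, system.tribe_table, system.genus_tables)
            hits += truth["tribe"] in res.tribe_candidates
        assert hits >= 190

    def test_genus_level_only_within_candidate_tribes(self):
        cfg = SimulationConfig(seed=8, n_clades=3)
        system = gen_reference_system(cfg)
        fossil, truth = gen_fossil(system, system.tribe_table.groups[0].name, 0.0, seed=1)
        res = hierarchical_assign(fossil, system.tribe_table, system.genus_tables)
        assert set(res.genus_reports) <= set(res.tribe_candidates)


class TestComparisonTable:
    def test_packaged_genus_comparison_grid(self):
        """The fossil vs Alcolapia/Oreochromis grid reproduces the printed
        mismatch pattern: lacrimal depth separates it from Alcolapia, the
        cleithral notch and flank-scale ratio from Oreochromis."""
        fossil = datasets.fossil_observation()
        table = datasets.oreochromini_genus_table()
        shared = FossilObservation(
            {k: v for k, v in fossil.traits.items() if k in table.vocabulary}
        )
        grid = comparison_table(shared, ["Alcolapia", "Oreochromis"], table).set_index("trait")
        assert grid.loc["#Lt", "Alcolapia"] == "+"
        assert grid.loc["#Lt", "Oreochromis"] == "+"
        assert grid.loc["lacrimal_depth_pctHL", "Alcolapia"] == "-"
        assert grid.loc["lacrimal_depth_pctHL", "Oreochromis"] == "(+)"
        assert grid.loc["flank_scale_wl_ratio", "Oreochromis"] == "-"
        assert grid.loc["notch_on_cleithrum", "Oreochromis"] == "-"
        assert grid.loc["notch_on_cleithrum", "Alcolapia"] == "?"

    def test_all_fit_grid(self):
        table = ReferenceTraitTable("genus", [GroupProfile("G", 1, {"Vt": TraitRange.interval(20, 30)})])
        grid = comparison_table(FossilObservation({"Vt": 22}), ["G"], table)
        assert set(grid["G"]) == {"+"}


class TestIO:
    def test_reference_table_round_trips(self, tribe_table, tmp_path):
        path = tmp_path / "tribes.tsv"
        write_reference_table(tribe_table, path)
        back = read_reference_table(path)
        assert {g.name for g in back.groups} >= {"Oreochromini", "Coptodonini"}
        assert back.group("Oreochromini").traits["#Lt"].members == frozenset({4, 5})
        assert back.group("Coptodonini").traits["Vt"].lo == 26
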