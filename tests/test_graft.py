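"""Monophyly assessment, clade-task building, rescaling and grafting algebra."""

import numpy as np
import pytest

from phylograft.graft import (
    CladeTask,
    GraftError,
    assess_monophyly,
    build_clade_tasks,
    graft_all,
    graft_subtree,
    rescale_subtree,
)
from phylograft.model import TaxaTable
from phylograft.trees import Chronogram


def dated(newick: str) -> Chronogram:
    t = Chronogram.from_newick(newick)
    t.compute_ages()
    return t


class TestAssessMonophyly:
    def test_interleaved_genera_flagged(self, simple_taxa):
        # A monophyletic; C and D interleave
        backbone = dated("((A1:1,A2:1):3,((C1:1,D1:1):1,(C2:1,D2:1):1):2);")
        verdict = assess_monophyly(backbone, simple_taxa)
        assert verdict["A"] is True
        assert verdict["C"] is False
        assert verdict["D"] is False

    def test_reciprocally_monophyletic_cherries(self, simple_taxa):
        backbone = dated(
            "(((A1:1,A2:1):1,(B1:1,B2:1):1):1,((C1:1,C2:1):1,(D1:1,D2:1):1):1);"
        )
        verdict = assess_monophyly(backbone, simple_taxa)
        assert all(verdict.values())

    def test_polytomy_mixing_two_genera_flags_both(self, simple_taxa):
        backbone = dated("((A1:1,A2:1):2,(C1:1,C2:1,D1:1,D2:1):2);")
        verdict = assess_monophyly(backbone, simple_taxa)
        assert verdict["C"] is False and verdict["D"] is False

    def test_singleton_trivially_monophyletic(self):
        taxa = TaxaTable([("A1", "", "A"), ("B1", "", "B")])
        backbone = dated("(A1:1,B1:1);")
        assert assess_monophyly(backbone, taxa) == {"A": True, "B": True}


class TestBuildCladeTasks:
    def test_all_monophyletic_one_task_per_multispecies_genus(self, simple_taxa):
        backbone = dated(
            "(((A1:1,A2:1):1,(B1:1,B2:1):1):1,((C1:1,C2:1):1,(D1:1,D2:1):1):1);"
        )
        tasks = build_clade_tasks(backbone, backbone, simple_taxa, {})
        assert sorted(t.genera for t in tasks) == [("A",), ("B",), ("C",), ("D",)]
        a = [t for t in tasks if t.genera == ("A",)][0]
        assert a.calibration_age == pytest.approx(1.0)

    def test_interleaved_pair_merged(self, simple_taxa):
        backbone = dated(
            "(((A1:1,A2:1):1,(B1:1,B2:1):1):2,((C1:1,D1:1):1,(C2:1,D2:1):1):2);"
        )
        tasks = build_clade_tasks(backbone, backbone, simple_taxa, {})
        merged = [t for t in tasks if len(t.genera) > 1]
        assert len(merged) == 1
        assert merged[0].genera == ("C", "D")
        assert set(merged[0].species) == {"C1", "C2", "D1", "D2"}
        assert merged[0].calibration_age == pytest.approx(2.0)

    def test_chained_interleaving_reaches_fixed_point(self):
        taxa = TaxaTable(
            [(s, "", s[0]) for s in ("A1", "A2", "B1", "B2", "C1", "C2", "X1", "X2")]
        )
        # A interleaves B, and their joint clade swallows C; X stays clean ->
        # fixed-point merging yields tasks {A,B,C} and {X}
        backbone = dated(
            "(((A1:3,B1:3):1,((A2:1,B2:1):1,(C1:1,C2:1):1):2):2,(X1:1,X2:1):5);"
        )
        tasks = build_clade_tasks(backbone, backbone, taxa, {})
        genera_sets = sorted(t.genera for t in tasks)
        assert ("X",) in genera_sets
        merged = [g for g in genera_sets if len(g) > 1]
        assert merged == [("A", "B", "C")]

    def test_alignments_assigned_when_two_species_present(self, simple_taxa):
        from conftest import make_records

        backbone = dated(
            "(((A1:1,A2:1):1,(B1:1,B2:1):1):1,((C1:1,C2:1):1,(D1:1,D2:1):1):1);"
        )
        alignments = {
            "aln1": make_records({"A1": "ACGT", "A2": "ACGA"}),
            "aln2": make_records({"A1": "ACGT", "B1": "ACGA"}),
        }
        tasks = build_clade_tasks(backbone, backbone, simple_taxa, alignments)
        a = [t for t in tasks if t.genera == ("A",)][0]
        assert a.alignment_ids == ("aln1",)


class TestRescaleSubtree:
    def make_task(self, age=10.0):
        return CladeTask(
            task_id="task_G",
            genera=("G",),
            species=("g1", "g2", "g3"),
            exemplars=("g1", "g3"),
            calibration_age=age,
        )

    def test_exemplars_spanning_root(self):
        sub = dated("((g1:0.5,g2:0.5):0.5,g3:1);")
        out = rescale_subtree(sub, self.make_task(10.0))
        assert out.root.age == 10.0  # bit-exact pin
        assert out.mrca(["g1", "g2"]).age == pytest.approx(5.0)

    def test_internal_anchor_arithmetic(self):
        # exemplar MRCA at relative age 2, root at 3, backbone age 10 -> f = 5
        sub = dated("((g1:2,g3:2):1,g2:3);")
        task = CladeTask(
            "task_G", ("G",), ("g1", "g2", "g3"), ("g1", "g3"), 10.0
        )
        out = rescale_subtree(sub, task)
        assert out.mrca(["g1", "g3"]).age == 10.0
        assert out.root.age == pytest.approx(15.0)

    def test_hpd_bounds_scaled_by_f(self):
        sub = dated("((g1:2[&hpd={1.5,2.5}],g3:2):1,g2:3);")
        # annotate the exemplar MRCA instead of a tip
        sub = Chronogram.from_newick("((g1:2,g3:2)[&hpd={1.5,2.5}]:1,g2:3);")
        sub.compute_ages()
        task = CladeTask("task_G", ("G",), ("g1", "g2", "g3"), ("g1", "g3"), 10.0)
        out = rescale_subtree(sub, task)
        node = out.mrca(["g1", "g3"])
        assert node.hpd_min == pytest.approx(7.5)
        assert node.hpd_max == pytest.approx(12.5)

    def test_zero_age_exemplar_mrca_rejected(self):
        sub = dated("((g1:0,g3:0):1,g2:1);")
        with pytest.raises(GraftError, match="age 0"):
            rescale_subtree(sub, self.make_task())


class TestGraftSubtree:
    def backbone(self):
        # exemplars g1, g3 form a cherry at age 2; stem to parent at age 8
        return dated("((g1:2,g3:2):6,(h1:4,h2:4):4);")

    def task(self):
        return CladeTask(
            "task_G", ("G",), ("g1", "g2", "g3", "g4"), ("g1", "g3"), 2.0
        )

    def test_exemplars_spanning_subtree_root_replaces_clade(self):
        sub = dated("((g1:1,g2:1):1,(g3:1.5,g4:1.5):0.5);")
        rescaled = rescale_subtree(sub, self.task())
        out = graft_subtree(self.backbone(), rescaled, self.task())
        assert out.n_tips() == 4 - 2 + 4  # backbone - pair + clade
        assert out.mrca(["g1", "g3"]).age == 2.0
        assert out.root.age == pytest.approx(8.0)  # untouched
        out.validate_dated()

    def test_stem_shortened_by_overshoot(self):
        # subtree root above the exemplar MRCA: d = 7 - 2 = 5; stem 6 -> 1
        sub = dated("(((g1:2,g3:2):4,g2:6):1,g4:7);")
        task = self.task()
        rescaled = rescale_subtree(sub, task)
        assert rescaled.root.age == pytest.approx(7.0)
        out = graft_subtree(self.backbone(), rescaled, task)
        sub_root = out.mrca(["g1", "g4"])
        assert sub_root.age == pytest.approx(7.0)
        assert sub_root.length == pytest.approx(1.0)  # stem 6 - d 5
        out.validate_dated()

    def test_negative_branch_raises_with_clade_name(self):
        # d = 10 - 2 = 8 > stem 6
        sub = dated("(((g1:2,g3:2):6,g2:8):2,g4:10);")
        rescaled = rescale_subtree(sub, self.task())
        with pytest.raises(GraftError, match="task_G"):
            graft_subtree(self.backbone(), rescaled, self.task())

    def test_clamp_mode_squeezes_with_warning(self):
        sub = dated("(((g1:2,g3:2):6,g2:8):2,g4:10);")
        rescaled = rescale_subtree(sub, self.task())
        with pytest.warns(UserWarning, match="clamped"):
            out = graft_subtree(self.backbone(), rescaled, self.task(), mode="clamp")
        out.validate_dated()
        assert out.mrca(["g1", "g4"]).age < 8.0


class TestGraftAll:
    def test_zero_tasks_returns_backbone(self):
        bb = dated("((g1:2,g3:2):6,(h1:4,h2:4):4);")
        out = graft_all(bb, {}, [])
        assert out.newick() == bb.newick()

    def test_two_disjoint_cherries_tip_count(self):
        bb = dated("((g1:2,g3:2):6,(h1:4,h2:4):4);")
        t1 = CladeTask("task_G", ("G",), ("g1", "g2", "g3"), ("g1", "g3"), 2.0)
        t2 = CladeTask("task_H", ("H",), ("h1", "h2", "h3", "h4"), ("h1", "h2"), 4.0)
        s1 = dated("((g1:1,g2:1):1,g3:2);")
        s2 = dated("((h1:2,h3:2):2,(h2:3,h4:3):1);")
        out = graft_all(bb, {"task_G": s1, "task_H": s2}, [t1, t2])
        assert out.n_tips() == 4 - 4 + 3 + 4
        assert out.mrca(["g1", "g3"]).age == 2.0
        assert out.mrca(["h1", "h2"]).age == 4.0
        out.validate_dated()

    def test_failing_graft_reports_partial(self):
        bb = dated("((g1:2,g3:2):6,(h1:4,h2:4):4);")
        t1 = CladeTask("task_G", ("G",), ("g1", "g2", "g3"), ("g1", "g3"), 2.0)
        bad = dated("(((g1:2,g3:2):6,g2:8):2,x:10);")  # will overshoot
        bad.prune_tips(["x"])
        bad.compute_ages()
        with pytest.raises(GraftError) as err:
            graft_all(bb, {"task_G": bad}, [t1])
        assert hasattr(err.value, "partial")


class TestGraftInvariants:
    def test_random_backbone_subtree_pairs(self):
        """Ultrametricity, bit-exact anchor preservation and HPD scaling on
        random simulated backbone/subtree pairs."""
        from conftest import random_ultrametric_tree

        rng = np.random.default_rng(99)
        for trial in range(30):
            n_clade = int(rng.integers(3, 7))
            clade_labels = [f"g{i}" for i in range(n_clade)]
            sub = random_ultrametric_tree(clade_labels, rng, depth=1.0)
            exemplars = sorted(rng.choice(clade_labels, size=2, replace=False))
            backbone = dated(
                f"(({exemplars[0]}:2,{exemplars[1]}:2):6,(h1:4,h2:4):4);"
            )
            # scatter an HPD annotation on the subtree root
            sub.root.hpd_min = sub.root.age * 0.8
            sub.root.hpd_max = sub.root.age * 1.2
            task = CladeTask(
                "task_G", ("G",), tuple(clade_labels), tuple(exemplars), 2.0
            )
            rescaled = rescale_subtree(sub, task)
            f = 2.0 / sub.mrca(exemplars).age
            assert rescaled.root.hpd_min == pytest.approx(sub.root.hpd_min * f)
            assert rescaled.root.hpd_max == pytest.approx(sub.root.hpd_max * f)
            assert rescaled.mrca(exemplars).age == 2.0  # bit-exact
            try:
                out = graft_subtree(backbone, rescaled, task)
            except GraftError:
                # overshoot beyond the stem must mean d >= stem
                d = rescaled.root.age - 2.0
                assert d >= 6.0
                continue
            out.validate_dated(tol=1e-9)
            assert out.mrca(exemplars).age == 2.0
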