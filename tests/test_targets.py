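"""Candidate selection workflow and target/pathway set algebra."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhythm.io import ExpressionMatrix, validate_annotation
from mirhythm.screen import screen
from mirhythm.targets import (
    d_vs_l_sets,
    map_targets,
    pathway_sets,
    select_candidates,
    venn,
)


def _screen_rows(specs):
    """Rows as produced by the rhythm screen; specs: (id, rhythmic, band,
    cluster, p, mean_expr)."""
    return pd.DataFrame(
        specs,
        columns=["feature_id", "rhythmic", "quartile_band", "cluster", "p", "mean_expr"],
    )


def _annotation(pairs):
    return validate_annotation(
        pd.DataFrame(
            [
                {"mature_id": m, "arm": "5p", "precursor_id": p, "locus_id": f"loc-{p}"}
                for m, p in pairs
            ]
        )
    )


class TestSelectCandidates:
    def _screens(self):
        mature = _screen_rows(
            [
                ("a", True, "75-100", "D1", 0.01, 900.0),
                ("b", True, "75-100", "D2", 0.02, 800.0),
                ("c", True, "50-75", "D1", 0.001, 300.0),   # fails quartile
                ("d", False, "75-100", "none", 0.50, 700.0),  # fails rhythm
                ("e", True, "75-100", "L1", 0.03, 600.0),   # precursor arrhythmic
            ]
        )
        pre = _screen_rows(
            [
                ("pre-a", True, "75-100", "D1", 0.01, 500.0),
                ("pre-b", True, "75-100", "D2", 0.04, 460.0),
                ("pre-c", True, "75-100", "D1", 0.01, 450.0),
                ("pre-d", True, "75-100", "none", 0.01, 420.0),
                ("pre-e", False, "75-100", "none", 0.70, 410.0),
                ("pre-low1", False, "0-25", "none", 0.9, 1.0),
                ("pre-low2", False, "0-25", "none", 0.9, 2.0),
                ("pre-low3", False, "0-25", "none", 0.9, 3.0),
            ]
        )
        ann = _annotation(
            [("a", "pre-a"), ("b", "pre-b"), ("c", "pre-c"), ("d", "pre-d"),
             ("e", "pre-e")]
        )
        return mature, pre, ann

    def test_exactly_engineered_candidates_selected(self):
        mature, pre, ann = self._screens()
        result = select_candidates(mature, pre, ann)
        assert result.all_candidates() == ["a", "b"]
        assert result.clusters == {"D1": ["a"], "D2": ["b"]}

    def test_mature_without_precursor_link_excluded_and_logged(self):
        mature, pre, ann = self._screens()
        mature = pd.concat(
            [mature, _screen_rows([("orphanly", True, "75-100", "D1", 0.01, 950.0)])]
        )
        result = select_candidates(mature, pre, ann)
        assert "orphanly" in result.excluded
        assert "orphanly" not in result.all_candidates()

    def test_precursor_below_median_fails_criterion(self):
        mature, pre, ann = self._screens()
        pre.loc[pre["feature_id"] == "pre-b", "mean_expr"] = 0.5  # below median
        result = select_candidates(mature, pre, ann)
        assert result.all_candidates() == ["a"]

    def test_monotone_in_alpha(self, design_meta):
        """Raising alpha never removes a candidate (screen-level property)."""
        rng = np.random.default_rng(31)
        rows_m, rows_p, links = {}, {}, []
        t = design_meta["zt_hours"].to_numpy(float)
        for i in range(12):
            mesor = 100 + 10 * i
            y = mesor * (1 + 0.4 * np.cos(2 * np.pi * (t - 15) / 24))
            rows_m[f"m{i}"] = y * np.exp(rng.normal(0, 0.15, t.size))
            rows_p[f"pre-m{i}"] = y * np.exp(rng.normal(0, 0.15, t.size))
            links.append((f"m{i}", f"pre-m{i}"))
        ann = _annotation(links)
        mat = ExpressionMatrix(pd.DataFrame(rows_m, index=list(design_meta["sample_id"])).T)
        pre = ExpressionMatrix(pd.DataFrame(rows_p, index=list(design_meta["sample_id"])).T)
        selected = {}
        for alpha in (0.01, 0.05, 0.20):
            sm = screen(mat, design_meta, alpha=alpha)
            sp = screen(pre, design_meta, alpha=alpha)
            selected[alpha] = set(select_candidates(sm, sp, ann).all_candidates())
        assert selected[0.01] <= selected[0.05] <= selected[0.20]


class TestMapTargets:
    def _targets(self):
        return pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m2", "m2"],
                "target_gene": ["G1", "G2", "G2", "G3"],
                "support_type": "Functional MTI",
                "species": "hsa",
            }
        )

    def _candidates(self, clusters):
        from mirhythm.targets import CandidateSet

        return CandidateSet(clusters=clusters)

    def test_cluster_union_deduplicates(self):
        gene_sets, unmapped = map_targets(
            self._candidates({"D1": ["m1", "m2"]}), self._targets()
        )
        assert gene_sets == {"D1": {"G1", "G2", "G3"}}
        assert unmapped == []

    def test_empty_cluster_empty_set(self):
        gene_sets, _ = map_targets(self._candidates({"L1": []}), self._targets())
        assert gene_sets == {"L1": set()}

    def test_unresolvable_candidate_logged_with_empty_contribution(self):
        gene_sets, unmapped = map_targets(
            self._candidates({"D1": ["no-human-homologue"]}), self._targets()
        )
        assert gene_sets == {"D1": set()}
        assert unmapped == ["no-human-homologue"]

    def test_id_map_translates_before_lookup(self):
        id_map = pd.DataFrame({"from_id": ["rno-m1"], "to_id": ["m1"]})
        gene_sets, unmapped = map_targets(
            self._candidates({"D1": ["rno-m1"]}), self._targets(), id_map=id_map
        )
        assert gene_sets == {"D1": {"G1", "G2"}}

    def test_filter_composition_with_strong_evidence(self, tmp_path):
        from mirhythm.io import read_targets

        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "miRNA": ["m1", "m1", "m2"],
                "Target Gene": ["G1", "G2", "G3"],
                "Support Type": ["Functional MTI", "Functional MTI (Weak)", "Functional MTI"],
            }
        ).to_csv(path, index=False)
        strong = read_targets(path, evidence_filter={"Functional MTI"})
        gene_sets, _ = map_targets(self._candidates({"D1": ["m1", "m2"]}), strong)
        assert gene_sets == {"D1": {"G1", "G3"}}  # weak row never contributes


def brute_force_regions(sets):
    labels = sorted(sets)
    regions = {}
    for element in set().union(*sets.values()):
        signature = tuple(l for l in labels if element in sets[l])
        regions.setdefault(signature, set()).add(element)
    return regions


class TestVenn:
    def test_two_set_example(self):
        regions = venn({"X": {"A", "B"}, "Y": {"B", "C"}})
        assert regions[("X",)]["count"] == 1
        assert regions[("Y",)]["count"] == 1
        assert regions[("X", "Y")]["count"] == 1

    def test_identical_sets_all_mass_in_intersection(self):
        regions = venn({"X": {"A", "B"}, "Y": {"A", "B"}, "Z": {"A", "B"}})
        assert regions[("X", "Y", "Z")]["count"] == 2
        assert all(
            v["count"] == 0 for k, v in regions.items() if k != ("X", "Y", "Z")
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sets(st.integers(min_value=0, max_value=30), max_size=20),
            min_size=2,
            max_size=3,
        )
    )
    def test_matches_brute_force_enumeration(self, raw_sets):
        sets = {f"S{i}": s for i, s in enumerate(raw_sets)}
        regions = venn(sets)
        brute = brute_force_regions(sets)
        for combo, info in regions.items():
            assert info["count"] == len(brute.get(combo, set()))
        union = set().union(*sets.values())
        assert sum(info["count"] for info in regions.values()) == len(union)

    def test_order_invariance(self):
        a = {"D": {1, 2, 3}, "L": {3, 4}}
        b = {"L": {3, 4}, "D": {1, 2, 3}}
        assert venn(a) == venn(b)

    def test_rejects_wrong_arity(self):
        with pytest.raises(ValueError):
            venn({"only": {1}})


def test_d_vs_l_collapse():
    gene_sets = {"D1": {"A", "B"}, "D2": {"B", "C"}, "L1": {"C", "D"}}
    combined = d_vs_l_sets(gene_sets)
    assert combined == {"D": {"A", "B", "C"}, "L": {"C", "D"}}


class TestPathwaySets:
    def _pathways(self, rows):
        return pd.DataFrame(rows, columns=["gene_symbol", "pathway_accession", "pathway_name"])

    def test_threshold_boundary(self):
        table = self._pathways(
            [["G1", "P1", "p1"], ["G2", "P1", "p1"], ["G3", "P1", "p1"],
             ["G1", "P2", "p2"], ["G2", "P2", "p2"]]
        )
        sets3, _ = pathway_sets({"D1": {"G1", "G2", "G3"}}, table, min_genes=3)
        assert sets3 == {"D1": {"P1"}}

    def test_min_genes_one_keeps_every_touched_pathway(self):
        table = self._pathways([["G1", "P1", "p1"], ["G2", "P2", "p2"]])
        sets1, _ = pathway_sets({"D1": {"G1", "G2"}}, table, min_genes=1)
        assert sets1 == {"D1": {"P1", "P2"}}

    def test_shared_pathway_via_different_genes(self):
        # the same pathway reached by disjoint gene sets in two clusters
        table = self._pathways(
            [[g, "P00059", "p53 pathway"] for g in ("G1", "G2", "G3", "H1", "H2", "H3")]
        )
        sets, coverage = pathway_sets(
            {"D1": {"G1", "G2", "G3"}, "D2": {"H1", "H2", "H3"}}, table
        )
        assert sets == {"D1": {"P00059"}, "D2": {"P00059"}}

    def test_unannotated_genes_counted_in_coverage(self):
        table = self._pathways([["G1", "P1", "p1"]])
        _, coverage = pathway_sets({"D1": {"G1", "GX"}}, table, min_genes=1)
        assert coverage["D1"]["unannotated"] == ["GX"]

    def test_empty_pathway_table_rejected(self):
        with pytest.raises(ValueError):
            pathway_sets({"D1": set()}, pd.DataFrame(), min_genes=3)


class TestEndToEndClusterMembership:
    def test_planted_acrophases_reproduce_cluster_lists(self, design_meta):
        """Candidates planted with known acrophases and abundances come out
        in exactly the intended D1/D2/L1 memberships."""
        t = design_meta["zt_hours"].to_numpy(float)
        plan = {
            "miR-128": ("D1", 13.0), "miR-129": ("D1", 14.5), "miR-139": ("D1", 16.0),
            "miR-150": ("D1", 15.6), "miR-425": ("D1", 17.0),
            "miR-148a": ("D2", 19.0), "miR-148b": ("D2", 20.5),
            "let-7g": ("D2", 22.0), "miR-185": ("D2", 23.0),
            "miR-30d": ("L1", 0.7),
        }
        rows_m, rows_p, links = {}, {}, []
        for name, (_, phi) in plan.items():
            profile = 1000.0 * (1 + 0.5 * np.cos(2 * np.pi * (t - phi) / 24))
            rows_m[name] = profile
            rows_p[f"pre-{name}"] = 0.6 * profile
            links.append((name, f"pre-{name}"))
        for i in range(30):  # arrhythmic low-abundance background
            rows_m[f"bg{i}"] = np.full(t.size, float(i + 1))
            rows_p[f"pre-bg{i}"] = np.full(t.size, float(i + 1) / 2)
            links.append((f"bg{i}", f"pre-bg{i}"))
        samples = list(design_meta["sample_id"])
        mat = ExpressionMatrix(pd.DataFrame(rows_m, index=samples).T)
        pre = ExpressionMatrix(pd.DataFrame(rows_p, index=samples).T)
        ann = _annotation(links)
        sm = screen(mat, design_meta)
        sp = screen(pre, design_meta)
        result = select_candidates(sm, sp, ann)
        expected = {}
        for name, (cluster, _) in plan.items():
            expected.setdefault(cluster, set()).add(name)
        assert {k: set(v) for k, v in result.clusters.items()} == expected
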