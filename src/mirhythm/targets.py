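"""Candidate selection and target/pathway set algebra per acrophase cluster.

The selection workflow keeps a mature miRNA as a candidate when it (1) is
rhythmic with mean expression strictly above the upper quartile of all
mature features, and (2) has at least one linked precursor that is itself
rhythmic with mean expression above the median of all precursors.
Candidates are grouped by the acrophase cluster of the mature arm; target
genes are unioned per cluster from a validated-interaction table, Venn
regions are computed by exact set algebra, and pathways are retained per
cluster when at least ``min_genes`` of the cluster's genes map to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .io import normalize_mirna_id

__all__ = [
    "CandidateSet",
    "select_candidates",
    "map_targets",
    "venn",
    "d_vs_l_sets",
    "pathway_sets",
]


@dataclass
class CandidateSet:
    """Per-cluster candidate miRNAs with their evidence trail.

    ``clusters`` maps cluster label -> ordered candidate ids; ``evidence``
    holds one row per candidate (mature p / quartile band, the supporting
    precursor and its p / median status); ``excluded`` lists ids that met
    the mature criterion but had no precursor link in the annotation.
    """

    clusters: dict[str, list[str]] = field(default_factory=dict)
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded: list[str] = field(default_factory=list)

    def all_candidates(self) -> list[str]:
        return [m for members in self.clusters.values() for m in members]


def select_candidates(
    screen_mature: pd.DataFrame,
    screen_pre: pd.DataFrame,
    annotation: pd.DataFrame,
) -> CandidateSet:
    """Apply both inclusion criteria and sort candidates into clusters.

    A mature feature with several precursors qualifies if *any* linked
    precursor passes criterion 2 (rhythmic, mean above the precursor
    median) — an assumption, since the selection rule for multi-precursor
    miRNAs is underdetermined.
    """
    pre_median = screen_pre["mean_expr"].median()
    pre_rows = screen_pre.set_index("feature_id")
    links = annotation.groupby("mature_id")["precursor_id"].agg(list)

    result = CandidateSet()
    records = []
    top = screen_mature[
        screen_mature["rhythmic"] & (screen_mature["quartile_band"] == "75-100")
    ]
    for _, row in top.iterrows():
        mid = row["feature_id"]
        if mid not in links.index:
            result.excluded.append(mid)
            continue
        support = None
        for pre_id in links.loc[mid]:
            if pre_id not in pre_rows.index:
                continue
            prow = pre_rows.loc[pre_id]
            if bool(prow["rhythmic"]) and prow["mean_expr"] > pre_median:
                support = (pre_id, float(prow["p"]), float(prow["mean_expr"]))
                break
        if support is None:
            continue
        cluster = row["cluster"]
        result.clusters.setdefault(cluster, []).append(mid)
        records.append(
            {
                "mirna_id": mid,
                "cluster": cluster,
                "mature_p": float(row["p"]),
                "mature_quartile": row["quartile_band"],
                "precursor_id": support[0],
                "precursor_p": support[1],
                "precursor_above_median": True,
            }
        )
    result.evidence = pd.DataFrame(records)
    return result


def map_targets(
    candidates: CandidateSet,
    targets: pd.DataFrame,
    id_map: pd.DataFrame | None = None,
    strip_species_prefix: bool = False,
) -> tuple[dict[str, set[str]], list[str]]:
    """Union of validated target genes per cluster.

    ``id_map`` is an optional two-column table (``from_id``, ``to_id``)
    mapping e.g. rat identifiers onto the human ids the target table uses.
    Candidates absent from the target table contribute an empty set and are
    returned in the unmapped list (e.g. a rat miRNA without a human
    homologue drops out here).
    """
    mapping = {}
    if id_map is not None:
        mapping = dict(zip(id_map.iloc[:, 0].astype(str), id_map.iloc[:, 1].astype(str)))
    by_mirna = targets.groupby("mirna_id")["target_gene"].agg(set)
    norm_index = {
        normalize_mirna_id(k, strip_species_prefix): k for k in by_mirna.index
    }
    gene_sets: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for cluster, members in candidates.clusters.items():
        genes: set[str] = set()
        for mid in members:
            query = mapping.get(mid, mid)
            query = normalize_mirna_id(query, strip_species_prefix)
            if query in norm_index:
                genes |= by_mirna[norm_index[query]]
            else:
                unmapped.append(mid)
        gene_sets[cluster] = genes
    return gene_sets, unmapped


def venn(sets: dict[str, set]) -> dict[tuple[str, ...], dict]:
    """Exact region decomposition of 2 or 3 labeled sets.

    Returns each nontrivial region (keyed by the sorted tuple of labels
    whose sets contain the region *exclusively*) with its count and sorted
    member list.  Region counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn analysis takes 2 or 3 sets")
    labels = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], dict] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(
                *(sets[l] for l in labels if l not in combo), set()
            )
            members = inside - outside
            regions[combo] = {
                "count": len(members),
                "members": sorted(members),
            }
    assert sum(r["count"] for r in regions.values()) == len(universe)
    return regions


def d_vs_l_sets(gene_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Collapse acrophase clusters into dark-phase (D1 u D2) vs light-phase
    (L1 u L2) gene sets for the two-set phase comparison."""
    dark = gene_sets.get("D1", set()) | gene_sets.get("D2", set())
    light = gene_sets.get("L1", set()) | gene_sets.get("L2", set())
    return {"D": dark, "L": light}


def pathway_sets(
    cluster_gene_sets: dict[str, set[str]],
    pathways: pd.DataFrame,
    min_genes: int = 3,
) -> tuple[dict[str, set[str]], dict]:
    """Pathways influenced by >= ``min_genes`` of each cluster's genes.

    Returns the per-cluster pathway-accession sets and a coverage report
    listing, per cluster, genes with no pathway annotation.
    """
    if pathways.empty:
        raise ValueError("pathway table is empty")
    gene_to_paths = pathways.groupby("gene_symbol")["pathway_accession"].agg(set)
    out: dict[str, set[str]] = {}
    coverage: dict[str, dict] = {}
    for cluster, genes in cluster_gene_sets.items():
        hits: dict[str, int] = {}
        unannotated = []
        for g in sorted(genes):
            if g in gene_to_paths.index:
                for acc in gene_to_paths[g]:
                    hits[acc] = hits.get(acc, 0) + 1
            else:
                unannotated.append(g)
        out[cluster] = {acc for acc, n in hits.items() if n >= min_genes}
        coverage[cluster] = {
            "n_genes": len(genes),
            "n_unannotated": len(unannotated),
            "unannotated": unannotated,
        }
    return out, coverage
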