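"""Gene-cluster families: grouping flagged BGCs across genomes.

Flagged regions are grouped into families by a weighted similarity over gene
content (Jaccard), conserved gene order (shared unordered adjacent pairs) and
sequence identity of matched genes, then refined so that every family is
homogeneous in core-enzyme signature and hook, and finally filtered to
families spanning at least two genera (single-genus families are likely
lineage-specific artefacts rather than conserved resistance clusters).

Cross-region gene matching uses reciprocal best local-alignment hits at >=40%
identity; unmatched genes count only in the Jaccard denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .homology import ScoringScheme, reciprocal_best_hits
from .mining import BGCRegion

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.3, 0.2, 0.5)


@dataclass(frozen=True)
class BGCPairSimilarity:
    """Similarity components between two regions, each in [0, 1]."""

    jaccard: float
    adjacency: float
    identity: float
    combined: float


@dataclass
class Family:
    family_id: str
    members: list[BGCRegion]
    core_signature: Optional[tuple[str, ...]] = None
    hook_signature: Optional[str] = None
    genera: set[str] = field(default_factory=set)
    class_counts: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def from_members(family_id: str, members: Sequence[BGCRegion]) -> "Family":
        members = sorted(members, key=lambda r: r.region_id)
        cores = {r.core_class_multiset() for r in members}
        hooks = {
            (r.best_hook().hook_id if r.best_hook() else None) for r in members
        }
        counts: dict[str, int] = {}
        for r in members:
            counts[r.taxonomic_class] = counts.get(r.taxonomic_class, 0) + 1
        return Family(
            family_id=family_id,
            members=list(members),
            core_signature=next(iter(cores)) if len(cores) == 1 else None,
            hook_signature=next(iter(hooks)) if len(hooks) == 1 else None,
            genera={r.genus for r in members},
            class_counts=counts,
        )

    def __len__(self) -> int:
        return len(self.members)


def _adjacent_pairs(region: BGCRegion) -> set[frozenset[str]]:
    ids = region.genes
    return {frozenset((a, b)) for a, b in zip(ids, ids[1:])}


def bgc_similarity(
    r1: BGCRegion,
    r2: BGCRegion,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    scheme: ScoringScheme | None = None,
    match_min_identity: float = 40.0,
) -> BGCPairSimilarity:
    """Weighted gene-content / adjacency / identity similarity of two regions.

    ``weights`` are (w_jaccard, w_adjacency, w_identity) and must sum to 1.
    Genes are matched across the regions by reciprocal best hits at
    ``match_min_identity``. Adjacency compares unordered pairs of neighbouring
    matched genes, so a region with its gene order reversed is still a perfect
    match.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights}")
    prot1 = {g.gene_id: g.protein for g in r1.gene_models}
    prot2 = {g.gene_id: g.protein for g in r2.gene_models}
    rbh = reciprocal_best_hits(
        prot1, prot2, scheme=scheme, min_identity=match_min_identity
    )
    n1, n2, nm = len(prot1), len(prot2), len(rbh)
    jaccard = nm / (n1 + n2 - nm) if (n1 + n2 - nm) else 0.0

    mapping = {a: b for a, (b, _) in rbh.items()}
    pairs1 = _adjacent_pairs(r1)
    pairs2 = _adjacent_pairs(r2)
    shared = 0
    for pair in pairs1:
        a, b = tuple(pair)
        if a in mapping and b in mapping:
            if frozenset((mapping[a], mapping[b])) in pairs2:
                shared += 1
    denom = len(pairs1) + len(pairs2) - shared
    if denom > 0:
        adjacency = shared / denom
    else:
        # both regions are single-gene: perfect when fully matched
        adjacency = 1.0 if (nm == n1 == n2) else 0.0

    identity = (
        sum(hit.percent_identity for _, hit in rbh.values()) / nm / 100.0
        if nm
        else 0.0
    )
    combined = (
        weights[0] * jaccard + weights[1] * adjacency + weights[2] * identity
    )
    return BGCPairSimilarity(jaccard, adjacency, identity, combined)


def _families_from_partition(
    member_lists: Sequence[Sequence[BGCRegion]],
) -> list[Family]:
    ordered = sorted(
        member_lists, key=lambda ms: min(r.region_id for r in ms)
    )
    return [
        Family.from_members(f"fam{i + 1:03d}", ms) for i, ms in enumerate(ordered)
    ]


def cluster_families(
    regions: Sequence[BGCRegion],
    distance_cutoff: float = 0.3,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    scheme: ScoringScheme | None = None,
) -> list[Family]:
    """Single-linkage families over pairwise distances 1 - combined.

    Two regions join the same family when connected by a chain of pairs with
    distance <= ``distance_cutoff``. Family ids are deterministic, ordered by
    each family's smallest member region id.
    """
    if not regions:
        raise ValueError("no regions to cluster")
    graph = nx.Graph()
    by_id = {r.region_id: r for r in regions}
    if len(by_id) != len(regions):
        raise ValueError("duplicate region ids")
    graph.add_nodes_from(by_id)
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sim = bgc_similarity(by_id[a], by_id[b], weights, scheme)
            if 1.0 - sim.combined <= distance_cutoff:
                graph.add_edge(a, b)
    components = [
        [by_id[rid] for rid in comp] for comp in nx.connected_components(graph)
    ]
    return _families_from_partition(components)


def refine_families(families: Sequence[Family]) -> list[Family]:
    """Split families so every family shares one core signature and one hook.

    Each input family is partitioned by the key (core-class multiset, best
    hook id); ids are re-derived deterministically. Idempotent; never merges.
    """
    parts: list[list[BGCRegion]] = []
    for fam in families:
        groups: dict[tuple, list[BGCRegion]] = {}
        for region in fam.members:
            bh = region.best_hook()
            key = (region.core_class_multiset(), bh.hook_id if bh else None)
            groups.setdefault(key, []).append(region)
        parts.extend(groups.values())
    return _families_from_partition(parts)


def drop_single_genus(families: Sequence[Family]) -> list[Family]:
    """Keep only families whose members span >= 2 distinct genera."""
    kept = [f.members for f in families if len(f.genera) >= 2]
    return _families_from_partition(kept)


def taxonomy_summary(families: Sequence[Family]):
    """Family x taxonomic-class member counts, plus global class totals.

    Returns (table, totals); table rows are family ids, columns taxonomic
    classes, both sorted; cells sum to the total number of member regions.
    """
    classes = sorted({c for f in families for c in f.class_counts})
    table = pd.DataFrame(
        [
            [f.class_counts.get(c, 0) for c in classes]
            for f in sorted(families, key=lambda f: f.family_id)
        ],
        index=[f.family_id for f in sorted(families, key=lambda f: f.family_id)],
        columns=classes,
        dtype=int,
    )
    totals = table.sum(axis=0)
    return table, totals


def family_table(families: Sequence[Family]) -> pd.DataFrame:
    """One-row-per-family summary table."""
    rows = []
    for f in sorted(families, key=lambda f: f.family_id):
        rows.append(
            {
                "family_id": f.family_id,
                "n_members": len(f),
                "core_signature": ";".join(f.core_signature or ()),
                "hook_id": f.hook_signature or "",
                "genera": ";".join(sorted(f.genera)),
                "classes": ";".join(
                    f"{c}:{n}" for c, n in sorted(f.class_counts.items())
                ),
                "members": ";".join(r.region_id for r in f.members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "n_members", "core_signature", "hook_id", "genera",
            "classes", "members",
        ],
    )


def import_external_assignments(path) -> dict[str, str]:
    """Read an externally computed family assignment (region_id TAB family).

    Adapter for parity runs against external cluster-family tools; returns a
    region_id -> family-label mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: region_id, family")
    col_r, col_f = df.columns[:2]
    return dict(zip(df[col_r], df[col_f]))


def families_from_assignments(
    regions: Sequence[BGCRegion], assignments: Mapping[str, str]
) -> list[Family]:
    """Build Family objects from an external region -> label assignment."""
    groups: dict[str, list[BGCRegion]] = {}
    for region in regions:
        label = assignments.get(region.region_id)
        if label is None:
            raise ValueError(f"no family assignment for {region.region_id}")
        groups.setdefault(label, []).append(region)
    return _families_from_partition(list(groups.values()))
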