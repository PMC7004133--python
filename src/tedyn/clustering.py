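"""Cross-species family clustering by the 80/80 rule.

Two elements are joined when their full-sequence global alignment shows
identity above 80% over more than 80% of their length (strict
inequalities); families are the connected components of the resulting
graph (single linkage).  A cluster containing elements from both genomes
("mixed") marks a family that predates the species split.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .align import AlignParams, global_align, identity_coverage


@dataclass
class ElementCluster:
    cluster_id: str
    member_ids: list[str]
    species_composition: dict[str, int]
    is_mixed: bool


def _edit_identity_estimate(a: str, b: str) -> float:
    """Cheap upper-ish identity estimate from the global edit distance."""
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def pairwise_8080_edges(
    sequences: dict[str, str],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    params: AlignParams | None = None,
    prefilter_margin: float = 0.10,
) -> list[tuple[str, str]]:
    """All element pairs passing the 80/80 rule (strict '>' on both).

    Pairs whose lengths already preclude 80% coverage are skipped, and a
    fast unit-cost edit-distance screen (edlib) drops pairs far below the
    identity threshold (a generous margin keeps borderline pairs, which
    are then decided by the full affine-gap alignment).
    """
    ids = sorted(sequences)
    missing = [i for i in ids if not sequences[i]]
    if missing:
        raise ValueError(f"empty sequences for {missing[:5]}")
    edges = []
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            la, lb = len(sequences[a]), len(sequences[b])
            if min(la, lb) <= min_coverage * max(la, lb):
                continue  # coverage unreachable: too many unaligned residues
            if _edit_identity_estimate(sequences[a], sequences[b]) < min_identity - prefilter_margin:
                continue
            aln = global_align(sequences[a], sequences[b], params)
            identity, coverage = identity_coverage(aln)
            if identity > min_identity and coverage > min_coverage:
                edges.append((a, b))
    return edges


def cluster_single_linkage(
    element_ids: list[str], edges: list[tuple[str, str]], genome_of: dict[str, str]
) -> tuple[list[ElementCluster], list[str]]:
    """Connected components of the 80/80 graph.

    Returns (clusters of size >= 2, unclustered singleton ids).  Cluster
    ids are assigned in order of each component's smallest member id, so
    the partition is independent of input order.
    """
    parent = {i: i for i in element_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        if a not in parent or b not in parent:
            raise ValueError(f"edge ({a},{b}) references unknown element")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    groups: dict[str, list[str]] = {}
    for i in element_ids:
        groups.setdefault(find(i), []).append(i)
    components = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    clusters: list[ElementCluster] = []
    unclustered: list[str] = []
    n = 0
    for comp in components:
        if len(comp) == 1:
            unclustered.append(comp[0])
            continue
        n += 1
        comp_genomes: dict[str, int] = {}
        for i in comp:
            g = genome_of[i]
            comp_genomes[g] = comp_genomes.get(g, 0) + 1
        clusters.append(
            ElementCluster(
                cluster_id=f"cluster_{n:04d}",
                member_ids=comp,
                species_composition=comp_genomes,
                is_mixed=len(comp_genomes) >= 2,
            )
        )
    return clusters, unclustered


def cluster_stats(
    clusters: list[ElementCluster],
    unclustered: list[str],
    ages_mya: dict[str, float] | None = None,
    genome_of: dict[str, str] | None = None,
) -> dict:
    """Summary in the shape the comparative analysis reports: fraction of
    elements in clusters of >= 2, number/fraction of mixed clusters,
    fraction of clustered elements that sit in mixed clusters, and
    per-cluster per-genome age medians."""
    n_clustered = sum(len(c.member_ids) for c in clusters)
    total = n_clustered + len(unclustered)
    n_mixed = sum(1 for c in clusters if c.is_mixed)
    in_mixed = sum(len(c.member_ids) for c in clusters if c.is_mixed)
    report: dict = {
        "n_elements": total,
        "n_clusters": len(clusters),
        "n_clustered_elements": n_clustered,
        "fraction_clustered": n_clustered / total if total else None,
        "n_mixed_clusters": n_mixed,
        "fraction_mixed_clusters": n_mixed / len(clusters) if clusters else None,
        "fraction_clustered_elements_in_mixed": in_mixed / n_clustered if n_clustered else None,
        "comparison_sequence": "full_element",
        "clusters": [],
    }
    for c in clusters:
        entry = {
            "cluster_id": c.cluster_id,
            "size": len(c.member_ids),
            "is_mixed": c.is_mixed,
            "species_composition": c.species_composition,
        }
        if ages_mya is not None and genome_of is not None:
            per_genome: dict[str, list[float]] = {}
            for i in c.member_ids:
                if i in ages_mya and ages_mya[i] is not None:
                    per_genome.setdefault(genome_of[i], []).append(ages_mya[i])
            entry["age_median_by_genome"] = {
                g: median(v) for g, v in per_genome.items() if v
            }
        report["clusters"].append(entry)
    return report
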