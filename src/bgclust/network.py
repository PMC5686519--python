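"""Cluster-level networks and genome-mining summary tables.

After per-class density clustering, each DBSCAN cluster becomes a node in a
class-wise similarity network: nodes carry size, known/unknown status and
aggregated compound names; an edge joins two same-class clusters when the
arithmetic mean of their cross-pair distances falls below a display
threshold.  Isolated nodes are retained — rare families that connect to
nothing are themselves a finding.  Prevalence tables count, per species
group, the strains carrying at least one member BGC of a cluster or class
(presence/absence, not multiplicity), alongside the percentage of member
BGCs flagged as horizontally acquired.  All percentages round half-up at
the table's stated precision so printed numbers are exactly reproducible
from their numerator and denominator.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog_io import KnownLabel
from .cluster import ClusterAssignment, find_singletons
from .hgt import HGTAnnotation
from .records import BGCRecord, GenomeMeta


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def cluster_distance(dist: pd.DataFrame, members_i: Sequence[str], members_j: Sequence[str]) -> float:
    """Mean of all cross-pair distances between two disjoint member sets."""
    if not members_i or not members_j:
        raise ValueError("cluster member sets must be non-empty")
    if set(members_i) & set(members_j):
        raise ValueError("cluster member sets must be disjoint")
    return float(dist.loc[list(members_i), list(members_j)].to_numpy().mean())


def build_network(
    assignments: Iterable[ClusterAssignment],
    dist: pd.DataFrame,
    known_labels: Mapping[tuple[str, int], KnownLabel] | None = None,
    edge_threshold: float = 0.75,
) -> nx.Graph:
    """One node per non-noise DBSCAN cluster; edges between same-class pairs.

    An edge is present iff the mean inter-cluster distance is <= the
    threshold; the distance is stored on the edge either way it is drawn.
    """
    known_labels = known_labels or {}
    g = nx.Graph(edge_threshold=float(edge_threshold))
    per_class: dict[str, dict[int, list[str]]] = {}
    for asg in assignments:
        cls = asg.class_label or "all"
        members = asg.cluster_members()
        per_class.setdefault(cls, {}).update(members)
        for cid, ids in sorted(members.items()):
            label = known_labels.get((cls, cid), KnownLabel(False))
            g.add_node(
                f"{cls}:{cid}",
                cluster_id=cid,
                bgc_class=cls,
                size=len(ids),
                known=label.known,
                compounds=";".join(label.compounds),
            )
    for cls, members in per_class.items():
        cids = sorted(members)
        for x in range(len(cids)):
            for y in range(x + 1, len(cids)):
                d = cluster_distance(dist, members[cids[x]], members[cids[y]])
                if d <= edge_threshold:
                    g.add_edge(f"{cls}:{cids[x]}", f"{cls}:{cids[y]}", distance=round(d, 6))
    return g


def export_graphml(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(g, str(path))
    return path


def export_sif(g: nx.Graph, sif_path: str | Path, attrs_path: str | Path) -> tuple[Path, Path]:
    """Cytoscape-compatible SIF plus a node-attribute TSV."""
    sif_path, attrs_path = Path(sif_path), Path(attrs_path)
    with open(sif_path, "w") as fh:
        connected = set()
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\trelated\t{v}\n")
            connected.update((u, v))
        for node in sorted(g.nodes):
            if node not in connected:
                fh.write(f"{node}\n")
    rows = [
        {
            "node": node,
            "bgc_class": data["bgc_class"],
            "cluster_id": data["cluster_id"],
            "size": data["size"],
            "known": data["known"],
            "compounds": data["compounds"],
        }
        for node, data in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["node", "bgc_class", "cluster_id", "size", "known", "compounds"]).to_csv(
        attrs_path, sep="\t", index=False, lineterminator="\n"
    )
    return sif_path, attrs_path


def carrier_genomes(library: Iterable[BGCRecord], membership: Mapping[str, object], key: object) -> set[str]:
    """Genomes carrying at least one BGC assigned to ``key``."""
    return {b.genome_id for b in library if membership.get(b.bgc_id) == key}


def prevalence_table(
    library: Sequence[BGCRecord],
    metadata: Sequence[GenomeMeta],
    membership: Mapping[str, object],
    hgt_annotations: Iterable[HGTAnnotation] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-(species group, key) strain prevalence and HGT percentages.

    ``membership`` maps bgc_id -> key (a class label, a cluster id, a
    compound — whatever stratum is being summarized).  A strain counts once
    per key regardless of how many member BGCs it carries.  Raises if a
    library genome has no metadata row.
    """
    meta_by_id = {m.genome_id: m for m in metadata}
    flagged = {a.bgc_id: a.flagged for a in hgt_annotations} if hgt_annotations else {}
    predicted = [b for b in library if b.source == "predicted"]
    for b in predicted:
        if b.genome_id not in meta_by_id:
            raise ValueError(f"genome {b.genome_id} has no metadata entry")

    group_sizes: dict[str, int] = {}
    for m in metadata:
        group_sizes[m.group] = group_sizes.get(m.group, 0) + 1

    keys = sorted({str(membership[b.bgc_id]) for b in predicted if b.bgc_id in membership})
    rows = []
    for group in sorted(group_sizes):
        for key in keys:
            members = [
                b
                for b in predicted
                if b.bgc_id in membership
                and str(membership[b.bgc_id]) == key
                and meta_by_id[b.genome_id].group == group
            ]
            strains = {b.genome_id for b in members}
            n_total = group_sizes[group]
            n_flagged = sum(1 for b in members if flagged.get(b.bgc_id, False))
            rows.append(
                {
                    "group": group,
                    "key": key,
                    "n_strains_with": len(strains),
                    "n_strains_total": n_total,
                    "percent": percent(len(strains), n_total, decimals),
                    "n_bgcs": len(members),
                    "percent_hgt": percent(n_flagged, len(members), decimals) if members else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "key", "n_strains_with", "n_strains_total", "percent", "n_bgcs", "percent_hgt"]
    )


def class_totals(
    library: Sequence[BGCRecord],
    assignments: Iterable[ClusterAssignment],
    known_labels: Mapping[tuple[str, int], KnownLabel] | None = None,
) -> pd.DataFrame:
    """Per-class totals, singleton counts and unknown percentages.

    A predicted BGC is *known* iff it sits in a cluster containing a
    reference record; everything else (members of unknown clusters, noise
    points, size-1 clusters) is unknown.  ``percent_unknown`` rounds
    half-up to the nearest integer.
    """
    assignments = list(assignments)
    known_labels = known_labels or {}
    singles = find_singletons(assignments)
    cluster_of: dict[str, tuple[str, int]] = {}
    for asg in assignments:
        cls = asg.class_label or "all"
        for bgc_id, lab in zip(asg.ids, asg.labels):
            if lab >= 0:
                cluster_of[bgc_id] = (cls, int(lab))

    predicted = [b for b in library if b.source == "predicted"]
    rows = []
    for cls in sorted({b.class_label for b in predicted}):
        members = [b for b in predicted if b.class_label == cls]
        n_bgcs = len(members)
        n_singletons = sum(1 for b in members if b.bgc_id in singles)
        n_unknown = 0
        for b in members:
            key = cluster_of.get(b.bgc_id)
            if key is None or not known_labels.get(key, KnownLabel(False)).known:
                n_unknown += 1
        rows.append(
            {
                "class": cls,
                "n_bgcs": n_bgcs,
                "n_singletons": n_singletons,
                "n_unknown": n_unknown,
                "percent_unknown": int(percent(n_unknown, n_bgcs, 0)) if n_bgcs else 0,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_bgcs", "n_singletons", "n_unknown", "percent_unknown"])
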