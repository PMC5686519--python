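"""Shared test helpers: record builders and independent oracles.

The oracle implementations here are deliberately naive (pure-Python sets
and loops, no shared code with the package) so they can serve as an
independent check of the vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from bgclust.records import BGCRecord, GeneRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng: np.random.Generator, length: int = 100) -> str:
    return "".join(rng.choice(AA, size=length).tolist())


def make_bgc(bgc_id: str, proteins, class_label: str = "NRPS", genome_id: str = "g1", **kw) -> BGCRecord:
    genes = []
    pos = 0
    for k, protein in enumerate(proteins):
        genes.append(GeneRecord(f"{bgc_id}_g{k + 1}", (pos, pos + 3 * len(protein)), "+", protein))
        pos += 3 * len(protein) + 50
    return BGCRecord(bgc_id, genome_id, class_label, (0, pos), genes, **kw)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    d = (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def canonical_labels(labels) -> list[int]:
    """Relabel clusters by order of first appearance; noise stays -1."""
    order: dict[int, int] = {}
    out = []
    for lab in labels:
        lab = int(lab)
        if lab < 0:
            out.append(-1)
            continue
        if lab not in order:
            order[lab] = len(order)
        out.append(order[lab])
    return out


def dbscan_oracle(D, eps: float, min_pts: int) -> list[int]:
    """Brute-force density-connectivity DBSCAN.

    Same contract as the implementation under test (neighborhood includes
    the point itself; border points join the cluster of their lowest-index
    core neighbor) but built from plain Python BFS over sets.
    """
    D = np.asarray(D)
    n = len(D)
    neighbors = [set(j for j in range(n) if D[i][j] <= eps) for i in range(n)]
    core = set(i for i in range(n) if len(neighbors[i]) >= min_pts)
    labels = [-1] * n
    cluster = 0
    assigned: set[int] = set()
    for start in range(n):
        if start not in core or start in assigned:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            c = frontier.pop()
            for j in neighbors[c]:
                if j in core and j not in comp:
                    comp.add(j)
                    frontier.append(j)
        for i in comp:
            labels[i] = cluster
            assigned.add(i)
        cluster += 1
    for i in range(n):
        if i in core:
            continue
        core_nb = sorted(j for j in neighbors[i] if j in core)
        if core_nb:
            labels[i] = labels[core_nb[0]]
    return canonical_labels(labels)


def silhouette_oracle(D, labels) -> dict[int, float]:
    """Brute-force silhouette per the textbook formula s = (b-a)/max(a,b).

    Noise (label < 0) excluded; size-1 clusters score 0.
    """
    D = np.asarray(D)
    labels = list(labels)
    clusters = sorted(set(l for l in labels if l >= 0))
    if len(clusters) < 2:
        return {}
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    out = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        own = [j for j in members[lab] if j != i]
        if not own:
            out[i] = 0.0
            continue
        a = sum(D[i][j] for j in own) / len(own)
        b = min(sum(D[i][j] for j in members[c]) / len(members[c]) for c in clusters if c != lab)
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out
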