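"""Distances, principal coordinates analysis, UPGMA trees and heatmap export.

Distances are computed on the binary methylated/unmethylated accession
profiles (simple mismatch proportion by default, Jaccard optionally).
PCoA follows the classical Gower double-centering construction; negative
eigenvalues are reported as-is rather than corrected.  UPGMA uses average
linkage with deterministic lexicographic tie-breaking and emits Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .bandmatrix_io import AccessionMeta
from .epigenotyping import EpigenotypeMatrix

__all__ = [
    "Ordination",
    "binary_distance",
    "pcoa",
    "upgma",
    "tree_to_newick",
    "cophenetic_matrix",
    "heatmap_export",
]


@dataclass
class Ordination:
    """PCoA result: coordinates on positive-eigenvalue axes, all eigenvalues."""

    coordinates: pd.DataFrame  # accessions x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def binary_distance(epi: EpigenotypeMatrix, metric: str = "mismatch") -> DistanceMatrix:
    """Pairwise distances between accession binary methylation profiles.

    ``mismatch`` is the simple-matching distance (fraction of bands whose
    0/1 methylation calls differ), which treats shared absence of
    methylation as agreement; ``jaccard`` ignores joint absences.
    """
    if len(epi.accessions) < 2:
        raise ValueError("need at least two accessions")
    x = epi.binary_methylated.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "mismatch":
                dij = float(np.mean(x[i] != x[j]))
            elif metric == "jaccard":
                union = np.sum((x[i] == 1) | (x[j] == 1))
                if union == 0:
                    warnings.warn(
                        "jaccard undefined for two all-zero profiles; using 0",
                        stacklevel=2,
                    )
                    dij = 0.0
                else:
                    inter = np.sum((x[i] == 1) & (x[j] == 1))
                    dij = float(1.0 - inter / union)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids=epi.accessions)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis (classical MDS).

    Double-centers B = -1/2 J D^2 J, eigendecomposes, and returns
    coordinates scaled by sqrt(eigenvalue) for positive eigenvalues.  All
    eigenvalues (including negative ones, which arise for non-Euclidean
    distances) are reported in descending order.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals).max()) if eigvals.size else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    columns = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=columns),
        eigenvalues=eigvals,
    )


def upgma(d: DistanceMatrix) -> dict:
    """Average-linkage (UPGMA) agglomerative tree on a distance matrix.

    Ties are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Returns a nested
    dict tree: leaves are ``{"name": str, "length": float}``; internal
    nodes are ``{"children": [...], "length": float, "height": float}``.
    The tree is ultrametric: every root-to-leaf path has equal length.
    """
    labels = list(d.ids)
    if len(labels) < 2:
        raise ValueError("need at least two leaves")
    dist = {
        frozenset((a, b)): float(d[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    # cluster key = smallest leaf label; value = (node, size, height)
    clusters: dict[str, tuple[dict, int]] = {
        lab: ({"name": lab, "height": 0.0}, 1) for lab in labels
    }
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                dd = dist[frozenset((a, b))]
                cand = (dd, a, b)
                if best is None or cand < best:
                    best = cand
        dd, a, b = best
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        height = dd / 2
        node_a["length"] = height - node_a["height"]
        node_b["length"] = height - node_b["height"]
        merged = {"children": [node_a, node_b], "height": height}
        new_key = min(a, b)
        # average-linkage update against every remaining cluster
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_key, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        clusters[new_key] = (merged, size_a + size_b)
    root, _ = clusters.popitem()[1]
    root["length"] = 0.0
    return root


def tree_to_newick(node: dict) -> str:
    """Serialize a UPGMA tree to a Newick string with branch lengths."""

    def fmt(n: dict) -> str:
        if "name" in n:
            return f"{n['name']}:{n.get('length', 0.0):g}"
        inner = ",".join(fmt(c) for c in n["children"])
        return f"({inner}):{n.get('length', 0.0):g}"

    return fmt(node).rsplit(":", 1)[0] + ";"


def cophenetic_matrix(node: dict) -> pd.DataFrame:
    """Cophenetic distances (twice the merge height) between all leaf pairs."""

    def leaves(n: dict) -> list[str]:
        if "name" in n:
            return [n["name"]]
        return [x for c in n["children"] for x in leaves(c)]

    labels = sorted(leaves(node))
    coph = pd.DataFrame(0.0, index=labels, columns=labels)

    def walk(n: dict) -> list[str]:
        if "name" in n:
            return [n["name"]]
        below = [walk(c) for c in n["children"]]
        for i, la in enumerate(below):
            for lb in below[i + 1 :]:
                for x in la:
                    for y in lb:
                        coph.loc[x, y] = coph.loc[y, x] = 2 * n["height"]
        return [x for group in below for x in group]

    walk(node)
    return coph


def heatmap_export(
    epi: EpigenotypeMatrix, meta: Iterable[AccessionMeta], path: str | Path | None = None
) -> pd.DataFrame:
    """Binary methylation codes, accessions ordered by clonal age.

    Rows are accessions annotated with clonal age (decades), columns are
    bands; cell values are the 0/1 methylation codes.  Ordering by age is
    stable: equal ages keep input order.  Written as TSV when ``path``
    is given.
    """
    age = {m.accession_id: m.clonal_age for m in meta}
    missing = [a for a in epi.accessions if a not in age]
    if missing:
        raise ValueError(f"metadata missing for accessions: {missing}")
    order = sorted(epi.accessions, key=lambda a: age[a])  # stable sort
    out = epi.binary_methylated.loc[order].copy()
    out.insert(0, "clonal_age_decades", [age[a] for a in order])
    out.index.name = "accession"
    if path is not None:
        out.to_csv(path, sep="\t")
    return out
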