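"""Clustering of alleles from a precomputed structure-distance matrix.

Two modes mirror the two matrix shapes: agglomerative (hierarchical)
clustering of a symmetric SD matrix, and nearest-neighbor assignment of
query alleles to labeled anchor alleles from a rectangular matrix. Cluster
number selection uses a medoid-based SSE (elbow curve) and the silhouette
coefficient, both computed directly from distances — no coordinate averages,
which would be unphysical for a distance-only representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .metric import (
    DistanceMatrix,
    KernelParams,
    ResidueSimilarityMatrix,
    structure_distance,
)
from .structure import CoarseStructure

__all__ = [
    "ClusterAssignment",
    "AnchorSet",
    "hierarchical_cluster",
    "nearest_neighbor_cluster",
    "sse",
    "silhouette",
    "scan_n_clusters",
    "select_closest_model",
    "LINKAGE_METHODS",
]

LINKAGE_METHODS = ("complete", "average", "single")


@dataclass
class ClusterAssignment:
    """Mapping allele -> cluster label, with optional supertype labels
    (nearest-neighbor mode attaches the anchor's subtype and supertype)."""

    labels: dict[str, str]
    supertypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not str(v) for v in self.labels.values()):
            raise ValueError("cluster labels must be non-empty")

    def members(self) -> dict[str, list[str]]:
        """Cluster label -> sorted member alleles."""
        out: dict[str, list[str]] = {}
        for allele, lab in self.labels.items():
            out.setdefault(lab, []).append(allele)
        return {k: sorted(v) for k, v in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "allele": a,
                "cluster": lab,
                "subtype": lab if self.supertypes else "",
                "supertype": self.supertypes.get(a, ""),
            }
            for a, lab in self.labels.items()
        ]
        return pd.DataFrame(rows, columns=["allele", "cluster", "subtype", "supertype"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")


@dataclass
class AnchorSet:
    """Anchor allele -> (subtype, supertype) dictionary for nearest-neighbor
    clustering. Order matters: it is the declared tie-break order."""

    anchors: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for aid, (sub, sup) in self.anchors.items():
            if not sub or not sup:
                raise ValueError(f"anchor {aid!r} must carry both subtype and supertype")

    @property
    def ids(self) -> list[str]:
        return list(self.anchors)

    def subtype(self, anchor_id: str) -> str:
        return self.anchors[anchor_id][0]

    def supertype(self, anchor_id: str) -> str:
        return self.anchors[anchor_id][1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnchorSet":
        df = pd.read_csv(path, comment="#", dtype=str)
        required = {"allele", "subtype", "supertype"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        dupes = df["allele"][df["allele"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"{path}: duplicate anchor id(s): {dupes}")
        return cls({r.allele: (r.subtype, r.supertype) for r in df.itertuples()})

    @classmethod
    def default(cls) -> "AnchorSet":
        """The shipped supertype/subtype anchor dictionary (33 class I alleles)."""
        from .config import default_anchor_table_path

        return cls.from_csv(default_anchor_table_path())


def hierarchical_cluster(
    dm: DistanceMatrix, n_clusters: int, linkage: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering on the precomputed SD matrix.

    Complete linkage is the default; average and single are exposed as
    options. The partition at any N equals cutting the full merge tree at N,
    and merge ties follow scipy's ordered-pair convention, so results are
    deterministic for a given matrix.
    """
    dm.require_symmetric()
    n = len(dm.row_labels)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    condensed = squareform(dm.values, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    flat = fcluster(tree, t=n_clusters, criterion="maxclust")
    # relabel clusters 1..N in order of first appearance for stable output
    relabel: dict[int, int] = {}
    labels = {}
    for allele, raw in zip(dm.row_labels, flat):
        relabel.setdefault(int(raw), len(relabel) + 1)
        labels[allele] = str(relabel[int(raw)])
    return ClusterAssignment(labels)


def nearest_neighbor_cluster(dm: DistanceMatrix, anchors: AnchorSet) -> ClusterAssignment:
    """Assign each query (column) the labels of its nearest anchor (row).

    Ties are broken by anchor order in the AnchorSet, with a warning.
    """
    missing = [a for a in anchors.ids if a not in dm.row_labels]
    if missing:
        raise ValueError(f"anchor(s) missing from distance matrix rows: {missing}")
    df = dm.to_dataframe().loc[anchors.ids]
    labels, supertypes = {}, {}
    for query in dm.col_labels:
        col = df[query].to_numpy()
        best = int(np.argmin(col))
        if np.count_nonzero(col == col[best]) > 1:
            warnings.warn(
                f"query {query!r}: SD tie between anchors; keeping first "
                f"({anchors.ids[best]!r}) in anchor order",
                stacklevel=2,
            )
        winner = anchors.ids[best]
        labels[query] = anchors.subtype(winner)
        supertypes[query] = anchors.supertype(winner)
    return ClusterAssignment(labels, supertypes)


def _medoid(members: list[str], df: pd.DataFrame) -> str:
    """Member minimizing total distance to the others; lexicographic tie-break."""
    members = sorted(members)
    totals = df.loc[members, members].to_numpy().sum(axis=1)
    return members[int(np.argmin(totals))]


def sse(dm: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Sum over clusters of member-to-centroid distances, the centroid being
    the medoid. Singleton clusters contribute zero."""
    dm.require_symmetric()
    missing = set(dm.row_labels) - set(assignment.labels)
    if missing:
        raise ValueError(f"allele(s) not covered by assignment: {sorted(missing)}")
    df = dm.to_dataframe()
    total = 0.0
    for members in assignment.members().values():
        medoid = _medoid(members, df)
        total += float(df.loc[members, medoid].sum())
    return total


def silhouette(dm: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Mean silhouette width over all alleles.

    a(i) is the mean within-cluster distance excluding self (0 for a
    singleton); b(i) is the smallest mean distance to another cluster;
    s(i) = (b - a) / max(a, b). Undefined for a single cluster.
    """
    dm.require_symmetric()
    clusters = assignment.members()
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    missing = set(dm.row_labels) - set(assignment.labels)
    if missing:
        raise ValueError(f"allele(s) not covered by assignment: {sorted(missing)}")
    df = dm.to_dataframe()
    scores = []
    for allele in dm.row_labels:
        own = assignment.labels[allele]
        own_members = clusters[own]
        if len(own_members) > 1:
            others = [m for m in own_members if m != allele]
            a_i = float(df.loc[allele, others].mean())
        else:
            a_i = 0.0
        b_i = min(
            float(df.loc[allele, members].mean())
            for lab, members in clusters.items()
            if lab != own
        )
        denom = max(a_i, b_i)
        scores.append(0.0 if denom == 0 else (b_i - a_i) / denom)
    return float(np.mean(scores))


def scan_n_clusters(
    dm: DistanceMatrix,
    n_min: int,
    n_max: int,
    linkage: str = "complete",
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """SSE and silhouette across consecutive cluster numbers.

    Returns one row per N with columns ``n_clusters``, ``sse``, ``silhouette``.
    When ``out_dir`` is given, writes the scan table (``cluster_scan.csv``)
    and the elbow/silhouette curves (``elbow.png``, ``silhouette.png``); the
    optimal N is read manually from the elbow or the silhouette peak.
    """
    dm.require_symmetric()
    n = len(dm.row_labels)
    if not (2 <= n_min <= n_max <= n - 1):
        raise ValueError(f"need 2 <= n_min <= n_max <= {n - 1}, got [{n_min}, {n_max}]")
    rows = []
    for n_clusters in range(n_min, n_max + 1):
        assignment = hierarchical_cluster(dm, n_clusters, linkage=linkage)
        rows.append(
            {
                "n_clusters": n_clusters,
                "sse": sse(dm, assignment),
                "silhouette": silhouette(dm, assignment),
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cluster_scan.csv", index=False, lineterminator="\n")
        _write_scan_plots(table, out_dir)
    return table


def _write_scan_plots(table: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for col, ylabel, fname in (
        ("sse", "SSE (sum of member-to-medoid SD)", "elbow.png"),
        ("silhouette", "silhouette coefficient", "silhouette.png"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(table["n_clusters"], table[col], marker="o")
        ax.set_xlabel("number of clusters N")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=150)
        plt.close(fig)


def select_closest_model(
    query: CoarseStructure,
    model_alleles: list[CoarseStructure],
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
) -> str:
    """Allele id of the model structure nearest to ``query`` in SD.

    The hook for downstream predictors that need a stand-in model for an
    allele lacking its own: each candidate model acts as its own anchor and
    the query is assigned by nearest neighbor. Ties keep list order.
    """
    if not model_alleles:
        raise ValueError("model allele list is empty")
    distances = [structure_distance(query, m, params, sim) for m in model_alleles]
    return model_alleles[int(np.argmin(distances))].allele_id
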