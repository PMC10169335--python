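"""Kernel structure similarity K and the induced structure distance SD.

Two coarse-grained binding grooves P1, P2 (superposed to a common reference)
are compared through

    K(P1, P2) = sum_i sum_j sqrt(w_i w_j) * S_ij / cosh^k(sigma * ||x_i - x_j||)

where the three factors are the geometric-mean weight of the residue pair,
their physicochemical similarity S_ij (a max-normalized flip of the Grantham
distance by default), and a spatial kernel that decays smoothly with the
Euclidean distance between the side-chain centroids. K is normalized into a
distance by

    SD(P1, P2) = sqrt(K(P1,P1) + K(P2,P2) - 2 K(P1,P2))

which is zero for identical structures, symmetric, and non-negative.

Pairwise matrix builders cache K values per unordered pair so each evaluation
happens exactly once: n(n+1)/2 evaluations for an n-allele symmetric matrix,
m + q + m*q for an m-anchor x q-query rectangular matrix.
"""

from __future__ import annotations

import itertools
import multiprocessing
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure import CoarseStructure, STANDARD_AA

__all__ = [
    "KernelParams",
    "ResidueSimilarityMatrix",
    "DistanceMatrix",
    "spatial_similarity",
    "physchem_similarity",
    "weight_outer",
    "kernel_similarity",
    "structure_distance",
    "pairwise_symmetric",
    "pairwise_anchor_query",
    "grantham_distance_matrix",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Side-chain composition, polarity and volume (Grantham 1974), per residue.
# The pairwise chemical distance is
#   D_ij = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)
# with rho fixed so the mean over the 190 pairs is 100; rounding to integers
# reproduces the published matrix (max 215 for Cys-Trp, min 5 for Leu-Ile).
_GRANTHAM_PROPERTIES = {
    "SER": (1.42, 9.2, 32.0), "ARG": (0.65, 10.5, 124.0), "LEU": (0.0, 4.9, 111.0),
    "PRO": (0.39, 8.0, 32.5), "THR": (0.71, 8.6, 61.0), "ALA": (0.0, 8.1, 31.0),
    "VAL": (0.0, 5.9, 84.0), "GLY": (0.74, 9.0, 3.0), "ILE": (0.0, 5.2, 111.0),
    "PHE": (0.0, 5.2, 132.0), "TYR": (0.20, 6.2, 136.0), "CYS": (2.75, 5.5, 55.0),
    "HIS": (0.58, 10.4, 96.0), "GLN": (0.89, 10.5, 85.0), "ASN": (1.33, 11.6, 56.0),
    "LYS": (0.33, 11.3, 119.0), "ASP": (1.38, 13.0, 54.0), "GLU": (0.92, 12.3, 83.0),
    "MET": (0.0, 5.7, 105.0), "TRP": (0.13, 5.4, 170.0),
}
_GRANTHAM_COEF = (1.833, 0.1018, 0.000399)
GRANTHAM_MAX = 215.0  # Cys-Trp, the largest entry of the published matrix

AA_ORDER = sorted(STANDARD_AA)


@dataclass(frozen=True)
class KernelParams:
    """Shape constants of the spatial kernel ``1 / cosh^k(sigma * d)``.

    ``sigma`` (1/Angstrom) sets the length scale over which spatial overlap
    decays; ``k`` sharpens the decay. Both must be positive.
    """

    sigma: float = 0.3
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.k <= 0:
            raise ValueError(f"sigma and k must be positive (got {self.sigma}, {self.k})")


def grantham_distance_matrix() -> pd.DataFrame:
    """The 20x20 Grantham chemical distance matrix, recomputed from the
    composition/polarity/volume formula and rounded to integers."""
    alpha, beta, gamma = _GRANTHAM_COEF
    props = np.array([_GRANTHAM_PROPERTIES[a] for a in AA_ORDER])
    diff = props[:, None, :] - props[None, :, :]
    raw = np.sqrt(alpha * diff[..., 0] ** 2 + beta * diff[..., 1] ** 2 + gamma * diff[..., 2] ** 2)
    iu = np.triu_indices(20, k=1)
    rho = 100.0 / raw[iu].mean()
    return pd.DataFrame(np.round(raw * rho), index=AA_ORDER, columns=AA_ORDER)


class ResidueSimilarityMatrix:
    """20x20 symmetric amino-acid similarity in [0, 1], diagonal = 1.

    The default is the max-normalized flip of the Grantham distance,
    ``S = 1 - G / max(G)``, so identical residues score 1 and the most
    chemically distant pair (Cys-Trp) scores 0.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.astype(float)
        idx = [self._canon(c) for c in table.index]
        cols = [self._canon(c) for c in table.columns]
        table.index, table.columns = idx, cols
        table = table.loc[sorted(idx), sorted(cols)]
        if list(table.index) != AA_ORDER or list(table.columns) != AA_ORDER:
            raise ValueError("similarity matrix must cover the 20 standard amino acids")
        v = table.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.isclose(np.diag(v).min(), v.max()):
            raise ValueError("diagonal must equal the maximum similarity")
        self.table = table
        self._values = v
        self._index = {aa: i for i, aa in enumerate(AA_ORDER)}

    @staticmethod
    def _canon(code: str) -> str:
        code = str(code).strip().upper()
        if len(code) == 1:
            code = ONE_TO_THREE.get(code, code)
        if code not in STANDARD_AA:
            raise ValueError(f"unknown residue code {code!r}")
        return code

    @property
    def values(self) -> np.ndarray:
        return self._values

    def encode(self, res_names: np.ndarray) -> np.ndarray:
        """Map residue names to row/column indices, erroring on unknowns."""
        try:
            return np.array([self._index[r] for r in res_names], dtype=int)
        except KeyError as exc:
            raise ValueError(f"residue name {exc.args[0]!r} not in similarity matrix") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = (self._canon(c) for c in pair)
        return float(self.table.loc[a, b])

    @classmethod
    def grantham_default(cls) -> "ResidueSimilarityMatrix":
        return cls(1.0 - grantham_distance_matrix() / GRANTHAM_MAX)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResidueSimilarityMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.8g", lineterminator="\n")


def spatial_similarity(a: CoarseStructure, b: CoarseStructure, params: KernelParams) -> np.ndarray:
    """Kernel matrix ``1 / cosh^k(sigma * ||x_i - x_j||)``, entries in (0, 1]."""
    d = cdist(a.coords, b.coords)
    return 1.0 / np.cosh(params.sigma * d) ** params.k


def physchem_similarity(
    a: CoarseStructure, b: CoarseStructure, sim: ResidueSimilarityMatrix
) -> np.ndarray:
    """Pure table lookup S[resname_a(i), resname_b(j)]."""
    ia, ib = sim.encode(a.res_names), sim.encode(b.res_names)
    return sim.values[np.ix_(ia, ib)]


def weight_outer(a: CoarseStructure, b: CoarseStructure) -> np.ndarray:
    """Geometric-mean weights: element-wise sqrt of the weight outer product."""
    return np.sqrt(np.outer(a.weights, b.weights))


def kernel_similarity(
    a: CoarseStructure,
    b: CoarseStructure,
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
) -> float:
    """K(a, b): grand sum of the element-wise product of the three factor matrices."""
    prod = spatial_similarity(a, b, params) * physchem_similarity(a, b, sim) * weight_outer(a, b)
    return float(prod.sum())


def _sd_from_k(k_aa: float, k_bb: float, k_ab: float) -> float:
    radicand = k_aa + k_bb - 2.0 * k_ab
    if radicand < 0:
        if radicand < -1e-6 * (k_aa + k_bb):
            warnings.warn(
                f"SD radicand {radicand:.3g} is negative beyond rounding noise; "
                "check that structures share a reference frame",
                RuntimeWarning,
                stacklevel=3,
            )
        radicand = 0.0
    return float(np.sqrt(radicand))


def structure_distance(
    a: CoarseStructure,
    b: CoarseStructure,
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
) -> float:
    """SD(a, b) = sqrt(K(a,a) + K(b,b) - 2 K(a,b)), clamped at 0 against rounding."""
    return _sd_from_k(
        kernel_similarity(a, a, params, sim),
        kernel_similarity(b, b, params, sim),
        kernel_similarity(a, b, params, sim),
    )


@dataclass
class DistanceMatrix:
    """Labeled SD matrix: square/symmetric (hierarchical mode) or
    rectangular anchor x query (nearest-neighbor mode)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    n_k_evaluations: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def require_symmetric(self) -> None:
        if not self.is_square:
            raise ValueError("distance matrix is not square with matching labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.8g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))

    def column_argmin(self, col: str, rows: list[str] | None = None) -> str:
        """Row label with the smallest distance in one column (first wins ties)."""
        rows = rows if rows is not None else self.row_labels
        sub = self.to_dataframe().loc[rows, col].to_numpy()
        return rows[int(np.argmin(sub))]


def _eval_one(args) -> tuple[tuple[str, str], float]:
    (ida, idb), a, b, params, sim = args
    return (ida, idb), kernel_similarity(a, b, params, sim)


def _compute_k_values(
    jobs: list[tuple[tuple[str, str], CoarseStructure, CoarseStructure]],
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
    workers: int,
) -> dict[tuple[str, str], float]:
    """Evaluate K for each listed pair exactly once, optionally in parallel.

    Each unit of work is a whole K evaluation and every cache key is written
    once, so the result is identical for any worker count.
    """
    tasks = [(key, a, b, params, sim) for key, a, b in jobs]
    if workers <= 1 or len(tasks) < 2:
        results = map(_eval_one, tasks)
    else:
        with multiprocessing.Pool(workers) as pool:
            results = pool.map(_eval_one, tasks)
    return dict(results)


def _check_unique(ids: list[str], what: str) -> None:
    seen = set()
    dupes = {i for i in ids if i in seen or seen.add(i)}
    if dupes:
        raise ValueError(f"duplicate {what} id(s): {sorted(dupes)}")


def pairwise_symmetric(
    alleles: list[CoarseStructure],
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
    workers: int = 1,
) -> DistanceMatrix:
    """Symmetric SD matrix over alleles; only the upper triangle is evaluated.

    K is computed once per unordered pair including self-pairs —
    n(n+1)/2 evaluations for n alleles — then SD entries are assembled by
    cache lookup. The diagonal is exactly zero by construction.
    """
    if len(alleles) < 2:
        raise ValueError("need at least 2 alleles")
    ids = [a.allele_id for a in alleles]
    _check_unique(ids, "allele")
    jobs = [
        ((ids[i], ids[j]), alleles[i], alleles[j])
        for i, j in itertools.combinations_with_replacement(range(len(alleles)), 2)
    ]
    kcache = _compute_k_values(jobs, params, sim, workers)
    n = len(alleles)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        sd = _sd_from_k(
            kcache[(ids[i], ids[i])], kcache[(ids[j], ids[j])], kcache[(ids[i], ids[j])]
        )
        values[i, j] = values[j, i] = sd
    return DistanceMatrix(list(ids), list(ids), values, n_k_evaluations=len(jobs))


def pairwise_anchor_query(
    anchors: list[CoarseStructure],
    queries: list[CoarseStructure],
    params: KernelParams,
    sim: ResidueSimilarityMatrix,
    workers: int = 1,
) -> DistanceMatrix:
    """Rectangular anchor x query SD matrix.

    Only self-similarities and anchor-query cross terms are evaluated —
    m + q + m*q K evaluations — never anchor-anchor or query-query pairs.
    """
    if not anchors or not queries:
        raise ValueError("anchor and query sets must be non-empty")
    anchor_ids = [a.allele_id for a in anchors]
    query_ids = [q.allele_id for q in queries]
    _check_unique(anchor_ids, "anchor")
    _check_unique(query_ids, "query")
    jobs: list[tuple[tuple[str, str], CoarseStructure, CoarseStructure]] = []
    for s in (*anchors, *queries):
        jobs.append(((s.allele_id, s.allele_id), s, s))
    for a in anchors:
        for q in queries:
            jobs.append(((a.allele_id, q.allele_id), a, q))
    kcache = _compute_k_values(jobs, params, sim, workers)
    values = np.zeros((len(anchors), len(queries)))
    for i, aid in enumerate(anchor_ids):
        for j, qid in enumerate(query_ids):
            values[i, j] = _sd_from_k(
                kcache[(aid, aid)], kcache[(qid, qid)], kcache[(aid, qid)]
            )
    return DistanceMatrix(anchor_ids, query_ids, values, n_k_evaluations=len(jobs))
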