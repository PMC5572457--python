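"""Drug-network construction and clustering.

A symmetric compound-compound distance matrix (structural, from pairwise 3D
pharmacophore similarity via D = 1 - S/3, or transcriptional, from GSEA
distances) is thresholded so that the retained edges are the fixed top
fraction (default 5%) of all pairs ranked by ascending distance. Communities
are found by affinity propagation on the negated distances; each community
carries an exemplar. Clustering the exemplars once more groups communities
into rich clubs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative square matrix over compound identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains missing values")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column identifiers differ")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def glob_to_distance(similarity: pd.DataFrame | np.ndarray, ids=None) -> DistanceMatrix:
    """Convert a pairwise 3D-similarity matrix with scores in [0, 3] to distances.

    Each pairwise score is the sum of three per-probe similarities in [0, 1]
    (shape, hydrophobic, polar), so the global score lies in [0, 3] and the
    distance is D = 1 - S/3; the diagonal is forced to zero.
    """
    if isinstance(similarity, pd.DataFrame):
        ids = tuple(str(i) for i in similarity.index)
        s = similarity.to_numpy(dtype=float)
    else:
        s = np.asarray(similarity, dtype=float)
        if ids is None:
            ids = tuple(f"c{i}" for i in range(s.shape[0]))
    if (s < 0).any() or (s > 3).any():
        raise ValueError("similarity entries must lie in [0, 3]")
    d = 1.0 - s / 3.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d)


def density_edge_count(n_nodes: int, density: float) -> int:
    """Number of edges retained at a target density: floor(density * C(n, 2))."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    return math.floor(density * (n_nodes * (n_nodes - 1) // 2))


@dataclass
class DrugNetwork:
    nodes: tuple[str, ...]
    edges: pd.DataFrame  # columns: drug_a, drug_b, distance
    density_target: float
    threshold_distance: float

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, d in self.edges.itertuples(index=False):
            g.add_edge(a, b, distance=d)
        return g


def threshold_by_density(dm: DistanceMatrix, density: float = 0.05) -> DrugNetwork:
    """Keep the top ``density`` fraction of compound pairs by ascending distance.

    k = floor(density * C(n, 2)) pairs are retained; the k-th pair's distance
    becomes the network's distance threshold. Pairs tied with the k-th
    distance are all included, so the edge count can exceed k under ties.
    """
    if dm.n < 2:
        raise ValueError("need at least two compounds")
    k = density_edge_count(dm.n, density)
    iu = np.triu_indices(dm.n, k=1)
    d = dm.values[iu]
    if k == 0:
        return DrugNetwork(dm.ids, pd.DataFrame(columns=["drug_a", "drug_b", "distance"]),
                           density, float("-inf"))
    order = np.argsort(d, kind="stable")
    threshold = float(d[order[k - 1]])
    keep = d <= threshold
    n_kept = int(keep.sum())
    if n_kept > k:
        warnings.warn(
            f"{n_kept - k} extra pairs tied at the cutoff distance {threshold:g} included"
        )
    rows = pd.DataFrame(
        {
            "drug_a": np.asarray(dm.ids)[iu[0][keep]],
            "drug_b": np.asarray(dm.ids)[iu[1][keep]],
            "distance": d[keep],
        }
    ).sort_values(["distance", "drug_a", "drug_b"], kind="stable").reset_index(drop=True)
    return DrugNetwork(dm.ids, rows, density, threshold)


def giant_component(net: DrugNetwork) -> tuple[int, int]:
    """(node count, edge count) of the largest connected component."""
    g = net.graph
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_nodes() == 0:
        return (0, 0)
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    return (sub.number_of_nodes(), sub.number_of_edges())


def affinity_propagation(
    similarity: np.ndarray,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    random_jitter: float = 1e-12,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Exemplar-based clustering by responsibility/availability message passing.

    Parameters
    ----------
    similarity : (n, n) array
        Symmetric similarities; for distance input use s = -D.
    preference : float or "median"
        Self-similarity controlling the number of exemplars; "median" uses
        the median off-diagonal similarity.
    damping : float in [0.5, 1)
        Message update damping factor.

    Returns
    -------
    labels : (n,) int array of exemplar indices per item
    exemplars : sorted unique exemplar indices
    converged : whether exemplar choices were stable for ``convergence_iter``
        consecutive iterations
    """
    s = np.array(similarity, dtype=float)
    n = s.shape[0]
    if s.shape != (n, n):
        raise ValueError("similarity must be square")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    if n == 1:
        return np.zeros(1, dtype=int), np.zeros(1, dtype=int), True

    if preference == "median":
        off = s[~np.eye(n, dtype=bool)]
        pref = float(np.median(off))
    else:
        pref = float(preference)
    np.fill_diagonal(s, pref)
    # tiny symmetric-tie-breaking noise, as in standard implementations
    rng = np.random.default_rng(seed)
    s = s + random_jitter * rng.standard_normal((n, n)) * (np.abs(s).max() + 1e-300)

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    for _ in range(max_iter):
        # responsibilities
        as_ = a + s
        first = as_.max(axis=1)
        first_k = as_.argmax(axis=1)
        as_[idx, first_k] = -np.inf
        second = as_.max(axis=1)
        r_new = s - first[:, None]
        r_new[idx, first_k] = s[idx, first_k] - second
        r = damping * r + (1 - damping) * r_new
        # availabilities
        rp = np.maximum(r, 0)
        rp[idx, idx] = r[idx, idx]
        col = rp.sum(axis=0)
        a_new = np.minimum(0, col[None, :] - rp)
        a_new[idx, idx] = col - rp[idx, idx]
        a = damping * a + (1 - damping) * a_new
        exemplars = np.flatnonzero(np.diag(a + r) > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars) and len(exemplars) > 0:
            stable += 1
            if stable >= convergence_iter:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.flatnonzero(np.diag(a + r) > 0)
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(np.diag(a + r)))])
    labels = exemplars[np.argmax(s[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    # refine: best exemplar within each cluster
    for e in exemplars:
        members = np.flatnonzero(labels == e)
        if len(members) > 1:
            sub = s[np.ix_(members, members)].sum(axis=0)
            best = members[int(np.argmax(sub))]
            labels[members] = best
    exemplars = np.unique(labels)
    if not converged:
        warnings.warn("affinity propagation did not converge; returning best labeling")
    return labels, exemplars, converged


@dataclass
class Community:
    id: int
    members: frozenset[str]
    exemplar: str
    reportable: bool = True


@dataclass
class RichClub:
    id: int
    community_ids: frozenset[int]
    exemplar_community: int


def detect_communities(
    dm: DistanceMatrix,
    min_size: int = 3,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    seed: int = 0,
) -> list[Community]:
    """Affinity-propagation communities on s = -D with exemplar labelling.

    Communities with more than ``min_size`` members are flagged reportable
    (strict inequality).
    """
    labels, exemplars, _ = affinity_propagation(
        -dm.values, preference=preference, damping=damping,
        max_iter=max_iter, convergence_iter=convergence_iter, seed=seed,
    )
    ids = np.asarray(dm.ids)
    out = []
    for cid, e in enumerate(sorted(exemplars)):
        members = frozenset(ids[labels == e])
        out.append(Community(id=cid, members=members, exemplar=str(ids[e]),
                             reportable=len(members) > min_size))
    return out


def build_rich_clubs(
    communities: list[Community],
    dm: DistanceMatrix,
    preference: float | str = "median",
    damping: float = 0.9,
    seed: int = 0,
    depth: int = 1,
) -> list[RichClub]:
    """Group communities into rich clubs by clustering their exemplars.

    One further level of affinity propagation is run on the exemplar-exemplar
    distance submatrix (``depth`` allows additional levels; each level
    re-clusters the surviving exemplars).
    """
    if not communities:
        raise ValueError("no communities to group")
    if len(communities) == 1:
        return [RichClub(id=0, community_ids=frozenset({communities[0].id}),
                         exemplar_community=communities[0].id)]
    pos = {d: i for i, d in enumerate(dm.ids)}
    comm_ids = [c.id for c in communities]
    ex_idx = np.array([pos[c.exemplar] for c in communities])
    group = {c.id: c.id for c in communities}  # community -> representative community
    reps = comm_ids[:]
    for _ in range(depth):
        if len(reps) < 2:
            break
        rep_ex = np.array([ex_idx[comm_ids.index(c)] for c in reps])
        sub = dm.values[np.ix_(rep_ex, rep_ex)]
        labels, _, _ = affinity_propagation(-sub, preference=preference,
                                            damping=damping, seed=seed)
        new_group = {reps[i]: reps[labels[i]] for i in range(len(reps))}
        group = {c: new_group[group[c]] for c in group}
        reps = sorted(set(new_group.values()))
    clubs: dict[int, list[int]] = {}
    for c, rep in group.items():
        clubs.setdefault(rep, []).append(c)
    return [
        RichClub(id=i, community_ids=frozenset(members), exemplar_community=rep)
        for i, (rep, members) in enumerate(sorted(clubs.items()))
    ]
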