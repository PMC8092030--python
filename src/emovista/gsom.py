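"""Growing self-organizing map (GSOM) and behavior-profile derivation.

The GSOM starts from a 2×2 rectangular grid and grows new boundary nodes
wherever a node's accumulated quantization error exceeds the growth
threshold

    GT = -D * ln(SF),

where D is the input dimension and SF ∈ (0,1) the user-facing spread
factor (larger SF → lower threshold → larger maps, independent of D).
Training is competitive: each input moves its best-matching node and the
grid neighbors inside the current radius toward itself by the current
learning rate; the winner accumulates squared quantization error.  When a
non-boundary node overflows, its error is distributed to its grid
neighbors instead of growing.  A growth phase is followed by a smoothing
phase (halved rate, radius 1, no growth).

Behavior profiles are then read off the trained map: nodes with enough
hits are merged along grid edges whose weight distance is below the map's
median adjacent-node distance, and each merged group of nodes becomes one
labeled profile (its label names the strongest mean feature dimensions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["GSOMConfig", "GSOMMap", "ProfileCluster", "growth_threshold",
           "train_gsom", "derive_profiles", "build_user_features"]

_DIRS = ((0, 1), (0, -1), (-1, 0), (1, 0))


def growth_threshold(D: int, SF: float) -> float:
    """Growth threshold GT = -D·ln(SF); strictly positive for SF in (0,1)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if not 0.0 < SF < 1.0:
        raise ValueError(f"spread factor must lie in (0, 1), got {SF}")
    return -D * math.log(SF)


@dataclass(frozen=True)
class GSOMConfig:
    sf: float = 0.3
    alpha0: float = 0.3
    fd: float = 0.5
    growth_epochs: int = 50
    smooth_epochs: int = 50
    neighborhood0: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sf < 1.0:
            raise ValueError("sf must lie in (0, 1)")
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in (0, 1]")
        if not 0.0 < self.fd < 1.0:
            raise ValueError("fd must lie in (0, 1)")


@dataclass
class GSOMMap:
    coords: list[tuple[int, int]]
    weights: np.ndarray  # (N, D)
    errors: np.ndarray  # (N,)
    hits: np.ndarray  # (N,) ints, BMU counts of the training inputs
    config: GSOMConfig

    def __post_init__(self) -> None:
        self.index: dict[tuple[int, int], int] = {
            c: i for i, c in enumerate(self.coords)}

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def dimension(self) -> int:
        return self.weights.shape[1]

    def bmu(self, x: np.ndarray) -> int:
        d = np.linalg.norm(self.weights - x, axis=1)
        return int(np.argmin(d))

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Best-matching node index for each row of X."""
        d = np.linalg.norm(X[:, None, :] - self.weights[None, :, :], axis=2)
        return d.argmin(axis=1)

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for i, (x, y) in enumerate(self.coords):
            for dx, dy in _DIRS:
                j = self.index.get((x + dx, y + dy))
                if j is not None and j > i:
                    pairs.append((i, j))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coords": [list(c) for c in self.coords],
            "weights": self.weights.tolist(),
            "errors": self.errors.tolist(),
            "hits": self.hits.tolist(),
            "config": self.config.__dict__,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GSOMMap":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            coords=[tuple(c) for c in d["coords"]],
            weights=np.array(d["weights"]),
            errors=np.array(d["errors"]),
            hits=np.array(d["hits"], dtype=np.int64),
            config=GSOMConfig(**d["config"]),
        )


def _new_node_weights(
    coords_index: Mapping[tuple[int, int], int],
    weights: np.ndarray,
    parent: tuple[int, int],
    new: tuple[int, int],
) -> np.ndarray:
    """Initialize a grown node's weights from its neighborhood.

    Case rules: average with the consecutive neighbor beyond the new node
    when one exists; otherwise extrapolate past the parent from the node on
    the parent's far side; otherwise extrapolate from any other parent
    neighbor; otherwise fall back to the parent pulled halfway toward the
    hypercube center.  Weights are clipped to [0, 1] so the map stays in
    the normalized input range.
    """
    w_p = weights[coords_index[parent]]
    dx, dy = new[0] - parent[0], new[1] - parent[1]
    beyond = (new[0] + dx, new[1] + dy)
    opposite = (parent[0] - dx, parent[1] - dy)
    if beyond in coords_index:
        w = 0.5 * (w_p + weights[coords_index[beyond]])
    elif opposite in coords_index:
        w = 2.0 * w_p - weights[coords_index[opposite]]
    else:
        for ox, oy in _DIRS:
            other = (parent[0] + ox, parent[1] + oy)
            if other != new and other in coords_index:
                w = 2.0 * w_p - weights[coords_index[other]]
                break
        else:
            w = 0.5 * (w_p + 0.5)
    return np.clip(w, 0.0, 1.0)


def train_gsom(X: np.ndarray | Sequence[Sequence[float]],
               config: GSOMConfig = GSOMConfig()) -> GSOMMap:
    """Train a GSOM on row vectors X (expected in [0,1]^D).

    Deterministic under a fixed config seed and fixed input order.  Node
    count never decreases and never falls below the initial 4.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a non-empty 2-D array")
    D = X.shape[1]
    GT = growth_threshold(D, config.sf)
    rng = np.random.default_rng(config.seed)

    coords: list[tuple[int, int]] = [(0, 0), (0, 1), (1, 0), (1, 1)]
    index = {c: i for i, c in enumerate(coords)}
    weights = rng.random((4, D))
    errors = np.zeros(4)

    def neighborhood(i: int, radius: int) -> tuple[np.ndarray, np.ndarray]:
        """Nodes within Chebyshev grid distance *radius* of node *i* and
        their Gaussian kernel values (winner 1, decaying with distance —
        the falloff keeps distinct map regions from contracting onto the
        global mean)."""
        cx, cy = coords[i]
        arr = np.array(coords)
        cheb = np.maximum(np.abs(arr[:, 0] - cx), np.abs(arr[:, 1] - cy))
        nb = np.nonzero(cheb <= radius)[0]
        sigma = max(radius / 2.0, 0.5)
        h = np.exp(-(cheb[nb] ** 2) / (2.0 * sigma * sigma))
        return nb, h

    total_epochs = config.growth_epochs + config.smooth_epochs
    lr = config.alpha0
    for epoch in range(total_epochs):
        growing = epoch < config.growth_epochs
        if growing:
            lr = config.alpha0 * (0.95 ** epoch)
            frac = 1.0 - epoch / max(config.growth_epochs, 1)
            radius = max(1, int(round(config.neighborhood0 * frac)))
        else:
            lr = 0.5 * config.alpha0 * (0.95 ** config.growth_epochs)
            radius = 1
        for x in X:
            d2 = np.einsum("nd,nd->n", weights - x, weights - x)
            winner = int(np.argmin(d2))
            nb, h = neighborhood(winner, radius)
            weights[nb] += (lr * h)[:, None] * (x - weights[nb])
            if not growing:
                continue
            errors[winner] += d2[winner]
            if errors[winner] <= GT:
                continue
            wx, wy = coords[winner]
            free = [(wx + ddx, wy + ddy) for ddx, ddy in _DIRS
                    if (wx + ddx, wy + ddy) not in index]
            if free:  # boundary node: grow into every free position
                for pos in free:
                    w_new = _new_node_weights(index, weights, (wx, wy), pos)
                    index[pos] = len(coords)
                    coords.append(pos)
                    weights = np.vstack([weights, w_new])
                    errors = np.append(errors, 0.0)
                errors[winner] = GT / 2.0
            else:  # interior node: distribute error to neighbors
                errors[winner] = GT / 2.0
                for ddx, ddy in _DIRS:
                    j = index.get((wx + ddx, wy + ddy))
                    if j is not None:
                        errors[j] += config.fd * errors[j]

    gmap = GSOMMap(coords=coords, weights=weights, errors=errors,
                   hits=np.zeros(len(coords), dtype=np.int64), config=config)
    assigned = gmap.assign(X)
    gmap.hits = np.bincount(assigned, minlength=len(coords)).astype(np.int64)
    return gmap


def _ridge_cutoff(dists: np.ndarray, separation: float = 3.0) -> float:
    """Edge-distance threshold separating within-region lattice edges from
    ridge edges between input regions.

    A two-means split of the adjacent-node weight distances picks the
    boundary; it is only applied when the two groups are well separated
    (mean ratio above *separation*), otherwise the map is treated as one
    region and nothing is cut.  Self-calibrating: no absolute distance
    scale is assumed.
    """
    if len(dists) < 2:
        return math.inf
    lo, hi = float(dists.min()), float(dists.max())
    if hi <= 0:
        return math.inf
    t = 0.5 * (lo + hi)
    for _ in range(64):
        below, above = dists[dists <= t], dists[dists > t]
        if len(below) == 0 or len(above) == 0:
            return math.inf
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    below, above = dists[dists <= t], dists[dists > t]
    if len(above) == 0 or below.mean() <= 0 or \
            above.mean() / max(below.mean(), 1e-12) < separation:
        return math.inf
    return float(t)


@dataclass
class ProfileCluster:
    profile_id: int
    node_coords: list[tuple[int, int]]
    member_ids: list[int]  # row indices into the training data
    mean_vector: np.ndarray
    label: str


def derive_profiles(
    gmap: GSOMMap,
    X: np.ndarray | Sequence[Sequence[float]],
    min_hits: int = 1,
    m: int = 3,
    feature_names: Sequence[str] | None = None,
) -> list[ProfileCluster]:
    """Group hit nodes into labeled behavior profiles.

    Nodes with at least *min_hits* best-matching inputs are merged along
    grid edges whose weight distance is below the median distance over all
    adjacent node pairs of the map; each connected group becomes one
    profile.  Profiles are labeled by their top-*m* mean feature
    dimensions and ordered by descending membership.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != gmap.dimension:
        raise ValueError("feature dimension does not match the map")
    assigned = gmap.assign(X)
    hits = np.bincount(assigned, minlength=gmap.n_nodes)
    qualified = set(np.nonzero(hits >= min_hits)[0])
    if not qualified:
        raise ValueError(f"no node reaches min_hits={min_hits}")

    pairs = gmap.adjacent_pairs()
    cutoff = _ridge_cutoff(
        np.array([np.linalg.norm(gmap.weights[i] - gmap.weights[j])
                  for i, j in pairs]) if pairs else np.empty(0))

    # Union-find over the whole lattice: merging may pass through low-hit
    # nodes, since a dense input region is typically surrounded by
    # interpolating nodes that win few inputs themselves.  Edges crossing a
    # ridge (adjacent weight distance >= the map median) stay cut, which is
    # what separates distinct input regions.
    parent = {i: i for i in range(gmap.n_nodes)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        if np.linalg.norm(gmap.weights[i] - gmap.weights[j]) < cutoff:
            parent[find(i)] = find(j)

    # A component qualifies through its min_hits nodes; it then absorbs
    # every hit node of the component so members always map to a cluster
    # node.
    groups: dict[int, list[int]] = {}
    for i in range(gmap.n_nodes):
        if hits[i] >= 1:
            groups.setdefault(find(i), []).append(i)
    groups = {root: nodes for root, nodes in groups.items()
              if any(i in qualified for i in nodes)}

    names = (list(feature_names) if feature_names is not None
             else [f"f{d}" for d in range(gmap.dimension)])
    profiles = []
    for nodes in groups.values():
        node_set = set(nodes)
        members = [int(r) for r in np.nonzero(
            np.isin(assigned, list(node_set)))[0]]
        mean_vec = X[members].mean(axis=0)
        top = np.argsort(-mean_vec, kind="stable")[:m]
        label = "+".join(names[int(t)] for t in top)
        profiles.append((len(members), nodes, members, mean_vec, label))
    profiles.sort(key=lambda p: (-p[0], sorted(p[1])[0]))
    return [
        ProfileCluster(profile_id=pid,
                       node_coords=[gmap.coords[i] for i in sorted(nodes)],
                       member_ids=members, mean_vector=mean_vec, label=label)
        for pid, (_n, nodes, members, mean_vec, label) in enumerate(profiles)
    ]


def build_user_features(
    user_ids: Sequence[str],
    topics: Sequence[str],
    emotion_scores: Sequence[Mapping[str, float]],
    topic_names: Sequence[str],
    emotion_names: Sequence[str],
) -> tuple[list[str], np.ndarray, list[str]]:
    """Per-user topic ⊕ emotion feature vectors.

    One observation per post: its author, its dominant topic label and its
    emotion score dict.  Each user's topic block is the distribution of
    their posts over *topic_names* and their emotion block the normalized
    sum of scores over *emotion_names*; each block sums to 1 (users with no
    scored emotion get a zero emotion block).  Returns (users, X, names).
    """
    t_index = {t: i for i, t in enumerate(topic_names)}
    e_index = {e: i for i, e in enumerate(emotion_names)}
    users = sorted(set(user_ids))
    u_index = {u: i for i, u in enumerate(users)}
    T, E = len(topic_names), len(emotion_names)
    X = np.zeros((len(users), T + E))
    for uid, topic, scores in zip(user_ids, topics, emotion_scores):
        row = u_index[uid]
        if topic in t_index:
            X[row, t_index[topic]] += 1.0
        for emo, s in scores.items():
            if emo in e_index and s > 0:
                X[row, T + e_index[emo]] += s
    for block in (slice(0, T), slice(T, T + E)):
        sums = X[:, block].sum(axis=1, keepdims=True)
        np.divide(X[:, block], sums, out=X[:, block], where=sums > 0)
    names = [f"topic:{t}" for t in topic_names] + \
        [f"emotion:{e}" for e in emotion_names]
    return users, X, names
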