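"""Seven-dimensional feature mapping for an interacting protein pair.

For an edge {P_i, P_j} with weight w_ij, neighbours are the vertices adjacent
to P_i or P_j other than the pair itself, and the focal edge is excluded from
every neighbourhood statistic:

* F1  weight w_ij of the pair's own interaction
* F2  maximum neighbouring edge weight (heterodimers should have weak
      neighbourhoods, so small F2 favours the positive class)
* F3  minimum neighbouring edge weight
* F4  max over common neighbours k of min(w_ik, w_jk) — a strong common
      partner suggests a larger complex
* F5  max over common neighbours k of |w_ik - w_jk| (default reading;
      alternatives available via ``f5_mode``)
* F6  max of the two proteins' domain counts (with multiplicity)
* F7  min of the two proteins' domain counts

F2-F5 default to 0 when no qualifying neighbour exists: zero is the
"no competing interaction" limit. An unannotated protein counts 0 domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .containers import DomainAnnotation, WeightedPPINetwork
from .dataset import ProteinPair

FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")

#: Feature subsets explored in the experiments; values are 0-based columns.
FEATURE_SETS: dict[str, tuple[int, ...]] = {
    "F1-5": (0, 1, 2, 3, 4),
    "F1-6": (0, 1, 2, 3, 4, 5),
    "F1-5,7": (0, 1, 2, 3, 4, 6),
    "F1-7": (0, 1, 2, 3, 4, 5, 6),
}

F5_MODES = ("common_abs_diff", "range", "inside_minus_min")


class FeatureVector(NamedTuple):
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: int
    f7: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class NeighborhoodView:
    """Edge weights around a focal pair, excluding the focal edge itself.

    ``neighbor_edge_weights`` collects w_xk for x in {i, j} and k outside the
    pair; ``common_neighbors`` maps each shared neighbour k to (w_ik, w_jk).
    """

    neighbor_edge_weights: tuple[float, ...]
    common_neighbors: dict[str, tuple[float, float]]


def neighborhood(network: WeightedPPINetwork, pair: ProteinPair) -> NeighborhoodView:
    """Collect the neighbouring edge weights of an interacting pair."""
    i, j = pair.a, pair.b
    if not network.has_edge(i, j):
        raise ValueError(f"pair {pair} is not an edge of the network")
    focal = {i, j}
    weights: list[float] = []
    for x in (i, j):
        for k in network.neighbors(x):
            if k not in focal:
                weights.append(network.weight(x, k))
    common = {}
    for k in sorted((network.neighbors(i) & network.neighbors(j)) - focal):
        common[k] = (network.weight(i, k), network.weight(j, k))
    return NeighborhoodView(tuple(weights), common)


def compute_features(
    network: WeightedPPINetwork,
    domains: DomainAnnotation,
    pair: ProteinPair,
    f5_mode: str = "common_abs_diff",
) -> FeatureVector:
    """Evaluate F1-F7 for one interacting pair; symmetric in the two proteins."""
    if f5_mode not in F5_MODES:
        raise ValueError(f"unknown f5_mode {f5_mode!r}; expected one of {F5_MODES}")
    i, j = pair.a, pair.b
    view = neighborhood(network, pair)
    f1 = network.weight(i, j)
    nw = view.neighbor_edge_weights
    f2 = max(nw) if nw else 0.0
    f3 = min(nw) if nw else 0.0
    common = view.common_neighbors.values()
    f4 = max((min(wik, wjk) for wik, wjk in common), default=0.0)
    if f5_mode == "common_abs_diff":
        f5 = max((abs(wik - wjk) for wik, wjk in common), default=0.0)
    elif f5_mode == "range":
        f5 = f2 - f3
    else:  # inside_minus_min
        f5 = f1 - f3 if nw else 0.0
    f6 = max(domains.n_domains(i), domains.n_domains(j))
    f7 = min(domains.n_domains(i), domains.n_domains(j))
    return FeatureVector(f1, f2, f3, f4, f5, f6, f7)


def feature_matrix(
    network: WeightedPPINetwork,
    domains: DomainAnnotation,
    pairs: list[ProteinPair],
    f5_mode: str = "common_abs_diff",
) -> np.ndarray:
    """Stack the feature vectors of many pairs into an (n, 7) array."""
    if not pairs:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([
        compute_features(network, domains, pair, f5_mode).as_array() for pair in pairs
    ])


def resolve_feature_set(feature_set: str | tuple[int, ...] | list[int] | None) -> tuple[int, ...]:
    """Map a feature-set name (e.g. ``"F1-5,7"``) or explicit column tuple to
    0-based column indices."""
    if feature_set is None:
        return FEATURE_SETS["F1-7"]
    if isinstance(feature_set, str):
        try:
            return FEATURE_SETS[feature_set]
        except KeyError as exc:
            raise ValueError(
                f"unknown feature set {feature_set!r}; expected one of {sorted(FEATURE_SETS)}"
            ) from exc
    cols = tuple(int(c) for c in feature_set)
    if any(c < 0 or c >= len(FEATURE_NAMES) for c in cols):
        raise ValueError(f"feature columns out of range: {cols}")
    return cols


def scale_features(
    train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, MinMaxScaler]:
    """Per-feature min-max scaling to [0, 1], fit on the training rows only.

    Applied values outside the training range are not clipped; a constant
    training column maps to 0 everywhere.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.size == 0:
        raise ValueError("train_matrix must be non-empty")
    scaler = MinMaxScaler(clip=False)
    train_scaled = scaler.fit_transform(train_matrix)
    # a constant column has data_range 0; force its output to exactly 0
    constant = scaler.data_range_ == 0
    if constant.any():
        train_scaled[:, constant] = 0.0
    applied = None
    if apply_matrix is not None:
        apply_matrix = np.asarray(apply_matrix, dtype=float)
        applied = scaler.transform(apply_matrix)
        if constant.any():
            applied[:, constant] = 0.0
    return train_scaled, applied, scaler
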