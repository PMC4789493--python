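"""Directed weighted hypothesis graphs and closed-test weight derivation.

A graphical multiple testing procedure is specified by ``m`` node weights
(the initial allocation of the familywise error level across hypotheses) and
an ``m x m`` matrix of transition weights (the fraction of a rejected
hypothesis' level that is propagated along each outgoing edge).  Removing a
node reallocates its weight along its outgoing edges and rewires the
remaining edges; applying the removal to every index outside a subset ``J``
yields the weighted-Bonferroni weights ``w_J`` of the intersection hypothesis
``H_J``.  The resulting weights are independent of the removal order, so the
full table over all ``2^m - 1`` nonempty subsets is well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: tolerance for the simplex constraints (weights / row sums <= 1, >= 0)
TOL = 1e-9
#: weights smaller than this are snapped to exact zero
SNAP = 1e-12

#: hard cap on the number of hypotheses for full subset enumeration
MAX_HYPOTHESES = 16


class GraphValidationError(ValueError):
    """A hypothesis graph violated one of its defining constraints."""


@dataclass(frozen=True)
class HypothesisGraph:
    """A validated weighted directed graph over ``m`` elementary hypotheses.

    Attributes
    ----------
    names
        Unique hypothesis labels, in testing order.
    weights
        Node weights ``w_i >= 0`` with ``sum(w) <= 1`` (fractions of alpha).
    transitions
        Edge weight matrix ``g_ij >= 0`` with zero diagonal and row sums
        at most 1.
    """

    names: tuple[str, ...]
    weights: np.ndarray
    transitions: np.ndarray

    @property
    def m(self) -> int:
        return len(self.names)

    def __post_init__(self) -> None:
        self.weights.setflags(write=False)
        self.transitions.setflags(write=False)


def validate_graph(
    weights: Iterable[float],
    transitions: Iterable[Iterable[float]],
    names: Iterable[str] | None = None,
) -> HypothesisGraph:
    """Check graph invariants and return a :class:`HypothesisGraph`.

    Values within :data:`TOL` of a bound are clamped to the bound; genuine
    violations raise :class:`GraphValidationError` naming the constraint.
    """
    w = np.asarray(list(weights), dtype=float)
    G = np.asarray([list(row) for row in transitions], dtype=float)
    m = w.shape[0]
    if m < 1:
        raise GraphValidationError("graph needs at least one hypothesis")
    if m > MAX_HYPOTHESES:
        raise GraphValidationError(
            f"m={m} exceeds the subset-enumeration limit of {MAX_HYPOTHESES}"
        )
    if G.shape != (m, m):
        raise GraphValidationError(
            f"transition matrix shape {G.shape} does not match {m} node weights"
        )
    if names is None:
        names = tuple(f"H{i + 1}" for i in range(m))
    else:
        names = tuple(str(n) for n in names)
        if len(names) != m:
            raise GraphValidationError("number of names does not match m")
        if len(set(names)) != m:
            raise GraphValidationError("hypothesis names must be unique")

    if np.any(w < -TOL):
        raise GraphValidationError("negative node weight")
    if np.any(G < -TOL):
        raise GraphValidationError("negative edge weight")
    if np.any(np.abs(np.diag(G)) > TOL):
        raise GraphValidationError("nonzero diagonal in transition matrix")
    if w.sum() > 1.0 + TOL:
        raise GraphValidationError(f"node weights sum to {w.sum():.6g} > 1")
    rowsums = G.sum(axis=1)
    if np.any(rowsums > 1.0 + TOL):
        bad = int(np.argmax(rowsums))
        raise GraphValidationError(
            f"row {bad} of transition matrix sums to {rowsums[bad]:.6g} > 1"
        )

    w = np.clip(w, 0.0, None)
    G = np.clip(G, 0.0, None)
    np.fill_diagonal(G, 0.0)
    if w.sum() > 1.0:
        w = w / w.sum()
    scale = np.maximum(rowsums, 1.0)
    G = G / scale[:, None]
    return HypothesisGraph(names=names, weights=w, transitions=G)


def remove_node(
    w: np.ndarray, G: np.ndarray, ell: int, active: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove node ``ell``, reallocating its weight along its edges.

    Arrays stay full-size ``m``; ``active`` is a boolean mask of the current
    index set.  For remaining ``j``: ``w_j += w_ell * g_ell,j`` and
    ``g'_jk = (g_jk + g_j,ell * g_ell,k) / (1 - g_j,ell * g_ell,j)`` with the
    convention that the updated edge is zero when the denominator vanishes
    (a two-cycle of total weight one).
    """
    if not active[ell]:
        raise ValueError(f"node {ell} is not in the current index set")
    if active.sum() < 2:
        raise ValueError("cannot remove a node from a singleton graph")
    w = w.copy()
    G = G.copy()
    keep = active.copy()
    keep[ell] = False

    w[keep] = w[keep] + w[ell] * G[ell, keep]
    w[ell] = 0.0

    g_to_ell = G[:, ell].copy()
    g_from_ell = G[ell, :].copy()
    num = G + g_to_ell[:, None] * g_from_ell[None, :]
    den = 1.0 - g_to_ell * g_from_ell
    newG = np.zeros_like(G)
    idx = np.where(keep)[0]
    for j in idx:
        if den[j] <= SNAP:
            continue
        newG[j, idx] = num[j, idx] / den[j]
    np.fill_diagonal(newG, 0.0)
    newG[ell, :] = 0.0
    newG[:, ell] = 0.0
    w[np.abs(w) < SNAP] = 0.0
    newG[np.abs(newG) < SNAP] = 0.0
    return w, newG, keep


@dataclass(frozen=True)
class SubsetWeights:
    """Weighted-Bonferroni weights ``w_J`` for every nonempty ``J`` of ``I``.

    Subsets are keyed by bitmask over positions ``0..m-1`` (bit ``i`` set
    means hypothesis ``i`` is in ``J``).  Each value is a full-length-``m``
    vector with ``w_{i,J} = 0`` for ``i`` outside ``J``.
    """

    names: tuple[str, ...]
    table: Mapping[int, np.ndarray] = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.names)

    def subsets(self) -> list[int]:
        return sorted(self.table)

    def weights(self, subset: int | Iterable[int]) -> np.ndarray:
        """Weight vector for a subset given as a bitmask or index iterable."""
        return self.table[as_bitmask(subset, self.m)]

    def to_frame(self) -> pd.DataFrame:
        """One row per subset (largest first), Table-style layout."""
        rows = sorted(self.table, key=lambda s: (-bin(s).count("1"), s))
        data = {
            "subset": [subset_label(s, self.m) for s in rows],
            **{
                name: [self.table[s][i] if s >> i & 1 else np.nan for s in rows]
                for i, name in enumerate(self.names)
            },
        }
        return pd.DataFrame(data)


def as_bitmask(subset: int | Iterable[int], m: int) -> int:
    """Normalize a subset given as bitmask or iterable of 0-based indices."""
    if isinstance(subset, (int, np.integer)):
        mask = int(subset)
    else:
        mask = 0
        for i in subset:
            mask |= 1 << int(i)
    if mask <= 0 or mask >= 1 << m:
        raise ValueError(f"invalid subset bitmask {mask} for m={m}")
    return mask


def subset_label(mask: int, m: int) -> str:
    """Render a bitmask as e.g. ``{1,3,4}`` with 1-based indices."""
    return "{" + ",".join(str(i + 1) for i in range(m) if mask >> i & 1) + "}"


def subset_members(mask: int) -> list[int]:
    return [i for i in range(mask.bit_length()) if mask >> i & 1]


def derive_weights(graph: HypothesisGraph) -> SubsetWeights:
    """Compute ``w_J`` for all nonempty ``J`` by recursive node removal.

    For each subset the indices outside ``J`` are removed one at a time; the
    result does not depend on the removal order, so any fixed order gives
    the canonical table.  ``w_I`` equals the graph's node weights.
    """
    m = graph.m
    full = (1 << m) - 1
    table: dict[int, np.ndarray] = {}
    # peel nodes off in decreasing-subset order, reusing each parent's graph
    state: dict[int, tuple[np.ndarray, np.ndarray]] = {
        full: (graph.weights.copy(), graph.transitions.copy())
    }
    active_of = lambda mask: np.array([bool(mask >> i & 1) for i in range(m)])
    for mask in range(full, 0, -1):
        if mask not in state:
            # find a parent with one extra element (always exists: add lowest missing bit)
            missing = [i for i in range(m) if not mask >> i & 1]
            parent = mask | (1 << missing[0])
            pw, pG = state[parent]
            w, G, _ = remove_node(pw, pG, missing[0], active_of(parent))
            state[mask] = (w, G)
        w = state[mask][0].copy()
        w[~active_of(mask)] = 0.0
        w[np.abs(w) < SNAP] = 0.0
        w.setflags(write=False)
        table[mask] = w
    return SubsetWeights(names=graph.names, table=table)


# ---------------------------------------------------------------------------
# JSON dialect: {"names": [...], "weights": [...], "transitions": [[...]]}

def graph_to_dict(graph: HypothesisGraph) -> dict:
    return {
        "names": list(graph.names),
        "weights": graph.weights.tolist(),
        "transitions": graph.transitions.tolist(),
    }


def graph_from_dict(d: Mapping) -> HypothesisGraph:
    return validate_graph(d["weights"], d["transitions"], d.get("names"))


def write_graph(graph: HypothesisGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(graph), fh, indent=1)
        fh.write("\n")


def read_graph(path) -> HypothesisGraph:
    with open(path) as fh:
        return graph_from_dict(json.load(fh))
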