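"""Connectome containers, directionality mixing, and graph-Laplacian construction.

The central object is a directed, weighted region-by-region adjacency matrix
``C`` whose entry ``c_ij`` is the axonal projection strength from region *i*
(rows are sources) to region *j* (columns are targets).  Pathology spread on
this graph is generated by the column-normalised Laplacian
``L = diag(columnsum(C_hat)) - C_hat`` where ``C_hat`` blends the forward and
transposed connectome according to a directionality parameter ``s``:
``s = 1`` is fully retrograde transport (pathology moves against axon
direction, i.e. along ``C`` in the Laplacian convention used here) and
``s = 0`` is fully anterograde (the transpose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "Connectome",
    "MixedConnectome",
    "LaplacianOperator",
    "ValidationReport",
    "load_connectome",
    "directional_mixture",
    "graph_laplacian",
    "validate_connectome",
]

#: relative tolerance for the column-sums-to-zero Laplacian check
COLUMN_SUM_RTOL = 1e-10


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered parcellation of brain regions.

    Parameters
    ----------
    region_ids:
        Unique, non-empty ordered region labels.
    hemisphere_pairing:
        Optional map from each region to its contralateral partner; must be an
        involution over ``region_ids`` (pairing twice returns the region).
    """

    region_ids: tuple[str, ...]
    hemisphere_pairing: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(ids) == 0:
            raise ValueError("atlas needs at least one region")
        if len(set(ids)) != len(ids):
            dupes = sorted({r for r in ids if list(ids).count(r) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")
        if self.hemisphere_pairing is not None:
            pairing = dict(self.hemisphere_pairing)
            for a, b in pairing.items():
                if a not in ids or b not in ids:
                    raise ValueError(f"pairing refers to unknown region {a!r} or {b!r}")
                if pairing.get(b) != a:
                    raise ValueError(f"hemisphere pairing is not an involution at {a!r}")
            object.__setattr__(self, "hemisphere_pairing", pairing)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, label: str) -> int:
        try:
            return self.region_ids.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in atlas") from None

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index(r) for r in labels], dtype=int)


@dataclass(frozen=True)
class Connectome:
    """Directed weighted connectome with zeroed diagonal.

    ``weights[i, j]`` is the projection strength from region *i* to region
    *j*.  Self-weights are dynamically inert (the spread equations sum over
    ``j != i``) and are zeroed on construction.  The *edge universe* used by
    percentage-based thresholding analyses is nevertheless the full ``n**2``
    entry grid, which reproduces the printed connection counts for the
    410-region (168 100) and 116-region (13 456) parcellations.
    """

    atlas: RegionAtlas
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != self.atlas.n_regions:
            raise ValueError(
                f"weights dimension {w.shape[0]} != atlas size {self.atlas.n_regions}"
            )
        if not np.all(np.isfinite(w)):
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValueError(f"non-finite weight at {tuple(bad)}")
        if np.any(w < 0):
            bad = np.argwhere(w < 0)[0]
            labels = (self.atlas.region_ids[bad[0]], self.atlas.region_ids[bad[1]])
            raise ValueError(f"negative weight at {labels}")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.atlas.n_regions

    @property
    def edge_universe_size(self) -> int:
        return self.n_regions**2

    def transpose(self) -> "Connectome":
        return Connectome(self.atlas, self.weights.T)

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return Connectome(self.atlas, weights)


@dataclass(frozen=True)
class MixedConnectome:
    """Directionality-blended connectome ``C_hat = (1 - s) C' + s C``."""

    source: Connectome
    s: float
    mixed_weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"directionality s must lie in [0, 1], got {self.s}")
        c = self.source.weights
        mixed = (1.0 - self.s) * c.T + self.s * c
        mixed.setflags(write=False)
        object.__setattr__(self, "mixed_weights", mixed)


@dataclass(frozen=True)
class LaplacianOperator:
    """Graph Laplacian ``L = diag(columnsum(C_hat)) - C_hat``.

    Columns sum to zero, so the pure-spread dynamics conserve total pathology;
    off-diagonal entries are non-positive (Metzler generator after negation).
    """

    matrix: np.ndarray
    s: float


def mixture_weights(weights: np.ndarray, s: float) -> np.ndarray:
    """Blend a raw weight matrix and its transpose: ``(1 - s) W' + s W``."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"directionality s must lie in [0, 1], got {s}")
    return (1.0 - s) * weights.T + s * weights


def laplacian_matrix(mixed: np.ndarray) -> np.ndarray:
    """``diag(columnsum(M)) - M`` for a mixed weight matrix ``M``."""
    return np.diag(mixed.sum(axis=0)) - mixed


def directional_mixture(connectome: Connectome, s: float) -> MixedConnectome:
    """Blend the connectome with its transpose according to directionality ``s``.

    ``s = 1`` keeps ``C`` (fully retrograde spread in the Laplacian convention
    used throughout), ``s = 0`` yields the transpose (fully anterograde), and
    intermediate values model directionally biased bidirectional transport.
    """
    return MixedConnectome(connectome, float(s))


def graph_laplacian(mixed: MixedConnectome) -> LaplacianOperator:
    """Column-sum graph Laplacian of a mixed connectome."""
    return LaplacianOperator(laplacian_matrix(mixed.mixed_weights), mixed.s)


@dataclass
class ValidationReport:
    """Report-only account of connectome irregularities."""

    negative_entries: list[tuple[str, str, float]]
    non_finite_entries: list[tuple[str, str]]
    nonzero_diagonal: list[tuple[str, float]]
    disconnected_regions: list[str]
    zero_out_strength: list[str]
    zero_in_strength: list[str]

    @property
    def ok(self) -> bool:
        return not (self.negative_entries or self.non_finite_entries)


def validate_connectome(
    connectome: Connectome | np.ndarray, atlas: RegionAtlas | None = None
) -> ValidationReport:
    """Inspect a connectome (or raw square matrix) and report irregularities.

    Never raises: negative or non-finite entries, nonzero diagonals (zeroed at
    ``Connectome`` construction), and regions with zero in- and/or
    out-strength are listed for the caller to act on.
    """
    if isinstance(connectome, Connectome):
        w = np.asarray(connectome.weights, dtype=float)
        atlas = connectome.atlas
    else:
        w = np.asarray(connectome, dtype=float)
        if atlas is None:
            atlas = RegionAtlas(tuple(f"R{i}" for i in range(w.shape[0])))
    ids = atlas.region_ids
    finite = np.isfinite(w)
    non_finite = [(ids[i], ids[j]) for i, j in np.argwhere(~finite)]
    wz = np.where(finite, w, 0.0)
    negative = [(ids[i], ids[j], float(wz[i, j])) for i, j in np.argwhere(wz < 0)]
    diag = np.diag(wz)
    nonzero_diag = [(ids[i], float(diag[i])) for i in np.flatnonzero(diag != 0)]
    off = wz.copy()
    np.fill_diagonal(off, 0.0)
    out_strength = off.sum(axis=1)
    in_strength = off.sum(axis=0)
    zero_out = [ids[i] for i in np.flatnonzero(out_strength == 0)]
    zero_in = [ids[i] for i in np.flatnonzero(in_strength == 0)]
    disconnected = sorted(set(zero_out) & set(zero_in), key=ids.index)
    return ValidationReport(
        negative_entries=negative,
        non_finite_entries=non_finite,
        nonzero_diagonal=nonzero_diag,
        disconnected_regions=disconnected,
        zero_out_strength=zero_out,
        zero_in_strength=zero_in,
    )


def _load_dense(df: pd.DataFrame, atlas: RegionAtlas | None) -> Connectome:
    labels = [str(c) for c in df.index]
    col_labels = [str(c) for c in df.columns]
    if len(labels) != len(col_labels):
        raise ValueError(
            f"dense connectome is not square: {len(labels)} rows, {len(col_labels)} columns"
        )
    if set(labels) != set(col_labels):
        raise ValueError("dense connectome row and column labels differ")
    df = df.loc[labels, labels]
    if atlas is None:
        atlas = RegionAtlas(tuple(labels))
    else:
        missing = set(atlas.region_ids) - set(labels)
        if missing:
            raise ValueError(f"regions missing from table: {sorted(missing)}")
        df = df.loc[list(atlas.region_ids), list(atlas.region_ids)]
    w = df.to_numpy(dtype=float)
    return Connectome(atlas, w)


def _load_edges(df: pd.DataFrame, atlas: RegionAtlas | None) -> Connectome:
    for col in ("source_region", "target_region", "weight"):
        if col not in df.columns:
            raise ValueError(f"edge list is missing column {col!r}")
    src = df["source_region"].astype(str)
    tgt = df["target_region"].astype(str)
    wts = df["weight"].astype(float)
    if atlas is None:
        seen: list[str] = []
        for r in pd.concat([src, tgt]):
            if r not in seen:
                seen.append(r)
        atlas = RegionAtlas(tuple(seen))
    w = np.zeros((atlas.n_regions, atlas.n_regions))
    for a, b, v in zip(src, tgt, wts):
        if a not in atlas.region_ids:
            raise ValueError(f"unknown region label {a!r} in edge list")
        if b not in atlas.region_ids:
            raise ValueError(f"unknown region label {b!r} in edge list")
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"invalid weight {v} on edge ({a}, {b})")
        w[atlas.index(a), atlas.index(b)] = v
    return Connectome(atlas, w)


def load_connectome(
    source, atlas: RegionAtlas | None = None, sep: str = "\t"
) -> Connectome:
    """Load a connectome from a dense-matrix or edge-list table.

    ``source`` may be a path or an already-parsed :class:`pandas.DataFrame`.
    Dense tables carry region labels in the first row and first column; edge
    lists have columns ``source_region``, ``target_region``, ``weight``.  Row
    and column order follow ``atlas`` when given, else file order.
    """
    if isinstance(source, pd.DataFrame):
        df = source
        if {"source_region", "target_region", "weight"} <= set(df.columns):
            return _load_edges(df, atlas)
        return _load_dense(df, atlas)
    head = pd.read_csv(source, sep=sep, nrows=0)
    if {"source_region", "target_region", "weight"} <= set(head.columns):
        return _load_edges(pd.read_csv(source, sep=sep), atlas)
    return _load_dense(pd.read_csv(source, sep=sep, index_col=0), atlas)
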