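"""Atom-based quadratic indices: local and total, non-stochastic and stochastic.

The local quadratic index of order *k* for atom *i* under atomic property
vector *x* is the quadratic form row

    Lq_k(x, i) = sum_j [M^k]_ij * x_i * x_j

where *M* is either the 0/1 heavy-atom adjacency (non-stochastic, ``ns``) or
its row-normalised counterpart (stochastic, ``ss``).  Totals aggregate the
local vector with one of six operators:

* ``N1`` — Manhattan-style sum of the locals
* ``N2`` — sum of squared locals (the printed form; a Euclidean-norm variant
  is available via ``n2_mode="euclidean_norm"``)
* ``GM`` — sign-preserving geometric mean (n-th root of the product, 0 when
  any local is 0)
* ``RA`` — range, max − min
* ``MX`` / ``MN`` — max / min

Two readings of the order *k* are supported.  ``walk_power`` (default) is the
standard quadratic-index formalism: ``M^k`` counts length-*k* walks.
``shortest_path_distance`` instead sets entry (i,j) to 1 iff the topological
distance between *i* and *j* — number of bonds on the shortest path, ignoring
bond multiplicity — equals *k*; the stochastic variant row-normalises that
indicator.  The two readings agree at k ≤ 1 and diverge beyond; both are
exposed because descriptor interpretations in the literature use the
distance language while the computation is traditionally a matrix power.

Total column names follow the field's convention ``T{ns|s}sq{k}({PROP}){AGG}``,
e.g. ``Tnsq13(VDW)N2`` — total non-stochastic quadratic index of order 13
weighted by the van der Waals volume, Euclidean (N2) operator.  The charge
property CHR is abbreviated ``CH`` inside column names.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .chem_core import (
    PROPERTY_NAMES,
    ChemError,
    MolecularGraph,
    PropertyTable,
    assign_properties,
)

MATRIX_KINDS = ("ns", "ss")
AGGREGATIONS = ("N1", "N2", "GM", "RA", "MX", "MN")

#: property code → token used inside canonical column names
PROPERTY_TOKENS = {p: ("CH" if p == "CHR" else p) for p in PROPERTY_NAMES}
_TOKEN_TO_PROPERTY = {v: k for k, v in PROPERTY_TOKENS.items()}

_NAME_RE = re.compile(r"^T(ns|ss)q(\d+)\(([A-Z]+)\)(N1|N2|GM|RA|MX|MN)$")


class DescriptorError(ValueError):
    pass


@dataclass
class QuadraticIndexConfig:
    """Which indices to compute.

    ``k_max`` defaults to 15 (orders 0..15), giving headroom over the orders
    typically selected by feature search (1–13 in published ERK models).
    """

    k_max: int = 15
    matrix_kinds: tuple[str, ...] = MATRIX_KINDS
    properties: tuple[str, ...] = PROPERTY_NAMES
    aggregations: tuple[str, ...] = AGGREGATIONS
    n2_mode: str = "sum_of_squares"  # or "euclidean_norm"
    k_semantics: str = "walk_power"  # or "shortest_path_distance"

    def __post_init__(self):
        if self.k_max < 1:
            raise DescriptorError("k_max must be >= 1")
        for kind in self.matrix_kinds:
            if kind not in MATRIX_KINDS:
                raise DescriptorError(f"unknown matrix kind {kind!r}")
        for p in self.properties:
            if p not in PROPERTY_NAMES:
                raise DescriptorError(f"unknown property {p!r}")
        for a in self.aggregations:
            if a not in AGGREGATIONS:
                raise DescriptorError(f"unknown aggregation {a!r}")
        if not (self.matrix_kinds and self.properties and self.aggregations):
            raise DescriptorError("empty selection")
        if self.n2_mode not in ("sum_of_squares", "euclidean_norm"):
            raise DescriptorError(f"unknown n2_mode {self.n2_mode!r}")
        if self.k_semantics not in ("walk_power", "shortest_path_distance"):
            raise DescriptorError(f"unknown k_semantics {self.k_semantics!r}")

    def column_names(self) -> list[str]:
        """Deterministic column order: kind, then k, then property, then aggregation."""
        return [
            descriptor_name(kind, k, prop, agg)
            for kind in self.matrix_kinds
            for k in range(self.k_max + 1)
            for prop in self.properties
            for agg in self.aggregations
        ]

    def fingerprint(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def descriptor_name(kind: str, k: int, prop: str, agg: str) -> str:
    prefix = "Tnsq" if kind == "ns" else "Tssq"
    return f"{prefix}{k}({PROPERTY_TOKENS[prop]}){agg}"


def parse_descriptor_name(name: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`descriptor_name` → (kind, k, property, aggregation)."""
    m = _NAME_RE.match(name)
    if not m:
        raise DescriptorError(f"not a canonical total-index name: {name!r}")
    kind = m.group(1)
    token = m.group(3)
    if token not in _TOKEN_TO_PROPERTY:
        raise DescriptorError(f"unknown property token {token!r} in {name!r}")
    return kind, int(m.group(2)), _TOKEN_TO_PROPERTY[token], m.group(4)


# -- structure matrices --------------------------------------------------------


def structure_matrix(
    g: MolecularGraph,
    kind: str,
    k: int,
    k_semantics: str = "walk_power",
) -> np.ndarray:
    """The graph matrix M^(k) entering the quadratic form.

    walk_power: k-th power of the (row-normalised, for ``ss``) adjacency;
    k = 0 is the identity.  shortest_path_distance: 0/1 indicator of
    topological distance exactly k (row-normalised for ``ss``; all-zero rows
    stay zero).
    """
    if k < 0:
        raise DescriptorError("order k must be >= 0")
    n = g.n_atoms
    if n == 1:
        return np.eye(1)
    A = g.adjacency_matrix()
    if kind == "ss" and k_semantics == "walk_power":
        rowsum = A.sum(axis=1, keepdims=True)
        if np.any(rowsum == 0):
            raise DescriptorError(
                f"stochastic matrix undefined: isolated atom in {g.id or 'graph'}"
            )
        A = A / rowsum
    if k_semantics == "walk_power":
        return np.linalg.matrix_power(A, k)
    # distance semantics
    dist = shortest_path(A, method="D", unweighted=True)
    M = (dist == k).astype(float)
    if kind == "ss":
        rowsum = M.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(rowsum > 0, M / np.where(rowsum == 0, 1, rowsum), 0.0)
    return M


def local_quadratic_index(
    g: MolecularGraph,
    kind: str,
    k: int,
    x: np.ndarray,
    k_semantics: str = "walk_power",
) -> np.ndarray:
    """Per-atom local quadratic indices Lq_k(x, i) = x_i * (M^k x)_i."""
    x = np.asarray(x, dtype=float)
    if x.shape != (g.n_atoms,):
        raise DescriptorError(
            f"property vector length {x.shape} does not match {g.n_atoms} atoms"
        )
    M = structure_matrix(g, kind, k, k_semantics)
    return x * (M @ x)


def total_index(locals_: np.ndarray, agg: str, n2_mode: str = "sum_of_squares") -> float:
    """Aggregate a local-index vector into a total index (never NaN)."""
    L = np.asarray(locals_, dtype=float)
    if L.size == 0:
        raise DescriptorError("empty local-index vector")
    if agg == "N1":
        return float(L.sum())
    if agg == "N2":
        ss = float((L**2).sum())
        return float(np.sqrt(ss)) if n2_mode == "euclidean_norm" else ss
    if agg == "GM":
        if np.any(L == 0):
            return 0.0
        # sign-preserving n-th root of the product, computed in log space
        sign = -1.0 if (np.sum(L < 0) % 2) else 1.0
        return float(sign * np.exp(np.mean(np.log(np.abs(L)))))
    if agg == "RA":
        return float(L.max() - L.min())
    if agg == "MX":
        return float(L.max())
    if agg == "MN":
        return float(L.min())
    raise DescriptorError(f"unknown aggregation {agg!r}")


# -- dataset-level computation -------------------------------------------------


def compute_descriptor_row(
    g: MolecularGraph,
    cfg: QuadraticIndexConfig,
    tables: Mapping[str, PropertyTable] | None = None,
    properties: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """All configured total indices for one molecule, keyed by canonical name."""
    if properties is None:
        properties = assign_properties(g, tables=tables, properties=cfg.properties)
    row: dict[str, float] = {}
    for kind in cfg.matrix_kinds:
        for k in range(cfg.k_max + 1):
            M = structure_matrix(g, kind, k, cfg.k_semantics)
            for prop in cfg.properties:
                x = properties[prop]
                L = x * (M @ x)
                for agg in cfg.aggregations:
                    row[descriptor_name(kind, k, prop, agg)] = total_index(
                        L, agg, cfg.n2_mode
                    )
    return row


def compute_named_descriptors(
    g: MolecularGraph,
    names: Sequence[str],
    tables: Mapping[str, PropertyTable] | None = None,
    n2_mode: str = "sum_of_squares",
    k_semantics: str = "walk_power",
) -> dict[str, float]:
    """Compute only the listed total indices (used when scoring a fixed model)."""
    parsed = [parse_descriptor_name(n) for n in names]
    props = sorted({p for _, _, p, _ in parsed})
    vectors = assign_properties(g, tables=tables, properties=props)
    out = {}
    for name, (kind, k, prop, agg) in zip(names, parsed):
        L = local_quadratic_index(g, kind, k, vectors[prop], k_semantics)
        out[name] = total_index(L, agg, n2_mode)
    return out


def compute_descriptor_matrix(
    dataset: Sequence[MolecularGraph],
    cfg: QuadraticIndexConfig | None = None,
    tables: Mapping[str, PropertyTable] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Compounds × named total quadratic indices.

    Row index = molecule ids (positional fallback); every cell is finite.  A
    per-molecule failure aborts with the molecule id when ``strict`` (default),
    or drops the row with a warning otherwise.
    """
    import warnings

    cfg = cfg or QuadraticIndexConfig()
    columns = cfg.column_names()
    rows, index = [], []
    for pos, g in enumerate(dataset):
        rid = g.id or f"mol{pos}"
        try:
            row = compute_descriptor_row(g, cfg, tables=tables)
            vals = [row[c] for c in columns]
            if not np.all(np.isfinite(vals)):
                raise DescriptorError("non-finite descriptor value")
        except (ChemError, DescriptorError) as exc:
            if strict:
                raise DescriptorError(f"molecule {rid!r}: {exc}") from exc
            warnings.warn(f"dropping molecule {rid!r}: {exc}")
            continue
        rows.append(vals)
        index.append(rid)
    return pd.DataFrame(rows, index=index, columns=columns)


# -- persistence ---------------------------------------------------------------


def write_descriptor_matrix(
    D: pd.DataFrame,
    path: str | Path,
    cfg: QuadraticIndexConfig | None = None,
    table_versions: Mapping[str, str] | None = None,
) -> None:
    """CSV plus a JSON sidecar recording the computation provenance."""
    path = Path(path)
    D.to_csv(path, index_label="id")
    sidecar = {
        "config": cfg.__dict__ if cfg else None,
        "config_fingerprint": cfg.fingerprint() if cfg else None,
        "table_versions": dict(table_versions or {}),
        "n_rows": int(D.shape[0]),
        "n_columns": int(D.shape[1]),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, default=list))


def read_descriptor_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
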