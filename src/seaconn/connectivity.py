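"""Connectivity-matrix algebra.

A single-generation connectivity matrix holds source→destination dispersal
probabilities estimated from particle tracking (rows sum to at most 1; the
deficit is advective loss through the open boundary).  Multigenerational
stepping-stone connectivity accumulates dispersal along all routes across
generations as the sum of matrix powers; because the accumulated sum can
exceed 1 it is also provided elementwise-capped at 1, the form used
downstream as a "probability of reaching j within G generations".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

LOG_OFFSET = 1e-50  # offset inside log10 so zero connectivity maps to -50


@dataclass
class ConnectivityMatrix:
    """Square nonnegative dispersal-probability matrix with provenance.

    ``node_ids`` label rows/columns (habitat cell ids or site ids);
    ``generations`` is 1 for a raw dispersal matrix, G for a multigeneration
    accumulation; ``capped`` records whether entries were capped at 1;
    ``symmetrization`` records the mode if symmetrized.
    """

    values: np.ndarray
    node_ids: list
    generations: int = 1
    capped: bool = False
    symmetrization: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.values.shape}")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match matrix size")
        transformed = bool(self.meta.get("transform"))
        if not transformed and np.any(self.values < 0):
            raise ValueError("connectivity entries must be nonnegative")
        if (self.generations == 1 and not self.capped
                and self.symmetrization is None and not transformed):
            rowsum = self.values.sum(axis=1)
            if np.any(rowsum > 1 + 1e-9):
                raise ValueError("single-generation rows must sum to <= 1")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Dense CSV with node-id header row/column + JSON metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.node_ids, columns=self.node_ids)
        df.to_csv(path, index_label="node_id")
        if sidecar:
            meta = {
                "generations": self.generations,
                "capped": self.capped,
                "symmetrization": self.symmetrization,
                **{k: v for k, v in self.meta.items() if _jsonable(v)},
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, default=str)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        node_ids = [int(c) if str(c).lstrip("-").isdigit() else c for c in df.columns]
        return cls(
            values=df.to_numpy(dtype=float),
            node_ids=node_ids,
            generations=int(meta.get("generations", 1)),
            capped=bool(meta.get("capped", False)),
            symmetrization=meta.get("symmetrization"),
            meta={k: v for k, v in meta.items()
                  if k not in ("generations", "capped", "symmetrization")},
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


class MultigenResult(NamedTuple):
    """Raw and probability-capped multigeneration connectivity."""

    raw: ConnectivityMatrix
    capped: ConnectivityMatrix


def multigen(M: ConnectivityMatrix, G: int = 64) -> MultigenResult:
    """Stepping-stone connectivity accumulated over G generations.

    Computes ``S_G = sum_{g=1..G} M^g`` by iterated multiplication and
    returns both the raw sum and the elementwise cap ``min(S_G, 1)`` (capped
    is the default downstream, the sum being read as a dispersal
    probability).  ``multigen(M, 1)`` returns M itself (both forms).
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if M.generations != 1:
        raise ValueError("multigen expects a single-generation matrix")
    A = M.values
    power = A.copy()
    total = A.copy()
    for _ in range(G - 1):
        power = power @ A
        total += power
    raw = replace(M, values=total, generations=G, capped=False,
                  meta={**M.meta, "accumulation": "sum of matrix powers"})
    capped = replace(M, values=np.minimum(total, 1.0), generations=G, capped=True,
                     meta={**M.meta, "accumulation": "sum of matrix powers"})
    return MultigenResult(raw=raw, capped=capped)


_SYM_MODES = {
    "min": np.minimum,
    "max": np.maximum,
    "mean": lambda a, b: 0.5 * (a + b),
}


def symmetrize(M: ConnectivityMatrix | np.ndarray, mode: str = "mean"):
    """Symmetric matrix from directed connectivity.

    Combines entry (i, j) with (j, i) elementwise by ``min``, ``max`` or
    ``mean``; the diagonal is preserved.  Accepts and returns either a
    :class:`ConnectivityMatrix` or a bare array.
    """
    if mode not in _SYM_MODES:
        raise ValueError(f"mode must be one of {sorted(_SYM_MODES)}, got {mode!r}")
    arr = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    out = _SYM_MODES[mode](arr, arr.T)
    np.fill_diagonal(out, np.diagonal(arr))
    if isinstance(M, ConnectivityMatrix):
        return replace(M, values=out, symmetrization=mode)
    return out


def log_transform(M: ConnectivityMatrix | np.ndarray):
    """Elementwise ``log10(x + 1e-50)``; zero connectivity maps to -50."""
    arr = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log transform requires nonnegative entries")
    out = np.log10(arr + LOG_OFFSET)
    if isinstance(M, ConnectivityMatrix):
        new = replace(M, meta={**M.meta, "transform": f"log10(x + {LOG_OFFSET:g})"})
        new.values = out  # bypass nonnegativity check: log values are negative
        return new
    return out


def site_connectivity(M: ConnectivityMatrix, site_cells: dict) -> ConnectivityMatrix:
    """Aggregate a cell-level matrix to site level.

    ``site_cells`` maps each site id to the habitat cell ids representing it;
    entry (a, b) of the result is the mean of M over all (cell of a, cell of
    b) pairs, including a == b (self-recruitment block mean).
    """
    index = {node: k for k, node in enumerate(M.node_ids)}
    rows = {}
    for site, cells in site_cells.items():
        if len(cells) == 0:
            raise ValueError(f"site {site!r} has no habitat cell assigned")
        try:
            rows[site] = np.asarray([index[c] for c in cells], dtype=int)
        except KeyError as e:
            raise ValueError(f"site {site!r} references unknown node {e.args[0]!r}") from e
    sites = list(site_cells)
    out = np.empty((len(sites), len(sites)))
    for ia, a in enumerate(sites):
        for ib, b in enumerate(sites):
            out[ia, ib] = M.values[np.ix_(rows[a], rows[b])].mean()
    result = ConnectivityMatrix.__new__(ConnectivityMatrix)
    result.values = out
    result.node_ids = sites
    result.generations = M.generations
    result.capped = M.capped
    result.symmetrization = M.symmetrization
    result.meta = {**M.meta, "aggregation": "site mean"}
    return result
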