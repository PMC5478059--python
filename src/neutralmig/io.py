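"""CSV interchange for community matrices, plus deterministic test fixtures.

Everything travels as plain CSV: wide (rows = plots, columns = species,
integer cells, optional ``row``/``col`` lattice-coordinate columns) or
long (``plot,species,count``).  Metacommunities use the two-column
``rank,abundance`` format with a commented key-value header (see
``LogseriesMetacommunity.to_csv``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .logseries import LogseriesMetacommunity, build_ranked_logseries
from .simulate import (
    CommunityMatrix,
    ImplicitConfig,
    LatticeConfig,
    run_implicit,
    run_lattice,
)

__all__ = [
    "read_community_matrix",
    "write_community_matrix",
    "make_fixtures",
    "write_manifest",
]

_COORD_COLS = ("row", "col")


def read_community_matrix(path: str | Path, dialect: str = "wide") -> CommunityMatrix:
    """Read a plot x species count matrix from CSV.

    ``dialect='wide'``: first column is the plot identifier, remaining
    columns are species (plus optional ``row``/``col`` coordinates).
    ``dialect='long'``: columns ``plot,species,count``.  Species whose
    total count is zero are dropped; plot order is preserved.  Negative or
    non-integer cells raise a format error naming the offending cell.
    """
    path = Path(path)
    if dialect == "wide":
        frame = pd.read_csv(path, index_col=0)
        coords = None
        coord_cols = [c for c in _COORD_COLS if c in frame.columns]
        if coord_cols:
            coords = frame[coord_cols].astype(np.int64)
            frame = frame.drop(columns=coord_cols)
    elif dialect == "long":
        long = pd.read_csv(path)
        expected = {"plot", "species", "count"}
        if not expected.issubset(long.columns):
            raise ValueError(f"long dialect needs columns {sorted(expected)}")
        frame = (
            long.pivot_table(
                index="plot", columns="species", values="count",
                aggfunc="sum", fill_value=0, sort=False,
            )
        )
        frame = frame.loc[pd.unique(long["plot"])]  # preserve plot order
        frame = frame[sorted(frame.columns)]
        coords = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    frame.index.name = None
    frame.columns.name = None
    if coords is not None:
        coords.index.name = None
    arr = frame.to_numpy()
    bad = np.argwhere((arr != np.floor(arr)) | (arr < 0))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"non-integer or negative count at plot {frame.index[r]!r}, "
            f"species {frame.columns[c]!r}: {arr[r, c]}"
        )
    mat = CommunityMatrix(frame.astype(np.int64), coords=coords)
    n_empty = int((mat.pooled() == 0).sum())
    if n_empty:
        import warnings

        warnings.warn(f"dropping {n_empty} species with zero total count")
        mat = mat.drop_empty_species()
    return mat


def write_community_matrix(
    mat: CommunityMatrix, path: str | Path, dialect: str = "wide"
) -> None:
    """Write a community matrix as wide or long CSV (lossless round trip)."""
    path = Path(path)
    if dialect == "wide":
        frame = mat.counts
        if mat.coords is not None:
            frame = pd.concat([mat.coords, mat.counts], axis=1)
        frame.to_csv(path, index_label="plot")
    elif dialect == "long":
        long = (
            mat.counts.stack().rename("count").reset_index()
        )
        long.columns = ["plot", "species", "count"]
        long = long[long["count"] > 0]
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic tiny assets for the unit-test suite.

    Returns a metacommunity of 10,000 individuals in 50 species, a
    spatially implicit matrix (10 plots, J=100, m=.2) and a 4x4 lattice
    matrix (J=50, m_adj=m_meta=.1), all fully determined by ``seed``.
    """
    meta = build_ranked_logseries(10_000, 50)
    implicit = run_implicit(
        meta,
        ImplicitConfig(n_plots=10, J=100, m=0.2, generations=100, seed=seed),
    )
    lattice = run_lattice(
        meta,
        LatticeConfig(
            rows=4, cols=4, J=50, m_adj=0.1, m_meta=0.1,
            generations=100, seed=seed + 1,
        ),
    )
    return {"meta": meta, "implicit": implicit, "lattice": lattice}


def write_manifest(path: str | Path, config: dict, outputs: list[str | Path]) -> None:
    """Echo the resolved configuration, seed and output checksums to JSON."""
    manifest = {
        "config": {k: _jsonable(v) for k, v in config.items()},
        "outputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in outputs
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if hasattr(v, "__dict__"):
        return {k: _jsonable(x) for k, x in vars(v).items()}
    return v
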