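"""Readers and writers: long-format panel CSV, GAL / edge-list spatial weights,
adjacency-state CSV round-trip, and run-configuration snapshots.

Area labels are arbitrary strings mapped to 0-based indices by sorted order;
time labels must form a contiguous integer sequence (the temporal random walk
and adjacency assume unit spacing).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import STDataset
from .stgraph import EdgeSet, SpatialGraph, STAdjacency

__all__ = [
    "read_dataset",
    "read_graph",
    "write_gal",
    "write_edgeset",
    "read_edgeset",
    "apply_edgeset_csv",
    "write_config",
]

REQUIRED_COLUMNS = ("area", "time", "Y", "E")


def read_dataset(path) -> STDataset:
    """Read a long-format panel CSV with columns area,time,Y,E plus covariates.

    The panel must be complete (every area x time combination present exactly
    once); an intercept column is prepended to the covariates.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    covs = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not covs:
        raise ValueError("dataset must contain at least one covariate column")
    dup = df.duplicated(subset=["area", "time"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicated (area,time) rows at lines {rows}")
    areas = sorted(df["area"].astype(str).unique())
    times = sorted(int(t) for t in df["time"].unique())
    if times != list(range(times[0], times[0] + len(times))):
        raise ValueError(f"time labels must be contiguous integers, got {times}")
    K, T = len(areas), len(times)
    if len(df) != K * T:
        raise ValueError(
            f"ragged panel: {len(df)} rows but {K} areas x {T} periods = {K * T}"
        )
    bad_e = df.index[df["E"] <= 0]
    if len(bad_e):
        raise ValueError(f"non-positive E at line {int(bad_e[0]) + 2}")
    if not np.allclose(df["Y"], np.round(df["Y"])) or (df["Y"] < 0).any():
        raise ValueError("Y must contain non-negative integer counts")
    a_idx = {a: i for i, a in enumerate(areas)}
    t_idx = {t: i for i, t in enumerate(times)}
    Y = np.zeros((K, T), dtype=int)
    E = np.zeros((K, T))
    X = np.ones((K, T, len(covs) + 1))
    for _, row in df.iterrows():
        k = a_idx[str(row["area"])]
        t = t_idx[int(row["time"])]
        Y[k, t] = int(round(row["Y"]))
        E[k, t] = float(row["E"])
        for j, c in enumerate(covs):
            X[k, t, j + 1] = float(row[c])
    return STDataset(
        Y=Y,
        E=E,
        X=X,
        covariate_names=("intercept", *covs),
        area_labels=tuple(areas),
        time_labels=tuple(times),
    )


def _read_gal(path: Path) -> dict[str, list[str]]:
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    header = lines[0].split()
    n = int(header[1]) if len(header) == 4 else int(header[0])
    nbrs: dict[str, list[str]] = {}
    i = 1
    while i < len(lines):
        name, deg = lines[i].split()[0], int(lines[i].split()[1])
        if deg > 0:
            nbrs[name] = lines[i + 1].split()
            i += 2
        else:
            nbrs[name] = []
            i += 1
    if len(nbrs) != n:
        raise ValueError(f"GAL header says {n} units but {len(nbrs)} were listed")
    return nbrs


def read_graph(path, labels: tuple[str, ...] | None = None) -> SpatialGraph:
    """Read a GAL file or a two-column edge-list CSV (header area_a,area_b).

    Asymmetric entries are symmetrised with a warning.  When ``labels`` (e.g.
    from a dataset) are supplied, graph node names must match them exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".gal":
        nbrs = _read_gal(path)
        names = sorted(nbrs)
        pairs = set()
        asym = False
        for a, ns in nbrs.items():
            for b in ns:
                if a == b:
                    continue
                if a not in (nbrs.get(b) or []):
                    asym = True
                pairs.add((min(a, b), max(a, b)))
        if asym:
            warnings.warn("asymmetric GAL neighbour lists; symmetrising")
    else:
        df = pd.read_csv(path)
        if not {"area_a", "area_b"}.issubset(df.columns):
            raise ValueError("edge-list CSV must have columns area_a,area_b")
        names = sorted(
            set(df["area_a"].astype(str)) | set(df["area_b"].astype(str))
        )
        pairs = {
            (min(a, b), max(a, b))
            for a, b in zip(df["area_a"].astype(str), df["area_b"].astype(str))
            if a != b
        }
    if labels is not None:
        unknown = sorted(set(names) - set(labels))
        if unknown:
            raise ValueError(f"graph labels not present in dataset: {unknown}")
        names = list(labels)
    idx = {a: i for i, a in enumerate(names)}
    edges = tuple(sorted((idx[a], idx[b]) for a, b in pairs))
    return SpatialGraph(len(names), edges, labels=tuple(names))


def write_gal(graph: SpatialGraph, path) -> None:
    labels = graph.labels or tuple(str(i) for i in range(graph.n_areas))
    nbrs: dict[str, list[str]] = {lb: [] for lb in labels}
    for a, b in graph.edges:
        nbrs[labels[a]].append(labels[b])
        nbrs[labels[b]].append(labels[a])
    out = [str(graph.n_areas)]
    for lb in labels:
        out.append(f"{lb} {len(nbrs[lb])}")
        if nbrs[lb]:
            out.append(" ".join(sorted(nbrs[lb])))
    Path(path).write_text("\n".join(out) + "\n")


def write_edgeset(edges: EdgeSet, path) -> None:
    """Adjacency-state CSV: kind,period,area_a,area_b,w; round-trips bit-exactly."""
    rows = [
        {"kind": e[0], "period": e[1], "area_a": e[2], "area_b": e[3], "w": int(v)}
        for e, v in zip(edges.entries, edges.values)
    ]
    pd.DataFrame(rows, columns=["kind", "period", "area_a", "area_b", "w"]).to_csv(
        path, index=False
    )


def read_edgeset(path) -> EdgeSet:
    df = pd.read_csv(path)
    entries = tuple(
        (str(r.kind), int(r.period), int(r.area_a), int(r.area_b))
        for r in df.itertuples()
    )
    return EdgeSet(entries, df["w"].to_numpy(dtype=np.uint8))


def apply_edgeset_csv(adjacency: STAdjacency, path) -> None:
    adjacency.set_from_edgeset(read_edgeset(path))


def write_config(path, **kwargs) -> None:
    """Snapshot of a run configuration, sufficient to re-run bit-identically."""
    Path(path).write_text(yaml.safe_dump(kwargs, sort_keys=False))
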