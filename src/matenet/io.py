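"""File formats and configuration.

Canonical interchange is the edge-list CSV (columns ``id1,id2``); the
Pajek ``.net`` format is supported for compatibility with classic
network visualization tools (1-based vertex numbering, quoted labels).
Genotypes travel as one row per individual with two columns per locus
(blank = missing); relatedness matrices as long-format CSV; model fits
and reports as JSON with sorted keys so equal runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .csbm import CSBMFit
from .relnet import RelatednessMatrix
from .simstand import MISSING, OffspringRecord

logger = logging.getLogger("matenet.io")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- networks

def write_edgelist_csv(network: nx.Graph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(map(str, e))) for e in network.edges())
    pd.DataFrame(rows, columns=["id1", "id2"]).to_csv(path, index=False)


def read_edgelist_csv(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need two id columns")
    g = nx.Graph()
    n_dup = n_self = 0
    for _, (a, b) in df.iloc[:, :2].iterrows():
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edges", path, n_dup)
    if n_self:
        logger.warning("%s: dropped %d self-loops", path, n_self)
    return g


def write_pajek(network: nx.Graph, path: str | Path) -> None:
    """Write a Pajek .net file (``*Vertices n`` then ``*Edges``)."""
    ids = sorted(map(str, network.nodes()))
    index = {v: k + 1 for k, v in enumerate(ids)}
    lines = [f"*Vertices {len(ids)}"]
    for v in ids:
        label = v.replace('"', "'")
        lines.append(f'{index[v]} "{label}"')
    lines.append("*Edges")
    for a, b in sorted(tuple(sorted((index[str(u)], index[str(v)]))) for u, v in network.edges()):
        lines.append(f"{a} {b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path) -> nx.Graph:
    """Parse a Pajek .net file; malformed lines raise with line numbers."""
    text = Path(path).read_text().splitlines()
    g = nx.Graph()
    labels: dict[int, str] = {}
    mode = None
    n_vertices = None
    n_dup = n_self = 0
    for ln, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2 or not parts[1].isdigit():
                raise ParseError(f"{path}:{ln}: malformed *Vertices header")
            n_vertices = int(parts[1])
            mode = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            mode = "edges"
            continue
        if line.startswith("*"):
            raise ParseError(f"{path}:{ln}: unsupported section {line!r}")
        if mode == "vertices":
            parts = line.split(None, 1)
            if not parts[0].isdigit():
                raise ParseError(f"{path}:{ln}: malformed vertex id")
            idx = int(parts[0])
            label = parts[1].strip() if len(parts) > 1 else str(idx)
            if label.startswith('"'):
                end = label.find('"', 1)
                if end < 0:
                    raise ParseError(f"{path}:{ln}: unterminated label quote")
                label = label[1:end]
            labels[idx] = label
            g.add_node(label)
        elif mode == "edges":
            parts = line.split()
            if len(parts) < 2 or not parts[0].isdigit() or not parts[1].isdigit():
                raise ParseError(f"{path}:{ln}: malformed edge line")
            a, b = int(parts[0]), int(parts[1])
            for v in (a, b):
                if v not in labels:
                    raise ParseError(f"{path}:{ln}: edge references unknown vertex {v}")
            if a == b:
                n_self += 1
                continue
            if g.has_edge(labels[a], labels[b]):
                n_dup += 1
                continue
            g.add_edge(labels[a], labels[b])
        else:
            raise ParseError(f"{path}:{ln}: content before *Vertices header")
    if n_vertices is not None and len(labels) != n_vertices:
        raise ParseError(f"{path}: header announced {n_vertices} vertices, found {len(labels)}")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edges", path, n_dup)
    if n_self:
        logger.warning("%s: dropped %d self-loops", path, n_self)
    return g


def read_network(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read a network from edge-list CSV or Pajek .net (by extension)."""
    fmt = format or ("pajek" if str(path).endswith(".net") else "csv")
    if fmt == "pajek":
        return read_pajek(path)
    if fmt == "csv":
        return read_edgelist_csv(path)
    raise ValueError(f"unknown network format {fmt!r}")


def write_network(network: nx.Graph, path: str | Path, format: str | None = None) -> None:
    fmt = format or ("pajek" if str(path).endswith(".net") else "csv")
    if fmt == "pajek":
        write_pajek(network, path)
    elif fmt == "csv":
        write_edgelist_csv(network, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


# ---------------------------------------------------------------- genotypes

def _locus_columns(n_loci: int) -> list[str]:
    return [f"L{l + 1:02d}_{a}" for l in range(n_loci) for a in (1, 2)]


def write_genotypes(ids: list[str], genotypes: np.ndarray, path: str | Path) -> None:
    """One row per individual, two columns per locus, blank = missing."""
    n, L, _ = genotypes.shape
    flat = genotypes.reshape(n, 2 * L).astype(object)
    flat[flat == MISSING] = ""
    df = pd.DataFrame(flat, columns=_locus_columns(L))
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)


def read_genotypes(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={"id": str})
    ids = df["id"].tolist()
    cols = [c for c in df.columns if c != "id"]
    if len(cols) % 2:
        raise ParseError(f"{path}: odd number of allele columns")
    arr = df[cols].to_numpy()
    arr = np.where(pd.isna(arr), MISSING, arr).astype(np.int16)
    return ids, arr.reshape(len(ids), len(cols) // 2, 2)


def write_coordinates(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    return df.set_index("id")


def write_pedigree(records: list[OffspringRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "offspring_id": [r.offspring_id for r in records],
            "mother_id": [r.mother_id for r in records],
            "true_father_id": [r.true_father_id for r in records],
        }
    ).to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)


# ------------------------------------------------------------- relatedness

def write_relatedness(relmatrix: RelatednessMatrix, path: str | Path) -> None:
    """Long-format CSV: id1,id2,r,n_loci over defined unordered pairs."""
    n = len(relmatrix.ids)
    iu, ju = np.triu_indices(n, 1)
    vals = relmatrix.values[iu, ju]
    keep = np.isfinite(vals)
    pd.DataFrame(
        {
            "id1": [relmatrix.ids[i] for i in iu[keep]],
            "id2": [relmatrix.ids[j] for j in ju[keep]],
            "r": vals[keep],
            "n_loci": relmatrix.n_loci[iu[keep], ju[keep]],
        }
    ).to_csv(path, index=False)


def read_relatedness(path: str | Path) -> RelatednessMatrix:
    df = pd.read_csv(path, dtype={"id1": str, "id2": str})
    ids = sorted(set(df["id1"]) | set(df["id2"]))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    vals = np.full((n, n), np.nan)
    nl = np.zeros((n, n), dtype=int)
    for _, row in df.iterrows():
        i, j = index[row["id1"]], index[row["id2"]]
        vals[i, j] = vals[j, i] = row["r"]
        if "n_loci" in df.columns:
            nl[i, j] = nl[j, i] = int(row["n_loci"])
    return RelatednessMatrix(ids=ids, values=vals, n_loci=nl)


# ---------------------------------------------------------------- fits

def write_fit(fit: CSBMFit, path: str | Path, settings: dict | None = None) -> None:
    payload = {
        "Q": fit.Q,
        "ids": list(map(str, fit.ids)),
        "U": np.round(fit.U, 12).tolist(),
        "B": np.round(fit.B, 12).tolist(),
        "logL": fit.logL,
        "aic": fit.aic,
        "n_restarts_used": fit.n_restarts_used,
        "best_restart_seed": fit.best_restart_seed,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_fit(path: str | Path) -> CSBMFit:
    d = json.loads(Path(path).read_text())
    return CSBMFit(
        Q=d["Q"],
        ids=d["ids"],
        U=np.asarray(d["U"], dtype=float),
        B=np.asarray(d["B"], dtype=float),
        logL=d["logL"],
        aic=d["aic"],
        n_restarts_used=d["n_restarts_used"],
        best_restart_seed=d["best_restart_seed"],
        converged=d["converged"],
        n_iter=d["n_iter"],
    )


def write_assignments(frame: pd.DataFrame, path: str | Path) -> None:
    frame.reset_index().to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str}).set_index("id")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------- config

@dataclasses.dataclass
class PipelineConfig:
    """All tunable pipeline parameters; round-trips through YAML/JSON."""

    # stand
    n_A: int = 178
    n_B: int = 120
    n_loci: int = 12
    alleles_per_locus: int = 10
    differentiation: float = 0.8
    extent: tuple[float, float] = (200.0, 250.0)
    species_clustering: float = 0.75
    # mating
    n_mothers: int = 51
    offspring_per_mother: int = 60
    dispersal_scale: float = 69.0
    compatibility: float = 0.2
    immigration: float = 0.45
    error_rate: float = 0.0
    # paternity
    max_mismatch: int = 0
    # relatedness
    min_loci: int = 6
    relatedness_threshold: float | None = None  # None -> calibrate; fallback 0.22
    max_calibration_pairs: int = 500
    # model
    Q_min: int = 2
    Q_max: int = 4
    override_Q: int | None = 3
    n_restarts: int = 10
    max_iter: int = 2000
    tol: float = 1e-6
    # classification / congruence
    epsilon: float = 0.05
    radius: float = 69.0
    hybrid_thresholds: tuple[float, float] = (0.2, 0.8)
    trait_noise: float = 0.1
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["hybrid_thresholds"] = list(self.hybrid_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        if "hybrid_thresholds" in d:
            d["hybrid_thresholds"] = tuple(d["hybrid_thresholds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
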