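"""File formats: rasters, graphs, configs, cluster tables, and run manifests.

Rasters are columnar TSV (unit_id, time_ms) with 1-based unit ids on disk
(0-based in memory); graphs are weighted edge-list TSV or MatrixMarket;
configs are YAML keyed by the configuration field names.  An HDF5 bundle
groups a raster with its initial voltages, config, and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
import yaml

from .netbuild import (TopologyConfig, ClusterAssignment, SynapticNetwork)


class RasterParseError(ValueError):
    pass


def write_raster(path, units: np.ndarray, times: np.ndarray) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("unit_id\ttime_ms\n")
        for u, t in zip(units, times):
            fh.write(f"{int(u) + 1}\t{t:.4f}\n")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    units, times = [], []
    with path.open() as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RasterParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                units.append(int(parts[0]) - 1)
                times.append(float(parts[1]))
            except ValueError as exc:
                raise RasterParseError(f"{path}:{lineno}: {exc}") from exc
    return (np.asarray(units, dtype=np.int64), np.asarray(times))


def write_graph_tsv(path, network_or_matrix,
                    unit_types: Optional[np.ndarray] = None) -> None:
    """Weighted directed edge list: src, dst, weight_nS, src_type, dst_type."""
    if isinstance(network_or_matrix, SynapticNetwork):
        W = network_or_matrix.weights
        types = np.where(network_or_matrix.is_excitatory, "E", "I")
    else:
        W = sp.csr_matrix(network_or_matrix)
        types = (unit_types if unit_types is not None
                 else np.full(W.shape[0], "E"))
    coo = sp.coo_matrix(W)
    with Path(path).open("w") as fh:
        fh.write("src\tdst\tweight_nS\tsrc_type\tdst_type\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}\t{j + 1}\t{w:.12g}\t{types[i]}\t{types[j]}\n")


def read_graph_tsv(path, n_units: Optional[int] = None) -> sp.csr_matrix:
    rows, cols, data = [], [], []
    with Path(path).open() as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RasterParseError(
                    f"{path}:{lineno}: expected >= 3 columns")
            rows.append(int(parts[0]) - 1)
            cols.append(int(parts[1]) - 1)
            data.append(float(parts[2]))
    n = n_units or (max(max(rows, default=0), max(cols, default=0)) + 1)
    if rows and (max(rows) >= n or max(cols) >= n):
        raise ValueError("unit id out of range")
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def write_graph_mtx(path, matrix) -> None:
    from scipy.io import mmwrite
    mmwrite(str(path), sp.coo_matrix(matrix))


def read_graph_mtx(path) -> sp.csr_matrix:
    from scipy.io import mmread
    return sp.csr_matrix(mmread(str(path)))


def write_clusters(path, clusters: ClusterAssignment) -> None:
    with Path(path).open("w") as fh:
        fh.write("unit\tcluster\n")
        for u, cs in enumerate(clusters.membership):
            for c in cs:
                fh.write(f"{u + 1}\t{c + 1}\n")


def read_clusters(path, n_units: int, n_clusters: int) -> ClusterAssignment:
    membership: list[set[int]] = [set() for _ in range(n_units)]
    with Path(path).open() as fh:
        fh.readline()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, c = line.split("\t")
            membership[int(u) - 1].add(int(c) - 1)
    return ClusterAssignment(
        n_units=n_units, n_clusters=n_clusters,
        membership=tuple(tuple(sorted(s)) for s in membership))


def write_config(path, config) -> None:
    data = dataclasses.asdict(config)
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_topology_config(path) -> TopologyConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return TopologyConfig(**data)


def write_manifest(path, manifest: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_run_bundle(path, run, config: Optional[dict] = None) -> None:
    """HDF5 bundle: raster + initial voltages + provenance."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("units", data=run.units)
        f.create_dataset("times_ms", data=run.times)
        if run.init_voltages is not None:
            f.create_dataset("init_voltages_mv", data=run.init_voltages)
        f.attrs["outcome"] = run.outcome
        f.attrs["truncation_time_ms"] = run.truncation_time_ms
        f.attrs["max_duration_ms"] = run.max_duration_ms
        f.attrs["n_units"] = run.n_units
        f.attrs["n_excitatory"] = run.n_excitatory
        if config:
            f.attrs["config_json"] = json.dumps(_jsonable(config))


def read_run_bundle(path):
    import h5py
    from .adex import SimulationRun

    with h5py.File(path, "r") as f:
        run = SimulationRun(
            units=f["units"][:], times=f["times_ms"][:],
            n_units=int(f.attrs["n_units"]),
            n_excitatory=int(f.attrs["n_excitatory"]),
            max_duration_ms=float(f.attrs["max_duration_ms"]),
            outcome=str(f.attrs["outcome"]),
            truncation_time_ms=float(f.attrs["truncation_time_ms"]),
            init_voltages=(f["init_voltages_mv"][:]
                           if "init_voltages_mv" in f else None),
        )
    return run
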