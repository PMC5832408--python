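"""Readers and writers for voxel tables, sweep tables and run configs.

Dose grids travel as tab-separated "voxel tables" with a documented header:

    # voxel_edge_cm: 0.127
    x_cm	y_cm	z_cm	dose_Gy[	region][	tcp]

Coordinates are voxel centers in cm (right-handed axes), doses in Gy.  The
``voxel_edge_cm`` metadata line is optional; without it the edge length is
inferred from the minimal inter-voxel spacing.  Values round-trip at 12
significant digits.  Run configurations are YAML documents validated against
a strict schema (unknown keys rejected).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import DoseGrid, TCPMap
from .mcmc import MCMCConfig

__all__ = [
    "read_dose_grid",
    "write_dose_grid",
    "write_tcp_map",
    "write_sweep",
    "read_sweep",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.12g"
_REQUIRED = ("x_cm", "y_cm", "z_cm", "dose_Gy")


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_dose_grid(path, grid: DoseGrid, region: np.ndarray | None = None,
                    tcp: np.ndarray | None = None) -> None:
    """Write a voxel table; deterministic column order, 12 significant digits."""
    cols: dict[str, np.ndarray] = {
        "x_cm": grid.positions[:, 0],
        "y_cm": grid.positions[:, 1],
        "z_cm": grid.positions[:, 2],
        "dose_Gy": grid.dose,
    }
    if region is not None:
        region = np.asarray(region, dtype=str)
        if region.shape != (grid.n,):
            raise ValueError("region labels must match the voxel count")
        if any("\t" in r for r in region):
            raise ValueError("region labels must not contain tabs")
        cols["region"] = region
    if tcp is not None:
        tcp = tcp.tcp if isinstance(tcp, TCPMap) else np.asarray(tcp, dtype=np.float64)
        if tcp.shape != (grid.n,):
            raise ValueError(f"tcp length {tcp.shape} does not match grid size {grid.n}")
        cols["tcp"] = tcp
    with open(path, "w") as fh:
        fh.write(f"# voxel_edge_cm: {_fmt(grid.voxel_edge)}\n")
        fh.write("\t".join(cols) + "\n")
        for k in range(grid.n):
            fields = [
                v[k] if isinstance(v[k], str) else _fmt(v[k]) for v in cols.values()
            ]
            fh.write("\t".join(fields) + "\n")


def write_tcp_map(path, grid: DoseGrid, tcp_map, *, stderr: np.ndarray | None = None,
                  seed: int | None = None) -> None:
    """Write per-voxel TCPs in the voxel-table format (dose grid + tcp column);
    Monte-Carlo outputs should carry their stderr and seed in the header."""
    tcp = tcp_map.tcp if isinstance(tcp_map, TCPMap) else np.asarray(tcp_map, dtype=np.float64)
    if tcp.shape != (grid.n,):
        raise ValueError(f"tcp length {tcp.shape} does not match grid size {grid.n}")
    with open(path, "w") as fh:
        fh.write(f"# voxel_edge_cm: {_fmt(grid.voxel_edge)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        header = ["x_cm", "y_cm", "z_cm", "dose_Gy", "tcp"]
        arrays = [grid.positions[:, 0], grid.positions[:, 1], grid.positions[:, 2], grid.dose, tcp]
        if stderr is not None:
            stderr = np.asarray(stderr, dtype=np.float64)
            if stderr.shape != (grid.n,):
                raise ValueError("stderr length does not match grid size")
            header.append("tcp_stderr")
            arrays.append(stderr)
        fh.write("\t".join(header) + "\n")
        for k in range(grid.n):
            fh.write("\t".join(_fmt(a[k]) for a in arrays) + "\n")


def read_dose_grid(path) -> tuple[DoseGrid, pd.DataFrame]:
    """Parse a voxel table into a DoseGrid.

    Returns the grid and the full parsed table (so optional ``region``/``tcp``
    columns stay available).  Malformed rows raise errors naming the line.
    """
    path = Path(path)
    voxel_edge: float | None = None
    header: list[str] | None = None
    rows: list[list[str]] = []
    row_lines: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("voxel_edge_cm"):
                    voxel_edge = float(body.split(":", 1)[1])
                continue
            if header is None:
                header = line.split("\t")
                missing = [c for c in _REQUIRED if c not in header]
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing columns {missing}")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append(fields)
            row_lines.append(lineno)
    if header is None or not rows:
        raise ValueError(f"{path}: no voxel rows found")

    df = pd.DataFrame(rows, columns=header)
    numeric = [c for c in header if c != "region"]
    for c in numeric:
        try:
            df[c] = df[c].astype(np.float64)
        except ValueError:
            bad = pd.to_numeric(df[c], errors="coerce").isna().idxmax()
            raise ValueError(
                f"{path}:{row_lines[bad]}: non-numeric value {df[c][bad]!r} in column {c!r}"
            ) from None
    neg = np.where(df["dose_Gy"].to_numpy() < 0)[0]
    if neg.size:
        raise ValueError(f"{path}:{row_lines[neg[0]]}: negative dose {df['dose_Gy'][neg[0]]}")
    positions = df[["x_cm", "y_cm", "z_cm"]].to_numpy()
    uniq = np.unique(positions, axis=0)
    if uniq.shape[0] != positions.shape[0]:
        # find the first duplicated row for the error message
        seen: set[tuple] = set()
        for k, p in enumerate(map(tuple, positions)):
            if p in seen:
                raise ValueError(f"{path}:{row_lines[k]}: duplicate voxel position {p}")
            seen.add(p)
    if voxel_edge is None:
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(positions).query(positions, k=2)
        voxel_edge = float(dist[:, 1].min())
    grid = DoseGrid(positions, df["dose_Gy"].to_numpy(), voxel_edge)
    return grid, df


def write_sweep(path, table: pd.DataFrame) -> None:
    """Write a sweep table as TSV (header always present, no quoting needed)."""
    for col in table.columns:
        if table[col].dtype == object and table[col].astype(str).str.contains("\t").any():
            raise ValueError(f"column {col!r} contains tab characters")
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d50: float = 72.8
    gamma50: float = 5.0
    label: str = "region"


class BystanderConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    j0: float = 2.0
    lam: float = 0.0
    cutoff_radius: float | None = None


class MCMCSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sweeps: int = 10_000
    burn_in_sweeps: int | None = None
    thinning: int = 1
    init: str = "independent-logistic"
    n_batches: int = 20

    def to_config(self, seed: int) -> MCMCConfig:
        return MCMCConfig(
            n_sweeps=self.n_sweeps,
            burn_in_sweeps=self.burn_in_sweeps,
            thinning=self.thinning,
            seed=seed,
            init=self.init,
            n_batches=self.n_batches,
        )


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int, int] = (10, 10, 10)
    voxel_edge: float = 0.1270
    base_dose: float = 57.0
    boost_delta: float = 40.0
    boost_fraction: float = 0.25
    boost_geometry: str = "slab"


class RunConfig(BaseModel):
    """Validated experiment configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    region: RegionConfig = Field(default_factory=RegionConfig)
    bystander: BystanderConfig = Field(default_factory=BystanderConfig)
    mcmc: MCMCSection = Field(default_factory=MCMCSection)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    seed: int = 0

    def echo(self, path) -> None:
        """Record the effective configuration next to the outputs."""
        Path(path).write_text(json.dumps(self.model_dump(), indent=2) + "\n")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
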