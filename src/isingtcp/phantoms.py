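"""Synthetic dose phantoms and the computational experiment drivers.

The phantoms emulate a small intermediate/high-risk prostate sub-volume of
~1000 cubic voxels (default 10x10x10 lattice, voxel edge 0.1270 cm) receiving
either a near-homogeneous dose or a base dose of 57 Gy with a boosted
sub-region.  Dose-like control parameters follow the conventions of the
homogeneous experiments: absolute dose = 87 Gy + dD, where 87 Gy is the level
at which the non-interacting average TCP first saturates at ~1 for
D50 = 72.8 Gy, gamma50 = 5.

Experiment drivers return long-format "sweep tables" (pandas DataFrames) with
one row per (control parameter, lambda, region); lambda = 0 rows are computed
in closed form from the logistic model, lambda > 0 rows by Metropolis MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bystander import BystanderParams, build_interaction_linearized
from .core import DoseGrid, RegionParams, logistic_tcp_voxel
from .mcmc import MCMCConfig, metropolis_run

__all__ = [
    "DEFAULT_SHAPE",
    "DEFAULT_VOXEL_EDGE",
    "DELTA_D_ORIGIN",
    "DEFAULT_PARAMS",
    "BoostPhantomSpec",
    "homogeneous_phantom",
    "boost_phantom",
    "dose_response_sweep",
    "phase_diagram",
    "boost_dose_sweep",
    "boost_volume_sweep",
    "delta_tcp_table",
]

DEFAULT_SHAPE = (10, 10, 10)
DEFAULT_VOXEL_EDGE = 0.1270  # cm
DELTA_D_ORIGIN = 87.0  # Gy; absolute dose = origin + dD
DEFAULT_PARAMS = RegionParams(d50=72.8, gamma50=5.0, label="intermediate/high risk")

SWEEP_COLUMNS = ["control", "control_name", "lam_cm", "j0_Gy", "region", "tcp_avg", "stderr", "seed"]


def _lattice_positions(shape: tuple[int, int, int], voxel_edge: float) -> np.ndarray:
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
    return idx.astype(np.float64) * voxel_edge


def homogeneous_phantom(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
    dose: float = DELTA_D_ORIGIN,
) -> DoseGrid:
    """Cubic-lattice phantom with the same dose in every voxel."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    pos = _lattice_positions(shape, voxel_edge)
    return DoseGrid(pos, np.full(pos.shape[0], float(dose)), voxel_edge)


@dataclass(frozen=True)
class BoostPhantomSpec:
    """Inhomogeneous phantom: base dose everywhere, plus ``boost_delta`` Gy in
    a fraction of voxels.  ``slab`` geometry fills contiguous lattice planes
    from one face (a single planar boosted/unboosted interface);
    ``centered-box`` grows a compact region around the lattice center."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_edge: float = DEFAULT_VOXEL_EDGE
    base_dose: float = 57.0
    boost_delta: float = 40.0
    boost_fraction: float = 0.25
    boost_geometry: str = "slab"

    def __post_init__(self) -> None:
        if not 0.0 <= self.boost_fraction <= 1.0:
            raise ValueError("boost_fraction must lie in [0, 1]")
        if self.base_dose < 0:
            raise ValueError("base_dose must be >= 0")
        if self.boost_geometry not in ("slab", "centered-box"):
            raise ValueError("boost_geometry must be 'slab' or 'centered-box'")


def boost_phantom(spec: BoostPhantomSpec) -> tuple[DoseGrid, np.ndarray]:
    """Build the boost phantom; returns the grid and the boolean boosted mask."""
    pos = _lattice_positions(spec.shape, spec.voxel_edge)
    n = pos.shape[0]
    n_boost = int(round(spec.boost_fraction * n))
    if spec.boost_fraction > 0 and n_boost < 1:
        raise ValueError(
            f"boost_fraction {spec.boost_fraction} selects no voxel on {n} voxels"
        )
    mask = np.zeros(n, dtype=bool)
    if n_boost > 0:
        if spec.boost_geometry == "slab":
            # positions are x-major: the first n_boost voxels fill x-planes
            order = np.arange(n)
        else:
            center = pos.mean(axis=0)
            cheb = np.max(np.abs(pos - center), axis=1)
            # compact box: nearest Chebyshev shells first, lexicographic tie-break
            order = np.lexsort((np.arange(n), cheb))
        mask[order[:n_boost]] = True
    dose = np.full(n, spec.base_dose)
    dose[mask] += spec.boost_delta
    return DoseGrid(pos, dose, spec.voxel_edge), mask


def _closed_form_row(dose: np.ndarray, mask: np.ndarray | None, params: RegionParams) -> tuple[float, float]:
    sel = slice(None) if mask is None else mask
    return float(np.mean(logistic_tcp_voxel(dose[sel], params))), 0.0


def _region_means(res_tcp, res_se, mask):
    sel = slice(None) if mask is None else mask
    tcp = res_tcp[sel]
    se = res_se[sel]
    return float(tcp.mean()), float(np.sqrt(np.sum(se**2)) / tcp.size)


def _sweep_rows(
    grid: DoseGrid,
    masks: dict[str, np.ndarray | None],
    params: RegionParams,
    lam: float,
    j0: float,
    cfg: MCMCConfig,
    seed: int,
    control: float,
    control_name: str,
) -> list[dict]:
    rows = []
    if lam == 0.0 or j0 == 0.0:
        for region, mask in masks.items():
            tcp, se = _closed_form_row(grid.dose, mask, params)
            rows.append(
                dict(control=control, control_name=control_name, lam_cm=lam, j0_Gy=j0,
                     region=region, tcp_avg=tcp, stderr=se, seed=-1)
            )
    else:
        bp = BystanderParams(j0=j0, lam=lam)
        J = build_interaction_linearized(grid, params, bp)
        res = metropolis_run(grid, params, J, replace(cfg, seed=seed))
        for region, mask in masks.items():
            tcp, se = _region_means(res.tcp_map, res.tcp_stderr, mask)
            rows.append(
                dict(control=control, control_name=control_name, lam_cm=lam, j0_Gy=j0,
                     region=region, tcp_avg=tcp, stderr=se, seed=seed)
            )
    return rows


def dose_response_sweep(
    delta_d_values: Sequence[float],
    lam_list: Sequence[float],
    j0: float = 2.0,
    cfg: MCMCConfig = MCMCConfig(),
    params: RegionParams = DEFAULT_PARAMS,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> pd.DataFrame:
    """Average TCP versus homogeneous dose shift dD (absolute dose 87+dD Gy)
    for each diffusion length; lambda = 0 rows are exact (non-interacting)."""
    rows: list[dict] = []
    seed = cfg.seed
    for lam in lam_list:
        for dd in delta_d_values:
            grid = homogeneous_phantom(shape, voxel_edge, DELTA_D_ORIGIN + dd)
            rows += _sweep_rows(grid, {"all": None}, params, lam, j0, cfg, seed, float(dd), "delta_d_Gy")
            seed += 1
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS).sort_values(
        ["lam_cm", "control"], ignore_index=True
    )


def phase_diagram(
    delta_d_values: Sequence[float],
    lam_values: Sequence[float],
    j0: float = 2.0,
    cfg: MCMCConfig = MCMCConfig(),
    eps: float = 0.02,
    params: RegionParams = DEFAULT_PARAMS,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_edge: float = DEFAULT_VOXEL_EDGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase classification over a (dD, lambda) grid.

    Returns (labels, tcp) arrays of shape (len(lam_values), len(delta_d_values)).
    A cell is 'uncontrolled' when TCP_avg <= eps, 'controlled' when
    >= 1 - eps, 'disordered' in between (default eps = 0.02)."""
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    df = dose_response_sweep(delta_d_values, lam_values, j0, cfg, params, shape, voxel_edge)
    tcp = np.empty((len(lam_values), len(delta_d_values)))
    for a, lam in enumerate(lam_values):
        sub = df[df.lam_cm == lam].set_index("control").tcp_avg
        tcp[a] = [sub[float(dd)] for dd in delta_d_values]
    labels = np.where(tcp <= eps, "uncontrolled", np.where(tcp >= 1 - eps, "controlled", "disordered"))
    return labels, tcp


def boost_dose_sweep(
    boost_deltas: Sequence[float],
    lam_list: Sequence[float],
    j0: float = 2.0,
    cfg: MCMCConfig = MCMCConfig(),
    boost_fraction: float = 0.25,
    base_dose: float = 57.0,
    params: RegionParams = DEFAULT_PARAMS,
    spec: BoostPhantomSpec | None = None,
) -> pd.DataFrame:
    """Average TCP in the boosted / unboosted / whole structure as the boost
    dose varies at fixed boost volume (default 25%, base 57 Gy)."""
    base_spec = spec or BoostPhantomSpec(base_dose=base_dose, boost_fraction=boost_fraction)
    rows: list[dict] = []
    seed = cfg.seed
    for lam in lam_list:
        for delta in boost_deltas:
            grid, mask = boost_phantom(replace(base_spec, boost_delta=float(delta)))
            masks = {"boosted": mask, "unboosted": ~mask, "all": None}
            rows += _sweep_rows(grid, masks, params, lam, j0, cfg, seed, float(delta), "boost_delta_Gy")
            seed += 1
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS).sort_values(
        ["lam_cm", "control", "region"], ignore_index=True
    )


def boost_volume_sweep(
    fractions: Sequence[float],
    lam_list: Sequence[float],
    boost_delta: float = 40.0,
    j0: float = 2.0,
    cfg: MCMCConfig = MCMCConfig(),
    base_dose: float = 57.0,
    params: RegionParams = DEFAULT_PARAMS,
    spec: BoostPhantomSpec | None = None,
) -> pd.DataFrame:
    """Whole-structure average TCP as the boosted volume fraction varies at
    fixed boost dose (default 40 Gy)."""
    base_spec = spec or BoostPhantomSpec(base_dose=base_dose, boost_delta=boost_delta)
    rows: list[dict] = []
    seed = cfg.seed
    for lam in lam_list:
        for frac in fractions:
            grid, mask = boost_phantom(replace(base_spec, boost_delta=boost_delta, boost_fraction=float(frac)))
            rows += _sweep_rows(grid, {"all": None}, params, lam, j0, cfg, seed, float(frac), "boost_fraction")
            seed += 1
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS).sort_values(
        ["lam_cm", "control"], ignore_index=True
    )


def delta_tcp_table(boost_sweep: pd.DataFrame) -> pd.DataFrame:
    """Per (control, lambda) difference boosted - unboosted average TCP."""
    wide = boost_sweep.pivot_table(
        index=["lam_cm", "control"], columns="region", values="tcp_avg"
    ).reset_index()
    wide["delta_tcp"] = wide["boosted"] - wide["unboosted"]
    return wide
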