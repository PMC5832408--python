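"""Core domain types and the logistic tumor-control-probability model.

The logistic dose-response model assigns each tumor voxel an independent
sterilization probability

    TCP_i = 1 / (1 + exp(-(4*gamma50/D50) * (D_i - D50)))

where ``D50`` is the dose sterilizing 50% of clonogens and ``gamma50`` the
normalized slope of the dose-response curve at ``D50``.  Introducing a binary
sterilization variable sigma_i in {0, 1} per voxel, this model is exactly a
non-interacting two-state lattice (Ising-type) model with external field
``B_i = D_i - D50`` and temperature ``k_B T = D50 / (4*gamma50)``; energies are
carried in Gy throughout and the inverse temperature ``beta = 4*gamma50/D50``
(per Gy) only enters Boltzmann weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .bystander import InteractionMatrix

__all__ = [
    "DoseGrid",
    "RegionParams",
    "RegionSpec",
    "SpinConfiguration",
    "TCPMap",
    "logistic_tcp_voxel",
    "tcp_region_geometric_mean",
    "tcp_multi_region",
    "inverse_temperature",
    "temperature",
    "local_temperature_tcp",
    "classify_hot_cold",
    "tumor_energy",
]


@dataclass(frozen=True)
class RegionParams:
    """Logistic dose-response parameters of one risk region.

    Parameters
    ----------
    d50 : float
        Dose (Gy) at which half of the clonogens are sterilized.
    gamma50 : float
        Normalized slope of the dose-response curve at ``d50``
        (dimensionless).  Large values give a steep, step-like response;
        in the lattice-model mapping this is a *low* tumor temperature.
    label : str
        Free-text region name.
    """

    d50: float
    gamma50: float
    label: str = "region"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d50) and self.d50 > 0):
            raise ValueError(f"d50 must be finite and > 0, got {self.d50}")
        if not (np.isfinite(self.gamma50) and self.gamma50 > 0):
            raise ValueError(f"gamma50 must be finite and > 0, got {self.gamma50}")

    @property
    def beta(self) -> float:
        """Inverse temperature 4*gamma50/d50 in 1/Gy."""
        return 4.0 * self.gamma50 / self.d50

    @property
    def kt(self) -> float:
        """Tumor temperature k_B*T = d50/(4*gamma50) in Gy."""
        return self.d50 / (4.0 * self.gamma50)


class DoseGrid:
    """Voxelized dose distribution on a cubic lattice.

    Holds voxel-center positions (cm), per-voxel dose (Gy) and the cubic
    voxel edge length ``voxel_edge`` (cm).  The dose plays the role of the
    external field of the lattice model through ``D_i - D50``.
    """

    def __init__(
        self,
        positions: Sequence[Sequence[float]] | np.ndarray,
        dose: Sequence[float] | np.ndarray,
        voxel_edge: float,
        *,
        validate: bool = True,
    ) -> None:
        self.positions = np.ascontiguousarray(positions, dtype=np.float64)
        self.dose = np.ascontiguousarray(dose, dtype=np.float64)
        self.voxel_edge = float(voxel_edge)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array of voxel centers")
        if self.dose.shape != (self.positions.shape[0],):
            raise ValueError("dose must be a length-N vector matching positions")
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.n < 1:
            raise ValueError("a dose grid needs at least one voxel")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("all doses must be finite")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if not (np.isfinite(self.voxel_edge) and self.voxel_edge > 0):
            raise ValueError("voxel_edge must be positive")
        if self.n > 1:
            # Pairwise-distinct positions and lattice spacing in one check:
            # the smallest inter-voxel distance must equal the voxel edge.
            tree = cKDTree(self.positions)
            dist, _ = tree.query(self.positions, k=2)
            min_spacing = float(dist[:, 1].min())
            if min_spacing == 0.0:
                raise ValueError("voxel positions must be pairwise distinct")
            if abs(min_spacing - self.voxel_edge) > 1e-9 * self.voxel_edge:
                raise ValueError(
                    f"nearest-neighbor spacing {min_spacing!r} does not match "
                    f"voxel_edge {self.voxel_edge!r}"
                )

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return (
            self.voxel_edge == other.voxel_edge
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.dose, other.dose)
        )

    def __repr__(self) -> str:
        return (
            f"DoseGrid(n={self.n}, voxel_edge={self.voxel_edge} cm, "
            f"dose range [{self.dose.min():.4g}, {self.dose.max():.4g}] Gy)"
        )


@dataclass(frozen=True)
class SpinConfiguration:
    """Binary sterilization state of all voxels; sigma_i = 1 means the
    i-th voxel is completely sterilized."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.sigma)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("sigma entries must be exactly 0 or 1")
        object.__setattr__(self, "sigma", np.ascontiguousarray(arr, dtype=np.int8))

    @property
    def n(self) -> int:
        return self.sigma.shape[0]


@dataclass(frozen=True)
class TCPMap:
    """Per-voxel sterilization probabilities."""

    tcp: np.ndarray

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.tcp, dtype=np.float64)
        if arr.size and (np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr))):
            raise ValueError("tcp entries must lie in [0, 1]")
        object.__setattr__(self, "tcp", arr)

    @property
    def n(self) -> int:
        return self.tcp.shape[0]


@dataclass(frozen=True)
class RegionSpec:
    """Partition of the tumor into R risk regions with volume fractions v_j."""

    volume_fractions: np.ndarray
    params: tuple[RegionParams, ...] = field(default=())
    assignment: np.ndarray | None = None  # voxel index -> region index

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.volume_fractions, dtype=np.float64)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("volume_fractions must be a non-empty vector")
        if np.any(v <= 0):
            raise ValueError("all volume fractions must be > 0")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("volume fractions must sum to 1 within 1e-12")
        if self.params and len(self.params) != v.size:
            raise ValueError("need one RegionParams per region")
        object.__setattr__(self, "volume_fractions", v)

    @property
    def n_regions(self) -> int:
        return self.volume_fractions.size


def _check_dose(dose: np.ndarray | float) -> np.ndarray:
    arr = np.asarray(dose, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("dose must be finite")
    return arr


def logistic_tcp_voxel(dose, params: RegionParams):
    """Voxel sterilization probability of the logistic model.

    Vectorized over ``dose``; strictly increasing, symmetric about
    ``(d50, 0.5)`` and equal to 0.5 at ``dose == d50``.
    """
    d = _check_dose(dose)
    out = expit(params.beta * (d - params.d50))
    return out if isinstance(out, np.ndarray) else float(out)


def tcp_region_geometric_mean(tcp_map) -> float:
    """Geometric mean of per-voxel TCPs (single risk-region TCP).

    Computed in log space so that N ~ 1e3 products of sub-unity
    probabilities do not underflow; any exactly-zero entry yields 0.
    """
    tcp = tcp_map.tcp if isinstance(tcp_map, TCPMap) else np.asarray(tcp_map, dtype=np.float64)
    if tcp.size == 0:
        raise ValueError("tcp map must be non-empty")
    if np.any(tcp == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(tcp))))


def tcp_multi_region(region_tcps, spec: RegionSpec) -> float:
    """Whole-tumor TCP as the volume-weighted product of region TCPs,
    ``prod_j TCP_j ** v_j``."""
    t = np.asarray(region_tcps, dtype=np.float64)
    if t.shape != (spec.n_regions,):
        raise ValueError(
            f"expected {spec.n_regions} region TCPs, got shape {t.shape}"
        )
    if np.any(t == 0.0):
        return 0.0
    return float(np.exp(np.sum(spec.volume_fractions * np.log(t))))


def inverse_temperature(params: RegionParams) -> float:
    """Inverse tumor temperature beta = 4*gamma50/d50 in 1/Gy."""
    return params.beta


def temperature(params: RegionParams) -> float:
    """Tumor temperature k_B*T = d50/(4*gamma50) in Gy."""
    return params.kt


class LocalTemperatureTCP(NamedTuple):
    tcp: float | np.ndarray
    ratio: float | np.ndarray  # T_i / T = beta * (D_i - d50)


def local_temperature_tcp(dose, params: RegionParams) -> LocalTemperatureTCP:
    """TCP expressed through the local-temperature ratio.

    With the local voxel temperature ``T_i = (D_i - D50)/k_B`` and the tumor
    temperature ``T = D50/(4 gamma50 k_B)``, the voxel TCP is
    ``1/(1 + exp(-T_i/T))`` -- algebraically identical to
    :func:`logistic_tcp_voxel`.  Returns both the TCP and the ratio T_i/T.
    """
    d = _check_dose(dose)
    ratio = params.beta * (d - params.d50)
    tcp = expit(ratio)
    if np.ndim(d) == 0:
        return LocalTemperatureTCP(float(tcp), float(ratio))
    return LocalTemperatureTCP(tcp, ratio)


def classify_hot_cold(grid: DoseGrid, params: RegionParams, hot_ratio: float = 3.0) -> np.ndarray:
    """Label voxels 'hot' (controlled with high probability, T_i/T >= hot_ratio)
    or 'cold'.  The default ratio 3 corresponds to a voxel TCP of ~0.95."""
    if hot_ratio <= 0:
        raise ValueError("hot_ratio must be > 0")
    ratio = params.beta * (grid.dose - params.d50)
    return np.where(ratio >= hot_ratio, "hot", "cold")


def tumor_energy(
    config,
    grid: DoseGrid,
    params: RegionParams,
    J: "InteractionMatrix | None" = None,
) -> float:
    """Configuration energy in Gy.

    ``E = sum_i (D50 - D_i) sigma_i - sum_{ordered i != j} J_ij sigma_i sigma_j``.
    The interaction double sum runs over *ordered* pairs without a 1/2
    factor because J_ij is directional (sensitization of voxel j by voxel
    i); diagonal terms are excluded by construction of the matrix.
    """
    sigma = config.sigma if isinstance(config, SpinConfiguration) else np.asarray(config)
    if sigma.shape != (grid.n,):
        raise ValueError(f"configuration length {sigma.shape} != grid size {grid.n}")
    sigma = sigma.astype(np.float64)
    e = float(np.dot(params.d50 - grid.dose, sigma))
    if J is not None:
        e -= float(sigma @ (J.csr @ sigma))
    return e
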