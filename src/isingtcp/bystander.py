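"""Bystander (voxel-voxel radio-sensitization) interaction matrices.

A radiation-damaged voxel is assumed to release a diffusible mediator that
radio-sensitizes nearby voxels.  The coupling imparted by source voxel i on
target voxel j is

    J_ij = J0 * TCP_i * exp(-|r_i - r_j| / lam)        (self-consistent)
    J_ij ~ J0 * TCP0(D_i) * exp(-|r_i - r_j| / lam)    (linearized)

with strength ``J0`` (Gy) and diffusion length ``lam`` (cm).  The linearized
form replaces the interacting marginal TCP_i by its non-interacting logistic
value and is the default used everywhere; the self-consistent form is solved
by fixed-point iteration on top of it.  Matrices are sparse and directed
(row = source voxel), truncated at a configurable cutoff radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .core import DoseGrid, RegionParams, logistic_tcp_voxel

__all__ = [
    "BystanderParams",
    "InteractionMatrix",
    "SelfConsistentInfo",
    "build_interaction_linearized",
    "build_interaction_selfconsistent",
    "neglectability_criterion",
    "NeglectabilityResult",
    "kernel_tail_fraction",
]


@dataclass(frozen=True)
class BystanderParams:
    """Strength J0 (Gy), range lam (cm) and sparse cutoff radius (cm) of the
    bystander interaction.  ``cutoff_radius`` defaults to 5*lam."""

    j0: float
    lam: float
    cutoff_radius: float | None = None

    def __post_init__(self) -> None:
        if self.j0 < 0:
            raise ValueError("j0 must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.cutoff_radius is None:
            object.__setattr__(self, "cutoff_radius", 5.0 * self.lam)
        if self.cutoff_radius < self.lam:
            raise ValueError("cutoff_radius must be >= lam")


@dataclass
class InteractionMatrix:
    """Sparse directed bystander couplings J_ij >= 0 in Gy.

    ``csr[i, j]`` is the sensitization of voxel j by voxel i; the diagonal is
    empty and entries exist only within the provenance cutoff radius.
    """

    csr: sparse.csr_matrix
    j0: float
    lam: float
    cutoff: float
    linearized: bool = True
    pair_mode: str = "ordered"

    def __post_init__(self) -> None:
        self.csr = sparse.csr_matrix(self.csr)
        if self.csr.shape[0] != self.csr.shape[1]:
            raise ValueError("interaction matrix must be square")
        if self.csr.diagonal().any():
            raise ValueError("interaction matrix must have an empty diagonal")
        if self.csr.nnz and self.csr.data.min() < 0:
            raise ValueError("couplings must be non-negative")

    @property
    def n(self) -> int:
        return self.csr.shape[0]

    @property
    def nnz(self) -> int:
        return self.csr.nnz

    def symmetrized(self) -> sparse.csr_matrix:
        """J + J^T, the kernel of the local energy field h = (J + J^T) sigma."""
        return (self.csr + self.csr.T).tocsr()

    def to_frame(self) -> pd.DataFrame:
        """Coordinate-format view (i, j, J_ij) for inspection/export."""
        coo = self.csr.tocoo()
        return pd.DataFrame({"i": coo.row, "j": coo.col, "J_Gy": coo.data})

    def write_text(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"# bystander couplings: n={self.n} j0_Gy={self.j0} lam_cm={self.lam} "
                f"cutoff_cm={self.cutoff} linearized={self.linearized} "
                f"pair_mode={self.pair_mode}\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def empty(cls, n: int, bp: BystanderParams, *, linearized: bool = True) -> "InteractionMatrix":
        return cls(
            sparse.csr_matrix((n, n)),
            j0=bp.j0,
            lam=bp.lam,
            cutoff=bp.cutoff_radius,
            linearized=linearized,
        )


def _kernel_from_source_tcp(
    grid: DoseGrid,
    bp: BystanderParams,
    source_tcp: np.ndarray,
    *,
    linearized: bool,
    pair_mode: str,
) -> InteractionMatrix:
    """Assemble J_ij = j0 * source_tcp[i] * exp(-d_ij/lam) within the cutoff."""
    n = grid.n
    if bp.j0 == 0.0 or bp.lam == 0.0 or n == 1:
        return InteractionMatrix.empty(n, bp, linearized=linearized)
    tree = cKDTree(grid.positions)
    pairs = tree.query_pairs(bp.cutoff_radius, output_type="ndarray")
    if pairs.size == 0:
        return InteractionMatrix.empty(n, bp, linearized=linearized)
    i, j = pairs[:, 0], pairs[:, 1]
    dist = np.linalg.norm(grid.positions[i] - grid.positions[j], axis=1)
    decay = np.exp(-dist / bp.lam)
    scale = 0.5 if pair_mode == "unordered" else 1.0
    if pair_mode not in ("ordered", "unordered"):
        raise ValueError("pair_mode must be 'ordered' or 'unordered'")
    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    data = scale * bp.j0 * np.concatenate([source_tcp[i] * decay, source_tcp[j] * decay])
    csr = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return InteractionMatrix(
        csr, j0=bp.j0, lam=bp.lam, cutoff=bp.cutoff_radius,
        linearized=linearized, pair_mode=pair_mode,
    )


def build_interaction_linearized(
    grid: DoseGrid,
    params: RegionParams,
    bp: BystanderParams,
    *,
    pair_mode: str = "ordered",
) -> InteractionMatrix:
    """Linearized bystander kernel: the source factor is the non-interacting
    logistic TCP of the emitting voxel, an explicit function of its dose."""
    tcp0 = np.atleast_1d(logistic_tcp_voxel(grid.dose, params))
    return _kernel_from_source_tcp(grid, bp, tcp0, linearized=True, pair_mode=pair_mode)


@dataclass
class SelfConsistentInfo:
    converged: bool
    n_iter: int
    max_delta_tcp: float


def build_interaction_selfconsistent(
    grid: DoseGrid,
    params: RegionParams,
    bp: BystanderParams,
    tol: float = 1e-4,
    max_iter: int = 25,
    marginal_fn: Callable[[DoseGrid, RegionParams, InteractionMatrix], np.ndarray] | None = None,
    *,
    pair_mode: str = "ordered",
) -> tuple[InteractionMatrix, SelfConsistentInfo]:
    """Fixed-point iteration for the non-linear bystander kernel.

    Starts from the linearized kernel, then repeatedly rebuilds the kernel
    from the marginal TCPs computed *under the current kernel* until the
    marginals move by less than ``tol`` (max over voxels).  Non-convergence
    is reported through the returned :class:`SelfConsistentInfo` flag rather
    than an exception -- the non-linear form is known to be less stable.

    ``marginal_fn(grid, params, J) -> tcp array`` defaults to exact
    enumeration for small grids and Metropolis sampling otherwise.
    """
    if marginal_fn is None:
        marginal_fn = _default_marginal_fn

    J = build_interaction_linearized(grid, params, bp, pair_mode=pair_mode)
    tcp_prev = marginal_fn(grid, params, J)
    if bp.j0 == 0.0 or bp.lam == 0.0 or grid.n == 1:
        return J, SelfConsistentInfo(converged=True, n_iter=1, max_delta_tcp=0.0)

    max_delta = np.inf
    for it in range(1, max_iter + 1):
        J = _kernel_from_source_tcp(grid, bp, tcp_prev, linearized=False, pair_mode=pair_mode)
        tcp = marginal_fn(grid, params, J)
        max_delta = float(np.max(np.abs(tcp - tcp_prev)))
        tcp_prev = tcp
        if max_delta < tol:
            return J, SelfConsistentInfo(converged=True, n_iter=it, max_delta_tcp=max_delta)
    return J, SelfConsistentInfo(converged=False, n_iter=max_iter, max_delta_tcp=max_delta)


def _default_marginal_fn(grid: DoseGrid, params: RegionParams, J: InteractionMatrix) -> np.ndarray:
    from . import exact, mcmc

    if grid.n <= exact.N_MAX_DEFAULT:
        return exact.enumerate_states(grid, params, J).c1
    cfg = mcmc.MCMCConfig(n_sweeps=5000, seed=0)
    return mcmc.metropolis_run(grid, params, J, cfg).tcp_map


@dataclass(frozen=True)
class NeglectabilityResult:
    negligible: bool
    lhs: float  # |D - D50| in Gy
    rhs: float  # 8*pi*J0*(lam/a)^3 in Gy


def neglectability_criterion(
    dose: float,
    params: RegionParams,
    bp: BystanderParams,
    voxel_edge: float,
    ratio: float = 10.0,
) -> NeglectabilityResult:
    """Test whether bystander couplings are negligible for a near-homogeneous
    dose ``D``: they are when ``|D - D50| >> 8*pi*J0*(lam/a)^3``.

    ``(lam/a)^3`` counts the voxels radio-sensitized in the vicinity of a
    single sterilized voxel.  The '>>' is operationalized as
    ``lhs >= ratio * rhs`` with a default factor of 10.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be > 0")
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    lhs = abs(float(dose) - params.d50)
    rhs = 8.0 * np.pi * bp.j0 * (bp.lam / voxel_edge) ** 3
    return NeglectabilityResult(negligible=lhs >= ratio * rhs, lhs=lhs, rhs=float(rhs))


def kernel_tail_fraction(lam: float, cutoff: float) -> float:
    """Fraction of the continuum exponential-kernel mass beyond the cutoff.

    The untruncated kernel integral is ``int 4 pi r^2 exp(-r/lam) dr = 8 pi
    lam^3``; the mass beyond radius ``c`` is the regularized upper incomplete
    gamma function Q(3, c/lam) = exp(-x)(x^2 + 2x + 2)/2 with x = c/lam.
    """
    if lam <= 0:
        return 0.0
    x = cutoff / lam
    return float(np.exp(-x) * (x * x + 2.0 * x + 2.0) / 2.0)
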