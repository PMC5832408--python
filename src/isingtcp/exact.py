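"""Exhaustive enumeration of the 2^N-state Boltzmann distribution.

For small voxel counts the interacting sterilization model

    P({sigma}) = Z^-1 exp(-beta * [sum_i (D50 - D_i) sigma_i
                                   - sum_{i != j} J_ij sigma_i sigma_j])

can be summed over every configuration, giving exact marginals (one-point
correlations = per-voxel TCPs), pairwise correlations, the all-voxel
sterilization probability and the partition function.  This is the oracle
against which the Metropolis sampler is validated; the state count doubles
per voxel, so enumeration is refused above ``n_max`` (default 20, ~1e6
states).  All accumulations run in log space with max-subtraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .bystander import InteractionMatrix
from .core import DoseGrid, RegionParams

__all__ = [
    "N_MAX_DEFAULT",
    "ExactSummary",
    "enumerate_states",
    "exact_marginal_tcp",
    "exact_n_voxel_tcp",
    "free_energy",
]

N_MAX_DEFAULT = 20
_CHUNK_BITS = 14  # enumerate states in chunks of 2^14 to bound memory


@dataclass
class ExactSummary:
    """Exact thermodynamic and correlation summary of a small voxel system.

    Attributes
    ----------
    logZ : float
        Log partition function (dimensionless).
    free_energy : float
        Tumor free energy -logZ / beta in Gy.
    c1 : ndarray
        One-point correlations = exact per-voxel TCPs.
    c2 : ndarray
        Two-point correlations <sigma_i sigma_j> (c2[i, i] = c1[i]).
    cN : float
        Probability that every voxel is sterilized.
    order_parameter : float
        Mean of c1 (the average TCP per voxel).
    """

    logZ: float
    free_energy: float
    c1: np.ndarray
    c2: np.ndarray
    cN: float
    order_parameter: float
    n: int
    beta: float

    def to_json(self, **kwargs) -> str:
        payload = {
            "n": self.n,
            "beta_per_Gy": self.beta,
            "logZ": self.logZ,
            "free_energy_Gy": self.free_energy,
            "c1": self.c1.tolist(),
            "c2": self.c2.tolist(),
            "cN": self.cN,
            "order_parameter": self.order_parameter,
        }
        return json.dumps(payload, **kwargs)


def state_energies(grid: DoseGrid, params: RegionParams, J: InteractionMatrix | None) -> np.ndarray:
    """Energies (Gy) of all 2^N configurations; bit i of the state index is
    sigma_i, so the all-sterilized configuration is the last index."""
    n = grid.n
    field = params.d50 - grid.dose  # (D50 - D_i)
    Jd = None if J is None or J.nnz == 0 else np.asarray(J.csr.todense())
    energies = np.empty(1 << n)
    bits = np.arange(n)
    for start in range(0, 1 << n, 1 << _CHUNK_BITS):
        stop = min(start + (1 << _CHUNK_BITS), 1 << n)
        idx = np.arange(start, stop, dtype=np.int64)
        S = ((idx[:, None] >> bits) & 1).astype(np.float64)
        e = S @ field
        if Jd is not None:
            e -= np.einsum("si,ij,sj->s", S, Jd, S)
        energies[start:stop] = e
    return energies


def enumerate_states(
    grid: DoseGrid,
    params: RegionParams,
    J: InteractionMatrix | None = None,
    n_max: int = N_MAX_DEFAULT,
) -> ExactSummary:
    """Exact summary by summation over all 2^N configurations.

    Raises
    ------
    ValueError
        If ``grid.n > n_max`` — the configuration space doubles per voxel
        (2^1004 states for a realistic grid), so large systems must use the
        Metropolis sampler instead.
    """
    n = grid.n
    if n > n_max:
        raise ValueError(
            f"exact enumeration over 2^{n} configurations refused (n_max={n_max}); "
            "use the MCMC engine for large voxel sets"
        )
    logw = -params.beta * state_energies(grid, params, J)
    logZ = float(logsumexp(logw))
    p = np.exp(logw - logZ)
    total = float(p.sum())
    if abs(total - 1.0) > 1e-12:
        raise AssertionError(f"state probabilities sum to {total}, not 1")

    bits = np.arange(n)
    c1 = np.zeros(n)
    c2 = np.zeros((n, n))
    for start in range(0, 1 << n, 1 << _CHUNK_BITS):
        stop = min(start + (1 << _CHUNK_BITS), 1 << n)
        idx = np.arange(start, stop, dtype=np.int64)
        S = ((idx[:, None] >> bits) & 1).astype(np.float64)
        ps = p[start:stop]
        c1 += ps @ S
        c2 += (S * ps[:, None]).T @ S
    cN = float(p[-1])  # all bits set = all voxels sterilized
    return ExactSummary(
        logZ=logZ,
        free_energy=-logZ / params.beta,
        c1=c1,
        c2=c2,
        cN=cN,
        order_parameter=float(c1.mean()),
        n=n,
        beta=params.beta,
    )


def exact_marginal_tcp(
    grid: DoseGrid,
    params: RegionParams,
    J: InteractionMatrix | None,
    i: int,
    n_max: int = N_MAX_DEFAULT,
) -> float:
    """Exact marginal sterilization probability of voxel i, obtained by
    summing the joint distribution over all other voxels.  With ``J=None``
    this reduces to the logistic single-voxel TCP."""
    if not 0 <= i < grid.n:
        raise IndexError(f"voxel index {i} out of range for n={grid.n}")
    return float(enumerate_states(grid, params, J, n_max=n_max).c1[i])


def exact_n_voxel_tcp(
    grid: DoseGrid,
    params: RegionParams,
    J: InteractionMatrix | None = None,
    n_max: int = N_MAX_DEFAULT,
) -> float:
    """N-voxel TCP: the probability that all voxels are sterilized, raised to
    1/N.  For J=None it coincides with the geometric mean of the per-voxel
    logistic TCPs."""
    summary = enumerate_states(grid, params, J, n_max=n_max)
    if summary.cN == 0.0:
        return 0.0
    return float(np.exp(np.log(summary.cN) / summary.n))


def free_energy(summary: ExactSummary, params: RegionParams) -> float:
    """Tumor free energy F = -k_B T ln Z = -logZ / beta, in Gy."""
    return -summary.logZ / params.beta
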