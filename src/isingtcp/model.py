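"""Model/Results front end.

:class:`TumorControlModel` bundles a dose grid, the logistic dose-response
parameters and (optionally) bystander couplings; ``fit()`` evaluates the
per-voxel sterilization probabilities either exactly (enumeration, small N)
or by Metropolis Monte Carlo, and returns a :class:`TumorControlResults`
carrying the estimates, their Monte-Carlo standard errors and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exact as _exact
from .bystander import BystanderParams, InteractionMatrix, build_interaction_linearized
from .core import (
    DoseGrid,
    RegionParams,
    classify_hot_cold,
    logistic_tcp_voxel,
    tcp_region_geometric_mean,
)
from .mcmc import MCMCConfig, MCMCResult, metropolis_run

__all__ = ["TumorControlModel", "TumorControlResults"]


class TumorControlModel:
    """Ising-like tumor control model on a voxelized dose distribution.

    Parameters
    ----------
    grid : DoseGrid
        Voxel positions, doses and edge length.
    params : RegionParams
        Logistic parameters (d50, gamma50) of the risk region.
    bystander : BystanderParams, optional
        Strength/range of the voxel-voxel radio-sensitization; when given,
        the linearized interaction matrix is built on construction.
    interactions : InteractionMatrix, optional
        Pre-built couplings (overrides ``bystander``).
    """

    def __init__(
        self,
        grid: DoseGrid,
        params: RegionParams,
        bystander: BystanderParams | None = None,
        interactions: InteractionMatrix | None = None,
        *,
        pair_mode: str = "ordered",
    ) -> None:
        self.grid = grid
        self.params = params
        self.bystander = bystander
        if interactions is not None:
            self.interactions = interactions
        elif bystander is not None:
            self.interactions = build_interaction_linearized(
                grid, params, bystander, pair_mode=pair_mode
            )
        else:
            self.interactions = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        d50: float,
        gamma50: float,
        voxel_edge: float | None = None,
        j0: float = 0.0,
        lam: float = 0.0,
        **kwargs,
    ) -> "TumorControlModel":
        """Build from a voxel table with columns x_cm, y_cm, z_cm, dose_Gy."""
        positions = df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
        dose = df["dose_Gy"].to_numpy(dtype=float)
        if voxel_edge is None:
            from scipy.spatial import cKDTree

            dist, _ = cKDTree(positions).query(positions, k=2)
            voxel_edge = float(dist[:, 1].min())
        grid = DoseGrid(positions, dose, voxel_edge)
        params = RegionParams(d50=d50, gamma50=gamma50)
        bp = BystanderParams(j0=j0, lam=lam) if j0 > 0 and lam > 0 else None
        return cls(grid, params, bystander=bp, **kwargs)

    @property
    def interacting(self) -> bool:
        return self.interactions is not None and self.interactions.nnz > 0

    def fit(self, method: str = "auto", **kwargs) -> "TumorControlResults":
        """Evaluate per-voxel TCPs.

        method : {'auto', 'closed-form', 'exact', 'mcmc'}
            'closed-form' applies the independent logistic model (only valid
            without interactions); 'exact' enumerates all configurations
            (N <= 20); 'mcmc' runs the Metropolis sampler.  'auto' picks the
            cheapest valid method.
        kwargs
            For 'mcmc': either ``cfg=MCMCConfig(...)`` or MCMCConfig fields.
        """
        if method == "auto":
            if not self.interacting:
                method = "closed-form"
            elif self.grid.n <= _exact.N_MAX_DEFAULT:
                method = "exact"
            else:
                method = "mcmc"

        if method == "closed-form":
            if self.interacting:
                raise ValueError("closed-form evaluation requires a non-interacting model")
            tcp = np.atleast_1d(logistic_tcp_voxel(self.grid.dose, self.params))
            return TumorControlResults(self, method, tcp_map=tcp)
        if method == "exact":
            summary = _exact.enumerate_states(self.grid, self.params, self.interactions)
            return TumorControlResults(
                self, method, tcp_map=summary.c1, exact_summary=summary
            )
        if method == "mcmc":
            cfg = kwargs.pop("cfg", None)
            if cfg is None:
                cfg = MCMCConfig(**kwargs)
            res = metropolis_run(self.grid, self.params, self.interactions, cfg)
            return TumorControlResults(
                self, method, tcp_map=res.tcp_map, mcmc_result=res
            )
        raise ValueError(f"unknown method {method!r}")


@dataclass
class TumorControlResults:
    """Per-voxel sterilization probabilities and derived summaries."""

    model: TumorControlModel
    method: str
    tcp_map: np.ndarray
    exact_summary: "_exact.ExactSummary | None" = None
    mcmc_result: MCMCResult | None = None

    @property
    def tcp_avg(self) -> float:
        """Order parameter: average TCP per voxel."""
        return float(self.tcp_map.mean())

    @property
    def tcp_avg_stderr(self) -> float:
        return self.mcmc_result.tcp_avg_stderr if self.mcmc_result is not None else 0.0

    @property
    def tcp_stderr(self) -> np.ndarray:
        if self.mcmc_result is not None:
            return self.mcmc_result.tcp_stderr
        return np.zeros_like(self.tcp_map)

    @property
    def n_voxel_tcp(self) -> float | None:
        """Whole-structure TCP.  Exact (C^(N))^(1/N) when enumerated; the
        geometric mean of voxel TCPs in the non-interacting closed form; not
        available from MCMC (signal-to-noise too small)."""
        if self.exact_summary is not None:
            cn = self.exact_summary.cN
            return 0.0 if cn == 0.0 else float(np.exp(np.log(cn) / self.exact_summary.n))
        if self.method == "closed-form":
            return tcp_region_geometric_mean(self.tcp_map)
        return None

    @property
    def free_energy(self) -> float | None:
        return self.exact_summary.free_energy if self.exact_summary is not None else None

    def hot_cold_counts(self, hot_ratio: float = 3.0) -> tuple[int, int]:
        labels = classify_hot_cold(self.model.grid, self.model.params, hot_ratio)
        n_hot = int((labels == "hot").sum())
        return n_hot, self.model.grid.n - n_hot

    def summary(self) -> str:
        m, g, p = self.model, self.model.grid, self.model.params
        J = m.interactions
        n_hot, n_cold = self.hot_cold_counts()
        lines = [
            "Tumor Control Model Results",
            "=" * 46,
            f"{'Voxels':<28}{g.n}",
            f"{'Voxel edge (cm)':<28}{g.voxel_edge:g}",
            f"{'Dose range (Gy)':<28}[{g.dose.min():.2f}, {g.dose.max():.2f}]",
            f"{'D50 (Gy)':<28}{p.d50:g}",
            f"{'gamma50':<28}{p.gamma50:g}",
            f"{'Tumor temperature kT (Gy)':<28}{p.kt:.4f}",
            f"{'Hot / cold voxels':<28}{n_hot} / {n_cold}",
        ]
        if J is not None and J.nnz:
            lines += [
                f"{'Bystander J0 (Gy)':<28}{J.j0:g}",
                f"{'Diffusion length (cm)':<28}{J.lam:g}",
                f"{'Couplings (nnz)':<28}{J.nnz}",
            ]
        else:
            lines.append(f"{'Bystander couplings':<28}none")
        lines += ["-" * 46, f"{'Method':<28}{self.method}"]
        if self.mcmc_result is not None:
            r = self.mcmc_result
            lines += [
                f"{'Sweeps (burn-in)':<28}{r.config.n_sweeps} ({r.config.burn_in_sweeps})",
                f"{'Retained samples':<28}{r.n_samples}",
                f"{'Acceptance rate':<28}{r.acceptance_rate:.4f}",
                f"{'Seed':<28}{r.seed}",
                f"{'TCP_avg':<28}{self.tcp_avg:.6f} +/- {self.tcp_avg_stderr:.6f}",
            ]
        else:
            lines.append(f"{'TCP_avg':<28}{self.tcp_avg:.6f}")
        if self.free_energy is not None:
            lines.append(f"{'Free energy (Gy)':<28}{self.free_energy:.6f}")
        ntcp = self.n_voxel_tcp
        if ntcp is not None:
            lines.append(f"{'N-voxel TCP':<28}{ntcp:.6f}")
        lines.append(
            f"{'Voxel TCP range':<28}[{self.tcp_map.min():.6f}, {self.tcp_map.max():.6f}]"
        )
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        g = self.model.grid
        return pd.DataFrame(
            {
                "x_cm": g.positions[:, 0],
                "y_cm": g.positions[:, 1],
                "z_cm": g.positions[:, 2],
                "dose_Gy": g.dose,
                "tcp": self.tcp_map,
                "tcp_stderr": self.tcp_stderr,
            }
        )
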