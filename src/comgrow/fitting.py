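"""Fit the community-count curve N_c(beta).

The empirical relationship between the final community count and a fixed
control parameter beta is well described by the one-parameter hyperbola

    N_c(beta) ~ n * beta / ((k + gamma) + beta),

which has the model's exact limits built in (0 communities of growth
origin at beta = 0, all n nodes as beta -> inf) and a single free shape
parameter gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import InvalidParameterError
from .growth import ModelParams, grow

__all__ = ["SweepResult", "FitResult", "sweep_nc", "predict_nc", "fit_gamma", "plot_sweep"]


@dataclass
class SweepResult:
    """Mean final community count over replicates along a fixed-beta grid."""

    betas: np.ndarray
    mean_nc: np.ndarray
    se_nc: np.ndarray
    n: int
    k: int
    m: int
    p: float
    n_reps: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"beta": self.betas, "mean_nc": self.mean_nc, "se_nc": self.se_nc}
        )


@dataclass
class FitResult:
    gamma: float
    rss: float
    predicted: np.ndarray
    degenerate: bool = False


def default_beta_grid(n_points: int = 12) -> np.ndarray:
    """Log-spaced grid covering the interesting range of beta."""
    return np.logspace(-2, 3, n_points)


def sweep_nc(
    params_template: ModelParams,
    beta_grid: Sequence[float],
    n_reps: int = 50,
    seed: Optional[int] = None,
) -> SweepResult:
    """Grow ``n_reps`` networks per fixed beta and record the mean N_c."""
    betas = np.asarray(beta_grid, dtype=float)
    if betas.size and np.any(np.diff(betas) <= 0):
        raise InvalidParameterError("beta grid must be strictly increasing")
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.empty_like(betas)
    ses = np.empty_like(betas)
    for j, beta in enumerate(betas):
        params = replace(params_template, beta_policy="fixed", beta_value=float(beta))
        counts = np.array(
            [grow(params, rng=rng).n_communities for _ in range(n_reps)], dtype=float
        )
        means[j] = counts.mean()
        ses[j] = counts.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
    return SweepResult(
        betas=betas,
        mean_nc=means,
        se_nc=ses,
        n=params_template.n_target,
        k=params_template.k,
        m=params_template.m,
        p=params_template.p,
        n_reps=n_reps,
    )


def predict_nc(beta, n: int, k: int, gamma: float):
    """Hyperbolic community-count curve; vectorised over beta."""
    beta = np.asarray(beta, dtype=float)
    out = n * beta / ((k + gamma) + beta)
    return float(out) if out.ndim == 0 else out


def fit_gamma(sweep: SweepResult, gamma_max: float = 1e4) -> FitResult:
    """Least-squares fit of gamma on gamma in (-k + eps, gamma_max]."""
    if sweep.betas.size < 3:
        raise InvalidParameterError("fit needs at least 3 grid points")
    degenerate = bool(np.allclose(sweep.mean_nc, sweep.mean_nc[0]))
    if degenerate:
        warnings.warn(
            "all sweep means are equal; gamma is unidentifiable", stacklevel=2
        )

    def rss(gamma: float) -> float:
        resid = sweep.mean_nc - predict_nc(sweep.betas, sweep.n, sweep.k, gamma)
        return float(resid @ resid)

    res = optimize.minimize_scalar(
        rss, bounds=(-sweep.k + 1e-6, gamma_max), method="bounded"
    )
    gamma = float(res.x)
    return FitResult(
        gamma=gamma,
        rss=rss(gamma),
        predicted=predict_nc(sweep.betas, sweep.n, sweep.k, gamma),
        degenerate=degenerate,
    )


def plot_sweep(sweep: SweepResult, fit: Optional[FitResult] = None, ax=None):
    """Simple N_c(beta) plot with the fitted curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(sweep.betas, sweep.mean_nc, yerr=sweep.se_nc, fmt="o", label="model")
    if fit is not None:
        grid = np.logspace(
            np.log10(sweep.betas[0]), np.log10(sweep.betas[-1]), 200
        )
        ax.plot(grid, predict_nc(grid, sweep.n, sweep.k, fit.gamma),
                "--", label=f"fit (gamma={fit.gamma:.2f})")
    ax.set_xscale("log")
    ax.set_xlabel("beta")
    ax.set_ylabel("N_c")
    ax.legend()
    return ax
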