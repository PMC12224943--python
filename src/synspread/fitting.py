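"""Concordance-based loss and parameter estimation for the spread model.

The fitting objective is Lin's concordance correlation coefficient (CCC)
between log10-transformed observed and predicted burdens, summed as
``sum_t (1 - CCC_t)`` over the observation time points and evaluated only at
regions with nonzero observed burden.  CCC penalises both location and scale
disagreement, unlike Pearson's r, which makes the seed scaling ``gamma``
identifiable.  Optimisation is bounded multi-start local search over
``(alpha, beta, gamma, s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import Connectome, RegionAtlas
from .dynamics import (
    EffectMode,
    GeneExpressionProfile,
    SeedSpec,
    SpreadParameters,
)

__all__ = [
    "PathologyDataset",
    "FitConfig",
    "FitResult",
    "lin_ccc",
    "masked_log10",
    "spread_loss",
    "fit_spread_model",
]

#: finite sentinel returned by the loss when a prediction fails
FAILED_LOSS = 1e6


@dataclass(frozen=True)
class PathologyDataset:
    """Group-averaged regional burden fractions at one or more time points."""

    atlas: RegionAtlas
    times: tuple[float, ...]
    observed: np.ndarray  # shape (n_times, n_regions)
    provenance: str = ""

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        times = tuple(float(t) for t in self.times)
        if len(times) == 0:
            raise ValueError("at least one time point is required")
        if obs.ndim == 1:
            obs = obs[None, :]
        if obs.shape != (len(times), self.atlas.n_regions):
            raise ValueError(
                f"observed shape {obs.shape} != ({len(times)}, {self.atlas.n_regions})"
            )
        if np.any(obs[np.isfinite(obs)] < 0):
            raise ValueError("observed burdens must be >= 0")
        obs = obs.copy()
        obs.setflags(write=False)
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "times", times)


@dataclass(frozen=True)
class FitConfig:
    """Bounds, multi-start count and tolerances for model fitting.

    The practical boxes ``alpha in [-5, 5]`` and ``beta in [0, 20]`` stand in
    for the model's unbounded / semi-unbounded constraints; fits hitting these
    box edges are flagged in the start diagnostics.  ``gamma`` is restricted
    to ``[1e-6, 1]`` and ``s`` to ``[0, 1]``.
    """

    alpha_bounds: tuple[float, float] = (-5.0, 5.0)
    beta_bounds: tuple[float, float] = (0.0, 20.0)
    gamma_bounds: tuple[float, float] = (1e-6, 1.0)
    s_bounds: tuple[float, float] = (0.0, 1.0)
    n_starts: int = 20
    rng_seed: int = 0
    log_floor: float = 1e-12
    maxiter: int = 300
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.beta_bounds[0] < 0:
            raise ValueError("beta lower bound must be >= 0")
        if not (0 < self.gamma_bounds[0] <= self.gamma_bounds[1] <= 1):
            raise ValueError("gamma bounds must lie within (0, 1]")
        if not (0 <= self.s_bounds[0] <= self.s_bounds[1] <= 1):
            raise ValueError("s bounds must lie within [0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters with per-time concordance diagnostics."""

    parameters: SpreadParameters | None
    ccc_per_time: tuple[float, ...]
    ave_ccc: float
    pearson_per_time: tuple[float, ...]
    status: str
    n_regions_used: tuple[int, ...]
    loss: float
    start_diagnostics: tuple[dict, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))**2)`` with
    1/n moments.  Equals 1 iff ``y == x`` elementwise; degrades for any
    location or scale shift, unlike Pearson's r.  Returns ``nan`` when both
    vectors are constant (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with >= 2 entries")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    if vx == 0.0 and vy == 0.0:
        return float("nan")
    denom = vx + vy + (mx - my) ** 2
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / denom)


def masked_log10(
    observed: np.ndarray, predicted: np.ndarray, log_floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 transform restricted to nonzero, finite observed entries.

    Returns ``(obs_log, pred_log, mask)`` where ``mask`` indexes the regions
    with ``observed > 0`` and finite; predicted values at masked-in regions
    are floored at ``log_floor`` before the log so exact zeros stay finite.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same shape")
    mask = np.flatnonzero(np.isfinite(observed) & (observed > 0))
    obs_log = np.log10(observed[mask])
    pred_log = np.log10(np.maximum(predicted[mask], log_floor))
    return obs_log, pred_log, mask


def spread_loss(
    params: SpreadParameters,
    data: PathologyDataset,
    connectome: Connectome,
    seed_regions: Sequence[str],
    gene: GeneExpressionProfile | None = None,
    mode: EffectMode = "global",
    config: FitConfig | None = None,
) -> float:
    """``sum_t (1 - CCC(log10 X(t), log10 X_hat(t)))`` over masked regions.

    Zero iff the prediction is perfectly concordant at every time point;
    prediction failures map to a large finite sentinel so optimisers continue.
    """
    from .estimator import NetworkSpreadModel  # circular-at-import, fine at call

    config = config or FitConfig()
    est = NetworkSpreadModel(
        connectome=connectome,
        seed_regions=tuple(seed_regions),
        times=data.times,
        gene=gene,
        gene_normalization=None,
        effect=mode,
        log_floor=config.log_floor,
    )
    prob = est._build_problem(data.observed)
    return est._loss(params.as_array(), prob)


def fit_spread_model(
    data: PathologyDataset,
    connectome: Connectome,
    seed_regions: Sequence[str],
    config: FitConfig | None = None,
    gene: GeneExpressionProfile | None = None,
    mode: EffectMode = "global",
    gene_normalization: str | None = None,
    fix_s: float | None = None,
) -> FitResult:
    """Bounded multi-start fit of ``(alpha, beta, gamma, s)``.

    Thin functional wrapper around :class:`synspread.estimator.NetworkSpreadModel`;
    deterministic given ``config.rng_seed``.
    """
    from .estimator import NetworkSpreadModel

    config = config or FitConfig()
    est = NetworkSpreadModel(
        connectome=connectome,
        seed_regions=tuple(seed_regions),
        times=data.times,
        gene=gene,
        gene_normalization=gene_normalization,
        effect=mode,
        alpha_bounds=config.alpha_bounds,
        beta_bounds=config.beta_bounds,
        gamma_bounds=config.gamma_bounds,
        s_bounds=config.s_bounds,
        fix_s=fix_s,
        n_starts=config.n_starts,
        log_floor=config.log_floor,
        maxiter=config.maxiter,
        tol=config.tol,
        random_state=config.rng_seed,
    )
    est.fit(data.observed)
    return est.result_
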