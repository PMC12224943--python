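"""Scikit-learn style estimator for the directionally biased spread model.

``NetworkSpreadModel`` fits the four global parameters (amplification /
clearance rate ``alpha``, diffusivity ``beta``, seed scaling ``gamma`` and
directionality ``s``) of the linear network-diffusion model

    X_hat(t) = expm((alpha I - beta L_hat(s)) t) @ X0(gamma)

to observed regional burdens by maximising Lin's concordance correlation
coefficient between log10 burdens, averaged over time points.  The mixed
Laplacian is affine in ``s`` (``L_hat(s) = (1 - s) L_ant + s L_ret``), so both
endpoint Laplacians are precomputed once per fit.

The class follows the scikit-learn contract: all constructor arguments are
stored verbatim, fitting state lives in trailing-underscore attributes, and
``get_params`` / ``set_params`` / ``clone`` work as usual, so the estimator
composes with sklearn model-selection utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import pearsonr, qmc
from sklearn.base import BaseEstimator

from .connectome import Connectome, laplacian_matrix
from .dynamics import (
    EffectMode,
    GeneExpressionProfile,
    SeedSpec,
    SpreadParameters,
    build_seed_vector,
    effective_weights,
)
from .fitting import FAILED_LOSS, FitResult, lin_ccc, masked_log10

__all__ = ["NetworkSpreadModel"]


@dataclass
class _Problem:
    """Preprocessed per-fit state shared across loss evaluations."""

    lap_ant: np.ndarray  # Laplacian at s = 0 (fully anterograde)
    lap_ret: np.ndarray  # Laplacian at s = 1 (fully retrograde)
    seed_indicator: np.ndarray  # 0/1 vector; X0 = gamma * indicator
    times: np.ndarray
    obs_logs: list[np.ndarray]
    masks: list[np.ndarray]


class NetworkSpreadModel(BaseEstimator):
    """Directionally biased connectome-diffusion model of pathology spread.

    Parameters
    ----------
    connectome:
        :class:`~synspread.connectome.Connectome` the dynamics run on.
    seed_regions:
        Labels of the injected region(s); the fitted ``gamma`` is placed there
        at t = 0.
    times:
        Months-post-injection at which burdens were observed (rows of ``X``).
    effect, gene, gene_normalization:
        Optional gene modulation of the connectome: ``"outgoing"`` scales
        efferent edges by regional expression, ``"incoming"`` afferent edges,
        ``"combined"`` both.  ``gene_normalization="mean"`` rescales the
        expression vector to unit mean before modulation.
    fix_s:
        Pin the directionality parameter (e.g. 0, 0.5 or 1 for the fixed-case
        comparisons); ``None`` fits it freely.
    n_starts, random_state:
        Multi-start count and seed; initial points are drawn from a seeded
        Latin hypercube over the box, so fits are bit-reproducible.

    Attributes
    ----------
    alpha_, beta_, gamma_, s_ : fitted parameters
    params_ : :class:`~synspread.dynamics.SpreadParameters`
    ccc_per_time_, ave_ccc_, pearson_per_time_ : concordance diagnostics
    n_regions_used_ : per-time nonzero-observation mask sizes
    status_ : ``"ok"`` or ``"failed"``
    result_ : :class:`~synspread.fitting.FitResult` summary
    """

    def __init__(
        self,
        connectome: Connectome | None = None,
        seed_regions: tuple[str, ...] = (),
        times: tuple[float, ...] = (3.0, 6.0),
        effect: EffectMode = "global",
        gene: GeneExpressionProfile | None = None,
        gene_normalization: str | None = "mean",
        alpha_bounds: tuple[float, float] = (-5.0, 5.0),
        beta_bounds: tuple[float, float] = (0.0, 20.0),
        gamma_bounds: tuple[float, float] = (1e-6, 1.0),
        s_bounds: tuple[float, float] = (0.0, 1.0),
        fix_s: float | None = None,
        n_starts: int = 20,
        log_floor: float = 1e-12,
        maxiter: int = 300,
        tol: float = 1e-10,
        random_state: int = 0,
    ) -> None:
        self.connectome = connectome
        self.seed_regions = seed_regions
        self.times = times
        self.effect = effect
        self.gene = gene
        self.gene_normalization = gene_normalization
        self.alpha_bounds = alpha_bounds
        self.beta_bounds = beta_bounds
        self.gamma_bounds = gamma_bounds
        self.s_bounds = s_bounds
        self.fix_s = fix_s
        self.n_starts = n_starts
        self.log_floor = log_floor
        self.maxiter = maxiter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _build_problem(self, observed: np.ndarray) -> _Problem:
        if self.connectome is None:
            raise ValueError("connectome is required")
        if not self.seed_regions:
            raise ValueError("seed_regions is required")
        times = np.asarray(list(self.times), dtype=float)
        observed = np.asarray(observed, dtype=float)
        if observed.ndim == 1:
            observed = observed[None, :]
        if observed.shape != (len(times), self.connectome.n_regions):
            raise ValueError(
                f"observed shape {observed.shape} != "
                f"({len(times)}, {self.connectome.n_regions})"
            )
        gene = self.gene
        if gene is not None and self.effect != "global":
            gene = gene.normalized(self.gene_normalization)
        w = effective_weights(self.connectome, gene, self.effect)
        lap_ret = laplacian_matrix(w)  # s = 1 keeps C
        lap_ant = laplacian_matrix(w.T)  # s = 0 uses the transpose
        indicator = build_seed_vector(
            self.connectome.atlas, SeedSpec(tuple(self.seed_regions), 1.0)
        )
        obs_logs, masks = [], []
        for row in observed:
            mask = np.flatnonzero(np.isfinite(row) & (row > 0))
            masks.append(mask)
            obs_logs.append(np.log10(row[mask]))
        return _Problem(lap_ant, lap_ret, indicator, times, obs_logs, masks)

    # ------------------------------------------------------------- objective

    def _predict_raw(self, theta: np.ndarray, prob: _Problem) -> np.ndarray | None:
        alpha, beta, gamma, s = theta
        lap = (1.0 - s) * prob.lap_ant + s * prob.lap_ret
        a = alpha * np.eye(lap.shape[0]) - beta * lap
        x = gamma * prob.seed_indicator
        order = np.argsort(prob.times)
        out = np.empty((len(prob.times), x.shape[0]))
        prev = 0.0
        with np.errstate(over="ignore", invalid="ignore"):
            for k in order:
                t = prob.times[k]
                if t != prev:
                    try:
                        x = expm(a * (t - prev)) @ x
                    except (ValueError, FloatingPointError):
                        return None
                    prev = t
                out[k] = x
        if not np.all(np.isfinite(out)):
            return None
        return out

    def _loss(self, theta: np.ndarray, prob: _Problem) -> float:
        pred = self._predict_raw(theta, prob)
        if pred is None:
            return FAILED_LOSS
        total = 0.0
        for row, mask, obs_log in zip(pred, prob.masks, prob.obs_logs):
            if mask.size < 2:
                return FAILED_LOSS
            pred_log = np.log10(np.maximum(row[mask], self.log_floor))
            ccc = lin_ccc(obs_log, pred_log)
            if not np.isfinite(ccc):
                return FAILED_LOSS
            total += 1.0 - ccc
        return total

    # ------------------------------------------------------------------- fit

    def fit(self, X: np.ndarray, y=None) -> "NetworkSpreadModel":
        """Fit the spread parameters to observed burdens.

        Parameters
        ----------
        X:
            Array of shape ``(n_times, n_regions)`` of observed regional
            burden fractions, rows ordered as ``self.times``.
        """
        prob = self._build_problem(X)
        if all(m.size < 2 for m in prob.masks):
            self._set_failed("fewer than two nonzero observations at every time point")
            return self

        lo = np.array(
            [self.alpha_bounds[0], self.beta_bounds[0], self.gamma_bounds[0], self.s_bounds[0]]
        )
        hi = np.array(
            [self.alpha_bounds[1], self.beta_bounds[1], self.gamma_bounds[1], self.s_bounds[1]]
        )
        if self.fix_s is not None:
            lo[3] = hi[3] = float(self.fix_s)
        free = lo < hi
        n_free = int(free.sum())

        # probe a larger Latin-hypercube batch (one loss evaluation each) and
        # launch local optimisation only from the most promising probes
        n_probes = max(8 * self.n_starts, 32)
        sampler = qmc.LatinHypercube(d=max(n_free, 1), seed=int(self.random_state))
        unit = sampler.random(n_probes)
        probes = np.tile((lo + hi) / 2.0, (n_probes, 1))
        if n_free:
            probes[:, free] = lo[free] + unit[:, :n_free] * (hi[free] - lo[free])
        probe_losses = np.array([self._loss(p, prob) for p in probes])
        order = np.argsort(probe_losses, kind="stable")
        starts = probes[order[: self.n_starts]]

        def objective(theta_free: np.ndarray) -> float:
            theta = lo.copy()
            theta[free] = theta_free
            return self._loss(theta, prob)

        best = None
        diagnostics = []
        for idx, start in enumerate(starts):
            res = minimize(
                objective,
                start[free],
                method="L-BFGS-B",
                bounds=list(zip(lo[free], hi[free])),
                options={"maxiter": self.maxiter, "ftol": self.tol, "gtol": 1e-10},
            )
            ok = res.fun < FAILED_LOSS / 2
            diagnostics.append(
                {"start": idx, "loss": float(res.fun), "nit": int(res.nit), "ok": ok}
            )
            if ok and (best is None or res.fun < best[0] - 0.0):
                best = (float(res.fun), res.x.copy(), idx)

        if best is None:
            self._set_failed("all optimisation starts failed", tuple(diagnostics))
            return self

        theta = lo.copy()
        theta[free] = best[1]
        self._finalize(theta, best[0], prob, tuple(diagnostics))
        return self

    def _set_failed(self, diagnostic: str, diagnostics: tuple = ()) -> None:
        self.status_ = "failed"
        self.diagnostic_ = diagnostic
        self.result_ = FitResult(
            parameters=None,
            ccc_per_time=(),
            ave_ccc=float("nan"),
            pearson_per_time=(),
            status="failed",
            n_regions_used=(),
            loss=float("nan"),
            start_diagnostics=diagnostics,
        )

    def _finalize(
        self, theta: np.ndarray, loss: float, prob: _Problem, diagnostics: tuple
    ) -> None:
        params = SpreadParameters(*theta)
        pred = self._predict_raw(theta, prob)
        cccs, pearsons, used = [], [], []
        for row, mask, obs_log in zip(pred, prob.masks, prob.obs_logs):
            pred_log = np.log10(np.maximum(row[mask], self.log_floor))
            cccs.append(lin_ccc(obs_log, pred_log))
            if obs_log.std() > 0 and pred_log.std() > 0:
                pearsons.append(float(pearsonr(obs_log, pred_log)[0]))
            else:
                pearsons.append(float("nan"))
            used.append(int(mask.size))
        self.alpha_, self.beta_, self.gamma_, self.s_ = map(float, theta)
        self.params_ = params
        self.loss_ = float(loss)
        self.ccc_per_time_ = tuple(cccs)
        self.ave_ccc_ = float(np.mean(cccs))
        self.pearson_per_time_ = tuple(pearsons)
        self.n_regions_used_ = tuple(used)
        self.status_ = "ok"
        self.diagnostic_ = ""
        self._problem_ = prob
        self.result_ = FitResult(
            parameters=params,
            ccc_per_time=self.ccc_per_time_,
            ave_ccc=self.ave_ccc_,
            pearson_per_time=self.pearson_per_time_,
            status="ok",
            n_regions_used=self.n_regions_used_,
            loss=self.loss_,
            start_diagnostics=diagnostics,
        )

    # --------------------------------------------------------------- predict

    def predict(self, times=None) -> np.ndarray:
        """Predicted burdens at ``times`` (default: the fitted time points)."""
        if getattr(self, "status_", None) != "ok":
            raise RuntimeError("model is not fitted (or the fit failed)")
        prob = self._problem_
        if times is not None:
            prob = _Problem(
                prob.lap_ant,
                prob.lap_ret,
                prob.seed_indicator,
                np.asarray(list(times), dtype=float),
                [],
                [],
            )
        out = self._predict_raw(self.params_.as_array(), prob)
        if out is None:
            raise RuntimeError("prediction overflowed at the fitted parameters")
        return out

    def score(self, X: np.ndarray, y=None) -> float:
        """Average CCC of log10 burdens on ``X`` at the fitted parameters."""
        if getattr(self, "status_", None) != "ok":
            raise RuntimeError("model is not fitted (or the fit failed)")
        observed = np.asarray(X, dtype=float)
        if observed.ndim == 1:
            observed = observed[None, :]
        pred = self.predict()
        cccs = []
        for obs_row, pred_row in zip(observed, pred):
            obs_log, pred_log, mask = masked_log10(obs_row, pred_row, self.log_floor)
            if mask.size < 2:
                return float("nan")
            cccs.append(lin_ccc(obs_log, pred_log))
        return float(np.mean(cccs))
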