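"""Maximum-likelihood fitting, bootstrap confidence intervals, threshold
extraction, and BIC model comparison.

All fits maximize a log-likelihood in nats: binomial per stimulus level for
the psychometric-function fit, Bernoulli per trial for the image-computable
models.  Probabilities are clamped to ``[1e-9, 1 - 1e-9]`` so the likelihood
stays finite.  Optimization is bounded local search (L-BFGS-B on
log-transformed gains/exponents) launched from a documented grid of start
points; the best converged start wins.

Model comparison uses ``BIC = ln L - (K/2) ln n`` -- the log-posterior
approximation in which *larger* is better and the difference of two BICs,
exponentiated, is a posterior odds ratio.

The two-stage (IC-2) fit profiles the first-stage surround strength
``rho_IE`` over a discrete grid (the convolution stage is recomputed per
``rho_IE``, cheaply, as a linear combination of cached center/surround
convolutions), profiles the first-stage exponent ``p1`` by bracketed 1-D
search (``p1`` enters only through the pooling step), and optimizes the
second-stage parameters ``(p2, g2)`` on the pooled channel responses from the
3 x 5 grid of starts.  If the best ``rho_IE`` lands on an end of the grid,
the grid is extended one step at a time until the optimum is interior (or a
hard bound is hit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from ltbseg.models import IC1Params, IC2Params, SDTParams, IC2Engine, get_engine
from ltbseg.stimulus import StimulusImage

P_CLAMP = 1e-9
GAIN_BOUNDS = (1e-6, 1e4)
EXP_BOUNDS = (0.1, 10.0)
RHO_GRID_DEFAULT = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)
RHO_STEP = 0.05
RHO_HARD_BOUNDS = (0.0, 1.0)


def bic(logL: float, K: int, n: int) -> float:
    """Bayes information criterion, ``ln L - (K/2) ln n`` (larger is better)."""
    return float(logL) - 0.5 * K * np.log(n)


@dataclass
class FitResult:
    """One fitted model: parameters, likelihood, and BIC."""

    model_id: str
    params: object
    logL: float
    K: int
    n: int
    converged: bool = True
    start_points: dict = field(default_factory=dict)

    @property
    def BIC(self) -> float:
        return bic(self.logL, self.K, self.n)

    def to_dict(self) -> dict:
        import dataclasses
        p = (dataclasses.asdict(self.params)
             if dataclasses.is_dataclass(self.params) else dict(self.params))
        return {"model_id": self.model_id, "params": p, "logL": self.logL,
                "K": self.K, "n": self.n, "BIC": self.BIC,
                "converged": self.converged}


def _clamp(p):
    return np.clip(p, P_CLAMP, 1.0 - P_CLAMP)


def _bernoulli_ll(prob_R: np.ndarray, resp_R: np.ndarray) -> float:
    p = _clamp(prob_R)
    return float(np.sum(np.where(resp_R, np.log(p), np.log1p(-p))))


# ---------------------------------------------------------------------------
# SDT psychometric function

def _sdt_nll(theta, levels, n_correct, n_trials, with_lapse):
    log_g, log_tau = theta[0], theta[1]
    lam = theta[2] if with_lapse else 0.0
    d = np.power(np.exp(log_g) * levels, np.exp(log_tau))
    pc = _clamp(lam / 2 + (1 - lam) * ndtr(d / 2))
    return -float(np.sum(n_correct * np.log(pc)
                         + (n_trials - n_correct) * np.log(1 - pc)))


def fit_sdt(levels, n_correct, n_trials, with_lapse: bool = False) -> FitResult:
    """Fit the SDT psychometric function to per-level binomial counts.

    Maximizes the binomial log-likelihood over ``(g, tau)`` (plus the lapse
    rate in ``[0, 0.1]`` when ``with_lapse``) from a grid of start points.
    Raises on fewer than two distinct stimulus levels and on degenerate data
    (all trials correct, or all incorrect, at every level), which leave the
    gain unidentifiable.
    """
    levels = np.asarray(levels, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    if len(np.unique(levels)) < 2:
        raise ValueError("need at least 2 distinct stimulus levels to fit")
    if np.any(n_trials <= 0):
        raise ValueError("every level must have at least one trial")
    if np.all(n_correct == n_trials):
        raise ValueError("degenerate data: all trials correct at every level; "
                         "the psychometric function is unidentifiable")
    if np.all(n_correct == 0):
        raise ValueError("degenerate data: no correct trials at any level")

    x_scale = float(np.median(levels[levels > 0]))
    g_starts = np.array([0.3, 1.0, 3.0, 10.0, 30.0]) / x_scale
    tau_starts = (0.5, 1.0, 2.0, 4.0)
    bounds = [(np.log(GAIN_BOUNDS[0]), np.log(GAIN_BOUNDS[1])),
              (np.log(EXP_BOUNDS[0]), np.log(EXP_BOUNDS[1]))]
    if with_lapse:
        bounds.append((0.0, 0.1))

    best = None
    for g0 in g_starts:
        for t0 in tau_starts:
            theta0 = [np.log(g0), np.log(t0)] + ([0.02] if with_lapse else [])
            res = optimize.minimize(
                _sdt_nll, theta0, args=(levels, n_correct, n_trials, with_lapse),
                method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
    params = SDTParams(g=float(np.exp(best.x[0])), tau=float(np.exp(best.x[1])),
                       lam=float(best.x[2]) if with_lapse else 0.0)
    return FitResult("sdt_lapse" if with_lapse else "sdt", params,
                     logL=-best.fun, K=3 if with_lapse else 2,
                     n=int(n_trials.sum()), converged=bool(best.success),
                     start_points={"g": list(g_starts), "tau": list(tau_starts)})


def threshold(params: SDTParams, target: float = 0.75) -> float:
    """Stimulus level at which the fitted function predicts ``target`` correct.

    Inverts the psychometric function (accounting for the lapse rate when
    present).  ``target = 0.5`` maps to level 0.
    """
    q = (target - params.lam / 2) / (1 - params.lam)
    if not 0.5 <= q < 1.0:
        raise ValueError(f"target {target} unreachable for lapse {params.lam}")
    d = 2.0 * ndtri(q)
    if d <= 0.0:
        return 0.0
    return float(d ** (1.0 / params.tau) / params.g)


@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs for psychometric parameters and threshold."""

    param_ci: dict
    threshold_ci: tuple
    param_samples: dict
    threshold_samples: np.ndarray
    n_failed: int
    degenerate: bool


def bootstrap_pf(levels, n_correct, n_trials, B: int = 200,
                 with_lapse: bool = False, target: float = 0.75,
                 level: float = 0.95, seed: Optional[int] = None) -> BootstrapResult:
    """Parametric bootstrap of the psychometric-function fit.

    For each of ``B`` resamples, the correct count at every stimulus level is
    redrawn from ``Binomial(n_i, p_i)`` with ``p_i`` the observed proportion,
    the model is refit, and percentile confidence intervals are formed for
    the parameters and the ``target`` threshold.  Resamples whose fits fail
    (degenerate draws) are counted in ``n_failed``; fully degenerate input
    (every observed proportion 0 or 1) is flagged.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    n_correct = np.asarray(n_correct, dtype=int)
    n_trials = np.asarray(n_trials, dtype=int)
    p_obs = n_correct / n_trials
    degenerate = bool(np.all((p_obs == 0) | (p_obs == 1)))

    names = ["g", "tau"] + (["lam"] if with_lapse else [])
    samples = {k: [] for k in names}
    thr_samples = []
    n_failed = 0
    for _ in range(B):
        c_star = rng.binomial(n_trials, p_obs)
        try:
            fit = fit_sdt(levels, c_star, n_trials, with_lapse=with_lapse)
            thr_samples.append(threshold(fit.params, target))
        except ValueError:
            n_failed += 1
            continue
        for k in names:
            samples[k].append(getattr(fit.params, k if k != "lam" else "lam"))
    if not thr_samples:
        raise ValueError("all bootstrap resamples were degenerate; "
                         "cannot form confidence intervals")

    alpha = (1.0 - level) / 2
    qs = (100 * alpha, 100 * (1 - alpha))
    param_ci = {k: tuple(np.percentile(samples[k], qs)) for k in names}
    thr = np.asarray(thr_samples)
    return BootstrapResult(param_ci=param_ci,
                           threshold_ci=tuple(np.percentile(thr, qs)),
                           param_samples={k: np.asarray(v) for k, v in samples.items()},
                           threshold_samples=thr,
                           n_failed=n_failed, degenerate=degenerate)


# ---------------------------------------------------------------------------
# IC-1 (one-stage) model

def _ic1_nll(theta, L_R, L_L, C, resp_R, divisive):
    g1, p1 = np.exp(theta[0]), np.exp(theta[1])
    if divisive:
        g2, tau2 = np.exp(theta[2]), np.exp(theta[3])
        den = 1.0 + np.power(g2 * C, tau2)
    else:
        den = 1.0
    u = (np.power(g1 * L_R, p1) - np.power(g1 * L_L, p1)) / den
    return -_bernoulli_ll(ndtr(u), resp_R)


def fit_ic1(L_R, L_L, C, resp_R, divisive: bool = False) -> FitResult:
    """Fit the one-stage model to per-trial features and binary responses.

    ``resp_R`` is True where the response was "right-oblique".  The additive
    form has K = 2 free parameters ``(g1, p1)``; with ``divisive=True`` the
    contrast-normalization pair ``(g2, tau2)`` is added (K = 4).
    """
    L_R = np.asarray(L_R, dtype=float)
    L_L = np.asarray(L_L, dtype=float)
    C = np.asarray(C, dtype=float)
    resp_R = np.asarray(resp_R, dtype=bool)
    if L_R.size == 0:
        raise ValueError("no trials supplied")

    scale = float(np.median(np.maximum(L_R, L_L)))
    if scale <= 0:
        scale = 1.0
    g1_starts = np.array([0.3, 1.0, 3.0, 10.0]) / scale
    g1_starts = np.clip(g1_starts, *GAIN_BOUNDS)
    p_starts = (0.5, 1.0, 2.0)
    log_gain_b = (np.log(GAIN_BOUNDS[0]), np.log(GAIN_BOUNDS[1]))
    log_exp_b = (np.log(EXP_BOUNDS[0]), np.log(EXP_BOUNDS[1]))
    bounds = [log_gain_b, log_exp_b] + ([log_gain_b, log_exp_b] if divisive else [])

    best = None
    for g0 in g1_starts:
        for p0 in p_starts:
            theta0 = [np.log(g0), np.log(p0)]
            if divisive:
                theta0 += [np.log(1.0), 0.0]
            res = optimize.minimize(
                _ic1_nll, theta0, args=(L_R, L_L, C, resp_R, divisive),
                method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
    th = best.x
    params = IC1Params(g1=float(np.exp(th[0])), p1=float(np.exp(th[1])),
                       g2=float(np.exp(th[2])) if divisive else 0.0,
                       tau2=float(np.exp(th[3])) if divisive else 1.0)
    return FitResult("ic1_div" if divisive else "ic1", params,
                     logL=-best.fun, K=4 if divisive else 2, n=int(L_R.size),
                     converged=bool(best.success),
                     start_points={"g1": list(g1_starts), "p1": list(p_starts)})


# ---------------------------------------------------------------------------
# IC-2 (two-stage) model

class _IC2Data:
    """Cached center/surround convolutions and pool indexing for a trial set."""

    def __init__(self, images: Sequence[StimulusImage], engine: IC2Engine):
        self.engine = engine
        C_rows, S_rows = [], []
        for img in images:
            c, s = engine.conv_cs(img)
            C_rows.append(c.astype(np.float32))
            S_rows.append(s.astype(np.float32))
        self.C = np.vstack(C_rows)
        self.S = np.vstack(S_rows)
        # (npix, 4) half-mean weights: columns R+, R-, L+, L-
        W = np.zeros((self.C.shape[1], 4), dtype=np.float32)
        for j, key in enumerate((("R", +1), ("R", -1), ("L", +1), ("L", -1))):
            idx = np.nonzero(engine._halves[key])[0]
            W[idx, j] = 1.0 / idx.size
        self._W = W

    _rho_cache: tuple = (None, None, None)

    def _signed_log_response(self, rho: float):
        """Cache (log|V|, positive-sign mask) for the current rho; p1 then
        costs a single exp instead of two pows."""
        if self._rho_cache[0] != rho:
            V = self.C - np.float32(rho) * self.S
            with np.errstate(divide="ignore"):
                logabs = np.log(np.abs(V), dtype=np.float32)
            self._rho_cache = (rho, logabs, V > 0)
        return self._rho_cache[1], self._rho_cache[2]

    def pool_matrix(self, rho: float, p1: float) -> np.ndarray:
        """(n_trials, 4) pooled channel responses, columns
        [L_R_ON, L_R_OFF, L_L_ON, L_L_OFF]."""
        if self.engine.order == "rectify_then_pool":
            logabs, pos = self._signed_log_response(rho)
            a = np.exp(np.float32(p1) * logabs)  # |V|^p1; exp(-inf) = 0 at V=0
            on = np.where(pos, a, np.float32(0.0))
            off = a - on
            m_on = on @ self._W  # half means per diagonal
            m_off = off @ self._W
            cols = [np.abs(m_on[:, 0] - m_on[:, 1]),
                    np.abs(m_off[:, 0] - m_off[:, 1]),
                    np.abs(m_on[:, 2] - m_on[:, 3]),
                    np.abs(m_off[:, 2] - m_off[:, 3])]
        else:
            V = self.C - np.float32(rho) * self.S
            m = V @ self._W
            cols = []
            for a, b in ((0, 1), (2, 3)):
                mp, mm = m[:, a], m[:, b]
                cols.append(np.abs(np.maximum(mp, 0)**p1 - np.maximum(mm, 0)**p1))
                cols.append(np.abs(np.maximum(-mp, 0)**p1 - np.maximum(-mm, 0)**p1))
        return np.column_stack(cols).astype(np.float64)


_SIGNS = np.array([1.0, 1.0, -1.0, -1.0])


def _ic2_inner_nll(theta, P, resp_R):
    g2, p2 = np.exp(theta[0]), np.exp(theta[1])
    u = np.power(g2 * P, p2) @ _SIGNS
    return -_bernoulli_ll(ndtr(u), resp_R)


def _ic2_fit_second_stage(P, resp_R, p2_starts, g2_starts):
    log_gain_b = (np.log(GAIN_BOUNDS[0]), np.log(GAIN_BOUNDS[1]))
    log_exp_b = (np.log(EXP_BOUNDS[0]), np.log(EXP_BOUNDS[1]))
    best = None
    for g0 in g2_starts:
        for p0 in p2_starts:
            res = optimize.minimize(
                _ic2_inner_nll, [np.log(g0), np.log(p0)], args=(P, resp_R),
                method="L-BFGS-B", bounds=[log_gain_b, log_exp_b],
                options={"ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
    return best


def _ic2_profile_p1(data: _IC2Data, resp_R, rho, p1_starts, p2_starts, g2_starts):
    """Profile log-likelihood over p1 at a fixed rho: coarse grid then a
    bracketed golden-section refinement on log(p1)."""
    cache = {}

    def nll_at(p1):
        key = round(float(p1), 6)
        if key not in cache:
            P = data.pool_matrix(rho, p1)
            # rescale pools to O(1) so the g2 grid starts are meaningful
            scale = float(np.median(P[P > 0])) if np.any(P > 0) else 1.0
            res = _ic2_fit_second_stage(P / scale, resp_R, p2_starts,
                                        np.asarray(g2_starts))
            g2 = float(np.exp(res.x[0])) / scale
            cache[key] = (res.fun, g2, float(np.exp(res.x[1])), bool(res.success))
        return cache[key][0]

    grid = sorted(p1_starts)
    vals = [nll_at(p) for p in grid]
    i = int(np.argmin(vals))
    lo = grid[i - 1] if i > 0 else max(EXP_BOUNDS[0], grid[0] / 2)
    hi = grid[i + 1] if i < len(grid) - 1 else min(EXP_BOUNDS[1], grid[-1] * 2)
    res = optimize.minimize_scalar(
        lambda t: nll_at(np.exp(t)), bounds=(np.log(lo), np.log(hi)),
        method="bounded", options={"xatol": 0.02, "maxiter": 15})
    p1_best = min(cache, key=lambda k: cache[k][0])
    nll, g2, p2, ok = cache[p1_best]
    return {"p1": float(p1_best), "p2": p2, "g2": g2, "nll": nll,
            "converged": ok and bool(res.success)}


def fit_ic2(images: Sequence[StimulusImage], resp_R,
            rho_grid: Sequence[float] = RHO_GRID_DEFAULT,
            engine: Optional[IC2Engine] = None,
            p1_starts: Sequence[float] = (0.5, 1.0, 2.0),
            p2_starts: Sequence[float] = (0.5, 1.0, 2.0),
            g2_starts: Optional[Sequence[float]] = None,
            extend_grid: bool = True) -> FitResult:
    """Fit the two-stage model to per-trial stimuli and binary responses.

    ``rho_IE`` is profiled over ``rho_grid``; if the optimum lands on a grid
    endpoint and ``extend_grid`` is set, the grid grows one 0.05 step at a
    time (down to 0.0 or up to 1.0) until the optimum is interior.  K = 4.
    """
    resp_R = np.asarray(resp_R, dtype=bool)
    if len(images) == 0:
        raise ValueError("no trials supplied")
    if len(images) != resp_R.size:
        raise ValueError("images and responses must have equal length")
    if g2_starts is None:
        g2_starts = np.logspace(-3, 1, 5)
    if engine is None:
        img = images[0]
        engine = get_engine(img.image_size, img.resolved_disc_radius())

    data = _IC2Data(images, engine)
    profile: dict[float, dict] = {}

    def evaluate(rho):
        if rho not in profile:
            profile[rho] = _ic2_profile_p1(data, resp_R, rho, p1_starts,
                                           p2_starts, g2_starts)

    grid = sorted(float(r) for r in rho_grid)
    for rho in grid:
        evaluate(rho)
    while extend_grid:
        best_rho = min(profile, key=lambda r: profile[r]["nll"])
        lo, hi = min(profile), max(profile)
        if best_rho <= lo and lo > RHO_HARD_BOUNDS[0] + 1e-12:
            evaluate(round(max(lo - RHO_STEP, RHO_HARD_BOUNDS[0]), 6))
        elif best_rho >= hi and hi < RHO_HARD_BOUNDS[1] - 1e-12:
            evaluate(round(min(hi + RHO_STEP, RHO_HARD_BOUNDS[1]), 6))
        else:
            break

    best_rho = min(profile, key=lambda r: profile[r]["nll"])
    entry = profile[best_rho]
    if not any(v["converged"] for v in profile.values()):
        raise RuntimeError("IC-2 fit failed to converge at every rho_IE")
    params = IC2Params(rho_IE=best_rho, p1=entry["p1"], p2=entry["p2"],
                       g2=entry["g2"])
    return FitResult("ic2", params, logL=-entry["nll"], K=4, n=int(resp_R.size),
                     converged=entry["converged"],
                     start_points={"rho_grid": sorted(profile),
                                   "rho_profile": {r: profile[r]["nll"]
                                                   for r in sorted(profile)},
                                   "p1": list(p1_starts), "p2": list(p2_starts),
                                   "g2": [float(g) for g in np.asarray(g2_starts)]})
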