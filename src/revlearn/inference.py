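"""Model fitting and evidence approximation.

Parameters are estimated by maximum a posteriori (MAP) optimization on a
transformed (unconstrained) scale with Gaussian priors, using BFGS from
multiple restarts. Model goodness is summarized by the log-model evidence
(LME) under the Laplace approximation — the negative variational free
energy — and by the BIC. 'Bayes-optimal' perceptual parameters minimize the
cumulative Shannon surprise of a fixed input sequence, independently of any
responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .agents import HGFParams, HGFState, RWParams, RandomParams, WSLSParams, softmax

__all__ = [
    "PriorSpec",
    "FitResult",
    "default_priors",
    "choice_probabilities",
    "negative_log_likelihood",
    "bayes_optimal_params",
    "fit_map",
    "laplace_lme",
    "bic",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# transforms and priors

_TRANSFORMS = {
    "identity": (lambda x: x, lambda z: z),
    "log": (np.log, np.exp),
    "logit": (lambda x: np.log(x / (1.0 - x)), lambda z: 1.0 / (1.0 + np.exp(-z))),
}


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior on a transformed parameter scale.

    ``transform`` maps the natural domain to the real line (identity, log or
    logit); the prior is Normal(mean, var) on that transformed scale.
    """

    transform: str
    mean: float
    var: float

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.var <= 0:
            raise ValueError("prior variance must be > 0")

    def to_transformed(self, x: float) -> float:
        return float(_TRANSFORMS[self.transform][0](x))

    def to_natural(self, z: float) -> float:
        return float(_TRANSFORMS[self.transform][1](z))

    def log_pdf(self, z: float) -> float:
        return float(stats.norm.logpdf(z, self.mean, np.sqrt(self.var)))

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mean, np.sqrt(self.var)))


def default_priors(model: str) -> dict[str, PriorSpec]:
    """Weakly-informative priors centered near the simulation regime."""
    table = {
        "random": {"b": PriorSpec("logit", 0.0, 1.0)},
        "wsls": {"epsilon": PriorSpec("logit", 0.0, 1.0)},
        "rw": {
            "alpha": PriorSpec("logit", 0.0, 1.0),
            "beta": PriorSpec("log", float(np.log(5.0)), 1.0),
        },
        "hgf": {
            "omega": PriorSpec("identity", -3.0, 16.0),
            "zeta": PriorSpec("log", 0.0, 1.0),
        },
    }
    if model not in table:
        raise ValueError(f"unknown model {model!r}")
    return table[model]


_PARAM_CLASSES = {
    "random": RandomParams,
    "wsls": WSLSParams,
    "rw": RWParams,
    "hgf": HGFParams,
}


def _make_params(model: str, values: dict):
    return _PARAM_CLASSES[model](**values)


# ---------------------------------------------------------------------------
# likelihood

_BLOCK_KEYS = ["subject", "run", "block"]


def _iter_blocks(trials: pd.DataFrame):
    keys = [k for k in _BLOCK_KEYS if k in trials.columns]
    if not keys:
        yield trials
        return
    for _, grp in trials.groupby(keys, sort=False):
        yield grp


def choice_probabilities(model: str, params, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial probability of the mapping choice y = 1.

    State (values, beliefs, previous choice) resets at each block boundary.
    """
    out = np.empty(len(trials))
    pos = 0
    for block in _iter_blocks(trials):
        y = block["y"].to_numpy()
        outcome = block["outcome"].to_numpy()
        n = len(block)
        if model == "random":
            out[pos : pos + n] = params.b
        elif model == "wsls":
            e2 = params.epsilon / 2.0
            p = np.empty(n)
            p[0] = 0.5
            prev_right = (y[:-1] == 1) == (outcome[:-1] == 1)
            p[1:] = np.where(prev_right, 1.0 - e2, e2)
            out[pos : pos + n] = p
        elif model == "rw":
            v = {1: params.v0, 0: params.v0}
            for t in range(n):
                out[pos + t] = softmax(np.array([v[1], v[0]]), params.beta)[0]
                yt = int(y[t])
                v[yt] = v[yt] + params.alpha * (outcome[t] - v[yt])
        elif model == "hgf":
            from .agents import hgf_response_prob

            u1 = block["u1"].to_numpy()
            state = HGFState(params)
            for t in range(n):
                out[pos + t] = hgf_response_prob(state.predict(), params.zeta)
                state.update(int(u1[t]))
        else:
            raise ValueError(f"unknown model {model!r}")
        pos += n
    return out


def negative_log_likelihood(model: str, params, trials: pd.DataFrame) -> float:
    """-sum_t log p(y_t | history, params) over valid trials.

    A zero-probability observed response yields +inf (with a warning), never
    an exception, so optimizers can recover via the line search.
    """
    if "valid" in trials.columns:
        trials = trials[trials["valid"].astype(bool)]
    p1 = choice_probabilities(model, params, trials)
    y = trials["y"].to_numpy()
    p_obs = np.where(y == 1, p1, 1.0 - p1)
    if np.any(p_obs <= 0.0):
        warnings.warn(
            f"{model}: observed response has zero probability; NLL = +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(-np.log(p_obs).sum())


# ---------------------------------------------------------------------------
# Bayes-optimal perceptual parameters

_BAYES_OPTIMAL_BOUNDS = {"hgf": (-12.0, 3.0), "rw": (1e-3, 1.0 - 1e-3)}


def _surprise(model: str, value: float, sequences: list[np.ndarray]) -> float:
    """Cumulative Shannon surprise of binary inputs under the perceptual model."""
    total = 0.0
    for seq in sequences:
        if model == "hgf":
            state = HGFState(HGFParams(omega=value, zeta=1.0))
            for u in seq:
                p = min(max(state.predict(), 1e-12), 1.0 - 1e-12)
                total -= np.log(p if u == 1 else 1.0 - p)
                state.update(int(u))
        else:  # rw: a single tracked probability, clipped away from 0/1
            v = 0.5
            for u in seq:
                p = min(max(v, 1e-12), 1.0 - 1e-12)
                total -= np.log(p if u == 1 else 1.0 - p)
                v = v + value * (u - v)
    return float(total)


def bayes_optimal_params(model: str, u1_sequence) -> float:
    """Perceptual parameter (omega for HGF, alpha for RW) minimizing surprise.

    ``u1_sequence`` is a binary array or a list of per-block binary arrays
    (the filter restarts at each block).
    """
    if model not in _BAYES_OPTIMAL_BOUNDS:
        raise ValueError(f"no Bayes-optimal parameter defined for model {model!r}")
    if isinstance(u1_sequence, (list, tuple)):
        sequences = [np.asarray(s) for s in u1_sequence]
    else:
        sequences = [np.asarray(u1_sequence)]
    lo, hi = _BAYES_OPTIMAL_BOUNDS[model]
    probes = np.linspace(lo, hi, 7)
    vals = [_surprise(model, p, sequences) for p in probes]
    if np.ptp(vals) < 1e-12:
        warnings.warn("surprise objective is flat; returning interval midpoint")
        return float((lo + hi) / 2.0)
    res = optimize.minimize_scalar(
        lambda v: _surprise(model, v, sequences),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# MAP fitting


@dataclass
class FitResult:
    """MAP fit of one model to one subject's responses."""

    model: str
    params: dict[str, float]  # natural scale
    nll: float
    log_joint: float
    lme: float | None
    bic: float | None
    n_trials: int
    converged: bool
    n_restarts: int
    theta_map: np.ndarray = field(repr=False)  # transformed scale
    param_names: list[str] = field(repr=False, default_factory=list)
    priors: dict[str, PriorSpec] = field(repr=False, default_factory=dict)
    _neg_log_joint: object = field(repr=False, default=None, compare=False)

    @property
    def d(self) -> int:
        return len(self.param_names)


def _neg_log_joint_fn(model: str, trials: pd.DataFrame, priors: dict[str, PriorSpec]):
    names = list(priors)

    def fn(theta: np.ndarray) -> float:
        natural = {n: priors[n].to_natural(z) for n, z in zip(names, theta)}
        try:
            params = _make_params(model, natural)
        except ValueError:
            return float("inf")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            nll = negative_log_likelihood(model, params, trials)
        log_prior = sum(priors[n].log_pdf(z) for n, z in zip(names, theta))
        return nll - log_prior

    return names, fn


def fit_map(
    model: str,
    trials: pd.DataFrame,
    priors: dict[str, PriorSpec] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    compute_evidence: bool = True,
) -> FitResult:
    """MAP estimation by BFGS from ``n_restarts`` prior-drawn initializations.

    Maximizes log-likelihood + log-prior on the transformed scale and
    returns natural-scale estimates together with LME (Laplace) and BIC.
    """
    priors = priors if priors is not None else default_priors(model)
    names, nlj = _neg_log_joint_fn(model, trials, priors)
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(max(1, n_restarts)):
        x0 = np.array([priors[n].sample(rng) for n in names])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nlj, x0, method="BFGS")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        any_converged = any_converged or bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {n_restarts} restarts failed to produce a finite log-joint "
            f"for model {model!r}"
        )
    theta = np.asarray(best.x, dtype=float)
    natural = {n: priors[n].to_natural(z) for n, z in zip(names, theta)}
    params_obj = _make_params(model, natural)
    nll = negative_log_likelihood(model, params_obj, trials)
    n_valid = int(trials["valid"].sum()) if "valid" in trials.columns else len(trials)
    fit = FitResult(
        model=model,
        params=natural,
        nll=float(nll),
        log_joint=float(-best.fun),
        lme=None,
        bic=None,
        n_trials=n_valid,
        converged=any_converged,
        n_restarts=n_restarts,
        theta_map=theta,
        param_names=names,
        priors=priors,
        _neg_log_joint=nlj,
    )
    fit.bic = bic(fit, n_valid)
    if compute_evidence:
        fit.lme = laplace_lme(fit)
    return fit


# ---------------------------------------------------------------------------
# evidence


def _fd_hessian(fn, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (full stencil, symmetric)."""
    d = len(x)
    H = np.empty((d, d))
    f0 = fn(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (fn(x + ei) - 2.0 * f0 + fn(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def laplace_lme(fit: FitResult, trials: pd.DataFrame | None = None) -> float:
    """Log-model evidence: log-joint + (d/2) log 2*pi - 0.5 log det H.

    H is the finite-difference Hessian of the negative log-joint at the MAP
    on the transformed scale. A non-positive-definite H is repaired by
    clipping its eigenvalues (with a warning).
    """
    nlj = fit._neg_log_joint
    if nlj is None:
        raise ValueError("FitResult carries no objective; refit with fit_map")
    H = _fd_hessian(nlj, fit.theta_map)
    eigvals = np.linalg.eigvalsh(H)
    if np.any(eigvals <= 0):
        warnings.warn(
            "Hessian not positive definite at the MAP; clipping eigenvalues",
            RuntimeWarning,
        )
        w, V = np.linalg.eigh(H)
        w = np.clip(w, 1e-8, None)
        H = V @ np.diag(w) @ V.T
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        raise RuntimeError("singular Hessian after eigenvalue repair")
    d = fit.d
    return float(fit.log_joint + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet)


def bic(fit: FitResult, n_trials: int) -> float:
    """Bayesian information criterion: 2*NLL + d*ln(n). Smaller is better."""
    return float(2.0 * fit.nll + fit.d * np.log(n_trials))


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    model: str,
    trials: pd.DataFrame,
    priors: dict[str, PriorSpec] | None = None,
    n_restarts: int = 4,
    seed: int = 0,
) -> float:
    """Leave-one-run-out mean held-out log predictive probability.

    Fits on all runs but one, scores mean log p(y_t) on the held-out run
    (per-block state reset applies as usual), and averages over folds.
    """
    runs = trials["run"].unique()
    if len(runs) < 2:
        raise ValueError("cross-validation needs at least two runs")
    scores = []
    for held in runs:
        train = trials[trials["run"] != held]
        test = trials[trials["run"] == held]
        if test["block"].nunique() < 1 or train["block"].nunique() < 1:
            raise ValueError("fold with no complete block")
        fit = fit_map(
            model, train, priors=priors, n_restarts=n_restarts, seed=seed,
            compute_evidence=False,
        )
        params = _make_params(model, fit.params)
        p1 = choice_probabilities(model, params, test)
        y = test["y"].to_numpy()
        p_obs = np.where(y == 1, p1, 1.0 - p1)
        scores.append(float(np.log(np.clip(p_obs, 1e-300, None)).mean()))
    return float(np.mean(scores))
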