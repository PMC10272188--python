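"""Closed-loop simulators for the four behavioral models.

All four agents choose between the two latent stimulus-response mappings
(y = 1: stimulus1->Go / stimulus2->NoGo; y = 0: the reverse) rather than
between motor responses, so a single choice variable covers both stimuli.

Models
------
Random      p(y=1) = b each trial, independent of history.
WSLS        noisy win-stay-lose-switch: repeat the previous mapping choice
            with probability 1 - eps/2 after reward, eps/2 after no reward.
Rescorla-Wagner
            delta-rule value learning over the two mappings with a constant
            learning rate alpha and a softmax(beta) choice rule; only the
            chosen option's value is updated.
HGF         two-level Hierarchical Gaussian Filter over the binary mapping
            evidence u1, with volatility coupling switched off. Belief
            updates are prediction errors weighted by a trial-by-trial
            precision weight phi2 that acts as a dynamic learning rate.
            Responses follow the unit-square sigmoid with determinism zeta.

Perceptual state resets at each block start (each block introduces a fresh
stimulus pair); parameters are shared across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import (
    GO,
    NOGO,
    BlockDesign,
    TaskConfig,
    encode_model_input,
    play_trial,
    response_for_mapping,
)

TRAJECTORY_COLUMNS = [
    "subject",
    "run",
    "block",
    "trial",
    "stimulus",
    "u1",
    "u1hat",
    "u2",
    "phi2",
    "delta1",
    "abs_delta1",
    "p_choice",
    "y",
    "response",
    "outcome",
    "outcome_category",
    "correct",
    "phase",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RandomParams:
    b: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"bias b must be in [0, 1], got {self.b}")


@dataclass(frozen=True)
class WSLSParams:
    epsilon: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"lapse epsilon must be in [0, 1], got {self.epsilon}")


@dataclass(frozen=True)
class RWParams:
    alpha: float = 0.3
    beta: float = 5.0
    v0: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"learning rate alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"inverse temperature beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError(f"initial value v0 must be in [0, 1], got {self.v0}")


@dataclass(frozen=True)
class HGFParams:
    omega: float = -3.0
    zeta: float = 0.5
    u2_0: float = 0.0
    phi2_0: float = 1.0
    # third-level constants are fixed at zero in the two-level variant
    theta: float = 0.0
    kappa: float = 0.0

    def __post_init__(self):
        if self.phi2_0 <= 0:
            raise ValueError(f"initial variance phi2_0 must be > 0, got {self.phi2_0}")
        if self.zeta < 0:
            raise ValueError(f"determinism zeta must be >= 0, got {self.zeta}")
        if self.theta != 0.0 or self.kappa != 0.0:
            raise ValueError("two-level variant requires theta = kappa = 0")


# ---------------------------------------------------------------------------
# model primitives


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


def rw_step(v_prev: float, r_prev: float, alpha: float) -> float:
    """Delta-rule update V <- V + alpha * (r - V)."""
    return v_prev + alpha * (r_prev - v_prev)


def softmax(values: np.ndarray, beta: float) -> np.ndarray:
    """Two-or-more-option softmax choice probabilities at inverse temp beta."""
    if beta < 0:
        raise ValueError(f"inverse temperature beta must be >= 0, got {beta}")
    z = beta * np.asarray(values, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def hgf_response_prob(u1hat: np.ndarray | float, zeta: float) -> np.ndarray | float:
    """Unit-square sigmoid: p(y=1) = u1hat^zeta / (u1hat^zeta + (1-u1hat)^zeta).

    zeta = 0 gives indifferent responding (p = 1/2); zeta = 1 is probability
    matching (p = u1hat); zeta -> inf approaches deterministic choice of the
    currently more probable mapping.
    """
    if zeta < 0:
        raise ValueError(f"zeta must be >= 0, got {zeta}")
    u = np.asarray(u1hat, dtype=float)
    a = u**zeta
    b = (1.0 - u) ** zeta
    out = a / (a + b)
    return float(out) if np.isscalar(u1hat) else out


@dataclass
class HGFTrajectory:
    """Per-trial belief trajectory of the two-level binary HGF."""

    u1: np.ndarray
    u1hat: np.ndarray  # prediction s(u2_prev), in (0, 1)
    phi1hat: np.ndarray  # Bernoulli variance of the prediction
    phi2hat: np.ndarray  # predicted level-2 variance phi2_prev + e^omega
    phi2: np.ndarray  # posterior precision weight (dynamic learning rate)
    delta1: np.ndarray  # outcome prediction error u1 - u1hat
    u2: np.ndarray  # posterior mean of the level-2 belief

    @property
    def abs_delta1(self) -> np.ndarray:
        """Unsigned prediction error (Bayesian surprise magnitude)."""
        return np.abs(self.delta1)


class HGFState:
    """Sequential two-level HGF update over binary inputs."""

    def __init__(self, params: HGFParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.u2 = self.params.u2_0
        self.phi2 = self.params.phi2_0

    def predict(self) -> float:
        """Prior outcome probability for the upcoming trial."""
        return float(sigmoid(self.u2))

    def update(self, u1: int) -> dict:
        """One filtering step; returns the trial's belief quantities."""
        if u1 not in (0, 1):
            raise ValueError(f"HGF input must be binary, got {u1!r}")
        u1hat = self.predict()
        phi1hat = u1hat * (1.0 - u1hat)
        phi2hat = self.phi2 + np.exp(self.params.omega)
        phi2 = 1.0 / (1.0 / phi2hat + phi1hat)
        delta1 = u1 - u1hat
        self.u2 = self.u2 + phi2 * delta1
        self.phi2 = phi2
        return {
            "u1hat": u1hat,
            "phi1hat": phi1hat,
            "phi2hat": phi2hat,
            "phi2": phi2,
            "delta1": delta1,
            "u2": self.u2,
        }


def hgf_filter(u1_sequence: np.ndarray, params: HGFParams) -> HGFTrajectory:
    """Filter a binary input sequence, returning the full belief trajectory."""
    u1_sequence = np.asarray(u1_sequence)
    if not np.isin(u1_sequence, (0, 1)).all():
        raise ValueError("HGF input sequence must be binary")
    n = len(u1_sequence)
    cols = {k: np.empty(n) for k in ("u1hat", "phi1hat", "phi2hat", "phi2", "delta1", "u2")}
    state = HGFState(params)
    for t, u1 in enumerate(u1_sequence):
        step = state.update(int(u1))
        for k in cols:
            cols[k][t] = step[k]
    return HGFTrajectory(u1=u1_sequence.astype(int), **cols)


# ---------------------------------------------------------------------------
# agents (closed-loop policies)


class _Agent:
    name = "abstract"

    def reset(self) -> None:  # new block: new stimulus pair
        pass

    def choice_prob(self) -> float:
        """p(choose mapping 1) for the upcoming trial."""
        raise NotImplementedError

    def observe(self, y: int, outcome: int, u1: int) -> None:
        pass

    def extras(self) -> dict:
        return {}


class RandomAgent(_Agent):
    name = "random"

    def __init__(self, params: RandomParams):
        self.params = params

    def choice_prob(self) -> float:
        return self.params.b


class WSLSAgent(_Agent):
    name = "wsls"

    def __init__(self, params: WSLSParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.prev_y = None
        self.prev_outcome = None

    def choice_prob(self) -> float:
        if self.prev_y is None:
            return 0.5
        e2 = self.params.epsilon / 2.0
        if self.prev_outcome == 1:
            return 1.0 - e2 if self.prev_y == 1 else e2
        return e2 if self.prev_y == 1 else 1.0 - e2

    def observe(self, y: int, outcome: int, u1: int) -> None:
        self.prev_y, self.prev_outcome = y, outcome


class RWAgent(_Agent):
    name = "rw"

    def __init__(self, params: RWParams):
        self.params = params
        self.reset()

    def reset(self) -> None:
        self.v = {1: self.params.v0, 0: self.params.v0}

    def choice_prob(self) -> float:
        p = softmax(np.array([self.v[1], self.v[0]]), self.params.beta)
        return float(p[0])

    def observe(self, y: int, outcome: int, u1: int) -> None:
        self.v[y] = rw_step(self.v[y], outcome, self.params.alpha)

    def extras(self) -> dict:
        return {"v1": self.v[1], "v0": self.v[0]}


class HGFAgent(_Agent):
    name = "hgf"

    def __init__(self, params: HGFParams):
        self.params = params
        self.state = HGFState(params)
        self._last = None

    def reset(self) -> None:
        self.state.reset()
        self._last = None

    def choice_prob(self) -> float:
        return hgf_response_prob(self.state.predict(), self.params.zeta)

    def observe(self, y: int, outcome: int, u1: int) -> None:
        self._last = self.state.update(u1)

    def extras(self) -> dict:
        if self._last is None:
            return {}
        d = self._last
        return {
            "u1hat": d["u1hat"],
            "u2": d["u2"],
            "phi2": d["phi2"],
            "delta1": d["delta1"],
            "abs_delta1": abs(d["delta1"]),
        }


# ---------------------------------------------------------------------------
# closed-loop simulation


def _simulate(
    design: list[BlockDesign],
    agent: _Agent,
    seed: int | np.random.SeedSequence,
    subject: int = 1,
) -> pd.DataFrame:
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    rows = []
    for block in design:
        agent.reset()
        for t in range(1, block.n_trials + 1):
            p1 = agent.choice_prob()
            y = int(rng.random() < p1)
            stim = int(block.stimuli[t - 1])
            response = response_for_mapping(y, stim)
            trial = play_trial(block, t, response)
            u1 = encode_model_input(stim, response, trial["outcome"])
            agent.observe(y, trial["outcome"], u1)
            row = {
                "subject": subject,
                "run": block.run,
                "block": block.block,
                "trial": t,
                "stimulus": stim,
                "u1": u1,
                "u1hat": np.nan,
                "u2": np.nan,
                "phi2": np.nan,
                "delta1": np.nan,
                "abs_delta1": np.nan,
                "p_choice": p1,
                "y": y,
                "response": response,
                "outcome": trial["outcome"],
                "outcome_category": trial["outcome_category"],
                "correct": int(response == block.correct_response(t)),
                "phase": trial["phase"],
            }
            row.update(agent.extras())
            rows.append(row)
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    return df[TRAJECTORY_COLUMNS + extra]


def simulate_random(design, params: RandomParams, seed, subject: int = 1):
    return _simulate(design, RandomAgent(params), seed, subject)


def simulate_wsls(design, params: WSLSParams, seed, subject: int = 1):
    return _simulate(design, WSLSAgent(params), seed, subject)


def simulate_rw(design, params: RWParams, seed, subject: int = 1):
    return _simulate(design, RWAgent(params), seed, subject)


def simulate_hgf(design, params: HGFParams, seed, subject: int = 1):
    return _simulate(design, HGFAgent(params), seed, subject)


AGENTS = {
    "random": (RandomParams, simulate_random),
    "wsls": (WSLSParams, simulate_wsls),
    "rw": (RWParams, simulate_rw),
    "hgf": (HGFParams, simulate_hgf),
}


def simulate(model: str, design, params=None, seed=0, subject: int = 1, **kwargs):
    """Simulate a named model; params may be a dataclass or keyword dict."""
    if model not in AGENTS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(AGENTS)}")
    cls, fn = AGENTS[model]
    if params is None:
        params = cls(**kwargs)
    return fn(design, params, seed, subject)
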