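"""Model-independent behavioral summaries.

p(staying) — the probability of repeating the previous latent mapping
choice, split by the previous trial's outcome — plus phase-wise accuracy
and reversal-aligned learning curves. "Correct" throughout means the
response matching the currently-contingent higher-reward option, not the
realized (probabilistic) reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import PHASES

_BLOCK_KEYS = ["subject", "run", "block"]


@dataclass
class BehaviorSummary:
    p_stay_given_correct: float
    p_stay_given_wrong: float
    proportion_correct: dict  # phase -> accuracy
    curve_offsets: np.ndarray | None = None
    curve_accuracy: np.ndarray | None = None


def _block_groups(trials: pd.DataFrame):
    keys = [k for k in _BLOCK_KEYS if k in trials.columns]
    if not keys:
        yield trials
        return
    for _, grp in trials.groupby(keys, sort=False):
        yield grp


def p_staying(trials: pd.DataFrame) -> tuple[float, float]:
    """(p(stay | previous correct), p(stay | previous wrong)).

    Staying means repeating the latent mapping choice y; the first trial of
    each block is excluded. A conditional with no qualifying trials is NaN
    (undefined), never silently 0.
    """
    stays_c, n_c, stays_w, n_w = 0, 0, 0, 0
    for grp in _block_groups(trials):
        y = grp["y"].to_numpy()
        outcome = grp["outcome"].to_numpy()
        if len(y) < 2:
            continue
        stay = y[1:] == y[:-1]
        prev_ok = outcome[:-1] == 1
        stays_c += int(stay[prev_ok].sum())
        n_c += int(prev_ok.sum())
        stays_w += int(stay[~prev_ok].sum())
        n_w += int((~prev_ok).sum())
    p_c = stays_c / n_c if n_c else float("nan")
    p_w = stays_w / n_w if n_w else float("nan")
    return p_c, p_w


def proportion_correct_by_phase(trials: pd.DataFrame) -> dict[str, float]:
    """Mean accuracy in each labelled learning phase (LN, LE, RN, RE)."""
    out = {}
    for phase in PHASES:
        sel = trials[trials["phase"] == phase]
        if len(sel) == 0:
            raise ValueError(f"no trials labelled {phase}")
        out[phase] = float(sel["correct"].mean())
    return out


def phase_accuracy_by_subject(trials: pd.DataFrame) -> pd.DataFrame:
    """Subjects x phases accuracy table (group plumbing for paired tests)."""
    rows = {}
    for subj, grp in trials.groupby("subject", sort=False):
        rows[subj] = proportion_correct_by_phase(grp)
    return pd.DataFrame.from_dict(rows, orient="index")[list(PHASES)]


def phase_contrast(trials: pd.DataFrame, phase_a: str, phase_b: str) -> dict:
    """Two-sided paired t-test of per-subject accuracy between two phases."""
    table = phase_accuracy_by_subject(trials)
    t, p = stats.ttest_rel(table[phase_a], table[phase_b])
    return {
        "t": float(t),
        "p": float(p),
        "mean_diff": float((table[phase_a] - table[phase_b]).mean()),
        "n": int(len(table)),
    }


def reversal_aligned_curve(
    trials: pd.DataFrame,
    pre_window: int = 20,
    post_window: int = 20,
    reversal_trials: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accuracy averaged across blocks at each offset from the reversal.

    Offset 0 is the first reversed trial; negative offsets precede the
    reversal. The reversal trial of each block is recovered from the phase
    labels (first RN trial) unless supplied explicitly. Offsets falling
    outside a block are dropped from that block's average (truncation).
    """
    offsets = np.arange(-pre_window, post_window)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    for grp in _block_groups(trials):
        correct = grp["correct"].to_numpy()
        tr = grp["trial"].to_numpy()
        if reversal_trials is not None:
            key = tuple(grp.iloc[0][k] for k in _BLOCK_KEYS if k in grp.columns)
            rev = reversal_trials[key]
        else:
            rn = tr[grp["phase"].to_numpy() == "RN"]
            if len(rn) == 0:
                raise ValueError("block has no RN trials; pass reversal_trials")
            rev = int(rn.min())
        for i, off in enumerate(offsets):
            t = rev + off
            hit = correct[tr == t]
            if len(hit):
                sums[i] += hit[0]
                counts[i] += 1
    if np.any(counts == 0):
        import warnings

        warnings.warn("some offsets fall outside every block and are NaN")
    with np.errstate(invalid="ignore"):
        return offsets, np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def summarize(trials: pd.DataFrame, pre_window: int = 20, post_window: int = 20) -> BehaviorSummary:
    p_c, p_w = p_staying(trials)
    offsets, curve = reversal_aligned_curve(trials, pre_window, post_window)
    return BehaviorSummary(
        p_stay_given_correct=p_c,
        p_stay_given_wrong=p_w,
        proportion_correct=proportion_correct_by_phase(trials),
        curve_offsets=offsets,
        curve_accuracy=curve,
    )
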