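"""Probabilistic Go/NoGo reversal-learning task generator.

The task is organized in blocks of 45 trials (3 runs x 4 blocks by default).
Each block uses a fresh pair of tactile patterns drawn from a set of eight;
one pattern is initially associated with 'Go', the other with 'NoGo', with a
70/30 reward contingency. At a random trial inside a reversal window
(trials 20-25 by default) the stimulus-response association flips and the
agent must reverse its choice preference.

Trials are labelled into four 10-trial learning phases around the reversal:
LN (learning naive), LE (learning expert), RN (reversal naive) and
RE (reversal expert).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GO = "Go"
NOGO = "NoGo"
CATEGORIES = ("HIT", "CR", "FA", "MISS")
PHASES = ("LN", "LE", "RN", "RE")


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent task configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the reversal-learning experiment.

    Defaults reproduce the full design: 3 runs x 4 blocks x 45 trials =
    540 trials, p_high = 0.7 contingency, reversal in trials 20-25
    (1-based, inclusive), eight tactile patterns, 10-trial phases.
    """

    n_runs: int = 3
    blocks_per_run: int = 4
    trials_per_block: int = 45
    p_high: float = 0.7
    reversal_window: tuple[int, int] = (20, 25)
    n_patterns: int = 8
    phase_len: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.reversal_window
        if not (0.5 < self.p_high <= 1.0):
            raise ConfigurationError(f"p_high must be in (0.5, 1], got {self.p_high}")
        if not (2 <= lo <= hi <= self.trials_per_block - 1):
            raise ConfigurationError(
                f"reversal_window {self.reversal_window} must lie inside "
                f"[2, {self.trials_per_block - 1}]"
            )
        if self.phase_len > self.trials_per_block // 2:
            raise ConfigurationError(
                f"phase_len {self.phase_len} exceeds half the block length"
            )
        if self.n_patterns < 2:
            raise ConfigurationError("need at least two tactile patterns")
        if min(self.n_runs, self.blocks_per_run, self.trials_per_block) < 1:
            raise ConfigurationError("counts must be positive")

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class BlockDesign:
    """One block's stimulus schedule and reward assignments.

    ``reversal_trial`` is the 1-based index of the FIRST trial governed by
    the reversed contingency. ``initial_mapping`` is 1 when stimulus 1 maps
    to Go before the reversal (the u1 = 1 coding), 0 otherwise.
    ``rewarded_response[t]`` is the response that yields reward on trial t;
    it equals the currently-correct response with probability p_high.
    """

    run: int
    block: int
    go_pattern_id: int
    nogo_pattern_id: int
    reversal_trial: int
    initial_mapping: int
    stimuli: np.ndarray  # values in {1, 2}
    rewarded_response: np.ndarray  # values in {"Go", "NoGo"}
    phases: np.ndarray = field(default=None)  # filled by assign_phases

    @property
    def n_trials(self) -> int:
        return len(self.stimuli)

    def mapping_at(self, trial_index: int) -> int:
        """Active stimulus->response mapping (1 or 0) at a 1-based trial."""
        pre = trial_index < self.reversal_trial
        return self.initial_mapping if pre else 1 - self.initial_mapping

    def correct_response(self, trial_index: int) -> str:
        """The higher-reward-probability response at a 1-based trial."""
        stim = self.stimuli[trial_index - 1]
        return response_for_mapping(self.mapping_at(trial_index), stim)


def response_for_mapping(mapping: int, stimulus: int) -> str:
    """Response prescribed by a latent mapping for a given stimulus.

    Mapping 1 is stimulus1->Go / stimulus2->NoGo; mapping 0 is the reverse.
    """
    if mapping == 1:
        return GO if stimulus == 1 else NOGO
    return NOGO if stimulus == 1 else GO


def generate_design(
    config: TaskConfig = TaskConfig(), seed: int | np.random.SeedSequence = 0
) -> list[BlockDesign]:
    """Generate the full block structure of one experiment.

    One master seed spawns an independent child stream per block, so
    extending ``blocks_per_run`` leaves earlier blocks untouched.
    Phase labels are assigned on the way out.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(config.n_blocks)
    blocks = []
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        run = b // config.blocks_per_run + 1
        block_in_run = b % config.blocks_per_run + 1
        go_pat, nogo_pat = rng.choice(config.n_patterns, size=2, replace=False)
        lo, hi = config.reversal_window
        reversal_trial = int(rng.integers(lo, hi + 1))
        n = config.trials_per_block
        # near-balanced stimulus multiset, randomly permuted
        stimuli = np.array([1] * ((n + 1) // 2) + [2] * (n // 2))
        rng.shuffle(stimuli)
        initial_mapping = int(rng.integers(0, 2))
        block = BlockDesign(
            run=run,
            block=block_in_run,
            go_pattern_id=int(go_pat),
            nogo_pattern_id=int(nogo_pat),
            reversal_trial=reversal_trial,
            initial_mapping=initial_mapping,
            stimuli=stimuli,
            rewarded_response=np.empty(n, dtype=object),
        )
        # reward pre-drawn per trial: currently-correct response wins w.p. p_high
        draws = rng.random(n)
        for t in range(1, n + 1):
            correct = block.correct_response(t)
            other = NOGO if correct == GO else GO
            block.rewarded_response[t - 1] = (
                correct if draws[t - 1] < config.p_high else other
            )
        block.phases = assign_phases(block, config)
        blocks.append(block)
    return blocks


def assign_phases(block: BlockDesign, config: TaskConfig) -> np.ndarray:
    """Label each trial LN / LE / RN / RE / none.

    LN = trials 1..phase_len; LE = the phase_len trials ending just before
    the reversal; RN = the first phase_len reversed trials; RE = the last
    phase_len trials of the block. Where windows overlap the later label
    wins, keeping every phase at exactly phase_len trials.
    """
    n, k, rev = block.n_trials, config.phase_len, block.reversal_trial
    if rev - k < 1 or rev + k - 1 > n:
        raise ConfigurationError(
            f"phase windows around reversal trial {rev} exceed block bounds"
        )
    labels = np.full(n, "none", dtype=object)
    labels[0:k] = "LN"
    labels[rev - 1 - k : rev - 1] = "LE"
    labels[rev - 1 : rev - 1 + k] = "RN"
    labels[n - k : n] = "RE"
    return labels


def categorize(response: str, outcome: int) -> str:
    """Outcome category: HIT/CR are the rewarded, FA/MISS the unrewarded."""
    if response == GO:
        return "HIT" if outcome == 1 else "FA"
    return "CR" if outcome == 1 else "MISS"


def play_trial(block: BlockDesign, trial_index: int, response: str) -> dict:
    """Resolve one trial: reward iff the response matches the assignment."""
    if response not in (GO, NOGO):
        raise ValueError(f"response must be {GO!r} or {NOGO!r}, got {response!r}")
    assigned = block.rewarded_response[trial_index - 1]
    outcome = int(response == assigned)
    return {
        "trial_in_block": trial_index,
        "stimulus": int(block.stimuli[trial_index - 1]),
        "response": response,
        "outcome": outcome,
        "outcome_category": categorize(response, outcome),
        "phase": block.phases[trial_index - 1] if block.phases is not None else "none",
        "valid": True,
    }


def design_input_sequence(block: BlockDesign) -> np.ndarray:
    """The block's binary evidence sequence u1, one value per trial.

    u1 = 1 iff the trial's pre-drawn rewarded response is the one mapping 1
    (stimulus1->Go / stimulus2->NoGo) prescribes. Because reward assignment
    is drawn before the response, this sequence is a property of the design
    alone: every agent, whatever it chooses, observes the same u1 on a
    given trial (see ``encode_model_input``).
    """
    return np.array(
        [
            int(block.rewarded_response[t - 1] == response_for_mapping(1, block.stimuli[t - 1]))
            for t in range(1, block.n_trials + 1)
        ]
    )


def encode_model_input(stimulus: int, response: str, outcome: int) -> int:
    """Binary evidence u1 for the latent mapping stimulus1->Go/stimulus2->NoGo.

    u1 = 1 iff the observed feedback supports mapping 1: the executed
    response was mapping-1-consistent and rewarded, or mapping-2-consistent
    and unrewarded.
    """
    mapping1_consistent = response == response_for_mapping(1, stimulus)
    return int(mapping1_consistent == bool(outcome))
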