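"""Cross-phase representational similarity analysis.

Condition-wise multi-voxel patterns from a pre-reversal epoch (LE) are
correlated with patterns from a post-reversal epoch (RN or RE), giving a
4x4 pre x post matrix over the outcome categories HIT, CR, FA, MISS. This
matrix is intentionally non-symmetric: rows and columns index different
epochs.

Two binary model RDMs encode competing hypotheses about what survives the
reversal: the stimulus-selective model predicts that patterns follow the
tactile stimulus (pre-HIT resembles post-CR, since the reversal swaps the
response mapped to each stimulus), while the outcome-selective model
predicts that patterns follow the outcome (pre-HIT resembles post-HIT).
The summary statistic is the mean correlation over model-similar cells
minus the mean over model-dissimilar cells; group inference uses a
one-sided Wilcoxon signed-rank test and a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

CONDITIONS = ("HIT", "CR", "FA", "MISS")

_STIMULUS_SIMILAR = {("HIT", "CR"), ("CR", "HIT"), ("FA", "MISS"), ("MISS", "FA")}


@dataclass(frozen=True)
class ModelRDM:
    """Binary 4x4 hypothesis matrix over (pre-condition, post-condition).

    1 marks model-similar cells, 0 model-dissimilar cells.
    """

    matrix: np.ndarray
    selectivity: str

    @property
    def similar_mask(self) -> np.ndarray:
        return self.matrix.astype(bool)


@dataclass
class CrossPhaseRDM:
    """Pearson correlations between pre- and post-epoch condition patterns."""

    matrix: np.ndarray  # 4x4, rows = pre conditions, cols = post conditions
    epoch_pair: str = "LE-RN"


@dataclass
class RSAGroupResult:
    per_subject: np.ndarray
    group_mean: float  # also reported as the permutation effect size
    signed_rank_p: float
    permutation_p: float
    n_permutations: int


def model_rdm(selectivity: str) -> ModelRDM:
    """The stimulus- or outcome-selective binary model RDM.

    The outcome model's similar set is the diagonal (same outcome category
    across the reversal); the stimulus model's similar set pairs HIT with CR
    and FA with MISS (same tactile stimulus once the mapping has flipped).
    """
    m = np.zeros((4, 4), dtype=int)
    if selectivity == "outcome":
        np.fill_diagonal(m, 1)
    elif selectivity == "stimulus":
        for i, a in enumerate(CONDITIONS):
            for j, b in enumerate(CONDITIONS):
                if (a, b) in _STIMULUS_SIMILAR:
                    m[i, j] = 1
    else:
        raise ValueError(
            f"selectivity must be 'stimulus' or 'outcome', got {selectivity!r}"
        )
    return ModelRDM(matrix=m, selectivity=selectivity)


def _validate_patterns(patterns: dict, epoch: str) -> int:
    missing = set(CONDITIONS) - set(patterns)
    if missing:
        raise ValueError(f"{epoch} epoch lacks conditions: {sorted(missing)}")
    lengths = {c: len(np.asarray(patterns[c])) for c in CONDITIONS}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"{epoch} epoch vectors differ in voxel count: {lengths}")
    n_vox = next(iter(lengths.values()))
    if n_vox < 3:
        raise ValueError("need at least 3 voxels per pattern")
    for c in CONDITIONS:
        if np.std(np.asarray(patterns[c], dtype=float)) == 0:
            raise ValueError(f"constant pattern vector for condition {c} ({epoch})")
    return n_vox


def empirical_rdm(
    pre: dict, post: dict, epoch_pair: str = "LE-RN"
) -> CrossPhaseRDM:
    """Pearson-correlation matrix between pre and post condition patterns."""
    n_pre = _validate_patterns(pre, "pre")
    n_post = _validate_patterns(post, "post")
    if n_pre != n_post:
        raise ValueError(f"voxel count differs pre ({n_pre}) vs post ({n_post})")
    m = np.empty((4, 4))
    for i, a in enumerate(CONDITIONS):
        for j, b in enumerate(CONDITIONS):
            m[i, j] = stats.pearsonr(
                np.asarray(pre[a], dtype=float), np.asarray(post[b], dtype=float)
            )[0]
    return CrossPhaseRDM(matrix=m, epoch_pair=epoch_pair)


def rsa_statistic(rdm: CrossPhaseRDM | np.ndarray, model: ModelRDM) -> float:
    """Mean correlation over model-similar minus model-dissimilar cells."""
    m = rdm.matrix if isinstance(rdm, CrossPhaseRDM) else np.asarray(rdm)
    if m.shape != model.matrix.shape:
        raise ValueError("RDM and model RDM shapes differ")
    sim = model.similar_mask
    return float(m[sim].mean() - m[~sim].mean())


def group_inference(
    per_subject_stats: np.ndarray | None = None,
    model: ModelRDM | None = None,
    subject_rdms: list | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> RSAGroupResult:
    """Group-level inference on the similar-minus-dissimilar statistic.

    (1) one-sided Wilcoxon signed-rank test across subjects (median > 0);
    (2) one-sided permutation test: each iteration independently permutes
    the pre (row) and post (column) condition labels of every subject's
    RDM, recomputes the group-mean statistic, and compares the observed
    mean against this null with (b+1)/(n+1) smoothing.
    """
    if subject_rdms is None:
        raise ValueError("subject_rdms are required (permutation operates on them)")
    if model is None:
        raise ValueError("a model RDM is required")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm = {n_perm} is very small; p-values will be coarse")
    mats = [
        r.matrix if isinstance(r, CrossPhaseRDM) else np.asarray(r)
        for r in subject_rdms
    ]
    if per_subject_stats is None:
        per_subject_stats = np.array([rsa_statistic(m, model) for m in mats])
    else:
        per_subject_stats = np.asarray(per_subject_stats, dtype=float)
    n_subj = len(per_subject_stats)
    if n_subj < 6:
        import warnings

        warnings.warn("fewer than 6 subjects: signed-rank p is unreliable")
    observed = float(per_subject_stats.mean())
    sr = stats.wilcoxon(per_subject_stats, alternative="greater")
    rng = np.random.default_rng(seed)
    sim = model.similar_mask
    null = np.empty(n_perm)
    for it in range(n_perm):
        total = 0.0
        for m in mats:
            pr = rng.permutation(4)
            pc = rng.permutation(4)
            perm = m[np.ix_(pr, pc)]
            total += perm[sim].mean() - perm[~sim].mean()
        null[it] = total / len(mats)
    b = int((null >= observed).sum())
    perm_p = (b + 1.0) / (n_perm + 1.0)
    return RSAGroupResult(
        per_subject=per_subject_stats,
        group_mean=observed,
        signed_rank_p=float(sr.pvalue),
        permutation_p=float(perm_p),
        n_permutations=n_perm,
    )


def synth_patterns(
    n_subjects: int = 32,
    n_voxels: int = 100,
    stim_signal: float = 0.0,
    outcome_signal: float = 1.0,
    noise_sd: float = 1.0,
    epoch_pair: str = "LE-RN",
    seed: int = 0,
) -> list[tuple[dict, dict]]:
    """Synthetic condition-wise voxel patterns with controllable coding.

    Each subject gets a stimulus-coding template per tactile pattern
    (shared by the conditions carrying that pattern, whose identity flips
    across the reversal: pre-HIT and post-CR share a stimulus) and an
    outcome-coding template per outcome category (shared by the same
    category across the reversal: pre-HIT and post-HIT). A condition's
    vector is ``stim_signal * stimulus_template + outcome_signal *
    outcome_template + Gaussian voxel noise``; the two signals therefore
    load on exactly the cells the respective model RDM marks similar.
    """
    if stim_signal < 0 or outcome_signal < 0:
        raise ValueError("signal amplitudes must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    # stimulus carried by each condition, before and after the reversal
    stim_of = {
        "pre": {"HIT": 0, "MISS": 0, "CR": 1, "FA": 1},
        "post": {"HIT": 1, "MISS": 1, "CR": 0, "FA": 0},
    }
    out_of = {c: i for i, c in enumerate(CONDITIONS)}  # category, epoch-invariant
    ss = np.random.SeedSequence(seed)
    subjects = []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        stim_templates = rng.standard_normal((2, n_voxels))
        out_templates = rng.standard_normal((4, n_voxels))
        epochs = {}
        for epoch in ("pre", "post"):
            epochs[epoch] = {
                c: stim_signal * stim_templates[stim_of[epoch][c]]
                + outcome_signal * out_templates[out_of[c]]
                + rng.normal(0.0, noise_sd, n_voxels)
                for c in CONDITIONS
            }
        subjects.append((epochs["pre"], epochs["post"]))
    return subjects
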