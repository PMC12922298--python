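"""Subject-wise permutation inference on median-ISFC group differences.

The observed statistic for each region pair is the within-neurotypical
median ISFC minus the within-autism median ISFC.  The null is built by
shuffling whole-subject group labels (never time points): each shuffle
keeps the group sizes, restricts the precomputed pooled pair tensor to
within-permuted-group pairs, and recomputes the same median difference.
Significance is called per pair from the two-sided percentile rule
(beyond the 97.5th / below the 2.5th null percentile for alpha = .05;
99.5th / 0.5th for alpha = .01), with no multiple-comparison correction.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isfc import PairwiseIsfcTensor, subject_pair_isfc
from .preprocess import CleanedSeries
from .synthetic import GROUPS

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass
class SignificanceMask:
    """Signed R x R significance calls: +1 NT > AUT, -1 NT < AUT, 0 n.s.

    Symmetric with a zero diagonal (the region-with-itself ISC values are
    never tested).
    """

    values: np.ndarray
    alpha: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InferenceError("mask must be square")
        if not np.array_equal(v, v.T):
            raise InferenceError("mask must be symmetric")
        if not np.isin(v, (-1, 0, 1)).all():
            raise InferenceError("mask entries must be in {-1, 0, +1}")
        v = v.astype(np.int8).copy()
        np.fill_diagonal(v, 0)
        self.values = v
        if not self.region_labels:
            self.region_labels = [
                f"ROI_{i + 1:03d}" for i in range(v.shape[0])
            ]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def significant_pairs(self) -> list[tuple[int, int, int]]:
        """Upper-triangle (i, j, sign) tuples of significant pairs."""
        iu = np.triu_indices(self.n_regions, k=1)
        sel = self.values[iu] != 0
        return [
            (int(i), int(j), int(s))
            for i, j, s in zip(iu[0][sel], iu[1][sel], self.values[iu][sel])
        ]


@dataclass
class PooledPairTensor:
    """ISFC matrices for all unordered pairs of the pooled two-group cohort.

    Precomputing every pooled pair once makes label permutations cheap:
    any relabeling only changes which pairs count as within-group.
    ``groups`` fixes the difference direction (first minus second).
    """

    matrices: np.ndarray
    subject_ids: list[str]
    labels: list[str]
    region_labels: list[str]
    pair_subjects: np.ndarray  # (n_pairs, 2) indices into subject_ids
    groups: tuple[str, str] = GROUPS

    def __post_init__(self) -> None:
        self.matrices = np.ascontiguousarray(self.matrices)
        self.matrices.setflags(write=False)
        self.pair_subjects = np.asarray(self.pair_subjects)
        counts = [self.labels.count(g) for g in self.groups]
        if min(counts) < 2:
            raise InferenceError("each group needs at least 2 subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def restrict(self, group: str) -> PairwiseIsfcTensor:
        """Within-group pair tensor for the true labels of ``group``."""
        lab = np.asarray(self.labels)
        mask = (lab[self.pair_subjects[:, 0]] == group) & (
            lab[self.pair_subjects[:, 1]] == group
        )
        return PairwiseIsfcTensor(
            pair_index=[
                (self.subject_ids[a], self.subject_ids[b])
                for a, b in self.pair_subjects[mask]
            ],
            matrices=self.matrices[mask].copy(),
            region_labels=list(self.region_labels),
        )


@dataclass
class PermutationResult:
    """Observed group difference plus its subject-wise permutation null."""

    observed_diff: np.ndarray
    null_quantiles: dict[float, np.ndarray]
    p_values: np.ndarray
    masks: dict[float, SignificanceMask]
    n_permutations: int
    seed: int | None
    region_labels: list[str]
    group_sizes: tuple[int, int]


def pooled_pair_tensor(
    subjects_all: list[CleanedSeries],
    labels: list[str] | None = None,
    groups: tuple[str, str] = GROUPS,
) -> PooledPairTensor:
    """Compute every pooled subject pair's symmetrized ISFC matrix once."""
    if labels is None:
        labels = [s.group for s in subjects_all]
    if len(labels) != len(subjects_all):
        raise InferenceError("labels length must match subject count")
    n = len(subjects_all)
    pair_subjects = []
    mats = []
    for i in range(n):
        for j in range(i + 1, n):
            mats.append(subject_pair_isfc(subjects_all[i], subjects_all[j]))
            pair_subjects.append((i, j))
    r = subjects_all[0].n_regions
    n_pairs = len(mats)
    logger.info(
        "pooled pair tensor: %d pairs x %d x %d = %d entries (%.1f MB)",
        n_pairs, r, r, n_pairs * r * r, n_pairs * r * r * 8 / 1e6,
    )
    return PooledPairTensor(
        matrices=np.stack(mats),
        subject_ids=[s.subject_id for s in subjects_all],
        labels=list(labels),
        region_labels=list(subjects_all[0].region_labels),
        pair_subjects=np.array(pair_subjects),
        groups=groups,
    )


def _median_diff(
    matrices: np.ndarray,
    pair_subjects: np.ndarray,
    labels: np.ndarray,
    groups: tuple[str, str],
) -> np.ndarray:
    la = labels[pair_subjects[:, 0]]
    lb = labels[pair_subjects[:, 1]]
    within_a = (la == groups[0]) & (lb == groups[0])
    within_b = (la == groups[1]) & (lb == groups[1])
    return np.median(matrices[within_a], axis=0) - np.median(
        matrices[within_b], axis=0
    )


def _label_assignments(
    n: int, n_first: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean (B, N) matrix: True where the subject gets the first label."""
    total = math.comb(n, n_first)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct label assignments exist; enumerating "
            f"exhaustively instead of drawing {n_permutations} shuffles",
            stacklevel=3,
        )
        out = np.zeros((total, n), dtype=bool)
        for b, combo in enumerate(itertools.combinations(range(n), n_first)):
            out[b, list(combo)] = True
        return out, True
    out = np.zeros((n_permutations, n), dtype=bool)
    for b in range(n_permutations):
        out[b, rng.permutation(n)[:n_first]] = True
    return out, False


def subject_wise_permutation_test(
    pool: PooledPairTensor,
    n_permutations: int = 5000,
    alphas: tuple[float, ...] = (0.05, 0.01),
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of the median-ISFC group difference, per pair.

    Each permutation reassigns group labels to whole subjects (preserving
    the observed group sizes) and recomputes the within-group median
    difference from the precomputed pooled pair tensor.  Per-pair two-sided
    p-values use the add-one convention
    ``p = (1 + #{|null| >= |obs|}) / (1 + B)`` so p is never zero.  When
    the number of distinct label assignments is at most ``n_permutations``
    the null is enumerated exhaustively (with a warning).
    """
    if n_permutations < 100:
        raise InferenceError("n_permutations must be at least 100")
    labels = np.asarray(pool.labels)
    n = pool.n_subjects
    n_first = int((labels == pool.groups[0]).sum())
    observed = _median_diff(
        pool.matrices, pool.pair_subjects, labels, pool.groups
    )

    rng = np.random.default_rng(seed)
    assign, _ = _label_assignments(n, n_first, n_permutations, rng)
    b_total = assign.shape[0]

    r = pool.n_regions
    iu = np.triu_indices(r, k=1)
    pa = pool.pair_subjects[:, 0]
    pb = pool.pair_subjects[:, 1]
    tri = pool.matrices[:, iu[0], iu[1]]  # (n_pairs, n_unique)
    null = np.empty((b_total, iu[0].size))
    for b in range(b_total):
        first = assign[b]
        within_a = first[pa] & first[pb]
        within_b = ~first[pa] & ~first[pb]
        null[b] = np.median(tri[within_a], axis=0) - np.median(
            tri[within_b], axis=0
        )

    obs_tri = observed[iu]
    p_tri = (1.0 + (np.abs(null) >= np.abs(obs_tri)).sum(axis=0)) / (
        1.0 + b_total
    )
    p_values = np.ones((r, r))
    p_values[iu] = p_tri
    p_values[(iu[1], iu[0])] = p_tri

    quantiles: dict[float, np.ndarray] = {}
    for q in (0.5, 2.5, 97.5, 99.5):
        qtri = np.percentile(null, q, axis=0)
        qmat = np.zeros((r, r))
        qmat[iu] = qtri
        qmat[(iu[1], iu[0])] = qtri
        quantiles[q] = qmat

    masks: dict[float, SignificanceMask] = {}
    for alpha in alphas:
        lo = np.percentile(null, 100 * alpha / 2.0, axis=0)
        hi = np.percentile(null, 100 * (1.0 - alpha / 2.0), axis=0)
        sig_tri = np.where(
            obs_tri > hi, 1, np.where(obs_tri < lo, -1, 0)
        ).astype(np.int8)
        mat = np.zeros((r, r), dtype=np.int8)
        mat[iu] = sig_tri
        mat[(iu[1], iu[0])] = sig_tri
        masks[alpha] = SignificanceMask(
            values=mat, alpha=alpha, region_labels=list(pool.region_labels)
        )

    n_second = n - n_first
    return PermutationResult(
        observed_diff=observed,
        null_quantiles=quantiles,
        p_values=p_values,
        masks=masks,
        n_permutations=b_total,
        seed=seed,
        region_labels=list(pool.region_labels),
        group_sizes=(n_first, n_second),
    )


def roi_count_map(mask: SignificanceMask) -> pd.DataFrame:
    """Per-region counts of significant positive/negative connections."""
    v = mask.values
    return pd.DataFrame(
        {
            "region": mask.region_labels,
            "positive_count": (v == 1).sum(axis=1),
            "negative_count": (v == -1).sum(axis=1),
        }
    )


@dataclass
class MotionCouplingResult:
    """Pairwise FD synchronization and its group comparison."""

    pair_table: pd.DataFrame
    observed_diff: float
    p_value: float
    n_permutations: int


def intersubject_motion_coupling(
    fd_series: list[np.ndarray],
    labels: list[str],
    subject_ids: list[str] | None = None,
    groups: tuple[str, str] = GROUPS,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> MotionCouplingResult:
    """Head-motion synchronization check.

    Computes the Pearson correlation of framewise-displacement series for
    every unordered subject pair (frame 0 dropped: FD is undefined there),
    then compares within-group median coupling between the two groups with
    the same subject-wise permutation machinery applied to the scalar
    statistic.  Low couplings and a null group comparison indicate that
    ISFC differences are not driven by synchronized motion.
    """
    n = len(fd_series)
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(n)]
    if len(labels) != n:
        raise InferenceError("labels length must match fd_series")
    fd = [np.asarray(f, dtype=float)[1:] for f in fd_series]
    for i, f in enumerate(fd):
        if f.std() < 1e-12:
            raise InferenceError(
                f"constant FD series for subject {subject_ids[i]}"
            )
    z = np.stack([(f - f.mean()) / f.std(ddof=1) for f in fd])
    t = z.shape[1]
    rows = []
    pair_subjects = []
    pair_r = []
    for i in range(n):
        for j in range(i + 1, n):
            r_ij = float(z[i] @ z[j]) / (t - 1)
            rows.append(
                {
                    "subject_a": subject_ids[i],
                    "subject_b": subject_ids[j],
                    "correlation": r_ij,
                    "group_a": labels[i],
                    "group_b": labels[j],
                }
            )
            pair_subjects.append((i, j))
            pair_r.append(r_ij)
    pair_subjects = np.array(pair_subjects)
    pair_r = np.array(pair_r)
    lab = np.asarray(labels)

    def stat(first: np.ndarray) -> float:
        wa = first[pair_subjects[:, 0]] & first[pair_subjects[:, 1]]
        wb = ~first[pair_subjects[:, 0]] & ~first[pair_subjects[:, 1]]
        return float(np.median(pair_r[wa]) - np.median(pair_r[wb]))

    observed = stat(lab == groups[0])
    rng = np.random.default_rng(seed)
    n_first = int((lab == groups[0]).sum())
    assign, _ = _label_assignments(n, n_first, n_permutations, rng)
    null = np.array([stat(a) for a in assign])
    p = float(
        (1.0 + (np.abs(null) >= abs(observed)).sum()) / (1.0 + null.size)
    )
    return MotionCouplingResult(
        pair_table=pd.DataFrame(rows),
        observed_diff=observed,
        p_value=p,
        n_permutations=int(null.size),
    )
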