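"""Pairwise inter-subject functional connectivity (ISFC).

ISFC correlates region i's time series in one subject with region j's
series in *another* subject.  Because idiosyncratic signals and noise are
uncorrelated across brains, only stimulus-locked coupling survives.  Here
ISFC is computed for every unordered subject pair within a group,
symmetrized per pair by averaging each matrix with its transpose, and
summarized per group by the entrywise median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CleanedSeries


class IsfcError(ValueError):
    pass


@dataclass
class PairwiseIsfcTensor:
    """Symmetrized R x R ISFC matrices for all unordered subject pairs.

    ``matrices`` has shape (n_pairs, R, R); ``pair_index[p]`` gives the
    (subject_a, subject_b) ids of slice p.
    """

    pair_index: list[tuple[str, str]]
    matrices: np.ndarray
    region_labels: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pair_index:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


@dataclass
class GroupIsfcSummary:
    """Per-group median ISFC matrix and its unique off-diagonal values."""

    median_matrix: np.ndarray
    unique_values: np.ndarray
    region_labels: list[str]
    group: str
    n_subjects: int


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd < 1e-12).any():
        bad = int(np.argmin(sd))
        raise IsfcError(f"zero-variance region column at index {bad}")
    return (x - x.mean(axis=0)) / sd


def subject_pair_isfc(
    series_a: CleanedSeries | np.ndarray, series_b: CleanedSeries | np.ndarray
) -> np.ndarray:
    """Symmetrized ISFC matrix for one subject pair.

    Entry [i, j] of the raw matrix is the Pearson correlation of subject
    a's region-i series with subject b's region-j series; the returned
    matrix is (raw + raw.T) / 2.  Its diagonal holds the symmetrized
    inter-subject correlation (ISC) of each region.
    """
    a = series_a.data if isinstance(series_a, CleanedSeries) else series_a
    b = series_b.data if isinstance(series_b, CleanedSeries) else series_b
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise IsfcError(f"shape mismatch: {a.shape} vs {b.shape}")
    t = a.shape[0]
    za, zb = _standardize(a), _standardize(b)
    raw = (za.T @ zb) / (t - 1)
    return (raw + raw.T) / 2.0


def group_pairwise_isfc(subjects: list[CleanedSeries]) -> PairwiseIsfcTensor:
    """ISFC matrices for every unordered pair of subjects in one group."""
    if len(subjects) < 2:
        raise IsfcError("need at least 2 subjects for pairwise ISFC")
    shapes = {s.data.shape for s in subjects}
    if len(shapes) != 1:
        raise IsfcError(f"inhomogeneous series shapes: {sorted(shapes)}")
    labels = subjects[0].region_labels
    for s in subjects[1:]:
        if s.region_labels != labels:
            raise IsfcError(
                f"region labels of {s.subject_id} differ from {subjects[0].subject_id}"
            )
    t = subjects[0].data.shape[0]
    z = np.stack([_standardize(s.data) for s in subjects])
    pair_index: list[tuple[str, str]] = []
    mats = []
    n = len(subjects)
    for i in range(n):
        for j in range(i + 1, n):
            raw = (z[i].T @ z[j]) / (t - 1)
            mats.append((raw + raw.T) / 2.0)
            pair_index.append((subjects[i].subject_id, subjects[j].subject_id))
    return PairwiseIsfcTensor(
        pair_index=pair_index,
        matrices=np.stack(mats),
        region_labels=list(labels),
    )


def median_isfc(
    tensor: PairwiseIsfcTensor, group: str = ""
) -> GroupIsfcSummary:
    """Entrywise median over all subject-pair ISFC matrices.

    Even pair counts use the midpoint of the two central order statistics
    (the standard sample median).
    """
    if tensor.n_pairs < 1:
        raise IsfcError("cannot take the median of an empty pair tensor")
    med = np.median(tensor.matrices, axis=0)
    med = (med + med.T) / 2.0  # medians of symmetric slices are symmetric
    iu = np.triu_indices(med.shape[0], k=1)
    n_subjects = len(tensor.subject_ids)
    return GroupIsfcSummary(
        median_matrix=med,
        unique_values=med[iu],
        region_labels=tensor.region_labels,
        group=group,
        n_subjects=n_subjects,
    )


def unique_pair_count(n_regions: int) -> int:
    """Number of unique off-diagonal region pairs, R(R-1)/2."""
    if n_regions < 2:
        raise IsfcError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


def isfc_difference(
    summary_nt: GroupIsfcSummary, summary_aut: GroupIsfcSummary
) -> np.ndarray:
    """Entrywise median-ISFC difference, neurotypical minus autism."""
    if summary_nt.region_labels != summary_aut.region_labels:
        raise IsfcError("region labels differ between group summaries")
    return summary_nt.median_matrix - summary_aut.median_matrix
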