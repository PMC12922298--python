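"""Cross-dataset replication of ISFC group differences.

A region pair "replicates" when it is significant with the same sign in
both the discovery and the replication dataset at the same region
indices.  The replication rate is the fraction of the discovery dataset's
significant pairs that replicate.  Chance overlap is assessed by randomly
permuting the region order of the replication mask — rows and columns
shuffled by the same permutation, which preserves the mask's degree
structure while destroying the region correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import SignificanceMask


class ReplicationError(ValueError):
    pass


@dataclass
class ReplicationResult:
    """Signed mask overlap, replication rate, and its ROI-shuffle null."""

    overlap: np.ndarray
    replicated_pairs: list[tuple[int, int, int]]
    rate: float
    null_rates: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int | None
    region_labels: list[str]


def _check_aligned(
    mask_discovery: SignificanceMask, mask_replication: SignificanceMask
) -> None:
    if mask_discovery.region_labels != mask_replication.region_labels:
        raise ReplicationError(
            "region-label order differs between masks; no silent reordering"
        )


def signed_overlap(
    mask_discovery: SignificanceMask, mask_replication: SignificanceMask
) -> np.ndarray:
    """Entrywise sum of two signed masks.

    +2 / -2 mark pairs significant with the same sign in both datasets;
    +-1 and 0 are non-replicated.
    """
    _check_aligned(mask_discovery, mask_replication)
    return (
        mask_discovery.values.astype(np.int8)
        + mask_replication.values.astype(np.int8)
    )


def _rate_from_values(
    disc: np.ndarray, repl: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> float:
    d = disc[iu]
    n_sig = int((d != 0).sum())
    if n_sig == 0:
        raise ReplicationError(
            "discovery mask has no significant pairs; rate undefined"
        )
    matched = int(((d != 0) & (repl[iu] == d)).sum())
    return matched / n_sig


def replication_rate(
    mask_discovery: SignificanceMask, mask_replication: SignificanceMask
) -> float:
    """Fraction of discovery-significant pairs replicated with matching sign."""
    _check_aligned(mask_discovery, mask_replication)
    iu = np.triu_indices(mask_discovery.n_regions, k=1)
    return _rate_from_values(mask_discovery.values, mask_replication.values, iu)


def roi_shuffle_pvalue(
    mask_discovery: SignificanceMask,
    mask_replication: SignificanceMask,
    n_shuffles: int = 5000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p for the replication rate under a region-order null.

    Each shuffle applies one random region permutation simultaneously to
    the rows and columns of the replication mask (discovery fixed) and
    recomputes the rate; ``p = (1 + #{null >= observed}) / (1 + B)``.
    """
    _check_aligned(mask_discovery, mask_replication)
    if n_shuffles < 100:
        raise ReplicationError("n_shuffles must be at least 100")
    r = mask_discovery.n_regions
    iu = np.triu_indices(r, k=1)
    disc = mask_discovery.values
    repl = mask_replication.values
    observed = _rate_from_values(disc, repl, iu)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        perm = rng.permutation(r)
        null[b] = _rate_from_values(disc, repl[np.ix_(perm, perm)], iu)
    p = float((1.0 + (null >= observed).sum()) / (1.0 + n_shuffles))
    return p, null


def replication_analysis(
    mask_discovery: SignificanceMask,
    mask_replication: SignificanceMask,
    n_shuffles: int = 5000,
    seed: int | None = None,
) -> ReplicationResult:
    """Full replication summary: overlap, rate, and ROI-shuffle p-value."""
    overlap = signed_overlap(mask_discovery, mask_replication)
    rate = replication_rate(mask_discovery, mask_replication)
    p, null = roi_shuffle_pvalue(
        mask_discovery, mask_replication, n_shuffles=n_shuffles, seed=seed
    )
    iu = np.triu_indices(mask_discovery.n_regions, k=1)
    sel = np.abs(overlap[iu]) == 2
    pairs = [
        (int(i), int(j), int(np.sign(s)))
        for i, j, s in zip(iu[0][sel], iu[1][sel], overlap[iu][sel])
    ]
    return ReplicationResult(
        overlap=overlap,
        replicated_pairs=pairs,
        rate=rate,
        null_rates=null,
        p_value=p,
        n_shuffles=n_shuffles,
        seed=seed,
        region_labels=list(mask_discovery.region_labels),
    )


def cross_dataset_correlation(
    diff_discovery: np.ndarray,
    diff_replication: np.ndarray,
    n_shuffles: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson correlation of the two group-difference matrices.

    Computed across the R(R-1)/2 unique upper-triangle values.  The
    permutation p applies the same row-and-column region shuffle to the
    replication matrix and is two-sided on |r|.
    """
    a = np.asarray(diff_discovery, dtype=float)
    b = np.asarray(diff_replication, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ReplicationError(f"shape mismatch: {a.shape} vs {b.shape}")
    r = a.shape[0]
    iu = np.triu_indices(r, k=1)
    x = a[iu]

    def corr(ymat: np.ndarray) -> float:
        y = ymat[iu]
        xs, ys = x.std(), y.std()
        if xs < 1e-15 or ys < 1e-15:
            raise ReplicationError("zero-variance upper triangle")
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(r)
        null[k] = corr(b[np.ix_(perm, perm)])
    p = float(
        (1.0 + (np.abs(null) >= abs(observed)).sum()) / (1.0 + n_shuffles)
    )
    return observed, p
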