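"""Post-fMRIPrep cleaning of ROI time series.

Implements the nuisance-removal chain applied to atlas-extracted BOLD
series before any inter-subject analysis: joint linear regression of an
intercept, a linear trend, six rigid-body motion parameters, mean white
matter and CSF signals, and a discrete-cosine high-pass basis; followed
by standardization of every region's residual series to zero mean and
unit sample (T-1) variance.  Also implements Power-style framewise
displacement and the mean-FD subject exclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

#: Head radius (mm) used to convert rotation differences to displacement.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: High-pass cutoff period (s) for the discrete-cosine basis.
DEFAULT_DCT_CUTOFF_S = 128.0

#: Mean-FD exclusion threshold (mm).
DEFAULT_FD_THRESHOLD = 0.5

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class PreprocessError(ValueError):
    """Raised for invalid cleaning inputs (rank deficiency, flat series, ...)."""


@dataclass
class ConfoundTable:
    """Per-subject nuisance regressors in the fMRIPrep dialect.

    Parameters
    ----------
    motion:
        (T, 6) array: translations in mm (x, y, z) then rotations in
        radians (x, y, z).
    wm_signal, csf_signal:
        Mean white-matter and CSF signals, length T.
    cosine_basis:
        (T, K) discrete-cosine high-pass regressors; may have K = 0.
    fd:
        Framewise displacement in mm, ``fd[0] == 0`` by convention.
    std_dvars:
        Standardized DVARS (dimensionless quality index); first frame 0.
    """

    motion: np.ndarray
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    cosine_basis: np.ndarray
    fd: np.ndarray
    std_dvars: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise PreprocessError(
                f"motion must be (T, 6), got {self.motion.shape}"
            )
        t = self.motion.shape[0]
        for name in ("wm_signal", "csf_signal", "fd", "std_dvars"):
            vec = np.asarray(getattr(self, name), dtype=float).ravel()
            if vec.shape[0] != t:
                raise PreprocessError(
                    f"{name} has length {vec.shape[0]}, expected T={t}"
                )
            setattr(self, name, vec)
        self.cosine_basis = np.asarray(self.cosine_basis, dtype=float)
        if self.cosine_basis.size == 0:
            self.cosine_basis = np.empty((t, 0))
        if self.cosine_basis.shape[0] != t:
            raise PreprocessError(
                f"cosine_basis has {self.cosine_basis.shape[0]} rows, expected {t}"
            )
        if abs(self.fd[0]) > 1e-12:
            raise PreprocessError("fd[0] must be 0 (no displacement at first frame)")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    @property
    def mean_fd(self) -> float:
        """Mean framewise displacement over frames 1..T-1."""
        return float(np.mean(self.fd[1:]))


@dataclass
class CleanedSeries:
    """One subject's confound-regressed, standardized T x R region series."""

    data: np.ndarray
    subject_id: str
    group: str
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("data must be a T x R matrix")
        if not self.region_labels:
            self.region_labels = [
                f"ROI_{i + 1:03d}" for i in range(self.data.shape[1])
            ]
        if len(self.region_labels) != self.data.shape[1]:
            raise PreprocessError("region_labels length must match R")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement from six motion parameters.

    FD[t] = sum of absolute backward differences of the three translations
    (mm) plus ``head_radius_mm`` times the sum of absolute differences of
    the three rotations (radians).  FD[0] is defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError(f"motion must be (T, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise PreprocessError("framewise displacement needs at least 2 frames")
    delta = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + head_radius_mm * delta[:, 3:].sum(axis=1)
    return fd


def mean_fd_exclusion(
    subjects: list[tuple[str, ConfoundTable]],
    threshold: float = DEFAULT_FD_THRESHOLD,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude subjects whose mean FD strictly exceeds ``threshold`` (mm).

    Returns the kept subject ids and a per-subject report table with
    columns ``subject_id``, ``mean_fd``, ``excluded``.  A subject at
    exactly the threshold is retained.
    """
    rows = []
    kept = []
    for subject_id, confounds in subjects:
        mfd = confounds.mean_fd
        excluded = mfd > threshold
        rows.append(
            {"subject_id": subject_id, "mean_fd": mfd, "excluded": excluded}
        )
        if not excluded:
            kept.append(subject_id)
    report = pd.DataFrame(rows, columns=["subject_id", "mean_fd", "excluded"])
    if not kept:
        raise PreprocessError(
            f"no subjects remain after mean-FD exclusion at {threshold} mm"
        )
    return kept, report


def build_dct_basis(
    n_timepoints: int,
    tr_seconds: float,
    cutoff_seconds: float = DEFAULT_DCT_CUTOFF_S,
) -> np.ndarray:
    """Discrete-cosine high-pass regressors (non-constant terms only).

    Returns the K = floor(2 * T * TR / cutoff) lowest-frequency cosine
    columns, i.e. the components with period longer than ``cutoff_seconds``.
    Columns are mutually orthogonal; the constant (k = 0) term is excluded
    because the regression design carries an explicit intercept.
    """
    if n_timepoints < 2:
        raise PreprocessError("need at least 2 timepoints for a DCT basis")
    if cutoff_seconds <= 0:
        raise PreprocessError("cutoff_seconds must be positive")
    k_max = int(np.floor(2.0 * n_timepoints * tr_seconds / cutoff_seconds))
    if k_max == 0:
        logger.warning(
            "DCT cutoff %.0f s exceeds 2*T*TR = %.0f s; returning empty basis",
            cutoff_seconds,
            2.0 * n_timepoints * tr_seconds,
        )
        return np.empty((n_timepoints, 0))
    t = np.arange(n_timepoints)
    k = np.arange(1, k_max + 1)
    # DCT-II family: cos(pi * (t + 1/2) * k / T); orthogonal over t.
    basis = np.cos(np.pi * np.outer(t + 0.5, k) / n_timepoints)
    return basis * np.sqrt(2.0 / n_timepoints)


def _design_matrix(confounds: ConfoundTable) -> tuple[np.ndarray, list[str]]:
    t = confounds.n_timepoints
    trend = np.linspace(-1.0, 1.0, t)
    cols = [np.ones(t), trend]
    names = ["intercept", "trend"]
    for i, name in enumerate(MOTION_COLUMNS):
        cols.append(confounds.motion[:, i])
        names.append(name)
    cols.append(confounds.wm_signal)
    names.append("white_matter")
    cols.append(confounds.csf_signal)
    names.append("csf")
    for k in range(confounds.cosine_basis.shape[1]):
        cols.append(confounds.cosine_basis[:, k])
        names.append(f"cosine{k:02d}")
    return np.column_stack(cols), names


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise naming the collinear columns if the design is rank deficient."""
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [names[j] for j in piv[len(diag):]]
    if bad:
        raise PreprocessError(
            "rank-deficient confound design; collinear columns: "
            + ", ".join(sorted(bad))
        )


def regress_confounds(
    series: np.ndarray,
    confounds: ConfoundTable,
    subject_id: str = "",
    group: str = "",
    region_labels: list[str] | None = None,
) -> CleanedSeries:
    """Remove nuisance signals from a T x R series and standardize.

    The design matrix is [intercept, linear trend, 6 motion parameters,
    white matter, CSF, cosine basis]; all regressors are fitted jointly in
    a single least-squares pass per region.  Residuals are shifted to zero
    mean and scaled to unit variance using the sample (T-1) standard
    deviation.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise PreprocessError("series must be a T x R matrix")
    if series.shape[0] != confounds.n_timepoints:
        raise PreprocessError(
            f"series has T={series.shape[0]} but confounds have "
            f"T={confounds.n_timepoints}"
        )
    labels = region_labels or [
        f"ROI_{i + 1:03d}" for i in range(series.shape[1])
    ]
    design, names = _design_matrix(confounds)
    # all-zero regressors (e.g. empty WM/CSF channels) are inert; drop them
    # so they are not reported as collinear
    norms = np.linalg.norm(design, axis=0)
    keep = norms > 1e-12 * max(1.0, norms.max())
    design = design[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    _check_rank(design, names)
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    resid = series - design @ beta

    sd = resid.std(axis=0, ddof=1)
    flat = np.where(sd < 1e-10 * max(1.0, np.abs(series).max()))[0]
    if flat.size:
        raise PreprocessError(
            "zero residual variance (region fully explained by confounds): "
            + ", ".join(labels[i] for i in flat)
        )
    cleaned = (resid - resid.mean(axis=0)) / sd
    return CleanedSeries(
        data=cleaned,
        subject_id=subject_id,
        group=group,
        region_labels=list(labels),
    )
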