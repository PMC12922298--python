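"""Two-group synthetic naturalistic-fMRI generator with a closed-form oracle.

The generative model emulates the signal structure that makes ISFC work:
every subject watches the same "movie", modelled as a latent T x R
Gaussian signal matrix whose columns have a prescribed cross-region
correlation Sigma_u and first-order autoregressive temporal coloring.
Subject s in group g observes

    x_s[t, r] = w_g[r] * u[t, r] + sigma * e_s[t, r]

with region-specific stimulus gains w_g in [0, 1] and white idiosyncratic
noise e_s, independent across subjects.  Because the latent draw is shared
and the noise is not, the population pairwise ISFC between regions i and j
(correlating different subjects) has the closed form

    rho_ij = w_i * w_j * Sigma_u[i, j] / sqrt((w_i^2 + sigma^2) * (w_j^2 + sigma^2))

which :func:`expected_pairwise_isfc` evaluates and the rest of the package
is validated against.  Group differences are planted by giving the two
groups different gain vectors, so the latent stimulus stays genuinely
shared across everyone.

The generator also simulates fMRIPrep-style confound tables: random-walk
motion parameters calibrated to a target mean framewise displacement
(with an optional fraction of "high movers" crossing the 0.5 mm exclusion
threshold), plus autocorrelated white-matter/CSF signals and standardized
DVARS, all independent of the latent stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .preprocess import ConfoundTable, build_dct_basis, framewise_displacement

#: Canonical group labels: neurotypical and autism.
GROUPS = ("NT", "AUT")

#: Mean FD (mm) targeted for planted high movers; safely above the 0.5 mm
#: exclusion threshold but realistic for a restless participant.
HIGH_MOVER_MEAN_FD = 0.8


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


def _as_matrix(x, r: int, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (r, r):
        raise ConfigurationError(f"{name} must be {r} x {r}, got {m.shape}")
    return m


@dataclass
class SyntheticConfig:
    """Parameters of the two-group generative model.

    Parameters
    ----------
    n_regions, n_timepoints:
        R atlas regions and T volumes per subject.
    tr_seconds:
        Repetition time in seconds (sampling interval of the series).
    group_sizes:
        (n_NT, n_AUT) subjects per group, each at least 2.
    stimulus_correlation:
        R x R unit-diagonal positive-semidefinite correlation matrix of
        the latent stimulus signals (Sigma_u).
    weights_by_group:
        Mapping group label -> length-R gain vector with entries in [0, 1].
    noise_sd:
        Idiosyncratic noise standard deviation sigma (> 0).  Latent
        signals have unit variance, so sigma is a noise-to-signal ratio.
    smoothness:
        Temporal autocorrelation length in TRs (AR(1) coloring with
        coefficient exp(-1/smoothness)); 0 means white latent signals.
    motion_mean_fd_by_group:
        Mapping group label -> target mean framewise displacement (mm)
        for ordinary movers.
    high_mover_fraction:
        Fraction of subjects (per cohort) whose motion is scaled to a
        mean FD above the 0.5 mm exclusion threshold.
    seed:
        Base seed for all randomness in :func:`build_dataset`.
    """

    n_regions: int
    n_timepoints: int
    group_sizes: tuple[int, int]
    stimulus_correlation: np.ndarray
    weights_by_group: dict[str, np.ndarray]
    tr_seconds: float = 2.0
    noise_sd: float = 1.0
    smoothness: float = 0.0
    motion_mean_fd_by_group: dict[str, float] = field(
        default_factory=lambda: {g: 0.15 for g in GROUPS}
    )
    high_mover_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_timepoints < 2:
            raise ConfigurationError("need n_regions >= 1 and n_timepoints >= 2")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        self.group_sizes = tuple(int(n) for n in self.group_sizes)
        if len(self.group_sizes) != 2 or min(self.group_sizes) < 2:
            raise ConfigurationError("group_sizes must be two integers >= 2")
        r = self.n_regions
        sigma_u = _as_matrix(self.stimulus_correlation, r, "stimulus_correlation")
        if not np.allclose(sigma_u, sigma_u.T, atol=1e-10):
            raise ConfigurationError("stimulus_correlation must be symmetric")
        if not np.allclose(np.diag(sigma_u), 1.0, atol=1e-10):
            raise ConfigurationError("stimulus_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(sigma_u)
        if eigvals[0] < -1e-10:
            raise ConfigurationError(
                "stimulus_correlation is not positive semidefinite: "
                f"smallest eigenvalue {eigvals[0]:.3e}"
            )
        self.stimulus_correlation = sigma_u
        weights = {}
        for g in GROUPS:
            if g not in self.weights_by_group:
                raise ConfigurationError(f"weights_by_group missing group {g!r}")
            w = np.asarray(self.weights_by_group[g], dtype=float).ravel()
            if w.shape[0] != r:
                raise ConfigurationError(
                    f"weights for {g} have length {w.shape[0]}, expected {r}"
                )
            if (w < 0).any() or (w > 1).any():
                raise ConfigurationError(f"weights for {g} must lie in [0, 1]")
            weights[g] = w
        self.weights_by_group = weights
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.smoothness < 0:
            raise ConfigurationError("smoothness must be nonnegative")
        if not 0.0 <= self.high_mover_fraction <= 1.0:
            raise ConfigurationError("high_mover_fraction must lie in [0, 1]")
        for g in GROUPS:
            if self.motion_mean_fd_by_group.get(g, 0.0) < 0:
                raise ConfigurationError("motion_mean_fd_by_group must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        raw = dict(raw)
        r = int(raw["n_regions"])
        sigma_u = raw.get("stimulus_correlation")
        if sigma_u is None:
            # Shorthand: a single off-diagonal value among the first
            # `coupled_regions` regions (identity elsewhere).
            rho = float(raw.pop("stimulus_offdiag", 0.5))
            k = int(raw.pop("coupled_regions", r))
            sigma_u = np.eye(r)
            sigma_u[:k, :k] = rho
            np.fill_diagonal(sigma_u, 1.0)
        raw["stimulus_correlation"] = np.asarray(sigma_u, dtype=float)
        weights = raw["weights_by_group"]
        raw["weights_by_group"] = {
            g: np.broadcast_to(np.asarray(w, dtype=float), (r,)).copy()
            for g, w in weights.items()
        }
        raw["group_sizes"] = tuple(raw["group_sizes"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in raw.items() if k in known})


@dataclass
class SubjectRecord:
    """One simulated subject: id, group label, and T x R series."""

    subject_id: str
    group: str
    data: np.ndarray


@dataclass
class SyntheticDataset:
    """A simulated two-group cohort with ground truth attached."""

    subjects: list[SubjectRecord]
    confounds: dict[str, ConfoundTable]
    truth_expected_isfc: dict[str, np.ndarray]
    planted_pairs: list[tuple[int, int, int]]
    region_labels: list[str]
    config: SyntheticConfig

    def series_by_group(self, group: str) -> list[np.ndarray]:
        return [s.data for s in self.subjects if s.group == group]


def _psd_factor(sigma_u: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD correlation matrix (handles singularity)."""
    eigvals, eigvecs = np.linalg.eigh(sigma_u)
    if eigvals[0] < -1e-10:
        raise ConfigurationError(
            f"stimulus_correlation not PSD: smallest eigenvalue {eigvals[0]:.3e}"
        )
    return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def sample_latent_stimulus(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the shared latent stimulus signal matrix (T x R).

    Columns are zero-mean unit-variance Gaussian with cross-column
    correlation ``config.stimulus_correlation``.  Temporal structure is a
    stationary AR(1) process with coefficient exp(-1/smoothness), applied
    identically to every column so the cross-column correlation is
    preserved exactly.
    """
    t, r = config.n_timepoints, config.n_regions
    factor = _psd_factor(config.stimulus_correlation)
    z = rng.standard_normal((t, r))
    if config.smoothness > 0:
        phi = math.exp(-1.0 / config.smoothness)
        innov_scale = math.sqrt(1.0 - phi * phi)
        u = np.empty_like(z)
        u[0] = z[0]
        for i in range(1, t):
            u[i] = phi * u[i - 1] + innov_scale * z[i]
    else:
        u = z
    return u @ factor.T


def synthesize_subject(
    latent: np.ndarray,
    weights: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed series: gain-scaled latent plus white idiosyncratic noise."""
    latent = np.asarray(latent, dtype=float)
    weights = np.asarray(weights, dtype=float).ravel()
    if latent.ndim != 2 or weights.shape[0] != latent.shape[1]:
        raise ConfigurationError(
            f"weights length {weights.shape[0]} does not match latent "
            f"shape {latent.shape}"
        )
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    return weights * latent + noise_sd * rng.standard_normal(latent.shape)


def expected_pairwise_isfc(config: SyntheticConfig, group: str) -> np.ndarray:
    """Population pairwise ISFC matrix implied by the generative model.

    rho_ij = w_i w_j Sigma_u[i, j] / sqrt((w_i^2 + sigma^2)(w_j^2 + sigma^2)),
    including the diagonal i = j (the inter-subject correlation of each
    region).  Exact for any T; the sample median ISFC converges to it.
    """
    if group not in config.weights_by_group:
        raise ConfigurationError(f"unknown group {group!r}")
    w = config.weights_by_group[group]
    s2 = config.noise_sd ** 2
    denom = np.sqrt(np.outer(w ** 2 + s2, w ** 2 + s2))
    return (np.outer(w, w) * config.stimulus_correlation) / denom


def _calibrated_motion_walk(
    t: int, target_mean_fd: float, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk motion parameters whose mean FD equals the target.

    Steps are iid Gaussian per parameter; mean FD is exactly linear in a
    global step scale, so one rescale from the realized to the target mean
    FD calibrates it to machine precision.
    """
    # Relative step scales: translations in mm, rotations in radians
    # (a rotation step contributes 50x its size to FD).
    step_sd = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01])
    steps = rng.standard_normal((t - 1, 6)) * step_sd
    walk = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    realized = framewise_displacement(walk)[1:].mean()
    scale = 0.0 if realized == 0 else target_mean_fd / realized
    return walk * scale


def _ar1_noise(t: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(t)
    u = np.empty(t)
    u[0] = z[0]
    innov = math.sqrt(1.0 - phi * phi)
    for i in range(1, t):
        u[i] = phi * u[i - 1] + innov * z[i]
    return u


def sample_motion_confounds(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, ConfoundTable]:
    """Simulate fMRIPrep-style confound tables for every subject.

    Motion is an independent random walk per subject, calibrated so mean
    FD matches the group target; a ``high_mover_fraction`` of each group's
    subjects is instead calibrated to mean FD above the 0.5 mm exclusion
    threshold.  WM/CSF signals are AR(1) noise uncorrelated with the
    latent stimulus; standardized DVARS is a positive noise series.
    """
    t = config.n_timepoints
    cosine = build_dct_basis(t, config.tr_seconds)
    tables: dict[str, ConfoundTable] = {}
    for group, n in zip(GROUPS, config.group_sizes):
        n_high = int(round(config.high_mover_fraction * n))
        high = set(rng.permutation(n)[:n_high].tolist())
        base_fd = config.motion_mean_fd_by_group.get(group, 0.15)
        for i in range(n):
            subject_id = f"sub-{group}{i + 1:02d}"
            target = HIGH_MOVER_MEAN_FD if i in high else base_fd
            motion = _calibrated_motion_walk(t, target, rng)
            wm = _ar1_noise(t, 0.3, rng)
            csf = _ar1_noise(t, 0.3, rng)
            dvars = np.abs(1.0 + 0.2 * rng.standard_normal(t))
            dvars[0] = 0.0
            tables[subject_id] = ConfoundTable(
                motion=motion,
                wm_signal=wm,
                csf_signal=csf,
                cosine_basis=cosine,
                fd=framewise_displacement(motion),
                std_dvars=dvars,
            )
    return tables


def build_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate the full two-group cohort from one shared latent draw."""
    rng = np.random.default_rng(config.seed)
    latent = sample_latent_stimulus(config, rng)
    subjects: list[SubjectRecord] = []
    for group, n in zip(GROUPS, config.group_sizes):
        w = config.weights_by_group[group]
        for i in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{group}{i + 1:02d}",
                    group=group,
                    data=synthesize_subject(latent, w, config.noise_sd, rng),
                )
            )
    confounds = sample_motion_confounds(config, rng)
    truth = {g: expected_pairwise_isfc(config, g) for g in GROUPS}
    diff = truth[GROUPS[0]] - truth[GROUPS[1]]
    planted = [
        (i, j, 1 if diff[i, j] > 0 else -1)
        for i in range(config.n_regions)
        for j in range(i + 1, config.n_regions)
        if abs(diff[i, j]) > 1e-12
    ]
    labels = [f"ROI_{i + 1:03d}" for i in range(config.n_regions)]
    return SyntheticDataset(
        subjects=subjects,
        confounds=confounds,
        truth_expected_isfc=truth,
        planted_pairs=planted,
        region_labels=labels,
        config=config,
    )


def default_two_group_config(
    n_regions: int = 15,
    n_timepoints: int = 300,
    group_sizes: tuple[int, int] = (15, 15),
    effect_regions: int = 5,
    nt_weight: float = 0.9,
    aut_weight: float = 0.3,
    background_weight: float = 0.5,
    stimulus_rho: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticConfig:
    """A ready-made configuration with a planted group difference.

    The first ``effect_regions`` regions respond to the stimulus with gain
    ``nt_weight`` in the neurotypical group but only ``aut_weight`` in the
    autism group (inter-subject hypoconnectivity); all other regions share
    ``background_weight``.  The latent stimulus is equicorrelated at
    ``stimulus_rho`` among the effect regions and independent elsewhere.
    """
    sigma_u = np.eye(n_regions)
    k = min(effect_regions, n_regions)
    sigma_u[:k, :k] = stimulus_rho
    np.fill_diagonal(sigma_u, 1.0)
    w_nt = np.full(n_regions, background_weight)
    w_aut = np.full(n_regions, background_weight)
    w_nt[:k] = nt_weight
    w_aut[:k] = aut_weight
    return SyntheticConfig(
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        group_sizes=group_sizes,
        stimulus_correlation=sigma_u,
        weights_by_group={"NT": w_nt, "AUT": w_aut},
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def null_config(**kwargs) -> SyntheticConfig:
    """A configuration with identical weights in both groups (no effect)."""
    kwargs.setdefault("nt_weight", 0.6)
    kwargs.setdefault("aut_weight", 0.6)
    kwargs.setdefault("background_weight", 0.6)
    return default_two_group_config(**kwargs)
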