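"""Noise-normalised minimum-norm source estimation (simplified dSPM).

The inverse kernel is the classic regularised minimum-norm operator

    W = R G' (G R G' + lambda2 * C)^{-1}

with identity source covariance R (optionally rescaled so that the whitened
gain has unit average power, which makes the kernel invariant to a global
rescaling of the noise covariance C).  dSPM divides each source's
minimum-norm estimate by its noise sensitivity sqrt(diag(W C W')), yielding
z-like current-density values: for data that is pure noise with covariance
C, each source's output has unit variance.

The noise covariance is estimated from pre-stimulus baseline samples pooled
over trials with analytic (Ledoit-Wolf) shrinkage toward a scaled identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf

from .atlas import DK_REGIONS, STIMULATED_REGION
from .evoked_metrics import Evoked, WindowSpec, window_mean
from .preprocess import EpochSet


@dataclass
class SourceModel:
    """Leadfield plus vertex-to-region labelling.

    Attributes
    ----------
    leadfield : ndarray, shape (n_channels, n_sources)
        Gain matrix mapping source amplitudes to sensor voltages.
    region_labels : ndarray of str, shape (n_sources,)
        Desikan-Killiany region of each source; every source has exactly one.
    ch_names : list of str
        Sensor labels matching the leadfield rows.
    source_positions : ndarray, shape (n_sources, 3), optional
    region_names : tuple of str
        Canonical region order for all region-level outputs.
    stimulated_region : str
        Region containing the TMS target (DLPFC).
    """

    leadfield: np.ndarray
    region_labels: np.ndarray
    ch_names: list[str]
    source_positions: np.ndarray | None = None
    region_names: tuple[str, ...] = DK_REGIONS
    stimulated_region: str = STIMULATED_REGION

    def __post_init__(self) -> None:
        self.leadfield = np.asarray(self.leadfield, dtype=np.float64)
        self.region_labels = np.asarray(self.region_labels)
        if not np.all(np.isfinite(self.leadfield)):
            raise ValueError("leadfield contains non-finite values")
        if self.leadfield.shape[1] != self.region_labels.size:
            raise ValueError("one region label per source is required")
        if self.leadfield.shape[0] != len(self.ch_names):
            raise ValueError("leadfield rows must match channel names")
        unknown = set(self.region_labels) - set(self.region_names)
        if unknown:
            raise ValueError(f"labels outside the atlas: {sorted(unknown)}")

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]

    def region_source_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_labels == region)


@dataclass
class NoiseCov:
    """Shrinkage-regularised sensor noise covariance."""

    matrix: np.ndarray
    shrinkage: float
    baseline_window: tuple[float, float]
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(self.matrix).min() <= 0:
            raise ValueError("noise covariance must be positive definite")


@dataclass
class InverseOperator:
    """Minimum-norm kernel with per-source dSPM normalisation factors."""

    kernel: np.ndarray  # sources x channels
    lambda2: float
    norm_factors: np.ndarray  # sqrt(diag(W C W'))
    ch_names: list[str]

    def __post_init__(self) -> None:
        if np.any(self.norm_factors <= 0):
            raise ValueError("normalisation factors must be positive")


@dataclass
class RegionSeries:
    """Per-region dSPM current-density time series (regions x time)."""

    data: np.ndarray
    region_names: tuple[str, ...]
    times: np.ndarray
    subject: str = ""
    condition: str = ""


def estimate_noise_cov(
    epochs: EpochSet, baseline: tuple[float, float] = (-500.0, -15.0)
) -> NoiseCov:
    """Ledoit-Wolf shrinkage covariance of pooled pre-stimulus samples."""
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials to estimate noise covariance")
    mask = epochs.time_mask(baseline)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    # (trials, channels, nb) -> (trials * nb, channels)
    x = epochs.data[:, :, mask].transpose(0, 2, 1).reshape(-1, epochs.n_channels)
    lw = LedoitWolf().fit(x)
    cov = lw.covariance_.copy()
    cov = 0.5 * (cov + cov.T)
    # guard against numerically semidefinite output
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        cov += (abs(w.min()) + 1e-12 * np.trace(cov) / cov.shape[0]) * np.eye(
            cov.shape[0]
        )
    return NoiseCov(
        matrix=cov,
        shrinkage=float(lw.shrinkage_),
        baseline_window=tuple(baseline),
        ch_names=list(epochs.ch_names),
    )


def compute_inverse(
    source_model: SourceModel,
    noise_cov: NoiseCov,
    lambda2: float = 1.0 / 9.0,
    rescale_source_cov: bool = False,
) -> InverseOperator:
    """Regularised minimum-norm kernel with dSPM normalisation.

    With ``rescale_source_cov`` the identity source covariance is scaled so
    that trace(G' C^{-1} G) * rho = n_channels, which makes the kernel
    invariant to a global rescaling of C (the regularisation then acts on a
    fixed signal-to-noise scale).
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    G = source_model.leadfield
    C = noise_cov.matrix
    if list(noise_cov.ch_names) and list(noise_cov.ch_names) != list(
        source_model.ch_names
    ):
        raise ValueError("noise covariance channels do not match the leadfield")
    rho = 1.0
    if rescale_source_cov:
        rho = G.shape[0] / np.trace(G.T @ np.linalg.solve(C, G))
    A = rho * (G @ G.T) + lambda2 * C
    try:
        K = rho * np.linalg.solve(A, G).T  # rho * G' A^{-1}
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular inverse system; increase lambda2"
        ) from err
    norm = np.sqrt(np.einsum("ij,jk,ik->i", K, C, K))
    return InverseOperator(
        kernel=K,
        lambda2=float(lambda2),
        norm_factors=norm,
        ch_names=list(source_model.ch_names),
    )


def apply_dspm(
    inverse_operator: InverseOperator,
    evoked: Evoked | np.ndarray,
    nave: int = 1,
) -> np.ndarray:
    """Noise-normalised source estimate z_i(t) = [W x(t)]_i / norm_i.

    ``nave`` scales the normalisation for trial-averaged input whose noise
    covariance is C / nave; the default 1 treats the input at single-trial
    noise level (group contrasts are invariant to this overall scale).
    """
    if isinstance(evoked, Evoked):
        if list(evoked.ch_names) != list(inverse_operator.ch_names):
            raise ValueError("evoked channels do not match the inverse operator")
        x = evoked.data
    else:
        x = np.asarray(evoked, dtype=float)
    if x.shape[0] != inverse_operator.kernel.shape[1]:
        raise ValueError("channel dimension mismatch")
    norm = inverse_operator.norm_factors / np.sqrt(nave)
    return (inverse_operator.kernel @ x) / norm[:, None]


def extract_region_series(
    source_z: np.ndarray,
    source_model: SourceModel,
    times: np.ndarray,
    subject: str = "",
    condition: str = "",
) -> RegionSeries:
    """Signed mean of member-source z values per atlas region."""
    out = np.empty((len(source_model.region_names), source_z.shape[1]))
    for i, region in enumerate(source_model.region_names):
        idx = source_model.region_source_indices(region)
        if idx.size == 0:
            raise ValueError(f"region {region!r} has no sources")
        out[i] = source_z[idx].mean(axis=0)
    return RegionSeries(
        data=out,
        region_names=tuple(source_model.region_names),
        times=np.asarray(times, dtype=float),
        subject=subject,
        condition=condition,
    )


def icf_dspm(
    region_series_paired: RegionSeries,
    region_series_single: RegionSeries,
    window: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Per-region window mean of the paired-minus-single dSPM difference."""
    a, b = region_series_paired, region_series_single
    if a.data.shape != b.data.shape or not np.allclose(a.times, b.times):
        raise ValueError("region series are not aligned")
    diff = a.data - b.data
    return np.asarray(window_mean(diff, a.times, window))
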