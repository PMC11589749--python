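"""Synthetic study-condition generator with recorded ground truth.

Two generators drive every downstream analysis:

* ``generate_tep_dataset`` emulates a paired-pulse (ICF) TMS-EEG study:
  two groups (treatment-resistant depression and healthy controls), two
  conditions per subject (single pulse, paired pulse), epoched sensor data
  produced by projecting a damped-sinusoid evoked response through a random
  well-conditioned leadfield and adding spatially correlated Gaussian noise.
  A group reduction of the paired-minus-single source response in the
  50-120 ms window is planted with a chosen standardised size at the
  stimulated (DLPFC) region and scaled elsewhere by a propagation profile.

* ``generate_expression_fixture`` emulates donor-level microarray probe
  tables in the style of the Allen Human Brain Atlas: six donors, probes
  with above-background flags, genes with one or two probes, planted
  failures for every downstream filter (background fraction, differential
  stability, 2-mm sample assignment, right hemisphere), and one cell type
  whose regional expression has an exactly planted correlation with a
  supplied 34-region map.

Everything planted is enumerated in a ground-truth record, and identical
seed + configuration reproduces identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .atlas import (
    CELL_TYPES,
    CHANNELS_64,
    DK_REGIONS,
    PROTECTED_CHANNELS,
    STIMULATED_REGION,
)
from .preprocess import EpochSet
from .source_inverse import SourceModel

# ---------------------------------------------------------------------------
# geometry shared between the source model and the expression fixture
# ---------------------------------------------------------------------------


def synthetic_region_centroids(n_regions: int = 34) -> np.ndarray:
    """Deterministic left-hemisphere region centroids (mm), 12 mm apart.

    A rectangular grid stands in for cortical geometry; only inter-centroid
    distances matter (sample assignment, propagation decay).
    """
    side = int(np.ceil(n_regions ** (1 / 3)))
    pts = []
    for i in range(n_regions):
        x = i % side
        y = (i // side) % side
        z = i // (side * side)
        pts.append((-30.0 - 12.0 * x, -24.0 + 12.0 * y, 10.0 + 12.0 * z))
    return np.asarray(pts)


def default_propagation_profile(
    n_regions: int = 34, decay_mm: float = 25.0
) -> np.ndarray:
    """Effect-propagation weights: 1 at the stimulated region, exponential
    decay with centroid distance elsewhere."""
    cents = synthetic_region_centroids(n_regions)
    stim = DK_REGIONS.index(STIMULATED_REGION) if n_regions == 34 else 0
    d = np.linalg.norm(cents - cents[stim], axis=1)
    return np.exp(-d / decay_mm)


def _region_names(n_regions: int) -> tuple[str, ...]:
    if n_regions == 34:
        return DK_REGIONS
    return tuple(f"region{i:02d}" for i in range(n_regions))


# ---------------------------------------------------------------------------
# TEP cohort configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactSpec:
    """Counts of planted artifacts per subject and condition."""

    n_bad_channels: int = 0
    n_bad_epochs: int = 0
    n_tms_transients: int = 0
    bad_channel_gain: float = 50.0
    bad_epoch_amplitude: float = 1500.0  # µV
    transient_amplitude: float = 5000.0  # µV


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic ICF TMS-EEG cohort.

    The defaults are the full study: 60 TRD / 30 HC subjects, 80 trials per
    condition, 64 channels at 3 kHz, epochs from -2000 to 2000 ms, 34
    Desikan-Killiany regions.  ``planted_effect_d`` is the standardised
    (Cohen's d) reduction of the paired-minus-single window response in the
    TRD group at the stimulated region; 0 defines the null configuration.
    """

    n_trd: int = 60
    n_hc: int = 30
    n_trials_per_condition: int = 80
    n_channels: int = 64
    sampling_rate: float = 3000.0
    epoch_window: tuple[float, float] = (-2000.0, 2000.0)
    n_regions: int = 34
    n_sources_per_region: int = 2
    planted_effect_d: float = 0.0
    propagation_profile: tuple[float, ...] | None = None
    noise_sd: float = 20.0  # µV, single-trial sensor noise scale
    artifact_spec: ArtifactSpec = ArtifactSpec()
    seed: int = 0

    # evoked-response and variance-component parameters (source units;
    # the waveform peaks near 100 ms post-stimulus, see ``evoked_waveform``)
    amp_single: float = 1.0
    icf_gain: float = 1.0
    between_subject_sd: float = 0.4
    subject_common_sd: float = 0.2
    leadfield_scale: float = 40.0  # µV at the sensors per unit source
    channel_gain_range: tuple[float, float] = (0.8, 1.2)
    waveform_components: tuple[tuple[float, float, float], ...] = (
        # (frequency Hz, decay tau ms, amplitude); the sum peaks near 90 ms
        (2.5, 350.0, 1.0),
        (8.0, 60.0, 0.15),
        (25.0, 25.0, 0.1),
    )

    def __post_init__(self) -> None:
        for name in (
            "n_trd",
            "n_hc",
            "n_trials_per_condition",
            "n_channels",
            "n_regions",
            "n_sources_per_region",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window start must precede end")
        if self.epoch_window[0] > -515.0 or self.epoch_window[1] < 130.0:
            raise ValueError(
                "epoch window must cover the baseline (-500..-15 ms) and the "
                "50-120 ms analysis window"
            )
        if self.propagation_profile is not None and (
            len(self.propagation_profile) != self.n_regions
        ):
            raise ValueError("propagation_profile length must equal n_regions")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def profile(self) -> np.ndarray:
        if self.propagation_profile is not None:
            return np.asarray(self.propagation_profile, dtype=float)
        return default_propagation_profile(self.n_regions)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["artifact_spec"] = dataclasses.asdict(self.artifact_spec)
        return d


@dataclass
class GroundTruth:
    """Everything the generator planted, for verification downstream."""

    config: dict[str, Any]
    effect_profile: np.ndarray
    planted_effect_d: float
    subjects: list[str]
    groups: dict[str, str]  # subject -> "TRD" | "HC"
    true_icf_index: dict[str, np.ndarray]  # subject -> per-region ICF amplitude
    group_mean_amplitudes: dict[str, dict[str, np.ndarray]]
    waveform: np.ndarray
    waveform_times: np.ndarray
    bad_channels: dict[str, dict[str, list[str]]]
    bad_epochs: dict[str, dict[str, list[int]]]
    transient_epochs: dict[str, dict[str, list[int]]]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "effect_profile": self.effect_profile.tolist(),
            "planted_effect_d": self.planted_effect_d,
            "subjects": self.subjects,
            "groups": self.groups,
            "true_icf_index": {k: v.tolist() for k, v in self.true_icf_index.items()},
            "group_mean_amplitudes": {
                g: {c: a.tolist() for c, a in d.items()}
                for g, d in self.group_mean_amplitudes.items()
            },
            "waveform": self.waveform.tolist(),
            "waveform_times": self.waveform_times.tolist(),
            "bad_channels": self.bad_channels,
            "bad_epochs": self.bad_epochs,
            "transient_epochs": self.transient_epochs,
        }


@dataclass
class TepDataset:
    """One synthetic cohort: epochs per subject/condition plus side tables."""

    epochs: dict[tuple[str, str], EpochSet]
    source_model: SourceModel
    clinical: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def subjects(self) -> list[str]:
        return self.ground_truth.subjects

    @property
    def conditions(self) -> tuple[str, str]:
        return ("single", "paired")


def evoked_waveform(
    times_ms: np.ndarray,
    components: tuple[tuple[float, float, float], ...] = SynthConfig.waveform_components,
) -> np.ndarray:
    """Damped-sinusoid evoked response, zero pre-stimulus, unit peak.

    Each component contributes a * exp(-t/tau) * sin(2*pi*f*t/1000) for
    t >= 0; with the default components the summed response peaks near
    100 ms after the pulse.
    """
    t = np.asarray(times_ms, dtype=float)
    w = np.zeros_like(t)
    post = t >= 0
    tp = t[post]
    for f, tau, a in components:
        w[post] += a * np.exp(-tp / tau) * np.sin(2 * np.pi * f * tp / 1000.0)
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def _make_leadfield(
    rng: np.random.Generator, n_channels: int, n_sources: int, scale: float
) -> np.ndarray:
    """Random leadfield; orthonormal columns when possible, otherwise
    condition number clipped to <= 50, then scaled to `scale` per column."""
    G = rng.standard_normal((n_channels, n_sources))
    if n_sources <= n_channels:
        Q, _ = np.linalg.qr(G)
        return scale * Q[:, :n_sources]
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    s = np.clip(s, s.max() / 50.0, None)
    G = U @ np.diag(s) @ Vt
    G *= scale / np.linalg.norm(G, axis=0).mean()
    return G


def _gaussian_bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def generate_tep_dataset(config: SynthConfig) -> TepDataset:
    """Simulate one cohort of epoched ICF TMS-EEG recordings.

    The paired-minus-single source amplitude at region r for subject s is

        icf(s, r) = icf_gain * profile_r + sigma_b * eps(s, r)
                    - is_trd(s) * d * sigma_b * profile_r

    with eps iid standard normal, so the standardised group difference is
    exactly ``planted_effect_d * profile_r`` (1 at the stimulated region).
    A subject-level amplitude offset shared by both conditions models
    between-subject excitability and cancels in the contrast.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    region_names = _region_names(cfg.n_regions)
    profile = cfg.profile()

    n_src = cfg.n_regions * cfg.n_sources_per_region
    ch_names = list(CHANNELS_64[: cfg.n_channels])
    if cfg.n_channels > len(CHANNELS_64):
        raise ValueError("at most 64 channels are supported")

    G = _make_leadfield(rng, cfg.n_channels, n_src, cfg.leadfield_scale)
    labels = np.repeat(region_names, cfg.n_sources_per_region)
    src_pos = np.repeat(
        synthetic_region_centroids(cfg.n_regions), cfg.n_sources_per_region, axis=0
    )
    source_model = SourceModel(
        leadfield=G,
        region_labels=labels,
        ch_names=ch_names,
        source_positions=src_pos,
        region_names=region_names,
        stimulated_region=(
            STIMULATED_REGION if cfg.n_regions == 34 else region_names[0]
        ),
    )

    # spatially correlated noise: random factor correlation, unit diagonal
    k = max(4, cfg.n_channels // 4)
    B = rng.standard_normal((cfg.n_channels, k))
    C0 = B @ B.T + 0.5 * np.eye(cfg.n_channels)
    dinv = 1.0 / np.sqrt(np.diag(C0))
    corr = C0 * np.outer(dinv, dinv)
    L = np.linalg.cholesky(corr)
    ch_gains = np.linspace(*cfg.channel_gain_range, cfg.n_channels)

    n_t = int(round((cfg.epoch_window[1] - cfg.epoch_window[0])
                    * cfg.sampling_rate / 1000.0)) + 1
    times = cfg.epoch_window[0] + np.arange(n_t) * 1000.0 / cfg.sampling_rate
    wave = evoked_waveform(times, cfg.waveform_components)

    subjects = [f"sub-T{i + 1:03d}" for i in range(cfg.n_trd)] + [
        f"sub-H{i + 1:03d}" for i in range(cfg.n_hc)
    ]
    groups = {s: ("TRD" if s.startswith("sub-T") else "HC") for s in subjects}

    spec = cfg.artifact_spec
    eligible_bad = [c for c in ch_names if c not in PROTECTED_CHANNELS]

    epochs: dict[tuple[str, str], EpochSet] = {}
    truth_icf: dict[str, np.ndarray] = {}
    bad_channels: dict[str, dict[str, list[str]]] = {}
    bad_epochs: dict[str, dict[str, list[int]]] = {}
    transients: dict[str, dict[str, list[int]]] = {}
    amp_sums = {g: {"single": np.zeros(cfg.n_regions), "paired": np.zeros(cfg.n_regions)}
                for g in ("TRD", "HC")}

    rep = cfg.n_sources_per_region
    for subj in subjects:
        is_trd = groups[subj] == "TRD"
        w_s = cfg.subject_common_sd * rng.standard_normal()
        eps = rng.standard_normal(cfg.n_regions)
        a_single = profile * (cfg.amp_single + w_s)
        icf = (
            cfg.icf_gain * profile
            + cfg.between_subject_sd * eps
            - (cfg.planted_effect_d * cfg.between_subject_sd * profile
               if is_trd else 0.0)
        )
        a_paired = a_single + icf
        truth_icf[subj] = icf
        amp_sums[groups[subj]]["single"] += a_single
        amp_sums[groups[subj]]["paired"] += a_paired

        bad_channels[subj] = {}
        bad_epochs[subj] = {}
        transients[subj] = {}
        for cond, amp in (("single", a_single), ("paired", a_paired)):
            sensor_sig = (G @ np.repeat(amp, rep))[:, None] * wave[None, :]
            z = rng.standard_normal(
                (cfg.n_trials_per_condition, cfg.n_channels, n_t)
            )
            noise = np.einsum("ck,tkn->tcn", L, z)
            noise *= (cfg.noise_sd * ch_gains)[None, :, None]
            data = sensor_sig[None, :, :] + noise

            planted_bad = sorted(
                rng.choice(eligible_bad, size=spec.n_bad_channels, replace=False)
                .tolist()
            )
            for name in planted_bad:
                data[:, ch_names.index(name), :] *= spec.bad_channel_gain

            trial_pool = rng.permutation(cfg.n_trials_per_condition)
            planted_epochs = sorted(trial_pool[: spec.n_bad_epochs].tolist())
            hi = cfg.epoch_window[1]
            for tr in planted_epochs:
                center = rng.uniform(min(130.0, hi - 60.0), hi - 50.0)
                data[tr] += spec.bad_epoch_amplitude * _gaussian_bump(
                    times, center, 5.0
                )[None, :]
            planted_tms = sorted(
                trial_pool[spec.n_bad_epochs:
                           spec.n_bad_epochs + spec.n_tms_transients].tolist()
            )
            for tr in planted_tms:
                data[tr] += spec.transient_amplitude * _gaussian_bump(
                    times, 10.0, 4.0
                )[None, :]

            epochs[(subj, cond)] = EpochSet(
                data=data,
                ch_names=list(ch_names),
                sfreq=cfg.sampling_rate,
                times=times.copy(),
            )
            bad_channels[subj][cond] = planted_bad
            bad_epochs[subj][cond] = planted_epochs
            transients[subj][cond] = planted_tms

    group_means = {
        g: {c: amp_sums[g][c] / (cfg.n_trd if g == "TRD" else cfg.n_hc)
            for c in ("single", "paired")}
        for g in ("TRD", "HC")
    }

    clinical = _clinical_table(rng, subjects, groups)

    truth = GroundTruth(
        config=cfg.to_dict(),
        effect_profile=profile,
        planted_effect_d=cfg.planted_effect_d,
        subjects=subjects,
        groups=groups,
        true_icf_index=truth_icf,
        group_mean_amplitudes=group_means,
        waveform=wave,
        waveform_times=times,
        bad_channels=bad_channels,
        bad_epochs=bad_epochs,
        transient_epochs=transients,
    )
    return TepDataset(
        epochs=epochs,
        source_model=source_model,
        clinical=clinical,
        ground_truth=truth,
    )


def _clinical_table(
    rng: np.random.Generator, subjects: list[str], groups: dict[str, str]
) -> pd.DataFrame:
    """Clinical covariates matched to the study's demographic summaries.

    Ages ~ N(45.4, 11.9) / N(45.6, 13.2) for TRD / HC, 40% female in both
    groups, MADRS ~ N(32.1, 7.1) clipped to the >=18 inclusion criterion and
    illness duration ~ N(10.9, 9.2) years for TRD; clinical scores are
    independent of the planted neurophysiological effect.
    """
    rows = []
    trd = [s for s in subjects if groups[s] == "TRD"]
    hc = [s for s in subjects if groups[s] == "HC"]
    sex_map: dict[str, str] = {}
    for members in (trd, hc):
        n_f = int(round(0.4 * len(members)))
        shuffled = list(rng.permutation(members))
        for i, s in enumerate(shuffled):
            sex_map[s] = "F" if i < n_f else "M"
    for s in subjects:
        is_trd = groups[s] == "TRD"
        age = rng.normal(45.37, 11.85) if is_trd else rng.normal(45.63, 13.16)
        rows.append(
            {
                "subject": s,
                "group": groups[s],
                "age": float(np.clip(age, 18.0, 80.0)),
                "sex": sex_map[s],
                "madrs": float(max(18.0, rng.normal(32.1, 7.1))) if is_trd
                else np.nan,
                "duration_illness": float(max(0.5, rng.normal(10.9, 9.2)))
                if is_trd else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExprFixtureConfig:
    """Conditions for the donor-level expression fixture.

    160 genes across six donors by default: half of the genes are stable
    across donors (these include the nine 8-gene cell-type marker sets) and
    survive the differential-stability filter; the other half have
    donor-independent regional profiles and are filtered out.  Genes whose
    only probe fails the background filter are planted in equal numbers on
    both sides so that the median-DS cutoff falls in the gap between the
    stable and unstable clusters.  Planted filter probes/samples exercise
    every preprocessing rule.
    """

    n_genes: int = 160
    n_donors: int = 6
    n_regions: int = 34
    cell_set_size: int = 8
    target_cell_type: str = "astrocyte"
    planted_correlation: float = 0.0
    target_map: tuple[float, ...] | None = None
    stable_fraction: float = 0.5
    n_bg_fail_probes: int = 8
    n_bg_fail_genes: int = 8
    second_probe_fraction: float = 0.3
    n_far_samples_per_donor: int = 3
    n_right_samples_per_donor: int = 3
    donor_noise_sd: float = 0.05
    probe_noise_sd: float = 0.02
    second_probe_noise_sd: float = 0.5
    bg_fail_above_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise ValueError("planted correlation must lie in [-1, 1]")
        if self.target_cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.target_cell_type!r}")
        if self.n_bg_fail_genes % 2:
            raise ValueError("n_bg_fail_genes must be even (balanced halves)")
        n_stable = int(round(self.stable_fraction * self.n_genes))
        need = self.cell_set_size * len(CELL_TYPES) + self.n_bg_fail_genes // 2
        if n_stable < need:
            raise ValueError(
                "stable genes cannot hold the marker sets plus the planted "
                "background failures"
            )
        if self.target_map is not None and len(self.target_map) != self.n_regions:
            raise ValueError("target_map length must equal n_regions")


@dataclass
class ExpressionFixture:
    """Donor-level probe tables plus gene-to-cell-type annotation."""

    probes: pd.DataFrame  # probe_id, gene_id
    intensities: pd.DataFrame  # probe_id x sample_id
    flags: pd.DataFrame  # probe_id x sample_id, bool
    samples: pd.DataFrame  # sample_id, donor_id, hemisphere, x, y, z
    cell_annotations: pd.DataFrame  # gene_id, cell_type
    region_centroids: pd.DataFrame  # region, x, y, z (left hemisphere)


@dataclass
class ExpressionGroundTruth:
    """Planted truth for the expression fixture."""

    config: dict[str, Any]
    target_map: np.ndarray
    gene_profiles: pd.DataFrame  # stable genes x regions (the planted truth)
    bg_surviving_probes: list[str]
    bg_surviving_genes: list[str]
    ds_surviving_genes: list[str]
    selected_probe: dict[str, str]
    assigned_samples: dict[str, str]  # sample_id -> region
    dropped_samples: dict[str, str]  # sample_id -> reason
    cell_sets: dict[str, list[str]]
    true_mean_correlation: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "target_map": self.target_map.tolist(),
            "bg_surviving_probes": self.bg_surviving_probes,
            "bg_surviving_genes": self.bg_surviving_genes,
            "ds_surviving_genes": self.ds_surviving_genes,
            "selected_probe": self.selected_probe,
            "assigned_samples": self.assigned_samples,
            "dropped_samples": self.dropped_samples,
            "cell_sets": self.cell_sets,
            "true_mean_correlation": self.true_mean_correlation,
        }


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std()


def _exact_corr_vector(
    rng: np.random.Generator, target: np.ndarray, rho: float
) -> np.ndarray:
    """Vector whose sample Pearson correlation with ``target`` is exactly rho."""
    zt = _standardize(target)
    e = rng.standard_normal(target.size)
    e = e - e.mean()
    e -= zt * (e @ zt) / (zt @ zt)
    ze = e / e.std()
    return rho * zt + np.sqrt(max(0.0, 1.0 - rho**2)) * ze


def generate_expression_fixture(
    config: ExprFixtureConfig,
) -> tuple[ExpressionFixture, ExpressionGroundTruth]:
    """Build a donor-level probe fixture with fully enumerated planted truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    region_names = _region_names(cfg.n_regions)
    cents = synthetic_region_centroids(cfg.n_regions)

    if cfg.target_map is not None:
        target = np.asarray(cfg.target_map, dtype=float)
    else:
        target = rng.standard_normal(cfg.n_regions)
    target = _standardize(target)

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    n_stable = int(round(cfg.stable_fraction * cfg.n_genes))
    stable_genes = genes[:n_stable]
    unstable_genes = genes[n_stable:]

    # marker sets occupy the first 9 * set_size stable genes; the target cell
    # type's genes carry the planted correlation with the target map
    cell_sets: dict[str, list[str]] = {}
    cursor = 0
    for ct in CELL_TYPES:
        cell_sets[ct] = stable_genes[cursor: cursor + cfg.cell_set_size]
        cursor += cfg.cell_set_size

    profiles = {}
    for g in stable_genes:
        if g in cell_sets[cfg.target_cell_type]:
            profiles[g] = _exact_corr_vector(rng, target, cfg.planted_correlation)
        else:
            profiles[g] = _standardize(rng.standard_normal(cfg.n_regions))
    gene_profiles = pd.DataFrame(profiles, index=list(region_names)).T

    # genes whose only probe fails the background filter; planted in equal
    # numbers on the stable (non-marker) and unstable side so the halves
    # stay balanced and the median-DS cutoff falls between the clusters
    half = cfg.n_bg_fail_genes // 2
    bg_fail_genes = stable_genes[n_stable - half:] + unstable_genes[:half]

    # --- samples ---------------------------------------------------------
    sample_rows = []
    assigned: dict[str, str] = {}
    dropped: dict[str, str] = {}
    far_offset = np.array([4.0, 0.0, 0.0]) / np.sqrt(1.0)
    for d in range(cfg.n_donors):
        donor = f"D{d + 1}"
        for r, region in enumerate(region_names):
            jitter = rng.uniform(-0.45, 0.45, size=3)  # |jitter| <= 0.78 mm
            sid = f"{donor}_s{r:03d}"
            x, y, z = cents[r] + jitter
            sample_rows.append((sid, donor, "L", x, y, z, region))
            assigned[sid] = region
        for j in range(cfg.n_far_samples_per_donor):
            r = int(rng.integers(cfg.n_regions))
            sid = f"{donor}_far{j}"
            x, y, z = cents[r] + far_offset + rng.uniform(-0.3, 0.3, size=3)
            sample_rows.append((sid, donor, "L", x, y, z, region_names[r]))
            dropped[sid] = "beyond_2mm"
        for j in range(cfg.n_right_samples_per_donor):
            r = int(rng.integers(cfg.n_regions))
            sid = f"{donor}_right{j}"
            x, y, z = cents[r] * np.array([-1.0, 1.0, 1.0])
            sample_rows.append((sid, donor, "R", x, y, z, region_names[r]))
            dropped[sid] = "right_hemisphere"
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "donor_id", "hemisphere", "x", "y", "z",
                 "nearest_region"],
    )

    # per-donor, per-gene regional truth (stable: shared; unstable: per-donor)
    donor_gene_region = {}
    for d in range(cfg.n_donors):
        donor = f"D{d + 1}"
        mat = np.empty((cfg.n_genes, cfg.n_regions))
        for i, g in enumerate(genes):
            if g in gene_profiles.index:
                mat[i] = gene_profiles.loc[g].to_numpy() + (
                    cfg.donor_noise_sd * rng.standard_normal(cfg.n_regions)
                )
            else:
                mat[i] = _standardize(rng.standard_normal(cfg.n_regions))
        donor_gene_region[donor] = mat

    # --- probes ----------------------------------------------------------
    probe_rows = []
    n_second = int(round(cfg.second_probe_fraction * cfg.n_genes))
    second_probe_genes = set(
        rng.choice(
            [g for g in genes if g not in bg_fail_genes],
            size=n_second, replace=False,
        ).tolist()
    )
    for g in genes:
        probe_rows.append((f"P_{g}_a", g, "primary"))
        if g in second_probe_genes:
            probe_rows.append((f"P_{g}_b", g, "secondary"))
    bg_host_genes = rng.choice(
        [g for g in genes if g not in bg_fail_genes],
        size=cfg.n_bg_fail_probes, replace=False,
    ).tolist()
    for j, g in enumerate(bg_host_genes):
        probe_rows.append((f"P_{g}_bg{j}", g, "bg_fail"))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "kind"])

    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_ids = samples["sample_id"].tolist()
    donor_of = samples.set_index("sample_id")["donor_id"].to_dict()
    nearest = samples.set_index("sample_id")["nearest_region"].to_dict()
    region_pos = {r: i for i, r in enumerate(region_names)}

    # base[sample, gene] looked up from each donor's gene-by-region truth
    donor_stack = np.stack([donor_gene_region[f"D{d + 1}"]
                            for d in range(cfg.n_donors)])
    donor_idx = np.array([int(donor_of[s][1:]) - 1 for s in sample_ids])
    sample_region_idx = np.array([region_pos[nearest[s]] for s in sample_ids])
    base_sg = donor_stack[donor_idx, :, sample_region_idx]  # samples x genes

    intens = np.empty((len(probes), len(sample_ids)))
    flags = np.ones_like(intens, dtype=bool)
    for pi, (pid, g, kind) in enumerate(
        probes[["probe_id", "gene_id", "kind"]].itertuples(index=False)
    ):
        noise_sd = (
            cfg.probe_noise_sd if kind == "primary" else cfg.second_probe_noise_sd
        )
        intens[pi] = base_sg[:, gene_pos[g]] + noise_sd * rng.standard_normal(
            len(sample_ids)
        )
        if kind == "bg_fail" or g in bg_fail_genes:
            flags[pi] = (
                rng.random(len(sample_ids)) < cfg.bg_fail_above_fraction
            )
    intensities = pd.DataFrame(
        intens, index=probes["probe_id"].tolist(), columns=sample_ids
    )
    flag_df = pd.DataFrame(
        flags, index=probes["probe_id"].tolist(), columns=sample_ids
    )

    annotations = pd.DataFrame(
        [(g, ct) for ct, gs in cell_sets.items() for g in gs],
        columns=["gene_id", "cell_type"],
    )
    centroid_df = pd.DataFrame(
        np.column_stack([cents]),
        columns=["x", "y", "z"],
    )
    centroid_df.insert(0, "region", list(region_names))

    # --- planted truth ---------------------------------------------------
    bg_survive_probes = [
        pid for pid, g, kind in
        probes[["probe_id", "gene_id", "kind"]].itertuples(index=False)
        if kind != "bg_fail" and g not in bg_fail_genes
    ]
    bg_survive_genes = [g for g in genes if g not in bg_fail_genes]
    ds_survive = [g for g in stable_genes if g not in bg_fail_genes]
    selected_probe = {g: f"P_{g}_a" for g in ds_survive}

    true_corr = {}
    for ct, gs in cell_sets.items():
        rs = [
            float(np.corrcoef(gene_profiles.loc[g].to_numpy(), target)[0, 1])
            for g in gs
        ]
        true_corr[ct] = float(np.mean(rs))

    truth = ExpressionGroundTruth(
        config=dataclasses.asdict(cfg),
        target_map=target,
        gene_profiles=gene_profiles,
        bg_surviving_probes=bg_survive_probes,
        bg_surviving_genes=bg_survive_genes,
        ds_surviving_genes=ds_survive,
        selected_probe=selected_probe,
        assigned_samples=assigned,
        dropped_samples=dropped,
        cell_sets=cell_sets,
        true_mean_correlation=true_corr,
    )
    fixture = ExpressionFixture(
        probes=probes[["probe_id", "gene_id"]].copy(),
        intensities=intensities,
        flags=flag_df,
        samples=samples[["sample_id", "donor_id", "hemisphere", "x", "y", "z"]]
        .copy(),
        cell_annotations=annotations,
        region_centroids=centroid_df,
    )
    return fixture, truth


# ---------------------------------------------------------------------------
# cohort bundle (directory of files consumed by every downstream module)
# ---------------------------------------------------------------------------


def generate_cohort_bundle(
    config: SynthConfig,
    path,
    expression_config: ExprFixtureConfig | None = None,
) -> dict[str, Any]:
    """Write a complete cohort (EEG + source model + expression + clinical)
    to ``path`` and return the manifest.

    The expression fixture's target map defaults to the cohort's planted
    effect-propagation profile, so the target cell type's regional
    expression correlates with the expected group-difference map.  The
    manifest records configuration and seeds only (no timestamps), so the
    same seed and configuration give byte-identical manifests.
    """
    from pathlib import Path

    from . import io as _io

    out = Path(path)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    dataset = generate_tep_dataset(config)

    if expression_config is None:
        expression_config = ExprFixtureConfig(
            n_regions=config.n_regions,
            target_map=tuple(config.profile().tolist()),
            planted_correlation=0.6 if config.planted_effect_d != 0 else 0.0,
            seed=config.seed + 1,
        )
    fixture, expr_truth = generate_expression_fixture(expression_config)

    files = []
    for (subj, cond), eps in sorted(dataset.epochs.items()):
        rel = f"epochs/{subj}_{cond}.h5"
        _io.save_epochs(out / rel, eps)
        files.append(rel)
    _io.save_source_model(out / "source_model.h5", dataset.source_model)
    dataset.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    _io.save_expression_fixture(out / "expression", fixture)
    _io.write_json(
        out / "ground_truth.json",
        {
            "tep": dataset.ground_truth.to_dict(),
            "expression": expr_truth.to_dict(),
        },
    )
    _io.write_yaml(out / "config.yaml", config.to_dict())

    manifest = {
        "config": config.to_dict(),
        "expression_config": dataclasses.asdict(expression_config),
        "seed": config.seed,
        "files": sorted(
            files
            + [
                "source_model.h5",
                "clinical.tsv",
                "config.yaml",
                "ground_truth.json",
            ]
            + [f"expression/{n}" for n in (
                "probes.tsv", "intensities.tsv", "flags.tsv", "samples.tsv",
                "cell_annotations.tsv", "region_centroids.tsv",
            )]
        ),
    }
    _io.write_json(out / "manifest.json", manifest)
    return manifest


def load_cohort_bundle(path) -> tuple[TepDataset, ExpressionFixture, dict]:
    """Read a bundle directory back into in-memory objects."""
    import json
    from pathlib import Path

    from . import io as _io

    src = Path(path)
    truth_raw = json.loads((src / "ground_truth.json").read_text())
    t = truth_raw["tep"]
    truth = GroundTruth(
        config=t["config"],
        effect_profile=np.asarray(t["effect_profile"]),
        planted_effect_d=t["planted_effect_d"],
        subjects=t["subjects"],
        groups=t["groups"],
        true_icf_index={k: np.asarray(v) for k, v in t["true_icf_index"].items()},
        group_mean_amplitudes={
            g: {c: np.asarray(a) for c, a in d.items()}
            for g, d in t["group_mean_amplitudes"].items()
        },
        waveform=np.asarray(t["waveform"]),
        waveform_times=np.asarray(t["waveform_times"]),
        bad_channels=t["bad_channels"],
        bad_epochs=t["bad_epochs"],
        transient_epochs=t["transient_epochs"],
    )
    epochs = {}
    for subj in truth.subjects:
        for cond in ("single", "paired"):
            epochs[(subj, cond)] = _io.load_epochs(
                src / "epochs" / f"{subj}_{cond}.h5"
            )
    dataset = TepDataset(
        epochs=epochs,
        source_model=_io.load_source_model(src / "source_model.h5"),
        clinical=pd.read_csv(src / "clinical.tsv", sep="\t"),
        ground_truth=truth,
    )
    fixture = _io.load_expression_fixture(src / "expression")
    return dataset, fixture, truth_raw["expression"]
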