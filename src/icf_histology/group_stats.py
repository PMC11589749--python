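"""Group comparisons, the 34-region t-map, and the end-to-end study run.

All group contrasts use the pooled-variance (Student) two-sample t-test:
the degrees of freedom reported by the study (n1 + n2 - 2) identify the
pooled form.  Cohen's d uses the pooled standard deviation.  The regional
t-map is computed HC minus TRD, so positive t means the index is reduced
in the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats

from .atlas import DK_REGIONS, ROI_ELECTRODES
from .evoked_metrics import WindowSpec, average_tep, icf_contrast, lmfp, roi_series, window_mean
from .preprocess import PreprocessParams, run_preprocessing
from .source_inverse import (
    apply_dspm,
    compute_inverse,
    estimate_noise_cov,
    extract_region_series,
    icf_dspm,
)
from .synthetic_data import TepDataset


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample t-test with effect size."""

    t: float
    df: int
    p: float
    cohen_d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict[str, float]:
        return {
            "t": self.t, "df": self.df, "p": self.p, "cohen_d": self.cohen_d,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "n_a": self.n_a, "n_b": self.n_b,
        }


@dataclass
class TMap:
    """Per-region t-values, canonical region order, HC minus TRD."""

    t: np.ndarray
    region_names: tuple[str, ...] = DK_REGIONS
    contrast: str = "HC - TRD"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size != len(self.region_names):
            raise ValueError("one t-value per region is required")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t-map contains non-finite values")


def _pooled_t(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TTestResult:
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 <= 0:
        raise ZeroDivisionError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = (mean_a - mean_b) / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    d = (mean_a - mean_b) / np.sqrt(sp2)
    return TTestResult(
        t=float(t), df=int(df), p=float(p), cohen_d=float(d),
        mean_a=float(mean_a), mean_b=float(mean_b),
        sd_a=float(sd_a), sd_b=float(sd_b), n_a=int(n_a), n_b=int(n_b),
    )


def two_sample_t(values_a, values_b) -> TTestResult:
    """Student (pooled-variance) t-test on raw observations, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    return _pooled_t(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TTestResult:
    """Pooled two-sample t from summary statistics only."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    return _pooled_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b)


def chi2_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def regional_tmap(
    icf_dspm_hc: np.ndarray,
    icf_dspm_trd: np.ndarray,
    region_names: tuple[str, ...] = DK_REGIONS,
) -> TMap:
    """Per-region HC-vs-TRD t-map over subjects x regions index matrices."""
    hc = np.atleast_2d(np.asarray(icf_dspm_hc, dtype=float))
    trd = np.atleast_2d(np.asarray(icf_dspm_trd, dtype=float))
    if hc.shape[1] != trd.shape[1] or hc.shape[1] != len(region_names):
        raise ValueError("index matrices must be subjects x regions")
    t = np.array(
        [two_sample_t(hc[:, r], trd[:, r]).t for r in range(hc.shape[1])]
    )
    return TMap(t=t, region_names=tuple(region_names))


def clinical_correlation(
    index_values, scores, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between a physiological index and a clinical score."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("zero variance in one of the variables")
    if method == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """End-to-end outputs of one cohort analysis."""

    subjects: list[str]
    groups: dict[str, str]
    excluded: list[str]
    sensor_icf_tep: dict[str, float]
    sensor_icf_lmfp: dict[str, float]
    icf_dspm_index: pd.DataFrame  # subjects x regions
    dlpfc_ttest: TTestResult
    sensor_tep_ttest: TTestResult
    sensor_lmfp_ttest: TTestResult
    tmap: TMap
    clinical_correlations: dict[str, tuple[float, float]]
    virtual_histology: pd.DataFrame | None = None
    params: dict[str, Any] = field(default_factory=dict)


def subject_icf_indices(
    dataset: TepDataset,
    window: WindowSpec = WindowSpec(),
    lambda2: float = 1.0 / 9.0,
    noise_baseline: tuple[float, float] = (-500.0, -15.0),
    preprocess: bool = True,
    preprocess_params: PreprocessParams | None = None,
    subjects: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-subject source and sensor ICF indices.

    For each subject: (optionally) preprocess both conditions, estimate one
    shrinkage noise covariance from the pooled pre-stimulus baselines, build
    the dSPM inverse, project the two condition evokeds, extract region
    series and window-average the paired-minus-single difference.

    Returns the subjects x regions ICF-dSPM index matrix and a dict of
    sensor indices (ICF-TEP and ICF-LMFP window means).
    """
    sm = dataset.source_model
    regions = sm.region_names
    subs = subjects if subjects is not None else dataset.subjects
    rows = {}
    sensor: dict[str, dict[str, float]] = {}
    for subj in subs:
        eps = {}
        for cond in ("single", "paired"):
            e = dataset.epochs[(subj, cond)]
            if preprocess:
                e = run_preprocessing(e, preprocess_params)
            eps[cond] = e
        pooled = eps["single"].copy()
        pooled.data = np.concatenate(
            [eps["single"].data, eps["paired"].data], axis=0
        )
        pooled.trial_ids = np.arange(pooled.data.shape[0])
        cov = estimate_noise_cov(pooled, baseline=noise_baseline)
        inv = compute_inverse(sm, cov, lambda2=lambda2)

        evoked = {c: average_tep(eps[c], condition=c) for c in ("single", "paired")}
        rs = {
            c: extract_region_series(
                apply_dspm(inv, evoked[c]), sm, evoked[c].times,
                subject=subj, condition=c,
            )
            for c in ("single", "paired")
        }
        rows[subj] = icf_dspm(rs["paired"], rs["single"], window)

        roi = {c: roi_series(evoked[c], ROI_ELECTRODES) for c in evoked}
        lm = {c: lmfp(evoked[c], ROI_ELECTRODES) for c in evoked}
        times = evoked["single"].times
        sensor[subj] = {
            "icf_tep": float(
                window_mean(icf_contrast(roi["paired"], roi["single"]), times, window)
            ),
            "icf_lmfp": float(
                window_mean(icf_contrast(lm["paired"], lm["single"]), times, window)
            ),
        }
    index = pd.DataFrame.from_dict(rows, orient="index", columns=list(regions))
    return index, sensor


def run_study(
    dataset: TepDataset,
    window: WindowSpec = WindowSpec(),
    lambda2: float = 1.0 / 9.0,
    preprocess: bool = True,
    preprocess_params: PreprocessParams | None = None,
    exclude: list[str] | None = None,
    correlation_method: str = "pearson",
    virtual_histology_inputs: tuple | None = None,
) -> StudyReport:
    """Run the full two-group analysis on one cohort.

    ``exclude`` lists subjects dropped for incomplete data; one exclusion
    list applies to every analysis (sensor, source, clinical).  When
    ``virtual_histology_inputs`` provides (expression_matrix, cell_sets,
    vh_config), the resampling test is run against the cohort's regional
    t-map.
    """
    excluded = list(exclude or [])
    subs = [s for s in dataset.subjects if s not in excluded]
    index, sensor = subject_icf_indices(
        dataset, window=window, lambda2=lambda2, preprocess=preprocess,
        preprocess_params=preprocess_params, subjects=subs,
    )
    groups = dataset.ground_truth.groups
    hc = [s for s in subs if groups[s] == "HC"]
    trd = [s for s in subs if groups[s] == "TRD"]
    stim = dataset.source_model.stimulated_region

    dlpfc = two_sample_t(index.loc[hc, stim], index.loc[trd, stim])
    tep_t = two_sample_t(
        [sensor[s]["icf_tep"] for s in hc], [sensor[s]["icf_tep"] for s in trd]
    )
    lmfp_t = two_sample_t(
        [sensor[s]["icf_lmfp"] for s in hc], [sensor[s]["icf_lmfp"] for s in trd]
    )
    tmap = regional_tmap(
        index.loc[hc].to_numpy(), index.loc[trd].to_numpy(),
        region_names=dataset.source_model.region_names,
    )

    clin = dataset.clinical.set_index("subject")
    corr = {}
    trd_index = index.loc[trd, stim].to_numpy()
    for score in ("madrs", "duration_illness"):
        vals = clin.loc[trd, score].to_numpy(dtype=float)
        corr[score] = clinical_correlation(trd_index, vals, correlation_method)

    vh = None
    if virtual_histology_inputs is not None:
        from .virtual_histology import run_virtual_histology

        expr, cell_sets, vh_config = virtual_histology_inputs
        vh = run_virtual_histology(expr, cell_sets, tmap.t, vh_config)

    return StudyReport(
        subjects=subs,
        groups={s: groups[s] for s in subs},
        excluded=excluded,
        sensor_icf_tep={s: sensor[s]["icf_tep"] for s in subs},
        sensor_icf_lmfp={s: sensor[s]["icf_lmfp"] for s in subs},
        icf_dspm_index=index,
        dlpfc_ttest=dlpfc,
        sensor_tep_ttest=tep_t,
        sensor_lmfp_ttest=lmfp_t,
        tmap=tmap,
        clinical_correlations=corr,
        params={
            "window": (window.start, window.end),
            "lambda2": lambda2,
            "preprocess": preprocess,
            "correlation_method": correlation_method,
        },
    )
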