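"""Monte-Carlo calibration of the full pipeline under known truth.

These routines regenerate many independent synthetic cohorts or expression
fixtures and push each through the actual analysis code, measuring
operating characteristics: recovery of the planted standardised effect,
type-I error of the group test under the null configuration, type-I error
of the virtual-histology resampling test, and agreement of the resampled
empirical p-value with exhaustive enumeration.

The replicate cohorts use a reduced problem size (fewer trials, channels
and samples than the full study conditions) chosen so that hundreds of
replicates run at desk scale; the planted effect structure, analysis
window, noise model and estimator chain are identical to the full
configuration.  Because sensor noise is white in time and averages out of
the 70 ms window mean, the standardised effect is insensitive to the
trial and sample counts (see the methods note).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_stats import subject_icf_indices, two_sample_t
from .synthetic_data import (
    ExprFixtureConfig,
    SynthConfig,
    generate_expression_fixture,
    generate_tep_dataset,
)
from .expression_pipeline import run_expression_pipeline
from .virtual_histology import (
    VHConfig,
    empirical_p_two_sided,
    enumerate_null_exact,
    exact_p_two_sided,
    resample_null,
    run_virtual_histology,
    set_mean_correlation,
)

#: Reduced-size cohort used for replicate-based calibration: identical
#: effect structure and estimators to the full study conditions, scaled
#: down in trials / channels / sampling rate so that hundreds of cohorts
#: are feasible.
REPLICATE_CONFIG = SynthConfig(
    n_trd=59,
    n_hc=29,
    n_trials_per_condition=8,
    n_channels=40,
    sampling_rate=250.0,
    epoch_window=(-600.0, 200.0),
    n_sources_per_region=1,
)


def _measure_cohort(config: SynthConfig):
    """Generate one cohort and return the stimulated-region group t-test."""
    dataset = generate_tep_dataset(config)
    index, _ = subject_icf_indices(dataset, preprocess=False)
    stim = dataset.source_model.stimulated_region
    groups = dataset.ground_truth.groups
    hc = [s for s in dataset.subjects if groups[s] == "HC"]
    trd = [s for s in dataset.subjects if groups[s] == "TRD"]
    return two_sample_t(index.loc[hc, stim], index.loc[trd, stim])


@dataclass
class EffectRecovery:
    planted_d: float
    mean_d: float
    sd_d: float
    frac_positive_t: float
    frac_reject: float
    n_replicates: int


def effect_recovery(
    planted_d: float,
    n_replicates: int = 200,
    seed: int = 0,
    base_config: SynthConfig = REPLICATE_CONFIG,
) -> EffectRecovery:
    """Recover the planted standardised group effect over replicate cohorts.

    Each replicate draws a fresh cohort (new subjects, leadfield and noise),
    runs the evoked -> dSPM -> region -> window pipeline and computes the
    HC-vs-TRD pooled t and Cohen's d at the stimulated region.
    """
    ds, ts, ps = [], [], []
    for i in range(n_replicates):
        cfg = dataclasses.replace(
            base_config, planted_effect_d=planted_d, seed=seed + i
        )
        res = _measure_cohort(cfg)
        ds.append(res.cohen_d)
        ts.append(res.t)
        ps.append(res.p)
    ds = np.asarray(ds)
    ts = np.asarray(ts)
    ps = np.asarray(ps)
    return EffectRecovery(
        planted_d=planted_d,
        mean_d=float(ds.mean()),
        sd_d=float(ds.std(ddof=1)),
        frac_positive_t=float((ts > 0).mean()),
        frac_reject=float((ps < 0.05).mean()),
        n_replicates=n_replicates,
    )


def null_cohort_rejection_rate(
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> float:
    """Type-I error of the stimulated-region group test under the null.

    Uses smaller null cohorts (20 TRD / 10 HC) by default; the test's
    calibration does not depend on the group sizes.
    """
    if base_config is None:
        base_config = dataclasses.replace(REPLICATE_CONFIG, n_trd=20, n_hc=10)
    rejections = 0
    for i in range(n_replicates):
        cfg = dataclasses.replace(
            base_config, planted_effect_d=0.0, seed=seed + i
        )
        if _measure_cohort(cfg).p < alpha:
            rejections += 1
    return rejections / n_replicates


def vh_null_rejection_rate(
    n_fixtures: int = 500,
    n_resamples: int = 1999,
    alpha: float = 0.05,
    seed: int = 0,
    fixture_config: ExprFixtureConfig | None = None,
) -> float:
    """Per-cell-type type-I error of the resampling test on null fixtures.

    Each fixture is a fresh donor-level probe table with no planted
    map correlation, processed by the full expression pipeline; the map is
    an independent random 34-vector.  Returns the fraction of (fixture,
    cell type) pairs with empirical p below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for i in range(n_fixtures):
        cfg = fixture_config or ExprFixtureConfig()
        cfg = dataclasses.replace(
            cfg, planted_correlation=0.0, target_map=None, seed=seed + 7919 * i
        )
        fixture, _ = generate_expression_fixture(cfg)
        matrix, cell_sets, _ = run_expression_pipeline(
            _probe_table(fixture),
            fixture.region_centroids,
            annotations=fixture.cell_annotations,
        )
        tmap = rng.standard_normal(matrix.values.shape[1])
        vh = run_virtual_histology(
            matrix, cell_sets, tmap,
            VHConfig(n_resamples=n_resamples, seed=int(rng.integers(2**31))),
        )
        hits += int((vh["p_empirical"] < alpha).sum())
        total += len(vh)
    return hits / total


def _probe_table(fixture):
    from .expression_pipeline import ProbeTable

    return ProbeTable(
        probes=fixture.probes,
        intensities=fixture.intensities,
        flags=fixture.flags,
        samples=fixture.samples,
    )


@dataclass
class ResampleAgreement:
    p_resampled: float
    p_exact: float
    mc_se: float
    within_3se: bool


def resample_enumeration_agreement(
    n_seeds: int = 20,
    n_resamples: int = 100_000,
    pool_size: int = 10,
    set_size: int = 2,
    seed: int = 0,
) -> list[ResampleAgreement]:
    """Compare resampled and exhaustive empirical p on small gene pools.

    For each seed a fresh random expression pool and map are drawn, an
    observed set statistic computed, the null both enumerated exactly and
    resampled, and the two p-values compared on the Monte-Carlo standard
    error scale.
    """
    out = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed + i)
        expr = pd.DataFrame(
            rng.standard_normal((pool_size, 34)),
            index=[f"G{j:03d}" for j in range(pool_size)],
        )
        tmap = rng.standard_normal(34)
        obs_set = list(expr.index[:set_size])
        observed = set_mean_correlation(obs_set, expr, tmap)
        exact = enumerate_null_exact(set_size, expr, tmap)
        p_exact = exact_p_two_sided(observed, exact)
        null = resample_null(
            set_size, expr, tmap,
            VHConfig(n_resamples=n_resamples, seed=seed + 1000 + i),
        )
        p_res = empirical_p_two_sided(observed, null)
        # MC SE of the doubled smaller tail
        q = min(p_exact / 2.0, 1.0 - p_exact / 2.0)
        se = 2.0 * np.sqrt(q * (1 - q) / n_resamples)
        out.append(
            ResampleAgreement(
                p_resampled=p_res,
                p_exact=p_exact,
                mc_se=float(se),
                within_3se=bool(abs(p_res - p_exact) <= 3 * se + 2 / (n_resamples + 1)),
            )
        )
    return out
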