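"""Shared configuration for the numbered analysis scripts.

The desk-scale cohort keeps the full study's group sizes (59 TRD / 29
HC), effect structure, analysis window, planted effect size (d = 0.52)
and artifact model, scaled down in trials, channels and sampling rate so
the whole narrative runs in a couple of minutes.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

from icf_histology.synthetic_data import ArtifactSpec, SynthConfig  # noqa: E402

DESK_CONFIG = SynthConfig(
    n_trd=59,
    n_hc=29,
    n_trials_per_condition=12,
    # at least as many channels as regions: with 34 sources an orthonormal
    # leadfield needs >= 34 sensors, otherwise dSPM crosstalk attenuates
    # the planted regional effect
    n_channels=40,
    sampling_rate=1000.0,
    epoch_window=(-600.0, 200.0),
    n_sources_per_region=1,
    planted_effect_d=0.52,
    # bad epochs and pulse transients exercise rejection and excision; no
    # bad channels: the synthetic leadfield is spatially unstructured, so
    # spherical-spline interpolation cannot reconstruct a lost sensor and
    # would inject condition-asymmetric error into every subject's
    # contrast (channel detection/interpolation is covered by the unit
    # tests on its own fixtures)
    artifact_spec=ArtifactSpec(n_bad_channels=0, n_bad_epochs=2,
                               n_tms_transients=1),
    seed=2026,
)
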