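"""On-disk formats: HDF5 epochs and source models, TSV expression tables,
JSON ground truth and manifest, YAML configuration.

A "cohort bundle" is a directory holding everything one study run needs:
epoch files per subject and condition, the source model, the clinical
table, an expression fixture, the generator's ground truth and a manifest
recording the configuration and seed.  Identical seed and configuration
produce byte-identical manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import EpochSet
from .source_inverse import SourceModel
from .synthetic_data import ExpressionFixture


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("times", data=epochs.times, track_times=False)
        f.create_dataset("trial_ids", data=epochs.trial_ids, track_times=False)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["ch_names"] = json.dumps(epochs.ch_names)
        f.attrs["bad_channels"] = json.dumps(epochs.bad_channels)
        f.attrs["reference"] = epochs.reference
        f.attrs["log"] = json.dumps(epochs.log)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            ch_names=json.loads(f.attrs["ch_names"]),
            sfreq=float(f.attrs["sfreq"]),
            times=f["times"][()],
            trial_ids=f["trial_ids"][()],
            bad_channels=json.loads(f.attrs["bad_channels"]),
            reference=str(f.attrs["reference"]),
            log=json.loads(f.attrs["log"]),
        )


def save_source_model(path: str | Path, model: SourceModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("leadfield", data=model.leadfield, track_times=False)
        f.create_dataset(
            "region_labels",
            data=np.array(model.region_labels, dtype="S"),
            track_times=False,
        )
        if model.source_positions is not None:
            f.create_dataset(
                "source_positions", data=model.source_positions,
                track_times=False,
            )
        f.attrs["ch_names"] = json.dumps(model.ch_names)
        f.attrs["region_names"] = json.dumps(list(model.region_names))
        f.attrs["stimulated_region"] = model.stimulated_region


def load_source_model(path: str | Path) -> SourceModel:
    with h5py.File(path, "r") as f:
        return SourceModel(
            leadfield=f["leadfield"][()],
            region_labels=f["region_labels"][()].astype(str),
            ch_names=json.loads(f.attrs["ch_names"]),
            source_positions=(
                f["source_positions"][()] if "source_positions" in f else None
            ),
            region_names=tuple(json.loads(f.attrs["region_names"])),
            stimulated_region=str(f.attrs["stimulated_region"]),
        )


def save_expression_fixture(directory: str | Path, fixture: ExpressionFixture) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fixture.probes.to_csv(d / "probes.tsv", sep="\t", index=False)
    fixture.intensities.to_csv(d / "intensities.tsv", sep="\t",
                               index_label="probe_id")
    fixture.flags.to_csv(d / "flags.tsv", sep="\t", index_label="probe_id")
    fixture.samples.to_csv(d / "samples.tsv", sep="\t", index=False)
    fixture.cell_annotations.to_csv(d / "cell_annotations.tsv", sep="\t",
                                    index=False)
    fixture.region_centroids.to_csv(d / "region_centroids.tsv", sep="\t",
                                    index=False)


def load_expression_fixture(directory: str | Path) -> ExpressionFixture:
    d = Path(directory)
    return ExpressionFixture(
        probes=pd.read_csv(d / "probes.tsv", sep="\t"),
        intensities=pd.read_csv(d / "intensities.tsv", sep="\t",
                                index_col="probe_id"),
        flags=pd.read_csv(d / "flags.tsv", sep="\t", index_col="probe_id")
        .astype(bool),
        samples=pd.read_csv(d / "samples.tsv", sep="\t"),
        cell_annotations=pd.read_csv(d / "cell_annotations.tsv", sep="\t"),
        region_centroids=pd.read_csv(d / "region_centroids.tsv", sep="\t"),
    )


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def write_yaml(path: str | Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
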