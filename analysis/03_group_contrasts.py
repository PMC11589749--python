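"""Group-level contrasts: sensor tests, regional t-map, clinical links.

Loads the per-subject indices from script 02, compares HC against TRD at
the stimulated region and at the sensor level, builds the 34-region
HC-minus-TRD t-map, and correlates the TRD group's stimulated-region
index with symptom severity and illness duration.
"""

import json

import numpy as np
import pandas as pd

from _common import DESK_CONFIG, RESULTS

from icf_histology.group_stats import (
    clinical_correlation,
    regional_tmap,
    two_sample_t,
)
from icf_histology.synthetic_data import generate_tep_dataset


def main() -> None:
    dataset = generate_tep_dataset(DESK_CONFIG)
    index = pd.read_csv(RESULTS / "02_icf_dspm_index.tsv", sep="\t",
                        index_col="subject")
    sensor = json.loads((RESULTS / "02_sensor_indices.json").read_text())

    groups = dataset.ground_truth.groups
    hc = [s for s in index.index if groups[s] == "HC"]
    trd = [s for s in index.index if groups[s] == "TRD"]
    stim = dataset.source_model.stimulated_region

    dlpfc = two_sample_t(index.loc[hc, stim], index.loc[trd, stim])
    tep = two_sample_t(
        [sensor[s]["icf_tep"] for s in hc],
        [sensor[s]["icf_tep"] for s in trd],
    )
    lmfp = two_sample_t(
        [sensor[s]["icf_lmfp"] for s in hc],
        [sensor[s]["icf_lmfp"] for s in trd],
    )
    tmap = regional_tmap(
        index.loc[hc].to_numpy(), index.loc[trd].to_numpy(),
        region_names=tuple(index.columns),
    )
    pd.DataFrame(
        {"region": list(index.columns), "t": tmap.t}
    ).to_csv(RESULTS / "03_tmap.tsv", sep="\t", index=False)

    clin = dataset.clinical.set_index("subject")
    corr = {}
    for score in ("madrs", "duration_illness"):
        r, p = clinical_correlation(
            index.loc[trd, stim].to_numpy(),
            clin.loc[trd, score].to_numpy(dtype=float),
        )
        corr[score] = {"r": round(r, 3), "p": round(p, 3)}

    out = {
        "stimulated_region": stim,
        "dlpfc_t": round(dlpfc.t, 3),
        "dlpfc_df": dlpfc.df,
        "dlpfc_p": round(dlpfc.p, 4),
        "dlpfc_cohen_d": round(dlpfc.cohen_d, 3),
        "sensor_tep_t": round(tep.t, 3),
        "sensor_tep_p": round(tep.p, 4),
        "sensor_lmfp_t": round(lmfp.t, 3),
        "sensor_lmfp_p": round(lmfp.p, 4),
        "tmap_peak_region": str(
            index.columns[int(np.argmax(np.abs(tmap.t)))]
        ),
        "clinical_correlations": corr,
        "planted_effect_d": DESK_CONFIG.planted_effect_d,
    }
    (RESULTS / "03_group_contrasts.json").write_text(
        json.dumps(out, indent=1, sort_keys=True) + "\n"
    )
    print(json.dumps(out, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
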