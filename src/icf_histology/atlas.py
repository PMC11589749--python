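"""Canonical Desikan-Killiany parcellation constants.

The study operates on the 34 cortical regions of one (left) hemisphere of
the Desikan-Killiany atlas.  Region order is fixed package-wide so that
region vectors (ICF-dSPM indices, t-maps, expression columns) are always
aligned by position.
"""

from __future__ import annotations

#: The 34 left-hemisphere Desikan-Killiany region names, canonical order.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

N_REGIONS: int = len(DK_REGIONS)

#: Region containing the DLPFC stimulation target (MNI [-38, 44, 26]).
STIMULATED_REGION: str = "rostralmiddlefrontal"
STIMULATED_REGION_INDEX: int = DK_REGIONS.index(STIMULATED_REGION)

#: The nine cell classes used for virtual histology.
CELL_TYPES: tuple[str, ...] = (
    "ependymal",
    "oligodendrocyte",
    "microglia",
    "CA1_pyramidal",
    "interneuron",
    "endothelial",
    "S1_pyramidal",
    "astrocyte",
    "mural",
)

#: 64 EEG channel labels (10-10 system) used by the synthetic recordings.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz", "F9", "F10",
)

#: Electrodes over the stimulation site, protected from automatic exclusion.
PROTECTED_CHANNELS: frozenset[str] = frozenset(
    {"F5", "F3", "F1", "F7", "AF3", "FC3", "FC5"}
)

#: Electrode cluster used for the sensor-level DLPFC readout.
ROI_ELECTRODES: tuple[str, ...] = ("F3", "F5", "AF3")


def region_index(name: str) -> int:
    """Position of ``name`` in the canonical region order."""
    try:
        return DK_REGIONS.index(name)
    except ValueError:
        raise KeyError(f"unknown Desikan-Killiany region: {name!r}") from None
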