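"""AHBA-style expression preprocessing to a genes x 34-region matrix.

From donor-level probe tables to a regional expression matrix: background
filtering (probes must exceed background in at least half of the samples),
differential-stability probe selection and gene filtering, nearest-region
sample assignment with a 2-mm cap and a left-hemisphere restriction,
within-donor normalisation, and donor averaging.  Cell-type marker sets
(nine classes) are loaded and restricted to the surviving genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import CELL_TYPES, DK_REGIONS


@dataclass
class ProbeTable:
    """Probe-level expression with background flags and donor structure."""

    probes: pd.DataFrame  # probe_id, gene_id
    intensities: pd.DataFrame  # probe_id x sample_id
    flags: pd.DataFrame  # probe_id x sample_id (bool)
    samples: pd.DataFrame  # sample_id, donor_id, hemisphere, x, y, z

    def __post_init__(self) -> None:
        if not self.flags.dtypes.map(lambda d: d == bool).all():
            raise ValueError("background flags must be boolean")
        if list(self.intensities.index) != list(self.probes["probe_id"]):
            raise ValueError("intensity rows must match the probe table")
        if self.probes.groupby("gene_id").size().min() < 1:
            raise ValueError("every gene needs at least one probe")
        coords = self.samples[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("sample coordinates must be finite")

    def subset(self, probe_ids: list[str]) -> "ProbeTable":
        keep = self.probes["probe_id"].isin(probe_ids)
        return ProbeTable(
            probes=self.probes[keep].reset_index(drop=True),
            intensities=self.intensities.loc[probe_ids],
            flags=self.flags.loc[probe_ids],
            samples=self.samples,
        )


@dataclass
class ExpressionMatrix:
    """Genes x regions expression with per-gene provenance."""

    values: pd.DataFrame  # gene_id x region (canonical order)
    provenance: pd.DataFrame  # gene_id, probe_id, ds_score
    normalization: str = "srs"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class CellTypeSets:
    """Disjoint gene sets, one per cell class."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        unknown = set(self.sets) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell classes: {sorted(unknown)}")
        seen: dict[str, str] = {}
        for ct, genes in self.sets.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g} assigned to both {seen[g]} and {ct}"
                    )
                seen[g] = ct

    def sizes(self) -> dict[str, int]:
        return {ct: len(genes) for ct, genes in self.sets.items()}


def filter_background(
    probe_table: ProbeTable, min_fraction: float = 0.5
) -> ProbeTable:
    """Keep probes above background in at least ``min_fraction`` of samples
    (boundary inclusive)."""
    frac = probe_table.flags.mean(axis=1)
    keep = frac[frac >= min_fraction].index.tolist()
    if not keep:
        raise ValueError("no probe survives the background filter")
    return probe_table.subset(keep)


def _donor_profiles(
    probe_table: ProbeTable, assignments: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Per-donor probe x region mean-intensity profiles over assigned samples."""
    sample_region = pd.Series(assignments, name="region")
    out: dict[str, pd.DataFrame] = {}
    samples = probe_table.samples.set_index("sample_id")
    for donor, grp in samples.groupby("donor_id"):
        sids = [s for s in grp.index if s in assignments]
        if not sids:
            continue
        sub = probe_table.intensities[sids]
        out[donor] = sub.T.groupby(sample_region.loc[sids]).mean().T
    return out


def differential_stability_scores(
    probe_table: ProbeTable, assignments: dict[str, str]
) -> pd.Series:
    """DS per probe: mean over donor pairs of the Pearson correlation
    between the probe's regional mean-expression profiles."""
    donors = _donor_profiles(probe_table, assignments)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least 2 donors")
    names = sorted(donors)
    scores = pd.Series(0.0, index=probe_table.intensities.index)
    counts = pd.Series(0, index=scores.index)
    for a, b in combinations(names, 2):
        pa, pb = donors[a], donors[b]
        common = pa.columns.intersection(pb.columns)
        if len(common) < 3:
            raise ValueError(
                f"donors {a} and {b} share fewer than 3 regions"
            )
        xa = pa[common].to_numpy()
        xb = pb[common].to_numpy()
        xa = xa - xa.mean(axis=1, keepdims=True)
        xb = xb - xb.mean(axis=1, keepdims=True)
        num = (xa * xb).sum(axis=1)
        den = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        scores += r
        counts += 1
    return scores / counts


def differential_stability_select(
    probe_table: ProbeTable,
    assignments: dict[str, str],
    gene_quantile: float = 0.5,
) -> tuple[ProbeTable, pd.DataFrame]:
    """Pick the max-DS probe per gene and drop low-stability genes.

    Genes are ranked by the DS of their selected probe; the bottom
    ``gene_quantile`` fraction is removed (0.5 keeps the top half).
    Returns the reduced table and a provenance frame (gene, probe, DS).
    """
    ds = differential_stability_scores(probe_table, assignments)
    prov = probe_table.probes.copy()
    prov["ds_score"] = ds.loc[prov["probe_id"]].to_numpy()
    best = prov.loc[prov.groupby("gene_id")["ds_score"].idxmax()]
    cutoff = best["ds_score"].quantile(gene_quantile)
    kept = best[best["ds_score"] >= cutoff].reset_index(drop=True)
    return probe_table.subset(kept["probe_id"].tolist()), kept


def assign_samples(
    samples: pd.DataFrame,
    region_centroids: pd.DataFrame,
    max_distance: float = 2.0,
) -> dict[str, str]:
    """Nearest-centroid assignment with a distance cap, left hemisphere only.

    Returns sample_id -> region for surviving samples; right-hemisphere
    samples and samples farther than ``max_distance`` mm from every region
    are dropped.
    """
    cents = region_centroids[["x", "y", "z"]].to_numpy(dtype=float)
    names = region_centroids["region"].tolist()
    tree = cKDTree(cents)
    left = samples[samples["hemisphere"] == "L"]
    if left.empty:
        return {}
    d, idx = tree.query(left[["x", "y", "z"]].to_numpy(dtype=float))
    return {
        sid: names[i]
        for sid, dist, i in zip(left["sample_id"], d, idx)
        if dist <= max_distance
    }


def _scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Normalise each row to (0, 1) via a robust sigmoid (median/IQR)."""
    med = np.median(x, axis=1, keepdims=True)
    q75, q25 = np.percentile(x, [75, 25], axis=1, keepdims=True)
    iqr = np.where(q75 - q25 > 0, (q75 - q25) / 1.35, 1.0)
    s = 1.0 / (1.0 + np.exp(-(x - med) / iqr))
    smin = s.min(axis=1, keepdims=True)
    smax = s.max(axis=1, keepdims=True)
    rng = np.where(smax - smin > 0, smax - smin, 1.0)
    return (s - smin) / rng


def build_matrix(
    probe_table: ProbeTable,
    assignments: dict[str, str],
    provenance: pd.DataFrame | None = None,
    normalization: str = "srs",
    region_names: tuple[str, ...] = DK_REGIONS,
) -> ExpressionMatrix:
    """Normalise within donor, average within region, then across donors.

    ``normalization``: ``srs`` scaled robust sigmoid (per gene across a
    donor's samples), ``zscore``, or ``identity``.
    """
    samples = probe_table.samples.set_index("sample_id")
    sample_region = pd.Series(assignments)
    donor_mats = []
    for donor, grp in samples.groupby("donor_id"):
        sids = [s for s in grp.index if s in assignments]
        if not sids:
            continue
        x = probe_table.intensities[sids].to_numpy(dtype=float)
        if normalization == "srs":
            x = _scaled_robust_sigmoid(x)
        elif normalization == "zscore":
            sd = x.std(axis=1, keepdims=True)
            x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        elif normalization != "identity":
            raise ValueError(f"unknown normalization {normalization!r}")
        df = pd.DataFrame(
            x, index=probe_table.intensities.index, columns=sids
        )
        donor_mats.append(df.T.groupby(sample_region.loc[sids]).mean().T)
    if not donor_mats:
        raise ValueError("no donor contributes any assigned sample")
    covered = set().union(*[set(m.columns) for m in donor_mats])
    missing = [r for r in region_names if r not in covered]
    if missing:
        raise ValueError(f"regions with zero samples in every donor: {missing}")
    stacked = pd.concat(donor_mats, keys=range(len(donor_mats)))
    region_mean = stacked.groupby(level=1).mean()[list(region_names)]

    gene_of = probe_table.probes.set_index("probe_id")["gene_id"]
    region_mean.index = gene_of.loc[region_mean.index].to_numpy()
    region_mean.index.name = "gene_id"
    region_mean = region_mean.sort_index()

    if provenance is None:
        provenance = probe_table.probes.copy()
        provenance["ds_score"] = np.nan
    provenance = provenance.set_index("gene_id").loc[region_mean.index]
    return ExpressionMatrix(
        values=region_mean,
        provenance=provenance.reset_index(),
        normalization=normalization,
    )


def load_cell_sets(
    annotations: pd.DataFrame, expression: ExpressionMatrix
) -> CellTypeSets:
    """Gene-to-cell-class sets restricted to genes in the matrix.

    ``annotations`` has columns gene_id, cell_type.  Raises on unknown
    classes, duplicate gene assignment, or any requested class with an
    empty intersection.
    """
    sets = CellTypeSets(
        sets={
            ct: sorted(grp["gene_id"].tolist())
            for ct, grp in annotations.groupby("cell_type")
        }
    )
    present = set(expression.genes)
    restricted = {
        ct: [g for g in genes if g in present] for ct, genes in sets.sets.items()
    }
    empty = [ct for ct, genes in restricted.items() if not genes]
    if empty:
        raise ValueError(f"cell classes with no gene in the matrix: {empty}")
    return CellTypeSets(sets=restricted)


def run_expression_pipeline(
    probe_table: ProbeTable,
    region_centroids: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    min_background_fraction: float = 0.5,
    max_distance: float = 2.0,
    ds_gene_quantile: float = 0.5,
    normalization: str = "srs",
    region_names: tuple[str, ...] | None = None,
) -> tuple[ExpressionMatrix, CellTypeSets | None, dict[str, Any]]:
    """Full chain: background -> assignment -> DS selection -> matrix.

    Returns the matrix, the (optional) restricted cell sets, and a log of
    the filter composition with per-stage counts.
    """
    if region_names is None:
        region_names = tuple(region_centroids["region"].tolist())
    log: dict[str, Any] = {"order": [
        "filter_background", "assign_samples",
        "differential_stability_select", "build_matrix",
    ]}
    pt = filter_background(probe_table, min_background_fraction)
    log["probes_after_background"] = len(pt.probes)
    log["genes_after_background"] = pt.probes["gene_id"].nunique()
    assignments = assign_samples(probe_table.samples, region_centroids, max_distance)
    log["samples_assigned"] = len(assignments)
    pt, provenance = differential_stability_select(
        pt, assignments, gene_quantile=ds_gene_quantile
    )
    log["genes_after_ds"] = len(provenance)
    matrix = build_matrix(
        pt, assignments, provenance=provenance,
        normalization=normalization, region_names=region_names,
    )
    log["final_genes"] = len(matrix.genes)
    cell_sets = None
    if annotations is not None:
        cell_sets = load_cell_sets(annotations, matrix)
        log["cell_set_sizes"] = cell_sets.sizes()
    return matrix, cell_sets, log
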