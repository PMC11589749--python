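import numpy as np
import pandas as pd
import pytest

from icf_histology.expression_pipeline import (
    CellTypeSets,
    ProbeTable,
    assign_samples,
    build_matrix,
    differential_stability_scores,
    differential_stability_select,
    filter_background,
    load_cell_sets,
    run_expression_pipeline,
)


def make_table(intensities, genes, samples, flags=None):
    """ProbeTable from an array, one probe per row named p0, p1, ..."""
    intensities = np.asarray(intensities, dtype=float)
    probe_ids = [f"p{i}" for i in range(intensities.shape[0])]
    sample_ids = list(samples["sample_id"])
    if flags is None:
        flags = np.ones_like(intensities, dtype=bool)
    return ProbeTable(
        probes=pd.DataFrame({"probe_id": probe_ids, "gene_id": genes}),
        intensities=pd.DataFrame(
            intensities, index=probe_ids, columns=sample_ids
        ),
        flags=pd.DataFrame(
            np.asarray(flags, dtype=bool), index=probe_ids, columns=sample_ids
        ),
        samples=samples,
    )


def make_samples(n, donors, hemisphere="L", coords=None):
    if coords is None:
        coords = np.zeros((n, 3))
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "donor_id": donors,
            "hemisphere": [hemisphere] * n if isinstance(hemisphere, str)
            else hemisphere,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )


# -- ProbeTable validation -------------------------------------------------


def test_probe_table_validation():
    samples = make_samples(2, ["d1", "d1"])
    with pytest.raises(ValueError):  # non-boolean flags
        ProbeTable(
            probes=pd.DataFrame({"probe_id": ["p0"], "gene_id": ["g1"]}),
            intensities=pd.DataFrame(
                np.ones((1, 2)), index=["p0"], columns=["s0", "s1"]
            ),
            flags=pd.DataFrame(
                np.ones((1, 2)), index=["p0"], columns=["s0", "s1"]
            ),
            samples=samples,
        )
    bad = make_samples(2, ["d1", "d1"])
    bad.loc[0, "x"] = np.nan
    with pytest.raises(ValueError):
        make_table(np.ones((1, 2)), ["g1"], bad)
    pt = make_table(np.ones((2, 2)), ["g1", "g2"], samples)
    with pytest.raises(ValueError):  # intensity rows out of sync
        ProbeTable(
            probes=pt.probes,
            intensities=pt.intensities.iloc[::-1],
            flags=pt.flags,
            samples=pt.samples,
        )


# -- background filter -----------------------------------------------------


def test_background_boundary_inclusive():
    # 10 samples; 5/10 above background survives (>= 0.5), 4/10 does not
    samples = make_samples(10, ["d1"] * 10)
    flags = np.zeros((3, 10), dtype=bool)
    flags[0, :5] = True  # exactly half
    flags[1, :4] = True  # below half
    flags[2, :] = True
    pt = make_table(np.ones((3, 10)), ["g1", "g2", "g3"], samples, flags)
    kept = filter_background(pt)
    assert list(kept.probes["probe_id"]) == ["p0", "p2"]


def test_background_all_fail_raises():
    samples = make_samples(4, ["d1"] * 4)
    pt = make_table(
        np.ones((2, 4)), ["g1", "g2"], samples,
        flags=np.zeros((2, 4), dtype=bool),
    )
    with pytest.raises(ValueError):
        filter_background(pt)


def test_background_custom_threshold():
    samples = make_samples(10, ["d1"] * 10)
    flags = np.zeros((1, 10), dtype=bool)
    flags[0, :3] = True
    pt = make_table(np.ones((1, 10)), ["g1"], samples, flags)
    assert len(filter_background(pt, min_fraction=0.3).probes) == 1
    with pytest.raises(ValueError):
        filter_background(pt, min_fraction=0.4)


# -- differential stability ------------------------------------------------


def _two_donor_table(profile_a, profile_b, regions):
    """One probe, two donors, one sample per region per donor."""
    n = len(regions)
    samples = make_samples(2 * n, ["d1"] * n + ["d2"] * n)
    intens = np.concatenate([profile_a, profile_b])[None, :]
    pt = make_table(intens, ["g1"], samples)
    assignments = {
        f"s{i}": regions[i % n] for i in range(2 * n)
    }
    return pt, assignments


def test_ds_identical_profiles_one():
    prof = np.array([1.0, 3.0, 2.0, 5.0])
    pt, asg = _two_donor_table(prof, prof, ["rA", "rB", "rC", "rD"])
    ds = differential_stability_scores(pt, asg)
    assert ds.loc["p0"] == pytest.approx(1.0)


def test_ds_anticorrelated_minus_one():
    prof = np.array([1.0, 3.0, 2.0, 5.0])
    pt, asg = _two_donor_table(prof, -prof, ["rA", "rB", "rC", "rD"])
    ds = differential_stability_scores(pt, asg)
    assert ds.loc["p0"] == pytest.approx(-1.0)


def test_ds_three_donor_brute_force():
    rng = np.random.default_rng(0)
    regions = [f"r{i}" for i in range(6)]
    n = len(regions)
    donors = ["d1"] * n + ["d2"] * n + ["d3"] * n
    samples = make_samples(3 * n, donors)
    intens = rng.uniform(1.0, 10.0, size=(5, 3 * n))
    genes = [f"g{i}" for i in range(5)]
    pt = make_table(intens, genes, samples)
    asg = {f"s{i}": regions[i % n] for i in range(3 * n)}
    ds = differential_stability_scores(pt, asg)
    for p in range(5):
        profiles = [intens[p, d * n:(d + 1) * n] for d in range(3)]
        rs = [
            np.corrcoef(profiles[a], profiles[b])[0, 1]
            for a, b in ((0, 1), (0, 2), (1, 2))
        ]
        assert ds.loc[f"p{p}"] == pytest.approx(np.mean(rs), abs=1e-12)


def test_ds_errors():
    prof = np.array([1.0, 2.0, 3.0])
    samples = make_samples(3, ["d1"] * 3)
    pt = make_table(prof[None, :], ["g1"], samples)
    asg = {f"s{i}": f"r{i}" for i in range(3)}
    with pytest.raises(ValueError):  # single donor
        differential_stability_scores(pt, asg)
    # two donors sharing only 2 regions
    pt2, asg2 = _two_donor_table(
        np.array([1.0, 2.0]), np.array([2.0, 1.0]), ["rA", "rB"]
    )
    with pytest.raises(ValueError):
        differential_stability_scores(pt2, asg2)


def test_ds_select_max_probe_and_quantile():
    # gene g1 has two probes: a reproducible one and a noisy one; the
    # reproducible probe must be selected.  g2 is unstable and must drop.
    regions = ["rA", "rB", "rC", "rD"]
    n = len(regions)
    samples = make_samples(2 * n, ["d1"] * n + ["d2"] * n)
    stable = np.array([1.0, 4.0, 2.0, 8.0])
    intens = np.vstack([
        np.concatenate([stable, stable]),              # p0: g1 stable
        np.concatenate([stable, stable[::-1]]),        # p1: g1 noisy
        np.concatenate([stable, -stable]),             # p2: g2 unstable
    ])
    pt = make_table(intens, ["g1", "g1", "g2"], samples)
    asg = {f"s{i}": regions[i % n] for i in range(2 * n)}
    kept, prov = differential_stability_select(pt, asg, gene_quantile=0.5)
    assert list(kept.probes["probe_id"]) == ["p0"]
    assert prov.set_index("gene_id").loc["g1", "probe_id"] == "p0"


# -- sample assignment -----------------------------------------------------


def test_assign_samples_distance_and_hemisphere():
    cents = pd.DataFrame(
        {"region": ["rA", "rB"], "x": [-10.0, -30.0], "y": [0.0, 0.0],
         "z": [0.0, 0.0]}
    )
    coords = np.array([
        [-10.0, 1.5, 0.0],   # 1.5 mm from rA -> assigned
        [-30.0, 0.0, 2.5],   # 2.5 mm from rB -> dropped
        [-29.0, 0.0, 0.0],   # 1 mm from rB -> assigned
        [-10.0, 0.0, 0.0],   # exact hit but right hemisphere -> dropped
    ])
    samples = make_samples(
        4, ["d1"] * 4, hemisphere=["L", "L", "L", "R"], coords=coords
    )
    asg = assign_samples(samples, cents)
    assert asg == {"s0": "rA", "s2": "rB"}


def test_assign_samples_boundary_inclusive_and_empty():
    cents = pd.DataFrame(
        {"region": ["rA"], "x": [-10.0], "y": [0.0], "z": [0.0]}
    )
    samples = make_samples(
        1, ["d1"], coords=np.array([[-10.0, 2.0, 0.0]])
    )
    assert assign_samples(samples, cents) == {"s0": "rA"}  # exactly 2 mm
    right = make_samples(1, ["d1"], hemisphere="R")
    assert assign_samples(right, cents) == {}


# -- build_matrix ----------------------------------------------------------


def test_build_matrix_single_donor_identity():
    regions = ("rA", "rB", "rC")
    samples = make_samples(3, ["d1"] * 3)
    intens = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    pt = make_table(intens, ["g1", "g2"], samples)
    asg = {"s0": "rA", "s1": "rB", "s2": "rC"}
    m = build_matrix(pt, asg, normalization="identity", region_names=regions)
    assert np.allclose(m.values.loc["g1"].to_numpy(), [1.0, 2.0, 3.0])
    assert np.allclose(m.values.loc["g2"].to_numpy(), [4.0, 5.0, 6.0])


def test_build_matrix_two_identical_donors():
    regions = ("rA", "rB", "rC")
    samples = make_samples(6, ["d1"] * 3 + ["d2"] * 3)
    row = np.array([1.0, 2.0, 3.0])
    pt = make_table(np.concatenate([row, row])[None, :], ["g1"], samples)
    asg = {f"s{i}": regions[i % 3] for i in range(6)}
    m = build_matrix(pt, asg, normalization="identity", region_names=regions)
    assert np.allclose(m.values.loc["g1"].to_numpy(), row)


def test_build_matrix_brute_force_group_by():
    rng = np.random.default_rng(1)
    regions = tuple(f"r{i}" for i in range(4))
    n_per = 3  # samples per region per donor
    donors = []
    asg = {}
    coords_regions = []
    k = 0
    for d in ("d1", "d2"):
        for r in regions:
            for _ in range(n_per):
                donors.append(d)
                asg[f"s{k}"] = r
                coords_regions.append(r)
                k += 1
    samples = make_samples(k, donors)
    intens = rng.uniform(1.0, 9.0, size=(6, k))
    pt = make_table(intens, [f"g{i}" for i in range(6)], samples)
    m = build_matrix(pt, asg, normalization="identity", region_names=regions)
    # manual: per-donor region means, then the average across donors
    for gi in range(6):
        expect = []
        for rj, r in enumerate(regions):
            per_donor = []
            for di in range(2):
                cols = [
                    c for c in range(k)
                    if donors[c] == f"d{di + 1}" and asg[f"s{c}"] == r
                ]
                per_donor.append(intens[gi, cols].mean())
            expect.append(np.mean(per_donor))
        assert np.allclose(
            m.values.loc[f"g{gi}"].to_numpy(), expect, atol=1e-12
        )


def test_build_matrix_sample_order_invariance():
    rng = np.random.default_rng(2)
    regions = ("rA", "rB", "rC")
    samples = make_samples(6, ["d1", "d2"] * 3)
    intens = rng.uniform(1.0, 9.0, size=(2, 6))
    pt = make_table(intens, ["g1", "g2"], samples)
    asg = {f"s{i}": regions[i // 2] for i in range(6)}
    m1 = build_matrix(pt, asg, normalization="srs", region_names=regions)
    perm = [3, 0, 5, 2, 1, 4]
    pt2 = ProbeTable(
        probes=pt.probes,
        intensities=pt.intensities.iloc[:, perm],
        flags=pt.flags.iloc[:, perm],
        samples=pt.samples.iloc[perm].reset_index(drop=True),
    )
    m2 = build_matrix(pt2, asg, normalization="srs", region_names=regions)
    assert np.allclose(m1.values.to_numpy(), m2.values.to_numpy())


def test_build_matrix_srs_range_and_rank_order():
    rng = np.random.default_rng(3)
    regions = tuple(f"r{i}" for i in range(5))
    samples = make_samples(5, ["d1"] * 5)
    intens = rng.uniform(1.0, 9.0, size=(3, 5))
    pt = make_table(intens, ["g1", "g2", "g3"], samples)
    asg = {f"s{i}": regions[i] for i in range(5)}
    m = build_matrix(pt, asg, normalization="srs", region_names=regions)
    vals = m.values.to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 1.0
    # the sigmoid is monotone, so within-gene region ranks are preserved
    for gi in range(3):
        assert np.array_equal(np.argsort(vals[gi]), np.argsort(intens[gi]))


def test_build_matrix_errors():
    regions = ("rA", "rB")
    samples = make_samples(2, ["d1"] * 2)
    pt = make_table(np.ones((1, 2)), ["g1"], samples)
    with pytest.raises(ValueError):  # unknown normalization
        build_matrix(
            pt, {"s0": "rA", "s1": "rB"}, normalization="minmax",
            region_names=regions,
        )
    with pytest.raises(ValueError):  # region with no sample anywhere
        build_matrix(
            pt, {"s0": "rA", "s1": "rA"}, normalization="identity",
            region_names=regions,
        )
    with pytest.raises(ValueError):  # nothing assigned at all
        build_matrix(pt, {}, normalization="identity", region_names=regions)


# -- cell sets -------------------------------------------------------------


def _tiny_matrix(genes):
    regions = ("rA", "rB", "rC")
    samples = make_samples(3, ["d1"] * 3)
    pt = make_table(
        np.arange(3 * len(genes), dtype=float).reshape(len(genes), 3),
        genes, samples,
    )
    asg = {"s0": "rA", "s1": "rB", "s2": "rC"}
    return build_matrix(pt, asg, normalization="identity", region_names=regions)


def test_load_cell_sets_restricts_to_matrix():
    m = _tiny_matrix(["g1", "g2", "g3"])
    ann = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g_absent"],
         "cell_type": ["astrocyte", "astrocyte", "astrocyte"]}
    )
    sets = load_cell_sets(ann, m)
    assert sets.sets == {"astrocyte": ["g1", "g2"]}


def test_cell_sets_errors():
    m = _tiny_matrix(["g1", "g2"])
    with pytest.raises(ValueError):  # unknown class
        load_cell_sets(
            pd.DataFrame({"gene_id": ["g1"], "cell_type": ["neuron"]}), m
        )
    with pytest.raises(ValueError):  # duplicate gene assignment
        CellTypeSets(sets={"astrocyte": ["g1"], "microglia": ["g1"]})
    with pytest.raises(ValueError):  # class empties out after restriction
        load_cell_sets(
            pd.DataFrame(
                {"gene_id": ["g1", "g_absent"],
                 "cell_type": ["astrocyte", "microglia"]}
            ),
            m,
        )


# -- full pipeline on the synthetic fixture --------------------------------


def _as_probe_table(fixture):
    return ProbeTable(
        probes=fixture.probes,
        intensities=fixture.intensities,
        flags=fixture.flags,
        samples=fixture.samples,
    )


def test_pipeline_survivors_match_planted_truth(expression_fixture):
    fixture, truth = expression_fixture
    matrix, cell_sets, log = run_expression_pipeline(
        _as_probe_table(fixture),
        fixture.region_centroids,
        annotations=fixture.cell_annotations,
    )
    assert sorted(matrix.genes) == sorted(truth.ds_surviving_genes)
    assert log["genes_after_background"] == len(truth.bg_surviving_genes)
    assert cell_sets.sets == truth.cell_sets
    prov = matrix.provenance.set_index("gene_id")["probe_id"].to_dict()
    assert prov == {
        g: truth.selected_probe[g] for g in truth.ds_surviving_genes
    }


def test_pipeline_assignment_matches_planted_truth(expression_fixture):
    fixture, truth = expression_fixture
    asg = assign_samples(fixture.samples, fixture.region_centroids)
    assert asg == truth.assigned_samples
    assert set(asg).isdisjoint(truth.dropped_samples)


def test_pipeline_background_matches_planted_truth(expression_fixture):
    fixture, truth = expression_fixture
    kept = filter_background(_as_probe_table(fixture))
    assert sorted(kept.probes["probe_id"]) == sorted(truth.bg_surviving_probes)
    assert (
        sorted(kept.probes["gene_id"].unique())
        == sorted(truth.bg_surviving_genes)
    )


def test_pipeline_deterministic(expression_fixture):
    fixture, _ = expression_fixture
    m1, _, _ = run_expression_pipeline(
        _as_probe_table(fixture), fixture.region_centroids
    )
    m2, _, _ = run_expression_pipeline(
        _as_probe_table(fixture), fixture.region_centroids
    )
    assert m1.values.equals(m2.values)
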