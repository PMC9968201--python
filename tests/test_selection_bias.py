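"""Tract weighting schemes, pseudo-participant sampling and augmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

import deprivix as dx
from deprivix.cluster_detection import bernoulli_scan
from deprivix.selection_bias import (
    StudyDesign,
    run_bias_simulation,
    sample_pseudo_participants,
    tract_weights,
)


def test_study_design_counts():
    d = StudyDesign()
    assert d.n_pseudo_cases == 324 - 277
    assert d.n_pseudo_controls == 407 - 306
    assert d.analytic_n == 277 + 306
    assert d.eligible_n == 324 + 407


def _toy_tracts(deciles):
    rows = []
    for i, (p, inc, edu) in enumerate(deciles):
        rows.append({"tract_id": f"T{i}", "pop_decile": p,
                     "inc_deprivation_decile": inc, "edu_deprivation_decile": edu,
                     "polygon": box(i, 0, i + 1, 1)})
    return pd.DataFrame(rows)


class TestTractWeights:
    def test_two_tract_arithmetic(self):
        tracts = _toy_tracts([(1, 1, 1), (2, 2, 2)])
        w = tract_weights(tracts, scheme="equal")
        np.testing.assert_allclose(w.weights, [1 / 9, 8 / 9])

    def test_literal_ses_cancels_to_equal(self, small_study):
        tracts = small_study["tracts"]
        eq = tract_weights(tracts, scheme="equal").weights
        ses = tract_weights(tracts, scheme="ses", variant="literal").weights
        np.testing.assert_allclose(ses, eq, rtol=0, atol=1e-15)

    def test_power_variant_upweights_deprived(self, small_study):
        tracts = small_study["tracts"]
        eq = tract_weights(tracts, scheme="equal").weights
        pw = tract_weights(tracts, scheme="ses", variant="power").weights
        dep = (tracts["inc_deprivation_decile"] + tracts["edu_deprivation_decile"]).to_numpy()
        top = dep >= np.percentile(dep, 75)
        assert pw[top].sum() > eq[top].sum()

    def test_case_role_population_only(self, small_study):
        tracts = small_study["tracts"]
        w = tract_weights(tracts, role="case")
        expected = tracts["pop_decile"].to_numpy(float)
        np.testing.assert_allclose(w.weights, expected / expected.sum())

    def test_weights_sum_to_one(self, small_study):
        for scheme, variant in [("equal", "literal"), ("ses", "literal"), ("ses", "power")]:
            w = tract_weights(small_study["tracts"], scheme=scheme, variant=variant)
            assert w.weights.sum() == pytest.approx(1.0)

    def test_zero_weights_rejected(self):
        tracts = _toy_tracts([(0, 0, 0), (0, 0, 0)])
        with pytest.raises(ValueError):
            tract_weights(tracts, scheme="equal")


class TestPseudoSampling:
    def test_empty(self, small_study, rng):
        w = tract_weights(small_study["tracts"], role="case")
        out = sample_pseudo_participants(small_study["tracts"], w, 0, rng)
        assert len(out) == 0

    def test_points_inside_polygons(self, small_study, rng):
        tracts = small_study["tracts"]
        w = tract_weights(tracts, scheme="equal")
        out = sample_pseudo_participants(tracts, w, 200, rng, label=0)
        polys = dict(zip(tracts["tract_id"], tracts["polygon"]))
        import shapely

        for _, row in out.iterrows():
            assert polys[row["tract_id"]].buffer(1e-9).contains(
                shapely.Point(row["x"], row["y_coord"]))
        assert (out["y"] == 0).all()

    def test_tract_frequencies_match_weights(self, rng):
        tracts = _toy_tracts([(i % 10 + 1, (i * 3) % 10 + 1, (i * 7) % 10 + 1)
                              for i in range(10)])
        w = tract_weights(tracts, scheme="equal")
        out = sample_pseudo_participants(tracts, w, 10_000, rng)
        counts = out["tract_id"].value_counts().reindex(tracts["tract_id"]).fillna(0)
        chi2, p = stats.chisquare(counts, f_exp=w.weights * 10_000)
        assert p > 1e-3


@pytest.fixture(scope="module")
def biased_study():
    cfg = dx.GeneratorConfig(seed=4, n_cases=150, n_controls=160, beta_ndi=0.0,
                             covariate_effects={}, control_low_ses_undersample=4.0)
    return dx.generate_study(cfg)


def test_augmentation_identity(biased_study):
    """Adding zero pseudo-participants reproduces the observed scan result."""
    p = biased_study["participants"]
    xy = p[["x", "y_coord"]].to_numpy(float)
    y = p["y"].to_numpy(int)
    ref = bernoulli_scan(xy, y, n_mc=99, seed=0)
    res = run_bias_simulation(
        p, biased_study["tracts"],
        design=StudyDesign(eligible_cases=150, participating_cases=150,
                           eligible_controls=160, participating_controls=160),
        n_datasets=2, schemes=("equal",), methods=("scan",), seed=5,
        scan_n_mc=99, reference={"scan": ref})
    for _, row in res.per_dataset.iterrows():
        assert row["scan_found"] == ref.found
        assert row["scan_area_km2"] == pytest.approx(ref.area_km2)
        if ref.found:
            assert row["scan_overlap_pct"] == pytest.approx(100.0)


def test_aggregate_definitions(biased_study):
    p = biased_study["participants"]
    xy = p[["x", "y_coord"]].to_numpy(float)
    y = p["y"].to_numpy(int)
    ref = bernoulli_scan(xy, y, n_mc=199, seed=0)
    res = run_bias_simulation(p, biased_study["tracts"], design=StudyDesign(),
                              n_datasets=5, schemes=("equal",), methods=("scan",),
                              seed=7, scan_n_mc=99, reference={"scan": ref})
    sub = res.per_dataset
    agg = res.aggregate.iloc[0]
    assert agg["pct_with_cluster"] == pytest.approx(100 * sub["scan_found"].mean())
    assert agg["pct_with_overlap"] == pytest.approx(100 * sub["scan_overlaps"].mean())
    sizes = np.sort(sub["scan_area_km2"].to_numpy())
    assert agg["size_median"] == pytest.approx(np.median(sizes))
    assert agg["size_lo"] == pytest.approx(np.percentile(sizes, 2.5))
    assert agg["size_hi"] == pytest.approx(np.percentile(sizes, 97.5))


def test_detection_frequency_grid_counts():
    from shapely.geometry import box, shape

    from deprivix.selection_bias import detection_frequency_grid

    hulls = [box(0, 0, 4, 4), box(0, 0, 4, 4), None, box(8, 8, 10, 10)]
    feats = detection_frequency_grid(hulls, bounds=(0, 0, 10, 10), cell_km=2.0)
    by_centroid = {tuple(np.round(shape(f["geometry"]).centroid.coords[0], 1)):
                   f["properties"] for f in feats}
    assert by_centroid[(1.0, 1.0)]["count"] == 2
    assert by_centroid[(1.0, 1.0)]["pct"] == pytest.approx(50.0)
    assert by_centroid[(9.0, 9.0)]["count"] == 1
    assert (5.0, 5.0) not in by_centroid


def test_determinism_under_master_seed(biased_study):
    p = biased_study["participants"]
    xy = p[["x", "y_coord"]].to_numpy(float)
    y = p["y"].to_numpy(int)
    ref = bernoulli_scan(xy, y, n_mc=99, seed=0)
    kw = dict(design=StudyDesign(), n_datasets=2, schemes=("equal",),
              methods=("scan",), seed=42, scan_n_mc=99, reference={"scan": ref})
    a = run_bias_simulation(p, biased_study["tracts"], **kw)
    b = run_bias_simulation(p, biased_study["tracts"], **kw)
    pd.testing.assert_frame_equal(a.per_dataset, b.per_dataset)
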