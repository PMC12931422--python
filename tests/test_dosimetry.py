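"""Marrow fraction table fidelity, weight assignment, dose sampling and DVH metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import marrowdose as md
from marrowdose.abm_fractions import BONE_SITE_NAMES, REFERENCE_AGES
from marrowdose.phantom import TISSUE_CORTICAL, TISSUE_SPONGIOSA, PhantomMeta


# ------------------------------------------------------------ oracle helpers

def sort_and_scan_metrics(doses, weights):
    """Brute-force weighted distribution metrics, independent of the DVH path."""
    doses = np.asarray(doses, float)
    weights = np.asarray(weights, float)
    total = weights.sum()
    mean = float((doses * weights).sum() / total)
    order = np.argsort(doses, kind="stable")
    d, w = doses[order], weights[order] / total

    def quantile(p):
        acc = 0.0
        for dv, wv in zip(d, w):
            acc += wv
            if acc >= p - 1e-12:
                return float(dv)
        return float(d[-1])

    def v_at(x):
        return float(100.0 * w[d >= x].sum())

    return {
        "mean": mean,
        "d50": quantile(0.5), "d10": quantile(0.9), "d1": quantile(0.99),
        "v5": v_at(5.0), "v10": v_at(10.0), "v20": v_at(20.0),
    }


def sample_from(doses, weights):
    n = len(doses)
    return md.WeightedDoseSample(
        points=np.zeros((n, 3)), weights=weights,
        site_ids=np.zeros(n, dtype=int), phantom_id="x", doses=doses,
    )


# ----------------------------------------------------------- fraction table

class TestFractionTable:
    @pytest.mark.parametrize(
        "site, age, sex, expected",
        [
            ("Craniofacial bones", 0, "F", 0.2412),
            ("Craniofacial bones", 0, "M", 0.2412),  # ages 0-10 are sex-shared
            ("Os coxae", 30, "F", 0.2495),
            ("Ankles and feet", 30, "M", 0.0),
            ("Ribs", 15, "M", 0.0951),
            ("Lumbar vertebrae", 30, "M", 0.1661),
        ],
    )
    def test_reference_values(self, site, age, sex, expected):
        assert md.abm_fraction_lookup(site, age, sex) == expected

    def test_nearest_reference_age_with_older_tie_break(self):
        # 22 is nearer 15 than 30; 22.5 ties and goes to the older column
        assert md.abm_fraction_lookup("Os coxae", 22, "M") \
            == md.abm_fraction_lookup("Os coxae", 15, "M")
        assert md.abm_fraction_lookup("Os coxae", 22.5, "M") \
            == md.abm_fraction_lookup("Os coxae", 30, "M")
        assert md.abm_fraction_lookup("Os coxae", 3, "M") \
            == md.abm_fraction_lookup("Os coxae", 5, "M")
        assert md.abm_fraction_lookup("Os coxae", 64, "F") \
            == md.abm_fraction_lookup("Os coxae", 30, "F")

    def test_all_columns_sum_to_one(self):
        for key, total in md.default_table().column_sums().items():
            assert total == pytest.approx(1.0, abs=0.002), key

    def test_site_names_case_insensitive_and_unknown_rejected(self):
        assert md.abm_fraction_lookup("os coxae", 30, "F") == 0.2495
        with pytest.raises(KeyError, match="unknown bone site"):
            md.abm_fraction_lookup("Femur of Hercules", 30, "M")
        assert len(BONE_SITE_NAMES) == 34
        assert REFERENCE_AGES == (0, 1, 5, 10, 15, 30)


# ---------------------------------------------------------------- weighting

def four_voxel_site_phantom():
    labels = np.zeros((8, 1, 1), dtype=np.int16)
    tissue = np.zeros_like(labels)
    labels[:6, 0, 0] = 1
    tissue[:2, 0, 0] = TISSUE_CORTICAL
    tissue[2:6, 0, 0] = TISSUE_SPONGIOSA
    return md.Phantom(
        label_volume=labels, tissue_volume=tissue, spacing=[1, 1, 1], origin=[0, 0, 0],
        meta=PhantomMeta(id="one", age_years=30, sex="F", height_cm=160, weight_kg=60),
        site_names={1: "Os coxae"},
    )


class TestVoxelWeights:
    def test_fraction_split_evenly_over_noncortical_voxels(self):
        sample = md.assign_voxel_weights(
            four_voxel_site_phantom(), md.RigidTransform.identity(), 30, "F")
        assert len(sample) == 4  # the two cortical voxels are excluded
        np.testing.assert_allclose(sample.weights, 0.2495 / 4)

    def test_weights_conserve_present_site_fractions(self, mini_phantom):
        table = md.default_table()
        sample = md.assign_voxel_weights(
            mini_phantom, md.RigidTransform.identity(), 30, "M")
        expected = sum(
            table.fraction(mini_phantom.site_names[s], 30, "M")
            for s in mini_phantom.site_ids
        )
        assert sample.weights.sum() == pytest.approx(expected, abs=1e-12)

    def test_full_skeleton_weights_sum_to_one(self):
        labels = np.arange(1, 35, dtype=np.int16).reshape(34, 1, 1)
        tissue = np.full_like(labels, TISSUE_SPONGIOSA)
        phantom = md.Phantom(
            label_volume=labels, tissue_volume=tissue, spacing=[1, 1, 1], origin=[0, 0, 0],
            meta=PhantomMeta(id="full", age_years=30, sex="M", height_cm=176, weight_kg=73),
            site_names={i + 1: name for i, name in enumerate(BONE_SITE_NAMES)},
        )
        for age, sex in [(30, "M"), (30, "F"), (0, "F"), (10, "M")]:
            sample = md.assign_voxel_weights(phantom, md.RigidTransform.identity(), age, sex)
            assert sample.weights.sum() == pytest.approx(1.0, abs=0.002)

    def test_positive_fraction_site_with_only_cortical_voxels_rejected(self):
        labels = np.zeros((4, 1, 1), dtype=np.int16)
        tissue = np.zeros_like(labels)
        labels[:3, 0, 0] = 1
        tissue[:3, 0, 0] = TISSUE_CORTICAL
        phantom = md.Phantom(
            label_volume=labels, tissue_volume=tissue, spacing=[1, 1, 1], origin=[0, 0, 0],
            meta=PhantomMeta(id="c", age_years=30, sex="F", height_cm=160, weight_kg=60),
            site_names={1: "Os coxae"},
        )
        with pytest.raises(ValueError, match="no non-cortical voxels"):
            md.assign_voxel_weights(phantom, md.RigidTransform.identity(), 30, "F")

    def test_zero_fraction_sites_are_dropped(self):
        phantom = four_voxel_site_phantom()
        # Os coxae holds no marrow at age 30M? it does; use a site that is zero:
        phantom.site_names[1] = "Ankles and feet"
        with pytest.raises(ValueError, match="no active marrow"):
            md.assign_voxel_weights(phantom, md.RigidTransform.identity(), 30, "M")

    def test_positions_are_transformed_to_patient_frame(self):
        t = md.RigidTransform(translation=[100, 0, 0])
        sample = md.assign_voxel_weights(four_voxel_site_phantom(), t, 30, "F")
        assert np.all(sample.points[:, 0] >= 100)


# ------------------------------------------------------------- dose sampling

class TestSampleDose:
    def grid(self):
        dose = np.zeros((4, 4, 4))
        dose[1, 1, 1] = 10.0
        return md.DoseGrid(values=dose, spacing=[2, 2, 2], origin=[0, 0, 0])

    def test_far_outside_grid_is_exactly_zero(self):
        assert md.sample_dose(self.grid(), [[1000.0, 0.0, 0.0]])[0] == 0.0

    def test_grid_node_is_exact(self):
        assert md.sample_dose(self.grid(), [[2.0, 2.0, 2.0]])[0] == 10.0

    def test_midpoint_interpolates_linearly(self):
        # midpoint between nodes (1,1,1)=10 and (2,1,1)=0 along x
        assert md.sample_dose(self.grid(), [[3.0, 2.0, 2.0]])[0] == pytest.approx(5.0)

    def test_never_negative(self):
        rng = np.random.default_rng(3)
        grid = md.DoseGrid(values=rng.uniform(0, 60, (5, 5, 5)),
                           spacing=[1, 1, 1], origin=[0, 0, 0])
        pts = rng.uniform(-2, 6, (500, 3))
        assert np.all(md.sample_dose(grid, pts) >= 0.0)


# ----------------------------------------------------------------- DVH math

class TestMeanDose:
    def test_uniform_field_mean_is_that_dose(self):
        s = sample_from(np.full(7, 2.0), np.linspace(0.1, 1, 7))
        assert md.mean_abm_dose(s) == pytest.approx(2.0)

    @pytest.mark.parametrize("w, expected", [([0.5, 0.5], 5.0), ([0.9, 0.1], 1.0)])
    def test_two_voxel_hand_arithmetic(self, w, expected):
        s = sample_from(np.array([0.0, 10.0]), np.array(w))
        assert md.mean_abm_dose(s) == pytest.approx(expected)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            md.mean_abm_dose(sample_from(np.ones(3), np.zeros(3)))


class TestDVH:
    def test_uniform_sample(self):
        dvh = md.compute_dvh(sample_from(np.full(5, 2.0), np.ones(5)))
        assert dvh.volume_at_least(1.0) == 100.0
        assert dvh.volume_at_least(3.0) == 0.0
        assert dvh.d_metric(50) == 2.0

    def test_two_atom_sample_uses_percentile_convention(self):
        dvh = md.compute_dvh(sample_from(np.array([0.0, 10.0]), np.array([0.5, 0.5])))
        assert dvh.volume_at_least(5.0) == 50.0
        assert dvh.d_metric(50) == 0.0   # median dose: half the marrow unirradiated
        assert dvh.d_metric(10) == 10.0  # 90th percentile dose

    def test_dvh_at_zero_is_100_and_curve_non_increasing(self):
        rng = np.random.default_rng(5)
        s = sample_from(rng.uniform(0, 60, 1000), rng.uniform(0, 1, 1000))
        dvh = md.compute_dvh(s)
        assert dvh.volume_at_least(0.0) == 100.0
        assert np.all(np.diff(dvh.v_percent) <= 1e-12)

    def test_quantile_orderings_hold(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            doses = rng.choice([0.0, 1.0, 5.0, 20.0, 50.0], size=200)
            s = sample_from(doses, rng.uniform(0, 1, 200))
            m = md.dose_metrics(s)
            assert m.d50 <= m.d10 <= m.d1
            assert m.v5 >= m.v10 >= m.v20

    def test_mean_equals_staircase_curve_integral(self):
        rng = np.random.default_rng(21)
        s = sample_from(rng.uniform(0, 60, 5000), rng.uniform(0, 1, 5000))
        dvh = md.compute_dvh(s)
        assert dvh.mean() == pytest.approx(md.mean_abm_dose(s), rel=1e-6)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(0.0, 100.0), st.floats(1e-3, 1.0)),
        min_size=1, max_size=150,
    ))
    def test_distribution_invariants_for_arbitrary_samples(self, pairs):
        """V(0)=100, V non-increasing, quantile ordering and mean bounds hold always."""
        doses = np.array([p[0] for p in pairs])
        weights = np.array([p[1] for p in pairs])
        s = sample_from(doses, weights)
        dvh = md.compute_dvh(s)
        m = md.dose_metrics(s)
        assert dvh.volume_at_least(0.0) == 100.0
        assert np.all(np.diff(dvh.v_percent) <= 1e-12)
        assert m.d50 <= m.d10 <= m.d1
        assert m.v5 >= m.v10 >= m.v20
        assert doses.min() - 1e-9 <= m.mean_gy <= doses.max() + 1e-9
        assert dvh.mean() == pytest.approx(m.mean_gy, rel=1e-9, abs=1e-9)

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            n = int(rng.integers(10, 10_000))
            doses = np.round(rng.uniform(0, 60, n), 2)  # force dose ties
            doses[rng.random(n) < 0.3] = 0.0            # and a zero atom
            weights = rng.uniform(0, 1, n)
            s = sample_from(doses, weights)
            m = md.dose_metrics(s)
            o = sort_and_scan_metrics(doses, weights)
            assert m.mean_gy == pytest.approx(o["mean"], abs=1e-9)
            for key in ("d50", "d10", "d1"):
                assert getattr(m, key) == pytest.approx(o[key], abs=1e-9), key
            for key in ("v5", "v10", "v20"):
                assert getattr(m, key) == pytest.approx(o[key], abs=1e-9), key


class TestDoseMetrics:
    def test_mean_per_rx(self):
        s = sample_from(np.array([0.0, 10.0]), np.array([0.5, 0.5]))
        m = md.dose_metrics(s, total_prescribed_gy=50.0)
        assert m.mean_per_rx == pytest.approx(0.1)

    def test_zero_prescription_reports_missing(self):
        s = sample_from(np.ones(3), np.ones(3))
        assert md.dose_metrics(s, total_prescribed_gy=0.0).mean_per_rx is None

    def test_all_zero_dose_gives_zero_metrics(self):
        m = md.dose_metrics(sample_from(np.zeros(4), np.ones(4)), 50.0)
        assert (m.mean_gy, m.d50, m.d10, m.d1, m.v5, m.v10, m.v20) \
            == (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def test_metrics_agree_between_dvh_and_direct_paths(self):
        rng = np.random.default_rng(2)
        doses = rng.uniform(0, 55, 3000)
        weights = rng.uniform(0, 1, 3000)
        s = sample_from(doses, weights)
        m = md.dose_metrics(s)
        dvh = md.compute_dvh(s)
        assert m.d50 == pytest.approx(dvh.percentile_dose(0.5), abs=1e-9)
        assert m.v10 == pytest.approx(dvh.volume_at_least(10.0), abs=1e-9)
        assert m.mean_gy == pytest.approx(md.mean_abm_dose(s), abs=1e-9)

    def test_zero_padding_the_dose_grid_changes_nothing(self, mini_phantom):
        sample = md.assign_voxel_weights(
            mini_phantom, md.RigidTransform.identity(), 30, "M")
        dose = np.zeros(mini_phantom.shape)
        dose[:, :, 40:] = 30.0
        grid = md.DoseGrid(values=dose, spacing=mini_phantom.spacing,
                           origin=mini_phantom.origin)
        padded = md.DoseGrid(
            values=np.pad(dose, 4), spacing=mini_phantom.spacing,
            origin=mini_phantom.origin - 4 * mini_phantom.spacing)
        m1 = md.dose_metrics(sample.with_doses(md.sample_dose(grid, sample.points)))
        m2 = md.dose_metrics(sample.with_doses(md.sample_dose(padded, sample.points)))
        assert m1.as_row() == m2.as_row()


class TestAccumulate:
    def test_single_session_is_identity(self):
        s = sample_from(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        out = md.accumulate_sessions([s])
        np.testing.assert_array_equal(out.doses, s.doses)

    def test_uniform_sessions_add(self):
        a = sample_from(np.full(4, 1.0), np.ones(4))
        b = sample_from(np.full(4, 1.0), np.ones(4))
        assert md.mean_abm_dose(md.accumulate_sessions([a, b])) == pytest.approx(2.0)

    def test_mean_of_sum_is_sum_of_means(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(0, 1, 100)
        a = sample_from(rng.uniform(0, 10, 100), w)
        b = sample_from(rng.uniform(0, 10, 100), w)
        total = md.mean_abm_dose(md.accumulate_sessions([a, b]))
        assert total == pytest.approx(md.mean_abm_dose(a) + md.mean_abm_dose(b), abs=1e-9)

    def test_mismatched_phantoms_rejected(self):
        a = sample_from(np.ones(3), np.ones(3))
        b = md.WeightedDoseSample(points=np.zeros((3, 3)), weights=np.ones(3),
                                  site_ids=np.zeros(3, int), phantom_id="other",
                                  doses=np.ones(3))
        with pytest.raises(ValueError, match="different phantoms"):
            md.accumulate_sessions([a, b])
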