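import numpy as np
import pytest

from bilatdot import (
    RepresentationSpec,
    ValidationError,
    build_bilateral,
    build_unilateral,
    enumerate_specs,
    single_feature_specs,
)
from bilatdot.representations import WAVELENGTH_CHOICES

from conftest import make_record


def toy_record(seed=0, r=8, t=6):
    rng = np.random.default_rng(seed)
    return make_record(rng.uniform(1, 2, size=(r, t)), rng.uniform(1, 2, size=(r, t)),
                       n_sources=2, n_detectors=r // 2)


class TestSpec:
    def test_fields_canonicalized(self):
        spec = RepresentationSpec((830, 760), ("robust", "relative_change"), "tf")
        assert spec.wavelengths == (760, 830)
        assert spec.normalizations == ("relative_change", "robust")
        assert spec.parts == ((760, "relative_change"), (760, "robust"),
                              (830, "relative_change"), (830, "robust"))

    @pytest.mark.parametrize("kwargs", [
        dict(wavelengths=(), normalizations=("zscore",), pooling="rf"),
        dict(wavelengths=(500,), normalizations=("zscore",), pooling="rf"),
        dict(wavelengths=(760,), normalizations=(), pooling="rf"),
        dict(wavelengths=(760,), normalizations=("minmax",), pooling="rf"),
        dict(wavelengths=(760,), normalizations=("zscore",), pooling="pca"),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            RepresentationSpec(**kwargs)

    def test_serialization_round_trip(self):
        spec = RepresentationSpec((760, 830), ("zscore", "zero_center"), "sf")
        assert RepresentationSpec.from_dict(spec.to_dict()) == spec

    def test_label_renders_design_steps(self):
        spec = RepresentationSpec((760, 830), ("relative_change", "zero_center"), "rf")
        assert spec.label() == "A: 760 nm, 830 nm; B: relative change + zero center; C: RF"


class TestEnumeration:
    def test_full_design_space_has_210_points(self):
        specs = enumerate_specs()
        assert len(specs) == 210
        assert len(set(specs)) == 210

    def test_single_wavelength_single_normalization_count(self):
        assert len(single_feature_specs()) == 2 * 4 * 5

    def test_order_is_stable(self):
        assert enumerate_specs() == enumerate_specs()

    def test_subset_size_bounds_control_count(self):
        # sizes 1..4 of 4 methods: 15 subsets -> 3 * 15 * 5
        assert len(enumerate_specs(max_normalizations=4)) == 225
        assert len(enumerate_specs(min_normalizations=2, max_normalizations=2)) == 3 * 6 * 5

    def test_wavelength_choices_cover_all_options(self):
        assert {s.wavelengths for s in enumerate_specs()} == set(WAVELENGTH_CHOICES)


class TestBuildUnilateral:
    def test_single_part_lengths(self):
        record = toy_record()
        spec = RepresentationSpec((760,), ("relative_change",), "tsd")
        assert len(build_unilateral(record, "left", spec).values) == 8

    def test_multi_part_concatenation(self):
        record = toy_record()
        spec = RepresentationSpec((760, 830), ("relative_change", "zero_center"), "rf")
        rep = build_unilateral(record, "left", spec)
        assert len(rep.values) == 4 * 8 * 6
        assert rep.parts == ((760, "relative_change"), (760, "zero_center"),
                             (830, "relative_change"), (830, "zero_center"))

    def test_all_210_length_contracts(self):
        """Exhaustive length check over the whole design space on a small record."""
        record = toy_record(r=8, t=6)
        for spec in enumerate_specs():
            rep = build_unilateral(record, "left", spec)
            assert len(rep.values) == spec.unilateral_length(8, 6)
            assert len(rep.parts) == spec.n_parts


class TestBuildBilateral:
    def test_identical_sides_give_zero(self):
        values = np.random.default_rng(1).uniform(1, 2, size=(6, 5))
        record = make_record(values, values)
        spec = RepresentationSpec((760, 830), ("zscore",), "tf")
        np.testing.assert_array_equal(build_bilateral(record, spec).values, np.zeros(2))

    def test_euclidean_distance_by_hand(self):
        # zero-centered parts differ by a fixed pattern with known norm
        left = np.array([[1.0, 1.0], [1.0, 1.0]])
        right = np.array([[1.0, 1.0], [4.0, 5.0]])
        record = make_record(left, right)
        spec = RepresentationSpec((760,), ("zero_center",), "tsd")
        # TSD(left)=[0,0]; TSD(right)=[0,0.5] after centering is unchanged by shift
        expected = np.linalg.norm([0.0 - 0.0, 0.5 - 0.0])
        assert build_bilateral(record, spec).values[0] == pytest.approx(expected, rel=1e-12)

    def test_side_swap_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 2, size=(6, 5)), rng.uniform(1, 2, size=(6, 5))
        spec = RepresentationSpec((760,), ("relative_change", "robust"), "sf")
        d1 = build_bilateral(make_record(a, b), spec).values
        d2 = build_bilateral(make_record(b, a), spec).values
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_entries_non_negative(self, small_cohort):
        spec = RepresentationSpec((760, 830), ("relative_change", "zscore", "robust"), "sf")
        for rec in small_cohort:
            assert np.all(build_bilateral(rec, spec).values >= 0)

    def test_triangle_inequality_across_blocks(self):
        rng = np.random.default_rng(3)
        a, b, c = (rng.uniform(1, 2, size=(6, 5)) for _ in range(3))
        spec = RepresentationSpec((760,), ("zscore",), "tf")
        d_ab = build_bilateral(make_record(a, b), spec).values[0]
        d_bc = build_bilateral(make_record(b, c), spec).values[0]
        d_ac = build_bilateral(make_record(a, c), spec).values[0]
        assert d_ac <= d_ab + d_bc + 1e-12

    def test_streamed_distances_match_full_vectors(self, small_cohort):
        spec = RepresentationSpec((760, 830), ("relative_change", "zero_center"), "rf")
        rec = small_cohort.records[0]
        d = build_bilateral(rec, spec).values
        left = build_unilateral(rec, "left", spec)
        right = build_unilateral(rec, "right", spec)
        part_len = len(left.values) // spec.n_parts
        for i in range(spec.n_parts):
            seg = slice(i * part_len, (i + 1) * part_len)
            assert d[i] == pytest.approx(
                np.linalg.norm(right.values[seg] - left.values[seg]), rel=1e-12)
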