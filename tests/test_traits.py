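import math

import numpy as np
import pytest
from skimage import draw

from xrfseed import (
    DegenerateInputError,
    ElementMapStack,
    assemble_records,
    measure_elements,
    measure_morphology,
    number_accessions,
    segment_accessions,
    split_seeds,
)
from xrfseed.classifier import predict_seed_mask, split_dataset, train_models
from xrfseed.synth import pixel_table_from_layout


def raster_ellipse(a, b, theta=0.0, pad=20):
    size = int(2 * a) + 2 * pad
    m = np.zeros((size, size), bool)
    rr, cc = draw.ellipse(size // 2, size // 2, b, a, rotation=theta, shape=m.shape)
    m[rr, cc] = True
    return m


class TestMorphologyClosedForms:
    def test_circle_limits(self):
        m = np.zeros((201, 201), bool)
        rr, cc = draw.disk((100, 100), 50)
        m[rr, cc] = True
        morph = measure_morphology(m)
        assert morph.eccentricity <= 0.05
        assert 0.95 <= morph.roundness <= 1.0
        assert morph.aspect_ratio <= 1.05

    def test_ellipse_eccentricity(self):
        morph = measure_morphology(raster_ellipse(50, 30))
        assert morph.eccentricity == pytest.approx(0.8, abs=0.02)
        assert morph.length == pytest.approx(100, rel=0.02)
        assert morph.width == pytest.approx(60, rel=0.02)

    def test_square_roundness(self):
        m = np.zeros((120, 120), bool)
        m[10:110, 10:110] = True
        morph = measure_morphology(m)
        assert morph.roundness == pytest.approx(math.pi / 4, abs=0.03)

    def test_parameter_recovery_on_random_ellipses(self, rng):
        errs_e, errs_a = [], []
        for _ in range(200):
            a = rng.uniform(15, 60)
            b = rng.uniform(15, a)
            theta = rng.uniform(0, math.pi)
            m = raster_ellipse(a, b, theta)
            morph = measure_morphology(m)
            true_e = math.sqrt(1 - b**2 / a**2)
            errs_e.append(abs(morph.eccentricity - true_e))
            errs_a.append(abs(morph.area / (math.pi * a * b) - 1))
        assert np.median(errs_e) <= 0.02
        assert np.median(errs_a) <= 0.02

    def test_scale_equivariance(self):
        m1 = raster_ellipse(30, 20)
        m2 = raster_ellipse(60, 40)
        a, b = measure_morphology(m1), measure_morphology(m2)
        assert b.area == pytest.approx(4 * a.area, rel=0.03)
        assert b.length == pytest.approx(2 * a.length, rel=0.03)
        assert b.perimeter == pytest.approx(2 * a.perimeter, rel=0.03)
        assert b.eccentricity == pytest.approx(a.eccentricity, abs=0.03)
        assert b.roundness == pytest.approx(a.roundness, abs=0.03)

    def test_pixel_size_scaling(self):
        m = raster_ellipse(30, 20)
        px = measure_morphology(m)
        um = measure_morphology(m, pixel_size=2.5)
        assert um.area == pytest.approx(px.area * 6.25)
        assert um.length == pytest.approx(px.length * 2.5)
        assert um.eccentricity == px.eccentricity

    def test_feret_variant_orders_like_ellipse(self):
        m = raster_ellipse(50, 30)
        f = measure_morphology(m, method="feret")
        assert f.length == pytest.approx(100, rel=0.03)

    def test_empty_region_rejected(self):
        with pytest.raises(DegenerateInputError):
            measure_morphology(np.zeros((5, 5), bool))


class TestMeasureElements:
    @staticmethod
    def stack_with(vals):
        h, w = vals.shape
        return ElementMapStack(
            rgb=np.zeros((h, w, 3), np.uint8),
            element_names=("Ca",),
            maps={"Ca": vals.astype(np.float32)},
        )

    def test_uniform_map_mean_exact(self):
        stack = self.stack_with(np.full((4, 4), 5.0))
        region = np.ones((4, 4), bool)
        assert measure_elements(region, stack)["Ca"] == 5.0

    def test_linearity_under_scaling(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        region = np.zeros((4, 4), bool)
        region[1:3, 1:3] = True
        base = measure_elements(region, self.stack_with(vals))["Ca"]
        tripled = measure_elements(region, self.stack_with(vals * 3))["Ca"]
        assert tripled == pytest.approx(3 * base)

    def test_half_and_half(self):
        vals = np.zeros((4, 4))
        vals[:2] = 2.0
        vals[2:] = 4.0
        region = np.ones((4, 4), bool)
        assert measure_elements(region, self.stack_with(vals))["Ca"] == 3.0

    def test_empty_region_rejected(self):
        with pytest.raises(DegenerateInputError):
            measure_elements(np.zeros((4, 4), bool), self.stack_with(np.ones((4, 4))))


@pytest.fixture(scope="module")
def pipeline_records(default_layout):
    rgb, stack, gt = default_layout
    table = pixel_table_from_layout(rgb, gt, rng_seed=0)
    train, _ = split_dataset(table, 0.8, 0)
    models = train_models(train, 0)
    acc_mask = segment_accessions(rgb)
    layout = number_accessions(acc_mask, n_rows=2)
    seed_mask = predict_seed_mask(models["xgboost"], rgb, acc_mask)
    labels = split_seeds(seed_mask)
    return assemble_records(labels, layout, stack), gt, stack


class TestAssembleRecords:
    def test_record_count_and_indices(self, pipeline_records):
        records, gt, _ = pipeline_records
        assert len(records) == len(gt.seed_specs)
        per_acc = {}
        for r in records:
            per_acc.setdefault(r.accession_index, []).append(r.seed_index)
        for acc, idxs in per_acc.items():
            assert idxs == list(range(1, len(idxs) + 1))

    def test_noiseless_element_means_recovered_exactly(self, pipeline_records):
        records, gt, stack = pipeline_records
        true_by_acc = {}
        for spec, acc in zip(gt.seed_specs, gt.seed_accession):
            true_by_acc[acc] = spec.element_means
        for r in records:
            for el in stack.element_names:
                assert r.element_means[el] == true_by_acc[r.accession_index][el]

    def test_no_seeds_empty_list(self, default_layout):
        rgb, stack, _ = default_layout
        layout = number_accessions(segment_accessions(rgb), n_rows=2)
        records = assemble_records(np.zeros(rgb.shape[:2], np.int32), layout, stack)
        assert records == []

    def test_orphan_seed_reported_with_index_zero(self, default_layout):
        rgb, stack, _ = default_layout
        layout = number_accessions(segment_accessions(rgb), n_rows=2)
        labels = np.zeros(rgb.shape[:2], np.int32)
        labels[0:8, 0:8] = 1  # background corner, outside every patch
        records = assemble_records(labels, layout, stack)
        assert len(records) == 1
        assert records[0].accession_index == 0
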