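"""Synapse pairing, input classification and rate summaries."""

import math

import numpy as np
import pytest

from synaptoloc.puncta_detection import DetectionParams, Punctum, PunctaSet
from synaptoloc.synapse_assembly import (
    classify_inputs,
    maxima_distance,
    pair_synapses,
    synapse_rates,
)
from synaptoloc.pipeline import analyze_fov

from oracles import brute_pair, random_puncta_set

PARAMS = DetectionParams(min_intensity=1, dilation_radius_px=2)


def make_punctum(pid, r, c, peak=50.0, channel=""):
    return Punctum(
        id=pid, channel=channel, max_row=r, max_col=c, peak=peak, region=frozenset({(r, c)})
    )


def make_set(positions, shape=(50, 50), channel="", pixel_size_nm=100.0):
    puncta = [make_punctum(i, r, c, channel=channel) for i, (r, c) in enumerate(positions)]
    return PunctaSet(channel=channel, puncta=puncta, shape=shape, pixel_size_nm=pixel_size_nm)


class TestMaximaDistance:
    def test_identical_maxima(self):
        a = make_punctum(0, 5, 5)
        assert maxima_distance(a, a, 100.0) == 0.0

    def test_three_four_five_triangle(self):
        a = make_punctum(0, 0, 0)
        b = make_punctum(1, 3, 4)
        assert maxima_distance(a, b, 100.0) == pytest.approx(500.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            r1, c1, r2, c2 = rng.integers(0, 100, 4)
            px = float(rng.uniform(10, 200))
            a, b = make_punctum(0, int(r1), int(c1)), make_punctum(1, int(r2), int(c2))
            expected = math.sqrt((r1 - r2) ** 2 + (c1 - c2) ** 2) * px
            assert maxima_distance(a, b, px) == pytest.approx(expected)


class TestPairing:
    def test_adjacent_singles_pair(self):
        pre = make_set([(10, 10)])
        post = make_set([(11, 11)])
        table = pair_synapses(pre, post, PARAMS)
        assert len(table) == 1
        assert table.synapses[0].pre_post_distance_nm == pytest.approx(math.sqrt(2) * 100)
        assert table.synapses[0].multi_overlap_count == 1

    def test_distant_puncta_do_not_pair(self):
        table = pair_synapses(make_set([(10, 10)]), make_set([(30, 30)]), PARAMS)
        assert len(table) == 0

    def test_nearest_pre_wins_and_multi_counted(self):
        pre = make_set([(10, 13), (10, 12)])  # 3 px and 2 px from post
        post = make_set([(10, 10)])
        table = pair_synapses(pre, post, PARAMS)
        (syn,) = table.synapses
        assert syn.pre_id == 1
        assert syn.multi_overlap_count == 2

    def test_distance_tie_breaks_to_lower_pre_id(self):
        pre = make_set([(10, 13), (13, 10)])  # both 3 px away
        post = make_set([(10, 10)])
        params = DetectionParams(min_intensity=1, dilation_radius_px=2)
        (syn,) = pair_synapses(pre, post, params).synapses
        assert syn.pre_id == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_synapses(make_set([(1, 1)], shape=(50, 50)), make_set([(1, 1)], shape=(40, 40)), PARAMS)

    def test_matches_brute_force_oracle(self):
        """Pairing and multi-overlap equal all-pairs pixel-intersection."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            pre = random_puncta_set(rng, int(rng.integers(1, 25)))
            post = random_puncta_set(rng, int(rng.integers(1, 25)))
            table = pair_synapses(pre, post, PARAMS)
            got = [(s.post_id, s.pre_id, s.multi_overlap_count) for s in table]
            assert got == brute_pair(pre, post, PARAMS)


class TestClassifyInputs:
    def _table(self, pre, post):
        return pair_synapses(pre, post, PARAMS)

    def test_single_vglut1_pixel_labels_vglut1(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        v1 = np.zeros((50, 50))
        v1[10, 11] = 100.0  # inside the dilated pre region
        v2 = np.zeros((50, 50))
        table = classify_inputs(
            self._table(pre, post), pre, v1, v2, {"vglut1": 50, "vglut2": 50}, PARAMS
        )
        assert table.synapses[0].input_label == "VGLUT1"

    def test_no_suprathreshold_signal_is_unassigned(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        blank = np.zeros((50, 50))
        table = classify_inputs(
            self._table(pre, post), pre, blank, blank, {"vglut1": 50, "vglut2": 50}, PARAMS
        )
        assert table.synapses[0].input_label == "unassigned"

    def test_larger_overlap_count_wins(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        v1, v2 = np.zeros((50, 50)), np.zeros((50, 50))
        v1[9:12, 9:12] = 100.0  # more overlapping pixels
        v2[10, 10] = 100.0
        table = classify_inputs(
            self._table(pre, post), pre, v1, v2, {"vglut1": 50, "vglut2": 50}, PARAMS
        )
        assert table.synapses[0].input_label == "VGLUT1"

    def test_exact_tie_left_unassigned(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        v1, v2 = np.zeros((50, 50)), np.zeros((50, 50))
        v1[10, 10] = 100.0
        v2[10, 11] = 100.0
        table = classify_inputs(
            self._table(pre, post), pre, v1, v2, {"vglut1": 50, "vglut2": 50}, PARAMS
        )
        assert table.synapses[0].input_label == "unassigned"

    def test_missing_threshold_is_config_error(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        with pytest.raises(ValueError):
            classify_inputs(
                self._table(pre, post), pre, np.zeros((50, 50)), None, {}, PARAMS
            )


class TestRates:
    def test_empty_table_with_detections(self):
        pre, post = make_set([(0, 0)] * 0), make_set([])
        table = pair_synapses(make_set([(10, 10)]), make_set([(40, 40)]), PARAMS)
        table.n_pre_detected, table.n_post_detected = 10, 10
        rates = synapse_rates(table)
        assert rates["pct_pre_synaptic"] == 0.0
        assert rates["pct_post_synaptic"] == 0.0
        assert rates["pct_multi_overlap"] is None  # zero synapses: undefined

    def test_counting_oracle_on_constructed_table(self):
        # 4 synapses from 10 pre / 10 post; one synapse has multi overlap
        pre = make_set([(5, 5), (5, 20), (20, 5), (20, 20), (20, 21)] + [(40, i * 5) for i in range(5)])
        post = make_set([(6, 6), (6, 21), (21, 6), (21, 21)] + [(45, i * 5) for i in range(6)])
        table = pair_synapses(pre, post, PARAMS)
        rates = synapse_rates(table)
        assert rates["pct_post_synaptic"] == pytest.approx(40.0)
        assert rates["pct_multi_overlap"] == pytest.approx(25.0)
        # distinct pre puncta: synapse at (21,21) shares territory with 2 pre
        assert rates["pct_pre_synaptic"] == pytest.approx(40.0)

    def test_all_vglut1(self):
        pre, post = make_set([(10, 10)]), make_set([(11, 11)])
        v1 = np.full((50, 50), 100.0)
        table = classify_inputs(
            pair_synapses(pre, post, PARAMS), pre, v1, None, {"vglut1": 50}, PARAMS
        )
        rates = synapse_rates(table)
        assert rates["pct_vglut1"] == 100.0
        assert rates["pct_vglut2"] == 0.0

    def test_zero_denominator_is_undefined(self):
        table = pair_synapses(make_set([]), make_set([]), PARAMS)
        rates = synapse_rates(table)
        assert all(v is None for v in rates.values())


class TestGroundTruthRecovery:
    def test_synthetic_fov_recovery(self, small_fov, analysis_config):
        """Synapse count, labels and pre-post distance recovered from images."""
        config, images, truth = small_fov
        result = analyze_fov(images, analysis_config)
        assert len(result.synapses) == len(truth)
        labels = {"CT": "VGLUT1", "sensory": "VGLUT2"}
        truth_xy = truth.synapses[["post_x_nm", "post_y_nm"]].to_numpy()
        px = config.pixel_size_nm
        post = result.puncta["homer"]
        correct = 0
        for syn in result.synapses:
            p = post.by_id(syn.post_id)
            pos = np.array([p.max_col * px, p.max_row * px])
            idx = int(np.argmin(np.linalg.norm(truth_xy - pos, axis=1)))
            if labels[truth.synapses.input_class.iloc[idx]] == syn.input_label:
                correct += 1
        assert correct == len(result.synapses)
        med = float(np.median(result.synapses.distances_nm()))
        assert abs(med - config.pre_post_sep_nm[0]) <= px
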