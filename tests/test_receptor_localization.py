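"""Receptor compartment assignment, summaries and distance histograms."""

import math

import numpy as np
import pytest

from synaptoloc.puncta_detection import DetectionParams, PunctaSet
from synaptoloc.receptor_localization import (
    assign_receptors,
    distance_histogram,
    localization_summary,
)
from synaptoloc.synapse_assembly import pair_synapses
from synaptoloc.pipeline import analyze_fov
from synaptoloc.synthetic_data import SynthConfig, generate_fov

from oracles import brute_assign, random_puncta_set
from test_synapse_assembly import make_set

PARAMS = DetectionParams(min_intensity=1, dilation_radius_px=2)
PX = 100.0  # nm/px used by make_set


def setup_synapse(pre_pos=(10, 10), post_pos=(11, 11)):
    pre = make_set([pre_pos], channel="pre")
    post = make_set([post_pos], channel="post")
    table = pair_synapses(pre, post, PARAMS)
    assert len(table) == 1
    return pre, post, table


class TestAssign:
    def test_receptor_on_post_is_postsynaptic(self):
        pre, post, table = setup_synapse()
        rec = make_set([(12, 12)], channel="rec")  # sqrt(2)*100 nm from post
        (a,) = assign_receptors(rec, table, post, pre, PARAMS)
        assert a.compartment == "postsynaptic"
        assert a.distance_nm == pytest.approx(math.sqrt(2) * PX)
        assert a.synapse_id == 0

    def test_receptor_on_pre_only_is_presynaptic(self):
        pre, post, table = setup_synapse(pre_pos=(10, 10), post_pos=(12, 12))
        rec = make_set([(8, 8)])  # overlaps pre region only
        (a,) = assign_receptors(rec, table, post, pre, PARAMS)
        assert a.compartment == "presynaptic"

    def test_post_beyond_cutoff_demoted_to_none(self):
        # receptor overlaps the post region but its maximum sits 450 nm away
        pre, post, table = setup_synapse(pre_pos=(30, 30), post_pos=(32, 32))
        rec_px = PunctaSet(
            channel="rec",
            puncta=make_set([(32, 36)]).puncta,  # shares pixels via dilation
            shape=(50, 50),
            pixel_size_nm=112.5,  # 4 px -> 450 nm
        )
        post450 = PunctaSet("post", post.puncta, (50, 50), 112.5)
        pre450 = PunctaSet("pre", pre.puncta, (50, 50), 112.5)
        table450 = pair_synapses(pre450, post450, PARAMS)
        (a,) = assign_receptors(rec_px, table450, post450, pre450, PARAMS, 400.0)
        assert a.compartment == "none"
        assert math.isnan(a.distance_nm)

    def test_shortest_distance_wins_between_pre_and_post(self):
        # receptor nearer the pre maximum than the post maximum -> presynaptic
        pre, post, table = setup_synapse(pre_pos=(10, 10), post_pos=(10, 14))
        rec = make_set([(10, 11)])
        (a,) = assign_receptors(rec, table, post, pre, PARAMS)
        assert a.compartment == "presynaptic"
        assert a.distance_nm == pytest.approx(PX)

    def test_no_overlap_is_none(self):
        pre, post, table = setup_synapse()
        rec = make_set([(40, 40)])
        (a,) = assign_receptors(rec, table, post, pre, PARAMS)
        assert a.compartment == "none"
        assert a.synapse_id is None

    def test_geometry_mismatch_rejected(self):
        pre, post, table = setup_synapse()
        rec = make_set([(5, 5)], shape=(60, 60))
        with pytest.raises(ValueError):
            assign_receptors(rec, table, post, pre, PARAMS)

    def test_matches_brute_force_oracle(self):
        """Compartment, synapse and distance equal exhaustive enumeration."""
        rng = np.random.default_rng(31)
        for _ in range(30):
            pre = random_puncta_set(rng, int(rng.integers(1, 15)), channel="pre")
            post = random_puncta_set(rng, int(rng.integers(1, 15)), channel="post")
            rec = random_puncta_set(rng, int(rng.integers(1, 20)), channel="rec")
            table = pair_synapses(pre, post, PARAMS)
            got = assign_receptors(rec, table, post, pre, PARAMS, 400.0)
            rows = [(s.id, s.pre_id, s.post_id) for s in table]
            expected = brute_assign(rec, rows, post, pre, PARAMS, 400.0)
            assert len(got) == len(rec.puncta)  # partition: one call each
            for a in got:
                comp, sid, dist = expected[a.receptor_id]
                assert a.compartment == comp
                assert a.synapse_id == sid
                assert (math.isnan(dist) and math.isnan(a.distance_nm)) or (
                    a.distance_nm == pytest.approx(dist)
                )

    def test_postsynaptic_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(37)
        pre = random_puncta_set(rng, 10, channel="pre")
        post = random_puncta_set(rng, 10, channel="post")
        rec = random_puncta_set(rng, 15, channel="rec")
        table = pair_synapses(pre, post, PARAMS)
        counts = []
        for cutoff in (0.0, 100.0, 200.0, 400.0, 1e9):
            a = assign_receptors(rec, table, post, pre, PARAMS, cutoff)
            counts.append(sum(1 for x in a if x.compartment == "postsynaptic"))
        assert counts == sorted(counts)


class TestSummary:
    def test_synapse_and_receptor_rates(self):
        pre = make_set([(5, 5), (20, 20), (35, 35)], channel="pre")
        post = make_set([(6, 6), (21, 21), (36, 36)], channel="post")
        table = pair_synapses(pre, post, PARAMS)
        rec = make_set([(7, 7), (40, 5)], channel="rec")
        assignments = assign_receptors(rec, table, post, pre, PARAMS)
        summary = localization_summary(assignments, table, rec)
        assert summary.pct_synapses_with_postsynaptic_receptor == pytest.approx(100 / 3)
        assert summary.pct_receptors_postsynaptic == pytest.approx(50.0)
        assert summary.n_synapses == 3 and summary.n_receptors == 2

    def test_stratified_rates_match_hand_counts(self, small_fov, analysis_config):
        config, images, truth = small_fov
        result = analyze_fov(images, analysis_config)
        loc = result.localization
        # hand-count: synapses with a postsynaptic receptor, per label
        by_label = {"VGLUT1": [0, 0], "VGLUT2": [0, 0]}
        post_ids = {a.synapse_id for a in result.assignments if a.compartment == "postsynaptic"}
        for syn in result.synapses:
            if syn.input_label in by_label:
                by_label[syn.input_label][1] += 1
                if syn.id in post_ids:
                    by_label[syn.input_label][0] += 1
        for label, attr in (
            ("VGLUT1", "pct_vglut1_synapses_with_postsynaptic_receptor"),
            ("VGLUT2", "pct_vglut2_synapses_with_postsynaptic_receptor"),
        ):
            num, den = by_label[label]
            assert getattr(loc, attr) == pytest.approx(100.0 * num / den)

    def test_empty_synapse_table_rates_undefined(self):
        pre, post = make_set([(10, 10)]), make_set([(40, 40)])
        table = pair_synapses(pre, post, PARAMS)
        rec = make_set([(5, 5)])
        summary = localization_summary([], table, rec)
        assert summary.pct_synapses_with_postsynaptic_receptor is None


class TestOccupancyRecovery:
    def test_recovered_occupancy_and_offset(self, analysis_config):
        """At 500 synapses the measured occupancy and receptor offset match truth."""
        config = SynthConfig(
            fov_size_px=(2048, 2048),
            n_ct_synapses=500,
            n_sensory_synapses=0,
            receptor_occupancy={"CT": 0.5, "sensory": 0.0},
            seed=17,
        )
        images, truth = generate_fov(config)
        result = analyze_fov(images, analysis_config)
        got = result.metrics["pct_synapses_with_postsynaptic_receptor"]
        assert abs(got - 50.0) <= 3.0
        med = result.metrics["median_receptor_post_distance_nm"]
        assert abs(med - config.receptor_offset_nm[0]) <= config.pixel_size_nm


class TestHistogram:
    def test_single_value_occupies_one_bin(self):
        h = distance_histogram([150.0] * 5)
        assert h.frequencies.sum() == pytest.approx(1.0)
        assert np.count_nonzero(h.frequencies) == 1
        assert h.median_nm == 150.0 and h.iqr_nm == 0.0

    def test_median_of_four(self):
        h = distance_histogram([100, 200, 300, 400])
        assert h.median_nm == pytest.approx(250.0)

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(41)
        d = rng.uniform(0, 500, 1000)
        h = distance_histogram(d, bin_width_nm=20)
        s = np.sort(d)

        def quantile(q):  # linear interpolation between order statistics
            pos = q * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert h.median_nm == pytest.approx(quantile(0.5))
        assert h.iqr_nm == pytest.approx(quantile(0.75) - quantile(0.25))
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([])
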