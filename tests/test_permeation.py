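"""Permeation analysis: event detection against generator ground truth,
fluxes and rates, selectivity, site occupancy, mode classification and
knock-on annotation."""

import numpy as np
import pytest

from cntchan.atoms import Trajectory
from cntchan.permeation import (ChannelGeometry, EventRecord, FluxSeries,
                                assign_sites, classify_modes, cumulative_flux,
                                detect_events, detect_knock_on,
                                permeation_rate, selectivity_ratio)
from cntchan.synthetic import (KineticParams, generate_permeation_trajectory)

GEOM = ChannelGeometry()


def make_traj(z_per_atom, tags, dt=0.01, x=None):
    """Trajectory from per-atom z(t) arrays (x = y = 0 unless given)."""
    z = np.stack(z_per_atom, axis=1)          # (frames, atoms)
    pos = np.zeros((*z.shape, 3))
    pos[:, :, 2] = z
    if x is not None:
        pos[:, :, 0] = np.asarray(x)[None, :]
    tags = np.array(tags, object)
    from cntchan.atoms import TAG_ELEMENTS
    elements = np.array([TAG_ELEMENTS[t] for t in tags], object)
    return Trajectory(pos, tags, elements, dt * np.arange(z.shape[0]))


class TestDetection:
    def test_recovers_ground_truth_counts(self, gen_events):
        _, truth, events = gen_events
        assert len(events) == len(truth)
        for sp in ("ion_K", "ion_Na"):
            assert sum(e.species == sp for e in events) == \
                sum(e.species == sp for e in truth)

    def test_monotone_single_ion_path(self):
        traj = make_traj([np.linspace(-12, 12, 60)], ["ion_K"])
        events = detect_events(traj, GEOM)
        assert len(events) == 1
        assert events[0].site_path == ["S4", "S3", "S2", "S1"]

    def test_oscillation_without_exit_is_no_event(self):
        z = -8.0 + 4.0 * np.sin(np.linspace(0, 8 * np.pi, 200))
        events = detect_events(make_traj([z], ["ion_K"]), GEOM)
        assert events == []

    def test_recrossing_requires_return_below_entrance(self):
        # up, almost out, back inside, then out: still a single event
        z = np.concatenate([np.linspace(-12, 8, 40),
                            np.linspace(8, 0, 10),
                            np.linspace(0, 12, 20)])
        events = detect_events(make_traj([z], ["ion_K"]), GEOM)
        assert len(events) == 1

    def test_event_count_invariant_under_frame_subsampling(self, gen_events):
        traj, truth, events = gen_events
        sub = detect_events(traj.subsample(2), GEOM)
        assert len(sub) == len(events) == len(truth)

    def test_untagged_trajectory_rejected(self):
        traj = make_traj([np.zeros(5)], ["water_O"])
        with pytest.raises(ValueError, match="ion"):
            detect_events(traj, GEOM)


class TestFluxAndRates:
    def test_flux_counts_match_bruteforce_tally(self, gen_events):
        traj, _, events = gen_events
        series = cumulative_flux(events, traj)
        for sp in ("ion_K", "ion_Na"):
            assert series.final_count(sp) == sum(e.species == sp
                                                 for e in events)
        for sp, c in series.counts.items():
            assert np.all(np.diff(c) >= 0)

    def test_three_events_final_count(self):
        events = [EventRecord("ion_K", 0, i * 100 - 1, i * 100)
                  for i in (1, 2, 3)]
        series = cumulative_flux(events, np.arange(400) * 0.01)
        assert series.final_count("ion_K") == 3

    def test_empty_events_zero_series(self):
        series = cumulative_flux([], np.arange(100) * 0.01)
        assert series.final_count("ion_K") == 0
        assert np.all(series.counts["ion_Na"] == 0)

    def test_uniform_10_events_over_1000ns_rate_1e7(self):
        # 10 traversals in a microsecond: the low-field K+ rate scale
        t = np.linspace(0.0, 1000.0, 10_001)
        exits = np.linspace(100, 1000, 10)
        counts = np.searchsorted(exits, t, side="right")
        series = FluxSeries(time=t, counts={"ion_K": counts})
        res = permeation_rate(series, "ion_K")
        assert res["count_rate_per_s"] == pytest.approx(1e7)
        assert res["rate_per_s"] == pytest.approx(1e7, rel=0.1)

    def test_zero_events_zero_rate(self):
        series = FluxSeries(time=np.linspace(0, 10, 11),
                            counts={"ion_K": np.zeros(11, int)})
        assert permeation_rate(series, "ion_K")["rate_per_s"] == 0.0

    def test_linear_staircase_slope_matches_count_over_duration(self):
        t = np.linspace(0.0, 200.0, 2001)
        exits = np.arange(5.0, 200.0, 5.0)
        series = FluxSeries(time=t, counts={
            "ion_K": np.searchsorted(exits, t, side="right")})
        res = permeation_rate(series, "ion_K")
        assert res["rate_per_s"] == pytest.approx(res["count_rate_per_s"],
                                                  rel=0.05)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            permeation_rate(FluxSeries(time=np.array([1.0]),
                                       counts={}), "ion_K")


class TestSelectivity:
    def test_simple_ratio(self):
        sr, qual = selectivity_ratio(8.0, 1.0, count_na=5)
        assert sr == 8.0 and qual == "measured"

    def test_reciprocal_property(self):
        sr_kn, _ = selectivity_ratio(7.5e7, 1.0e7, count_na=3)
        sr_nk, _ = selectivity_ratio(1.0e7, 7.5e7, count_na=3)
        assert sr_kn * sr_nk == pytest.approx(1.0)

    def test_zero_na_gives_lower_bound_with_pseudo_event(self):
        sr, qual = selectivity_ratio(1.2e7, 0.0, count_na=0,
                                     duration_ns=1000.0)
        assert qual == "lower_bound"
        assert sr == pytest.approx(1.2e7 / 1e6)

    def test_both_zero_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            selectivity_ratio(0.0, 0.0, count_na=0, duration_ns=100.0)


class TestSites:
    def test_exact_site_position(self):
        traj = make_traj([np.full(3, 1.35)], ["ion_K"])
        occ = assign_sites(traj, GEOM)
        assert np.all(occ == 1)          # S2

    def test_midway_with_tight_tolerance_is_inter_site(self):
        geom = ChannelGeometry(site_tolerance=0.5)
        traj = make_traj([np.full(3, 0.0)], ["ion_K"])  # between S2 and S3
        assert np.all(assign_sites(traj, geom) == -1)

    def test_occupancy_matches_ground_truth_dwell_midpoints(self, gen_traj):
        traj, truth = gen_traj
        occ = assign_sites(traj, GEOM)
        ion_idx = traj.atom_indices("ion_K", "ion_Na")
        labels = GEOM.site_labels
        for e in truth:
            col = int(np.nonzero(ion_idx == e.atom_index)[0][0])
            for lab, fr in e.site_dwell_frames:
                assert occ[fr, col] >= 0
                assert labels[occ[fr, col]] == lab


class TestModes:
    def _constructed(self, n_waters):
        frames = 40
        ion = np.concatenate([np.linspace(-12, -4.05, 10),
                              np.full(20, -4.05),
                              np.linspace(-4.05, 12, 10)])
        partner = np.full(frames, 4.05)
        waters = [np.full(frames, z)
                  for z in np.linspace(-1.0, 1.0, n_waters)]
        tags = ["ion_K", "ion_K"] + ["water_O"] * n_waters
        return make_traj([ion, partner] + waters, tags)

    def test_persistent_two_waters_is_mode1(self):
        traj = self._constructed(2)
        events = detect_events(traj, GEOM)
        res = classify_modes(events, traj, GEOM)
        assert [e.mode for e in res["events"]] == ["mode1"]

    def test_persistent_one_water_is_mode2(self):
        traj = self._constructed(1)
        events = detect_events(traj, GEOM)
        res = classify_modes(events, traj, GEOM)
        assert [e.mode for e in res["events"]] == ["mode2"]

    def test_lone_ion_unclassified(self):
        traj = make_traj([np.linspace(-12, 12, 60), np.full(60, 14.0)],
                         ["ion_K", "water_O"])
        events = detect_events(traj, GEOM)
        res = classify_modes(events, traj, GEOM)
        assert res["events"][0].mode == "unclassified"
        assert res["n_unclassified"] == 1

    @pytest.mark.parametrize("p1", [0.1, 0.5, 0.76, 0.9])
    def test_classifier_recovers_generator_mixture(self, p1):
        n = 400
        params = KineticParams(n_events=n, mode1_prob=p1, na_fraction=0.0,
                               seed=int(100 * p1))
        traj, truth = generate_permeation_trajectory(params)
        events = detect_events(traj, GEOM)
        res = classify_modes(events, traj, GEOM)
        truth_frac = np.mean([e.mode == "mode1" for e in truth])
        # classification must agree with ground truth, which itself lies
        # within binomial bounds of the requested mixture
        assert res["fractions"]["mode1"] == pytest.approx(truth_frac,
                                                          abs=1e-12)
        assert abs(truth_frac - p1) <= 3 * np.sqrt(p1 * (1 - p1) / n)

    def test_fractions_sum_to_one(self, gen_events):
        traj, _, events = gen_events
        res = classify_modes(events, traj, GEOM)
        assert res["fractions"]["mode1"] + res["fractions"]["mode2"] == \
            pytest.approx(1.0)


class TestKnockOn:
    def test_scripted_two_ion_knock_on(self):
        # incoming ion reaches S4; the ion bound at S2 advances to S1
        bound = np.array([1.35, 1.35, 1.35, 1.35, 4.05, 4.05])
        incoming = np.array([-12.0, -12.0, -9.0, -4.05, -4.05, -4.05])
        traj = make_traj([bound, incoming], ["ion_K", "ion_K"])
        ann = detect_knock_on([], traj, GEOM, window_frames=5,
                              approach_cutoff=6.0)
        assert any(a.from_site == "S2" and a.to_site == "S1" for a in ann)

    def test_single_ion_traversal_no_knock_on(self):
        traj = make_traj([np.linspace(-12, 12, 80)], ["ion_K"])
        assert detect_knock_on([], traj, GEOM) == []

    def test_generator_na_events_all_knocked_by_k(self, gen_events):
        traj, truth, events = gen_events
        ann = detect_knock_on(events, traj, GEOM)
        na_events = [e for e in events if e.species == "ion_Na"]
        assert len(na_events) == sum(e.species == "ion_Na" for e in truth)
        for e in na_events:
            hits = [a for a in ann
                    if a.atom_index == e.atom_index
                    and e.entry_frame <= a.frame <= e.exit_frame]
            assert hits and all(a.partner_species == "ion_K" for a in hits)

    def test_na_radial_offset_recorded(self, gen_events):
        _, _, events = gen_events
        na = [e for e in events if e.species == "ion_Na"]
        k = [e for e in events if e.species == "ion_K"]
        assert np.mean([e.radial_mean for e in na]) == pytest.approx(2.0,
                                                                     abs=0.3)
        assert np.mean([e.radial_mean for e in k]) < 1.0
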