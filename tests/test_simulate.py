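"""Simulator physics, determinism and ground-truth consistency."""

from datetime import date as Date

import numpy as np
import pytest

from sensorgraphs.events import split_by_day, validate_event_log
from sensorgraphs.graphs import build_daily_matrix, mask_impossible
from sensorgraphs.simulate import (
    CohortSpec,
    ResidentModel,
    generate_topology,
    inject_visitor_noise,
    simulate_cohort,
    simulate_participant,
)
from sensorgraphs.trends import fit_linear_trend


class TestGenerateTopology:
    def test_deterministic_and_indirect_bathroom(self):
        a = generate_topology(5, seed=3)
        b = generate_topology(5, seed=3)
        assert a == b
        assert not a.is_possible("bedroom", "bathroom")

    def test_single_room(self):
        topo = generate_topology(1, seed=0)
        assert topo.n == 1
        assert topo.possible_transitions == frozenset({(topo.rooms[0],) * 2})

    def test_connected_with_nonadjacent_pair(self):
        for seed in range(5):
            topo = generate_topology(6, seed=seed)
            possible = {(a, b) for a, b in topo.possible_transitions if a != b}
            all_pairs = {
                (a, b) for a in topo.rooms for b in topo.rooms if a != b
            }
            assert possible < all_pairs  # at least one non-adjacent pair
            # hub keeps the flat connected
            assert all(topo.neighbors(r) for r in topo.rooms)


class TestSimulateParticipant:
    def test_stationary_resident_rarely_fires(self):
        """With re-trigger off and nowhere to go, at most the entry events."""
        topo = generate_topology(1, seed=0)
        model = ResidentModel.default_for(topo, retrigger_rate=0.0)
        model.night_rate = 0.0
        log, _ = simulate_participant(model, days=5, seed=1)
        days = split_by_day(log)
        assert all(len(d) <= 1 for d in days)

    def test_entry_only_mode_reduces_events(self):
        topo = generate_topology(5, seed=2)
        dense = ResidentModel.default_for(topo, retrigger_rate=0.5)
        sparse = ResidentModel.default_for(topo, emission_mode="entry_only")
        log_dense, _ = simulate_participant(dense, days=5, seed=3)
        log_sparse, _ = simulate_participant(sparse, days=5, seed=3)
        assert len(log_sparse) < len(log_dense) / 3

    def test_emitted_log_is_physical(self):
        """Sorted, cool-down clean, and consecutive rooms always connected."""
        topo = generate_topology(5, seed=4)
        model = ResidentModel.default_for(topo)
        log, _ = simulate_participant(model, days=10, seed=5)
        assert log.is_sorted()
        assert validate_event_log(log, topo).ok
        rooms = [topo.sensor_map[s] for s in log.sensor_ids]
        assert all(
            topo.is_possible(a, b) for a, b in zip(rooms, rooms[1:])
        )

    def test_absence_days_silent_and_recorded(self):
        topo = generate_topology(5, seed=6)
        model = ResidentModel.default_for(topo)
        gone = (Date(2015, 1, 3), Date(2015, 1, 4))
        log, truth = simulate_participant(
            model, days=6, seed=7, absence_dates=gone
        )
        observed_dates = {d.date for d in split_by_day(log)}
        assert observed_dates.isdisjoint(gone)
        assert truth.absence_dates == gone
        assert all(truth.daily_event_counts[d.isoformat()] == 0 for d in gone)

    def test_ground_truth_counts_match_log(self):
        topo = generate_topology(5, seed=8)
        model = ResidentModel.default_for(topo)
        log, truth = simulate_participant(model, days=8, seed=9)
        for day in split_by_day(log):
            assert truth.daily_event_counts[day.date.isoformat()] == len(day)

    def test_injected_decline_recovered_from_daily_counts(self):
        """The event rate declines at the injected fractional slope."""
        slope = -0.003
        errors = []
        for seed in range(12):
            topo = generate_topology(5, seed=100 + seed)
            model = ResidentModel.default_for(topo)
            log, _ = simulate_participant(
                model, days=200, seed=200 + seed, activity_slope=slope
            )
            days = split_by_day(log)
            counts = np.array([len(d) for d in days], dtype=float)
            t = np.array([(d.date - days[0].date).days for d in days], dtype=float)
            fit = fit_linear_trend(counts / counts[:7].mean(), x=t)
            errors.append(abs(fit.slope - slope) / abs(slope))
        assert np.mean(errors) < 0.30

    def test_retrigger_rate_scales_diagonal_mass(self):
        """Doubling the re-trigger rate roughly doubles within-room mass."""
        diag_mass = {}
        for rate in (0.25, 0.5):
            masses = []
            for seed in range(10):
                topo = generate_topology(5, seed=50)
                model = ResidentModel.default_for(topo, retrigger_rate=rate)
                log, _ = simulate_participant(model, days=3, seed=300 + seed)
                for day in split_by_day(log):
                    M = build_daily_matrix(day, topo)
                    masses.append(np.trace(M.values))
            diag_mass[rate] = np.mean(masses)
        ratio = diag_mass[0.5] / diag_mass[0.25]
        assert 1.6 < ratio < 2.4


class TestVisitorNoise:
    def _participant(self, seed=11):
        topo = generate_topology(5, seed=seed)
        model = ResidentModel.default_for(topo)
        log, _ = simulate_participant(model, days=10, seed=seed)
        return topo, log

    def test_zero_rate_identity(self):
        topo, log = self._participant()
        noisy, idx = inject_visitor_noise(log, topo, 0.0, seed=1)
        assert len(idx) == 0
        assert noisy.frame.equals(log.frame)

    def test_same_seed_same_injections(self):
        topo, log = self._participant()
        a, idx_a = inject_visitor_noise(log, topo, 5.0, seed=2)
        b, idx_b = inject_visitor_noise(log, topo, 5.0, seed=2)
        assert a.frame.equals(b.frame)
        assert np.array_equal(idx_a, idx_b)

    def test_contaminated_log_still_respects_cooldown(self):
        topo, log = self._participant()
        noisy, idx = inject_visitor_noise(log, topo, 30.0, seed=3)
        assert len(idx) > 0
        assert validate_event_log(noisy, topo).n_cooldown_violations == 0

    def test_masking_absorbs_visitor_noise(self):
        """Masked daily matrices move less under contamination than unmasked."""
        topo, log = self._participant(seed=13)
        noisy, _ = inject_visitor_noise(log, topo, 40.0, seed=4)
        clean_days = {d.date: d for d in split_by_day(log)}
        noisy_days = {d.date: d for d in split_by_day(noisy)}
        unmasked_shift = masked_shift = 0.0
        for date in clean_days:
            cu = build_daily_matrix(clean_days[date], topo, mask=False)
            nu = build_daily_matrix(noisy_days[date], topo, mask=False)
            unmasked_shift += np.abs(cu.values - nu.values).sum()
            cm, _ = mask_impossible(cu, topo)
            nm, _ = mask_impossible(nu, topo)
            masked_shift += np.abs(cm.values - nm.values).sum()
        assert masked_shift < unmasked_shift


class TestSimulateCohort:
    def test_empty_spec(self):
        cohort = simulate_cohort(CohortSpec(n_intervention=0, n_control=0))
        assert cohort.logs == {} and cohort.assessments == []

    def test_deterministic_for_seed(self, tmp_path):
        spec = CohortSpec(
            n_intervention=2, n_control=1, study_days=15, seed=42,
            retrigger_rate=0.2,
        )
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        a.to_directory(tmp_path / "a")
        b.to_directory(tmp_path / "b")
        for sub in sorted((tmp_path / "a").rglob("*")):
            if sub.is_file():
                twin = tmp_path / "b" / sub.relative_to(tmp_path / "a")
                assert sub.read_bytes() == twin.read_bytes()

    def test_cohort_composition_and_truth(self):
        spec = CohortSpec(
            n_intervention=2, n_control=2, study_days=12, seed=5,
            retrigger_rate=0.2, visitor_rate_per_day=2.0,
        )
        cohort = simulate_cohort(spec)
        groups = [s.group for s in cohort.statuses.values()]
        assert groups.count("intervention") == 2 and groups.count("control") == 2
        for pid, truth in cohort.ground_truth.participants.items():
            expected = (
                spec.intervention_slope
                if truth.group == "intervention"
                else spec.control_slope
            )
            assert truth.activity_slope == expected
            assert truth.expected_pd_slope == -expected
        assert cohort.ground_truth.expected_pd_slopes["control"] == 0.001
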