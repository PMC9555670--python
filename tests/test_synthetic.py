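import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from proxnet.grouping import evaluate_all_pairs, assign_groups
from proxnet.ingest import assign_participants, parse_raw_log, sessionize, symmetrize
from proxnet.synthetic import (
    B2Truth,
    GroundTruth,
    StreamConfig,
    match_participants,
    simulate_b2_network,
    simulate_tag_stream,
    write_raw_log,
)


class TestSimulateB2Network:
    def test_extreme_negative_intercept_gives_empty_network(self):
        adj, _ = simulate_b2_network(B2Truth(mu=-20.0), np.zeros((50, 0)), 50, seed=0)
        assert adj.sum() == 0

    def test_density_half_at_zero_intercept(self):
        n = 200
        adj, _ = simulate_b2_network(B2Truth(mu=0.0), np.zeros((n, 0)), n, seed=1)
        dyads = n * (n - 1) // 2
        density = adj[np.triu_indices(n, 1)].mean()
        se = np.sqrt(0.25 / dyads)
        assert abs(density - 0.5) < 3 * se

    def test_covariate_enters_through_both_actors(self):
        # x_i = 1 for everyone, gamma = log 2: dyad log-odds = 2 log 2
        n = 200
        X = np.ones((n, 1))
        adj, _ = simulate_b2_network(B2Truth(mu=0.0, gamma=(np.log(2),)), X, n, seed=2)
        dyads = n * (n - 1) // 2
        target = expit(2 * np.log(2))  # = 0.8
        se = np.sqrt(target * (1 - target) / dyads)
        assert abs(adj[np.triu_indices(n, 1)].mean() - target) < 3 * se

    def test_density_converges_to_logistic_mu(self):
        n, mu = 150, -1.2
        adj, _ = simulate_b2_network(B2Truth(mu=mu), np.zeros((n, 0)), n, seed=3)
        dyads = n * (n - 1) // 2
        p = expit(mu)
        assert abs(adj[np.triu_indices(n, 1)].mean() - p) < 3 * np.sqrt(p * (1 - p) / dyads)

    def test_matrix_symmetric_zero_diagonal_and_effects_returned(self):
        adj, truth = simulate_b2_network(B2Truth(mu=0.0, sigma_a=1.0), np.zeros((20, 0)), 20, seed=4)
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        assert len(truth.actor_effects) == 20

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            B2Truth(mu=np.nan)
        with pytest.raises(ValueError):
            B2Truth(mu=0.0, sigma_a=-1.0)


class TestStreamConfigValidation:
    def test_bad_probabilities(self):
        with pytest.raises(ValueError, match="probability"):
            StreamConfig(group_size_probs=(0.5, 0.4))

    def test_bad_rates(self):
        with pytest.raises(ValueError):
            StreamConfig(encounter_rate=-1)
        with pytest.raises(ValueError):
            StreamConfig(duration_s=0)


class TestSimulateTagStream:
    def test_zero_arrivals_give_empty_log(self):
        records, truth = simulate_tag_stream(StreamConfig(arrival_rate=0.0, seed=1))
        assert len(records) == 0
        assert truth.sessions == [] and truth.group_map == {}

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = StreamConfig(duration_s=900, seed=7)
        a, _ = simulate_tag_stream(cfg)
        b, _ = simulate_tag_stream(cfg)
        write_raw_log(a, tmp_path / "a.csv")
        write_raw_log(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_tag_reuse_respects_recharge_gap(self):
        cfg = StreamConfig(duration_s=3600, n_tags=20, seed=11)
        _, truth = simulate_tag_stream(cfg)
        by_tag = {}
        for pid, tag, start, end in truth.sessions:
            by_tag.setdefault(tag, []).append((start, end))
        for intervals in by_tag.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert s2 - e1 >= cfg.recharge_gap_s

    def test_records_lie_inside_both_sessions(self):
        cfg = StreamConfig(duration_s=900, seed=13)
        records, truth = simulate_tag_stream(cfg)
        spans = {}
        for pid, tag, start, end in truth.sessions:
            spans.setdefault(tag, []).append((start, end))
        for col in ("reporter_tag", "opposing_tag"):
            for tag, t in zip(records[col], records["timestamp_s"]):
                assert any(s <= t <= e for s, e in spans[tag])

    def test_group_sessions_pairwise_overlap(self):
        cfg = StreamConfig(duration_s=1800, seed=17, group_size_probs=(0.3, 0.5, 0.2))
        _, truth = simulate_tag_stream(cfg)
        spans = {pid: (s, e) for pid, _, s, e in truth.sessions}
        by_group = {}
        for pid, gid in truth.group_map.items():
            by_group.setdefault(gid, []).append(pid)
        for members in by_group.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert spans[a][0] <= spans[b][1] and spans[b][0] <= spans[a][1]

    def test_round_trip_through_raw_log(self, tmp_path):
        records, _ = simulate_tag_stream(StreamConfig(duration_s=600, seed=19))
        path = tmp_path / "log.csv"
        write_raw_log(records, path)
        back = parse_raw_log(path)
        pd.testing.assert_frame_equal(
            records.sort_values(["timestamp_s", "reporter_tag", "opposing_tag"],
                                ignore_index=True),
            back.sort_values(["timestamp_s", "reporter_tag", "opposing_tag"],
                             ignore_index=True),
        )

    def test_empty_records_write_header_only(self, tmp_path):
        records, _ = simulate_tag_stream(StreamConfig(arrival_rate=0.0, seed=1))
        path = tmp_path / "empty.csv"
        write_raw_log(records, path)
        assert path.read_text().strip() == "timestamp_s,reporter_tag,opposing_tag,distance_cm"

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, truth = simulate_tag_stream(StreamConfig(duration_s=600, seed=23))
        truth.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.sessions == truth.sessions
        assert back.group_map == truth.group_map
        assert back.true_contacts == truth.true_contacts


def noise_free_config(seed, **overrides):
    """Planted groups in sustained close proximity, background encounters
    short and rare: the regime where the pipeline recovers truth exactly."""
    defaults = dict(
        duration_s=1200,
        arrival_rate=2.5,
        group_proximity_cm=45.0,
        group_proximity_sd_cm=3.0,
        coexit_lag_s=10,
        encounter_mean_s=4.0,
        encounter_sd_s=1.5,
        encounter_rate=0.01,
        seed=seed,
    )
    defaults.update(overrides)
    return StreamConfig(**defaults)


def run_grouping(records):
    sessions = sessionize(records)
    annotated = assign_participants(records, sessions)
    pair_seconds = symmetrize(annotated)
    criteria = evaluate_all_pairs(pair_seconds, sessions)
    participants = [s.participant_id for s in sessions]
    return sessions, assign_groups(criteria, participants)


def induced_partitions(truth, sessions, group_map):
    """Recovered and planted partitions over the planted participant ids
    that are observable in the log."""
    mapping = match_participants(truth, sessions)
    recovered = {}
    for pid, gid in group_map.items():
        recovered.setdefault(gid, set()).add(mapping[pid])
    observed = set(mapping.values())
    planted = {}
    for pid, gid in truth.group_map.items():
        if pid in observed:
            planted.setdefault(gid, set()).add(pid)
    return ({frozenset(v) for v in recovered.values()},
            {frozenset(v) for v in planted.values()})


class TestPlantedStructureRecovery:
    def test_two_person_parties_meet_all_three_criteria(self):
        # only pairs, no strangers' encounters: every party must be grouped
        cfg = noise_free_config(seed=31, group_size_probs=(0.0, 1.0), encounter_rate=0.0)
        records, truth = simulate_tag_stream(cfg)
        assert len(truth.sessions) >= 4
        sessions, group_map = run_grouping(records)
        recovered, planted = induced_partitions(truth, sessions, group_map)
        assert recovered == planted
        assert all(len(g) == 2 for g in planted)

    def test_short_planted_encounter_recovered_second_for_second(self):
        from proxnet.contacts import extract_contacts
        cfg = noise_free_config(seed=37)
        records, truth = simulate_tag_stream(cfg)
        sessions, group_map = run_grouping(records)
        mapping = match_participants(truth, sessions)
        pair_seconds = symmetrize(assign_participants(records, sessions))
        contacts = extract_contacts(pair_seconds, group_map)
        got = {
            tuple(sorted((mapping[a], mapping[b]))): n
            for a, b, n in zip(contacts["participant_a"], contacts["participant_b"],
                               contacts["contact_seconds"])
        }
        expected = {
            pair: sum(1 for _, d in trace if d < 150)
            for pair, trace in truth.true_contacts.items()
        }
        expected = {p: n for p, n in expected.items() if n > 0}
        assert got == expected
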