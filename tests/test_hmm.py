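"""Block caller: transition kernel, Viterbi optimality, merging, recovery."""
import itertools

import numpy as np
import pytest

from dhblocks import hmm, simulate as sim
from dhblocks._util import HET, MISSING, P1, P2, ConfigError

PARAMS = hmm.HmmParams()


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        assert np.allclose(hmm.transition_matrix(0.0, PARAMS), np.eye(3))

    def test_rows_sum_to_one(self):
        for d in (0.0, 1e3, 1e5, 1e7, 1e12):
            T = hmm.transition_matrix(d, PARAMS)
            assert np.allclose(T.sum(axis=1), 1.0)
            assert (T >= 0).all()

    def test_switch_probability_is_haldane_r(self):
        d = 250_000.0
        T = hmm.transition_matrix(d, PARAMS)
        r = 0.5 * (1 - np.exp(-2 * d * PARAMS.rho * 1e-8))
        assert T[0, 1] == pytest.approx(r)
        assert T[1, 0] == pytest.approx(r)

    def test_switch_probability_increasing_and_limits_to_half(self):
        distances = np.logspace(2, 8, 40)  # below saturation of the Haldane map
        switches = [hmm.transition_matrix(d, PARAMS)[0, 1] for d in distances]
        assert all(b > a for a, b in zip(switches, switches[1:]))
        assert hmm.transition_matrix(1e12, PARAMS)[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_het_entry_scales_with_prior(self):
        lo = hmm.transition_matrix(1e6, hmm.HmmParams(het_prior=0.001))[0, 2]
        hi = hmm.transition_matrix(1e6, hmm.HmmParams(het_prior=0.01))[0, 2]
        assert hi > lo

    @pytest.mark.parametrize("kw", [{"eps": 0.0}, {"eps": 0.6}, {"rho": 0.0},
                                    {"het_prior": 1.0}, {"min_block_markers": 0}])
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ConfigError):
            hmm.HmmParams(**kw)


def brute_force_best(calls, positions, params):
    """Exhaustive max over all 3^n state paths, vectorised over paths."""
    n = len(calls)
    obs = np.array([{P1: 0, P2: 1, HET: 2, MISSING: 3}[c] for c in calls])
    paths = np.array(list(itertools.product(range(3), repeat=n)), dtype=np.intp)
    log_e = hmm.emission_log_matrix(params)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.stationary_distribution(params))
    lp = log_pi[paths[:, 0]] + log_e[paths[:, 0], obs[0]]
    for t in range(1, n):
        with np.errstate(divide="ignore"):
            log_t = np.log(hmm.transition_matrix(float(positions[t] - positions[t - 1]), params))
        lp += log_t[paths[:, t - 1], paths[:, t]] + log_e[paths[:, t], obs[t]]
    return float(lp.max())


class TestViterbi:
    def test_empty_sequence_gives_empty_path(self):
        assert len(hmm.viterbi_path([], [], PARAMS)) == 0

    def test_unanimous_calls_give_constant_path(self):
        calls = [P1] * 40
        pos = list(range(10_000, 410_000, 10_000))
        assert (hmm.viterbi_path(calls, pos, PARAMS) == P1).all()

    def test_clean_switch_is_placed_between_the_evidence(self):
        calls = [P1] * 50 + [P2] * 50
        pos = list(range(10_000, 1_010_000, 10_000))
        path = hmm.viterbi_path(calls, pos, PARAMS)
        assert (path[:50] == P1).all() and (path[50:] == P2).all()

    def test_isolated_error_is_absorbed(self):
        calls = [P1] * 50 + [P2] + [P1] * 49
        pos = list(range(10_000, 1_010_000, 10_000))
        assert (hmm.viterbi_path(calls, pos, PARAMS) == P1).all()

    def test_missing_calls_carry_no_evidence(self):
        calls = [P1] * 10 + [MISSING] * 5 + [P1] * 10
        pos = list(range(10_000, 260_000, 10_000))
        assert (hmm.viterbi_path(calls, pos, PARAMS) == P1).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_viterbi_matches_brute_force_on_short_sequences(self, seed):
        """DP result attains the exhaustive 3^n maximum (n = 10)."""
        rng = np.random.default_rng(seed)
        n = 10
        calls = rng.choice([P1, P2, HET, MISSING], size=n, p=[0.4, 0.4, 0.1, 0.1])
        pos = np.cumsum(rng.integers(1_000, 100_000, size=n))
        path = hmm.viterbi_path(calls, pos, PARAMS)
        lp = hmm.path_joint_logprob(path, calls, pos, PARAMS)
        assert lp == pytest.approx(brute_force_best(calls, pos, PARAMS), rel=1e-12)

    def test_label_swap_equivariance(self):
        rng = np.random.default_rng(77)
        calls = list(rng.choice([P1, P2, MISSING], size=60, p=[0.5, 0.45, 0.05]))
        pos = list(np.cumsum(rng.integers(1_000, 50_000, size=60)))
        swap = {P1: P2, P2: P1, HET: HET, MISSING: MISSING}
        a = hmm.viterbi_path(calls, pos, PARAMS)
        b = hmm.viterbi_path([swap[c] for c in calls], pos, PARAMS)
        assert [swap[s] for s in a] == list(b)


class TestPathToBlocks:
    POS = list(range(10_000, 1_010_000, 10_000))

    def test_single_run_single_block(self):
        blocks = hmm.path_to_blocks([P1] * 100, self.POS, PARAMS, raw_calls=[P1] * 100)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start, b.end, b.label, b.n_markers, b.n_discordant) == (
            10_000, 1_000_000, P1, 100, 0)

    def test_small_block_merged_into_flank(self):
        """Hand-traced merge: P1 x50 | P2 x3 | P1 x47 -> one P1 block, 3 discordant."""
        path = [P1] * 50 + [P2] * 3 + [P1] * 47
        blocks = hmm.path_to_blocks(path, self.POS, PARAMS, raw_calls=path)
        assert len(blocks) == 1
        assert blocks[0].label == P1
        assert blocks[0].n_markers == 100
        assert blocks[0].n_discordant == 3

    def test_merge_prefers_better_supported_flank(self):
        path = [P1] * 4 + [HET] * 2 + [P2] * 94
        blocks = hmm.path_to_blocks(path, self.POS, PARAMS, raw_calls=path)
        # HET (2) absorbed by P2 flank (94 > 4); then P1 (4) absorbed by P2
        assert [b.label for b in blocks] == [P2]
        assert blocks[0].n_markers == 100

    def test_blocks_partition_markers_and_alternate(self):
        path = [P1] * 30 + [P2] * 40 + [P1] * 30
        blocks = hmm.path_to_blocks(path, self.POS, PARAMS, raw_calls=path)
        assert [b.label for b in blocks] == [P1, P2, P1]
        assert sum(b.n_markers for b in blocks) == 100
        for a, b in zip(blocks, blocks[1:]):
            assert a.end < b.start
            assert a.label != b.label


class TestCallBlocks:
    def test_parent_like_line_is_one_block_per_chromosome(self):
        calls_by_chrom = {
            "A01": (list(range(10_000, 510_000, 10_000)), [P1] * 50),
            "A02": (list(range(10_000, 310_000, 10_000)), [P1] * 30),
        }
        blocks = hmm.call_blocks(calls_by_chrom, PARAMS, line="LP08-like")
        assert len(blocks) == 2
        assert {b.label for b in blocks} == {P1}

    def test_empty_chromosome_yields_no_blocks(self, caplog):
        blocks = hmm.call_blocks({"A09": ([], [])}, PARAMS)
        assert blocks == []

    def test_noiseless_line_recovers_truth_exactly(self, noiseless_population):
        """With eps = 0 in the data, blocks equal truth segments marker-bounded."""
        res = noiseless_population
        pos = [m.position for m in res.markers]
        truth_blocks = sim.truth_to_blocks(res.truth, res.markers)
        for line in res.truth.lines:
            called = hmm.call_blocks({"A03": (pos, res.calls[line]["A03"])}, PARAMS, line=line)
            expected = [
                (b.start, b.end, b.label) for b in truth_blocks[line]
                if b.n_markers >= PARAMS.min_block_markers
            ]
            got = [(b.start, b.end, b.label) for b in called]
            if expected == got:
                continue
            # small true segments may be merged; every remaining boundary must
            # still coincide with a truth boundary
            truth_bounds = {b.start for b in truth_blocks[line]} | {b.end for b in truth_blocks[line]}
            assert all(b.start in truth_bounds and b.end in truth_bounds for b in called)

    def test_breakpoints_localised_to_true_intervals(self, noiseless_population):
        """eps = 0: every inferred breakpoint interval contains a true crossover."""
        res = noiseless_population
        pos = np.array([m.position for m in res.markers])
        for line in res.truth.lines:
            called = hmm.call_blocks({"A03": (list(pos), res.calls[line]["A03"])},
                                     PARAMS, line=line)
            xos = res.truth.crossovers[line]["A03"]
            for a, b in zip(called, called[1:]):
                assert any(a.end < x < b.start for x in xos), (a, b)

    def test_recovery_above_99_percent_with_default_noise(self, small_population):
        res = small_population
        pos = [m.position for m in res.markers]
        correct = total = 0
        for line in res.truth.lines:
            raw = res.calls[line]["A03"]
            path = hmm.viterbi_path(raw, pos, PARAMS)
            truth_labels = res.truth.labels_at_markers(line, res.markers, "A03")
            nonmiss = raw != MISSING
            correct += int((path[nonmiss] == truth_labels[nonmiss]).sum())
            total += int(nonmiss.sum())
        assert correct / total >= 0.99

    def test_block_count_not_above_raw_run_count(self, small_population):
        res = small_population
        pos = [m.position for m in res.markers]
        for line in res.truth.lines[:5]:
            raw = res.calls[line]["A03"]
            raw_runs = 1 + int(np.sum(raw[1:] != raw[:-1]))
            blocks = hmm.call_blocks({"A03": (pos, raw)}, PARAMS, line=line)
            assert len(blocks) <= raw_runs


class TestWindowedVote:
    def test_agrees_with_viterbi_away_from_boundaries(self):
        calls = [P1] * 60 + [P2] * 60
        pos = list(range(10_000, 1_210_000, 10_000))
        vote = hmm.windowed_vote_path(calls, window=11)
        vit = hmm.viterbi_path(calls, pos, PARAMS)
        assert (vote[:55] == vit[:55]).all()
        assert (vote[-55:] == vit[-55:]).all()


def test_blocks_tsv_round_trip(tmp_path, small_population):
    res = small_population
    pos = [m.position for m in res.markers]
    blocks = hmm.call_blocks({"A03": (pos, res.calls["DH001"]["A03"])}, PARAMS, line="DH001")
    p = tmp_path / "blocks.tsv"
    hmm.write_blocks_tsv(str(p), blocks)
    assert hmm.read_blocks_tsv(str(p)) == blocks
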