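"""Unit and property tests for the neutral ORF-decay simulator."""
import math

import numpy as np
import pytest

import retrofossil as rf
from retrofossil._codec import InvalidSequenceError
from retrofossil.decay import NOT_REACHED


def enumerate_stop_fraction(orf_seq: str) -> float:
    """Brute-force oracle: fraction of the 3L single substitutions that
    break intactness (create an internal stop or destroy the ATG)."""
    broken = 0
    total = 0
    for pos in range(len(orf_seq)):
        for base in "ACGT":
            if base == orf_seq[pos]:
                continue
            total += 1
            mutated = orf_seq[:pos] + base + orf_seq[pos + 1 :]
            if not rf.is_orf_intact(mutated, len(orf_seq)):
                broken += 1
    assert total == 3 * len(orf_seq)
    return broken / total


class TestIsOrfIntact:
    @pytest.mark.parametrize(
        "seq,length,expected",
        [
            ("ATGAAATAA", 9, True),  # unmutated toy ORF
            ("ATGTAATAA", 9, False),  # internal stop at codon 2
            ("ATGAATAA", 9, False),  # 1-bp deletion changed the length
            ("CTGAAATAA", 9, False),  # destroyed start codon
            ("ATGAAATAAC", 10, True),  # trailing partial codon never a stop
        ],
    )
    def test_basic(self, seq, length, expected):
        assert rf.is_orf_intact(seq, length) is expected

    def test_start_codon_requirement_toggle(self):
        assert rf.is_orf_intact("CTGAAATAA", 9, require_start_codon=False)

    def test_non_acgt_raises(self):
        with pytest.raises(InvalidSequenceError):
            rf.is_orf_intact("ATGNNNTAA", 9)


class TestMutateOnce:
    def test_substitution(self):
        assert rf.mutate_once("ATG", "sub", 0, base="C") == "CTG"

    def test_deletion(self):
        assert rf.mutate_once("ATG", "del", 1) == "AG"

    def test_insertion(self):
        assert rf.mutate_once("ATG", "ins", 2, base="A") == "ATGA"

    def test_substitution_changes_exactly_one_base(self, rng):
        seq = rf.random_intact_orf(60, rng).seq
        out = rf.mutate_once(seq, "sub", 17, rng)
        assert len(out) == len(seq)
        diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert diffs == [17]

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            rf.mutate_once("ATG", "sub", 3, base="C")


def _toy_config(**kw):
    defaults = dict(
        horizon_years=1e6,
        census_interval_years=5e4,
        n_replicates=300,
        seed=11,
    )
    defaults.update(kw)
    return rf.SimulationConfig(**defaults)


class TestSimulateDecay:
    def test_zero_rates_never_decay(self, rng):
        orf = rf.random_intact_orf(90, rng)
        params = rf.MutationParameters(0.0, 0.0, 0.0, 1.0)
        traj = rf.simulate_decay(orf, params, _toy_config())
        assert (traj.intact_counts == traj.n_replicates).all()

    def test_seed_determinism(self, rng):
        orf = rf.random_intact_orf(150, rng)
        params = rf.PRESETS["nwm-like"]
        t1 = rf.simulate_decay(orf, params, _toy_config())
        t2 = rf.simulate_decay(orf, params, _toy_config())
        assert (t1.intact_counts == t2.intact_counts).all()
        t3 = rf.simulate_decay(orf, params, _toy_config(seed=12))
        assert (t1.intact_counts != t3.intact_counts).any()

    def test_census_zero_all_intact(self, rng):
        orf = rf.random_intact_orf(90, rng)
        traj = rf.simulate_decay(orf, rf.PRESETS["nwm-like"], _toy_config())
        assert traj.intact_counts[0] == traj.n_replicates
        assert traj.census_times[0] == 0.0

    def test_substitution_only_matches_poisson_thinning(self, rng):
        # one census; mean substitution count m per replicate; the survival
        # probability is sum_k Pois(k; m) (1 - f_stop)^k = exp(-m f_stop)
        orf = rf.random_intact_orf(90, rng)
        f_stop = enumerate_stop_fraction(orf.seq)
        m = 0.25
        sub_rate = m / (len(orf.seq) * 5e4)  # g = 1 year
        params = rf.MutationParameters(sub_rate, 0.0, 0.0, 1.0)
        config = rf.SimulationConfig(
            horizon_years=5e4, census_interval_years=5e4, n_replicates=4000, seed=5
        )
        traj = rf.simulate_decay(orf, params, config)
        observed = traj.intact_fractions[-1]
        expected = math.exp(-m * f_stop)
        se = math.sqrt(expected * (1 - expected) / config.n_replicates)
        assert abs(observed - expected) <= 3 * se

    def test_doubling_sub_rate_cannot_help(self, rng):
        orf = rf.random_intact_orf(90, rng)
        base = rf.MutationParameters(2e-7, 0.0, 0.0, 1.0)
        double = rf.MutationParameters(4e-7, 0.0, 0.0, 1.0)
        cfg = _toy_config(n_replicates=2000)
        f1 = rf.simulate_decay(orf, base, cfg).intact_fractions[-1]
        f2 = rf.simulate_decay(orf, double, cfg).intact_fractions[-1]
        se = math.sqrt(2 * 0.25 / cfg.n_replicates)  # conservative paired bound
        assert f2 <= f1 + 3 * se

    def test_generation_time_equivalence(self, rng):
        # halving g at fixed rates == doubling all rates at fixed g
        orf = rf.random_intact_orf(90, rng)
        fast_g = rf.MutationParameters(2e-7, 1e-8, 1e-8, 0.5)
        fast_rates = rf.MutationParameters(4e-7, 2e-8, 2e-8, 1.0)
        cfg = _toy_config(n_replicates=2000)
        f1 = rf.simulate_decay(orf, fast_g, cfg).intact_fractions[-1]
        f2 = rf.simulate_decay(orf, fast_rates, rf.SimulationConfig(
            horizon_years=cfg.horizon_years,
            census_interval_years=cfg.census_interval_years,
            n_replicates=cfg.n_replicates,
            seed=99,
        )).intact_fractions[-1]
        p = (f1 + f2) / 2
        se = math.sqrt(max(p * (1 - p), 1 / cfg.n_replicates) * 2 / cfg.n_replicates)
        assert abs(f1 - f2) <= 3 * se

    def test_rejects_non_intact_start(self):
        with pytest.raises(ValueError):
            rf.simulate_decay(
                rf.CodingSequence("x", "ATGTAATAA"),
                rf.PRESETS["nwm-like"],
                _toy_config(),
            )


def linear_scan_percentiles(fractions, times, percentiles):
    """Independent oracle: naive scan over the whole trajectory."""
    out = {}
    for p in percentiles:
        out[p] = NOT_REACHED
        for f, t in zip(fractions, times):
            if f <= p:
                out[p] = t
                break
    return out


class TestRetentionPercentiles:
    def test_constant_one_never_reached(self):
        traj = rf.DecayTrajectory(
            [0.0, 1e6, 2e6], [100, 100, 100], 100, rf.PRESETS["nwm-like"]
        )
        calls = rf.retention_percentiles(traj)
        assert calls == {0.01: NOT_REACHED, 0.05: NOT_REACHED}

    def test_threshold_scan_example(self):
        traj = rf.DecayTrajectory(
            [0.0, 20e6, 40e6], [1000, 40, 9], 1000, rf.PRESETS["nwm-like"]
        )
        calls = rf.retention_percentiles(traj, (0.01, 0.05))
        assert calls[0.05] == 20e6
        assert calls[0.01] == 40e6

    def test_monotone_in_percentile(self):
        traj = rf.DecayTrajectory(
            [0.0, 1e6, 2e6, 3e6], [100, 30, 4, 0], 100, rf.PRESETS["nwm-like"]
        )
        calls = rf.retention_percentiles(traj, (0.01, 0.05, 0.5))
        assert calls[0.5] <= calls[0.05] <= calls[0.01]

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            counts = np.sort(rng.integers(0, 101, n))[::-1].copy()
            counts[0] = 100
            times = np.arange(n) * 5e4
            traj = rf.DecayTrajectory(times, counts, 100, rf.PRESETS["nwm-like"])
            ps = (0.01, 0.05, float(rng.uniform(0.001, 1.0)))
            expected = linear_scan_percentiles(counts / 100, times, ps)
            assert rf.retention_percentiles(traj, ps) == expected

    def test_invalid_percentile(self):
        traj = rf.DecayTrajectory([0.0], [10], 10, rf.PRESETS["nwm-like"])
        with pytest.raises(ValueError):
            rf.retention_percentiles(traj, (0.0,))
        with pytest.raises(ValueError):
            rf.retention_percentiles(traj, (1.5,))


class TestRetentionTest:
    def test_age_zero_not_flagged(self, rng):
        orf = rf.random_intact_orf(90, rng)
        result = rf.retention_test(
            0.0, orf, rf.PRESETS["nwm-like"], _toy_config(n_replicates=50)
        )
        assert result.intact_fraction == 1.0
        assert not result.candidate_selected

    def test_old_intact_copy_flagged(self, rng):
        # strongly mutagenic toy parameters: nothing survives 1 My neutrally
        orf = rf.random_intact_orf(120, rng)
        params = rf.MutationParameters(5e-6, 0.0, 0.0, 1.0)
        result = rf.retention_test(1e6, orf, params, _toy_config(n_replicates=200))
        assert result.intact_fraction < 0.05
        assert result.candidate_selected

    def test_age_beyond_horizon_rejected(self, rng):
        orf = rf.random_intact_orf(90, rng)
        with pytest.raises(ValueError):
            rf.retention_test(2e6, orf, rf.PRESETS["nwm-like"], _toy_config())
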