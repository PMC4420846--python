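"""Synthetic generators: determinism, noise model and invariant repair."""

import numpy as np
import pytest

from ensift import (
    BITS_PER_RESIDUE,
    FingerprintSimConfig,
    compute_auroc,
    make_toy_complex,
    simulate_centroid_scores,
    simulate_fingerprints,
)
from ensift.synthetic_data import signal_positions


def _by_compound(sifts):
    out = {}
    for s in sifts:
        out.setdefault(s.compound_id, []).append(s)
    return out


class TestSimulateFingerprints:
    def test_bit_identical_for_same_config_and_seed(self):
        cfg = FingerprintSimConfig(n_active=10, n_inactive=10, n_decoy=5,
                                   n_conformations=4, n_residues=6, seed=13)
        first, labels1 = simulate_fingerprints(cfg)
        second, labels2 = simulate_fingerprints(cfg)
        assert labels1 == labels2
        assert len(first) == len(second)
        for a, b in zip(first, second):
            assert (a.compound_id, a.conformation_id) == (b.compound_id, b.conformation_id)
            np.testing.assert_array_equal(a.bits, b.bits)

    def test_chunks_satisfy_interaction_invariants(self):
        cfg = FingerprintSimConfig(n_active=20, n_inactive=20, n_decoy=10,
                                   n_conformations=5, n_residues=8,
                                   background_rate=0.3, seed=2)
        sifts, _ = simulate_fingerprints(cfg)
        for s in sifts:
            chunks = s.bits.reshape(-1, BITS_PER_RESIDUE)
            payload_any = chunks[:, 1:].any(axis=1)
            np.testing.assert_array_equal(chunks[:, 0].astype(bool), payload_any)
            fired = chunks[:, 0] == 1
            assert (chunks[fired, 1] | chunks[fired, 2]).all()

    def test_noiseless_actives_reproduce_signal_exactly(self):
        cfg = FingerprintSimConfig(n_active=5, n_inactive=5, n_decoy=0,
                                   n_conformations=4, n_residues=6,
                                   flip_prob=0.0, background_rate=0.0,
                                   pose_fail_prob=0.0, seed=3)
        sifts, labels = simulate_fingerprints(cfg)
        signal = set(signal_positions(cfg))
        for s in sifts:
            on = set(np.flatnonzero(s.bits))
            interaction_on = {i for i in on if i % BITS_PER_RESIDUE >= 3}
            if labels[s.compound_id] == 1:
                assert interaction_on == signal
            else:
                assert not interaction_on

    @pytest.mark.parametrize("flip_prob,expected", [(0.5, 0.5), (0.3, 0.7)])
    def test_signal_bit_frequency_matches_bernoulli_mean(self, flip_prob, expected):
        cfg = FingerprintSimConfig(n_active=200, n_inactive=0, n_decoy=0,
                                   n_conformations=20, n_residues=10,
                                   flip_prob=flip_prob, background_rate=0.0,
                                   pose_fail_prob=0.0, seed=21)
        sifts, _ = simulate_fingerprints(cfg)
        signal = signal_positions(cfg)
        values = np.mean([s.bits[signal] for s in sifts], axis=0)
        n_draws = 200 * 20
        se = np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(values - expected) < 4 * se + 1e-9)

    def test_profile_variance_shrinks_with_ensemble_size(self):
        # the denoising law: Var(profile value at a signal bit) ≈ p(1−p)/s
        p = 0.3
        base = FingerprintSimConfig(n_active=400, n_inactive=0, n_decoy=0,
                                    n_residues=10, flip_prob=p,
                                    background_rate=0.0, pose_fail_prob=0.0,
                                    seed=5)
        for s_size in (5, 20):
            cfg = base.with_(n_conformations=s_size)
            sifts, _ = simulate_fingerprints(cfg)
            bit = signal_positions(cfg)[0]
            per_compound = [
                np.mean([s.bits[bit] for s in group])
                for group in _by_compound(sifts).values()
            ]
            expected_var = p * (1 - p) / s_size
            assert np.var(per_compound) == pytest.approx(expected_var, rel=0.35)

    def test_total_pose_failure_drops_compound(self):
        cfg = FingerprintSimConfig(n_active=50, n_inactive=50, n_decoy=0,
                                   n_conformations=2, n_residues=4,
                                   pose_fail_prob=0.6, seed=8)
        sifts, labels = simulate_fingerprints(cfg)
        surviving = {s.compound_id for s in sifts}
        assert surviving == set(labels)          # no zero-pose labels
        assert len(labels) < 100                 # some compounds dropped
        assert min(len(v) for v in _by_compound(sifts).values()) >= 1

    def test_correlated_mode_repeats_errors_across_conformations(self):
        # at ρ=1 every conformation of a compound carries identical bits
        cfg = FingerprintSimConfig(n_active=20, n_inactive=20, n_decoy=0,
                                   n_conformations=6, n_residues=6,
                                   noise_correlation=1.0,
                                   pose_fail_prob=0.0, seed=9)
        sifts, _ = simulate_fingerprints(cfg)
        for group in _by_compound(sifts).values():
            for s in group[1:]:
                np.testing.assert_array_equal(s.bits, group[0].bits)

    @pytest.mark.parametrize("bad", [
        {"flip_prob": 1.0}, {"background_rate": -0.1},
        {"noise_correlation": 1.5}, {"n_signal_bits": 10**6},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FingerprintSimConfig(**bad)

    def test_config_file_roundtrip(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "n_active = 12\nn_inactive = 8\nn_decoy = 0\n"
            "flip_prob = 0.25\nseed = 4\n"
        )
        cfg = FingerprintSimConfig.from_file(path)
        assert cfg.n_active == 12 and cfg.flip_prob == 0.25 and cfg.seed == 4


class TestToyComplexes:
    def test_empty_plan_gives_zero_sift(self):
        from ensift import compute_sift

        receptor, pose = make_toy_complex({}, n_residues=4)
        assert not compute_sift(receptor, pose).bits.any()

    def test_unknown_interaction_class_rejected(self):
        with pytest.raises(ValueError, match="unplantable"):
            make_toy_complex({0: ["halogen_bond"]})

    def test_residue_index_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_toy_complex({5: ["polar"]}, n_residues=3)

    def test_deterministic_for_fixed_seed(self):
        r1, p1 = make_toy_complex({0: ["hb_donor"]}, seed=3)
        r2, p2 = make_toy_complex({0: ["hb_donor"]}, seed=3)
        np.testing.assert_array_equal(
            [a.coords for a in p1.atoms], [a.coords for a in p2.atoms]
        )


class TestCentroidScores:
    def test_uninformative_conformation_near_half(self):
        scores = simulate_centroid_scores({"c": 0.0}, n_pos=100, n_neg=100,
                                          seed=0)
        pos, neg = scores["c"]
        # 3 standard errors of AUROC at n=100/100 is ~0.11
        assert abs(compute_auroc(pos, neg) - 0.5) < 0.12

    def test_fully_informative_conformation_separates(self):
        scores = simulate_centroid_scores({"c": 1.0}, n_pos=100, n_neg=100,
                                          seed=0)
        pos, neg = scores["c"]
        assert compute_auroc(pos, neg) > 0.95  # Φ(3/√2) ≈ 0.983

    def test_informativeness_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            simulate_centroid_scores({"c": 1.2}, seed=0)
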