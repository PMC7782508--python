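"""Bayesian posterior maps, entropy, and the attention window."""

import numpy as np
import pytest

from elmsearch.belief import (
    FixationRecord,
    MemoryBuffer,
    PosteriorMap,
    attention_probability,
    ct_exponent,
    entropy,
    posterior_ct,
    posterior_elm_update,
)
from elmsearch.evidence import evidence_moments, sample_elm_response
from elmsearch.grid import generate_grid


def _record(rng, n, T, a_scale=3.0, k_scale=6.0, target=None):
    a = rng.uniform(0.5, a_scale, n)
    k = rng.uniform(1.0, k_scale, n)
    W = np.array([
        rng.normal(*_moments(T, ai, ki, target == i))
        for i, (ai, ki) in enumerate(zip(a, k))
    ])
    return FixationRecord(location=np.zeros(2), T_f=T, W=W, a=a, k=k)


def _moments(T, a, k, present):
    from elmsearch.visibility import TemporalVisibility
    m, v = evidence_moments(T, TemporalVisibility(a, k), present)
    return m, np.sqrt(v)


class TestElmUpdate:
    def test_zero_dprime_leaves_posterior(self, rng):
        p = PosteriorMap.from_probabilities(rng.dirichlet(np.ones(20)))
        out = posterior_elm_update(p, rng.normal(size=20), np.zeros(20))
        assert out.p == pytest.approx(p.p, abs=1e-14)

    def test_two_location_hand_case(self):
        p = PosteriorMap.from_probabilities([0.5, 0.5])
        out = posterior_elm_update(p, np.array([0.5, -0.5]), np.array([1.0, 1.0]))
        z = np.exp(0.5) + np.exp(-0.5)
        assert out.p == pytest.approx([np.exp(0.5) / z, np.exp(-0.5) / z], abs=1e-4)
        assert out.p[0] == pytest.approx(0.7311, abs=1e-4)

    def test_recursion_equals_batch_product(self, rng):
        # three sequential updates equal the batch form with summed exponents
        n = 50
        p = PosteriorMap.uniform(n)
        total = np.zeros(n)
        for _ in range(3):
            W = rng.normal(size=n)
            d = rng.uniform(0, 3, n)
            total += d**2 * W
            p = posterior_elm_update(p, W, d)
        batch = PosteriorMap(total - np.log(n))
        assert p.log_p == pytest.approx(batch.log_p, abs=1e-10)

    def test_incremental_equals_batch_many_seeds(self):
        # five-fixation histories, 100 seeds, agreement to 1e-10
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 30
            p = PosteriorMap.uniform(n)
            total = np.zeros(n)
            for _ in range(5):
                d = rng.uniform(0, 4, n)
                W = sample_elm_response(rng.random(n) < 0.1, d, rng)
                total += d**2 * W
                p = posterior_elm_update(p, W, d)
            batch = PosteriorMap(total - np.log(n))
            np.testing.assert_allclose(p.p, batch.p, atol=1e-10)

    def test_normalisation_invariant(self, rng):
        p = PosteriorMap.uniform(400)
        for _ in range(20):
            p = posterior_elm_update(p, rng.normal(size=400) * 50,
                                     rng.uniform(0, 3, 400))
            assert np.exp(p.log_p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_overflow_handled_in_log_domain(self):
        p = PosteriorMap.uniform(3)
        out = posterior_elm_update(
            p, np.array([500.0, 0.0, -500.0]), np.array([2.0, 1.0, 2.0])
        )
        assert np.isfinite(out.log_p[0])
        assert out.p[0] == pytest.approx(1.0)


class TestPosteriorCt:
    def test_zero_evidence_gives_uniform(self):
        n = 10
        rec = FixationRecord(np.zeros(2), 0.3, np.zeros(n),
                             np.full(n, 2.0), np.full(n, 5.0))
        buf = MemoryBuffer()
        buf.append(rec)
        assert posterior_ct(buf).p == pytest.approx(np.full(n, 1 / n))

    def test_unlimited_memory_matches_direct_sum(self, rng):
        n = 25
        buf = MemoryBuffer(capacity=None)
        expo = np.zeros(n)
        for _ in range(4):
            rec = _record(rng, n, T=rng.uniform(0.1, 0.5), target=3)
            buf.append(rec)
            expo += rec.a**2 * rec.W / (2 + 2 * np.exp(-rec.T_f * rec.k))
        direct = np.exp(expo - expo.max())
        direct /= direct.sum()
        assert posterior_ct(buf).p == pytest.approx(direct, abs=1e-12)

    def test_memory_one_ignores_older_records(self, rng):
        n = 25
        latest = _record(rng, n, T=0.3, target=3)
        older1 = _record(rng, n, T=0.2, target=3)
        older2 = _record(rng, n, T=0.4, target=3)
        buf_a = MemoryBuffer(capacity=1)
        for r in (older1, latest):
            buf_a.append(r)
        buf_b = MemoryBuffer(capacity=1)
        for r in (older2, latest):
            buf_b.append(r)
        assert posterior_ct(buf_a).p == pytest.approx(posterior_ct(buf_b).p)

    def test_capacity_keeps_last_m(self, rng):
        buf = MemoryBuffer(capacity=3)
        recs = [_record(rng, 5, T=0.2) for _ in range(6)]
        for r in recs:
            buf.append(r)
        assert len(buf) == 3
        assert buf.records == recs[-3:]

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            posterior_ct(MemoryBuffer())

    def test_calibration_against_simulation(self):
        # the continuous-time posterior is a proper posterior for the leaky
        # accumulated evidence: among simulated trials where it assigns
        # probability p to a location, that location holds the target in
        # ~p of the cases (empirical-Bayes calibration check)
        rng = np.random.default_rng(0)
        n, T, trials = 3, 0.25, 4000
        a = np.array([2.5, 2.0, 1.5])
        k = np.array([6.0, 4.0, 8.0])
        probs, hits = [], []
        for _ in range(trials):
            target = rng.integers(n)
            W = np.array([
                rng.normal(*_moments(T, a[i], k[i], i == target)) for i in range(n)
            ])
            rec = FixationRecord(np.zeros(2), T, W, a, k)
            buf = MemoryBuffer()
            buf.append(rec)
            p = posterior_ct(buf).p
            probs.extend(p)
            hits.extend(np.arange(n) == target)
        probs, hits = np.array(probs), np.array(hits, dtype=float)
        for lo, hi in [(0.2, 0.4), (0.4, 0.6), (0.6, 0.8)]:
            mask = (probs >= lo) & (probs < hi)
            assert mask.sum() > 50
            assert hits[mask].mean() == pytest.approx(
                probs[mask].mean(), abs=0.05
            )

    def test_concentrates_on_persistent_target(self):
        # ten fixations of d' = 3 evidence at the target drive its
        # posterior above 0.9 in most histories
        finals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 400
            d = np.full(n, 0.2)
            d[7] = 3.0
            p = PosteriorMap.uniform(n)
            for _ in range(10):
                W = sample_elm_response(np.arange(n) == 7, d, rng)
                p = posterior_elm_update(p, W, d)
            finals.append(p.p[7])
        assert np.median(finals) > 0.9


class TestEntropy:
    def test_uniform_is_log_n(self):
        assert entropy(PosteriorMap.uniform(400)) == pytest.approx(np.log(400),
                                                                   abs=1e-12)
        assert entropy(PosteriorMap.uniform(400)) == pytest.approx(5.9915, abs=1e-4)

    def test_delta_is_zero(self):
        p = np.zeros(50)
        p[3] = 1.0
        assert entropy(PosteriorMap.from_probabilities(p)) == 0.0

    def test_below_uniform_for_nonuniform(self, rng):
        for _ in range(10):
            p = PosteriorMap.from_probabilities(rng.dirichlet(np.ones(400)))
            assert entropy(p) < np.log(400)


class TestAttentionProbability:
    def test_uniform_mass_counts_nodes(self):
        grid = generate_grid(400, 7.5)
        p = PosteriorMap.uniform(400)
        point = grid[37]
        n_in = int((((grid - point) ** 2).sum(axis=1) <= 0.25).sum())
        assert attention_probability(p, point, grid) == pytest.approx(n_in / 400)

    @pytest.mark.filterwarnings("ignore:no predefined location")
    def test_never_exceeds_one(self, rng):
        grid = generate_grid(400, 7.5)
        for _ in range(20):
            p = PosteriorMap.from_probabilities(rng.dirichlet(np.ones(400)))
            pt = rng.uniform(-7.5, 7.5, 2)
            assert attention_probability(p, pt, grid) <= 1.0 + 1e-12

    def test_empty_window_warns_and_returns_zero(self):
        grid = generate_grid(400, 7.5)
        p = PosteriorMap.uniform(400)
        with pytest.warns(UserWarning, match="no predefined location"):
            assert attention_probability(p, [50.0, 50.0], grid) == 0.0


class TestCtExponent:
    def test_matches_formula(self, rng):
        rec = _record(rng, 10, T=0.3)
        expected = rec.a**2 * rec.W / (2 + 2 * np.exp(-0.3 * rec.k))
        assert ct_exponent(rec) == pytest.approx(expected, rel=1e-12)
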