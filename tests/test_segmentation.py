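import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voicelaws as vl
from voicelaws.errors import DegenerateDataError


def naive_scan(values, thr):
    """Brute-force per-sample run scan: the independent segmentation oracle."""
    tokens, silences = [], []
    kind = None
    start = 0
    for i, v in enumerate(values):
        k = "tok" if v > thr else "sil"
        if k != kind:
            if kind == "tok":
                tokens.append((start, i - start, float(np.sum(values[start:i]))))
            elif kind == "sil":
                silences.append((start, i - start))
            kind, start = k, i
    n = len(values)
    if kind == "tok":
        tokens.append((start, n - start, float(np.sum(values[start:n]))))
    elif kind == "sil":
        silences.append((start, n - start))
    return tokens, silences


class TestResolveThreshold:
    def test_one_to_ten_at_80(self):
        e = vl.EnergySeries(np.arange(1.0, 11.0), 1.0)
        t = vl.resolve_threshold(e, 80.0)
        assert t.resolved_energy == 3.0
        assert np.sum(e.values < t.resolved_energy) == 2  # exactly 20%

    def test_theta_to_100_limit_is_minimum(self, rng):
        e = vl.EnergySeries(rng.random(1000), 1.0)
        t = vl.resolve_threshold(e, 99.99)
        assert t.resolved_energy == e.values.min()
        assert np.sum(e.values < t.resolved_energy) == 0

    def test_continuous_series_strict_below_fraction(self, rng):
        e = vl.EnergySeries(rng.random(10000), 1.0)
        t = vl.resolve_threshold(e, 80.0)
        assert np.sum(e.values < t.resolved_energy) == 2000

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateDataError):
            vl.resolve_threshold(vl.EnergySeries(np.ones(10), 1.0), 50.0)

    def test_monotone_in_theta(self, rng):
        e = vl.EnergySeries(rng.random(5000) ** 2, 1.0)
        thetas = [10, 30, 50, 70, 90, 99]
        resolved = [vl.resolve_threshold(e, t).resolved_energy for t in thetas]
        assert all(a >= b for a, b in zip(resolved, resolved[1:]))

    @given(st.integers(0, 2**31 - 1), st.integers(5, 95))
    @settings(max_examples=30, deadline=None)
    def test_strict_below_never_exceeds_quota(self, seed, theta):
        vals = np.random.default_rng(seed).random(503)
        t = vl.resolve_threshold(vl.EnergySeries(vals, 1.0), float(theta))
        q = (100 - theta) / 100
        assert np.sum(vals < t.resolved_energy) <= q * vals.size


class TestExtractEvents:
    def test_hand_case(self):
        e = vl.EnergySeries(np.array([0.0, 5.0, 5.0, 0.0]), 1.0)
        ev = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0))
        assert len(ev.tokens) == 1
        tok = ev.tokens[0]
        assert (tok.start_index, tok.length_samples, tok.energy) == (1, 2, 10.0)
        assert [s.length_samples for s in ev.silences] == [1, 1]

    def test_all_above_threshold(self):
        e = vl.EnergySeries(np.full(7, 3.0) + np.arange(7) * 0.1, 1.0)
        ev = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0))
        assert len(ev.tokens) == 1 and len(ev.silences) == 0
        assert ev.tokens[0].length_samples == 7

    def test_ties_count_as_silence(self):
        e = vl.EnergySeries(np.array([1.0, 2.0, 1.0]), 1.0)
        ev = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0))
        assert len(ev.tokens) == 1 and ev.tokens[0].start_index == 1

    def test_matches_naive_scan_and_conserves(self, rng):
        vals = rng.random(10000) ** 3
        e = vl.EnergySeries(vals, 16000.0)
        t = vl.resolve_threshold(e, 60.0)
        ev = vl.extract_events(e, t)
        toks, sils = naive_scan(vals, t.resolved_energy)
        assert [(x.start_index, x.length_samples) for x in ev.tokens] == [
            (s, l) for s, l, _ in toks]
        assert [(x.start_index, x.length_samples) for x in ev.silences] == sils
        np.testing.assert_allclose(
            ev.token_energies, [en for _, _, en in toks], rtol=1e-9)
        # conservation: sum of token energies == total above-threshold energy
        np.testing.assert_allclose(
            ev.token_energies.sum(), vals[vals > t.resolved_energy].sum(),
            rtol=1e-12)

    def test_tiling(self, rng):
        vals = rng.random(4321)
        e = vl.EnergySeries(vals, 1.0)
        ev = vl.segment(e, 45.0)
        total = sum(t.length_samples for t in ev.tokens) + sum(
            s.length_samples for s in ev.silences)
        assert total == ev.series_length == 4321

    def test_boundary_drop_removes_edge_runs(self):
        vals = np.array([5.0, 0.0, 5.0, 5.0, 0.0, 5.0])
        e = vl.EnergySeries(vals, 1.0)
        keep = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0), "keep")
        drop = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0), "drop")
        assert len(keep.tokens) == 3
        assert len(drop.tokens) == 1  # the interior run [2,3]
        assert drop.tokens[0].start_index == 2
        assert drop.n_dropped_edge_runs == 2

    def test_concatenation_yields_union(self, rng):
        a = rng.random(500)
        b = rng.random(500)
        thr = vl.ThresholdSpec(50.0, 0.5)
        gap = np.full(10, 0.1)  # below threshold
        joined = vl.EnergySeries(np.concatenate([a, gap, b]), 1.0)
        ea = vl.extract_events(vl.EnergySeries(a, 1.0), thr)
        eb = vl.extract_events(vl.EnergySeries(b, 1.0), thr)
        ej = vl.extract_events(joined, thr)
        expect = [(t.start_index, t.length_samples) for t in ea.tokens] + [
            (t.start_index + 510, t.length_samples) for t in eb.tokens]
        assert [(t.start_index, t.length_samples) for t in ej.tokens] == expect

    def test_zero_tokens_is_legal(self):
        e = vl.EnergySeries(np.array([0.1, 0.2, 0.3]), 1.0)
        ev = vl.extract_events(e, vl.ThresholdSpec(50.0, 1.0))
        assert len(ev) == 0 and len(ev.silences) == 1
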