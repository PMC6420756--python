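"""Histosketch core: bin assignment, CWS hashing, creation, updates, decay,
streaming and serialization."""

import dataclasses
import io
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from microsketch import (
    CountMinSketch,
    CWSDraw,
    EmptySpectrumError,
    HistoSketch,
    IncompatibleSketchError,
    KmerSpectrum,
    NothingToSketchError,
    SketchConfig,
    SketchFormatError,
    apply_decay,
    assign_bin,
    create_histosketch,
    cws_draw,
    cws_hash,
    load_sketch,
    read_fastq,
    save_sketch,
    sketch_stream,
    update_histosketch,
)
from microsketch.histosketch import _cws_randoms, sketch_from_json, sketch_to_json
from microsketch.synthetic_data import exact_spectrum, generate_reads, make_community


class TestAssignBin:
    def test_single_bin(self):
        assert assign_bin(123456, 1, 0) == 0

    def test_deterministic(self):
        assert assign_bin(987, 100, 7) == assign_bin(987, 100, 7)

    def test_uniformity_chi_square(self):
        kmers = np.random.default_rng(0).integers(0, 4**21, size=100_000)
        bins = assign_bin(kmers, 100, master_seed=3)
        counts = np.bincount(np.asarray(bins), minlength=100)
        assert chisquare(counts).pvalue > 0.001


class TestCWSDraws:
    def test_pure_function(self):
        assert cws_draw(3, 5, 11) == cws_draw(3, 5, 11)

    def test_neighbouring_slots_uncorrelated(self):
        i = np.arange(10_000, dtype=np.uint64)
        r0, _, _ = _cws_randoms(i, np.uint64(0), master_seed=1)
        r1, _, _ = _cws_randoms(i, np.uint64(1), master_seed=1)
        assert abs(np.corrcoef(r0, r1)[0, 1]) < 0.05

    def test_gamma_and_uniform_moments(self):
        # r, c ~ Gamma(shape=2, scale=1): mean 2, var 2; beta ~ U(0,1): mean 1/2
        i = np.arange(100_000, dtype=np.uint64)
        r, c, beta = _cws_randoms(i, np.uint64(7), master_seed=2)
        se = math.sqrt(2.0 / len(i))
        assert abs(r.mean() - 2.0) < 3 * se
        assert abs(c.mean() - 2.0) < 3 * se
        assert abs(beta.mean() - 0.5) < 3 * math.sqrt(1 / 12 / len(i))


class TestCWSHash:
    def test_unit_weight_zero_beta(self):
        y, a = cws_hash(1.0, CWSDraw(r=1.0, c=1.0, beta=0.0))
        assert y == pytest.approx(1.0)
        assert a == pytest.approx(1.0 / math.e)

    def test_symbolic_simplification(self):
        # beta=1, r=log(W), c=1 collapses to y=1, a=1/W
        for w in (2.0, 7.0, 1e6):
            y, a = cws_hash(w, CWSDraw(r=math.log(w), c=1.0, beta=1.0))
            assert y == pytest.approx(1.0)
            assert a == pytest.approx(1.0 / w)

    def test_monotone_in_weight(self):
        draw = CWSDraw(r=1.3, c=0.7, beta=0.4)
        y1, a1 = cws_hash(3.0, draw)
        y2, a2 = cws_hash(6.0, draw)
        assert y2 > y1 and a2 < a1

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            cws_hash(0.0, CWSDraw(1, 1, 0.5))


def _spectrum(weights, num_bins=None):
    weights = np.asarray(weights, dtype=float)
    return KmerSpectrum(num_bins or len(weights), weights)


class TestCreate:
    def test_single_nonzero_bin_wins_everywhere(self):
        cfg = SketchConfig(sketch_size=32, num_bins=10, master_seed=1)
        hs = create_histosketch(_spectrum([0, 0, 0, 5.0, 0, 0, 0, 0, 0, 0]), cfg)
        assert np.all(hs.S == 3)

    def test_selection_tracks_weight(self):
        cfg = SketchConfig(sketch_size=512, num_bins=2, master_seed=1)
        hs = create_histosketch(_spectrum([1.0, 1e6]), cfg)
        assert np.mean(hs.S == 1) > 0.99  # P(bin 0) ~ 1e-6 per slot

    def test_matches_bruteforce_double_loop(self):
        cfg = SketchConfig(sketch_size=16, num_bins=8, master_seed=7)
        W = np.array([0, 1.0, 2.0, 0, 3.0, 0.5, 0, 4.0])
        hs = create_histosketch(_spectrum(W), cfg)
        for j in range(16):
            best_a, best_i = math.inf, None
            for i in range(8):
                if W[i] <= 0:
                    continue
                _, a = cws_hash(W[i], cws_draw(i, j, 7))
                if a < best_a:
                    best_a, best_i = a, i
            assert hs.S[j] == best_i
            assert hs.A[j] == pytest.approx(best_a, rel=0, abs=0)

    def test_empty_spectrum_rejected(self):
        cfg = SketchConfig(sketch_size=8, num_bins=4, master_seed=1)
        with pytest.raises(EmptySpectrumError):
            create_histosketch(_spectrum([0.0, 0, 0, 0]), cfg)


class TestUpdate:
    def _cfg(self):
        return SketchConfig(sketch_size=64, num_bins=100, epsilon=1e-5, master_seed=3)

    def test_first_update_fills_all_slots(self):
        cfg = self._cfg()
        hs = HistoSketch(cfg)
        cms = CountMinSketch(cfg.epsilon, cfg.delta, cfg.master_seed)
        cms.add(17, 4.0)
        update_histosketch(hs, 17, cms)
        assert np.all(hs.S == 17) and np.all(np.isfinite(hs.A))

    def test_losing_update_changes_nothing(self):
        cfg = self._cfg()
        cms = CountMinSketch(cfg.epsilon, cfg.delta, cfg.master_seed)
        cms.add(17, 1e9)
        hs = HistoSketch(cfg)
        update_histosketch(hs, 17, cms)
        before_s, before_a = hs.S.copy(), hs.A.copy()
        cms.add(55, 1e-6)
        update_histosketch(hs, 55, cms)
        # a tiny-weight bin essentially never beats a huge incumbent
        assert np.mean(hs.S != before_s) < 0.1
        assert np.all(hs.A <= before_a)

    def test_replay_equals_batch_any_order(self):
        rng = np.random.default_rng(4)
        cfg = self._cfg()
        W = np.zeros(100)
        nz = rng.choice(100, 30, replace=False)
        W[nz] = rng.integers(1, 20, size=30)
        batch = create_histosketch(_spectrum(W), cfg)
        for order in (sorted(nz), sorted(nz, reverse=True), list(rng.permutation(nz))):
            cms = CountMinSketch(cfg.epsilon, cfg.delta, cfg.master_seed)
            hs = HistoSketch(cfg)
            for b in order:
                cms.add(int(b), float(W[b]))
                update_histosketch(hs, int(b), cms)
            assert np.array_equal(hs.S, batch.S)
            assert np.array_equal(hs.A, batch.A)


class TestDecay:
    def test_zero_is_identity(self):
        cfg = SketchConfig(sketch_size=8, num_bins=4, master_seed=1)
        hs = create_histosketch(_spectrum([1.0, 2, 3, 4]), cfg)
        cms = CountMinSketch(master_seed=1)
        cms.add(1, 5)
        a_before, counters_before = hs.A.copy(), cms.counters.copy()
        apply_decay(hs, cms, 0.0)
        assert np.array_equal(hs.A, a_before)
        assert np.array_equal(cms.counters, counters_before)

    def test_decay_arithmetic(self):
        cfg = SketchConfig(sketch_size=4, num_bins=2, master_seed=1)
        hs = HistoSketch(cfg, np.zeros(4, dtype=np.int64), np.ones(4))
        cms = CountMinSketch(master_seed=1)
        cms.add(0, 10.0)
        apply_decay(hs, cms, 0.02)
        assert hs.A[0] == pytest.approx(1.0 / 0.98)
        assert cms.estimate(0) == pytest.approx(9.8)

    def test_repeated_decay_inflates_hashes_only(self):
        cfg = SketchConfig(sketch_size=8, num_bins=4, master_seed=1)
        hs = create_histosketch(_spectrum([1.0, 2, 3, 4]), cfg)
        cms = CountMinSketch(master_seed=1)
        s_before = hs.S.copy()
        last = hs.A.copy()
        for _ in range(3):
            apply_decay(hs, cms, 0.1)
            assert np.all(hs.A > last)
            last = hs.A.copy()
        assert np.array_equal(hs.S, s_before)


class TestSketchStream:
    def _records(self, community, n_reads, seed):
        fq = generate_reads(community, n_reads, 100, 0.001, seed=seed)
        return read_fastq(io.BytesIO(fq))

    def test_snapshot_count(self, small_community, small_config):
        cfg = dataclasses.replace(small_config, interval=100)
        snaps = list(sketch_stream(self._records(small_community, 1000, 2), cfg))
        assert len(snaps) == 11  # 10 interval flushes + the final snapshot
        assert snaps[-1].reads_consumed == 1000

    def test_whole_input_equals_batch_create(self, small_community, small_config):
        records = list(self._records(small_community, 300, 3))
        final = list(sketch_stream(iter(records), small_config))[-1]
        spectrum = exact_spectrum(records, small_config.k, small_config.num_bins,
                                  small_config.master_seed)
        batch = create_histosketch(spectrum, small_config)
        assert np.array_equal(final.S, batch.S)
        assert np.allclose(final.A, batch.A)

    def test_counter_count_does_not_change_result(self, small_community, small_config):
        records = list(self._records(small_community, 400, 4))
        cfg1 = dataclasses.replace(small_config, interval=100, num_counters=1)
        cfg4 = dataclasses.replace(small_config, interval=100, num_counters=4)
        final1 = list(sketch_stream(iter(records), cfg1))[-1]
        final4 = list(sketch_stream(iter(records), cfg4))[-1]
        assert np.array_equal(final1.S, final4.S)
        assert np.array_equal(final1.A, final4.A)

    def test_no_valid_kmers_raises(self, small_config):
        fq = b"@r1\nNNNNNNNNNNNNNNNNNNNNNNNN\n+\nIIIIIIIIIIIIIIIIIIIIIIII\n"
        with pytest.raises(NothingToSketchError):
            list(sketch_stream(read_fastq(io.BytesIO(fq)), small_config))

    def test_deterministic_end_to_end(self, small_community, small_config):
        a = list(sketch_stream(self._records(small_community, 200, 5), small_config))[-1]
        b = list(sketch_stream(self._records(small_community, 200, 5), small_config))[-1]
        assert a == b


class TestSerialization:
    def _sketch(self):
        cfg = SketchConfig(k=15, sketch_size=16, num_bins=50, master_seed=9,
                           decay_ratio=0.02)
        hs = create_histosketch(_spectrum(np.arange(50, dtype=float) + 1, 50), cfg)
        hs.reads_consumed = 123
        return hs

    def test_round_trip(self):
        hs = self._sketch()
        assert load_sketch(save_sketch(hs)) == hs

    def test_json_round_trip(self):
        hs = self._sketch()
        assert sketch_from_json(sketch_to_json(hs)) == hs

    def test_truncated_rejected(self):
        data = save_sketch(self._sketch())
        with pytest.raises(SketchFormatError):
            load_sketch(data[:-8])

    def test_bad_magic_rejected(self):
        data = save_sketch(self._sketch())
        with pytest.raises(SketchFormatError):
            load_sketch(b"XXXX" + data[4:])

    def test_mismatched_k_not_comparable_downstream(self):
        from microsketch import jaccard_similarity

        hs = self._sketch()
        other = load_sketch(save_sketch(hs))
        object.__setattr__(other.config, "k", 21)
        with pytest.raises(IncompatibleSketchError, match="k"):
            jaccard_similarity(hs, other)
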