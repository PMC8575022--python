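"""Kernel PFMs, perturbation deltas, effect sizes, combined tests."""

import numpy as np
import pytest

from dismir.encoding import EncoderConfig, encode
from dismir.io import GenomicRegion, MethylRead
from dismir.interpretation import (
    delta_scores,
    fisher_combine,
    kernel_activated_reads,
    kernel_pfm,
    motif_match_correlation,
    mwu_effect_size,
    pfm_probabilities,
    quadrant_summary,
    write_meme,
)
from dismir.model import ModelConfig, build_model

CFG = ModelConfig(
    input_length=12, conv1_filters=4, conv1_width=3, pool_width=2,
    lstm_units=3, conv2_filters=3, conv2_width=2, dense_units=(8, 4, 1),
    seed=0,
)


def encode_seq(seq, meth=None):
    meth = meth or "." * len(seq)
    read = MethylRead("r", "chr1", 0, "+", seq, meth)
    return encode(read, EncoderConfig(trim5=0, length=len(seq))).matrix


def plant_acg_kernel(model, kernel_id=0):
    """Make kernel `kernel_id` fire exactly on 'ACG' windows."""
    conv = model.network.layers[0]
    W = conv.params["W"].reshape(conv.width, conv.in_channels, conv.filters)
    W[:, :, kernel_id] = 0.0
    W[0, 0, kernel_id] = 1.0  # A
    W[1, 1, kernel_id] = 1.0  # C
    W[2, 2, kernel_id] = 1.0  # G
    conv.params["W"] = W.reshape(conv.width * conv.in_channels, conv.filters)
    conv.params["b"][kernel_id] = -2.0  # only a full ACG match exceeds 0
    return model


def brute_force_pfm(reads, kernel, bias, top_fraction):
    """Literal double loop over every read and offset."""
    w = kernel.shape[0]
    entries = []
    kernel = kernel.astype(np.float64)
    for read in reads:
        for off in range(read.shape[0] - w + 1):
            window = read[off:off + w].astype(np.float64)
            act = max(float((window * kernel).sum() + bias), 0.0)
            entries.append((act, window))
    entries.sort(key=lambda e: -e[0])
    n_top = max(1, int(np.ceil(top_fraction * len(entries))))
    counts4 = np.zeros((w, 4))
    counts5 = np.zeros((w, 5))
    for act, window in entries[:n_top]:
        counts4 += act * window[:, :4]
        counts5[:, [0, 2, 3]] += act * window[:, [0, 2, 3]]
        counts5[:, 4] += act * window[:, 4]
        counts5[:, 1] += act * (window[:, 1] - window[:, 4])
    return counts4, counts5


class TestKernelPfm:
    def test_planted_acg_kernel_concentrates_on_acg(self):
        model = plant_acg_kernel(build_model(CFG))
        reads = [encode_seq("TTACGTTTTTTT"), encode_seq("ACGTTTACGTTT"),
                 encode_seq("TTTTTTTTTTTT")]
        (pfm,) = kernel_pfm(model, reads, top_fraction=0.1, kernel_ids=[0])
        probs = pfm_probabilities(pfm)
        np.testing.assert_allclose(probs[0], [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(probs[1], [0, 1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(probs[2], [0, 0, 1, 0], atol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        model = build_model(CFG)
        reads = [rng.random((12, 5)).astype(np.float32) for _ in range(8)]
        kernels = model.network.layers[0]
        kernels.params["b"][:] = 1.0  # guarantee positive activations
        W = kernels.params["W"].reshape(3, 5, 4)
        for k in range(4):
            for frac in (1.0, 0.2):
                (pfm,) = kernel_pfm(model, reads, top_fraction=frac,
                                    kernel_ids=[k])
                c4, c5 = brute_force_pfm(reads, W[:, :, k],
                                         kernels.params["b"][k], frac)
                np.testing.assert_allclose(pfm.counts4, c4, atol=1e-9)
                np.testing.assert_allclose(pfm.counts5, c5, atol=1e-9)

    def test_counts5_rows_sum_to_counts4_rows(self, rng):
        model = build_model(CFG)
        model.network.layers[0].params["b"][:] = 1.0
        reads = [encode_seq("ACGTACGTACGT", ".M...U...M..")]
        pfms = kernel_pfm(model, reads, top_fraction=1.0)
        for pfm in pfms:
            np.testing.assert_allclose(pfm.counts4.sum(axis=1),
                                       pfm.counts5.sum(axis=1), atol=1e-5)

    def test_empty_reserved_errors(self):
        with pytest.raises(ValueError):
            kernel_pfm(build_model(CFG), [])


class TestMemeExport:
    def test_normalization_and_reparse(self, tmp_path, rng):
        model = plant_acg_kernel(build_model(CFG))
        reads = [encode_seq("TTACGTTTTTTT")]
        pfms = kernel_pfm(model, reads, top_fraction=1.0, kernel_ids=[0])
        path = tmp_path / "motifs.meme"
        write_meme(pfms, path)
        text = path.read_text()
        assert "MEME version 4" in text and "MOTIF kernel_0" in text
        # re-parse the probability block and compare to 6 decimals
        lines = text.splitlines()
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("letter-probability")) + 1
        parsed = np.array([[float(v) for v in lines[start + j].split()]
                           for j in range(3)])
        np.testing.assert_allclose(parsed, pfm_probabilities(pfms[0]), atol=1e-6)
        np.testing.assert_allclose(parsed.sum(axis=1), 1.0, atol=1e-5)

    def test_empty_list_valid_header(self, tmp_path):
        path = tmp_path / "motifs.meme"
        write_meme([], path)
        assert path.read_text().startswith("MEME version 4")

    def test_zero_row_errors_naming_kernel(self, tmp_path):
        from dismir.interpretation import PFM

        bad = PFM(kernel_id=3, width=2, counts4=np.zeros((2, 4)),
                  counts5=np.zeros((2, 5)), n_contributing=1)
        with pytest.raises(ValueError, match="3"):
            write_meme([bad], tmp_path / "x.meme")


class TestDeltaScores:
    REGION = GenomicRegion("chr1", 0, 60)

    @staticmethod
    def mean_meth_scorer(x):
        """Affine scorer: fraction of CpG cytosines that are methylated."""
        n_cpg = np.maximum((x[:, :-1, 1] * x[:, 1:, 2]).sum(axis=1), 1)
        return x[:, :, 4].sum(axis=1) / n_cpg

    def test_affine_scorer_deltas_additive(self):
        seq = ("ACG" * 8 + "T" * 36)[:60]  # wait: ensure known CpG count
        seq = "ACGT" * 15  # CpG at every 'CG': 15 per 60bp, 12 per window?
        ds = delta_scores(self.mean_meth_scorer, self.REGION, seq, L=16)
        assert ds.windows, "expected qualifying windows"
        for win in ds.windows:
            k = len(win.cpg_positions)
            np.testing.assert_allclose(win.delta_single, -1 / k, atol=1e-6)
            assert win.delta_all == pytest.approx(-1.0, abs=1e-6)
            assert win.delta_sum == pytest.approx(win.delta_all, abs=1e-6)

    def test_constant_scorer_all_zero(self):
        ds = delta_scores(lambda x: np.full(len(x), 0.7), self.REGION,
                          "ACGT" * 15, L=16)
        for win in ds.windows:
            assert win.delta_all == 0.0
            np.testing.assert_array_equal(win.delta_single, 0.0)

    def test_low_cpg_windows_skipped(self):
        # only 2 CpGs in the whole region -> no window qualifies
        seq = "ACGTTTTTTTTTACGTTTTT"
        ds = delta_scores(self.mean_meth_scorer, self.REGION, seq, L=16)
        assert ds.windows == []

    def test_baseline_is_fully_methylated(self):
        seen = {}

        def spy(x):
            seen["first"] = x[0].copy()
            return np.zeros(len(x))

        delta_scores(spy, self.REGION, "ACGT" * 15, L=16)
        first = seen["first"]
        np.testing.assert_array_equal(first[:, 4], first[:, 1] * (
            np.arange(16) < 15))  # all full CpGs methylated


class TestKernelActivatedReads:
    def test_top_count(self, rng):
        model = build_model(CFG)
        reads = rng.random((2000, 12, 5)).astype(np.float32)
        idx = kernel_activated_reads(model, 0, reads, top_fraction=0.005)
        assert len(idx) == 10

    def test_tie_warning_and_stable_order(self):
        model = plant_acg_kernel(build_model(CFG))
        reads = np.stack([encode_seq("TTTTTTTTTTTT")] * 50)
        with pytest.warns(UserWarning, match="degenerate"):
            idx = kernel_activated_reads(model, 0, reads, top_fraction=0.1)
        np.testing.assert_array_equal(idx, np.arange(5))

    def test_containment_of_planted_motif(self, rng):
        model = plant_acg_kernel(build_model(CFG))
        with_motif = [encode_seq("TTTTACGTTTTT") for _ in range(3)]
        without = [encode_seq("TTTTTTTTTTTT") for _ in range(97)]
        reads = np.stack(with_motif + without)
        idx = kernel_activated_reads(model, 0, reads, top_fraction=0.03)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_few_reads_warns_and_returns_one(self, rng):
        model = build_model(CFG)
        reads = rng.random((5, 12, 5)).astype(np.float32)
        with pytest.warns(UserWarning):
            idx = kernel_activated_reads(model, 0, reads, top_fraction=0.001)
        assert len(idx) == 1


class TestEffectSize:
    def test_complete_separation(self):
        assert mwu_effect_size([1, 2, 3], [4, 5, 6]) == 1.0

    def test_identical_multisets(self):
        assert mwu_effect_size([1, 2, 2, 5], [1, 2, 2, 5]) == 0.5

    def test_pair_enumeration(self):
        assert mwu_effect_size([1, 3], [2, 4]) == 0.75

    def test_complement_identity_ties_included(self, rng):
        for _ in range(100):
            x = rng.integers(0, 8, size=rng.integers(1, 12)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(1, 12)).astype(float)
            pairs = [(0.5 if a == b else float(b > a)) for a in x for b in y]
            assert mwu_effect_size(x, y) == pytest.approx(np.mean(pairs))
            assert mwu_effect_size(x, y) + mwu_effect_size(y, x) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mwu_effect_size([], [1.0])


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_df4_closed_form(self):
        # chi2 = -2(ln .5 + ln .5); survival (1 + chi2/2) e^{-chi2/2}
        chi2 = -2 * 2 * np.log(0.5)
        expected = (1 + chi2 / 2) * np.exp(-chi2 / 2)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_identity(self):
        assert fisher_combine([0.37]) == pytest.approx(0.37)

    def test_replication_strengthens_small_p(self):
        combined = [fisher_combine([0.1] * k) for k in range(1, 6)]
        assert combined == sorted(combined, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0])
        with pytest.raises(ValueError):
            fisher_combine([1.5])
        with pytest.warns(UserWarning):
            assert fisher_combine([1.5, 0.5], truncate=True) < 1.0


class TestQuadrantSummary:
    def test_haldane_corrected_or(self):
        pairs = [(0.9, 0.1)] * 10 + [(0.1, 0.9)] * 10
        flags = [True] * 10 + [False] * 10
        table, odds, p = quadrant_summary(pairs, flags)
        np.testing.assert_array_equal(table, [[10, 0], [0, 10]])
        assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))
        assert p < 1e-4

    def test_independent_flags_or_near_one(self, rng):
        n = 2000
        pairs = np.column_stack([rng.random(n), rng.random(n)])
        flags = rng.random(n) < 0.5
        _, odds, p = quadrant_summary(pairs, flags)
        assert 0.7 < odds < 1.4

    def test_degenerate_table_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            quadrant_summary([(0.9, 0.1)] * 5, [True] * 5)


def test_motif_match_correlation_recovers_exact_motif():
    from dismir.interpretation import PFM

    motif = "TACGTCAT"
    onehot = np.zeros((8, 4))
    for i, b in enumerate(motif):
        onehot[i, "ACGT".index(b)] = 1.0
    pfm = PFM(kernel_id=0, width=8, counts4=onehot * 3.0,
              counts5=np.zeros((8, 5)), n_contributing=3)
    assert motif_match_correlation(pfm, motif) == pytest.approx(1.0)
    # a uniform PFM correlates poorly
    flat = PFM(kernel_id=1, width=8, counts4=np.ones((8, 4)),
               counts5=np.zeros((8, 5)), n_contributing=1)
    assert motif_match_correlation(flat, motif) < 0.3
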