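"""Velocity search, peak location, dual-code quantification, crosstalk."""

import numpy as np
import pytest

from dropcode.demod import (CrosstalkMatrix, build_crosstalk_matrix,
                            decode_trace, locate_all_peaks, quantify_bead,
                            scan_velocity)
from dropcode.mls import OverlapCounts, overlap_counts


def place(bank, i, offset, b1=1.0, b2=1.0, baseline=0.0, length=None):
    """Synthesise a noiseless trace with one bead at grid velocity i."""
    length = length or bank.trace_length
    trace = np.full(length, baseline)
    m1, m2 = bank.masks1[i], bank.masks2[i]
    L = max(m1.size, m2.size)
    trace[offset:offset + m1.size] += b1 * bank.duty1 * m1
    trace[offset:offset + m2.size] += b2 * m2
    return trace


class TestScanVelocity:
    @pytest.mark.parametrize("i,offset", [(0, 10), (20, 100), (40, 150)])
    def test_exact_recovery_at_grid_velocity(self, small_bank, i, offset):
        trace = place(small_bank, i, offset)
        hit = scan_velocity(trace, small_bank)
        assert hit is not None
        _, v_c, x_c = hit
        assert v_c == pytest.approx(small_bank.velocity_grid[i])
        assert x_c == offset

    def test_off_grid_velocity_within_one_step(self, small_bank, codes):
        from dropcode.mls import render_mask
        grid = small_bank.velocity_grid
        step = grid[1] - grid[0]
        v_true = float(grid[13]) + 0.4 * step
        m1 = render_mask(codes[0], v_true, small_bank.exposure)
        m2 = render_mask(codes[1], v_true, small_bank.exposure)
        trace = np.zeros(small_bank.trace_length)
        trace[40:40 + m1.size] += 0.5 * m1
        trace[40:40 + m2.size] += m2
        hit = scan_velocity(trace, small_bank)
        assert hit is not None
        _, v_c, _ = hit
        assert abs(v_c - v_true) <= step

    def test_background_only_no_detection(self, small_bank):
        rng = np.random.default_rng(0)
        trace = 1.0 + rng.normal(0, 0.003, small_bank.trace_length)
        assert scan_velocity(trace, small_bank) is None

    def test_invalid_trace_rejected(self, small_bank):
        with pytest.raises(ValueError):
            scan_velocity(np.array([]), small_bank)
        with pytest.raises(ValueError):
            scan_velocity(np.full(300, np.nan), small_bank)


class TestLocatePeaks:
    def test_two_separated_beads(self, small_bank):
        i = 5
        L = int(small_bank.mask_lengths[i])
        trace = place(small_bank, i, 10) + place(small_bank, i, 10 + L + 40)
        psi = small_bank.correlation_matrix(trace)
        peaks = locate_all_peaks(psi[i], min_separation=L, threshold=1.0)
        assert sorted(peaks) == [10, 10 + L + 40]

    def test_single_bead_single_peak(self, small_bank):
        i = 5
        trace = place(small_bank, i, 30)
        psi = small_bank.correlation_matrix(trace)
        peaks = locate_all_peaks(psi[i],
                                 int(small_bank.mask_lengths[i]), 1.0)
        assert peaks == [30]

    def test_all_zero_vector_empty(self):
        assert locate_all_peaks(np.zeros(100), 10, 0.5) == []


class TestCrosstalkMatrix:
    def test_no_overlap_is_diagonal(self):
        M = build_crosstalk_matrix(OverlapCounts(32, 32, 0), bit_extent=2.0,
                                   duty1=0.5)
        assert M.matrix[0, 1] == 0 and M.matrix[1, 0] == 0
        b1, b2 = M.invert(32.0, 64.0)  # p_k = n_k * extent * d_k * b_k
        assert b1 == pytest.approx(1.0)
        assert b2 == pytest.approx(1.0)

    def test_identical_codes_singular(self):
        with pytest.raises(ValueError, match="singular"):
            build_crosstalk_matrix(OverlapCounts(32, 32, 32), 1.0)

    def test_forward_of_unit_intensities(self):
        # n1 = n2 = 32, o = 16, unit extent, duty 1: p1 = p2 = 32 + 16
        M = build_crosstalk_matrix(OverlapCounts(32, 32, 16), 1.0)
        assert M.forward(1.0, 1.0) == (pytest.approx(48.0),
                                       pytest.approx(48.0))
        b = M.invert(48.0, 48.0)
        assert b == (pytest.approx(1.0), pytest.approx(1.0))

    def test_inverse_forward_identity(self):
        M = build_crosstalk_matrix(OverlapCounts(32, 32, 16), 3.7,
                                   duty1=0.5)
        for b1, b2 in [(0.3, 1.9), (2.0, 0.1)]:
            assert M.invert(*M.forward(b1, b2)) == (
                pytest.approx(b1, abs=1e-9), pytest.approx(b2, abs=1e-9))

    def test_from_masks_matches_rendered_pure_traces(self, small_bank):
        # forward map columns = raw peaks of rendered pure-B1 / pure-B2
        # traces, measured by brute-force correlation
        i = 20
        m1, m2 = small_bank.masks1[i], small_bank.masks2[i]
        M = CrosstalkMatrix.from_masks(m1, m2, duty1=small_bank.duty1)
        pure1 = place(small_bank, i, 50, b1=1.0, b2=0.0)
        pure2 = place(small_bank, i, 50, b1=0.0, b2=1.0)
        seg1 = pure1[50:50 + max(m1.size, m2.size)]
        seg2 = pure2[50:50 + max(m1.size, m2.size)]
        assert M.matrix[0, 0] == pytest.approx(seg1[:m1.size] @ m1)
        assert M.matrix[1, 0] == pytest.approx(seg1[:m2.size] @ m2)
        assert M.matrix[0, 1] == pytest.approx(seg2[:m1.size] @ m1)
        assert M.matrix[1, 1] == pytest.approx(seg2[:m2.size] @ m2)

    def test_from_counts_equals_from_masks_integer_extent(self, codes):
        from dropcode.mls import render_mask
        m1 = render_mask(codes[0], 126.0, 1.0)  # exactly 2 px per bit
        m2 = render_mask(codes[1], 126.0, 1.0)
        Ma = CrosstalkMatrix.from_masks(m1, m2, duty1=0.5)
        Mb = CrosstalkMatrix.from_counts(overlap_counts(*codes), 2.0,
                                         duty1=0.5)
        assert np.allclose(Ma.matrix, Mb.matrix)


class TestQuantifyBead:
    def test_known_mixture_recovered(self, small_bank):
        i = 12
        trace = place(small_bank, i, 80, b1=2.0, b2=3.0, baseline=1.0)
        xt = CrosstalkMatrix.from_masks(small_bank.masks1[i],
                                        small_bank.masks2[i],
                                        duty1=small_bank.duty1)
        det = quantify_bead(trace, small_bank, i, 80, xt)
        assert det.b1 == pytest.approx(2.0, abs=1e-6)
        assert det.b2 == pytest.approx(3.0, abs=1e-6)
        assert det.flags == []

    def test_baseline_only_zero_intensities(self, small_bank):
        i = 12
        trace = np.ones(small_bank.trace_length)
        xt = CrosstalkMatrix.from_masks(small_bank.masks1[i],
                                        small_bank.masks2[i],
                                        duty1=small_bank.duty1)
        det = quantify_bead(trace, small_bank, i, 80, xt)
        assert det.b1 == pytest.approx(0.0, abs=1e-9)
        assert det.b2 == pytest.approx(0.0, abs=1e-9)

    def test_edge_position_rejected(self, small_bank):
        i = 12
        xt = CrosstalkMatrix.from_masks(small_bank.masks1[i],
                                        small_bank.masks2[i])
        with pytest.raises(ValueError, match="past the trace"):
            quantify_bead(np.ones(small_bank.trace_length), small_bank, i,
                          290, xt)


class TestDecodeTrace:
    def test_localization_within_bit_extent(self, small_bank):
        for i, offset in [(3, 25), (25, 120), (38, 60)]:
            trace = 1.0 + place(small_bank, i, offset, b1=0.5, b2=0.8)
            dets = decode_trace(trace, small_bank)
            assert len(dets) == 1
            assert abs(dets[0].x_c - offset) <= small_bank.bit_extent[i]

    def test_amplitude_linearity(self, small_bank):
        # decoded (b1, b2) scale with rendered amplitudes: slope 1,
        # intercept 0, R^2 > 0.999 on a noiseless sweep
        i = 18
        amps = np.linspace(0.2, 2.0, 10)
        got1, got2 = [], []
        for a in amps:
            trace = 1.0 + place(small_bank, i, 60, b1=a, b2=0.7 * a)
            det = decode_trace(trace, small_bank)[0]
            got1.append(det.b1)
            got2.append(det.b2)
        for got, true in [(np.array(got1), amps),
                          (np.array(got2), 0.7 * amps)]:
            slope, intercept = np.polyfit(true, got, 1)
            r = np.corrcoef(true, got)[0, 1]
            assert slope == pytest.approx(1.0, abs=0.01)
            assert intercept == pytest.approx(0.0, abs=0.01)
            assert r**2 > 0.999

    def test_two_beads_both_decoded(self, small_bank):
        i = 10
        L = int(small_bank.mask_lengths[i])
        trace = (1.0 + place(small_bank, i, 15, b1=1.0, b2=0.5)
                 + place(small_bank, i, 15 + L + 30, b1=0.4, b2=1.2))
        dets = decode_trace(trace, small_bank)
        assert len(dets) == 2
        assert abs(dets[0].x_c - 15) <= small_bank.bit_extent[i]
        assert abs(dets[1].x_c - (15 + L + 30)) <= small_bank.bit_extent[i]

    def test_truncated_edge_bead_not_quantified(self, small_bank):
        # a streak whose mask support would overhang the trace end is
        # dropped by the edge policy
        i = 40
        L = int(small_bank.mask_lengths[i])
        m1, m2 = small_bank.masks1[i], small_bank.masks2[i]
        trace = np.ones(small_bank.trace_length)
        start = small_bank.trace_length - L + 30  # 30 px hang off the end
        keep = small_bank.trace_length - start
        trace[start:] += (0.5 * small_bank.duty1 * m1[:keep] + m2[:keep])
        dets = decode_trace(trace, small_bank)
        assert all(d.x_c + int(small_bank.mask_lengths[
            small_bank.index_of(d.v_c)]) <= trace.size for d in dets)
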