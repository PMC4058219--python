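"""Probability maps, mask selection, and the energy diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cspress import phantom
from cspress.sampling import (
    ProbabilityMap,
    SamplingMask,
    apply_window,
    build_ipdf,
    build_power_pdf,
    central_rows,
    correlation_2d,
    epr,
    hamming2d,
    lowres_mask,
    pdf_random_mask,
    rowwise_correlation,
    select_mask,
    vd_pdf,
)


class TestProbabilityMap:
    def test_normalizes_to_unit_mass(self, rng):
        m = ProbabilityMap(rng.random((8, 8)))
        assert m.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="negative"):
            ProbabilityMap(np.array([[1.0, -0.1], [0.5, 0.5]]))


class TestBuildIpdf:
    def test_constant_magnitude_reference_gives_uniform_map(self):
        m = build_ipdf([np.full((4, 4), 2.0 + 0j)])
        assert np.allclose(m.values, 1 / 16)

    def test_duplicate_references_change_nothing(self, ref_kspaces):
        one = build_ipdf(ref_kspaces[:1])
        two = build_ipdf(ref_kspaces[:1] * 2)
        assert np.allclose(one.values, two.values)

    def test_hand_worked_4x4_sum(self):
        a = np.arange(16, dtype=float).reshape(4, 4)
        b = np.ones((4, 4))
        m = build_ipdf([a.astype(complex), (-b).astype(complex)])
        expected = (a + b) / (a + b).sum()
        assert np.allclose(m.values, expected)

    def test_line_mode_is_constant_along_rows(self, ref_kspaces):
        m = build_ipdf(ref_kspaces, mode="line")
        assert np.allclose(m.values, m.values[:, :1])

    def test_errors(self, ref_kspaces):
        with pytest.raises(ValueError, match="at least one"):
            build_ipdf([])
        with pytest.raises(ValueError, match="shapes"):
            build_ipdf([ref_kspaces[0], np.ones((4, 4))])


class TestHamming2d:
    def test_corner_value_is_hamming_endpoint_squared(self):
        w = hamming2d(128, 128)
        assert w[0, 0] == pytest.approx(0.08 * 0.08)

    def test_peak_is_one_at_dc_bin(self):
        w = hamming2d(128, 128)
        assert w[64, 64] == pytest.approx(1.0)
        assert w.max() == pytest.approx(1.0)

    def test_matches_brute_force_formula_at_every_index(self):
        N = 128
        w = hamming2d(N, N)
        for m in range(0, N, 7):
            for n in range(0, N, 11):
                expect = (0.54 - 0.46 * np.cos(2 * np.pi * m / N)) * (
                    0.54 - 0.46 * np.cos(2 * np.pi * n / N)
                )
                assert w[m, n] == pytest.approx(expect, rel=1e-12)

    def test_symmetric_about_dc_and_strictly_positive(self):
        w = hamming2d(64, 64)
        assert w.min() > 0
        assert np.allclose(w, w[(64 - np.arange(64)) % 64][:, (64 - np.arange(64)) % 64])


class TestApplyWindow:
    def test_alpha_zero_returns_ipdf(self, ref_kspaces):
        ipdf = build_ipdf(ref_kspaces)
        assert np.allclose(apply_window(ipdf, 0.0).values, ipdf.values)

    @pytest.mark.parametrize("alpha", [0.8, 1.4])
    def test_uniform_ipdf_yields_window_power_shape(self, alpha):
        uni = ProbabilityMap(np.ones((32, 32)))
        w = hamming2d(32, 32) ** alpha
        out = apply_window(uni, alpha)
        assert np.allclose(out.values, w / w.sum())

    def test_divide_variant_boosts_periphery(self):
        uni = ProbabilityMap(np.ones((32, 32)))
        out = apply_window(uni, 1.0, operator="divide")
        assert out.values[0, 0] == out.values.max()


class TestSelectMask:
    def test_full_budget_selects_everything(self, ref_kspaces, test_kspace):
        wpdf = apply_window(build_ipdf(ref_kspaces), 0.8)
        m = select_mask(wpdf, 128 * 128, "point", 4)
        assert m.n_points == 128 * 128
        assert epr(m, test_kspace) == pytest.approx(1.0)

    def test_single_point_is_argmax(self, rng):
        wpdf = ProbabilityMap(rng.random((8, 8)))
        m = select_mask(wpdf, 1, "point", center_rows=0)
        assert m.values[np.unravel_index(np.argmax(wpdf.values), (8, 8))]
        assert m.n_points == 1

    def test_matches_full_sort_topk_oracle_with_tie_order(self, rng):
        for _ in range(100):
            vals = rng.integers(0, 5, size=(8, 8)).astype(float)  # many ties
            wpdf = ProbabilityMap(vals + 1e-12)
            k = int(rng.integers(1, 64))
            m = select_mask(wpdf, k, "point", center_rows=0)
            order = sorted(
                ((r, c) for r in range(8) for c in range(8)),
                key=lambda rc: (-wpdf.values[rc], rc[0], rc[1]),
            )
            oracle = np.zeros((8, 8), dtype=bool)
            for r, c in order[:k]:
                oracle[r, c] = True
            assert np.array_equal(m.values, oracle)

    def test_masks_nested_in_budget(self, ref_kspaces):
        wpdf = apply_window(build_ipdf(ref_kspaces), 0.8)
        prev = None
        for n in (1000, 4000, 8000, 12000):
            m = select_mask(wpdf, n, "point", 4).values
            if prev is not None:
                assert np.all(prev <= m)
            prev = m

    def test_center_rows_always_on_and_counted(self, ref_kspaces):
        wpdf = apply_window(build_ipdf(ref_kspaces), 0.8)
        m = select_mask(wpdf, 600, "point", center_rows=4)
        assert m.values[central_rows(128, 4)].all()
        assert m.n_points == 600
        with pytest.raises(ValueError, match="central rows"):
            select_mask(wpdf, 100, "point", center_rows=4)

    def test_line_mode_selects_whole_rows(self, ref_kspaces):
        m = select_mask(build_ipdf(ref_kspaces, "line"), 16, "line", 4)
        rows = m.values.any(axis=1)
        assert rows.sum() == 16 and m.values[rows].all()
        assert m.n_points == 16 * 128


class TestVdPdf:
    def test_center_is_maximal(self):
        m = vd_pdf(64, 64, 10.0)
        assert m.values[32, 32] == m.values.max()

    def test_p_zero_is_uniform(self):
        assert np.allclose(vd_pdf(16, 16, 0.0).values, 1 / 256)

    def test_matches_brute_force_formula_at_every_index(self):
        N, p = 128, 10.0
        m = vd_pdf(N, N, p)
        rows = np.arange(N) - N // 2
        rmax = np.hypot(rows.min(), rows.min())
        raw = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                r = np.hypot(i - N // 2, j - N // 2) / rmax
                raw[i, j] = max(1.0 - r, 0.0) ** p
        assert np.allclose(m.values, raw / raw.sum())


class TestPdfRandomMask:
    def test_exact_count_and_determinism(self):
        pdf = vd_pdf(16, 16, 5.0)
        a = pdf_random_mask(pdf, 60, seed=9)
        b = pdf_random_mask(pdf, 60, seed=9)
        assert a.n_points == 60
        assert np.array_equal(a.values, b.values)

    def test_full_budget_is_all_ones_regardless_of_seed(self):
        pdf = vd_pdf(8, 8, 2.0)
        # p = 2 leaves one exactly-zero corner cell; a uniform map covers all
        m = pdf_random_mask(ProbabilityMap(np.ones((8, 8))), 64, seed=3)
        assert m.values.all()

    def test_uniform_pdf_gives_uniform_inclusion_frequencies(self):
        pdf = ProbabilityMap(np.ones((8, 8)))
        n_draw, n_rep = 16, 10_000
        counts = np.zeros((8, 8))
        for s in range(n_rep):
            counts += pdf_random_mask(pdf, n_draw, seed=s).values
        p = n_draw / 64
        sigma = np.sqrt(p * (1 - p) / n_rep)
        assert np.all(np.abs(counts / n_rep - p) < 3.5 * sigma + 1e-12)

    def test_too_few_nonzero_entries_rejected(self):
        sparse = np.zeros((8, 8))
        sparse[0, :4] = 1.0
        with pytest.raises(ValueError, match="nonzero"):
            pdf_random_mask(ProbabilityMap(sparse), 10, seed=0)

    def test_forced_center_rows_present(self):
        pdf = vd_pdf(16, 16, 5.0)
        m = pdf_random_mask(pdf, 80, seed=2, center_rows=2)
        assert m.values[central_rows(16, 2)].all()
        assert m.n_points == 80


class TestLowresMask:
    def test_extremes(self):
        assert lowres_mask(16, 16, 256).values.all()
        m = lowres_mask(16, 16, 1)
        assert m.n_points == 1 and m.values[8, 8]

    def test_matches_radius_sort_oracle(self):
        m = lowres_mask(16, 16, 64)
        idx = np.arange(16) - 8
        R = np.hypot(*np.meshgrid(idx, idx, indexing="ij"))
        order = sorted(
            ((r, c) for r in range(16) for c in range(16)),
            key=lambda rc: (R[rc], rc[0], rc[1]),
        )
        oracle = np.zeros((16, 16), dtype=bool)
        for r, c in order[:64]:
            oracle[r, c] = True
        assert np.array_equal(m.values, oracle)


class TestEpr:
    def test_full_and_empty_masks(self, test_kspace):
        ones = SamplingMask(np.ones((128, 128), dtype=int))
        assert epr(ones, test_kspace) == pytest.approx(1.0)
        none = SamplingMask(np.zeros((128, 128), dtype=int))
        assert epr(none, test_kspace) == 0.0

    def test_hand_computed_ratio(self):
        k = np.zeros((4, 4), dtype=complex)
        k[0, 0], k[1, 1], k[2, 2], k[3, 3], k[0, 3] = 1, 2, 3, 4, 2j
        mask = np.zeros((4, 4), dtype=int)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = mask[0, 3] = mask[0, 1] = 1
        # energy: sampled 1 + 4 + 9 + 4 + 0 = 18; total 1+4+9+16+4 = 34
        assert epr(SamplingMask(mask), k) == pytest.approx(18 / 34)

    def test_zero_kspace_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            epr(SamplingMask(np.ones((4, 4), dtype=int)), np.zeros((4, 4)))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nested_masks_have_nondecreasing_epr(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        wpdf = ProbabilityMap(rng.random((8, 8)) + 1e-9)
        values = [
            epr(select_mask(wpdf, n, "point", 0), k) for n in (4, 16, 40, 64)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))


class TestCorrelations:
    def test_map_proportional_to_magnitude_is_perfectly_correlated(self, rng):
        k = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        m = ProbabilityMap(np.abs(k))
        assert correlation_2d(m, k) == pytest.approx(1.0)

    def test_constant_map_is_undefined(self, rng):
        k = rng.standard_normal((8, 8))
        assert np.isnan(correlation_2d(ProbabilityMap(np.ones((8, 8))), k))

    def test_rowwise_flags_zero_variance_rows(self, rng):
        k = rng.standard_normal((4, 4))
        vals = rng.random((4, 4))
        vals[2] = 0.25
        out = rowwise_correlation(ProbabilityMap(vals), k)
        assert np.isnan(out[2]) and np.isfinite(np.delete(out, 2)).all()


def test_power_pdf_uses_squared_magnitude(ref_kspaces):
    m = build_power_pdf(ref_kspaces[:2])
    acc = np.abs(ref_kspaces[0]) ** 2 + np.abs(ref_kspaces[1]) ** 2
    assert np.allclose(m.values, acc / acc.sum())
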