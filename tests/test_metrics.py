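"""Metric quartet against brute-force oracles, closed forms, and invariances."""

import numpy as np
import pytest

from treedenoise.cloud import PointCloud
from treedenoise.metrics import (
    build_correspondence,
    compute_report,
    evaluate,
    hausdorff_oneway,
    hausdorff_symmetric,
    pc_mse,
    pc_snr,
    ssim3d,
)

from conftest import brute_force_hausdorff


@pytest.fixture
def pair(rng):
    ref = PointCloud(rng.uniform(-1, 1, size=(200, 3)))
    est = PointCloud(ref.points + rng.normal(scale=0.02, size=(200, 3)))
    return ref, est


class TestCorrespondence:
    def test_paired_identity(self, pair):
        ref, est = pair
        corr = build_correspondence(ref, est, "paired")
        np.testing.assert_array_equal(corr.mapping, np.arange(ref.n))

    def test_paired_requires_equal_sizes(self, pair, rng):
        ref, _ = pair
        small = PointCloud(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            build_correspondence(ref, small, "paired")

    def test_nearest_on_identical_is_identity(self, pair):
        ref, _ = pair
        corr = build_correspondence(ref, ref, "nearest")
        np.testing.assert_array_equal(corr.mapping, np.arange(ref.n))

    def test_nearest_matches_exhaustive(self, rng):
        ref = PointCloud(rng.uniform(size=(80, 3)))
        est = PointCloud(rng.uniform(size=(60, 3)))
        corr = build_correspondence(ref, est, "nearest")
        for i in range(est.n):
            d2 = np.sum((ref.points - est.points[i]) ** 2, axis=1)
            assert d2[corr.mapping[i]] == pytest.approx(d2.min())


class TestPcMse:
    def test_identical_zero(self, pair):
        ref, _ = pair
        corr = build_correspondence(ref, ref, "paired")
        assert pc_mse(ref, ref, corr) == 0.0

    def test_unit_offset(self, pair):
        ref, _ = pair
        est = PointCloud(ref.points + np.array([1.0, 0, 0]))
        corr = build_correspondence(ref, est, "paired")
        assert pc_mse(ref, est, corr) == pytest.approx(1.0)

    def test_nearest_mode_matches_brute_force(self, rng):
        ref = PointCloud(rng.uniform(size=(50, 3)))
        est = PointCloud(rng.uniform(size=(40, 3)))
        corr = build_correspondence(ref, est, "nearest")
        brute = np.mean([
            min(np.sum((r - e) ** 2) for r in ref.points) for e in est.points
        ])
        assert pc_mse(ref, est, corr) == pytest.approx(brute, abs=1e-12)

    def test_common_permutation_invariance(self, pair, rng):
        ref, est = pair
        corr = build_correspondence(ref, est, "paired")
        base = pc_mse(ref, est, corr)
        perm = rng.permutation(ref.n)
        ref_p, est_p = PointCloud(ref.points[perm]), PointCloud(est.points[perm])
        corr_p = build_correspondence(ref_p, est_p, "paired")
        assert pc_mse(ref_p, est_p, corr_p) == pytest.approx(base, rel=1e-12)


class TestPcSnr:
    def test_perfect_estimate_infinite(self, pair):
        ref, _ = pair
        corr = build_correspondence(ref, ref, "paired")
        assert pc_snr(ref, ref, corr) == float("inf")

    def test_scaling_residuals_by_ten_drops_20db(self, pair):
        ref, est = pair
        resid = est.points - ref.points
        est10 = PointCloud(ref.points + 10.0 * resid)
        corr = build_correspondence(ref, est, "paired")
        a = pc_snr(ref, est, corr)
        b = pc_snr(ref, est10, build_correspondence(ref, est10, "paired"))
        assert a - b == pytest.approx(20.0, abs=1e-9)

    def test_closed_form_20db(self):
        # Ps = 100 * Pn -> exactly 20 dB
        ref = PointCloud(np.array([[10.0, 0, 0], [0, 10.0, 0]]))  # Ps = 100
        est = PointCloud(ref.points + np.array([[1.0, 0, 0], [1.0, 0, 0]]))  # Pn = 1
        corr = build_correspondence(ref, est, "paired")
        assert pc_snr(ref, est, corr) == pytest.approx(20.0)

    def test_monotone_in_mse(self, pair):
        ref, est = pair
        resid = est.points - ref.points
        corr = build_correspondence(ref, est, "paired")
        snrs = []
        for s in (0.5, 1.0, 2.0, 4.0):
            e = PointCloud(ref.points + s * resid)
            snrs.append(pc_snr(ref, e, corr))
        assert all(a > b for a, b in zip(snrs, snrs[1:]))


class TestHausdorff:
    def test_identical_zero(self, pair):
        ref, _ = pair
        assert hausdorff_oneway(ref, ref) == 0.0

    def test_345_triangle(self):
        A = PointCloud(np.array([[0.0, 0, 0]]))
        B = PointCloud(np.array([[3.0, 4.0, 0]]))
        assert hausdorff_oneway(A, B) == pytest.approx(5.0)

    def test_matches_double_loop(self, rng):
        A = PointCloud(rng.uniform(size=(200, 3)))
        B = PointCloud(rng.uniform(size=(200, 3)))
        assert hausdorff_oneway(A, B) == pytest.approx(
            brute_force_hausdorff(A.points, B.points), abs=1e-12
        )

    def test_symmetric_bounds_oneway(self, rng):
        A = PointCloud(rng.uniform(size=(50, 3)))
        B = PointCloud(rng.uniform(size=(60, 3)))
        s = hausdorff_symmetric(A, B)
        assert s >= hausdorff_oneway(A, B) - 1e-15
        assert s >= hausdorff_oneway(B, A) - 1e-15

    def test_zero_iff_subset(self, rng):
        B = PointCloud(rng.uniform(size=(40, 3)))
        A = B.take(np.arange(0, 40, 2))
        assert hausdorff_oneway(A, B) == 0.0


def _ssim_reference(ref, est, mapping, k, K1, K2, L):
    """Independent step-by-step recomputation of the neighborhood SSIM."""
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    vals = []
    for i in range(est.n):
        def signal(pts, q):
            d2 = np.sum((pts - q) ** 2, axis=1)
            nb = pts[np.argsort(d2, kind="stable")[:k]]
            c = nb.mean(axis=0)
            return np.sort(np.linalg.norm(nb - c, axis=1))
        x = signal(ref.points, ref.points[mapping[i]])
        y = signal(est.points, est.points[i])
        mx, my, vx, vy = x.mean(), y.mean(), x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        vals.append(((2 * mx * my + C1) * (2 * cxy + C2))
                    / ((mx**2 + my**2 + C1) * (vx + vy + C2)))
    return float(np.mean(vals))


class TestSsim3d:
    def test_self_similarity_is_one(self, pair):
        ref, _ = pair
        corr = build_correspondence(ref, ref, "paired")
        assert ssim3d(ref, ref, corr) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_translation_invariance(self, pair):
        ref, _ = pair
        est = PointCloud(ref.points + np.array([10.0, -5.0, 2.0]))
        corr = build_correspondence(ref, est, "paired")
        assert ssim3d(ref, est, corr) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_recomputation(self, pair):
        ref, est = pair
        corr = build_correspondence(ref, est, "paired")
        k, K1, K2 = 8, 0.01, 0.03
        L = float(np.linalg.norm(ref.points.max(0) - ref.points.min(0)))
        mine = ssim3d(ref, est, corr, k_ssim=k, K1=K1, K2=K2, L_range=L)
        theirs = _ssim_reference(ref, est, corr.mapping, k, K1, K2, L)
        assert mine == pytest.approx(theirs, abs=1e-9)

    def test_k_too_large_rejected(self, pair):
        ref, est = pair
        corr = build_correspondence(ref, est, "paired")
        with pytest.raises(ValueError):
            ssim3d(ref, est, corr, k_ssim=ref.n)


class TestEvaluate:
    def test_perfect_denoised_report(self, pair):
        ref, est = pair
        rep_noisy, rep_den = evaluate(ref, est, ref)
        assert rep_den.mse == 0.0
        assert rep_den.hausdorff == 0.0
        assert rep_den.ssim == pytest.approx(1.0, abs=1e-9)
        assert rep_noisy.mse > 0

    def test_settings_recorded(self, pair):
        ref, est = pair
        _, rep = evaluate(ref, est, est, mode="paired", k_ssim=8)
        assert rep.params["correspondence"] == "paired"
        assert rep.params["k_ssim"] == 8
        assert rep.params["frame"] == "raw"

    def test_aggregation_matches_recomputation(self, rng):
        # mirrors batch evaluation: mean/std over per-cloud metrics
        mses = []
        for i in range(10):
            ref = PointCloud(rng.uniform(size=(60, 3)))
            est = PointCloud(ref.points + rng.normal(scale=0.05, size=(60, 3)))
            rep = compute_report(ref, est, k_ssim=8)
            mses.append(rep.mse)
        agg_mean, agg_std = float(np.mean(mses)), float(np.std(mses))
        assert agg_mean == pytest.approx(np.sum(mses) / 10, rel=1e-12)
        assert agg_std == pytest.approx(np.sqrt(np.mean((np.array(mses) - agg_mean) ** 2)))

    def test_csv_footer_matches_recomputation(self, rng, tmp_path):
        from treedenoise.metrics import reports_to_csv
        reports = []
        for i in range(5):
            ref = PointCloud(rng.uniform(size=(60, 3)))
            est = PointCloud(ref.points + rng.normal(scale=0.05, size=(60, 3)))
            reports.append(compute_report(ref, est, k_ssim=8))
        path = tmp_path / "batch.csv"
        reports_to_csv(reports, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 5 + 2
        mean_row = [float(v) for v in lines[-2].split(",")[1:]]
        assert mean_row[0] == pytest.approx(np.mean([r.mse for r in reports]))

    def test_frame_mismatch_rejected(self, pair, rng):
        from treedenoise.cloud import normalize
        ref, est = pair
        with pytest.raises(ValueError, match="frame"):
            evaluate(ref, est, normalize(est))
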