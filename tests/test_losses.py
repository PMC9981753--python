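"""Loss terms against closed forms, hand enumerations, and brute-force oracles."""

import numpy as np
import pytest

from loiseg.losses import (
    EPS,
    LossBreakdown,
    auxnet_fit_loss,
    boundary_consistency_loss,
    bce_with_logits,
    edge_suppression_loss,
    lpn_loss,
    pseudo_boundary_target,
    render_lpn_target,
    soft_edge_map,
    supervised_segmentation_loss,
    weak_segmentation_loss,
)
from loiseg.network import CellModel, ModelConfig
from loiseg.nn import Tensor


def _logit(p):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return np.log(p / (1 - p)).astype(np.float32)


def _frames(arrs):
    return Tensor(np.stack(arrs).astype(np.float32)[:, None])


# ---------------------------------------------------------------------------
# LPN loss
# ---------------------------------------------------------------------------

class TestLpnLoss:
    def test_optimum_prediction_is_zero(self):
        """The loss minimum (1 at positive cells, 0 elsewhere, exact offsets)."""
        lois = np.array([[9.0, 17.0]])
        heat, off, pos = render_lpn_target(lois, (8, 8), stride=4, sigma=3.0)
        hard = pos.astype(np.float32)
        loss = lpn_loss(
            Tensor(np.where(hard > 0, 50.0, -50.0).astype(np.float32)[None, None]),
            Tensor(off[None]), lois, stride=4, sigma=3.0,
        )
        assert float(loss.data) < 1e-6

    def test_soft_target_prediction_small_residual(self):
        """Predicting the rendered Gaussian leaves only the focal tail epsilon."""
        lois = np.array([[9.0, 17.0]])
        heat, off, pos = render_lpn_target(lois, (8, 8), stride=4, sigma=3.0)
        loss = lpn_loss(
            Tensor(_logit(heat)[None, None]), Tensor(off[None]),
            lois, stride=4, sigma=3.0,
        )
        assert float(loss.data) < 0.1

    def test_empty_image_zero_scores(self):
        score_logits = Tensor(np.full((1, 1, 8, 8), -50.0, dtype=np.float32))
        offsets = Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32))
        loss = lpn_loss(score_logits, offsets, np.zeros((0, 2)), stride=4, sigma=3.0)
        assert float(loss.data) < 1e-6

    def test_hand_evaluation_on_8x8(self):
        """Independent scalar evaluation of the focal + L1 formula."""
        rng = np.random.default_rng(0)
        lois = np.array([[13.0, 22.5]])
        p = rng.uniform(0.05, 0.95, (8, 8)).astype(np.float32)
        off_pred = rng.normal(0, 1, (2, 8, 8)).astype(np.float32)
        loss = lpn_loss(
            Tensor(_logit(p)[None, None]), Tensor(off_pred[None]),
            lois, stride=4, sigma=3.0,
        )
        # reference, written out longhand
        heat = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                heat[i, j] = np.exp(
                    -((4 * i - 13.0) ** 2 + (4 * j - 22.5) ** 2) / (2 * 9.0)
                )
        ci, cj = int(13.0 // 4), int(22.5 // 4)
        heat[ci, cj] = 1.0
        ref = 0.0
        for i in range(8):
            for j in range(8):
                pc = np.clip(p[i, j], EPS, 1 - EPS)
                if (i, j) == (ci, cj):
                    ref += (1 - pc) ** 2 * -np.log(pc)
                else:
                    ref += (1 - heat[i, j]) ** 4 * pc**2 * -np.log(1 - pc)
        ref += (
            abs(off_pred[0, ci, cj] - (13.0 - 4 * ci))
            + abs(off_pred[1, ci, cj] - (22.5 - 4 * cj))
        ) / 2.0
        assert float(loss.data) == pytest.approx(ref, rel=1e-4)

    def test_target_rendering_max_of_gaussians(self):
        lois = np.array([[4.0, 4.0], [4.0, 12.0]])
        heat, _, pos = render_lpn_target(lois, (4, 4), stride=4, sigma=2.0)
        assert heat[1, 1] == 1.0 and heat[1, 3] == 1.0
        # between the two peaks the target is the max of both Gaussians
        expected = max(
            np.exp(-((4 - 4) ** 2 + (8 - 4) ** 2) / 8.0),
            np.exp(-((4 - 4) ** 2 + (8 - 12) ** 2) / 8.0),
        )
        assert heat[1, 2] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# supervised segmentation loss
# ---------------------------------------------------------------------------

class TestSupervisedLoss:
    def test_perfect_match_near_zero(self):
        gt = np.zeros((16, 16), dtype=np.float32)
        gt[4:12, 4:12] = 1.0
        logits = Tensor(np.where(gt > 0, 30.0, -30.0).astype(np.float32)[None, None])
        loss = supervised_segmentation_loss(logits, np.array([[0, 0]]), [gt])
        assert float(loss.data) < 1e-6

    def test_half_everywhere_is_ln2(self):
        gt = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(np.float32)
        logits = Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32))
        loss = supervised_segmentation_loss(logits, np.array([[0, 0]]), [gt])
        assert float(loss.data) == pytest.approx(np.log(2), rel=1e-5)

    def test_matches_pixel_sum_oracle(self):
        rng = np.random.default_rng(2)
        gt = (rng.random((24, 24)) > 0.6).astype(np.float32)
        p = rng.uniform(0.01, 0.99, (1, 1, 16, 16)).astype(np.float32)
        origin = np.array([[3, 5]])
        loss = supervised_segmentation_loss(Tensor(_logit(p)), origin, [gt])
        ref = 0.0
        for r in range(16):
            for c in range(16):
                y = gt[3 + r, 5 + c]
                ref += -(y * np.log(p[0, 0, r, c]) + (1 - y) * np.log(1 - p[0, 0, r, c]))
        assert float(loss.data) == pytest.approx(ref / 256, rel=1e-3)

    def test_unmatched_prediction_errors(self):
        logits = Tensor(np.zeros((2, 1, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="matched"):
            supervised_segmentation_loss(
                logits, np.zeros((2, 2), int), [np.ones((8, 8), np.float32)]
            )


# ---------------------------------------------------------------------------
# weak segmentation loss
# ---------------------------------------------------------------------------

class TestWeakLoss:
    def test_exact_tiling_near_zero(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:14] = True
        a = np.zeros((16, 16), dtype=np.float32)
        a[2:8, 2:8] = 1.0
        b = np.zeros((16, 16), dtype=np.float32)
        b[2:8, 8:14] = 1.0
        consistency, overlap = weak_segmentation_loss(_frames([a, b]), mask)
        assert float(consistency.data) < 1e-4
        assert float(overlap.data) < 1e-6

    def test_full_overlap_extreme_is_one(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:7, 3:7] = True
        a = mask.astype(np.float32)
        consistency, overlap = weak_segmentation_loss(_frames([a, a.copy()]), mask)
        assert float(overlap.data) == pytest.approx(1.0, rel=1e-4)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        mask = rng.random((32, 32)) > 0.5
        frames = rng.uniform(0, 1, (3, 32, 32)).astype(np.float32)
        consistency, overlap = weak_segmentation_loss(_frames(list(frames)), mask)
        # brute force, double loops
        pc = np.clip(frames, 0, 1 - EPS)
        cons_ref, q_total, pair_total = 0.0, 0.0, 0.0
        for x in range(32):
            for y in range(32):
                q = 1.0 - np.prod(1.0 - pc[:, x, y])
                qc = np.clip(q, EPS, 1 - EPS)
                m = 1.0 if mask[x, y] else 0.0
                cons_ref += -(m * np.log(qc) + (1 - m) * np.log(1 - qc))
                q_total += q
                for j in range(3):
                    for k in range(j + 1, 3):
                        pair_total += pc[j, x, y] * pc[k, x, y]
        assert float(consistency.data) == pytest.approx(cons_ref / 1024, rel=1e-3)
        assert float(overlap.data) == pytest.approx(pair_total / q_total, rel=1e-3)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        mask = rng.random((16, 16)) > 0.5
        frames = list(rng.uniform(0, 1, (4, 16, 16)).astype(np.float32))
        c1, o1 = weak_segmentation_loss(_frames(frames), mask)
        c2, o2 = weak_segmentation_loss(_frames(frames[::-1]), mask)
        assert float(c1.data) == pytest.approx(float(c2.data), rel=1e-5)
        assert float(o1.data) == pytest.approx(float(o2.data), rel=1e-5)

    def test_single_prediction_overlap_is_zero(self):
        rng = np.random.default_rng(5)
        mask = rng.random((16, 16)) > 0.5
        frames = [rng.uniform(0, 1, (16, 16)).astype(np.float32)]
        _, overlap = weak_segmentation_loss(_frames(frames), mask)
        assert float(overlap.data) == pytest.approx(0.0, abs=1e-6)

    def test_no_predictions_background_term(self):
        mask = np.zeros((8, 8), dtype=bool)
        consistency, overlap = weak_segmentation_loss(
            Tensor(np.zeros((0, 1, 8, 8), dtype=np.float32)), mask
        )
        assert float(consistency.data) < 1e-4
        assert float(overlap.data) == 0.0

    def test_strictly_increases_under_corruption(self):
        """A pixel pushed outside the mask, or a duplicated instance, raises the loss."""
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:14] = True
        a = np.zeros((16, 16), dtype=np.float32)
        a[2:8, 2:8] = 1.0
        b = np.zeros((16, 16), dtype=np.float32)
        b[2:8, 8:14] = 1.0
        c0, o0 = weak_segmentation_loss(_frames([a, b]), mask)
        base = float(c0.data) + float(o0.data)
        # (a) claim a background pixel
        a_bad = a.copy()
        a_bad[12, 12] = 1.0
        c1, o1 = weak_segmentation_loss(_frames([a_bad, b]), mask)
        assert float(c1.data) + float(o1.data) > base + 1e-3
        # (b) duplicate an instance
        c2, o2 = weak_segmentation_loss(_frames([a, b, a.copy()]), mask)
        assert float(c2.data) + float(o2.data) > base + 1e-3


# ---------------------------------------------------------------------------
# auxnet losses
# ---------------------------------------------------------------------------

class TestAuxnetLosses:
    def test_pseudo_boundary_of_square_is_ring(self):
        frame = np.zeros((12, 12), dtype=np.float32)
        frame[4:9, 4:9] = 1.0  # 5x5 square
        target = pseudo_boundary_target([frame], (12, 12))
        expected = set()
        for r in range(3, 10):
            for c in range(3, 10):
                inside = 4 <= r <= 8 and 4 <= c <= 8
                interior = 5 <= r <= 7 and 5 <= c <= 7
                if (inside or _adjacent_to_square(r, c)) and not interior:
                    expected.add((r, c))
        got = set(zip(*np.nonzero(target)))
        assert got == expected

    def test_perfect_fit_near_zero(self):
        frame = np.zeros((12, 12), dtype=np.float32)
        frame[4:9, 4:9] = 1.0
        target = pseudo_boundary_target([frame], (12, 12)).astype(np.float32)
        aux_logits = Tensor(np.where(target > 0, 30.0, -30.0)[None, None])
        loss = auxnet_fit_loss(aux_logits, _frames([frame]))
        assert float(loss.data) < 1e-6

    def test_empty_predictions_zero_auxnet(self):
        aux_logits = Tensor(np.full((1, 1, 8, 8), -30.0, dtype=np.float32))
        loss = auxnet_fit_loss(aux_logits, Tensor(np.zeros((0, 1, 8, 8), np.float32)))
        assert float(loss.data) < 1e-6

    def test_boundary_consistency_agreement_zero(self):
        rng = np.random.default_rng(6)
        frames = rng.uniform(0, 1, (2, 16, 16)).astype(np.float32)
        mask = np.ones((16, 16), dtype=bool)
        edges = soft_edge_map(_frames(list(frames))).data.reshape(16, 16)
        loss = boundary_consistency_loss(_frames(list(frames)), edges, mask)
        assert float(loss.data) < 1e-10

    def test_flat_predictions_zero_aux_zero(self):
        frames = [np.full((16, 16), 0.4, dtype=np.float32)]
        mask = np.zeros((16, 16), dtype=bool)
        mask[6:10, 6:10] = True  # restriction region away from the frame border
        loss = boundary_consistency_loss(
            _frames(frames), np.zeros((16, 16), np.float32), mask
        )
        assert float(loss.data) < 1e-8

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(7)
        frames = rng.uniform(0, 1, (2, 16, 16)).astype(np.float64)
        aux = rng.uniform(0, 1, (16, 16)).astype(np.float32)
        mask = np.ones((16, 16), dtype=bool)
        loss = boundary_consistency_loss(
            _frames(list(frames.astype(np.float32))), aux, mask
        )
        # oracle: central differences with zero padding, per instance,
        # scaled so a unit step saturates at 1
        total = np.zeros((16, 16))
        for k in range(2):
            p = np.pad(frames[k], 1)
            gr = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
            gc = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
            total += 2.0 * np.sqrt(gr**2 + gc**2 + 1e-12)
        total = np.clip(total, 0, 1)
        ref = np.mean((total - aux.astype(np.float64)) ** 2)
        assert float(loss.data) == pytest.approx(ref, rel=1e-3)


def _adjacent_to_square(r, c):
    return 3 <= r <= 9 and 3 <= c <= 9


class TestEdgeSuppression:
    def test_zero_when_edges_lie_on_boundaries(self):
        frame = np.zeros((12, 12), dtype=np.float32)
        frame[4:9, 4:9] = 1.0
        mask = frame > 0.5
        # auxnet claims boundary everywhere the prediction has an edge
        edges = soft_edge_map(_frames([frame])).data.reshape(12, 12)
        aux = (edges > 0).astype(np.float32)
        loss = edge_suppression_loss(_frames([frame]), aux, mask)
        assert float(loss.data) < 1e-7

    def test_positive_for_edges_off_boundary(self):
        frame = np.zeros((12, 12), dtype=np.float32)
        frame[4:9, 4:9] = 1.0
        mask = frame > 0.5
        loss = edge_suppression_loss(
            _frames([frame]), np.zeros((12, 12), np.float32), mask
        )
        assert float(loss.data) > 1e-3

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(12)
        frames = rng.uniform(0, 1, (2, 16, 16)).astype(np.float64)
        aux = rng.uniform(0, 1, (16, 16))
        mask = np.ones((16, 16), dtype=bool)
        loss = edge_suppression_loss(
            _frames(list(frames.astype(np.float32))), aux.astype(np.float32), mask
        )
        total = np.zeros((16, 16))
        for k in range(2):
            p = np.pad(frames[k], 1)
            gr = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
            gc = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
            total += 2.0 * np.sqrt(gr**2 + gc**2 + 1e-12)
        total = np.clip(total, 0, 1)
        ref = np.mean(total * (1.0 - aux))
        assert float(loss.data) == pytest.approx(ref, rel=1e-3)

    def test_isolates_auxnet(self):
        model = CellModel(ModelConfig(seed=21), with_auxnet=True)
        rng = np.random.default_rng(13)
        img = rng.random((64, 64)).astype(np.float32)
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:40, 20:40] = True
        fp = model.backbone(img)
        logits, origins = model.segment_at_lois(fp, np.array([[30.0, 30.0]]))
        frames = logits.sigmoid().scatter_crops(origins, (64, 64))
        aux_logits = model.auxnet(img)
        for p in model.parameters():
            p.grad = None
        edge_suppression_loss(frames, aux_logits.sigmoid().detach(), mask).backward()
        assert all(
            p.grad is None or not p.grad.any() for p in model.auxnet.parameters()
        )
        assert any(
            p.grad is not None and p.grad.any() for p in model.seg_head.parameters()
        )


# ---------------------------------------------------------------------------
# gradient-isolation contracts & breakdown bookkeeping
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def setup():
    model = CellModel(ModelConfig(seed=11), with_auxnet=True)
    rng = np.random.default_rng(8)
    img = rng.random((64, 64)).astype(np.float32)
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:30, 10:30] = True
    fp = model.backbone(img)
    logits, origins = model.segment_at_lois(fp, np.array([[20.0, 20.0]]))
    frames = logits.sigmoid().scatter_crops(origins, (64, 64))
    aux_logits = model.auxnet(img)
    return model, frames, aux_logits, mask


class TestGradientContracts:
    def test_auxnet_fit_isolates_main_network(self, setup):
        model, frames, aux_logits, _ = setup
        for p in model.parameters():
            p.grad = None
        loss = auxnet_fit_loss(aux_logits, frames.detach())
        loss.backward()
        main = model.backbone.parameters() + model.seg_head.parameters()
        assert all(p.grad is None or not p.grad.any() for p in main)
        assert any(p.grad is not None and p.grad.any() for p in model.auxnet.parameters())

    def test_boundary_consistency_isolates_auxnet(self, setup):
        model, frames, aux_logits, mask = setup
        for p in model.parameters():
            p.grad = None
        loss = boundary_consistency_loss(frames, aux_logits.sigmoid().detach(), mask)
        loss.backward()
        assert all(
            p.grad is None or not p.grad.any() for p in model.auxnet.parameters()
        )
        assert any(
            p.grad is not None and p.grad.any() for p in model.seg_head.parameters()
        )

    def test_all_terms_nonnegative_finite(self, setup):
        model, frames, aux_logits, mask = setup
        c, o = weak_segmentation_loss(frames, mask)
        terms = [
            c, o,
            auxnet_fit_loss(aux_logits, frames.detach()),
            boundary_consistency_loss(frames, aux_logits.sigmoid().detach(), mask),
        ]
        for t in terms:
            v = float(t.data)
            assert np.isfinite(v) and v >= 0

    def test_breakdown_total_is_weighted_sum(self):
        total, bd = LossBreakdown.combine(
            {"a": Tensor(2.0), "b": Tensor(3.0)}, {"a": 1.0, "b": 0.5}
        )
        assert float(total.data) == pytest.approx(3.5)
        assert bd.total == pytest.approx(3.5)
        assert "c" not in bd.terms  # inactive terms absent, not zero

    def test_bce_with_logits_matches_reference(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 3, (8, 8)).astype(np.float32)
        y = (rng.random((8, 8)) > 0.5).astype(np.float32)
        got = bce_with_logits(Tensor(z), y).data
        p = 1 / (1 + np.exp(-z.astype(np.float64)))
        ref = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        np.testing.assert_allclose(got, ref, rtol=1e-4, atol=1e-6)
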