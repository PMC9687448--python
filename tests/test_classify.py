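"""Candidate extraction, patch construction and the shallow CNN classifier."""

import numpy as np
import pytest
from scipy import ndimage

from octovessel import classify as clf
from octovessel import nn
from octovessel.preprocess import PreprocessedFrame
from octovessel.segment import TrainConfig


def _pf(image):
    image = np.asarray(image, dtype=np.float32)
    return PreprocessedFrame(
        image=image,
        lumen_offset=np.zeros(image.shape[0], dtype=int),
        guidewire_interval=(0, 0),
        valid_mask=np.ones(image.shape, dtype=bool),
        raw_depth=image.shape[1],
    )


# --- blob extraction -------------------------------------------------------

def test_two_disjoint_squares():
    m = np.zeros((20, 20), dtype=np.uint8)
    m[2:4, 2:4] = 1
    m[10:12, 10:12] = 1
    blobs = clf.extract_blobs(m)
    assert len(blobs) == 2
    assert all(b.area_px == 4 for b in blobs)


def test_empty_mask_gives_no_blobs():
    assert clf.extract_blobs(np.zeros((8, 8), dtype=np.uint8)) == []


def test_blob_across_theta_wrap_is_single():
    """A component split across A-line 0 and the last A-line is one blob."""
    m = np.zeros((16, 10), dtype=np.uint8)
    m[14:16, 4:6] = 1
    m[0:2, 4:6] = 1
    blobs = clf.extract_blobs(m)
    assert len(blobs) == 1
    assert blobs[0].area_px == 8
    a0, a1 = blobs[0].aline_min, blobs[0].aline_max
    assert (a0, a1) == (14, 18)  # circular half-open box


def test_wrap_blobs_match_doubled_theta_flood_fill(rng):
    """Component count equals flood fill on the θ-doubled image."""
    for _ in range(10):
        m = (rng.random((12, 15)) > 0.8).astype(np.uint8)
        blobs = clf.extract_blobs(m)
        tripled = np.concatenate([m, m, m], axis=0)
        lab, _ = ndimage.label(tripled, structure=np.ones((3, 3), int))
        # components intersecting the middle copy extend across the wrap
        # without truncation; canonicalize their pixels modulo the height
        comp = {lab[i, j] for i in range(12, 24) for j in range(15) if lab[i, j]}
        merged = {
            frozenset((r % 12, cc) for r, cc in zip(*np.nonzero(lab == c)))
            for c in comp
        }
        assert len(blobs) == len(merged)
        got = {frozenset(map(tuple, b.pixels)) for b in blobs}
        assert got == merged


def test_blob_invariants(rng):
    m = (rng.random((20, 20)) > 0.85).astype(np.uint8)
    for b in clf.extract_blobs(m):
        assert b.area_px == len(b.pixels)
        assert b.r_min <= b.pixels[:, 1].min()
        assert b.r_max == b.pixels[:, 1].max() + 1


# --- patches ---------------------------------------------------------------

def test_patch_crop_arithmetic(rng):
    """A 10x6 tight box grows to 16x12 with 3-px context, then resizes to 30x30."""
    img = rng.random((64, 64)).astype(np.float32)
    m = np.zeros((64, 64), dtype=np.uint8)
    m[20:30, 40:46] = 1
    blob = clf.extract_blobs(m)[0]
    assert (blob.aline_max - blob.aline_min, blob.r_max - blob.r_min) == (10, 6)
    patch = clf.make_patch(blob, _pf(img))
    assert patch.image.shape == (30, 30)


def test_patch_identity_when_crop_is_30x30(rng):
    img = rng.random((64, 64)).astype(np.float32)
    m = np.zeros((64, 64), dtype=np.uint8)
    m[10:34, 20:44] = 1  # 24x24 box → 30x30 crop
    blob = clf.extract_blobs(m)[0]
    patch = clf.make_patch(blob, _pf(img))
    np.testing.assert_allclose(patch.image, img[7:37, 17:47], atol=1e-6)


def test_patch_centers_blob(rng):
    """The blob centroid lands at the patch centre within a pixel."""
    img = rng.random((64, 64)).astype(np.float32)
    m = np.zeros((64, 64), dtype=np.uint8)
    m[12:20, 30:40] = 1
    blob = clf.extract_blobs(m)[0]
    # centroid sits at the centre of the tight box, which maps to patch centre
    box_center = ((blob.aline_min + blob.aline_max - 1) / 2, (blob.r_min + blob.r_max - 1) / 2)
    assert abs(blob.centroid[0] - box_center[0]) <= 1.0
    assert abs(blob.centroid[1] - box_center[1]) <= 1.0
    patch = clf.make_patch(blob, _pf(img))
    assert patch.image.shape == (30, 30)


def test_patch_wraps_theta_and_replicates_depth(rng):
    img = rng.random((32, 20)).astype(np.float32)
    m = np.zeros((32, 20), dtype=np.uint8)
    m[30:32, 0:4] = 1
    m[0:2, 0:4] = 1  # wrap blob at the depth edge
    blob = clf.extract_blobs(m)[0]
    patch = clf.make_patch(blob, _pf(img))
    assert patch.image.shape == (30, 30)
    assert np.isfinite(patch.image).all()


# --- classifier network ----------------------------------------------------

def test_classifier_architecture_layer_counts():
    model = clf.build_classifier(seed=0)
    convs = [l for l in model.layers if isinstance(l, nn.Conv2d)]
    pools = [l for l in model.layers if isinstance(l, nn.MaxPool2d)]
    fcs = [l for l in model.layers if isinstance(l, nn.Linear)]
    assert (len(convs), len(pools), len(fcs)) == (3, 2, 1)
    assert [c.weight.value.shape[0] for c in convs] == [8, 16, 32]
    assert all(c.weight.value.shape[2:] == (3, 3) for c in convs)
    assert all(c.stride == 2 for c in convs)


def test_classifier_parameter_count_closed_form():
    """conv1 3*3*1*8+8 + conv2 3*3*8*16+16 + conv3 3*3*16*32+32
    + BN 2*(8+16+32) + FC 32*2+2 = 6066."""
    model = clf.build_classifier(seed=0)
    total = sum(p.value.size for p in model.params())
    assert total == 80 + 1168 + 4640 + 112 + 66 == 6066


def test_classifier_softmax_output(rng):
    model = clf.build_classifier(seed=0)
    probs = model.predict_proba(rng.random((5, 30, 30)).astype(np.float32))
    assert probs.shape == (5, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_classifier_prediction_determinism(rng):
    x = rng.random((4, 30, 30)).astype(np.float32)
    a = clf.build_classifier(seed=3).predict_proba(x)
    b = clf.build_classifier(seed=3).predict_proba(x)
    np.testing.assert_array_equal(a, b)


# --- training assembly -----------------------------------------------------

def test_training_assembly_balances_1_to_7(rng):
    """10 positives and 70 negatives → 70:70 after 7x positive rotation."""
    pos = [clf.CandidatePatch(rng.random((30, 30)), label=1) for _ in range(10)]
    neg = [clf.CandidatePatch(rng.random((30, 30)), label=0) for _ in range(70)]
    x, y = clf.assemble_training_patches(pos + neg)
    assert len(y) == 140
    assert (y == 1).sum() == 70
    assert (y == 0).sum() == 70


def test_train_classifier_rejects_single_class(rng):
    pos = [clf.CandidatePatch(rng.random((30, 30)), label=1) for _ in range(4)]
    with pytest.raises(ValueError, match="both classes"):
        clf.train_classifier(clf.build_classifier(), pos, TrainConfig(max_epochs=1))


def test_train_classifier_separates_bright_from_dark(rng):
    """A tiny sanity task: dark-centre patches vs uniform patches."""
    def dark_patch():
        p = 0.6 + 0.05 * rng.normal(size=(30, 30))
        p[12:18, 12:18] *= 0.2
        return np.clip(p, 0, 1)

    def flat_patch():
        return np.clip(0.6 + 0.05 * rng.normal(size=(30, 30)), 0, 1)

    patches = [clf.CandidatePatch(dark_patch(), label=1) for _ in range(6)]
    patches += [clf.CandidatePatch(flat_patch(), label=0) for _ in range(42)]
    model = clf.build_classifier(seed=0)
    tc = TrainConfig(max_epochs=10, drop_period=5, batch_size=16, seed=0)
    clf.train_classifier(model, patches, tc)
    test = np.stack([dark_patch() for _ in range(10)] + [flat_patch() for _ in range(10)])
    pred = (model.predict_proba(test)[:, 1] >= 0.5).astype(int)
    truth = np.array([1] * 10 + [0] * 10)
    assert (pred == truth).mean() >= 0.9


# --- filtering -------------------------------------------------------------

class _StubClassifier:
    """Decides by mean patch intensity: dark = vessel."""

    def __init__(self, keep_all=None):
        self.keep_all = keep_all

    def predict_proba(self, patches):
        if self.keep_all is True:
            p1 = np.ones(len(patches))
        elif self.keep_all is False:
            p1 = np.zeros(len(patches))
        else:
            p1 = (np.asarray(patches).mean(axis=(1, 2)) < 0.5).astype(float)
        return np.stack([1 - p1, p1], axis=1)


def test_filter_keeps_all_when_classifier_accepts(rng):
    m = (rng.random((32, 32)) > 0.9).astype(np.uint8)
    blobs = clf.extract_blobs(m)
    cleaned, decisions = clf.filter_candidates(m, blobs, _StubClassifier(True), _pf(rng.random((32, 32))))
    np.testing.assert_array_equal(cleaned, m)
    assert all(d["kept"] for d in decisions)


def test_filter_empties_mask_when_classifier_rejects(rng):
    m = (rng.random((32, 32)) > 0.9).astype(np.uint8)
    blobs = clf.extract_blobs(m)
    cleaned, decisions = clf.filter_candidates(m, blobs, _StubClassifier(False), _pf(rng.random((32, 32))))
    assert cleaned.sum() == 0
    assert all(not d["kept"] for d in decisions)


def test_filter_set_algebra(rng):
    """Cleaned pixels = union of kept blobs; never adds pixels."""
    m = (rng.random((40, 40)) > 0.88).astype(np.uint8)
    img = rng.random((40, 40)).astype(np.float32)
    blobs = clf.extract_blobs(m)
    cleaned, decisions = clf.filter_candidates(m, blobs, _StubClassifier(), _pf(img))
    assert not np.any(cleaned & ~m)  # subset
    kept_px = set()
    for d, b in zip(decisions, blobs):
        if d["kept"]:
            kept_px |= set(map(tuple, b.pixels))
    got_px = set(zip(*np.nonzero(cleaned)))
    assert got_px == kept_px
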