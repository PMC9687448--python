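"""Fixed-seed end-to-end phantom benchmark: generate → preprocess → segment →
classify → track → evaluate.

This is the package's reference experiment: a set of desk-preset phantom
pullbacks is split by segment into train/validation/test, the segmentation
and classification networks are trained on the training segments, and every
pipeline-level quantity (pixel Dice before/after candidate filtering,
classifier patch accuracy, frame-presence agreement, track recovery) is
measured on the held-out segments.  All randomness derives from one seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import classify as clf
from . import evaluate as ev
from . import preprocess as pp
from . import segment as seg
from . import track as tr
from .phantom import GroundTruthScene, PhantomParams, generate_pullback


@dataclasses.dataclass(eq=False)
class PhantomCase:
    """One generated pullback with its pre-processed frames and aligned labels."""

    index: int
    params: PhantomParams
    scene: GroundTruthScene
    pfs: list[pp.PreprocessedFrame]
    images: np.ndarray  # (n_frames, alines, roi)
    labels: np.ndarray  # truth labels carried through shift/crop
    valid: np.ndarray


@dataclasses.dataclass(eq=False)
class BenchmarkResult:
    dice_before_filter: float
    dice_after_filter: float
    sensitivity: float
    specificity: float
    classifier_accuracy: float
    n_test_patches: int
    frame_percent_difference: float
    tubes_total: int
    tubes_recovered: int
    tracks_per_tube_ok: bool
    side_branches_total: int
    side_branches_rejected: int
    truth_track_recovery_ok: bool
    threshold: float
    seg_history: dict
    clf_history: dict
    cases_test: list[PhantomCase]
    cleaned_masks: dict[int, np.ndarray]
    raw_masks: dict[int, np.ndarray]
    classifier: clf.PatchClassifier
    segmenter: seg.SegNet


def _make_case(index: int, seed: int, n_frames: int) -> PhantomCase:
    params = PhantomParams.desk(seed=seed, n_frames=n_frames)
    pullback, lab, scene = generate_pullback(params)
    pfs = pp.preprocess_pullback(pullback, params.catheter_radius_px)
    images = np.stack([pf.image for pf in pfs])
    labels = np.stack([pp.shift_labels(lab.data[fi], pfs[fi]) for fi in range(len(pfs))])
    valid = np.stack([pf.valid_mask for pf in pfs])
    return PhantomCase(index, params, scene, pfs, images, labels, valid)


def _select_crops(cases: list[PhantomCase], n_crops: int, crop: int, rng: np.random.Generator):
    """Training crops: vessel-centred (jittered) and random background, ~50/50.

    Crop-level sampling concentrates the scarce vessel pixels so the
    inverse-median-frequency class weights stay in a trainable range while
    the network remains fully convolutional at inference.
    """
    xs, ys, vs = [], [], []
    pool_pos, pool_bg = [], []
    for c in cases:
        for fi in range(c.images.shape[0]):
            alines, depths = np.nonzero(c.labels[fi] & c.valid[fi])
            if alines.size:
                pool_pos.append((c, fi, alines, depths))
            else:
                pool_bg.append((c, fi))
    for i in range(n_crops):
        if i % 2 == 0 and pool_pos:
            c, fi, alines, depths = pool_pos[rng.integers(len(pool_pos))]
            j = rng.integers(alines.size)
            ca = int(alines[j] + rng.integers(-8, 9))
            cd = int(depths[j] + rng.integers(-8, 9))
        else:
            src = pool_bg if pool_bg else pool_pos
            item = src[rng.integers(len(src))]
            c, fi = item[0], item[1]
            ca, cd = int(rng.integers(c.images.shape[1])), int(rng.integers(c.images.shape[2]))
        n_a, n_d = c.images.shape[1:]
        rows = np.arange(ca - crop // 2, ca + crop // 2) % n_a
        cd = min(max(cd, crop // 2), n_d - crop // 2)
        cols = np.arange(cd - crop // 2, cd + crop // 2)
        xs.append(c.images[fi][np.ix_(rows, cols)])
        ys.append(c.labels[fi][np.ix_(rows, cols)])
        vs.append(c.valid[fi][np.ix_(rows, cols)])
    return np.stack(xs), np.stack(ys), np.stack(vs)


def _select_threshold(model: seg.SegNet, cases: list[PhantomCase],
                      grid=(0.5, 0.7, 0.9, 0.95, 0.99, 0.995)) -> float:
    """Operating probability threshold maximizing pooled Dice on validation frames."""
    from . import nn

    model.train(False)
    pooled = {th: ev.ConfusionCounts(0, 0, 0, 0) for th in grid}
    for c in cases:
        for i in range(0, c.images.shape[0], 8):
            x = c.images[i : i + 8][:, None].astype(np.float32)
            probs = nn.softmax(model.forward(x), axis=1)[:, 1]
            for th in grid:
                masks = (probs >= th) & c.valid[i : i + 8]
                pooled[th] = pooled[th] + ev.confusion(masks, c.labels[i : i + 8], c.valid[i : i + 8])
    best_th, best_dice = grid[0], -1.0
    for th in grid:
        d = ev.metrics(pooled[th])["dice"]
        if not np.isnan(d) and d > best_dice:
            best_th, best_dice = th, d
    return best_th


def _collect_patches(cases: list[PhantomCase], masks: dict[int, np.ndarray]) -> list[clf.CandidatePatch]:
    patches = []
    for c in cases:
        for fi, pf in enumerate(c.pfs):
            for blob in clf.extract_blobs(masks[c.index][fi], frame=fi):
                patch = clf.make_patch(blob, pf)
                inside = float(c.labels[fi][blob.pixels[:, 0], blob.pixels[:, 1]].mean())
                patch.label = int(inside >= 0.5)
                patches.append(patch)
    return patches


def _background_patches(cases: list[PhantomCase], n: int, rng: np.random.Generator) -> list[clf.CandidatePatch]:
    """Negative training patches from vessel-free boxes (tissue, confusers).

    Keeps the candidate classes at the protocol's 1:7 positive:negative ratio
    when the segmenter itself produces too few false-positive candidates.
    """
    out: list[clf.CandidatePatch] = []
    tries = 0
    while len(out) < n and tries < 50 * n:
        tries += 1
        c = cases[rng.integers(len(cases))]
        fi = int(rng.integers(c.images.shape[0]))
        n_a, n_d = c.images.shape[1:]
        h = int(rng.integers(5, 21))
        w = int(rng.integers(5, 21))
        a0 = int(rng.integers(n_a))
        d0 = int(rng.integers(0, max(n_d - w, 1)))
        rows = np.arange(a0, a0 + h) % n_a
        if c.labels[fi][np.ix_(rows, np.arange(d0, d0 + w))].any():
            continue
        alines = np.repeat(rows, w)
        depths = np.tile(np.arange(d0, d0 + w), h)
        blob = clf.CandidateBlob(
            frame=fi, pixels=np.stack([alines, depths], axis=1),
            aline_min=a0, aline_max=a0 + h, r_min=d0, r_max=d0 + w,
            area_px=h * w, centroid=(float(a0 + h / 2) % n_a, d0 + w / 2),
        )
        patch = clf.make_patch(blob, c.pfs[fi])
        patch.label = 0
        out.append(patch)
    return out


def _tube_matches_track(tube, track: tr.MicrovesselTrack, n_alines: int) -> bool:
    """A kept track matches a tube when frame ranges overlap and the track's
    centroid falls inside the tube's angular neighbourhood."""
    f0, f1 = track.frame_range
    if f1 <= tube.frame_start or f0 >= tube.frame_stop:
        return False
    tube_aline = float(np.mean(tube.centers[:, 0]))
    track_aline = float(np.mean([b.centroid[0] for _, b in track.members]))
    d = abs(tube_aline - track_aline)
    return min(d, n_alines - d) <= tube.radius_alines + 6


def _track_masks(case: PhantomCase, masks: np.ndarray, min_frames: int):
    per_frame = [clf.extract_blobs(masks[fi], frame=fi) for fi in range(masks.shape[0])]
    tracks = tr.link_blobs(per_frame, n_alines=case.images.shape[1])
    for t in tracks:
        tr.apply_definition(t, min_frames=min_frames)
        if t.kept:
            tr.quantify(t, case.params.radial_px_um, case.params.frame_pitch_mm)
    return tracks


def _truth_masks(case: PhantomCase) -> np.ndarray:
    """Ground-truth labels restricted to the valid (non-blanked) region."""
    return (case.labels.astype(bool) & case.valid).astype(np.uint8)


def side_branch_masks(case: PhantomCase, branch) -> np.ndarray:
    """Candidate masks of one side branch in lumen-aligned coordinates.

    The branch region starts at the true lumen boundary, so after the pixel
    shift its pixels occupy depths [0, depth_extent) on its A-lines — a
    lumen-contiguous candidate by construction.
    """
    n_f, n_a, roi = case.images.shape
    vol = np.zeros_like(case.labels)
    cols = (branch.aline_start + np.arange(branch.width_alines)) % n_a
    extent = min(branch.depth_extent_px, roi)
    for fi in range(branch.frame_start, branch.frame_stop):
        vol[fi][cols, :extent] = 1
    return vol


def check_track_recovery(case: PhantomCase, tracks: list[tr.MicrovesselTrack],
                         min_frames: int = 3) -> dict:
    """Per-pullback tube/side-branch accounting against kept tracks."""
    n_a = case.images.shape[1]
    kept = [t for t in tracks if t.kept]
    tubes = [t for t in case.scene.microvessel_tubes if t.n_frames >= min_frames]
    matches = {ti: [k for k in kept if _tube_matches_track(tube, k, n_a)]
               for ti, tube in enumerate(tubes)}
    recovered = sum(1 for m in matches.values() if len(m) >= 1)
    exactly_one = all(len(m) == 1 for m in matches.values())
    # every kept track should belong to some tube (no spurious kept tracks)
    matched_ids = {id(k) for m in matches.values() for k in m}
    spurious = [k for k in kept if id(k) not in matched_ids]
    return {
        "n_tubes": len(tubes),
        "recovered": recovered,
        "exactly_one": exactly_one and not spurious,
        "n_spurious": len(spurious),
    }


def run_benchmark(
    seed: int = 1,
    n_pullbacks: int = 20,
    n_frames: int = 40,
    n_train: int = 14,
    n_val: int = 3,
    n_train_crops: int = 1200,
    n_val_crops: int = 150,
    crop_px: int = 48,
    seg_epochs: int = 20,
    seg_drop_period: float = 6.0,
    clf_epochs: int = 25,
    min_frames: int = 3,
) -> BenchmarkResult:
    """Run the end-to-end phantom benchmark at the configured problem size."""
    rng = np.random.default_rng(seed)
    cases = [_make_case(i, seed * 1000 + i, n_frames) for i in range(n_pullbacks)]
    order = rng.permutation(n_pullbacks)
    train_cases = [cases[i] for i in order[:n_train]]
    val_cases = [cases[i] for i in order[n_train : n_train + n_val]]
    test_cases = [cases[i] for i in order[n_train + n_val :]]

    x_tr, y_tr, v_tr = _select_crops(train_cases, n_train_crops, crop_px, rng)
    x_va, y_va, v_va = _select_crops(val_cases, n_val_crops, crop_px, rng)

    tc = seg.TrainConfig(max_epochs=seg_epochs, drop_period=seg_drop_period,
                         batch_size=16, seed=seed)
    model = seg.build_segnet(seg.SegModelConfig(input_hw=(256, 200)), seed=seed)
    seg_history = seg.train_segmenter(model, x_tr, y_tr, v_tr, tc,
                                      val_images=x_va, val_labels=y_va, val_valid=v_va)

    threshold = _select_threshold(model, val_cases)
    raw_masks = {c.index: seg.predict_masks(model, c.pfs, threshold=threshold) for c in cases}

    # pooled pixel metrics on held-out pullbacks, before candidate filtering
    pooled = ev.ConfusionCounts(0, 0, 0, 0)
    for c in test_cases:
        pooled = pooled + ev.confusion(raw_masks[c.index], c.labels, c.valid)
    m_before = ev.metrics(pooled)

    # candidate classifier on segmentation blobs of the training segments;
    # scarce negatives are topped up from vessel-free boxes to the 1:7 ratio
    train_patches = _collect_patches(train_cases, raw_masks)
    n_pos = sum(p.label for p in train_patches)
    if n_pos == 0:
        # degenerate segmenter output: fall back to truth-label candidates so
        # the classifier still trains on real vessel appearance
        truth = {c.index: _truth_masks(c) for c in train_cases}
        train_patches += [p for p in _collect_patches(train_cases, truth) if p.label == 1]
        n_pos = sum(p.label for p in train_patches)
    n_neg = len(train_patches) - n_pos
    if n_neg < 7 * n_pos:
        train_patches += _background_patches(train_cases, 7 * n_pos - n_neg, rng)
    classifier = clf.build_classifier(seed=seed)
    tc_clf = seg.TrainConfig(max_epochs=clf_epochs, batch_size=16, seed=seed)
    clf_history = clf.train_classifier(classifier, train_patches, tc_clf)

    test_patches = _collect_patches(test_cases, raw_masks)
    n_pos_t = sum(p.label for p in test_patches)
    n_neg_t = len(test_patches) - n_pos_t
    if n_neg_t < 7 * n_pos_t:
        test_patches += _background_patches(test_cases, 7 * n_pos_t - n_neg_t, rng)
    if test_patches:
        probs = classifier.predict_proba(np.stack([p.image for p in test_patches]))[:, 1]
        pred_lab = (probs >= 0.5).astype(int)
        true_lab = np.array([p.label for p in test_patches])
        clf_acc = float((pred_lab == true_lab).mean())
    else:
        clf_acc = float("nan")

    cleaned_masks: dict[int, np.ndarray] = {}
    for c in test_cases:
        vol = np.empty_like(raw_masks[c.index])
        for fi, pf in enumerate(c.pfs):
            blobs = clf.extract_blobs(raw_masks[c.index][fi], frame=fi)
            vol[fi], _ = clf.filter_candidates(raw_masks[c.index][fi], blobs, classifier, pf)
        cleaned_masks[c.index] = vol
    pooled_after = ev.ConfusionCounts(0, 0, 0, 0)
    for c in test_cases:
        pooled_after = pooled_after + ev.confusion(cleaned_masks[c.index], c.labels, c.valid)
    m_after = ev.metrics(pooled_after)

    # frame-level presence agreement on held-out pullbacks
    auto, manual, total = set(), set(), 0
    for c in test_cases:
        nf = c.images.shape[0]
        auto |= {total + fi for fi in range(nf) if cleaned_masks[c.index][fi].any()}
        manual |= {total + fi for fi in range(nf) if _truth_masks(c)[fi].any()}
        total += nf
    agree = ev.frame_presence_agreement(auto, manual, total)

    # track recovery on held-out pullbacks (predicted pipeline masks)
    tubes_total = recovered = 0
    per_tube_ok = True
    for c in test_cases:
        tracks = _track_masks(c, cleaned_masks[c.index], min_frames)
        rec = check_track_recovery(c, tracks, min_frames)
        tubes_total += rec["n_tubes"]
        recovered += rec["recovered"]
        per_tube_ok = per_tube_ok and rec["exactly_one"]

    # mechanical track check on ground-truth masks: every tube → exactly one
    # kept track; every side branch (as a lumen-contiguous candidate region
    # carried through the same shift bookkeeping) rejected
    truth_ok = True
    sb_total = sb_rejected = 0
    for c in test_cases:
        tracks = _track_masks(c, _truth_masks(c), min_frames)
        rec = check_track_recovery(c, tracks, min_frames)
        truth_ok = truth_ok and rec["exactly_one"] and rec["recovered"] == rec["n_tubes"]
        for br in c.scene.side_branches:
            sb_total += 1
            sb_tracks = _track_masks(c, side_branch_masks(c, br), min_frames)
            if sb_tracks and all(not t.kept for t in sb_tracks):
                sb_rejected += 1

    return BenchmarkResult(
        dice_before_filter=m_before["dice"],
        dice_after_filter=m_after["dice"],
        sensitivity=m_after["sensitivity"],
        specificity=m_after["specificity"],
        classifier_accuracy=clf_acc,
        n_test_patches=len(test_patches),
        frame_percent_difference=agree["percent_difference"],
        tubes_total=tubes_total,
        tubes_recovered=recovered,
        tracks_per_tube_ok=per_tube_ok,
        side_branches_total=sb_total,
        side_branches_rejected=sb_rejected,
        truth_track_recovery_ok=truth_ok,
        threshold=threshold,
        seg_history=seg_history,
        clf_history=clf_history,
        cases_test=test_cases,
        cleaned_masks=cleaned_masks,
        raw_masks=raw_masks,
        classifier=classifier,
        segmenter=model,
    )
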