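"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and first-principles
definitions, deliberately sharing no code with the package, so that the
vectorized implementations are checked against an independent path.
"""

import math


def brute_confusion(truth, pred, classes):
    """Pixel-by-pixel confusion counts {(i, j): n}."""
    counts = {(i, j): 0 for i in classes for j in classes}
    h = len(truth)
    w = len(truth[0])
    for y in range(h):
        for x in range(w):
            counts[(truth[y][x], pred[y][x])] += 1
    return counts


def brute_boundaries(mask, cls):
    """Boundary pixels of one class: 4-neighbour of a different class."""
    h = len(mask)
    w = len(mask[0])
    pts = []
    for y in range(h):
        for x in range(w):
            if mask[y][x] != cls:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny][nx] != cls:
                    pts.append((y, x))
                    break
    return pts


def brute_bf(truth_pts, pred_pts, tol):
    if not truth_pts and not pred_pts:
        return 1.0
    if not truth_pts or not pred_pts:
        return 0.0

    def frac_matched(src, dst):
        hit = 0
        for (y, x) in src:
            best = min(math.hypot(y - v, x - u) for (v, u) in dst)
            if best <= tol:
                hit += 1
        return hit / len(src)

    precision = frac_matched(pred_pts, truth_pts)
    recall = frac_matched(truth_pts, pred_pts)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def brute_metrics(truth, pred, classes, tol):
    """All five metrics (percent scale) from first principles."""
    cm = brute_confusion(truth, pred, classes)
    total = sum(cm.values())
    tp = {c: cm[(c, c)] for c in classes}
    truth_n = {c: sum(cm[(c, j)] for j in classes) for c in classes}
    pred_n = {c: sum(cm[(i, c)] for i in classes) for c in classes}
    present = [c for c in classes if truth_n[c] + pred_n[c] > 0]

    global_acc = sum(tp.values()) / total

    accs = []
    ious = []
    for c in present:
        accs.append(tp[c] / truth_n[c] if truth_n[c] > 0 else 0.0)
        union = truth_n[c] + pred_n[c] - tp[c]
        ious.append(tp[c] / union if union > 0 else 0.0)
    mean_acc = sum(accs) / len(accs)
    mean_iou = sum(ious) / len(ious)

    weighted = 0.0
    for c, iou in zip(present, ious):
        weighted += (truth_n[c] / total) * iou

    bfs = []
    for c in present:
        bfs.append(brute_bf(brute_boundaries(truth, c),
                            brute_boundaries(pred, c), tol))
    mean_bf = sum(bfs) / len(bfs)

    return {
        "global_accuracy": 100 * global_acc,
        "mean_accuracy": 100 * mean_acc,
        "mean_iou": 100 * mean_iou,
        "weighted_iou": 100 * weighted,
        "mean_bf": 100 * mean_bf,
    }
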