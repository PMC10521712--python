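"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible — explicit Python loops,
no vectorization, no reuse of the package's numerics — so that agreement
with the package is meaningful evidence of correctness.
"""

import math

import numpy as np


def loop_local_histogram(x, centers, widths, S, T):
    """Nested-loop windowed soft binning of a channels-last (H, W, K) map.

    Output channel ordering is bin-major within each source channel
    (channel k occupies slots k*B .. k*B+B-1); replicate padding on the
    bottom/right edges keeps the spatial size."""
    H, W, K = x.shape
    B = centers.shape[0]
    xp = np.pad(x, ((0, S - 1), (0, T - 1), (0, 0)), mode="edge")
    out = np.zeros((H, W, B * K))
    for r in range(H):
        for c in range(W):
            for k in range(K):
                for b in range(B):
                    acc = 0.0
                    for s in range(S):
                        for t in range(T):
                            v = xp[r + s, c + t, k]
                            acc += math.exp(-widths[b, k] ** 2
                                            * (v - centers[b, k]) ** 2)
                    out[r, c, k * B + b] = acc / (S * T)
    return out


def loop_reduce_channels(x, weights):
    """Per-pixel matrix product, (H, W, D) x (K, D) -> (H, W, K)."""
    H, W, D = x.shape
    K = weights.shape[0]
    out = np.zeros((H, W, K))
    for r in range(H):
        for c in range(W):
            for k in range(K):
                acc = 0.0
                for d in range(D):
                    acc += weights[k, d] * x[r, c, d]
                out[r, c, k] = acc
    return out


def loop_metrics(pred, truth):
    """Pixel-loop confusion counts and metrics for binary masks."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1

    def ratio(a, b):
        return a / b if b else 1.0
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": ratio(tp, tp + fp),
        "recall": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "dice": ratio(2 * tp, 2 * tp + fp + fn),
        "iou_positive": ratio(tp, tp + fp + fn),
        "iou_overall": 0.5 * (ratio(tp, tp + fp + fn)
                              + ratio(tn, tn + fp + fn)),
    }


def loop_weighted_bce(probs, truth, w):
    """Per-pixel summed weighted cross entropy with the 1e-7 clamp."""
    eps = 1e-7
    total = 0.0
    n = 0
    for p, y in zip(probs.ravel(), truth.ravel()):
        p = min(max(p, eps), 1 - eps)
        total += -(w * y * math.log(p) + (1 - y) * math.log(1 - p))
        n += 1
    return total / n


def point_in_ellipse(px, py, cx, cy, a, b, theta):
    u = (px - cx) * math.cos(theta) + (py - cy) * math.sin(theta)
    v = -(px - cx) * math.sin(theta) + (py - cy) * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def loop_ellipse_interior_count(h, w, ellipses):
    """Count pixels inside any ellipse by looping over every pixel."""
    count = 0
    for y in range(h):
        for x in range(w):
            if any(point_in_ellipse(x, y, *e) for e in ellipses):
                count += 1
    return count
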