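"""Independent brute-force reference implementations of every metric.

Deliberately naive (per-pixel Python loops, all-pairs boundary distances)
so they share no code or vectorisation tricks with the package; the test
suite checks the package against these on random inputs.
"""

from __future__ import annotations

import numpy as np


def confusion_loops(pred, truth, n):
    cm = np.zeros((n, n), dtype=np.int64)
    for p, t in zip(np.asarray(pred).reshape(-1), np.asarray(truth).reshape(-1)):
        cm[int(t), int(p)] += 1
    return cm


def dice_loops(pred, truth):
    x = np.asarray(pred).astype(bool).reshape(-1)
    y = np.asarray(truth).astype(bool).reshape(-1)
    inter = sum(1 for a, b in zip(x, y) if a and b)
    tot = int(x.sum()) + int(y.sum())
    return 1.0 if tot == 0 else 2.0 * inter / tot


def iou_per_class_loops(cm):
    out = []
    n = cm.shape[0]
    for i in range(n):
        tp = cm[i, i]
        fp = sum(cm[j, i] for j in range(n) if j != i)
        fn = sum(cm[i, j] for j in range(n) if j != i)
        out.append(1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn))
    return out


def mrecall_loops(cm):
    recalls = []
    for i in range(cm.shape[0]):
        support = cm[i, :].sum()
        if support > 0:
            recalls.append(cm[i, i] / support)
    return float(np.mean(recalls)) if recalls else float("nan")


def accuracy_eq8_loops(cm):
    n = cm.shape[0]
    tp = sum(cm[i, i] for i in range(n))
    fp = sum(cm[j, i] for i in range(n) for j in range(n) if j != i)
    fn = sum(cm[i, j] for i in range(n) for j in range(n) if j != i)
    return tp / (tp + fp + fn)


def pixel_accuracy_loops(cm):
    return np.trace(cm) / cm.sum()


def boundary_loops(mask):
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not m[ni, nj]:
                    out[i, j] = True
                    break
    return out


def hd95_loops(pred, truth, spacing=None):
    x = np.asarray(pred).astype(bool)
    y = np.asarray(truth).astype(bool)
    if not x.any() and not y.any():
        return 0.0
    if x.any() != y.any():
        return float("inf")
    bx = [tuple(p) for p in np.argwhere(boundary_loops(x))]
    by = [tuple(p) for p in np.argwhere(boundary_loops(y))]
    directed = []
    for p in bx:
        directed.append(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in by))
    for q in by:
        directed.append(min(np.hypot(p[0] - q[0], p[1] - q[1]) for p in bx))
    val = float(np.percentile(directed, 95))
    return val * spacing if spacing else val


def ece_loops(probs, truth, n_bins):
    """probs: (C, H, W) or (B, C, H, W); equal-width confidence bins."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 3:
        p = p[None]
        truth = np.asarray(truth)[None]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    conf_all, correct_all = [], []
    for b in range(p.shape[0]):
        for i in range(p.shape[2]):
            for j in range(p.shape[3]):
                vec = p[b, :, i, j]
                c = int(np.argmax(vec))
                conf_all.append(vec[c])
                correct_all.append(1.0 if c == truth[b][i, j] else 0.0)
    total = len(conf_all)
    val = 0.0
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        sel = [(cf, cr) for cf, cr in zip(conf_all, correct_all)
               if (lo <= cf < hi) or (k == n_bins - 1 and cf == hi)]
        if not sel:
            continue
        confs = [s[0] for s in sel]
        corrs = [s[1] for s in sel]
        val += (len(sel) / total) * abs(np.mean(corrs) - np.mean(confs))
    return val


def entropy_loops(probs):
    p = np.asarray(probs, dtype=np.float64)
    c, h, w = p.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for k in range(c):
                if p[k, i, j] > 0:
                    s -= p[k, i, j] * np.log(p[k, i, j])
            out[i, j] = s
    return out
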