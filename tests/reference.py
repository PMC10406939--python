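"""Independent straight-line reference implementations used as test oracles.

Everything here is deliberately written with explicit per-pixel loops and
scalar arithmetic, sharing no code with the package, so that agreement
with the vectorized implementations is meaningful.
"""

import math

import numpy as np


def pcnn_reference(stimulus, beta, v_e, alpha_e, alpha_f, v_f, alpha_l, v_l,
                   kernel, n_iter, feedback="full"):
    """Per-pixel PCNN dynamics: F, L, U, E updates and firing order.

    Per iteration n (1-based): F and L accumulate the kernel-weighted
    neighbour firings of the previous iteration (edge-replicated),
    U = F*(1+beta*L), the threshold decays by exp(-alpha_E) and jumps by
    V_E per previous firing, and Y fires on the strict inequality U > E.
    Returns the first-fire iteration map (0 = never fired).
    """
    s = np.asarray(stimulus, dtype=np.float64)
    h, w = s.shape
    df, dl, de = math.exp(-alpha_f), math.exp(-alpha_l), math.exp(-alpha_e)
    F = [[0.0] * w for _ in range(h)]
    L = [[0.0] * w for _ in range(h)]
    Y = [[0.0] * w for _ in range(h)]
    E = [[float(s.max())] * w for _ in range(h)]
    first = np.zeros((h, w), dtype=np.int64)

    for n in range(1, n_iter + 1):
        link = [[0.0] * w for _ in range(h)]
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        wt = kernel[dy + 1][dx + 1]
                        if wt != 0.0:
                            ii = min(max(i + dy, 0), h - 1)
                            jj = min(max(j + dx, 0), w - 1)
                            acc += wt * Y[ii][jj]
                link[i][j] = acc
        newY = [[0.0] * w for _ in range(h)]
        for i in range(h):
            for j in range(w):
                if feedback == "full":
                    F[i][j] = df * F[i][j] + v_f * link[i][j] + s[i, j]
                else:
                    F[i][j] = s[i, j]
                L[i][j] = dl * L[i][j] + v_l * link[i][j]
                U = F[i][j] * (1.0 + beta * L[i][j])
                E[i][j] = de * E[i][j] + v_e * Y[i][j]
                if U > E[i][j]:
                    newY[i][j] = 1.0
                    if first[i, j] == 0:
                        first[i, j] = n
        Y = newY
    return first


def confusion_reference(pred, ref):
    """Nested-loop confusion counts."""
    tp = fp = fn = tn = 0
    for p, r in zip(np.asarray(pred).ravel(), np.asarray(ref).ravel()):
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def mann_whitney_auc(probs, ref):
    """AUC as the normalized Mann-Whitney U statistic (tie-aware ranks)."""
    probs = np.asarray(probs, dtype=np.float64).ravel()
    ref = np.asarray(ref).ravel().astype(bool)
    from scipy.stats import rankdata

    ranks = rankdata(probs)
    n_pos = int(ref.sum())
    n_neg = ref.size - n_pos
    u = ranks[ref].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def grey_open_3x3_reference(img, i, j):
    """Opening value at (i, j) by direct min/max enumeration.

    Erosion and dilation are each computed on the image grid with
    edge-replicated borders: the erosion stage takes the 3x3 window
    minimum of the (replicated) image, and the dilation stage takes the
    maximum of the erosion over 3x3 window centers clamped to the grid.
    """
    img = np.asarray(img, dtype=np.int64)
    h, w = img.shape

    def at(y, x):
        return img[min(max(y, 0), h - 1), min(max(x, 0), w - 1)]

    def eroded(cy, cx):
        return min(at(cy + dy, cx + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1))

    best = None
    for cy in (i - 1, i, i + 1):
        for cx in (j - 1, j, j + 1):
            e = eroded(min(max(cy, 0), h - 1), min(max(cx, 0), w - 1))
            best = e if best is None else max(best, e)
    return best
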