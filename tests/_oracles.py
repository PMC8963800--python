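"""Independent reference implementations used as test oracles.

Everything here is written straight from the definitions, separately from
the library code paths: the eight Kirsch kernels are hard-coded literals,
the texture descriptor is a naive double loop, AUC is exhaustive pairwise
comparison, and the confusion tally is a plain Python loop.
"""

import numpy as np

# The eight 3x3 Kirsch kernels, written out by hand. Direction n points at
# ring neighbor n (clockwise from the top-left corner); the three +5 weights
# sit on neighbor n and its two ring-adjacent neighbors.
KIRSCH_MASKS = [
    np.array([[5, 5, -3], [5, 0, -3], [-3, -3, -3]]),    # n=0 top-left
    np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]]),    # n=1 top
    np.array([[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]]),    # n=2 top-right
    np.array([[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]]),    # n=3 right
    np.array([[-3, -3, -3], [-3, 0, 5], [-3, 5, 5]]),    # n=4 bottom-right
    np.array([[-3, -3, -3], [-3, 0, -3], [5, 5, 5]]),    # n=5 bottom
    np.array([[-3, -3, -3], [5, 0, -3], [5, 5, -3]]),    # n=6 bottom-left
    np.array([[5, -3, -3], [5, 0, -3], [5, -3, -3]]),    # n=7 left
]

# ring neighbor n -> (row, col) offset, clockwise from top-left
RING = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def naive_loop_code(patch):
    """Texture code of one 3x3 patch, straight from the formula."""
    patch = np.asarray(patch, dtype=float)
    responses = [float((mask * patch).sum()) for mask in KIRSCH_MASKS]
    # rank of |m_n|: largest magnitude -> exponent 7; ties -> smaller n wins
    by_magnitude = sorted(range(8), key=lambda n: (-abs(responses[n]), n))
    exponents = {}
    for rank, n in enumerate(by_magnitude):
        exponents[n] = 7 - rank
    center = patch[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(RING):
        if patch[1 + dr, 1 + dc] - center >= 0:
            code += 2 ** exponents[n]
    return code


def naive_loop_histogram(matrix):
    """Normalized 256-bin histogram via an explicit double loop."""
    matrix = np.asarray(matrix, dtype=float)
    rows, cols = matrix.shape
    counts = np.zeros(256)
    for r in range(1, rows - 1):
        for c in range(1, cols - 1):
            counts[naive_loop_code(matrix[r - 1 : r + 2, c - 1 : c + 2])] += 1
    return counts / counts.sum()


def pairwise_auc(y_true, scores):
    """AUC as exhaustive Mann-Whitney comparison; ties count one half."""
    pos = [s for yv, s in zip(y_true, scores) if yv == 1]
    neg = [s for yv, s in zip(y_true, scores) if yv == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def tally_confusion(y_true, y_pred):
    """(TP, FP, TN, FN) by plain counting."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
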