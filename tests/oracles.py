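"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most literal form of the underlying
definition (explicit threshold enumeration, all-pairs comparison, exhaustive
sign-flip enumeration), deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def average_precision_oracle(scores, labels) -> float:
    """Step-wise AP by explicit enumeration of every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    assert n_pos > 0
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & labels).sum())
        precision = tp / int(pred.sum())
        recall = tp / int(n_pos)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def auroc_oracle(scores, labels) -> float:
    """Mean over all positive x negative pairs of [s+ > s-] + 0.5 [s+ == s-]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    assert len(pos) and len(neg)
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def best_dice_oracle(scores, labels) -> float:
    """Dense maximum of Dice over all distinct score values plus {0, 1}."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    best = 0.0
    for t in set(scores) | {0.0, 1.0}:
        pred = scores >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        if 2 * tp + fp + fn > 0:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


def fleiss_kappa_oracle(category_counts: np.ndarray) -> float:
    """Direct evaluation of the Fleiss formula on an items x categories table."""
    counts = np.asarray(category_counts, dtype=float)
    n_items, _ = counts.shape
    n_raters = counts[0].sum()
    assert (counts.sum(axis=1) == n_raters).all()
    p_item = (np.sum(counts * (counts - 1), axis=1)) / (n_raters * (n_raters - 1))
    p_bar = p_item.mean()
    p_cat = counts.sum(axis=0) / (n_items * n_raters)
    p_e = np.sum(p_cat**2)
    return (p_bar - p_e) / (1 - p_e)


def _signed_rank_stat(diffs: np.ndarray) -> float:
    """W = min(sum of positive ranks, sum of negative ranks), mid-ranked ties."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    w_minus = ranks[diffs < 0].sum()
    return min(w_plus, w_minus)


def wilcoxon_exact_oracle(diffs) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    assert 1 <= n <= 20
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    total_rank = ranks.sum()
    observed = _signed_rank_stat(diffs)
    count = 0
    # enumerate assignments in blocks: bit j of k says whether diff j is positive
    for start in range(0, 2**n, 65536):
        ks = np.arange(start, min(start + 65536, 2**n), dtype=np.uint32)
        bits = (ks[:, None] >> np.arange(n)) & 1
        w_plus = bits @ ranks
        w_min = np.minimum(w_plus, total_rank - w_plus)
        count += int((w_min <= observed + 1e-9).sum())
    return min(1.0, count / 2.0**n)


def enumerate_origins_oracle(dim: int, size: int, stride: int) -> list[int]:
    """Window origins by literal scanning, including the border-snapped one."""
    origins = []
    pos = 0
    while pos + size <= dim:
        origins.append(pos)
        pos += stride
    if origins[-1] + size < dim:
        origins.append(dim - size)
    return origins


def coverage_map_oracle(height, width, tile_size, stride, prob_of_window):
    """Assemble the mean-aggregated cell map by independent nested loops.

    ``prob_of_window(row, col)`` gives the probability of the window with
    top-left corner (row, col).  A window contributes to a cell iff the
    cell's (possibly truncated) pixel block lies entirely inside the window.
    """
    n_rows = -(-height // stride)
    n_cols = -(-width // stride)
    values = np.zeros((n_rows, n_cols))
    counts = np.zeros((n_rows, n_cols), dtype=int)
    windows = [
        (r, c)
        for r in enumerate_origins_oracle(height, tile_size, stride)
        for c in enumerate_origins_oracle(width, tile_size, stride)
    ]
    for cr in range(n_rows):
        for cc in range(n_cols):
            r0, r1 = cr * stride, min((cr + 1) * stride, height)
            c0, c1 = cc * stride, min((cc + 1) * stride, width)
            for wr, wc in windows:
                if wr <= r0 and r1 <= wr + tile_size and wc <= c0 and c1 <= wc + tile_size:
                    values[cr, cc] += prob_of_window(wr, wc)
                    counts[cr, cc] += 1
    return values / np.maximum(counts, 1), counts
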