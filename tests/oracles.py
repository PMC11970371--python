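"""Independent oracles used by the tests.

These deliberately avoid the package's forward-algorithm and sklearn code
paths: the chain LLR is recomputed by exhaustively enumerating every hidden
state path, and average precision by a direct by-rank formula.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from haploscreen.core import MISSING, MarkerPanel, HMMParams
from haploscreen.hmm import _chain_sequence, transition_probs


def enumerate_chain_llr(
    disease_alleles: np.ndarray,
    hapA: np.ndarray,
    hapB: np.ndarray,
    panel: MarkerPanel,
    params: HMMParams,
    direction: str,
    include_origin: bool,
) -> float:
    """ln L1 - ln L0 by summing over all 3^T hidden-state paths."""
    seq = _chain_sequence(panel, direction, include_origin)
    seq = np.array(
        [
            m
            for m in seq
            if disease_alleles[m] != MISSING
            and (hapA[m] != MISSING or hapB[m] != MISSING)
        ],
        dtype=int,
    )
    T = seq.size
    if T == 0:
        return 0.0
    g = params.g
    f = panel.alt_freq
    cm, bp = panel.cm, panel.pos_bp.astype(float)
    dcv = panel.dcv_index

    log_emit = np.empty((T, 3))
    log_kern = np.empty((T, 3, 3))
    log_nullA = np.zeros(T)
    log_nullB = np.zeros(T)
    prev = dcv
    for t, m in enumerate(seq):
        a, b, d, fm = int(hapA[m]), int(hapB[m]), int(disease_alleles[m]), f[m]
        fa = fm if a == 1 else 1.0 - fm
        fb = fm if b == 1 else 1.0 - fm
        eA = 1.0 if a == MISSING else ((1.0 - g) if a == d else g)
        eB = 1.0 if b == MISSING else ((1.0 - g) if b == d else g)
        if a != MISSING and b != MISSING:
            eN = 0.5 * (fa + fb)
        else:
            eN = fa if a != MISSING else fb
        log_emit[t] = np.log([eA, eB, eN])
        log_nullA[t] = 0.0 if a == MISSING else np.log(fa)
        log_nullB[t] = 0.0 if b == MISSING else np.log(fb)
        with np.errstate(divide="ignore"):
            log_kern[t] = np.log(
                transition_probs(
                    abs(cm[m] - cm[prev]) / 100.0, abs(bp[m] - bp[prev]), params
                )
            )
        prev = m

    n_paths = 3**T
    digits = (np.arange(n_paths)[:, None] // (3 ** np.arange(T))[None, :]) % 3
    # start-state mass split over IBD_A / IBD_B
    w = np.full(n_paths, -np.inf)
    for s0 in (0, 1):
        w = np.logaddexp(w, np.log(0.5) + log_kern[0][s0, digits[:, 0]])
    for t in range(1, T):
        w = w + log_kern[t][digits[:, t - 1], digits[:, t]]
    w = w + log_emit[np.arange(T)[None, :], digits].sum(axis=1)
    logL1 = float(logsumexp(w))
    logL0 = float(np.logaddexp(log_nullA.sum(), log_nullB.sum()) - np.log(2.0))
    return logL1 - logL0


def average_precision_by_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP as the mean of precision at each positive, scanning ranks.

    Equivalent to step-wise interpolation of the PR curve; ties are handled
    by sweeping distinct score thresholds, never trapezoidal over precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    ap = 0.0
    prev_recall = 0.0
    for thr in np.sort(np.unique(scores))[::-1]:
        sel = scores >= thr
        tp = int((labels & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
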