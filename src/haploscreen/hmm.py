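"""IBD scoring model: log-likelihood ratio of IBD vs non-IBD around a DCV.

The statistic (the *IBD score*) is ln(L1/L0) for a disease haplotype tested
against an individual's two phased haplotypes. Two Markov chains start at the
marker nearest the DCV ("marker 0") and extend outwards in opposite
directions, because the boundaries of the shared segment are unknown.

Hidden states of the alternative model (H1):

``IBD_A`` / ``IBD_B``
    the disease haplotype is identical by descent with test haplotype A / B
    at the current marker; the chain tracks that haplotype's allele, which
    matches the disease allele with probability 1 - g (g absorbs genotype
    and imputation error).
``nonIBD``
    sharing has ended; absorbing, since the IBD segment containing the DCV
    is contiguous. The emission marginalizes over which haplotype is read,
    i.e. the mean population frequency of the two observed alleles.

Transitions over an interval of ``d`` Morgans and ``b`` bp:
IBD survives with probability exp(-decay_meioses * d); conditional on
survival the chain hops to the other test haplotype with probability
s = min(1, switch_rate_per_bp * b), absorbing block phase-switch errors.

The null model (H0) is random sharing: the mean over the two test
haplotypes of the product of the population frequencies of their observed
alleles, so both hypotheses condition on the same observations.

Transitions are applied between consecutive *informative* markers (distance
accumulates over skipped ones), which makes skipping a marker exactly
equivalent to deleting it from the panel.

A chain ends at the first marker where the cumulative LLR falls
``drop_threshold`` ln-units below its running maximum — the operational
reading of "sharing has stopped" that tolerates isolated errors — and its
value is that running maximum. The score of a pair is the sum of the left
and right chain values; the DCV marker itself is counted by the right chain
only. The score against a set of disease haplotypes is the maximum over the
set. No linkage disequilibrium is modelled: target IBD segments are longer
than LD blocks.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    DiseaseHaplotype,
    HMMParams,
    MarkerPanel,
    PhasedCohort,
    ScoreRecord,
)

__all__ = [
    "emission_prob",
    "transition_probs",
    "chain_llr",
    "ChainResult",
    "score_pair",
    "score_against_set",
    "score_matrix",
    "score_cohort",
]

_LN2 = np.log(2.0)


def emission_prob(disease_allele, test_allele, alt_freq, g, state) -> float:
    """Per-marker emission probability of the observed test allele.

    ``state`` is "IBD" or "nonIBD". Under IBD the test allele copies the
    disease allele up to error rate ``g``; under nonIBD it is an independent
    population draw, so the emission is the frequency of the observed allele
    and the disease allele is irrelevant.
    """
    if disease_allele not in (0, 1) or test_allele not in (0, 1):
        raise ValueError("emission_prob requires non-missing alleles")
    if not (0.0 < alt_freq < 1.0):
        raise ValueError("alt_freq must lie strictly in (0, 1)")
    if state == "IBD":
        return 1.0 - g if disease_allele == test_allele else g
    if state == "nonIBD":
        return alt_freq if test_allele == 1 else 1.0 - alt_freq
    raise ValueError(f"unknown state {state!r}")


def transition_probs(
    delta_morgans: float, delta_bp: float, params: HMMParams
) -> np.ndarray:
    """3x3 transition kernel over (IBD_A, IBD_B, nonIBD) for one interval."""
    if delta_morgans < 0 or delta_bp < 0:
        raise ValueError("distances must be non-negative")
    decay = np.exp(-params.decay_meioses * delta_morgans)
    s = min(1.0, params.switch_rate_per_bp * delta_bp)
    return np.array(
        [
            [decay * (1 - s), decay * s, 1 - decay],
            [decay * s, decay * (1 - s), 1 - decay],
            [0.0, 0.0, 1.0],
        ]
    )


def _chain_sequence(
    panel: MarkerPanel, direction: str, include_origin: bool
) -> np.ndarray:
    dcv = panel.dcv_index
    if dcv is None:
        raise ValueError("panel has no DCV index; call set_dcv/trim_panel first")
    if direction == "right":
        start = dcv if include_origin else dcv + 1
        return np.arange(start, len(panel))
    if direction == "left":
        start = dcv if include_origin else dcv - 1
        return np.arange(start, -1, -1)
    raise ValueError("direction must be 'left' or 'right'")


def _chain_scores(
    d_alleles: np.ndarray,
    hapA: np.ndarray,
    hapB: np.ndarray,
    panel: MarkerPanel,
    params: HMMParams,
    direction: str,
    include_origin: bool,
    drop_threshold: float | None = None,
    collect_trajectory: bool = False,
):
    """Vectorized directional chain over N individuals.

    Returns (score, end_index, n_emitted[, trajectory, marker_sequence]).
    """
    panel.require_frequencies()
    if d_alleles[panel.dcv_index] == MISSING:
        raise ValueError("disease haplotype is missing at the DCV marker")
    seq = _chain_sequence(panel, direction, include_origin)
    seq = seq[d_alleles[seq] != MISSING]
    N = hapA.shape[0]
    dcv = panel.dcv_index
    score = np.zeros(N)
    end = np.full(N, dcv, dtype=np.int64)
    emitted = np.zeros(N, dtype=np.int64)
    if seq.size == 0:
        if collect_trajectory:
            return score, end, emitted, np.empty((N, 0)), seq
        return score, end, emitted

    g = params.g
    k = params.decay_meioses
    r = params.switch_rate_per_bp
    drop = params.drop_threshold if drop_threshold is None else drop_threshold

    cm = panel.cm
    bp = panel.pos_bp.astype(np.float64)
    freq = panel.alt_freq

    prev_cm = np.full(N, cm[dcv])
    prev_bp = np.full(N, bp[dcv])
    aA = np.full(N, 0.5)
    aB = np.full(N, 0.5)
    aN = np.zeros(N)
    logL1 = np.zeros(N)
    SA = np.zeros(N)
    SB = np.zeros(N)
    runmax = np.full(N, -np.inf)
    terminated = np.zeros(N, dtype=bool)
    llr_prev = np.zeros(N)
    traj = np.empty((N, seq.size)) if collect_trajectory else None

    for t, m in enumerate(seq):
        a = hapA[:, m]
        b = hapB[:, m]
        use = ((a != MISSING) | (b != MISSING)) & ~terminated
        if not use.any():
            if collect_trajectory:
                traj[:, t] = llr_prev
            continue
        d = int(d_alleles[m])
        fm = freq[m]

        dm = np.abs(cm[m] - prev_cm) / 100.0  # Morgans
        db = np.abs(bp[m] - prev_bp)
        decay = np.exp(-k * dm)
        s = np.minimum(1.0, r * db)

        tA = decay * ((1.0 - s) * aA + s * aB)
        tB = decay * (s * aA + (1.0 - s) * aB)
        tN = (1.0 - decay) * (aA + aB) + aN

        eA = np.where(a == MISSING, 1.0, np.where(a == d, 1.0 - g, g))
        eB = np.where(b == MISSING, 1.0, np.where(b == d, 1.0 - g, g))
        fa = np.where(a == 1, fm, 1.0 - fm)
        fb = np.where(b == 1, fm, 1.0 - fm)
        both = (a != MISSING) & (b != MISSING)
        eN = np.where(both, 0.5 * (fa + fb), np.where(a != MISSING, fa, fb))

        nA = tA * eA
        nB = tB * eB
        nN = tN * eN
        norm = nA + nB + nN

        aA = np.where(use, nA / norm, aA)
        aB = np.where(use, nB / norm, aB)
        aN = np.where(use, nN / norm, aN)
        logL1 = np.where(use, logL1 + np.log(norm), logL1)
        SA = np.where(use, SA + np.log(np.where(a == MISSING, 1.0, fa)), SA)
        SB = np.where(use, SB + np.log(np.where(b == MISSING, 1.0, fb)), SB)
        prev_cm = np.where(use, cm[m], prev_cm)
        prev_bp = np.where(use, bp[m], prev_bp)
        emitted += use

        llr = np.where(use, logL1 - (np.logaddexp(SA, SB) - _LN2), llr_prev)
        if collect_trajectory:
            traj[:, t] = llr
        improved = use & (llr > runmax)
        runmax = np.where(improved, llr, runmax)
        end = np.where(improved, m, end)
        terminated |= use & (llr < runmax - drop)
        llr_prev = llr
        if terminated.all():
            if collect_trajectory:
                traj[:, t + 1 :] = llr_prev[:, None]
            break

    score = np.where(emitted > 0, runmax, 0.0)
    end = np.where(emitted > 0, end, dcv)
    if collect_trajectory:
        return score, end, emitted, traj, seq
    return score, end, emitted


class ChainResult(NamedTuple):
    llr: float
    end_index: int
    n_markers_used: int
    trajectory: np.ndarray | None = None
    marker_sequence: np.ndarray | None = None


def chain_llr(
    disease: DiseaseHaplotype,
    hapA: np.ndarray,
    hapB: np.ndarray,
    panel: MarkerPanel,
    direction: str,
    params: HMMParams,
    include_origin: bool | None = None,
    drop_threshold: float | None = None,
    return_trajectory: bool = False,
) -> ChainResult:
    """One directional chain for a single (disease haplotype, individual) pair.

    ``include_origin`` defaults to True for the right chain and False for the
    left chain, so that the DCV marker is counted exactly once by
    :func:`score_pair`. With ``return_trajectory`` the cumulative LLR after
    each informative marker is also returned (used by exhaustive-enumeration
    cross-checks).
    """
    disease.validate_on(panel)
    if include_origin is None:
        include_origin = direction == "right"
    A = np.asarray(hapA, dtype=np.int8)[None, :]
    B = np.asarray(hapB, dtype=np.int8)[None, :]
    out = _chain_scores(
        disease.alleles,
        A,
        B,
        panel,
        params,
        direction,
        include_origin,
        drop_threshold=drop_threshold,
        collect_trajectory=return_trajectory,
    )
    if return_trajectory:
        score, endi, emitted, traj, seq = out
        return ChainResult(
            float(score[0]), int(endi[0]), int(emitted[0]), traj[0], seq
        )
    score, endi, emitted = out
    return ChainResult(float(score[0]), int(endi[0]), int(emitted[0]))


def score_pair(
    disease: DiseaseHaplotype,
    hapA: np.ndarray,
    hapB: np.ndarray,
    panel: MarkerPanel,
    params: HMMParams,
    individual_id: str = "",
) -> ScoreRecord:
    """IBD score of one individual against one disease haplotype.

    Sum of the left and right chain values; the DCV marker belongs to the
    right chain.
    """
    left = chain_llr(disease, hapA, hapB, panel, "left", params)
    right = chain_llr(disease, hapA, hapB, panel, "right", params)
    return ScoreRecord(
        individual_id=individual_id,
        hap_id=disease.hap_id,
        ibd_score=left.llr + right.llr,
        left_end_index=left.end_index,
        right_end_index=right.end_index,
        n_markers_used=left.n_markers_used + right.n_markers_used,
    )


def score_against_set(
    disease_haps: Sequence[DiseaseHaplotype],
    hapA: np.ndarray,
    hapB: np.ndarray,
    panel: MarkerPanel,
    params: HMMParams,
    individual_id: str = "",
) -> ScoreRecord:
    """Best IBD score over a set of disease haplotypes for one variant.

    Ties are broken toward the lexicographically smallest hap_id.
    """
    if not disease_haps:
        raise ValueError("empty disease-haplotype set")
    best: ScoreRecord | None = None
    for hap in sorted(disease_haps, key=lambda h: h.hap_id):
        rec = score_pair(hap, hapA, hapB, panel, params, individual_id)
        if best is None or rec.ibd_score > best.ibd_score:
            best = rec
    return best


def score_matrix(
    disease_haps: Sequence[DiseaseHaplotype],
    cohort: PhasedCohort,
    panel: MarkerPanel,
    params: HMMParams,
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Scores for every (disease haplotype, individual) pair.

    Returns a DataFrame indexed by hap_id with one column per individual.
    Work may be chunked over individuals (``chunk_size``); results are
    independent of the chunking because every pair is scored in isolation.
    """
    if not disease_haps:
        raise ValueError("empty disease-haplotype set")
    haps = sorted(disease_haps, key=lambda h: h.hap_id)
    N = cohort.n_individuals
    chunk = N if chunk_size is None else max(1, int(chunk_size))
    mat = np.empty((len(haps), N))
    for hi, hap in enumerate(haps):
        hap.validate_on(panel)
        for start in range(0, N, chunk):
            sl = slice(start, min(start + chunk, N))
            A = cohort.alleles[sl, 0, :]
            B = cohort.alleles[sl, 1, :]
            l_score, _, _ = _chain_scores(
                hap.alleles, A, B, panel, params, "left", False
            )
            r_score, _, _ = _chain_scores(
                hap.alleles, A, B, panel, params, "right", True
            )
            mat[hi, sl] = l_score + r_score
    return pd.DataFrame(
        mat, index=[h.hap_id for h in haps], columns=cohort.individual_ids
    )


def score_cohort(
    disease_haps: Sequence[DiseaseHaplotype],
    cohort: PhasedCohort,
    panel: MarkerPanel,
    params: HMMParams,
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Per-individual best score over the disease-haplotype set.

    Returns a DataFrame with columns individual_id, hap_id (best haplotype,
    ties to the smallest hap_id), ibd_score.
    """
    mat = score_matrix(disease_haps, cohort, panel, params, chunk_size)
    best_pos = np.argmax(mat.to_numpy(), axis=0)  # first occurrence: lowest id
    return pd.DataFrame(
        {
            "individual_id": mat.columns,
            "hap_id": mat.index.to_numpy()[best_pos],
            "ibd_score": mat.to_numpy()[best_pos, np.arange(mat.shape[1])],
        }
    )
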