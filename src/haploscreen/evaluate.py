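"""Evaluation against simulation truth: sensitivity, FPR, PR curves, grids.

AUPRC is computed as average precision (step-wise interpolation), which is
the appropriate summary for heavily imbalanced carrier screens; a random
classifier's AUPRC converges to the baseline rate (positives / cohort
size). Two sensitivity definitions are reported in by-haplotype-count
analyses: *ancestor-aware* counts only cases that share a founder with the
disease haplotypes in use, while *all-case* counts every simulated case.
With the full haplotype set the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .core import HMMParams, MarkerPanel, PhasedCohort
from .hmm import score_matrix
from .null import NullDistribution, critical_value
from .simulate import ScenarioSpec, TruthTable, run_scenario

__all__ = ["EvalSummary", "confusion", "pr_curve", "run_grid"]


@dataclass
class EvalSummary:
    """Metrics for one simulated scenario at one critical value."""

    locus_id: str
    founder_mode: str
    sharing_length_cm: float
    rng_seed: int
    n_cases: int
    n_controls: int
    sensitivity: float
    fpr: float
    auprc: float
    baseline_rate: float
    threshold: float
    percentile: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fpr", "auprc", "baseline_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) and not np.isnan(v):
                raise ValueError(f"{name}={v} outside [0, 1]")


def confusion(calls: pd.DataFrame, truth: TruthTable) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) for boolean ``call`` against the truth table."""
    c = calls.set_index("individual_id")["call"]
    t = truth.table.set_index("individual_id")["is_case"]
    if set(c.index) != set(t.index):
        raise ValueError("calls and truth cover different individuals")
    c = c.reindex(t.index)
    tp = int((c & t).sum())
    fp = int((c & ~t).sum())
    tn = int((~c & ~t).sum())
    fn = int((~c & t).sum())
    return tp, fp, tn, fn


def pr_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall over all thresholds plus AUPRC (average precision)."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("AUPRC undefined with zero cases")
    precision, recall, _ = precision_recall_curve(labels, scores)
    auprc = float(average_precision_score(labels, scores))
    return precision, recall, auprc


def _sensitivity(scores, is_case, source_hap, threshold, haps_in_use, mode):
    called = scores > threshold
    if mode == "all":
        denom_mask = is_case
    else:  # ancestor-aware
        denom_mask = is_case & np.isin(source_hap, list(haps_in_use))
    denom = int(denom_mask.sum())
    if denom == 0:
        return float("nan")
    return float((called & denom_mask).sum() / denom)


def run_grid(
    scenarios: Sequence[ScenarioSpec],
    cohort: PhasedCohort,
    panel: MarkerPanel,
    params: HMMParams,
    percentile: float = 99.0,
    control_cohort: PhasedCohort | None = None,
    chunk_size: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and evaluate every scenario at the control critical value.

    For each scenario the disease haplotypes are derived, cases implanted
    and errors injected via :func:`run_scenario`; every disease-test pair is
    scored, the per-individual maximum is compared with the
    ``percentile``-critical value of the control cohort (the base cohort
    minus that scenario's donors, unmodified, scored against the identical
    haplotype set), and the summary metrics recorded. A second table
    reports sensitivity and AUPRC as a function of the number of disease
    haplotypes in use (nested prefix subsets, threshold recomputed per
    subset). Scoring may be chunked; all outputs are independent of
    execution order.
    """
    summaries: list[dict] = []
    by_nhaps: list[dict] = []
    for spec in scenarios:
        test, haps, truth = run_scenario(spec, cohort, panel)
        ctrl = (
            control_cohort
            if control_cohort is not None
            else cohort.drop(set(cohort.individual_ids) - set(test.individual_ids))
        )
        test_mat = score_matrix(haps, test, panel, params, chunk_size)
        ctrl_mat = score_matrix(haps, ctrl, panel, params, chunk_size)

        is_case = truth.table["is_case"].to_numpy()
        source = truth.table["source_hap_id"].to_numpy()
        hap_ids = list(test_mat.index)

        for k in range(1, len(hap_ids) + 1):
            in_use = hap_ids[:k]
            t_scores = test_mat.iloc[:k].to_numpy().max(axis=0)
            c_scores = ctrl_mat.iloc[:k].to_numpy().max(axis=0)
            nd = NullDistribution(
                spec.locus_id, list(ctrl_mat.columns), c_scores,
                panel_fingerprint=panel.fingerprint(),
            )
            thr = critical_value(nd, percentile)
            ancestor_in_use = (
                hap_ids if spec.founder_mode == "single" else in_use
            )
            _, _, auprc_k = pr_curve(t_scores, is_case)
            row = {
                "locus_id": spec.locus_id,
                "founder_mode": spec.founder_mode,
                "sharing_length_cm": spec.sharing_length_cm,
                "rng_seed": spec.rng_seed,
                "n_haps_used": k,
                "sensitivity": _sensitivity(
                    t_scores, is_case, source, thr, ancestor_in_use, "ancestor"
                ),
                "sensitivity_all": _sensitivity(
                    t_scores, is_case, source, thr, in_use, "all"
                ),
                "auprc": auprc_k,
                "threshold": thr,
            }
            by_nhaps.append(row)
            if k == len(hap_ids):
                called = t_scores > thr
                n_cases = int(is_case.sum())
                n_controls = int((~is_case).sum())
                fp = int((called & ~is_case).sum())
                summaries.append(
                    asdict(
                        EvalSummary(
                            locus_id=spec.locus_id,
                            founder_mode=spec.founder_mode,
                            sharing_length_cm=spec.sharing_length_cm,
                            rng_seed=spec.rng_seed,
                            n_cases=n_cases,
                            n_controls=n_controls,
                            sensitivity=row["sensitivity"],
                            fpr=fp / n_controls if n_controls else float("nan"),
                            auprc=auprc_k,
                            baseline_rate=n_cases / (n_cases + n_controls),
                            threshold=thr,
                            percentile=percentile,
                        )
                    )
                )
    return pd.DataFrame(summaries), pd.DataFrame(by_nhaps)
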