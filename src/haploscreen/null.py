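"""Empirical null calibration of IBD scores against a control cohort.

Under the null the LLR statistic is asymptotically chi-square, but local LD
makes control scores deviate from that distribution, so significance is
assessed empirically: the critical value is an order statistic of control
scores and p-values are add-one exceedance fractions. Controls must be
scored against the identical disease-haplotype set and marker panel as the
test cohort (the null is LD- and panel-specific), which is enforced via a
panel fingerprint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NullDistribution",
    "critical_value",
    "empirical_p",
    "call_carriers",
    "top_n",
]


@dataclass
class NullDistribution:
    """Per-control best IBD scores for one variant's disease-haplotype set."""

    variant_id: str
    control_ids: list
    control_scores: np.ndarray
    panel_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.control_scores = np.asarray(self.control_scores, dtype=np.float64)
        if self.control_scores.ndim != 1:
            raise ValueError("control_scores must be 1-D")
        if len(self.control_ids) != self.control_scores.size:
            raise ValueError("control_ids length does not match scores")
        if not np.all(np.isfinite(self.control_scores)):
            raise ValueError("control scores must be finite")
        if self.n_controls < 100:
            warnings.warn(
                f"only {self.n_controls} controls; the 99th percentile "
                "critical value is unstable below ~100",
                stacklevel=2,
            )

    @property
    def n_controls(self) -> int:
        return int(self.control_scores.size)

    def check_panel(self, fingerprint: str) -> None:
        if self.panel_fingerprint is not None and fingerprint != self.panel_fingerprint:
            raise ValueError(
                "null distribution was computed on a different marker panel; "
                "refusing to mix panels"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.control_ids,
                "variant_id": self.variant_id,
                "ibd_score": self.control_scores,
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            if self.panel_fingerprint:
                fh.write(f"#panel_fingerprint={self.panel_fingerprint}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "NullDistribution":
        fingerprint = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#panel_fingerprint="):
                fingerprint = first.strip().split("=", 1)[1]
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        variant = str(df["variant_id"].iloc[0]) if len(df) else ""
        return cls(
            variant_id=variant,
            control_ids=df["individual_id"].astype(str).tolist(),
            control_scores=df["ibd_score"].to_numpy(),
            panel_fingerprint=fingerprint,
        )


def critical_value(null: NullDistribution, percentile: float = 99.0) -> float:
    """Conservative percentile threshold of the control-score null.

    Returns the ceil(percentile/100 * n)-th order statistic (no
    interpolation), so the fraction of controls strictly above it is at most
    1 - percentile/100 by construction.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    n = null.n_controls
    if n == 0:
        raise ValueError("empty null distribution")
    k = math.ceil(percentile / 100.0 * n)  # 1-based order statistic
    return float(np.sort(null.control_scores)[k - 1])


def empirical_p(score: float, null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{controls >= score}) / (n + 1)."""
    n = null.n_controls
    return float((1 + np.count_nonzero(null.control_scores >= score)) / (n + 1))


def call_carriers(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag individuals whose best score strictly exceeds ``threshold``.

    ``scores`` needs columns individual_id and ibd_score. Returns the table
    with ``call`` and ``rank`` columns, ordered by descending score with ties
    broken by individual_id.
    """
    out = scores.copy()
    out = out.sort_values(
        ["ibd_score", "individual_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["call"] = out["ibd_score"] > threshold
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_n(scores: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` highest-scoring individuals; ties broken by individual_id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = scores.sort_values(
        ["ibd_score", "individual_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if n > len(ranked):
        warnings.warn(
            f"top_n: n={n} exceeds cohort size {len(ranked)}; returning everyone",
            stacklevel=2,
        )
        return ranked
    return ranked.head(n)
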