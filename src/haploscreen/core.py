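"""Core domain types: markers, genetic maps, phased cohorts, model parameters.

Coordinate conventions follow VCF: physical positions are 1-based base pairs.
Genetic positions are centiMorgans (cM); likelihood arithmetic uses Morgans.
A :class:`MarkerPanel` is always a single-chromosome window trimmed around one
disease-causing variant (DCV); the marker nearest the DCV is "marker 0", the
origin from which the two scoring chains extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import hashlib

import numpy as np

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "Marker",
    "GeneticMap",
    "MarkerPanel",
    "PhasedCohort",
    "DiseaseHaplotype",
    "HMMParams",
    "ScoreRecord",
    "interpolate_cm",
    "trim_panel",
    "window_mask",
    "slice_cohort",
]


@dataclass(frozen=True)
class Marker:
    """A single biallelic SNP marker."""

    chrom: str
    pos_bp: int
    cm: float
    ref_allele: str
    alt_allele: str
    alt_freq: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alt_freq < 1.0):
            raise ValueError(
                f"marker {self.chrom}:{self.pos_bp} has alt_freq={self.alt_freq}; "
                "frequencies must lie strictly in (0, 1)"
            )


class GeneticMap:
    """Piecewise-linear bp -> cM map from (pos_bp, cM) anchor points."""

    def __init__(self, chrom: str, pos_bp, cm):
        pos_bp = np.asarray(pos_bp, dtype=np.int64)
        cm = np.asarray(cm, dtype=np.float64)
        if pos_bp.ndim != 1 or pos_bp.shape != cm.shape or pos_bp.size < 2:
            raise ValueError("genetic map needs >= 2 (pos_bp, cm) anchor pairs")
        if np.any(np.diff(pos_bp) <= 0):
            raise ValueError("genetic map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic map cM must be non-decreasing")
        self.chrom = chrom
        self.pos_bp = pos_bp
        self.cm = cm

    def interpolate(self, pos_bp):
        """cM at ``pos_bp`` (scalar or array); exact at anchors."""
        pos = np.asarray(pos_bp)
        lo, hi = self.pos_bp[0], self.pos_bp[-1]
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(
                f"position outside genetic-map range for {self.chrom}: "
                f"[{lo}, {hi}] bp"
            )
        out = np.interp(pos, self.pos_bp, self.cm)
        return float(out) if np.isscalar(pos_bp) else out


def interpolate_cm(gmap: GeneticMap, pos_bp) -> float:
    """Genetic position (cM) of ``pos_bp`` by linear interpolation."""
    return gmap.interpolate(pos_bp)


class MarkerPanel:
    """Ordered biallelic markers on one chromosome around a DCV.

    Backed by parallel arrays for speed; ``dcv_index`` marks the marker
    nearest the DCV locus (ties resolved toward the lower index).
    ``alt_freq`` may contain NaN on a freshly loaded skeleton; frequencies
    must be attached (and validated) before scoring.
    """

    def __init__(
        self,
        chrom: str,
        pos_bp,
        cm,
        ref,
        alt,
        alt_freq,
        dcv_pos_bp: int | None = None,
        impute_r2=None,
    ):
        self.chrom = str(chrom)
        self.pos_bp = np.asarray(pos_bp, dtype=np.int64)
        self.cm = np.asarray(cm, dtype=np.float64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.alt_freq = np.asarray(alt_freq, dtype=np.float64)
        self.impute_r2 = (
            None if impute_r2 is None else np.asarray(impute_r2, dtype=np.float64)
        )
        n = self.pos_bp.size
        for name in ("cm", "ref", "alt", "alt_freq"):
            if getattr(self, name).size != n:
                raise ValueError(f"panel field {name} length mismatch")
        if n == 0:
            raise ValueError("empty marker panel")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("panel pos_bp must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("panel cM must be non-decreasing")
        known = ~np.isnan(self.alt_freq)
        if np.any((self.alt_freq[known] <= 0) | (self.alt_freq[known] >= 1)):
            raise ValueError("alt_freq values must lie strictly in (0, 1)")
        self.dcv_pos_bp = None
        self.dcv_index = None
        if dcv_pos_bp is not None:
            self.set_dcv(int(dcv_pos_bp))

    def __len__(self) -> int:
        return int(self.pos_bp.size)

    def marker(self, i: int) -> Marker:
        return Marker(
            self.chrom,
            int(self.pos_bp[i]),
            float(self.cm[i]),
            str(self.ref[i]),
            str(self.alt[i]),
            float(self.alt_freq[i]),
        )

    def nearest_index(self, pos_bp: int) -> int:
        """Index of the marker nearest ``pos_bp``; ties go to the lower index."""
        j = int(np.searchsorted(self.pos_bp, pos_bp))
        if j == 0:
            return 0
        if j >= len(self):
            return len(self) - 1
        d_lo = pos_bp - int(self.pos_bp[j - 1])
        d_hi = int(self.pos_bp[j]) - pos_bp
        return j - 1 if d_lo <= d_hi else j

    def set_dcv(self, dcv_pos_bp: int) -> None:
        self.dcv_pos_bp = int(dcv_pos_bp)
        self.dcv_index = self.nearest_index(self.dcv_pos_bp)

    def subset(self, mask_or_index) -> "MarkerPanel":
        idx = np.asarray(mask_or_index)
        return MarkerPanel(
            self.chrom,
            self.pos_bp[idx],
            self.cm[idx],
            self.ref[idx],
            self.alt[idx],
            self.alt_freq[idx],
            dcv_pos_bp=self.dcv_pos_bp,
            impute_r2=None if self.impute_r2 is None else self.impute_r2[idx],
        )

    def fingerprint(self) -> str:
        """Stable hash of marker identities; used to refuse mixing panels."""
        h = hashlib.sha256()
        h.update(self.chrom.encode())
        h.update(self.pos_bp.tobytes())
        h.update("".join(map(str, self.ref)).encode())
        h.update("".join(map(str, self.alt)).encode())
        return h.hexdigest()[:16]

    def require_frequencies(self) -> None:
        if np.any(np.isnan(self.alt_freq)):
            raise ValueError(
                "panel has markers without alt_freq; attach frequencies first"
            )


class PhasedCohort:
    """Phased haplotype pairs for a set of individuals over one panel.

    ``alleles`` has shape (n_individuals, 2, n_markers) with entries in
    {0, 1, MISSING(-1)}.
    """

    def __init__(self, individual_ids, alleles):
        self.individual_ids = list(map(str, individual_ids))
        self.alleles = np.asarray(alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("alleles must have shape (n_individuals, 2, n_markers)")
        if self.alleles.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length does not match alleles")
        if not np.all(np.isin(self.alleles, [-1, 0, 1])):
            raise ValueError("alleles must be 0, 1 or MISSING (-1)")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def copy(self) -> "PhasedCohort":
        return PhasedCohort(list(self.individual_ids), self.alleles.copy())

    def drop(self, ids) -> "PhasedCohort":
        ids = set(map(str, ids))
        keep = [i for i, x in enumerate(self.individual_ids) if x not in ids]
        return PhasedCohort(
            [self.individual_ids[i] for i in keep], self.alleles[keep]
        )


@dataclass
class DiseaseHaplotype:
    """A pedigree-phased haplotype known to carry the DCV."""

    hap_id: str
    variant_id: str
    alleles: np.ndarray  # (n_markers,) int8 in {0,1,MISSING}
    dcv_chrom: str
    dcv_pos_bp: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 1:
            raise ValueError("disease haplotype alleles must be 1-D")

    def validate_on(self, panel: MarkerPanel) -> None:
        if self.alleles.size != len(panel):
            raise ValueError(
                f"disease haplotype {self.hap_id} has {self.alleles.size} markers; "
                f"panel has {len(panel)}"
            )
        if panel.dcv_index is None:
            raise ValueError("panel has no DCV index set")
        if self.alleles[panel.dcv_index] == MISSING:
            raise ValueError(
                f"disease haplotype {self.hap_id} is missing at the DCV marker"
            )


@dataclass(frozen=True)
class HMMParams:
    """Tunable parameters of the IBD scoring model.

    g
        Combined genotype + imputation error rate per allele (default 1%).
    decay_meioses
        Expected meioses separating the test and disease haplotypes from
        their common founder; the probability that IBD survives an interval
        of ``d`` Morgans is exp(-decay_meioses * d).
    switch_rate_per_bp
        Prior rate of phase-switch errors along the chromosome; default one
        switch per 20.05 Mbp, matching rates observed for statistical phasing.
    drop_threshold
        A chain terminates once its cumulative log-likelihood ratio falls
        this many ln-units below its running maximum.
    """

    g: float = 0.01
    decay_meioses: float = 20.0
    switch_rate_per_bp: float = 1.0 / 20.05e6
    drop_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.g < 0.5):
            raise ValueError("g must lie in (0, 0.5)")
        if self.decay_meioses <= 0:
            raise ValueError("decay_meioses must be positive")
        if self.switch_rate_per_bp < 0:
            raise ValueError("switch_rate_per_bp must be non-negative")
        if self.drop_threshold <= 0:
            raise ValueError("drop_threshold must be positive")


@dataclass
class ScoreRecord:
    """Per (disease haplotype, test individual) IBD score."""

    individual_id: str
    hap_id: str
    ibd_score: float
    left_end_index: int
    right_end_index: int
    n_markers_used: int

    def __post_init__(self) -> None:
        if self.left_end_index > self.right_end_index:
            raise ValueError("left_end_index must be <= right_end_index")


def window_mask(panel: MarkerPanel, dcv_pos_bp: int, flank_cm: float) -> np.ndarray:
    """Boolean mask of markers with cM within +/- flank_cm of the DCV."""
    if flank_cm <= 0:
        raise ValueError("flank_cm must be positive")
    dcv_cm = float(
        np.interp(dcv_pos_bp, panel.pos_bp.astype(float), panel.cm)
    )
    mask = (panel.cm >= dcv_cm - flank_cm) & (panel.cm <= dcv_cm + flank_cm)
    if not mask.any():
        raise ValueError(
            f"no markers within +/-{flank_cm} cM of {panel.chrom}:{dcv_pos_bp}"
        )
    return mask


def trim_panel(panel: MarkerPanel, dcv_pos_bp: int, flank_cm: float) -> MarkerPanel:
    """Trim to markers within ``flank_cm`` of the DCV; recompute dcv_index."""
    mask = window_mask(panel, dcv_pos_bp, flank_cm)
    out = panel.subset(mask)
    out.set_dcv(dcv_pos_bp)
    return out


def slice_cohort(cohort: PhasedCohort, mask_or_index) -> PhasedCohort:
    """Restrict a cohort to the markers selected by ``mask_or_index``."""
    idx = np.asarray(mask_or_index)
    return PhasedCohort(list(cohort.individual_ids), cohort.alleles[:, :, idx])
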