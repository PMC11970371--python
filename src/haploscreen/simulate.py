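"""Synthetic cohorts and founder-effect scenario simulation.

The cohort generator emulates the features of real phased reference panels
that the scoring model is sensitive to: haplotypes are mosaics of a small
pool of founder haplotypes, with founder-switch points Poisson in genetic
distance, which induces linkage disequilibrium between nearby markers and
realistic background haplotype sharing between "unrelated" individuals.
Allele frequencies are drawn from a U-shaped Beta(0.8, 0.8) spectrum
truncated to [0.01, 0.99] and recorded as realized cohort frequencies.

Founder-effect scenarios implant a known disease haplotype over a chosen
genetic length around the DCV into designated case individuals, then add
1% genotype errors and phase-switch errors at one switch per 20.05 Mbp to
the whole test cohort, mimicking imputed-and-statistically-phased array
data. Two founder modes are supported: *single* (all disease haplotypes
descend from one ancestor and share a core around the DCV) and *multiple*
(independent founders, no shared core). Everything is reproducible from
integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    MISSING,
    DiseaseHaplotype,
    MarkerPanel,
    PhasedCohort,
)

__all__ = [
    "ScenarioSpec",
    "TruthTable",
    "synth_cohort",
    "derive_disease_haplotypes",
    "implant_case",
    "inject_genotype_errors",
    "inject_phase_switch_errors",
    "run_scenario",
    "load_scenarios",
]

DEFAULT_SWITCH_RATE_PER_BP = 1.0 / 20.05e6


@dataclass
class ScenarioSpec:
    """One simulated founder-effect dataset."""

    locus_id: str = "locus"
    founder_mode: str = "single"  # single | multiple
    n_disease_haps: int = 10
    n_cases_per_hap: int = 5
    sharing_length_cm: float = 2.0
    genotype_error_rate: float = 0.01
    phase_switch_rate_per_bp: float = DEFAULT_SWITCH_RATE_PER_BP
    core_length_cm: float | None = None  # None: max(5 cM, sharing length)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_mode not in ("single", "multiple"):
            raise ValueError("founder_mode must be 'single' or 'multiple'")
        if self.sharing_length_cm <= 0:
            raise ValueError("sharing_length_cm must be positive")
        for name in ("genotype_error_rate",):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.phase_switch_rate_per_bp < 0:
            raise ValueError("phase_switch_rate_per_bp must be >= 0")

    @property
    def n_cases(self) -> int:
        return self.n_disease_haps * self.n_cases_per_hap

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


@dataclass
class TruthTable:
    """Case/control truth for one simulated test cohort."""

    table: pd.DataFrame  # individual_id, is_case, source_hap_id, lo_cm, hi_cm
    n_disease_haps: int
    n_cases_per_hap: int

    def __post_init__(self) -> None:
        expected = self.n_disease_haps * self.n_cases_per_hap
        got = int(self.table["is_case"].sum())
        if got != expected:
            raise ValueError(f"truth table has {got} cases, expected {expected}")

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].sum())

    @property
    def case_ids(self) -> list:
        return self.table.loc[self.table["is_case"], "individual_id"].tolist()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, size: int,
                    lo: float = 0.01, hi: float = 0.99) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def synth_cohort(
    n_individuals: int = 503,
    n_markers: int = 2000,
    n_founders: int = 16,
    founder_switch_cm: float = 0.5,
    freq_spectrum: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    map_cm_per_mb: float = 1.0,
    seed: int = 0,
    chrom: str = "1",
    start_bp: int = 1_000_000,
    marker_spacing_cm: float = 0.01,
) -> tuple[PhasedCohort, MarkerPanel]:
    """Generate a phased mosaic-of-founders cohort with LD and a linear map.

    Defaults give 503 individuals over a 20-cM window at ~100 markers/cM,
    the control-cohort scale the screening design assumes. Markers that come
    out monomorphic in the realized cohort are dropped (frequencies must lie
    strictly in (0, 1)), so ``n_markers`` is an upper bound. The DCV is
    placed at the central marker.
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_markers < 10:
        raise ValueError("n_markers must be >= 10")
    rng = np.random.default_rng(seed)
    if freq_spectrum is None:
        f = _truncated_beta(rng, 0.8, 0.8, n_markers)
    else:
        f = np.asarray(freq_spectrum(rng, n_markers), dtype=float)
        if np.all(f <= 0) or np.all(f >= 1):
            raise ValueError("degenerate frequency spectrum")

    spacing_bp = max(1, int(round(marker_spacing_cm / map_cm_per_mb * 1e6)))
    pos_bp = start_bp + spacing_bp * np.arange(n_markers, dtype=np.int64)
    cm = (pos_bp - pos_bp[0]) / 1e6 * map_cm_per_mb
    span_cm = float(cm[-1] - cm[0])

    founders = (rng.random((n_founders, n_markers)) < f[None, :]).astype(np.int8)

    n_haps = 2 * n_individuals
    alleles = np.empty((n_haps, n_markers), dtype=np.int8)
    for h in range(n_haps):
        if np.isinf(founder_switch_cm):
            alleles[h] = founders[rng.integers(n_founders)]
            continue
        n_sw = rng.poisson(span_cm / founder_switch_cm)
        cuts = np.sort(rng.uniform(cm[0], cm[-1], size=n_sw))
        seg = np.searchsorted(cuts, cm, side="right")  # segment id per marker
        ids = rng.integers(n_founders, size=n_sw + 1)
        alleles[h] = founders[ids[seg], np.arange(n_markers)]

    realized = alleles.mean(axis=0)
    keep = (realized > 0.0) & (realized < 1.0)
    alleles = alleles[:, keep]
    pos_bp = pos_bp[keep]
    cm = cm[keep]
    realized = realized[keep]
    m = alleles.shape[1]

    panel = MarkerPanel(
        chrom,
        pos_bp,
        cm,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        alt_freq=realized,
        dcv_pos_bp=int(pos_bp[m // 2]),
    )
    cohort = PhasedCohort(
        [f"ind{i:05d}" for i in range(n_individuals)],
        alleles.reshape(n_individuals, 2, m),
    )
    return cohort, panel


def derive_disease_haplotypes(
    cohort: PhasedCohort,
    panel: MarkerPanel,
    mode: str,
    n_haps: int = 10,
    core_length_cm: float = 5.0,
    seed: int = 0,
    variant_id: str = "DCV",
) -> tuple[list[DiseaseHaplotype], list[str]]:
    """Build disease haplotypes from cohort members; returns (haps, donor_ids).

    single mode: one ancestor haplotype is copied over a window of length
    uniform in [core_length_cm, panel span] around the DCV and spliced onto
    a distinct background haplotype for each disease haplotype, so all of
    them share an ancestral core of at least ``core_length_cm``.
    multiple mode: ``n_haps`` haplotypes taken verbatim from distinct
    individuals (independent founders, no enforced core).
    Donor individuals must be removed from any test cohort.
    """
    if mode not in ("single", "multiple"):
        raise ValueError("mode must be 'single' or 'multiple'")
    rng = np.random.default_rng(seed)
    dcv = panel.dcv_index
    dcv_cm = panel.cm[dcv]
    span = float(panel.cm[-1] - panel.cm[0])
    if core_length_cm > span:
        raise ValueError("core_length_cm exceeds the panel span")

    n_needed = n_haps + 1 if mode == "single" else n_haps
    if n_needed > cohort.n_individuals:
        raise ValueError(
            f"need {n_needed} donor individuals, cohort has {cohort.n_individuals}"
        )
    donors_idx = rng.choice(cohort.n_individuals, size=n_needed, replace=False)
    haps: list[DiseaseHaplotype] = []

    if mode == "single":
        anc_ind, backgrounds = donors_idx[0], donors_idx[1:]
        ancestor = cohort.alleles[anc_ind, rng.integers(2)]
        for j, bg in enumerate(backgrounds):
            length = rng.uniform(core_length_cm, span)
            lo, hi = dcv_cm - length / 2.0, dcv_cm + length / 2.0
            window = (panel.cm >= lo) & (panel.cm <= hi)
            alleles = cohort.alleles[bg, rng.integers(2)].copy()
            alleles[window] = ancestor[window]
            haps.append(
                DiseaseHaplotype(
                    hap_id=f"{variant_id}_hap{j:02d}",
                    variant_id=variant_id,
                    alleles=alleles,
                    dcv_chrom=panel.chrom,
                    dcv_pos_bp=panel.dcv_pos_bp,
                )
            )
    else:
        for j, don in enumerate(donors_idx):
            alleles = cohort.alleles[don, rng.integers(2)].copy()
            haps.append(
                DiseaseHaplotype(
                    hap_id=f"{variant_id}_hap{j:02d}",
                    variant_id=variant_id,
                    alleles=alleles,
                    dcv_chrom=panel.chrom,
                    dcv_pos_bp=panel.dcv_pos_bp,
                )
            )
    donor_ids = [cohort.individual_ids[i] for i in donors_idx]
    return haps, donor_ids


def implant_case(
    individual: np.ndarray,
    disease_hap: DiseaseHaplotype,
    panel: MarkerPanel,
    sharing_length_cm: float,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Replace one random haplotype of ``individual`` (shape (2, m)) with the
    disease haplotype over [dcv - L/2, dcv + L/2] cM; returns (alleles,
    (lo_cm, hi_cm))."""
    rng = np.random.default_rng(seed)
    dcv_cm = panel.cm[panel.dcv_index]
    lo = dcv_cm - sharing_length_cm / 2.0
    hi = dcv_cm + sharing_length_cm / 2.0
    window = (panel.cm >= lo) & (panel.cm <= hi)
    if not window.any():
        raise ValueError("implant interval contains no markers")
    out = np.asarray(individual, dtype=np.int8).copy()
    which = int(rng.integers(2))
    out[which, window] = disease_hap.alleles[window]
    return out, (float(lo), float(hi))


def inject_genotype_errors(
    cohort: PhasedCohort, rate: float, seed: int = 0
) -> PhasedCohort:
    """Flip each non-missing allele independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    out = cohort.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        flip = (rng.random(out.alleles.shape) < rate) & (out.alleles != MISSING)
        out.alleles[flip] = 1 - out.alleles[flip]
    return out


def inject_phase_switch_errors(
    cohort: PhasedCohort,
    panel: MarkerPanel,
    rate_per_bp: float = DEFAULT_SWITCH_RATE_PER_BP,
    seed: int = 0,
) -> PhasedCohort:
    """Exchange haplotype labels after Poisson switch points along bp.

    Mimics block phasing errors from statistical phasing; the default rate is
    one switch per 20.05 Mbp.
    """
    if rate_per_bp < 0:
        raise ValueError("rate_per_bp must be >= 0")
    out = cohort.copy()
    if rate_per_bp == 0:
        return out
    rng = np.random.default_rng(seed)
    lo, hi = float(panel.pos_bp[0]), float(panel.pos_bp[-1])
    span = hi - lo
    for i in range(out.n_individuals):
        n_sw = rng.poisson(rate_per_bp * span)
        if n_sw == 0:
            continue
        cuts = np.sort(rng.uniform(lo, hi, size=n_sw))
        parity = np.searchsorted(cuts, panel.pos_bp, side="right") % 2
        swap = parity == 1
        a = out.alleles[i, 0, swap].copy()
        out.alleles[i, 0, swap] = out.alleles[i, 1, swap]
        out.alleles[i, 1, swap] = a
    return out


def run_scenario(
    spec: ScenarioSpec, cohort: PhasedCohort, panel: MarkerPanel
) -> tuple[PhasedCohort, list[DiseaseHaplotype], TruthTable]:
    """Simulate one founder-effect dataset: derive disease haplotypes,
    implant cases, inject genotype and phase-switch errors.

    Disease-haplotype donors are removed from the test cohort and stay
    error-free; everyone remaining (cases and controls alike) receives
    errors. Fully deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds = rng.integers(2**31, size=4)

    core = (
        max(5.0, spec.sharing_length_cm)
        if spec.core_length_cm is None
        else max(spec.core_length_cm, spec.sharing_length_cm)
    )
    haps, donor_ids = derive_disease_haplotypes(
        cohort,
        panel,
        spec.founder_mode,
        n_haps=spec.n_disease_haps,
        core_length_cm=core,
        seed=int(seeds[0]),
        variant_id=spec.locus_id,
    )
    test = cohort.drop(donor_ids)
    if spec.n_cases > test.n_individuals:
        raise ValueError("cohort too small for requested number of cases")

    case_rng = np.random.default_rng(int(seeds[1]))
    case_idx = case_rng.choice(test.n_individuals, size=spec.n_cases, replace=False)
    rows = {
        "individual_id": list(test.individual_ids),
        "is_case": np.zeros(test.n_individuals, dtype=bool),
        "source_hap_id": [""] * test.n_individuals,
        "lo_cm": np.full(test.n_individuals, np.nan),
        "hi_cm": np.full(test.n_individuals, np.nan),
    }
    for j, idx in enumerate(case_idx):
        hap = haps[j // spec.n_cases_per_hap]
        alleles, (lo, hi) = implant_case(
            test.alleles[idx],
            hap,
            panel,
            spec.sharing_length_cm,
            seed=int(case_rng.integers(2**31)),
        )
        test.alleles[idx] = alleles
        rows["is_case"][idx] = True
        rows["source_hap_id"][idx] = hap.hap_id
        rows["lo_cm"][idx] = lo
        rows["hi_cm"][idx] = hi

    test = inject_genotype_errors(test, spec.genotype_error_rate, seed=int(seeds[2]))
    test = inject_phase_switch_errors(
        test, panel, spec.phase_switch_rate_per_bp, seed=int(seeds[3])
    )
    truth = TruthTable(
        table=pd.DataFrame(rows),
        n_disease_haps=spec.n_disease_haps,
        n_cases_per_hap=spec.n_cases_per_hap,
    )
    return test, haps, truth


def load_scenarios(path) -> list[ScenarioSpec]:
    """Read scenario specs from a YAML file (a list of key-value blocks)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    return [ScenarioSpec.from_dict(d) for d in raw]
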