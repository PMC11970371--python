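"""File formats: phased VCF, genetic maps, frequency tables, result tables.

The scoring pipeline consumes already-imputed, already-phased VCF (pipe
separator in GT); running imputation or phasing is out of scope. Marker
filtering follows the preparation rules used for array screening: biallelic
markers only, imputation quality R2 >= 0.3, frequencies strictly inside
(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GeneticMap, MarkerPanel, PhasedCohort, slice_cohort

__all__ = [
    "MarkerFilterReport",
    "VcfData",
    "read_phased_vcf",
    "write_phased_vcf",
    "annotate_cm",
    "read_genetic_map",
    "read_frequency_table",
    "attach_frequencies",
    "AttachResult",
    "filter_markers",
    "write_results",
    "read_results",
]


@dataclass
class MarkerFilterReport:
    """Counts of markers removed by each preparation rule."""

    n_input: int = 0
    non_biallelic: int = 0
    imputation_quality: int = 0
    frequency_missing: int = 0
    out_of_window: int = 0
    retained: int = 0

    def check(self) -> None:
        removed = (
            self.non_biallelic
            + self.imputation_quality
            + self.frequency_missing
            + self.out_of_window
        )
        if removed + self.retained != self.n_input:
            raise ValueError("filter report does not account for all markers")

    def __str__(self) -> str:
        return (
            f"markers in: {self.n_input}; removed non-biallelic: "
            f"{self.non_biallelic}, low imputation quality: "
            f"{self.imputation_quality}, no usable frequency: "
            f"{self.frequency_missing}, outside window: {self.out_of_window}; "
            f"retained: {self.retained}"
        )


class VcfData(NamedTuple):
    cohort: PhasedCohort
    panel: MarkerPanel
    n_multiallelic: int


def read_phased_vcf(
    path,
    region: tuple[str, int, int] | None = None,
    r2_key: str = "R2",
) -> VcfData:
    """Read a phased VCF into a cohort plus a marker-panel skeleton.

    All genotypes must be phased ("|"); an unphased genotype is a hard
    error naming the offending record (half-calls and fully missing "./."
    are tolerated and become missing alleles). Multiallelic records are
    dropped and counted. The skeleton has cm=0 (annotate with a genetic map)
    and alt_freq=NaN (attach frequencies) and carries the ``r2_key`` INFO
    value where present.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pos, ref, alt, r2 = [], [], [], []
    gts = []
    chrom_seen: str | None = None
    n_multi = 0
    for v in vcf:
        if region is not None:
            c, lo, hi = region
            if v.CHROM != c or not (lo <= v.POS <= hi):
                continue
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if chrom_seen is None:
            chrom_seen = v.CHROM
        elif v.CHROM != chrom_seen:
            raise ValueError(
                f"multiple chromosomes in input ({chrom_seen}, {v.CHROM}); "
                "provide a single-chromosome window"
            )
        col = np.empty((len(samples), 2), dtype=np.int8)
        for si, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased and not (a < 0 and b < 0):
                raise ValueError(
                    f"unphased genotype for sample {samples[si]} at "
                    f"{v.CHROM}:{v.POS}; phased input is required"
                )
            col[si, 0] = a if a >= 0 else MISSING
            col[si, 1] = b if b >= 0 else MISSING
        gts.append(col)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        val = v.INFO.get(r2_key)
        r2.append(float(val) if val is not None else np.nan)
    vcf.close()
    if not pos:
        raise ValueError(f"no usable biallelic records in {path}")
    m = len(pos)
    panel = MarkerPanel(
        chrom_seen,
        np.asarray(pos, dtype=np.int64),
        np.zeros(m),
        np.asarray(ref, dtype=object),
        np.asarray(alt, dtype=object),
        np.full(m, np.nan),
        impute_r2=np.asarray(r2),
    )
    alleles = np.stack(gts, axis=2)  # (n_samples, 2, m)
    return VcfData(PhasedCohort(samples, alleles), panel, n_multi)


def write_phased_vcf(
    cohort: PhasedCohort, panel: MarkerPanel, path, r2: bool = True
) -> None:
    """Write a minimal phased VCF 4.2 (GT only, optional R2/AF INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt freq">\n')
        if r2 and panel.impute_r2 is not None:
            fh.write(
                '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R2">\n'
            )
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.individual_ids)
            + "\n"
        )
        for j in range(len(panel)):
            info = []
            if not np.isnan(panel.alt_freq[j]):
                info.append(f"AF={panel.alt_freq[j]:.6g}")
            if r2 and panel.impute_r2 is not None and not np.isnan(panel.impute_r2[j]):
                info.append(f"R2={panel.impute_r2[j]:.4g}")
            cols = [
                panel.chrom,
                str(int(panel.pos_bp[j])),
                ".",
                str(panel.ref[j]),
                str(panel.alt[j]),
                ".",
                "PASS",
                ";".join(info) if info else ".",
                "GT",
            ]
            for i in range(cohort.n_individuals):
                a, b = cohort.alleles[i, 0, j], cohort.alleles[i, 1, j]
                cols.append(
                    f"{'.' if a == MISSING else int(a)}|"
                    f"{'.' if b == MISSING else int(b)}"
                )
            fh.write("\t".join(cols) + "\n")


def annotate_cm(panel: MarkerPanel, gmap: GeneticMap) -> MarkerPanel:
    """Return the panel with cM interpolated from the genetic map."""
    cm = gmap.interpolate(panel.pos_bp)
    return MarkerPanel(
        panel.chrom,
        panel.pos_bp,
        cm,
        panel.ref,
        panel.alt,
        panel.alt_freq,
        dcv_pos_bp=panel.dcv_pos_bp,
        impute_r2=panel.impute_r2,
    )


def read_genetic_map(path, chrom: str | None = None) -> GeneticMap:
    """Read a 3-column (chrom, pos_bp, cM) whitespace genetic map.

    A header line is auto-detected and skipped. If ``chrom`` is given only
    that chromosome's anchors are used.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("genetic map needs 3 columns: chrom, pos_bp, cM")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    df = df.iloc[:, :3]
    df.columns = ["chrom", "pos_bp", "cm"]
    if chrom is not None:
        df = df[df["chrom"].astype(str) == str(chrom)]
        if df.empty:
            raise ValueError(f"no genetic-map anchors for chromosome {chrom}")
    elif df["chrom"].nunique() > 1:
        raise ValueError("genetic map covers several chromosomes; pass chrom=")
    return GeneticMap(
        str(df["chrom"].iloc[0]),
        df["pos_bp"].astype(np.int64).to_numpy(),
        df["cm"].astype(float).to_numpy(),
    )


def read_frequency_table(path) -> pd.DataFrame:
    """Read a tab-separated (chrom, pos, ref, alt, alt_freq) table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "alt_freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"frequency table must have columns {sorted(required)}")
    return df


class AttachResult(NamedTuple):
    panel: MarkerPanel
    kept_mask: np.ndarray
    n_complemented: int
    n_dropped: int


def attach_frequencies(panel: MarkerPanel, freq_table: pd.DataFrame) -> AttachResult:
    """Set per-marker alt_freq from an annotation table.

    Matching is on (chrom, pos, ref, alt). Entries with ref/alt swapped
    relative to the VCF get the complemented frequency and are flagged
    (counted); markers with no entry, a strand-flip, or a frequency of
    exactly 0 or 1 are dropped. Use ``kept_mask`` to slice cohorts in step.
    """
    tbl = {}
    for row in freq_table.itertuples(index=False):
        tbl[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = float(
            row.alt_freq
        )
    freqs = np.full(len(panel), np.nan)
    n_comp = 0
    for j in range(len(panel)):
        key = (panel.chrom, int(panel.pos_bp[j]), str(panel.ref[j]), str(panel.alt[j]))
        swapped = (key[0], key[1], key[3], key[2])
        if key in tbl:
            freqs[j] = tbl[key]
        elif swapped in tbl:
            freqs[j] = 1.0 - tbl[swapped]
            n_comp += 1
    keep = ~np.isnan(freqs) & (freqs > 0.0) & (freqs < 1.0)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no markers retained after frequency annotation")
    out = MarkerPanel(
        panel.chrom,
        panel.pos_bp[keep],
        panel.cm[keep],
        panel.ref[keep],
        panel.alt[keep],
        freqs[keep],
        dcv_pos_bp=panel.dcv_pos_bp,
        impute_r2=None if panel.impute_r2 is None else panel.impute_r2[keep],
    )
    return AttachResult(out, keep, n_comp, n_dropped)


def filter_markers(
    panel: MarkerPanel,
    cohort: PhasedCohort,
    min_impute_r2: float = 0.3,
    require_biallelic: bool = True,
    n_non_biallelic: int = 0,
    n_out_of_window: int = 0,
) -> tuple[MarkerPanel, PhasedCohort, MarkerFilterReport]:
    """Apply marker preparation rules and report per-rule removal counts.

    Markers with imputation quality below ``min_impute_r2`` are removed;
    markers lacking the quality field are kept with a warning (treated as
    genotyped rather than imputed). Markers without a usable frequency are
    removed. ``n_non_biallelic`` / ``n_out_of_window`` let callers fold in
    counts from earlier stages (VCF reading, window trimming) so the report
    accounts for every input marker.
    """
    m = len(panel)
    report = MarkerFilterReport(
        n_input=m + n_non_biallelic + n_out_of_window,
        non_biallelic=n_non_biallelic,
        out_of_window=n_out_of_window,
    )
    keep = np.ones(m, dtype=bool)
    if panel.impute_r2 is not None:
        has_r2 = ~np.isnan(panel.impute_r2)
        low = has_r2 & (panel.impute_r2 < min_impute_r2)
        keep &= ~low
        report.imputation_quality = int(low.sum())
        if (~has_r2).any():
            warnings.warn(
                f"{int((~has_r2).sum())} markers lack an imputation-quality "
                "field; kept as genotyped",
                stacklevel=2,
            )
    no_freq = np.isnan(panel.alt_freq) & keep
    report.frequency_missing = int(no_freq.sum())
    keep &= ~no_freq
    report.retained = int(keep.sum())
    report.check()
    if not keep.any():
        raise ValueError("no markers retained after filtering")
    out_panel = panel.subset(keep)
    if panel.dcv_pos_bp is not None:
        out_panel.set_dcv(panel.dcv_pos_bp)
    return out_panel, slice_cohort(cohort, keep), report


def write_results(results: pd.DataFrame, path) -> None:
    """Write the result table: tab-separated, ordered by descending score
    then individual_id, scores at 6 significant digits."""
    cols = [
        "individual_id",
        "variant_id",
        "best_hap_id",
        "ibd_score",
        "empirical_p",
        "call",
        "rank",
    ]
    df = results.copy()
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"results missing column {c}")
    df = df[cols].sort_values(
        ["ibd_score", "individual_id"], ascending=[False, True], kind="mergesort"
    )
    df["ibd_score"] = df["ibd_score"].map(lambda x: f"{x:.6g}")
    df["empirical_p"] = df["empirical_p"].map(lambda x: f"{x:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
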