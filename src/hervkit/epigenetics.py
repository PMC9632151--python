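"""TSS-window association of locus expression with histone peaks and DNA
methylation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval
from .detection import HervLocus
from .expression import bh_adjust

log = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1", "H3K4me3", "H3K9me3")


@dataclass
class PeakSet:
    mark: str
    body_site: str
    individual: str
    peaks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.mark not in HISTONE_MARKS:
            raise ValueError(f"unknown histone mark {self.mark!r}")
        self.peaks = tuple(sorted(self.peaks, key=lambda p: (p.chrom, p.start)))


@dataclass
class MethylationTrack:
    """CpG records: (chrom, position, beta, coverage)."""

    records: pd.DataFrame  # columns chrom, pos, beta, coverage

    def __post_init__(self) -> None:
        betas = self.records["beta"]
        if ((betas < 0) | (betas > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")


def tss_window(locus: HervLocus, window: int = 5000) -> GenomicInterval:
    tss = locus.tss
    return GenomicInterval(locus.chrom, max(0, tss - window), tss + window + 1, locus.strand)


def peaks_near_tss(
    loci: Sequence[HervLocus],
    peak_sets: Sequence[PeakSet],
    window: int = 5000,
) -> pd.DataFrame:
    """Boolean loci x marks frame: True when any peak of that mark overlaps
    [TSS - window, TSS + window]."""
    flags = pd.DataFrame(
        False, index=[l.locus_id for l in loci], columns=sorted({ps.mark for ps in peak_sets})
    )
    for locus in loci:
        win = tss_window(locus, window)
        for ps in peak_sets:
            if flags.loc[locus.locus_id, ps.mark]:
                continue
            for peak in ps.peaks:
                if peak.chrom != win.chrom:
                    continue
                if peak.start < win.end and peak.end > win.start:
                    flags.loc[locus.locus_id, ps.mark] = True
                    break
    return flags


def peak_expression_test(
    expr: pd.Series,
    flags: pd.DataFrame,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-mark two-sided rank-sum comparing expression of loci with vs
    without a nearby peak; BH across marks. Cells with an undersized group
    are skipped (logged)."""
    rows = []
    for mark in flags.columns:
        flagged = expr[flags.index[flags[mark]]].dropna()
        unflagged = expr[flags.index[~flags[mark]]].dropna()
        if len(flagged) < min_group or len(unflagged) < min_group:
            log.info("peak_expression_test: skipping %s (group too small)", mark)
            continue
        if flagged.nunique() == 1 and unflagged.nunique() == 1 and flagged.iloc[0] == unflagged.iloc[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(flagged, unflagged, alternative="two-sided").pvalue)
        rows.append(
            {
                "mark": mark,
                "n_flagged": len(flagged),
                "n_unflagged": len(unflagged),
                "median_flagged": float(flagged.median()),
                "median_unflagged": float(unflagged.median()),
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["mark", "n_flagged", "n_unflagged", "median_flagged", "median_unflagged", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def methylation_level(
    track: MethylationTrack,
    locus: HervLocus,
    window: int = 5000,
) -> float:
    """Coverage-weighted mean CpG beta in the TSS window; NaN when no
    records fall inside."""
    tss = locus.tss
    rec = track.records
    mask = (
        (rec["chrom"] == locus.chrom)
        & (rec["pos"] >= tss - window)
        & (rec["pos"] <= tss + window)
    )
    sub = rec[mask]
    if sub.empty or sub["coverage"].sum() == 0:
        return float("nan")
    return float((sub["beta"] * sub["coverage"]).sum() / sub["coverage"].sum())


def methylation_expression_tests(
    levels: pd.DataFrame,
    tpm: pd.DataFrame,
    expressed_tpm: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(a) expressed-vs-silent methylation rank-sum per site; (b) per-locus
    Pearson correlation of methylation vs log2(TPM+1) across sites.

    ``levels`` and ``tpm`` are loci x sites. Expressed means TPM >=
    ``expressed_tpm``, silent means TPM == 0; loci in between are excluded
    from (a). BH is applied within each family.
    """
    site_rows = []
    for site in levels.columns:
        lv = levels[site]
        tp = tpm[site]
        expressed = lv[(tp >= expressed_tpm) & lv.notna()]
        silent = lv[(tp == 0) & lv.notna()]
        if len(expressed) < 3 or len(silent) < 3:
            continue
        p = float(stats.mannwhitneyu(expressed, silent, alternative="two-sided").pvalue)
        site_rows.append(
            {
                "body_site": site,
                "n_expressed": len(expressed),
                "n_silent": len(silent),
                "median_expressed": float(expressed.median()),
                "median_silent": float(silent.median()),
                "p": p,
            }
        )
    site_df = pd.DataFrame(
        site_rows,
        columns=["body_site", "n_expressed", "n_silent", "median_expressed", "median_silent", "p"],
    )
    site_df["fdr"] = bh_adjust(site_df["p"].to_numpy()) if len(site_df) else np.nan

    locus_rows = []
    log_tpm = np.log2(tpm + 1.0)
    for locus in levels.index:
        lv = levels.loc[locus]
        ex = log_tpm.loc[locus]
        mask = lv.notna() & ex.notna()
        if mask.sum() < 3:
            continue
        a, b = lv[mask].to_numpy(), ex[mask].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r, p = stats.pearsonr(a, b)
        locus_rows.append({"locus_id": locus, "r": float(r), "p": float(p), "n_sites": int(mask.sum())})
    locus_df = pd.DataFrame(locus_rows, columns=["locus_id", "r", "p", "n_sites"])
    locus_df["fdr"] = bh_adjust(locus_df["p"].to_numpy()) if len(locus_df) else np.nan
    return site_df, locus_df


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | Path, mark: str, body_site: str, individual: str) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            peaks.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return PeakSet(mark=mark, body_site=body_site, individual=individual, peaks=tuple(peaks))


def write_narrowpeak(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(ps.peaks, 1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{ps.mark}_peak{i}\t0\t.\t0\t-1\t-1\t-1\n"
            )


def read_methylation(path: str | Path) -> MethylationTrack:
    """Read a bedMethyl-style TSV: chrom, pos, coverage, percent (0-100)."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "coverage", "percent"], comment="#")
    return MethylationTrack(
        records=pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"].astype(int),
                "beta": df["percent"].astype(float) / 100.0,
                "coverage": df["coverage"].astype(int),
            }
        )
    )


def write_methylation(track: MethylationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in track.records.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.coverage}\t{row.beta * 100.0:.2f}\n")
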