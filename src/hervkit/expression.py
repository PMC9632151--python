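"""Expression normalization, specificity summaries, sample similarity, and
the generic two-group differential-expression contract.

Expression matrices are loci x samples DataFrames throughout. The DE
reference engine is a two-sided rank-sum test on log2(TPM + 1); it sits
behind a stable interface so heavier engines can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import SampleMeta

log = logging.getLogger(__name__)


@dataclass
class ExpressionStudy:
    """Counts plus derived TPM and sample metadata."""

    counts: pd.DataFrame
    effective_length: pd.Series
    meta: list[SampleMeta] = field(default_factory=list)
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.effective_length.index):
            raise ValueError("counts and effective_length must share loci")
        if (self.effective_length <= 0).any():
            raise ValueError("effective lengths must be positive")
        if self.tpm is None:
            self.tpm = compute_tpm(self.counts, self.effective_length)

    @property
    def log_tpm(self) -> pd.DataFrame:
        return np.log2(self.tpm + 1.0)

    def site_of(self) -> dict[str, str]:
        return {m.sample_id: m.body_site for m in self.meta}


def compute_tpm(counts: pd.DataFrame, effective_length: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and effective lengths.

    All-zero sample columns stay all-zero.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = effective_length.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("effective lengths must be positive for every locus")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def site_specificity(expressed: pd.DataFrame, ubiquity_threshold: int = 40) -> pd.DataFrame:
    """Summarize per-locus expression breadth across body sites.

    ``expressed`` is loci x sites boolean. A locus is site-specific when
    expressed in exactly one site and ubiquitous when expressed in
    >= ubiquity_threshold sites.
    """
    n_sites = expressed.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "n_sites": n_sites,
            "specificity": np.where(n_sites == 1, "site-specific", "shared"),
            "ubiquitous": n_sites >= ubiquity_threshold,
        },
        index=expressed.index,
    )


def sample_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance 1 - Spearman correlation of expression.

    Constant columns have undefined correlation; it is treated as 0
    (distance 1) and logged.
    """
    values = expr.to_numpy(dtype=float)
    n = values.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    constant = values.std(axis=0) == 0
    if constant.any():
        log.warning("sample_distance: %d constant column(s); correlation treated as 0", constant.sum())
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / np.outer(norms, norms)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=expr.columns, columns=expr.columns)


def embed_mds(distance: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a distance matrix."""
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("embedding requires >= 3 samples")
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0, None))
    # deterministic sign: largest-|value| coordinate positive per axis
    for c in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, c]))
        if coords[pivot, c] < 0:
            coords[:, c] = -coords[:, c]
    return pd.DataFrame(coords, index=distance.index, columns=[f"MDS{i + 1}" for i in range(k)])


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def pairwise_de(
    tpm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    engine: str = "ranksum",
) -> pd.DataFrame:
    """Two-group differential expression on log2(TPM + 1).

    Returns a per-locus frame with columns lfc (mean log2 difference,
    a - b), p, fdr, and engine. Reference engine: two-sided Wilcoxon
    rank-sum.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group requires >= 2 samples")
    if engine != "ranksum":
        raise ValueError(f"unknown engine {engine!r}")
    la = np.log2(tpm[group_a].to_numpy(dtype=float) + 1.0)
    lb = np.log2(tpm[group_b].to_numpy(dtype=float) + 1.0)
    lfc = la.mean(axis=1) - lb.mean(axis=1)
    pvals = np.ones(tpm.shape[0])
    for i in range(tpm.shape[0]):
        a, b = la[i], lb[i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
            continue
        pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return pd.DataFrame(
        {"lfc": lfc, "p": pvals, "fdr": bh_adjust(pvals), "engine": engine},
        index=tpm.index,
    )


def preferential_expression(
    tpm: pd.DataFrame,
    expressed: pd.DataFrame,
    groups: Mapping[str, str],
    site: str,
    alpha: float = 0.05,
) -> pd.Series:
    """Loci expressed in ``site`` at significantly higher level than at every
    other site where they are expressed (positive lfc, FDR < alpha)."""
    sites = [s for s in expressed.columns if s != site]
    site_samples = [s for s, g in groups.items() if g == site]
    candidate = expressed[site].copy()
    for other in sites:
        other_samples = [s for s, g in groups.items() if g == other]
        if len(site_samples) < 2 or len(other_samples) < 2:
            continue
        both = expressed[site] & expressed[other]
        if not both.any():
            continue
        de = pairwise_de(tpm, site_samples, other_samples)
        ok = (de["lfc"] > 0) & (de["fdr"] < alpha)
        candidate &= ~both | ok
    return candidate
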