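"""Presence-aware genotyping, variant QC, normalization, cis-QTL mapping
with permutations, LD utilities, and matched-background enrichment.

Dosages are variants x individuals arrays with NaN for missing calls.
Expression enters QTL mapping as an inverse-normal-transformed loci x
individuals matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import nearest_tss_distance
from .expression import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GenotypeStudy:
    """Variants x individuals dosage matrix with variant metadata."""

    dosage: np.ndarray  # float, NaN = missing
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt
    individuals: list[str]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.variants), len(self.individuals)):
            raise ValueError("dosage dimensions do not match metadata")

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            alt = np.nanmean(self.dosage, axis=1) / 2.0
        return np.minimum(alt, 1.0 - alt)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "GenotypeStudy":
        keep = np.asarray(keep)
        return GenotypeStudy(
            dosage=self.dosage[keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            individuals=list(self.individuals),
        )


# ---------------------------------------------------------------------------
# Presence calls
# ---------------------------------------------------------------------------


def presence_from_contigs(
    contig_hits: Mapping[tuple[str, str], Sequence[bool]],
    loci: Sequence[str] | None = None,
    individuals: Sequence[str] | None = None,
) -> dict[tuple[str, str], str]:
    """Presence call per (locus, individual): present iff >= 1 uniquely
    mapping contig. Pairs listed in the optional grids but absent from the
    hit map are called absent."""
    calls = {}
    if loci is not None and individuals is not None:
        for locus in loci:
            for ind in individuals:
                calls[(locus, ind)] = "absent"
    for key, flags in contig_hits.items():
        calls[key] = "present" if any(flags) else "absent"
    return calls


def mask_expression(expr: pd.DataFrame, calls: Mapping[tuple[str, str], str]) -> pd.DataFrame:
    """Replace expression of absent (locus, individual) pairs with NaN."""
    out = expr.copy().astype(float)
    for (locus, ind), state in calls.items():
        if state == "absent" and locus in out.index and ind in out.columns:
            out.loc[locus, ind] = np.nan
    return out


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------


def hwe_pvalue(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Hardy-Weinberg chi-square test (1 df) on genotype counts."""
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 1.0
    p_alt = (n_het + 2 * n_alt_hom) / (2 * n)
    expected = np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2]) * n
    observed = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    mask = expected > 0
    chi2 = ((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum()
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc(
    g: GenotypeStudy,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> np.ndarray:
    """Indices of variants passing missingness, MAF, and HWE filters."""
    if len(g.individuals) < 10:
        raise ValueError("variant_qc requires >= 10 individuals")
    keep = []
    maf = g.maf()
    for vi in range(g.dosage.shape[0]):
        row = g.dosage[vi]
        missing = np.isnan(row).mean()
        if missing >= max_missing:
            continue
        if np.isnan(maf[vi]) or maf[vi] < min_maf:
            continue
        obs = row[~np.isnan(row)]
        counts = [(obs == k).sum() for k in (0, 1, 2)]
        if hwe_pvalue(*counts) < hwe_alpha:
            continue
        keep.append(vi)
    return np.array(keep, dtype=int)


def site_variant_filter(
    g: GenotypeStudy,
    min_minor_carriers: int = 10,
    min_maf: float = 0.01,
) -> np.ndarray:
    """Per-body-site variant filter: minor allele carried by >= 10 samples
    and MAF >= 1%."""
    keep = []
    maf = g.maf()
    for vi in range(g.dosage.shape[0]):
        row = g.dosage[vi]
        obs = row[~np.isnan(row)]
        if obs.size == 0 or np.isnan(maf[vi]) or maf[vi] < min_maf:
            continue
        alt_freq = obs.mean() / 2.0
        if alt_freq <= 0.5:
            carriers = (obs >= 1).sum()  # alt is minor
        else:
            carriers = (obs <= 1).sum()  # ref is minor
        if carriers < min_minor_carriers:
            continue
        keep.append(vi)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Weighted trimmed log2 ratio of one sample against the reference.

    Follows the original trimmed-mean-of-M-values procedure: zero-count genes
    excluded pairwise, the top/bottom 30% of M and 5% of A trimmed by rank,
    inverse asymptotic variance weights.
    """
    mask = (obs > 0) & (ref > 0)
    if mask.sum() == 0:
        return 0.0
    po = obs[mask] / lib_obs
    pr = ref[mask] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (lib_ref - ref[mask]) / (lib_ref * ref[mask])
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 0.0
    f = float((w[keep] * m[keep]).sum() / w[keep].sum())
    if abs(f) < 1e-6:
        f = 0.0
    return f


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile (of library-size
    normalized counts) is closest to the mean upper-quartile.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("tmm_factors requires >= 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.array(
        [_tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx]) for j in range(x.shape[1])]
    )
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def inverse_normal(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transform: v -> Phi^-1((rank - 0.5) / n).

    Ties get average ranks; missing values are preserved.
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    mask = ~np.isnan(v)
    n = int(mask.sum())
    if n == 0:
        return out
    obs = v[mask]
    if np.all(obs == obs[0]):
        log.warning("inverse_normal: all values equal; mapping to 0")
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(obs)
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def inverse_normal_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse normal transform to each locus (row) across samples."""
    return pd.DataFrame(
        np.vstack([inverse_normal(expr.iloc[i].to_numpy()) for i in range(expr.shape[0])]),
        index=expr.index,
        columns=expr.columns,
    )


# ---------------------------------------------------------------------------
# LD utilities and genotype PCs
# ---------------------------------------------------------------------------


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    mask = ~np.isnan(d1) & ~np.isnan(d2)
    if mask.sum() < 3:
        raise ValueError("ld_r2 requires >= 3 complete pairs")
    a, b = d1[mask], d2[mask]
    if a.std() == 0 or b.std() == 0:
        log.warning("ld_r2: constant dosage vector; r2 defined as 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_ld(
    g: GenotypeStudy,
    window: int = 200,
    step: int = 100,
    r2_max: float = 0.2,
) -> list[str]:
    """Sliding-window LD pruning: within each window of ``window`` variants
    (advancing by ``step``), greedily drop the later-positioned variant of
    any pair with r2 > r2_max. Returns kept variant ids."""
    order = g.variants.sort_values(["chrom", "pos"]).index.to_numpy()
    removed: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for idx in order:
        by_chrom.setdefault(g.variants.loc[idx, "chrom"], []).append(int(idx))
    for chrom_indices in by_chrom.values():
        start = 0
        while start < len(chrom_indices):
            win = [i for i in chrom_indices[start : start + window] if i not in removed]
            for ai in range(len(win)):
                if win[ai] in removed:
                    continue
                for bi in range(ai + 1, len(win)):
                    if win[bi] in removed:
                        continue
                    try:
                        r2 = ld_r2(g.dosage[win[ai]], g.dosage[win[bi]])
                    except ValueError:
                        continue
                    if r2 > r2_max:
                        removed.add(win[bi])
            if start + window >= len(chrom_indices):
                break
            start += step
    return [g.variants.loc[i, "variant_id"] for i in order if i not in removed]


def genotype_pcs(g: GenotypeStudy, k: int = 3) -> pd.DataFrame:
    """Top-k principal component scores of individuals from the centered,
    mean-imputed dosage matrix; deterministic sign convention."""
    x = g.dosage.T.copy()  # individuals x variants
    if k >= min(x.shape):
        raise ValueError("k must be < min(dims)")
    col_mean = np.nanmean(x, axis=0)
    nan_pos = np.isnan(x)
    x[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s[k - 1] <= 1e-12:
        raise ValueError("k exceeds the rank of the dosage matrix")
    scores = u[:, :k] * s[:k]
    for c in range(k):
        pivot = np.argmax(np.abs(scores[:, c]))
        if scores[pivot, c] < 0:
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(scores, index=g.individuals, columns=[f"PC{i + 1}" for i in range(k)])


def factor_count_schedule(n_samples: int) -> int:
    """Hidden-factor count by sample size: <150 -> 15, 150-249 -> 30,
    250-349 -> 45, >= 350 -> 60."""
    if n_samples < 150:
        return 15
    if n_samples < 250:
        return 30
    if n_samples < 350:
        return 45
    return 60


def hidden_factors(expr: pd.DataFrame, n_factors: int | None = None) -> pd.DataFrame:
    """Expression hidden factors: top-k sample-space principal components.

    Stand-in for latent-factor methods; k defaults to the sample-size
    schedule and is clipped below n_samples.
    """
    n_samples = expr.shape[1]
    k = factor_count_schedule(n_samples) if n_factors is None else n_factors
    if k >= n_samples:
        log.warning("hidden_factors: k=%d clipped to %d", k, n_samples - 1)
        k = n_samples - 1
    x = expr.to_numpy(dtype=float).T  # samples x loci
    x = np.where(np.isnan(x), np.nanmean(x, axis=0, keepdims=True), x)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(k, int((s > 1e-12).sum()))
    scores = u[:, :k] * s[:k]
    for c in range(k):
        pivot = np.argmax(np.abs(scores[:, c]))
        if scores[pivot, c] < 0:
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(scores, index=expr.columns, columns=[f"F{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# cis-QTL mapping
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residuals of y on [1, covariates]; returns (residuals, n_covariates)."""
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        return y - y.mean(), 0
    c = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(c, y, rcond=None)
    return y - c @ beta, covariates.shape[1]


def cis_variant_indices(
    g: GenotypeStudy, chrom: str, tss: int, window: int = 1_000_000
) -> np.ndarray:
    pos = g.variants["pos"].to_numpy()
    mask = (g.variants["chrom"].to_numpy() == chrom) & (np.abs(pos - tss) <= window)
    return np.where(mask)[0]


def cis_scan(
    expr_int: pd.DataFrame,
    tss_map: Mapping[str, tuple[str, int]],
    g: GenotypeStudy,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    min_obs: int = 20,
) -> pd.DataFrame:
    """Nominal cis associations for every (locus, cis variant) pair.

    Expression is residualized on the covariates, then each variant's dosage
    is fit by least squares against the residual; the t-test uses
    n - 2 - n_covariates degrees of freedom.
    """
    cov = None
    if covariates is not None:
        cov = covariates.loc[list(expr_int.columns)].to_numpy(dtype=float)
    records = []
    ind_index = {ind: i for i, ind in enumerate(g.individuals)}
    col_to_g = np.array([ind_index[c] for c in expr_int.columns])
    for locus in expr_int.index:
        chrom, tss = tss_map[locus]
        cis_idx = cis_variant_indices(g, chrom, tss, window)
        if cis_idx.size == 0:
            continue
        y_all = expr_int.loc[locus].to_numpy(dtype=float)
        y_mask = ~np.isnan(y_all)
        if y_mask.sum() < min_obs:
            continue
        y = y_all[y_mask]
        c_sub = cov[y_mask] if cov is not None else None
        y_res, n_cov = _residualize(y, c_sub)
        for vi in cis_idx:
            x_all = g.dosage[vi][col_to_g][y_mask]
            x_mask = ~np.isnan(x_all)
            n = int(x_mask.sum())
            dof = n - 2 - n_cov
            if n < min_obs or dof < 1:
                continue
            x = x_all[x_mask]
            yr = y_res[x_mask]
            sxx = ((x - x.mean()) ** 2).sum()
            if sxx == 0:
                continue
            sxy = ((x - x.mean()) * (yr - yr.mean())).sum()
            beta = sxy / sxx
            syy = ((yr - yr.mean()) ** 2).sum()
            resvar = max(syy - beta * sxy, 0.0) / dof
            se = math.sqrt(resvar / sxx) if resvar > 0 else 0.0
            if se == 0:
                p = 0.0 if beta != 0 else 1.0
            else:
                t = beta / se
                p = float(2.0 * stats.t.sf(abs(t), dof))
            records.append(
                {
                    "locus_id": locus,
                    "variant_id": g.variants.loc[vi, "variant_id"],
                    "beta": beta,
                    "se": se,
                    "p_nominal": p,
                    "n": n,
                }
            )
    return pd.DataFrame(
        records, columns=["locus_id", "variant_id", "beta", "se", "p_nominal", "n"]
    )


def permutation_pass(
    expr_int: pd.DataFrame,
    tss_map: Mapping[str, tuple[str, int]],
    g: GenotypeStudy,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    min_obs: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus empirical p-value for the best cis association.

    The statistic is the maximum absolute correlation between residualized
    expression and residualized dosage over the cis window (equivalent to
    the minimum nominal p at common sample size). Sample labels of the
    residualized expression are permuted; the empirical p carries the
    add-one correction (1 + #{perm >= obs}) / (1 + n_perm). With
    ``exhaustive=True`` all n! permutations are enumerated (small n only).
    """
    if n_perm < 100 and not exhaustive:
        log.warning("permutation_pass: n_perm=%d is low", n_perm)
    rng = np.random.default_rng(seed)
    cov_frame = covariates.loc[list(expr_int.columns)] if covariates is not None else None
    ind_index = {ind: i for i, ind in enumerate(g.individuals)}
    col_to_g = np.array([ind_index[c] for c in expr_int.columns])
    records = []
    for locus in expr_int.index:
        chrom, tss = tss_map[locus]
        cis_idx = cis_variant_indices(g, chrom, tss, window)
        if cis_idx.size == 0:
            continue
        y_all = expr_int.loc[locus].to_numpy(dtype=float)
        y_mask = ~np.isnan(y_all)
        n = int(y_mask.sum())
        if n < max(min_obs, 3):
            continue
        y = y_all[y_mask]
        cov_sub = cov_frame.to_numpy(dtype=float)[y_mask] if cov_frame is not None else None
        y_res, n_cov = _residualize(y, cov_sub)
        dof = n - 2 - n_cov
        if dof < 1:
            continue
        x = g.dosage[np.ix_(cis_idx, col_to_g)][:, y_mask].T.astype(float)  # n x m
        col_mean = np.nanmean(x, axis=0)
        nan_pos = np.isnan(x)
        if nan_pos.any():
            x[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
        xr = np.empty_like(x)
        for j in range(x.shape[1]):
            xr[:, j], _ = _residualize(x[:, j], cov_sub)
        x_norm = np.linalg.norm(xr, axis=0)
        good = x_norm > 1e-12
        if not good.any():
            continue
        xn = xr[:, good] / x_norm[good]
        y_norm = np.linalg.norm(y_res)
        if y_norm <= 1e-12:
            continue
        yn = y_res / y_norm
        obs_r = np.abs(xn.T @ yn)
        obs_stat = float(obs_r.max())
        best_j = int(np.argmax(obs_r))
        if exhaustive:
            perms = np.array(list(itertools.permutations(range(n))))
        else:
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        yp = yn[perms.T]  # n x P
        null_stats = np.abs(xn.T @ yp).max(axis=0)
        n_total = perms.shape[0]
        p_emp = float((1 + (null_stats >= obs_stat - 1e-12).sum()) / (1 + n_total))

        def _r_to_p(r: float) -> float:
            r = min(abs(r), 1.0 - 1e-15)
            t = r * math.sqrt(dof / (1.0 - r * r))
            return float(2.0 * stats.t.sf(t, dof))

        r_thresh = float(np.quantile(null_stats, 1.0 - alpha))
        records.append(
            {
                "locus_id": locus,
                "best_variant": g.variants.loc[cis_idx[np.where(good)[0][best_j]], "variant_id"],
                "p_nominal_min": _r_to_p(obs_stat),
                "p_perm": p_emp,
                "nominal_threshold": _r_to_p(r_thresh),
                "n_cis_variants": int(good.sum()),
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "locus_id",
            "best_variant",
            "p_nominal_min",
            "p_perm",
            "nominal_threshold",
            "n_cis_variants",
        ],
    )


def call_ehervs(perm_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust the permutation p-values across loci and flag eHERVs."""
    out = perm_results.copy()
    out["qvalue"] = bh_adjust(out["p_perm"].to_numpy())
    out["is_eherv"] = out["qvalue"] <= alpha
    return out


# ---------------------------------------------------------------------------
# Matched-background enrichment
# ---------------------------------------------------------------------------


def tss_distances(variants: pd.DataFrame, tss_by_chrom: Mapping[str, Sequence[int]]) -> np.ndarray:
    out = np.empty(len(variants))
    for i, row in enumerate(variants.itertuples()):
        positions = tss_by_chrom.get(row.chrom, ())
        out[i] = nearest_tss_distance(row.pos, positions) if len(positions) else np.inf
    return out


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    return edges


def matched_background(
    targets: pd.DataFrame,
    pool: pd.DataFrame,
    tss_by_chrom: Mapping[str, Sequence[int]],
    n_bins_maf: int = 20,
    n_bins_dist: int = 20,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Match each target variant to one pool variant with the same
    chromosome, MAF quantile bin, and log-TSS-distance bin.

    ``targets`` and ``pool`` carry variant_id, chrom, pos, maf; the pool
    must exclude the targets. Sampling is without replacement; empty bins
    fall back to the nearest non-empty bin on the same chromosome.
    Returns (matched ids, kept target ids) — targets with no available
    match are dropped from both sets and logged.
    """
    overlap = set(targets["variant_id"]) & set(pool["variant_id"])
    if overlap:
        raise ValueError("pool must exclude target variants")
    all_maf = np.concatenate([targets["maf"].to_numpy(), pool["maf"].to_numpy()])
    t_dist = np.log10(1 + tss_distances(targets, tss_by_chrom))
    p_dist = np.log10(1 + tss_distances(pool, tss_by_chrom))
    all_dist = np.concatenate([t_dist, p_dist])
    maf_edges = _quantile_bins(all_maf, n_bins_maf)
    dist_edges = _quantile_bins(all_dist, n_bins_dist)

    def bin_of(value: float, edges: np.ndarray) -> int:
        return int(np.clip(np.searchsorted(edges, value, side="right") - 1, 0, len(edges) - 2))

    pool_bins: dict[tuple[str, int, int], list[int]] = {}
    for i, row in enumerate(pool.itertuples()):
        key = (row.chrom, bin_of(row.maf, maf_edges), bin_of(p_dist[i], dist_edges))
        pool_bins.setdefault(key, []).append(i)

    rng = np.random.default_rng(seed)
    used: set[int] = set()
    matched, kept = [], []
    n_fallback = n_dropped = 0
    for i, row in enumerate(targets.itertuples()):
        mb = bin_of(row.maf, maf_edges)
        db = bin_of(t_dist[i], dist_edges)
        choice = None
        for radius in range(max(len(maf_edges), len(dist_edges))):
            candidates = []
            for dm in range(-radius, radius + 1):
                for dd in range(-radius, radius + 1):
                    if max(abs(dm), abs(dd)) != radius:
                        continue
                    key = (row.chrom, mb + dm, db + dd)
                    candidates.extend(j for j in pool_bins.get(key, ()) if j not in used)
            if candidates:
                if radius > 0:
                    n_fallback += 1
                choice = int(rng.choice(np.array(sorted(candidates))))
                break
        if choice is None:
            n_dropped += 1
            continue
        used.add(choice)
        matched.append(pool.iloc[choice]["variant_id"])
        kept.append(row.variant_id)
    if n_fallback:
        log.info("matched_background: %d target(s) used a fallback bin", n_fallback)
    if n_dropped:
        log.warning("matched_background: %d unmatched target(s) dropped", n_dropped)
    return matched, kept


def enrichment_test(
    targets: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, set[str]],
    drop_categories: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-category Fisher enrichment of targets vs matched background.

    Odds ratio is the sample cross-product ad/bc with a 0.5 continuity
    correction when any cell is zero; p is the two-tailed Fisher exact test;
    FDR is BH across categories.
    """
    targets = set(targets)
    background = set(background)
    if targets & background:
        raise ValueError("targets and background must be disjoint")
    drop = set(drop_categories)
    categories = sorted(
        {
            cat
            for vid in itertools.chain(targets, background)
            for cat in annotation.get(vid, ())
        }
        - drop
    )
    rows = []
    for cat in categories:
        a = sum(1 for v in targets if cat in annotation.get(v, ()))
        c = sum(1 for v in background if cat in annotation.get(v, ()))
        b = len(targets) - a
        d = len(background) - c
        if a == 0 and c == 0:
            continue
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append({"category": cat, "odds_ratio": odds, "p": p, "a": a, "b": b, "c": c, "d": d})
    df = pd.DataFrame(rows, columns=["category", "odds_ratio", "p", "a", "b", "c", "d"])
    df["fdr"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def expand_gwas_ld(
    gwas_hits: pd.DataFrame,
    g: GenotypeStudy,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.8,
) -> list[str]:
    """Genome-wide-significant GWAS variants plus all panel variants in LD
    (r2 > r2_thresh) with any of them.

    ``gwas_hits`` carries variant_id and p. Hits absent from the genotype
    panel are kept without expansion (logged).
    """
    sig = gwas_hits[gwas_hits["p"] < p_thresh]
    vid_to_idx = {v: i for i, v in enumerate(g.variants["variant_id"])}
    out = set(sig["variant_id"])
    n_absent = 0
    for vid in sig["variant_id"]:
        if vid not in vid_to_idx:
            n_absent += 1
            continue
        vi = vid_to_idx[vid]
        chrom = g.variants.loc[vi, "chrom"]
        same_chrom = np.where(g.variants["chrom"].to_numpy() == chrom)[0]
        for vj in same_chrom:
            if vj == vi:
                continue
            try:
                if ld_r2(g.dosage[vi], g.dosage[vj]) > r2_thresh:
                    out.add(g.variants.loc[vj, "variant_id"])
            except ValueError:
                continue
    if n_absent:
        log.warning("expand_gwas_ld: %d hit(s) absent from the panel", n_absent)
    return sorted(out)
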