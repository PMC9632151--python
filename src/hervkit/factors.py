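"""Biological-factor effects on locus expression.

Per-site sex/ethnicity differential expression and age correlations, plus a
global linear mixed model with a fixed body-site effect, a random intercept
per individual, and the factor of interest (sex/ethnicity fixed, age as a
covariate). Factor significance comes from a likelihood-ratio test of the
ML fits with and without the factor term.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SampleMeta
from .expression import bh_adjust, pairwise_de

log = logging.getLogger(__name__)

SEX_SPECIFIC_SITES = ("ovary", "prostate", "testis", "uterus", "vagina")


def per_site_factor_de(
    tpm: pd.DataFrame,
    meta: Sequence[SampleMeta],
    factor: str,
    exclude_sites: Sequence[str] | None = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Two-level factor DE within each body site (rank-sum engine, BH per
    site). Sex-specific sites are excluded from the sex analysis by default.

    The log fold change is level_hi - level_lo with levels taken in sorted
    order (e.g. male - female for sex coded female/male).
    """
    if factor not in ("sex", "ethnicity"):
        raise ValueError("factor must be 'sex' or 'ethnicity'")
    if exclude_sites is None:
        exclude_sites = SEX_SPECIFIC_SITES if factor == "sex" else ()
    exclude = {s.lower() for s in exclude_sites}
    by_site: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_site.setdefault(m.body_site, []).append(m)
    frames = []
    for site in sorted(by_site):
        if site.lower() in exclude:
            continue
        members = by_site[site]
        levels = sorted({getattr(m, factor) for m in members})
        if len(levels) != 2:
            log.info("per_site_factor_de: skipping %s (%d %s level(s))", site, len(levels), factor)
            continue
        lo, hi = levels
        group_hi = [m.sample_id for m in members if getattr(m, factor) == hi]
        group_lo = [m.sample_id for m in members if getattr(m, factor) == lo]
        if len(group_hi) < min_group or len(group_lo) < min_group:
            log.info("per_site_factor_de: skipping %s (group too small)", site)
            continue
        de = pairwise_de(tpm, group_hi, group_lo)
        de = de.reset_index().rename(columns={"index": "locus_id"})
        de.insert(1, "body_site", site)
        de.insert(2, "factor", factor)
        de.insert(3, "level_hi", hi)
        de.insert(4, "level_lo", lo)
        frames.append(de)
    if not frames:
        return pd.DataFrame(
            columns=["locus_id", "body_site", "factor", "level_hi", "level_lo", "lfc", "p", "fdr", "engine"]
        )
    return pd.concat(frames, ignore_index=True)


def age_correlation(
    tpm: pd.DataFrame,
    meta: Sequence[SampleMeta],
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-(locus, site) Pearson correlation of log2(TPM+1) with age; BH per
    site; FDR-significant records get a direction label."""
    by_site: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_site.setdefault(m.body_site, []).append(m)
    frames = []
    for site in sorted(by_site):
        members = [m for m in by_site[site] if m.sample_id in tpm.columns]
        if len(members) < min_samples:
            log.info("age_correlation: skipping %s (n=%d)", site, len(members))
            continue
        ages = np.array([m.age for m in members])
        if np.std(ages) == 0:
            continue
        expr = np.log2(tpm[[m.sample_id for m in members]].to_numpy(dtype=float) + 1.0)
        rows = []
        for i, locus in enumerate(tpm.index):
            y = expr[i]
            if np.std(y) == 0:
                continue
            r, p = stats.pearsonr(ages, y)
            rows.append({"locus_id": locus, "body_site": site, "r": float(r), "p": float(p)})
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["direction"] = np.where(
            df["fdr"] < 0.05, np.where(df["r"] > 0, "increasing", "decreasing"), "ns"
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["locus_id", "body_site", "r", "p", "fdr", "direction"])
    return pd.concat(frames, ignore_index=True)


def fit_global_lmm(
    observations: pd.DataFrame,
    factor: str,
    min_sites: int = 6,
    min_per_level: int = 2,
) -> dict:
    """Mixed-model factor effect for one locus across body sites.

    ``observations`` has columns value, body_site, individual, and the
    factor column (sex/ethnicity categorical, age numeric). The model is
    value ~ body_site (fixed) + factor + random intercept per individual,
    fit by maximum likelihood; the factor p-value is a likelihood-ratio
    test against the model without the factor term.
    """
    import statsmodels.formula.api as smf

    df = observations.dropna(subset=["value", "body_site", "individual", factor]).copy()
    n_sites = df["body_site"].nunique()
    if n_sites < min_sites:
        raise ValueError(f"locus observed in {n_sites} site(s); needs >= {min_sites}")
    categorical = not np.issubdtype(df[factor].dtype, np.number)
    if categorical:
        counts = df.groupby(factor)["individual"].nunique()
        if (counts < min_per_level).any():
            raise ValueError("factor level with too few individuals")
        term = f"C({factor})"
        df_extra = df[factor].nunique() - 1
    else:
        term = factor
        df_extra = 1
    flag = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if df["body_site"].nunique() > 1:
                full_f = f"value ~ C(body_site) + {term}"
                null_f = "value ~ C(body_site)"
            else:
                full_f = f"value ~ {term}"
                null_f = "value ~ 1"
            full = smf.mixedlm(full_f, df, groups=df["individual"]).fit(reml=False)
            null = smf.mixedlm(null_f, df, groups=df["individual"]).fit(reml=False)
        except Exception as exc:  # singular / non-converging fits are flagged
            return {"estimate": np.nan, "se": np.nan, "p": np.nan, "flag": f"fit_failed: {exc}"}
    if not (full.converged and null.converged):
        flag = "non_converged"
    lrt = 2.0 * (full.llf - null.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=df_extra))
    # report the (last) factor coefficient: for a 2-level factor this is the
    # hi-vs-lo contrast; for age it is the slope
    coef_names = [name for name in full.params.index if factor in name]
    estimate = float(full.params[coef_names[-1]]) if coef_names else np.nan
    se = float(full.bse[coef_names[-1]]) if coef_names else np.nan
    return {
        "estimate": estimate,
        "se": se,
        "p": p,
        "lrt": float(lrt),
        "n_sites": int(n_sites),
        "n_individuals": int(df["individual"].nunique()),
        "flag": flag,
    }


def global_factor_scan(
    log_expr: pd.DataFrame,
    meta: Sequence[SampleMeta],
    factor: str,
    min_sites: int = 6,
) -> pd.DataFrame:
    """Fit the global LMM for every locus and BH-adjust across loci."""
    meta_by_sample = {m.sample_id: m for m in meta}
    rows = []
    for locus in log_expr.index:
        obs = []
        for sample_id in log_expr.columns:
            m = meta_by_sample.get(sample_id)
            if m is None:
                continue
            value = log_expr.loc[locus, sample_id]
            if np.isnan(value):
                continue
            obs.append(
                {
                    "value": value,
                    "body_site": m.body_site,
                    "individual": m.individual_id,
                    "sex": m.sex,
                    "ethnicity": m.ethnicity,
                    "age": m.age,
                }
            )
        df = pd.DataFrame(obs)
        if df.empty:
            continue
        try:
            res = fit_global_lmm(df, factor, min_sites=min_sites)
        except ValueError as exc:
            log.info("global_factor_scan: %s skipped (%s)", locus, exc)
            continue
        res["locus_id"] = locus
        res["factor"] = factor
        rows.append(res)
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
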