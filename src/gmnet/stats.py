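"""Group-comparison and anhedonia-correlation statistics.

Implements the statistical layer applied to per-subject small-worldness
values: Welch t-tests and a Yates-corrected chi-square for demographics, an
ANCOVA (OLS with a group indicator plus covariates) for group differences in
sigma controlling for total grey-matter volume, partial correlations between
sigma and the anhedonia scales, a Fisher r-to-z test for the difference of
the two groups' correlation coefficients, and Benjamini-Hochberg FDR
correction within each test family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t",
    "welch_t_raw",
    "chi2_yates",
    "ancova_group_effect",
    "partial_correlation",
    "compare_correlations_fisher",
    "fdr_bh",
    "run_full_statistics",
]


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    group_coef: float
    n: int


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, df, p) with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("at least one group must have positive variance")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_raw(x, y):
    """Welch's t-test on raw vectors; agrees with the summary form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    return welch_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))


def chi2_yates(counts):
    """Chi-square test of independence on a 2x2 table, Yates-corrected.

    Returns (chi2, df, p); the continuity correction clamps the statistic at
    0 for perfectly proportional tables.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=True)
    return float(chi2), int(df), float(p)


def _design(group, covariates):
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("group must be binary")
    indicator = (group == levels[0]).astype(float)
    X = [np.ones_like(indicator), indicator]
    names = ["intercept", f"group[{levels[0]}]"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(indicator):
            cov = cov.T
        for k in range(cov.shape[1]):
            X.append(cov[:, k])
            names.append(f"cov{k}")
    return np.column_stack(X), names, levels


def ancova_group_effect(y, group, covariates=None) -> AncovaResult:
    """ANCOVA for a group effect: OLS of y on intercept + group + covariates.

    The F statistic for the group term has (1, n - p) degrees of freedom and
    equals the squared t of the group coefficient from the same fit.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    X, names, _ = _design(group, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    t_group = fit.tvalues[1]
    F = float(t_group**2)
    df_den = int(fit.df_resid)
    p = float(sps.f.sf(F, 1, df_den))
    return AncovaResult(F, 1, df_den, p, float(fit.params[1]), len(y))


def partial_correlation(x, y, covariates=None):
    """Partial correlation of x and y given covariates (residual method).

    Rows with missing values are dropped listwise.  Returns (r, n, k, p)
    where k is the number of covariates and p comes from the t distribution
    with n - k - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(cov).any(axis=1))
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    if n <= k + 3:
        raise ValueError("need n > k + 3 complete observations")
    Z = np.column_stack([np.ones(n), cov])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("degenerate residual variance")
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, n, k, p


def compare_correlations_fisher(r1, n1, k1, r2, n2, k2):
    """z-test for the difference of two independent (partial) correlations.

    Fisher r-to-z transform with variance 1/(n - 3 - k) per group:
    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3-k1) + 1/(n2-3-k2)).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    d1, d2 = n1 - 3 - k1, n2 - 3 - k2
    if d1 <= 0 or d2 <= 0:
        raise ValueError("need n - 3 - k > 0 in each group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / d1 + 1 / d2)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and the rejection set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# composite analysis plan
# ---------------------------------------------------------------------------

_PATIENT_EXTRA = ["duration_illness", "cpz_dose"]


def _group_split(cohort: pd.DataFrame):
    return cohort[cohort["group"] == "patient"], cohort[cohort["group"] == "control"]


def _demographics(cohort: pd.DataFrame) -> pd.DataFrame:
    pat, con = _group_split(cohort)
    rows = []
    for var in ["age", "education", "gm_volume", "pas", "sas"]:
        x = pat[var].dropna().to_numpy(float)
        y = con[var].dropna().to_numpy(float)
        try:
            t, df, p = welch_t_raw(x, y)
        except ValueError as err:  # e.g. too few complete observations
            rows.append({"variable": var, "test": "welch_t", "status": f"failed: {err}",
                         "n_patient": len(x), "n_control": len(y)})
            continue
        rows.append(
            {"variable": var, "test": "welch_t", "statistic": t, "df": df,
             "p_unc": p, "n_patient": len(x), "n_control": len(y), "status": "ok"}
        )
    table = pd.crosstab(cohort["group"], cohort["sex"]).reindex(
        index=["patient", "control"]
    )
    chi2, df, p = chi2_yates(table.to_numpy())
    rows.append(
        {"variable": "sex", "test": "chi2_yates", "statistic": chi2, "df": df,
         "p_unc": p, "n_patient": int(table.loc["patient"].sum()),
         "n_control": int(table.loc["control"].sum())}
    )
    return pd.DataFrame(rows)


def _ancova_family(
    merged: pd.DataFrame, scopes: list, scope_label: str
) -> pd.DataFrame:
    rows = []
    for scope in scopes:
        sub = merged[merged["region"] == scope].dropna(subset=["sigma"])
        if len(sub) < 5 or sub["group"].nunique() < 2:
            rows.append({"scope": f"{scope_label}:{scope}", "status": "insufficient"})
            continue
        res = ancova_group_effect(
            sub["sigma"].to_numpy(), sub["group"].to_numpy(),
            sub[["gm_volume"]].to_numpy(),
        )
        rows.append(
            {"scope": f"{scope_label}:{scope}", "test": "ancova_F",
             "statistic": res.F, "df": f"(1, {res.df_den})", "p_unc": res.p,
             "sigma_patient": sub.loc[sub.group == "patient", "sigma"].mean(),
             "sigma_control": sub.loc[sub.group == "control", "sigma"].mean(),
             "status": "ok"}
        )
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok" if "status" in out else pd.Series([], dtype=bool)
    if ok.any():
        p_adj, _ = fdr_bh(out.loc[ok, "p_unc"].to_numpy())
        out.loc[ok, "p_fdr"] = p_adj
        out.loc[ok, "significance"] = [
            "significant" if a <= 0.05 else ("trend" if a <= 0.1 else "ns")
            for a in p_adj
        ]
    return out


def _correlation_family(
    merged: pd.DataFrame, scopes: list, scope_label: str, scale: str
) -> pd.DataFrame:
    rows = []
    pat, con = _group_split(merged)
    for scope in scopes:
        row = {"scope": f"{scope_label}:{scope}", "scale": scale.upper()}
        try:
            sp = pat[pat["region"] == scope]
            sc = con[con["region"] == scope]
            r1, n1, k1, p1 = partial_correlation(
                sp["sigma"], sp[scale], sp[["gm_volume"] + _PATIENT_EXTRA]
            )
            r2, n2, k2, p2 = partial_correlation(
                sc["sigma"], sc[scale], sc[["gm_volume"]]
            )
            z, p = compare_correlations_fisher(r1, n1, k1, r2, n2, k2)
        except ValueError as err:
            rows.append({**row, "status": f"failed: {err}"})
            continue
        rows.append(
            {**row, "r_patient": r1, "n_patient": n1, "k_patient": k1,
             "p_patient": p1, "r_control": r2, "n_control": n2,
             "k_control": k2, "p_control": p2, "z": z, "p_unc": p,
             "status": "ok"}
        )
    return pd.DataFrame(rows)


def run_full_statistics(
    cohort: pd.DataFrame,
    global_sigma: pd.DataFrame,
    icn_sigma: pd.DataFrame | None = None,
    regional_sigma: pd.DataFrame | None = None,
    retained_regions: list | None = None,
    q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """The full analysis plan on a cohort with per-subject sigma values.

    Inputs are the covariate table and per-subject sigma tables
    (``subject_id``, ``region``, ``sigma``; the global table may instead have
    a single ``sigma`` column).  Steps: (a) demographics tests; (b) ANCOVA on
    sigma controlling for GM volume at global, ICN and regional scope, FDR
    within each scope family; (c) per-group partial correlations of sigma
    with PAS and SAS (patients additionally control illness duration and
    antipsychotic dose; missing SAS drops listwise); (d) Fisher z comparison
    of the group coefficients per scope/scale, FDR within each family;
    (e) post-hoc per-group correlations reported for scopes passing the
    z-test.  Education is deliberately not a covariate.
    """
    results: dict[str, pd.DataFrame] = {}
    results["demographics"] = _demographics(cohort)

    if "region" not in global_sigma.columns:
        global_sigma = global_sigma.assign(region="whole_brain")
    families = [("global", global_sigma)]
    if icn_sigma is not None:
        families.append(("icn", icn_sigma))
    if regional_sigma is not None:
        families.append(("region", regional_sigma))

    corr_frames = []
    for label, sigma_table in families:
        merged = cohort.merge(
            sigma_table[["subject_id", "region", "sigma"]], on="subject_id"
        )
        scopes = sorted(sigma_table["region"].unique().tolist())
        if label == "region" and retained_regions is not None:
            scopes = [s for s in scopes if s in retained_regions]
        results[f"ancova_{label}"] = _ancova_family(merged, scopes, label)
        for scale in ("pas", "sas"):
            corr = _correlation_family(merged, scopes, label, scale)
            ok = corr["status"] == "ok"
            if ok.any():
                p_adj, _ = fdr_bh(corr.loc[ok, "p_unc"].to_numpy(), q)
                corr.loc[ok, "p_fdr"] = p_adj
                corr.loc[ok, "significance"] = [
                    "significant" if a <= q else ("trend" if a <= 0.1 else "ns")
                    for a in p_adj
                ]
            corr["family"] = f"{label}:{scale.upper()}"
            corr_frames.append(corr)
    results["correlation_comparisons"] = pd.concat(corr_frames, ignore_index=True)

    cc = results["correlation_comparisons"]
    if "significance" in cc.columns:
        posthoc = cc[cc["significance"] == "significant"]
    else:
        posthoc = cc.iloc[0:0]
    results["posthoc_correlations"] = posthoc[
        [c for c in ["scope", "scale", "r_patient", "p_patient",
                     "r_control", "p_control", "z", "p_unc", "p_fdr"]
         if c in posthoc.columns]
    ].reset_index(drop=True)
    return results
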