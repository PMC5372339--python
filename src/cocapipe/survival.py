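"""Survival validation of a derived signature in an independent cohort.

Luminal-A-like samples are split by hierarchical clustering on the signature
features (Pearson distance, complete linkage) and the resulting groups are
compared with Kaplan-Meier curves, (stratified) log-rank tests and a Cox
proportional-hazards fit adjusted for covariates.

Right-censored survival records live in a plain DataFrame with ``time``,
``event`` (0/1), ``group`` and optional ``stratum`` / covariate columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2, norm

from .classifiers import hcluster_cut

logger = logging.getLogger(__name__)

__all__ = [
    "validate_survival_table",
    "split_by_signature",
    "km_estimate",
    "logrank_test",
    "cox_hr",
]


def validate_survival_table(surv: pd.DataFrame) -> pd.DataFrame:
    """Check the survival-table contract: time >= 0, event in {0, 1}."""
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return surv


def split_by_signature(
    expr: pd.DataFrame, signature: list | pd.Index, k: int = 2
) -> tuple[pd.Series, list]:
    """Cluster samples on signature-feature expression into k groups.

    Uses Pearson distance with complete linkage. Signature features absent
    from the matrix are reported (and logged); at least two must be present.
    Groups are relabeled by decreasing size (1 = largest) — orientation
    toward outcome is *not* imposed before testing.

    Returns ``(labels, missing_features)``.
    """
    signature = pd.Index(signature)
    present = expr.index.intersection(signature)
    missing = list(signature.difference(expr.index))
    if missing:
        logger.warning(
            "split_by_signature: %d of %d signature features absent: %s",
            len(missing), len(signature), missing,
        )
    if len(present) < 2:
        raise ValueError("fewer than 2 signature features present in the matrix")
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to split")
    sub = expr.loc[present]
    if (sub.std(axis=1) == 0).all():
        raise ValueError("all signature features are constant")
    raw = hcluster_cut(sub, distance="pearson", method="complete", k=k)
    order = raw.value_counts().index  # largest first; ties by first occurrence
    remap = {old: new + 1 for new, old in enumerate(order)}
    return raw.map(remap).rename("signature_group"), missing


def km_estimate(
    surv: pd.DataFrame, group_col: str = "group", alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group with Greenwood bands.

    Returns, per group, a step table indexed by event time with columns
    ``n_risk``, ``n_event``, ``survival``, ``lower``, ``upper``; the
    confidence band uses the Greenwood variance on the log-survival scale.
    Empty groups are skipped; a group with no events gets an empty step
    table (the curve is constant at 1).
    """
    validate_survival_table(surv)
    if surv["event"].sum() < 1:
        logger.warning("km_estimate: no events at all; curves are constant at 1")
    z = norm.ppf(1 - alpha / 2)
    out: dict[str, pd.DataFrame] = {}
    for g, sub in surv.groupby(group_col, observed=True):
        if len(sub) == 0:
            continue
        times = np.sort(sub.loc[sub["event"] == 1, "time"].unique())
        rows = []
        s = 1.0
        var_sum = 0.0  # running sum of d / (n (n - d))
        for t in times:
            n_risk = int((sub["time"] >= t).sum())
            d = int(((sub["time"] == t) & (sub["event"] == 1)).sum())
            if n_risk == 0:
                continue
            s *= 1.0 - d / n_risk
            if n_risk > d:
                var_sum += d / (n_risk * (n_risk - d))
            if s > 0:
                se_log = np.sqrt(var_sum)
                lower = s * np.exp(-z * se_log)
                upper = min(s * np.exp(z * se_log), 1.0)
            else:
                lower = upper = 0.0
            rows.append(
                {"time": t, "n_risk": n_risk, "n_event": d,
                 "survival": s, "lower": lower, "upper": upper}
            )
        cols = ["time", "n_risk", "n_event", "survival", "lower", "upper"]
        out[str(g)] = pd.DataFrame(rows, columns=cols).set_index("time")
    return out


def logrank_test(
    surv: pd.DataFrame,
    group_col: str = "group",
    strata_col: str | None = None,
) -> tuple[float, int, float]:
    """Multi-group (optionally stratified) log-rank test.

    Observed-minus-expected event counts and their covariance are
    accumulated over the pooled risk set at every event time — per stratum
    when ``strata_col`` is given, then summed across strata — and the
    chi-squared statistic is formed from the first G-1 groups.

    Returns ``(chi2_statistic, df, p_value)``.
    """
    validate_survival_table(surv)
    groups = sorted(surv[group_col].dropna().unique(), key=str)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    g_index = {g: i for i, g in enumerate(groups)}
    ng = len(groups)

    if strata_col is None:
        parts = [surv]
    else:
        parts = [sub for _, sub in surv.groupby(strata_col, observed=True)]

    o_minus_e = np.zeros(ng)
    cov = np.zeros((ng, ng))
    for part in parts:
        times = np.sort(part.loc[part["event"] == 1, "time"].unique())
        t_all = part["time"].to_numpy()
        ev = part["event"].to_numpy()
        gi = part[group_col].map(g_index).to_numpy()
        for t in times:
            at_risk = t_all >= t
            n = at_risk.sum()
            if n == 0:
                continue
            n_g = np.bincount(gi[at_risk], minlength=ng).astype(float)
            dying = at_risk & (t_all == t) & (ev == 1)
            d = dying.sum()
            d_g = np.bincount(gi[dying], minlength=ng).astype(float)
            e_g = d * n_g / n
            o_minus_e += d_g - e_g
            if n > 1:
                factor = d * (n - d) / (n - 1)
                v = factor * (np.diag(n_g / n) - np.outer(n_g, n_g) / n**2)
                cov += v
    # drop one group to obtain a full-rank system
    u = o_minus_e[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    df = ng - 1
    p = float(chi2.sf(stat, df))
    return stat, df, p


def cox_hr(
    surv: pd.DataFrame,
    group_col: str = "group",
    covariates: list[str] | None = None,
    strata_col: str | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit; hazard ratio for the group indicator.

    The group column (binary, or categorical with a reference level taken as
    the first sorted value) and any covariates enter a partial-likelihood
    fit with Efron handling of ties; the hazard ratio is exp(coef) with a
    Wald 95% CI. Raises on constant covariates or non-convergence.
    """
    validate_survival_table(surv)
    covariates = covariates or []
    cols = [group_col] + covariates
    data = surv[["time", "event"] + cols + ([strata_col] if strata_col else [])].dropna()

    design = pd.DataFrame(index=data.index)
    levels = sorted(data[group_col].unique(), key=str)
    if len(levels) < 2:
        raise ValueError("group column is constant")
    for lev in levels[1:]:
        design[f"{group_col}_{lev}"] = (data[group_col] == lev).astype(float)
    for cov in covariates:
        col = data[cov]
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        if col.dtype == object or str(col.dtype) == "category":
            for lev in sorted(col.unique(), key=str)[1:]:
                design[f"{cov}_{lev}"] = (col == lev).astype(float)
        else:
            design[cov] = col.astype(float)
    design["time"] = data["time"]
    design["event"] = data["event"]
    if strata_col:
        design["_stratum"] = data[strata_col]

    n_events = int(data["event"].sum())
    if n_events < design.shape[1] - 2 - (1 if strata_col else 0):
        raise ValueError(
            f"too few events ({n_events}) for the number of parameters"
        )

    cph = CoxPHFitter()
    try:
        cph.fit(
            design,
            duration_col="time",
            event_col="event",
            strata="_stratum" if strata_col else None,
        )
    except Exception as exc:  # convergence / separation
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    out = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_lower": np.exp(summary["coef lower 95%"]),
            "ci_upper": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    out.index.name = "term"
    return out
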