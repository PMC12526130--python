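"""Structure signature derivation and survival analysis.

Sample-level mean expression (library-size normalized, log1p) is
correlated gene-by-gene with the TSS across samples; genes with Pearson
r strictly above a threshold (default 0.6) form the *structure
signature*. Patients scored by mean z-scored signature expression are
median-split into high/low groups and compared by Kaplan–Meier curves,
the log-rank test, and a proportional-hazards model adjusted for age,
sex, and MGMT status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .core import ExpressionMatrix, SurvivalTable, ValidationError

__all__ = [
    "normalize_expression",
    "sample_mean_expression",
    "gene_tss_correlation",
    "StructureSignature",
    "derive_signature",
    "score_and_stratify",
    "km_estimate",
    "logrank_test",
    "cox_adjusted",
]


def normalize_expression(expr: ExpressionMatrix, target_sum: float | None = None) -> np.ndarray:
    """Library-size scaling to a common total (median by default) + log1p."""
    X = np.asarray(expr.values, dtype=float)
    totals = X.sum(axis=1)
    if target_sum is None:
        positive = totals[totals > 0]
        target_sum = float(np.median(positive)) if len(positive) else 1.0
    scale = np.divide(
        target_sum, totals, out=np.ones_like(totals), where=totals > 0
    )
    return np.log1p(X * scale[:, None])


def sample_mean_expression(
    exprs: dict[str, ExpressionMatrix], normalize: bool = True
) -> pd.DataFrame:
    """Samples × genes table of per-sample mean (normalized) expression."""
    rows = {}
    genes = None
    for sid in sorted(exprs):
        em = exprs[sid]
        if genes is None:
            genes = list(em.genes)
        elif list(em.genes) != genes:
            raise ValidationError("gene lists differ between samples")
        X = normalize_expression(em) if normalize else np.asarray(em.values, float)
        rows[sid] = X.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


def gene_tss_correlation(
    exprs: dict[str, ExpressionMatrix],
    tss_per_sample: dict[str, float],
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-gene Pearson r between sample-mean expression and TSS.

    Returns a frame indexed by gene with columns ``r`` and ``undefined``
    (True for genes constant across samples, which carry NaN).
    """
    means = sample_mean_expression(exprs, normalize=normalize)
    missing = set(means.index) - set(tss_per_sample)
    if missing:
        raise ValidationError(f"samples without a TSS value: {sorted(missing)}")
    if len(means) < 3:
        raise ValidationError("correlation needs at least 3 samples")
    tss = np.array([tss_per_sample[s] for s in means.index], dtype=float)
    X = means.to_numpy(dtype=float)
    sd = X.std(axis=0)
    const = (sd == 0) | (np.ptp(tss) == 0)
    r = np.full(X.shape[1], np.nan)
    ok = ~const
    if ok.any():
        Xc = X[:, ok] - X[:, ok].mean(axis=0)
        tc = tss - tss.mean()
        r[ok] = (Xc * tc[:, None]).sum(axis=0) / (
            np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((tc**2).sum())
        )
    return pd.DataFrame({"r": r, "undefined": const}, index=means.columns)


@dataclass(frozen=True)
class StructureSignature:
    """Genes whose sample-mean expression tracks the TSS."""

    per_gene_r: pd.Series
    genes: tuple[str, ...]
    threshold: float
    display_table: pd.DataFrame  # genes with r > 0.5 or r < −0.4, for reporting

    def is_empty(self) -> bool:
        return len(self.genes) == 0


def derive_signature(
    per_gene_r: pd.DataFrame | pd.Series, threshold: float = 0.6
) -> StructureSignature:
    """Select signature genes with r strictly above ``threshold``.

    The reporting table additionally lists genes with r > 0.5 or
    r < −0.4 (the display range used for correlation bar plots). An empty
    signature raises a warning; callers should then skip the survival
    stage.
    """
    if isinstance(per_gene_r, pd.DataFrame):
        r = per_gene_r["r"]
    else:
        r = per_gene_r
    r = r.astype(float)
    selected = tuple(r.index[r > threshold])
    if not selected:
        warnings.warn("empty structure signature: no gene exceeds the threshold", stacklevel=2)
    display = r[(r > 0.5) | (r < -0.4)].sort_values(ascending=False)
    return StructureSignature(
        per_gene_r=r,
        genes=selected,
        threshold=float(threshold),
        display_table=display.to_frame(name="r"),
    )


def score_and_stratify(
    expression: pd.DataFrame, signature: StructureSignature
) -> pd.DataFrame:
    """Score patients by mean z-scored signature expression; median split.

    ``expression`` is patients × genes (bulk or pseudo-bulk). Signature
    genes absent from the matrix are dropped with a warning; if none
    remain it is an error. Scores strictly above the median → ``high``,
    else ``low`` (ties go low, matching the structure classification).
    """
    if signature.is_empty():
        raise ValidationError("cannot stratify with an empty signature")
    if len(expression) < 4:
        raise ValidationError("stratification needs at least 4 patients")
    present = [g for g in signature.genes if g in expression.columns]
    dropped = set(signature.genes) - set(present)
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature gene(s) absent from expression: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    if not present:
        raise ValidationError("no signature gene measured in the expression matrix")
    X = expression[present].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    score = Z.mean(axis=1)
    med = float(np.median(score))
    group = np.where(score > med, "high", "low")
    return pd.DataFrame(
        {"score": score, "group": group}, index=expression.index
    )


def km_estimate(table: SurvivalTable, groups: pd.Series | None = None) -> dict:
    """Kaplan–Meier product-limit curves per group with Greenwood 95% CI.

    ``groups`` maps patient_id → group label (defaults to the table's
    ``group`` column). Ties are handled by the simultaneous-event
    convention of the product-limit estimator. Returns
    {group: DataFrame(time, survival, at_risk, ci_low, ci_high)}.
    """
    df = table.table
    if groups is None:
        if "group" not in df.columns:
            raise ValidationError("no group column and no groups given")
        groups = pd.Series(df["group"].to_numpy(), index=df["patient_id"])
    out = {}
    for g in sorted(pd.unique(groups)):
        ids = groups.index[groups == g]
        sub = df[df["patient_id"].isin(ids)]
        if len(sub) == 0:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        surv = kmf.survival_function_["KM_estimate"]
        ev = kmf.event_table
        # Greenwood variance: S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = ev["observed"] / (
                ev["at_risk"] * (ev["at_risk"] - ev["observed"])
            )
        term = term.replace([np.inf, -np.inf], 0.0).fillna(0.0)
        var = surv.to_numpy() ** 2 * term.cumsum().to_numpy()
        half = 1.959963984540054 * np.sqrt(var)
        curve = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "ci_low": np.clip(surv.to_numpy() - half, 0.0, 1.0),
                "ci_high": np.clip(surv.to_numpy() + half, 0.0, 1.0),
            }
        )
        out[str(g)] = curve.reset_index(drop=True)
    return out


def logrank_test(table: SurvivalTable, groups: pd.Series) -> dict:
    """Two-group log-rank chi-square (1 df) over pooled event times."""
    df = table.table.set_index("patient_id")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError("log-rank comparison needs exactly 2 groups")
    parts = []
    for g in levels:
        ids = groups.index[groups == g]
        sub = df.loc[df.index.intersection(ids)]
        if len(sub) == 0:
            raise ValidationError(f"group {g!r} has no patients")
        parts.append(sub)
    res = _ll_logrank(
        parts[0]["time"], parts[1]["time"],
        event_observed_A=parts[0]["event"], event_observed_B=parts[1]["event"],
    )
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


def cox_adjusted(
    table: SurvivalTable, group_col: str = "group", covariates=("age", "sex", "mgmt")
) -> dict:
    """Proportional-hazards model for the group effect, adjusted.

    Partial-likelihood estimation with Efron handling of tied event
    times (lifelines). Categorical covariates (sex, MGMT, group) are
    dummy-coded; the returned hazard ratio is for the group indicator
    (second sorted level vs first). Non-convergence raises with the
    optimizer's diagnostics; complete separation is flagged by lifelines'
    own warnings.
    """
    df = table.table.copy()
    cols = [group_col, *covariates]
    for c in cols:
        if c not in df.columns:
            raise ValidationError(f"survival table lacks covariate {c!r}")
        if df[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} is constant across the cohort")
    design = pd.DataFrame({"time": df["time"], "event": df["event"]})
    name_map = {}
    for c in cols:
        if pd.api.types.is_numeric_dtype(df[c]):
            design[c] = df[c].astype(float)
            name_map[c] = c
        else:
            levels = sorted(df[c].astype(str).unique())
            ref, rest = levels[0], levels[1:]
            for lev in rest:
                col = f"{c}_{lev}"
                design[col] = (df[c].astype(str) == lev).astype(float)
            name_map[c] = f"{c}_{rest[-1]}" if rest else c
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failures carry diagnostics
        raise ValidationError(f"hazard model did not converge: {exc}") from exc
    key = name_map[group_col]
    coef = float(cph.params_[key])
    se = float(cph.standard_errors_[key])
    return {
        "coef": coef,
        "hazard_ratio": float(np.exp(coef)),
        "se": se,
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "p": float(cph.summary.loc[key, "p"]),
        "covariate_coefs": {k: float(v) for k, v in cph.params_.items()},
    }
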