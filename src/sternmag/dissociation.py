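"""Reaction-time dissociation regression and group-homogeneity statistics.

Two nested linear models dissociate Sternberg reaction times into a
preparation/execution intercept, a serial memory-scanning slope in the set
size SZ, a target-probe offset, and (in the full model) exposure terms:

    baseline:  RT = a0 + a1*SZ + a2*TG
    exposure:  RT = b0 + b1*SZ + (b2 + b3*SZ)*EX + b4*TG

The exposure model restricted to EX = 0 rows reduces to the baseline model
(a0 = b0, a1 = b1, a2 = b4).  Fits are ordinary least squares on
correct-response trials; coefficient inference uses the Student-t reference
with n − k degrees of freedom.  From the full-model fit the derived exposure
effects are computed: the net exposure delay ΔRT(SZ) = b2 + b3·SZ, the
scanning-slope ratio b3/b1 and its implied search-time inflation 1 + b3/b1,
and the percentage change of the intercept 100·|b2|/b0.

Group homogeneity (demographics, habits, error/omission counts) is assessed
with Welch's unequal-variance two-sample t-test from summary statistics,
reporting the 95% confidence interval of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

EQ1_TERMS = ("intercept", "SZ", "TG")
EQ2_TERMS = ("intercept", "SZ", "EX", "SZxEX", "TG")


class FitError(ValueError):
    """The regression cannot be estimated from the given records."""


@dataclass
class ModelFit:
    """OLS fit of the baseline ('eq1') or exposure ('eq2') dissociation model."""

    model_id: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    n_used: int
    df_resid: int
    resid_sd_hat: float
    excluded: dict[str, int]

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.df_resid)
        return {
            k: (v - tcrit * self.std_errors[k], v + tcrit * self.std_errors[k])
            for k, v in self.coefficients.items()
        }

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "n_used": self.n_used,
            "df_resid": self.df_resid,
            "resid_sd_hat": self.resid_sd_hat,
            "excluded": self.excluded,
        }


@dataclass
class DerivedEffects:
    """Exposure-effect quantities derived from the full-model coefficients."""

    delta_rt_by_sz: dict[int, float]
    scan_ratio: float
    scan_inflation: float
    percent_beta0_change: float

    def to_dict(self) -> dict:
        return {
            "delta_rt_by_sz": {str(k): v for k, v in self.delta_rt_by_sz.items()},
            "scan_ratio": self.scan_ratio,
            "scan_inflation": self.scan_inflation,
            "percent_beta0_change": self.percent_beta0_change,
        }


@dataclass
class GroupComparison:
    """Welch two-sample comparison of one variable between two groups."""

    variable: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    mean_diff: float
    ci95: tuple[float, float]
    t: float
    df: float
    p: float


def design_matrix(records: pd.DataFrame, model_id: str) -> np.ndarray:
    sz = records["block_sz"].to_numpy(float)
    tg = records["is_target"].to_numpy(float)
    ones = np.ones_like(sz)
    if model_id == "eq1":
        return np.column_stack([ones, sz, tg])
    if model_id == "eq2":
        ex = records["exposed"].to_numpy(float)
        return np.column_stack([ones, sz, ex, sz * ex, tg])
    raise ValueError(f"unknown model_id {model_id!r}")


def _usable_rows(records: pd.DataFrame, include_error_rts: bool) -> pd.DataFrame:
    keep = ["correct", "error"] if include_error_rts else ["correct"]
    return records[records["outcome"].isin(keep) & records["rt_ms"].notna()]


def fit_sternberg(
    records: pd.DataFrame,
    model_id: str = "eq2",
    include_error_rts: bool = False,
    weights: np.ndarray | None = None,
) -> ModelFit:
    """Fit the dissociation regression to trial-level records by OLS.

    Error and omission trials are excluded by default (``include_error_rts``
    keeps error RTs).  ``weights`` enables the cell-mean mode: fitting
    per-cell mean RTs weighted by cell counts, which reproduces the
    trial-level coefficients under a balanced design.
    """
    terms = EQ1_TERMS if model_id == "eq1" else EQ2_TERMS
    used = _usable_rows(records, include_error_rts)
    if len(used) == 0:
        raise FitError("no usable rows (all records are errors/omissions or empty)")
    if used["block_sz"].nunique() < 2:
        raise FitError("need at least two distinct set sizes to identify the slope")
    if model_id == "eq2" and used["exposed"].nunique() < 2:
        raise FitError("exposure model needs both exposed and sham records")
    X = design_matrix(used, model_id)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")
    y = used["rt_ms"].to_numpy(float)
    model = sm.OLS(y, X) if weights is None else sm.WLS(y, X, weights=weights)
    res = model.fit()
    outcome_counts = records["outcome"].value_counts()
    excluded = {
        "error": int(outcome_counts.get("error", 0)) if not include_error_rts else 0,
        "omission": int(outcome_counts.get("omission", 0)),
    }
    return ModelFit(
        model_id=model_id,
        coefficients=dict(zip(terms, map(float, res.params))),
        std_errors=dict(zip(terms, map(float, res.bse))),
        t_values=dict(zip(terms, map(float, res.tvalues))),
        p_values=dict(zip(terms, map(float, res.pvalues))),
        n_used=int(res.nobs),
        df_resid=int(res.df_resid),
        resid_sd_hat=float(np.sqrt(res.scale)),
        excluded=excluded,
    )


def fit_on_cell_means(records: pd.DataFrame, model_id: str = "eq2") -> ModelFit:
    """Fit the model to per-cell mean RTs, weighted by cell trial counts."""
    cells = cell_means(records)
    cells = cells[cells["n"] > 0].copy()
    cells = cells.rename(columns={"mean_rt_ms": "rt_ms"})
    cells["outcome"] = "correct"
    return fit_sternberg(
        cells, model_id=model_id, weights=cells["n"].to_numpy(float)
    )


def derived_effects_from_coefficients(
    beta0: float,
    beta1: float,
    beta2: float,
    beta3: float,
    set_sizes=(1, 2, 3, 4),
) -> DerivedEffects:
    """Exposure-effect arithmetic on explicit coefficients.

    ΔRT(SZ) = b2 + b3·SZ; scan ratio b3/b1; inflation 1 + b3/b1; intercept
    change 100·|b2|/b0 percent.
    """
    if beta1 == 0:
        raise ZeroDivisionError("scanning slope beta1 is zero; ratio undefined")
    ratio = beta3 / beta1
    return DerivedEffects(
        delta_rt_by_sz={int(sz): beta2 + beta3 * sz for sz in set_sizes},
        scan_ratio=ratio,
        scan_inflation=1.0 + ratio,
        percent_beta0_change=100.0 * abs(beta2) / beta0,
    )


def derived_effects(fit: ModelFit, set_sizes=(1, 2, 3, 4)) -> DerivedEffects:
    if fit.model_id != "eq2":
        raise ValueError("derived effects require the exposure model fit")
    c = fit.coefficients
    return derived_effects_from_coefficients(
        c["intercept"], c["SZ"], c["EX"], c["SZxEX"], set_sizes=set_sizes
    )


def cell_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean correct-response RT per (EX, TG, SZ) cell.

    Dispersion is reported as the standard error of the mean.  Cells present
    in the design but without usable trials appear with n = 0 and no mean.
    """
    used = _usable_rows(records, include_error_rts=False)
    grouped = used.groupby(["exposed", "is_target", "block_sz"])["rt_ms"]
    out = grouped.agg(mean_rt_ms="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["sem"] = np.where(out["n"] > 0, out["sd"] / np.sqrt(out["n"].clip(lower=1)), np.nan)
    levels = [
        sorted(records["exposed"].unique()),
        sorted(records["is_target"].unique()),
        sorted(records["block_sz"].unique()),
    ]
    full = pd.MultiIndex.from_product(levels, names=["exposed", "is_target", "block_sz"])
    out = (
        out.set_index(["exposed", "is_target", "block_sz"])
        .reindex(full)
        .reset_index()
    )
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def welch_test(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variable: str = "",
    level: float = 0.95,
) -> GroupComparison:
    """Welch's unequal-variance t-test from summary statistics.

    Returns the mean difference a − b, its Welch–Satterthwaite degrees of
    freedom, the two-sided p-value, and the 95% confidence interval.  With
    zero variance in both groups and equal means the comparison is
    degenerate and p is reported as 1.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two observations")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    diff = mean_a - mean_b
    se = float(np.sqrt(va + vb))
    if se == 0.0:
        # degenerate: no sampling variability at all
        if diff == 0.0:
            return GroupComparison(
                variable, mean_a, mean_b, sd_a, sd_b, n_a, n_b,
                mean_diff=0.0, ci95=(0.0, 0.0), t=0.0, df=float(n_a + n_b - 2), p=1.0,
            )
        return GroupComparison(
            variable, mean_a, mean_b, sd_a, sd_b, n_a, n_b,
            mean_diff=diff, ci95=(diff, diff),
            t=float(np.inf) if diff > 0 else float(-np.inf),
            df=float(n_a + n_b - 2), p=0.0,
        )
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df))
    return GroupComparison(
        variable, mean_a, mean_b, sd_a, sd_b, n_a, n_b,
        mean_diff=diff, ci95=(diff - tcrit * se, diff + tcrit * se),
        t=float(t), df=float(df), p=p,
    )


def compare_groups(profiles: pd.DataFrame, group_col: str = "exposed") -> pd.DataFrame:
    """Welch comparisons (sham minus exposed) for every numeric profile column."""
    a = profiles[profiles[group_col] == 0]  # sham first, matching the summary tables
    b = profiles[profiles[group_col] == 1]
    rows = []
    for col in profiles.columns:
        if col in ("subject_id", group_col):
            continue
        cmp_ = welch_test(
            a[col].mean(), a[col].std(ddof=1), len(a),
            b[col].mean(), b[col].std(ddof=1), len(b),
            variable=col,
        )
        rows.append(
            {
                "variable": col,
                "mean_sham": cmp_.mean_a,
                "sd_sham": cmp_.sd_a,
                "mean_exposed": cmp_.mean_b,
                "sd_exposed": cmp_.sd_b,
                "mean_diff": cmp_.mean_diff,
                "ci95_low": cmp_.ci95[0],
                "ci95_high": cmp_.ci95[1],
                "t": cmp_.t,
                "df": cmp_.df,
                "p": cmp_.p,
            }
        )
    return pd.DataFrame(rows)


def error_omission_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and SD of per-subject error and omission counts."""
    per_subject = (
        records.assign(
            error=(records["outcome"] == "error").astype(int),
            omission=(records["outcome"] == "omission").astype(int),
        )
        .groupby(["exposed", "subject_id"])[["error", "omission"]]
        .sum()
        .reset_index()
    )
    rows = []
    for kind in ("error", "omission"):
        for ex, grp in per_subject.groupby("exposed"):
            counts = grp[kind]
            rows.append(
                {
                    "type": kind,
                    "exposed": int(ex),
                    "n_subjects": len(counts),
                    "mean": float(counts.mean()),
                    "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def error_omission_comparisons(records: pd.DataFrame) -> pd.DataFrame:
    """Welch tests of error / omission counts between sham and exposed groups."""
    summary = error_omission_summary(records)
    rows = []
    for kind in ("error", "omission"):
        sub = summary[summary["type"] == kind].set_index("exposed")
        if set(sub.index) != {0, 1}:
            continue
        cmp_ = welch_test(
            sub.loc[0, "mean"], sub.loc[0, "sd"], int(sub.loc[0, "n_subjects"]),
            sub.loc[1, "mean"], sub.loc[1, "sd"], int(sub.loc[1, "n_subjects"]),
            variable=kind,
        )
        rows.append(
            {
                "variable": kind,
                "mean_sham": cmp_.mean_a,
                "mean_exposed": cmp_.mean_b,
                "mean_diff": cmp_.mean_diff,
                "ci95_low": cmp_.ci95[0],
                "ci95_high": cmp_.ci95[1],
                "t": cmp_.t,
                "df": cmp_.df,
                "p": cmp_.p,
            }
        )
    return pd.DataFrame(rows)
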