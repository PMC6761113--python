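"""Outcome analyses for implant surveillance: Charlson categorization, Cox
proportional-hazards survivorship with log-rank tests, negative binomial
pain-count regression with AIC-driven grouping of rare implant systems,
and the revision-vs-pain t-test.

All analyses default to the single-implant subset (one primary surgery,
one acetabular and one femoral component), so each event can be
attributed to a unique implant system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "CoxResult",
    "NBResult",
    "categorize_cci",
    "compute_cci",
    "fit_cox",
    "collapse_rare_systems",
    "fit_negative_binomial",
    "ttest_pain_by_revision",
    "filter_single_implant",
]

log = logging.getLogger(__name__)

CCI_CATEGORIES = ("none", "low", "moderate", "high")


def categorize_cci(cci: int) -> str:
    """Charlson Comorbidity Index -> none (0), low (1), moderate (2), high (>=3)."""
    cci = int(cci)
    if cci < 0:
        raise ValueError("CCI must be non-negative")
    if cci == 0:
        return "none"
    if cci == 1:
        return "low"
    if cci == 2:
        return "moderate"
    return "high"


# Quan-style ICD-9 prefix map for the 17 Charlson categories with their
# original weights. Deliberately compact: CCI normally arrives precomputed;
# this helper exists for corpora that only carry diagnosis codes.
_CHARLSON_ICD9_PREFIXES: dict[str, tuple[int, tuple[str, ...]]] = {
    "mi": (1, ("410", "412")),
    "chf": (1, ("428",)),
    "pvd": (1, ("443.9", "441", "785.4")),
    "cvd": (1, ("430", "431", "432", "433", "434", "435", "436", "437", "438")),
    "dementia": (1, ("290",)),
    "copd": (1, ("490", "491", "492", "493", "494", "495", "496")),
    "rheum": (1, ("710.0", "710.1", "714.0", "725")),
    "pud": (1, ("531", "532", "533", "534")),
    "liver_mild": (1, ("571.2", "571.5", "571.6")),
    "dm": (1, ("250.0", "250.1", "250.2", "250.3")),
    "dm_compl": (2, ("250.4", "250.5", "250.6", "250.7")),
    "hemiplegia": (2, ("342", "344.1")),
    "renal": (2, ("582", "583", "585", "586", "588.0")),
    "malignancy": (2, ("14", "15", "16", "17", "18", "19", "200", "201", "202", "203", "204", "205", "206", "207", "208")),
    "liver_severe": (3, ("456.0", "456.1", "572.2", "572.3", "572.4")),
    "mets": (6, ("196", "197", "198", "199")),
    "aids": (6, ("042",)),
}
# within each pair the severe form supersedes the mild one
_CHARLSON_HIERARCHY = (
    ("dm_compl", "dm"),
    ("liver_severe", "liver_mild"),
    ("mets", "malignancy"),
)


def compute_cci(dx_codes: Sequence[str]) -> int:
    """Charlson index from ICD-9 diagnosis codes via prefix matching.

    Each comorbidity category counts once at its weight; when both the
    mild and severe form of a condition are coded, only the severe form
    counts (standard Charlson hierarchy).
    """
    codes = [str(c).strip() for c in dx_codes]
    present = {
        name
        for name, (_, prefixes) in _CHARLSON_ICD9_PREFIXES.items()
        if any(code.startswith(p) for code in codes for p in prefixes)
    }
    for severe, mild in _CHARLSON_HIERARCHY:
        if severe in present:
            present.discard(mild)
    return sum(_CHARLSON_ICD9_PREFIXES[name][0] for name in present)


@dataclass
class CoxResult:
    hazard_ratios: pd.DataFrame  # index: covariate; columns: hr, ci_low, ci_high, p
    logrank_statistic: float
    logrank_p: float
    n: int
    n_events: int
    person_years: float


@dataclass
class NBResult:
    irr: pd.DataFrame  # index: covariate; columns: irr, ci_low, ci_high, p
    aic: float
    cutoff: int
    aic_by_cutoff: dict[int, float]
    n: int
    reference_system: str


def filter_single_implant(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep patients with a single primary surgery and a complete, unique
    acetabular + femoral pair (flag column ``single_implant``)."""
    if "single_implant" in rows.columns:
        return rows[rows["single_implant"].astype(bool)].copy()
    return rows.copy()


def _design(rows: pd.DataFrame, covariates: Sequence[str], reference: Mapping[str, str]):
    """Dummy-encode categorical covariates with explicit reference levels."""
    X = pd.DataFrame(index=rows.index)
    for cov in covariates:
        col = rows[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            ref = reference.get(cov)
            levels = [l for l in pd.unique(col.astype(str)) if l != ref]
            if ref is None and levels:
                ref = sorted(pd.unique(col.astype(str)))[0]
                levels = [l for l in sorted(pd.unique(col.astype(str))) if l != ref]
            for level in sorted(levels):
                X[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    # drop constant columns (inestimable)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def fit_cox(
    rows: pd.DataFrame,
    outcome: str = "revision",
    covariates: Sequence[str] = ("implant_system", "age_at_surgery", "gender", "race", "ethnicity", "cci_category"),
    duration_col: str | None = None,
    event_col: str | None = None,
    reference: Mapping[str, str] | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit for time to first event of ``outcome``.

    Expects columns ``time_to_<outcome>`` (years to first event or
    censoring) and ``event_<outcome>`` (0/1) unless explicit duration/event
    columns are given. Categorical covariates are dummy-coded against a
    reference level (default: the most frequent implant system). A
    log-rank test across implant-system strata is reported alongside.
    """
    duration_col = duration_col or f"time_to_{outcome}"
    event_col = event_col or f"event_{outcome}"
    if rows[event_col].sum() < 1:
        raise ValueError("no events observed: Cox model inestimable")
    reference = dict(reference or {})
    if "implant_system" in covariates and "implant_system" not in reference:
        reference["implant_system"] = rows["implant_system"].mode().iloc[0]
    X = _design(rows, covariates, reference)
    df = X.copy()
    df["_T"] = rows[duration_col].astype(float).clip(lower=1e-6)
    df["_E"] = rows[event_col].astype(int)
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="_T",
        event_col="_E",
        robust=False,
        fit_options={"step_size": 0.5},
    )
    summary = cph.summary
    hr = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    if "implant_system" in rows.columns:
        lr = multivariate_logrank_test(
            df["_T"], rows["implant_system"], df["_E"]
        )
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
    else:
        lr_stat, lr_p = float("nan"), float("nan")
    return CoxResult(
        hazard_ratios=hr,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
        n=len(df),
        n_events=int(df["_E"].sum()),
        person_years=float(df["_T"].sum()),
    )


def collapse_rare_systems(col: pd.Series, cutoff: int) -> pd.Series:
    counts = col.value_counts()
    rare = set(counts[counts < cutoff].index)
    return col.where(~col.isin(rare), "other")


def fit_negative_binomial(
    rows: pd.DataFrame,
    response: str = "pain_count_post",
    covariates: Sequence[str] = (
        "implant_system",
        "age_at_surgery",
        "gender",
        "race",
        "ethnicity",
        "pain_count_prior",
        "follow_up",
    ),
    grouping_cutoffs: Sequence[int] = (1, 5, 10, 25, 50),
    reference_system: str | None = None,
    include_bmi: bool = False,
) -> NBResult:
    """Negative binomial regression of post-implant pain-mention counts.

    The implant system enters as the femoral x acetabular interaction
    (already composed into one label). For each candidate cutoff, systems
    with fewer patients than the cutoff collapse into "other"; the fit
    minimizing AIC is returned, with the most frequent system as the
    reference level. IRRs are exponentiated coefficients.
    """
    import statsmodels.api as sm

    y = rows[response].astype(float)
    if y.var() == 0:
        raise ValueError("response has zero variance")
    covariates = list(covariates) + (["bmi"] if include_bmi else [])
    if reference_system is None:
        reference_system = rows["implant_system"].mode().iloc[0]

    best: tuple[float, int, object, pd.DataFrame] | None = None
    aic_by_cutoff: dict[int, float] = {}
    for cutoff in grouping_cutoffs:
        work = rows.copy()
        work["implant_system"] = collapse_rare_systems(
            work["implant_system"].astype(str), cutoff
        )
        X = _design(work, covariates, {"implant_system": reference_system})
        X = sm.add_constant(X, has_constant="add")
        model = sm.NegativeBinomial(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # singular design at extreme cutoffs
            log.warning("NB fit failed at cutoff %d: %s", cutoff, exc)
            continue
        aic_by_cutoff[cutoff] = float(res.aic)
        if best is None or res.aic < best[0]:
            best = (float(res.aic), cutoff, res, X)
    if best is None:
        raise ValueError("no negative binomial fit converged")
    aic, cutoff, res, X = best
    assert aic <= min(aic_by_cutoff.values()) + 1e-9
    params = res.params.drop(labels=["alpha"], errors="ignore")
    conf = res.conf_int()
    conf = conf.loc[params.index]
    irr = pd.DataFrame(
        {
            "irr": np.exp(params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p": res.pvalues.loc[params.index],
        }
    ).drop(index=["const"], errors="ignore")
    return NBResult(irr, aic, cutoff, aic_by_cutoff, len(rows), reference_system)


def ttest_pain_by_revision(
    rows: pd.DataFrame,
    mode: str = "fixed_window",
    count_col: str = "pain_count_post",
    revision_col: str = "had_revision",
    follow_up_col: str = "follow_up",
) -> dict:
    """Welch two-sided t-test of pain-mention burden, revision vs not.

    ``fixed_window`` compares raw counts inside a common fixed-length
    post-operative window (follow-up is controlled by construction of the
    window); ``rate_per_year`` compares counts divided by follow-up years.
    """
    grp_rev = rows[rows[revision_col].astype(bool)]
    grp_no = rows[~rows[revision_col].astype(bool)]
    if len(grp_rev) < 2 or len(grp_no) < 2:
        raise ValueError("each group needs at least 2 patients")
    if mode == "fixed_window":
        a, b = grp_rev[count_col].astype(float), grp_no[count_col].astype(float)
    elif mode == "rate_per_year":
        a = grp_rev[count_col].astype(float) / grp_rev[follow_up_col].clip(lower=1e-6)
        b = grp_no[count_col].astype(float) / grp_no[follow_up_col].clip(lower=1e-6)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "mean_revision": float(a.mean()),
        "mean_no_revision": float(b.mean()),
        "t": float(t),
        "p": float(p),
        "n_revision": len(a),
        "n_no_revision": len(b),
        "mode": mode,
    }
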