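"""Cohort-level statistics: eligibility, eye averaging, group tests, reports.

The analysis layer mirrors a standard exploratory case-control workflow:
participants with screening flags are excluded; OCT-A metrics of a
participant's eligible eyes are averaged; CSVD cases (Fazekas >= 1) are
compared with controls by Mann-Whitney U; discrimination is summarized by
the ROC AUC with a Hanley-McNeil confidence interval; and associations of
MRI burden (natural-log WMI, NOL) with OCT-A metrics are estimated by
ordinary least squares, unadjusted and controlled for age. Tests are
two-sided at alpha = 0.05 with no multiple-testing correction (exploratory
design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError, InsufficientDataError, OctavascError
from .records import EXCLUSION_REASONS, OCTA_METRICS, ParticipantRecord

#: Metrics entering the ROC and regression tables.
ANALYSIS_METRICS = (
    "vd_sup", "sd_sup", "vdi_sup", "vd_deep", "sd_deep", "vdi_deep", "cc_mean", "cc_sd",
)

#: Human-readable row labels of the descriptive table.
TABLE1_LABELS = {
    "age": "Age",
    "moca": "MoCA",
    "vd_sup": "Vessel Density, superficial",
    "vdi_sup": "Vessel Diameter Index, superficial",
    "vd_deep": "Vessel Density, deep",
    "vdi_deep": "Vessel Diameter Index, deep",
    "cc_mean": "Choriocapillaris reflectivity, mean",
    "cc_sd": "Choriocapillaris reflectivity, SD",
    "nol": "NOL",
    "wmi": "WMI",
}


# --------------------------------------------------------------------------
# eligibility and eye averaging
# --------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    counts_by_reason: dict
    n_total: int
    n_excluded: int
    n_included: int
    n_overlapping: int  # records carrying more than one flag

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "n": self.counts_by_reason.get(r, 0)} for r in EXCLUSION_REASONS]
        rows.append({"reason": "total_excluded", "n": self.n_excluded})
        rows.append({"reason": "included", "n": self.n_included})
        return pd.DataFrame(rows)


def apply_eligibility(
    records: list[ParticipantRecord],
) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Drop any record with at least one screening flag.

    A record with several flags is excluded once but counted under every
    reason; the report states how many such overlapping records exist.
    """
    included = [r for r in records if not r.is_excluded]
    excluded = [r for r in records if r.is_excluded]
    counts = {
        reason: sum(1 for r in excluded if reason in r.exclusion_flags)
        for reason in EXCLUSION_REASONS
    }
    return included, ExclusionReport(
        counts_by_reason=counts,
        n_total=len(records),
        n_excluded=len(excluded),
        n_included=len(included),
        n_overlapping=sum(1 for r in excluded if len(r.exclusion_flags) > 1),
    )


def average_eyes(record: ParticipantRecord, min_quality: int = 8) -> dict:
    """Arithmetic mean of each OCT-A metric over the eligible eyes.

    An eye is eligible if its quality index (where known) meets the minimum.

    Raises
    ------
    InsufficientDataError
        If no eligible eye is available.
    """
    eligible = [
        eye
        for eye in record.eyes
        if record.eye_quality.get(eye, min_quality) >= min_quality
    ]
    if not eligible:
        raise InsufficientDataError(
            f"participant {record.id} has no eligible eye for OCT-A analyses"
        )
    out: dict[str, float] = {}
    for m in OCTA_METRICS:
        vals = [record.eyes[eye][m] for eye in eligible if m in record.eyes[eye]]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            out[m] = float(np.mean(vals))
    return out


def analysis_frame(
    records: list[ParticipantRecord], min_quality: int = 8
) -> tuple[pd.DataFrame, list[str]]:
    """Per-participant analysis table (eye-averaged metrics plus covariates).

    Returns the table and the ids of participants dropped from OCT-A analyses
    for lack of an eligible eye (they keep their MRI/covariate row).
    """
    rows, dropped = [], []
    for rec in records:
        row = {
            "id": rec.id,
            "group": rec.group,
            "is_case": int(rec.group == "case"),
            "age": rec.age,
            "sex": rec.sex,
            "fazekas": rec.fazekas,
            "moca": rec.moca,
        }
        if rec.mri is not None:
            row["nol"] = rec.mri.nol
            row["wmi"] = rec.mri.wmi
            row["log_wmi"] = rec.mri.log_wmi if rec.mri.log_wmi is not None else np.nan
        try:
            row.update(average_eyes(rec, min_quality=min_quality))
        except InsufficientDataError:
            dropped.append(rec.id)
        rows.append(row)
    return pd.DataFrame(rows), dropped


# --------------------------------------------------------------------------
# group comparison and discrimination
# --------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    U: float
    p: float
    n1: int
    n2: int
    method: str = "asymptotic"


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    p: float
    direction: str = "case_high"  # which orientation yields AUC >= 0.5


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midrank sums for the first sample. The p-value is
    exact (full enumeration) when n1 + n2 <= 12 and there are no ties, and
    otherwise uses the normal approximation with tie and continuity
    correction. With every observation tied the statistic is its null mean
    and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size

    if n1 + n2 <= 12 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=u1, p=float(res.pvalue), n1=n1, n2=n2, method="exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=u1, p=1.0, n1=n1, n2=n2, method="degenerate")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(U=u1, p=float(p), n1=n1, n2=n2, method="asymptotic")


def roc_analysis(scores, labels, direction: str = "auto") -> RocResult:
    """ROC discrimination of cases from controls by one metric.

    AUC is the midrank (ties = half credit) probability that a case scores
    above a control; with ``direction="auto"`` the orientation giving
    AUC >= 0.5 is reported. The 95% CI uses the Hanley-McNeil variance and
    the p-value is the equivalent Mann-Whitney test's.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise OctavascError("scores and labels must align")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both classes must be present for ROC analysis")
    mw = mann_whitney(pos, neg)
    auc = mw.U / (pos.size * neg.size)
    used_direction = "case_high"
    if direction == "auto" and auc < 0.5:
        auc = 1.0 - auc
        used_direction = "case_low"
    elif direction == "case_low":
        auc = 1.0 - auc
        used_direction = "case_low"
    n1, n2 = pos.size, neg.size
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    return RocResult(auc=float(auc), ci95=(float(lo), float(hi)), p=mw.p, direction=used_direction)


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

@dataclass
class CoefEstimate:
    beta: float
    ci95: tuple[float, float]
    p: float


@dataclass
class RegressionResult:
    outcome: str
    covariates: tuple
    coefficients: dict  # predictor/covariate name -> CoefEstimate
    nobs: int


def fit_regression(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple = (),
) -> RegressionResult:
    """OLS of an MRI burden parameter on one OCT-A metric (plus covariates).

    Per-coefficient 95% CIs come from the t distribution. Rows with missing
    values in any used column are dropped.
    """
    cols = [outcome, predictor, *covariates]
    df = data[cols].dropna()
    n_params = len(cols)  # intercept + predictor + covariates
    if len(df) <= n_params + 1:
        raise InsufficientDataError(
            f"need more than {n_params + 1} complete observations, have {len(df)}"
        )
    regressors = [predictor, *covariates]
    sub = df[regressors].to_numpy(dtype=float)
    if len(regressors) > 1:
        corr = np.corrcoef(sub, rowvar=False)
        for i in range(len(regressors)):
            for j in range(i + 1, len(regressors)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise CollinearityError(
                        f"collinear regressors: ({regressors[i]}, {regressors[j]})"
                    )
    for i, name in enumerate(regressors):
        if np.std(sub[:, i]) == 0:
            raise CollinearityError(f"collinear regressors: ({name}, intercept)")
    X = sm.add_constant(df[regressors].to_numpy(dtype=float))
    fit = sm.OLS(df[outcome].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    names = ["intercept", *regressors]
    coefs = {
        name: CoefEstimate(
            beta=float(fit.params[i]),
            ci95=(float(ci[i][0]), float(ci[i][1])),
            p=float(fit.pvalues[i]),
        )
        for i, name in enumerate(names)
    }
    return RegressionResult(
        outcome=outcome, covariates=tuple(covariates), coefficients=coefs, nobs=int(fit.nobs)
    )


# --------------------------------------------------------------------------
# age matching and report assembly
# --------------------------------------------------------------------------

def greedy_age_match(df: pd.DataFrame) -> tuple[list, list]:
    """1:1 greedy nearest-age matching of cases to controls (no replacement).

    Controls (the smaller group in the study design) each take the unused
    case closest in age, in order of ascending achievable age difference.
    Returns (matched case ids, matched control ids).
    """
    cases = df[df["group"] == "case"][["id", "age"]].to_numpy(dtype=object)
    controls = df[df["group"] == "control"][["id", "age"]].to_numpy(dtype=object)
    if len(cases) == 0 or len(controls) == 0:
        raise InsufficientDataError("both groups required for age matching")
    pairs = sorted(
        ((abs(float(ca) - float(co)), ci, coi)
         for ci, ca in cases
         for coi, co in controls),
        key=lambda t: t[0],
    )
    used_cases: list = []
    used_controls: list = []
    for _, ci, coi in pairs:
        if ci in used_cases or coi in used_controls:
            continue
        used_cases.append(ci)
        used_controls.append(coi)
        if len(used_controls) == min(len(cases), len(controls)):
            break
    return used_cases, used_controls


@dataclass
class AnalysisReport:
    """Tables-1-to-3-shaped output of a cohort analysis run."""

    table1: pd.DataFrame
    roc: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    exclusions: pd.DataFrame
    flow_voids: pd.DataFrame
    matched_case_ids: list = field(default_factory=list)
    matched_control_ids: list = field(default_factory=list)
    dropped_octa_ids: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def save(self, out_dir, manifest: dict | None = None) -> dict:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, table in (
            ("table1", self.table1),
            ("roc", self.roc),
            ("table2", self.table2),
            ("table3", self.table3),
            ("exclusions", self.exclusions),
            ("flow_voids", self.flow_voids),
        ):
            path = out / f"{name}.csv"
            table.to_csv(path, index=False)
            paths[name] = str(path)
        if manifest is not None:
            manifest = dict(manifest)
            manifest["notes"] = self.notes
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            paths["manifest"] = str(out / "manifest.json")
        return paths


def _mw_p(df: pd.DataFrame, var: str, case_ids=None) -> float:
    sub = df if case_ids is None else df[df["id"].isin(case_ids) | (df["group"] == "control")]
    a = sub.loc[sub["group"] == "case", var].dropna()
    b = sub.loc[sub["group"] == "control", var].dropna()
    if len(a) == 0 or len(b) == 0:
        return np.nan
    return mann_whitney(a, b).p


def _fmt_group(df, var, mask=None):
    vals = (df if mask is None else df[mask])[var].dropna()
    if len(vals) == 0:
        return np.nan, np.nan
    return float(vals.mean()), float(vals.std(ddof=1))


def _regression_rows(df, outcomes, predictors, label):
    rows = []
    for outcome in outcomes:
        for pred in predictors:
            if pred not in df.columns or df[pred].notna().sum() < 4:
                continue
            for covs in ((), ("age",)):
                try:
                    res = fit_regression(df, outcome, pred, covariates=covs)
                except (InsufficientDataError, CollinearityError):
                    continue
                est = res.coefficients[pred]
                rows.append(
                    {
                        "sample": label,
                        "outcome": outcome,
                        "predictor": pred,
                        "adjusted_for_age": bool(covs),
                        "beta": est.beta,
                        "ci_low": est.ci95[0],
                        "ci_high": est.ci95[1],
                        "p": est.p,
                        "n": res.nobs,
                    }
                )
    return pd.DataFrame(rows)


def build_reports(
    records: list[ParticipantRecord],
    min_quality: int = 8,
    void_sets: dict | None = None,
) -> AnalysisReport:
    """Run the full statistical layer and assemble the report bundle.

    Produces: a descriptive table with group means +- SD and Mann-Whitney
    p-values (whole-cohort and age-matched comparisons); a ROC table for
    discriminating Fazekas >= 1; regression tables for the overall sample
    (unadjusted and age-adjusted) and for cases only; the exclusion report;
    and the flow-void comparison (count/size location tests, count dispersion
    test, and — when per-eye void sets are supplied — the equal-slopes
    intercept comparison).
    """
    from .choriocap import compare_void_intercepts, void_count_dispersion_test

    included, excl = apply_eligibility(records)
    df, dropped = analysis_frame(included, min_quality=min_quality)
    notes: list[str] = []
    if dropped:
        notes.append(f"dropped from OCT-A analyses (no eligible eye): {sorted(dropped)}")

    # age-matched subgroup
    matched_cases: list = []
    matched_controls: list = []
    try:
        matched_cases, matched_controls = greedy_age_match(df)
    except InsufficientDataError:
        notes.append("age-matched subgroup unavailable (a group is empty)")

    # Table 1
    t1_vars = [v for v in TABLE1_LABELS if v in df.columns]
    rows = []
    is_case = df["group"] == "case"
    for var in t1_vars:
        all_m, all_s = _fmt_group(df, var)
        con_m, con_s = _fmt_group(df, var, ~is_case)
        cas_m, cas_s = _fmt_group(df, var, is_case)
        mat_m, mat_s = _fmt_group(df, var, df["id"].isin(matched_cases))
        rows.append(
            {
                "parameter": TABLE1_LABELS[var],
                "variable": var,
                "all_mean": all_m, "all_sd": all_s,
                "controls_mean": con_m, "controls_sd": con_s,
                "matched_cases_mean": mat_m, "matched_cases_sd": mat_s,
                "p_matched": _mw_p(df, var, matched_cases) if matched_cases else np.nan,
                "cases_mean": cas_m, "cases_sd": cas_s,
                "p_all": _mw_p(df, var),
            }
        )
    table1 = pd.DataFrame(rows)

    # ROC table (Fazekas >= 1 discrimination)
    roc_rows = []
    for m in ANALYSIS_METRICS:
        if m not in df.columns:
            continue
        sub = df[[m, "is_case"]].dropna()
        if sub["is_case"].nunique() < 2:
            continue
        res = roc_analysis(sub[m], sub["is_case"])
        roc_rows.append(
            {
                "metric": m,
                "auc": res.auc,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "p": res.p,
                "direction": res.direction,
            }
        )
    roc = pd.DataFrame(roc_rows)

    # Tables 2 and 3
    preds = [m for m in ANALYSIS_METRICS if m in df.columns]
    table2 = _regression_rows(df, ("log_wmi", "nol"), preds, "overall")
    table3 = _regression_rows(df[is_case], ("log_wmi", "nol"), preds, "cases_only")

    # flow-void comparisons
    fv_rows = []
    if "fv_n" in df.columns and df["fv_n"].notna().sum() >= 6:
        a = df.loc[is_case, "fv_n"].dropna()
        b = df.loc[~is_case, "fv_n"].dropna()
        if len(a) >= 3 and len(b) >= 3:
            fv_rows.append({"test": "void_count_location", "statistic": np.nan,
                            "p": mann_whitney(a, b).p})
            fv_rows.append({"test": "void_count_dispersion", "statistic": np.nan,
                            "p": void_count_dispersion_test(a, b)})
            am = df.loc[is_case, "fv_mean_um2"].dropna()
            bm = df.loc[~is_case, "fv_mean_um2"].dropna()
            if len(am) and len(bm):
                fv_rows.append({"test": "void_mean_size_location", "statistic": np.nan,
                                "p": mann_whitney(am, bm).p})
    if void_sets:
        case_ids = set(df.loc[is_case, "id"])
        grp_a = [v for pid, vs in void_sets.items() if pid not in case_ids for v in vs]
        grp_b = [v for pid, vs in void_sets.items() if pid in case_ids for v in vs]
        if len(grp_a) >= 3 and len(grp_b) >= 3:
            try:
                cmp_res = compare_void_intercepts(grp_a, grp_b)
                fv_rows.append(
                    {
                        "test": "void_intercept_difference",
                        "statistic": cmp_res.intercept_difference,
                        "p": cmp_res.p,
                    }
                )
            except (InsufficientDataError, OctavascError) as err:
                notes.append(f"intercept comparison unavailable: {err}")
    flow_voids = pd.DataFrame(fv_rows, columns=["test", "statistic", "p"])

    return AnalysisReport(
        table1=table1,
        roc=roc,
        table2=table2,
        table3=table3,
        exclusions=excl.to_frame(),
        flow_voids=flow_voids,
        matched_case_ids=list(matched_cases),
        matched_control_ids=list(matched_controls),
        dropped_octa_ids=dropped,
        notes=notes,
    )
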