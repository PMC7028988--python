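"""Cohort-level statistics: densities, group comparisons, survival analysis.

Per-ROI percent-positive densities are aggregated to a per-patient median;
patients are stratified high/low at the median (densities) or mean (HID
features) of the analysis population; survival is compared with Kaplan-Meier
curves (Greenwood variance), the Mantel-Haenszel log-rank test and univariate
Cox proportional-hazards regression (Efron tie handling), and distributional
comparisons between HPV strata use the one-sided Mann-Whitney U test.

The Kaplan-Meier estimator with Greenwood's variance is implemented directly
(it is needed with its variance exposed for error bars); log-rank and Cox go
through lifelines, Mann-Whitney through scipy, behind this module's surface.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import phenotype_mask

__all__ = [
    "percent_positive",
    "patient_density",
    "stratify",
    "KMFit",
    "km_estimate",
    "logrank_test",
    "CoxFit",
    "cox_univariate",
    "mann_whitney",
    "ks_normality",
    "RunTablesConfig",
    "CohortReport",
    "run_tables",
]

ALPHA = 0.05


# --------------------------------------------------------------------------
# Densities
# --------------------------------------------------------------------------

def percent_positive(cells: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Percent of cells belonging to ``phenotype``, per ROI.

    ROIs with zero cells are skipped (logged via the returned frame's attrs).
    """
    rows = []
    skipped = []
    member = phenotype_mask(cells, phenotype)
    for roi_id, grp in cells.groupby("roi_id", sort=True):
        n = len(grp)
        if n == 0:
            skipped.append(roi_id)
            continue
        pct = 100.0 * member.loc[grp.index].sum() / n
        rows.append({"roi_id": roi_id, "patient_id": grp["patient_id"].iloc[0], "percent": pct})
    out = pd.DataFrame(rows, columns=["roi_id", "patient_id", "percent"])
    out.attrs["skipped_rois"] = skipped
    return out


def patient_density(per_roi: pd.DataFrame) -> pd.Series:
    """Median per-ROI percentage per patient (the patient's density feature)."""
    return per_roi.groupby("patient_id")["percent"].median()


def stratify(values: pd.Series, cut: str = "median") -> pd.Series:
    """Label each patient 'high' or 'low' against the population cut statistic.

    ``cut`` is 'median' or 'mean', computed over the values supplied (pass the
    subgroup's values for subgroup-specific cuts).  Strictly greater than the
    cut is 'high'; a tie at the cut is 'low'.
    """
    values = values.dropna()
    if len(values) < 2:
        raise ValueError("need >= 2 patients with the feature to stratify")
    if values.nunique() == 1:
        raise ValueError("all feature values identical; no stratification possible")
    if cut == "median":
        c = values.median()
    elif cut == "mean":
        c = values.mean()
    else:
        raise ValueError(f"cut must be 'median' or 'mean', got {cut!r}")
    return pd.Series(np.where(values > c, "high", "low"), index=values.index, name="group")


# --------------------------------------------------------------------------
# Survival machinery
# --------------------------------------------------------------------------

@dataclass
class KMFit:
    """Product-limit curve with Greenwood variances at the event times."""

    event_times: np.ndarray  # distinct times with >= 1 observed event
    survival: np.ndarray     # S(t) just after each event time
    greenwood_var: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "greenwood_se": np.sqrt(self.greenwood_var),
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMFit:
    """Kaplan-Meier product-limit estimator with Greenwood's variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i with
    d_i events and n_i at risk;  Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i)).
    Subjects censored at an event time remain at risk at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    distinct = np.unique(times[events == 1])
    s = 1.0
    gw_sum = 0.0
    surv, gvar, at_risk, n_ev = [], [], [], []
    for t in distinct:
        n_i = int(np.sum(times >= t))  # censored-at-t subjects still at risk
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw_sum += d_i / (n_i * (n_i - d_i))
            gvar.append(s**2 * gw_sum)
        else:
            gvar.append(0.0)  # S(t) = 0: Greenwood variance degenerates to 0
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KMFit(
        event_times=distinct,
        survival=np.array(surv),
        greenwood_var=np.array(gvar),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank test: (chi-square statistic, p)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("no events in either group; log-rank test undefined")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Univariate Cox fit for a binary covariate."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_hr: float
    se_log_hr: float
    n: int
    n_events: int
    separation_flagged: bool = False


def cox_univariate(
    times: Sequence[float],
    events: Sequence[int],
    covariate: Sequence[int],
    ties: str = "efron",
) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Wald CI and p).

    The covariate must be binary with both levels present and at least one
    event overall.  Monotone-likelihood (complete separation) is flagged and
    the CI reported as unbounded.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate)
    if set(np.unique(x)) - {0, 1}:
        # allow high/low labels
        x = (np.asarray(x) == "high").astype(int) if x.dtype.kind in "OU" else x.astype(int)
    x = x.astype(int)
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("covariate must take both levels")
    if e.sum() < 1:
        raise ValueError("need at least one event")

    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # small strata routinely trip lifelines' separation heuristics;
            # genuine monotone likelihood is flagged via the SE check below
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # convergence failure == monotone likelihood
        return CoxFit(
            hr=np.inf, ci_low=0.0, ci_high=np.inf, p=np.nan,
            log_hr=np.inf, se_log_hr=np.inf, n=len(df), n_events=int(e.sum()),
            separation_flagged=True,
        )
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    flagged = not np.isfinite(se) or se > 50
    z = sps.norm.ppf(0.975)
    return CoxFit(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)) if not flagged else 0.0,
        ci_high=float(np.exp(beta + z * se)) if not flagged else np.inf,
        p=p,
        log_hr=beta,
        se_log_hr=se,
        n=len(df),
        n_events=int(e.sum()),
        separation_flagged=flagged,
    )


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "less",
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test for unpaired data: (U of group A, p).

    Exact enumeration when the combined sample is small (n_a + n_b <= 12,
    no ties); tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_normality(values: Sequence[float]) -> float:
    """Kolmogorov-Smirnov p-value against a fitted normal (diagnostic only;
    the pipeline always uses the rank test regardless of this result)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3 or v.std() == 0:
        return np.nan
    return float(sps.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue)


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

@dataclass
class RunTablesConfig:
    alpha: float = ALPHA
    density_cut: str = "median"
    hid_cut: str = "mean"
    subgroup_cuts: bool = True  # cut computed within each analysis population
    mw_alternative: str = "less"  # HPV-negative (A) stochastically less than HPV+ (B)


@dataclass
class CohortReport:
    density_table: pd.DataFrame
    cox_table: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    notes: list[str]
    n_tests: int

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("Cohort analysis report\n======================\n\n")
        buf.write("Feature distributions (per-patient medians) and HPV comparison\n")
        buf.write(self.density_table.to_string(index=False))
        buf.write("\n\nUnivariate Cox regression, high vs low stratification\n")
        buf.write(self.cox_table.to_string(index=False))
        buf.write(f"\n\nStatistical tests performed: {self.n_tests} (alpha = {ALPHA}; ")
        buf.write("no multiple-testing correction, pre-specified hypotheses)\n")
        for note in self.notes:
            buf.write(f"note: {note}\n")
        return buf.getvalue()


def _population_masks(patients: pd.DataFrame) -> dict[str, pd.Series]:
    hpv = patients["hpv_status"]
    return {
        "all": pd.Series(True, index=patients.index),
        "hpv_positive": hpv == "positive",
        "hpv_negative": hpv == "negative",
    }


def run_tables(
    patients: pd.DataFrame,
    features: pd.DataFrame,
    config: RunTablesConfig | None = None,
) -> CohortReport:
    """Produce the cohort's summary tables.

    ``patients`` needs patient_id, time_months, event, hpv_status;
    ``features`` is indexed by patient_id with one column per feature
    (per-patient densities and HID values).  Emits a distribution table with
    HPV-stratum medians and one-sided Mann-Whitney p-values, a univariate Cox
    grid over the three populations (all / HPV+ / HPV-) with high/low
    stratification, and per-stratum KM curve data with Greenwood errors.
    """
    config = config or RunTablesConfig()
    patients = patients.set_index("patient_id") if "patient_id" in patients.columns else patients
    notes: list[str] = []
    n_tests = 0

    if len(patients) < 2:
        notes.append("insufficient n: fewer than 2 patients; no tests performed")
        return CohortReport(pd.DataFrame(), pd.DataFrame(), {}, notes, 0)

    pops = _population_masks(patients)
    density_rows = []
    cox_rows = []
    km_curves: dict[str, pd.DataFrame] = {}

    for feature in features.columns:
        vals = features[feature].reindex(patients.index)
        row = {"feature": feature}
        for pop_name, mask in pops.items():
            row[f"median_{pop_name}"] = vals[mask].median()
        neg = vals[pops["hpv_negative"]].dropna()
        pos = vals[pops["hpv_positive"]].dropna()
        if len(neg) and len(pos):
            try:
                _, p = mann_whitney(neg, pos, alternative=config.mw_alternative)
                row["mw_p"] = p
                n_tests += 1
            except ValueError as err:
                row["mw_p"] = np.nan
                notes.append(f"{feature}: Mann-Whitney skipped ({err})")
        else:
            row["mw_p"] = np.nan
        ksp = ks_normality(vals.dropna())
        row["ks_normality_p"] = ksp
        density_rows.append(row)

        cut = config.hid_cut if feature.startswith("hid_") else config.density_cut
        for pop_name, mask in pops.items():
            sub = patients[mask]
            sub_vals = vals[mask].dropna()
            crow = {"feature": feature, "population": pop_name, "cut": cut}
            try:
                cut_vals = sub_vals if config.subgroup_cuts else vals.dropna()
                groups = stratify(sub_vals, cut=cut)
                if not config.subgroup_cuts:
                    c = cut_vals.median() if cut == "median" else cut_vals.mean()
                    groups = pd.Series(
                        np.where(sub_vals > c, "high", "low"), index=sub_vals.index
                    )
                merged = sub.loc[groups.index]
                fit = cox_univariate(
                    merged["time_months"], merged["event"], (groups == "high").astype(int)
                )
                stat, lr_p = logrank_test(
                    merged.loc[groups == "high", "time_months"],
                    merged.loc[groups == "high", "event"],
                    merged.loc[groups == "low", "time_months"],
                    merged.loc[groups == "low", "event"],
                )
                n_tests += 2
                crow.update(
                    hr=fit.hr, ci_low=fit.ci_low, ci_high=fit.ci_high, cox_p=fit.p,
                    logrank_p=lr_p, n=fit.n, n_events=fit.n_events,
                    n_high=int((groups == "high").sum()),
                    significant=bool(fit.p < config.alpha) if np.isfinite(fit.p) else False,
                )
                for gname in ("high", "low"):
                    g = merged.loc[groups == gname]
                    if len(g):
                        km = km_estimate(g["time_months"], g["event"])
                        km_curves[f"{feature}|{pop_name}|{gname}"] = km.as_frame()
            except ValueError as err:
                crow.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, cox_p=np.nan,
                            logrank_p=np.nan, n=len(sub), n_events=int(sub["event"].sum()),
                            n_high=0, significant=False)
                notes.append(f"{feature} [{pop_name}]: survival analysis skipped ({err})")
            cox_rows.append(crow)

    return CohortReport(
        density_table=pd.DataFrame(density_rows),
        cox_table=pd.DataFrame(cox_rows),
        km_curves=km_curves,
        notes=notes,
        n_tests=n_tests,
    )
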