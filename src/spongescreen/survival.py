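"""Survival stage: median split, Kaplan-Meier, log-rank, Cox screening.

Cox proportional-hazards models are fitted with lifelines (Efron tie
handling, Newton-Raphson); categorical covariates are expanded to
reference-coded indicators with the clinically conventional reference
levels (stage I, T1, N0, M0, G1, male, low expression).  The log-rank
test is computed directly from the observed-minus-expected event table
with hypergeometric variance, which also powers the maximally selected
rank-statistic cutpoint search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats as sps

from .rankstats import TestResult

__all__ = [
    "CoxResult", "median_split", "kaplan_meier", "logrank_test",
    "cox_fit", "cox_screen", "optimal_cutoff",
]

REFERENCE_LEVELS = {
    "expr_group": ["low", "high"],
    "sex": ["male", "female"],
    "stage": ["I", "II", "III", "IV"],
    "t_stage": ["T1", "T2", "T3", "T4"],
    "n_stage": ["N0", "N1", "N2", "N3"],
    "m_stage": ["M0", "M1"],
    "grade": ["G1", "G2", "G3"],
}


@dataclass
class CoxResult:
    """Per-covariate hazard-ratio table plus the model log-likelihood.

    ``table`` columns: covariate, level, beta, hr, ci_low, ci_high, p —
    one row per expanded (reference-coded) model term.  ``diagnostics``
    collects fitter warnings (e.g. suspected monotone likelihood /
    complete separation).
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    diagnostics: tuple = ()

    def beta(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def median_split(values: pd.Series) -> pd.Series:
    """high/low labels at the median; ties (value == median) go to low."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least two samples to split")
    med = values.median()
    if values.nunique() == 1:
        raise ValueError("all values identical; median split is degenerate")
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"records lack a {col!r} column")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return records


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve: time, at_risk, events, survival."""
    records = _check_records(records)
    if len(records) == 0:
        raise ValueError("need at least one record")
    km = KaplanMeierFitter()
    km.fit(records["time"], records["event"])
    table = km.event_table.copy()
    out = pd.DataFrame({
        "time": table.index.to_numpy(float),
        "at_risk": table["at_risk"].to_numpy(float),
        "events": table["observed"].to_numpy(float),
        "survival": km.survival_function_["KM_estimate"].to_numpy(float),
    })
    return out.reset_index(drop=True)


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> TestResult:
    """Two-group log-rank test (1-df chi-square).

    At every distinct event time the observed events in group 1 are
    compared against the hypergeometric expectation given the risk sets;
    the squared standardised sum of differences is the statistic.
    """
    records = _check_records(records)
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    g1 = sorted(groups)[0]
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(int)
    in1 = (records[group_col] == g1).to_numpy()
    chi2, _ = _logrank_core(time, event, in1)
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return TestResult(statistic=chi2, p=p, method="log-rank")


def _logrank_core(time, event, in_group1) -> tuple:
    """(chi-square, signed O-E sum) of the two-group log-rank test."""
    order = np.argsort(time, kind="stable")
    time, event, in1 = time[order], event[order], in_group1[order]
    n = len(time)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk1 = int(in1.sum())
    while i < n:
        j = i
        d = d1 = 0
        removed = removed1 = 0
        while j < n and time[j] == time[i]:
            removed += 1
            removed1 += int(in1[j])
            if event[j]:
                d += 1
                d1 += int(in1[j])
            j += 1
        if d > 0 and at_risk > 1:
            e1 = d * at_risk1 / at_risk
            v = (d * (at_risk1 / at_risk) * (1 - at_risk1 / at_risk)
                 * (at_risk - d) / (at_risk - 1))
            o_minus_e += d1 - e1
            var += v
        at_risk -= removed
        at_risk1 -= removed1
        i = j
    if var <= 0:
        return 0.0, 0.0
    return float(o_minus_e**2 / var), float(o_minus_e)


def _expand_covariates(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Reference-code categorical covariates; numerics pass through."""
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} not in records")
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            design[cov] = col.astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)  # already an indicator
        else:
            levels = REFERENCE_LEVELS.get(cov)
            if levels is None:
                levels = sorted(col.dropna().unique())
            observed = [l for l in levels if l in set(col)]
            extra = sorted(set(col.dropna()) - set(observed))
            observed += extra
            for level in observed[1:]:
                design[f"{cov}[{level}]"] = (col == level).astype(float)
    return design


def cox_fit(records: pd.DataFrame, covariates) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald 95% CIs."""
    records = _check_records(records)
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    design = _expand_covariates(records, covariates)
    if design.shape[1] == 0:
        raise ValueError("no usable covariates")
    frame = pd.concat([records[["time", "event"]], design], axis=1).dropna()
    if frame.shape[0] < design.shape[1] + 1:
        raise ValueError("too few complete records for the model")
    fitter = CoxPHFitter()
    diagnostics: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            # tight Newton-Raphson stopping so estimates agree with
            # direct partial-likelihood maximisation to ~1e-6
            fitter.fit(frame, duration_col="time", event_col="event",
                       fit_options={"precision": 1e-9, "max_steps": 100})
        diagnostics = [str(w.message) for w in caught
                       if issubclass(w.category, ConvergenceWarning)]
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summary = fitter.summary
    rows = []
    for term in design.columns:
        beta = float(summary.loc[term, "coef"])
        se = float(summary.loc[term, "se(coef)"])
        cov_name, level = (term.split("[", 1) + [""])[:2]
        with np.errstate(over="ignore"):
            # separation can drive |beta| or se huge; inf CI bounds are the
            # honest report, not an exception
            rows.append({
                "term": term,
                "covariate": cov_name,
                "level": level.rstrip("]"),
                "beta": beta,
                "hr": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "p": float(summary.loc[term, "p"]),
            })
    return CoxResult(table=pd.DataFrame(rows),
                     log_likelihood=float(fitter.log_likelihood_),
                     n=int(frame.shape[0]),
                     n_events=int(frame["event"].sum()),
                     diagnostics=tuple(diagnostics))


def cox_screen(records: pd.DataFrame, candidate_covariates,
               univ_p_enter: float = 0.05) -> tuple:
    """Univariate screen then a joint model of the passing covariates.

    Each candidate is fitted alone; a candidate enters the multivariate
    model if any of its expanded levels has Wald p below ``univ_p_enter``.
    Returns (univariate table, multivariate CoxResult or None).
    """
    records = _check_records(records)
    univ_rows = []
    passing = []
    for cov in candidate_covariates:
        try:
            res = cox_fit(records, [cov])
        except RuntimeError as err:
            # separation / non-convergence: report the candidate as
            # unusable instead of aborting the whole screen
            univ_rows.append(pd.DataFrame([{
                "model": "univariate", "term": cov, "covariate": cov,
                "level": "", "beta": np.nan, "hr": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "status": f"non-convergent: {err}"}]))
            continue
        tab = res.table.copy()
        tab.insert(0, "model", "univariate")
        tab["status"] = "ok"
        univ_rows.append(tab)
        if (tab["p"] < univ_p_enter).any():
            passing.append(cov)
    univariate = pd.concat(univ_rows, ignore_index=True)
    multivariate = cox_fit(records, passing) if passing else None
    return univariate, multivariate


def optimal_cutoff(values: pd.Series, records: pd.DataFrame,
                   quantile_band=(0.1, 0.9)) -> dict:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Scans every observed value inside the quantile band as a candidate
    split of ``values`` and returns the cut with the largest log-rank
    statistic.  The accompanying p-value is the naive 1-df chi-square
    tail and is NOT corrected for the multiplicity of the scan — flagged
    in the result.
    """
    values = pd.Series(values).astype(float)
    records = _check_records(records)
    if len(records) < 10 or records["event"].sum() < 1:
        raise ValueError("need >= 10 records with at least one event")
    lo, hi = values.quantile(quantile_band[0]), values.quantile(quantile_band[1])
    cuts = sorted(v for v in values.unique() if lo <= v < hi)
    if not cuts:
        raise ValueError("no admissible cutpoint inside the quantile band")
    time = records["time"].to_numpy(float)
    event = records["event"].to_numpy(int)
    best = None
    for cut in cuts:
        in_low = (values <= cut).to_numpy()
        if in_low.all() or not in_low.any():
            continue
        chi2, _ = _logrank_core(time, event, in_low)
        if best is None or chi2 > best["statistic"]:
            best = {"cutpoint": float(cut), "statistic": float(chi2)}
    if best is None:
        raise ValueError("no admissible cutpoint inside the quantile band")
    best["p_naive"] = float(sps.chi2.sf(best["statistic"], df=1))
    best["multiplicity_corrected"] = False
    best["note"] = ("p_naive ignores the multiplicity of the cutpoint scan; "
                    "treat it as descriptive only")
    return best
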