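"""Survival analysis: clinical preprocessing, Cox screening, and bootstrap boosted-Cox risk scores.

Clinical side: MELD score with the dialysis substitution rule, the ISGLS
post-hepatectomy liver-failure flag, and the cohort imputation rules
(medians for continuous labs/anthropometrics, 0 for unknown staging flags,
G = 2 as the modal grade). Classical screening runs one univariable Cox
proportional-hazards fit per covariate and feeds every covariate with
P < alpha into a multivariable model with conditional backward selection.

Machine-learning side: gradient-boosted regression trees with Cox partial-
likelihood loss, trained over bootstrap rounds (canonically 1000). Each round
resamples the training patients with replacement, scores that round's
out-of-bag patients ("validation") and the fixed held-out test patients, and
records its concordance indices and impurity feature importances; per-patient
risk scores are averaged across rounds. Evaluation splits the averaged risks
at the median into low/high groups compared by Kaplan–Meier curves and the
log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.ensemble import GradientBoostingSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = [
    "compute_meld",
    "isgls_liver_failure",
    "DEFAULT_IMPUTATION_RULES",
    "impute_clinical",
    "filter_outcomes",
    "univariable_cox_screen",
    "multivariable_cox",
    "concordance_index",
    "RiskScoreSet",
    "fit_risk_model",
    "KMSplitResult",
    "km_logrank_split",
    "feature_importance_distribution",
]


# ---------------------------------------------------------------------------
# Clinical definitions
# ---------------------------------------------------------------------------

def compute_meld(bilirubin: float, creatinine: float, inr: float,
                 dialysis_last_week: bool = False) -> float:
    """MELD score: 9.57 ln(creatinine) + 3.78 ln(bilirubin) + 11.2 ln(INR) + 6.43.

    Units: creatinine and total bilirubin in mg/dL, INR dimensionless. If the
    patient was dialyzed within the week before the labs, creatinine is set
    to 4.0 before evaluation.
    """
    if bilirubin <= 0 or creatinine <= 0 or inr <= 0:
        raise ValueError("lab values must be positive")
    if dialysis_last_week:
        creatinine = 4.0
    return 9.57 * math.log(creatinine) + 3.78 * math.log(bilirubin) + 11.2 * math.log(inr) + 6.43


def isgls_liver_failure(inr_pod5: float, bilirubin_pod5: float,
                        inr_uln: float = 1.2, bilirubin_uln: float = 1.1) -> bool:
    """Post-hepatectomy liver failure flag (ISGLS): increased INR with
    concomitant hyperbilirubinemia on/after postoperative day 5."""
    return bool(inr_pod5 > inr_uln and bilirubin_pod5 > bilirubin_uln)


# Continuous labs/anthropometrics get the column median; staging flags whose
# absence means "not documented" get 0; the G grading gets 2, the modal grade.
DEFAULT_IMPUTATION_RULES: dict[str, object] = {
    "ca19_9": "median",
    "ldh": "median",
    "weight": "median",
    "height": "median",
    "days_diagnosis_to_surgery": "median",
    "biliary_stent": ("constant", 0),
    "perineural_invasion": ("constant", 0),
    "uicc_stage": ("constant", 0),
    "V": ("constant", 0),
    "L": ("constant", 0),
    "T": ("constant", 0),
    "G": ("constant", 2),
}


def impute_clinical(table: pd.DataFrame, rules: dict[str, object] | None = None,
                    train_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Fill missing clinical values per rule; adds ``<col>_imputed`` flags.

    ``rules`` maps a column to ``"median"`` or ``("constant", value)``.
    Medians are computed on training rows only when ``train_mask`` is given.
    A rule naming a column absent from the table is a configuration error.
    """
    if rules is None:
        rules = DEFAULT_IMPUTATION_RULES
    out = table.copy()
    for col, rule in rules.items():
        if col not in out.columns:
            raise KeyError(f"imputation rule references missing column {col!r}")
        missing = out[col].isna()
        out[f"{col}_imputed"] = missing
        if not missing.any():
            continue
        if rule == "median":
            ref = out.loc[train_mask, col] if train_mask is not None else out[col]
            fill = ref.median()
            if pd.isna(fill):
                raise ValueError(f"column {col!r} has no observed values to take a median of")
        elif isinstance(rule, tuple) and rule[0] == "constant":
            fill = rule[1]
        else:
            raise ValueError(f"unknown imputation rule {rule!r} for column {col!r}")
        out.loc[missing, col] = fill
    return out


def filter_outcomes(outcomes: pd.DataFrame, exclude_ihm: bool = True,
                    exclude_r2: bool = True) -> pd.DataFrame:
    """Drop in-hospital deaths and unsuccessful (R2) resections before regression.

    Expects optional boolean columns ``in_hospital_death`` and ``r2_resection``;
    missing columns are treated as all-False.
    """
    keep = pd.Series(True, index=outcomes.index)
    if exclude_ihm and "in_hospital_death" in outcomes:
        keep &= ~outcomes["in_hospital_death"].astype(bool)
    if exclude_r2 and "r2_resection" in outcomes:
        keep &= ~outcomes["r2_resection"].astype(bool)
    return outcomes.loc[keep]


# ---------------------------------------------------------------------------
# Classical Cox screening
# ---------------------------------------------------------------------------

def univariable_cox_screen(table: pd.DataFrame, covariates: list[str],
                           time_col: str = "time", event_col: str = "event",
                           alpha: float = 0.05) -> pd.DataFrame:
    """One univariable Cox PH fit per covariate.

    Returns a DataFrame (covariate, hr, ci_low, ci_high, p, flagged); a
    covariate is flagged for the multivariable stage iff p < alpha (strict).
    Constant covariates are skipped with a warning.
    """
    rows = []
    for cov in covariates:
        x = table[cov]
        if x.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped")
            continue
        cph = CoxPHFitter()
        cph.fit(table[[time_col, event_col, cov]], duration_col=time_col, event_col=event_col)
        s = cph.summary.loc[cov]
        rows.append(
            {
                "covariate": cov,
                "hr": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
                "flagged": bool(s["p"] < alpha),
            }
        )
    return pd.DataFrame(rows)


def _drop_collinear(table: pd.DataFrame, covariates: list[str],
                    r_max: float = 0.999) -> list[str]:
    """Keep the first of any group of (near-)exactly collinear covariates."""
    kept: list[str] = []
    for cov in covariates:
        collinear = False
        for prev in kept:
            r = np.corrcoef(table[cov].astype(float), table[prev].astype(float))[0, 1]
            if np.isfinite(r) and abs(r) > r_max:
                warnings.warn(f"covariate {cov!r} is collinear with {prev!r}; dropped")
                collinear = True
                break
        if not collinear:
            kept.append(cov)
    return kept


def multivariable_cox(table: pd.DataFrame, covariates: list[str],
                      time_col: str = "time", event_col: str = "event",
                      removal_threshold: float = 0.05):
    """Multivariable Cox PH with conditional backward selection.

    Iteratively refits and removes the covariate with the largest P-value
    >= ``removal_threshold`` until every retained covariate is significant.
    Returns (summary DataFrame with hr/ci/p per retained covariate, retained
    covariate list); an empty model (no survivor) is a valid outcome, not an
    error. Exactly collinear covariates are reduced to one representative
    first (the partial likelihood is unidentifiable otherwise).
    """
    current = _drop_collinear(table, list(covariates))
    while current:
        cph = CoxPHFitter()
        cph.fit(table[[time_col, event_col] + current], duration_col=time_col,
                event_col=event_col)
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] >= removal_threshold:
            current = [c for c in current if c != worst]
            continue
        summary = pd.DataFrame(
            {
                "covariate": current,
                "hr": cph.summary["exp(coef)"].values,
                "ci_low": cph.summary["exp(coef) lower 95%"].values,
                "ci_high": cph.summary["exp(coef) upper 95%"].values,
                "p": cph.summary["p"].values,
            }
        )
        return summary, current
    return pd.DataFrame(columns=["covariate", "hr", "ci_low", "ci_high", "p"]), []


# ---------------------------------------------------------------------------
# Boosted-Cox risk modelling with bootstrap averaging
# ---------------------------------------------------------------------------

def concordance_index(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Censoring-aware concordance of risk scores against observed outcomes."""
    c, *_ = concordance_index_censored(np.asarray(event, dtype=bool),
                                       np.asarray(time, dtype=float),
                                       np.asarray(risk, dtype=float))
    return float(c)


DEFAULT_HPO_SPACE = {
    "n_estimators": (50, 500),
    "max_depth": (1, 4),
    "learning_rate": (0.01, 0.3),
    "subsample": (0.5, 1.0),
}

_DEFAULT_GBM_PARAMS = {
    "n_estimators": 100,
    "max_depth": 2,
    "learning_rate": 0.1,
    "subsample": 1.0,
}


@dataclass
class RiskScoreSet:
    """Bootstrap-averaged risk scores and per-round diagnostics."""

    patient_ids: np.ndarray
    train_ids: np.ndarray
    test_ids: np.ndarray
    val_risk: pd.Series  # mean out-of-bag risk per training patient
    test_risk: pd.Series  # mean risk per held-out test patient
    val_concordance: np.ndarray  # per round
    test_concordance: np.ndarray  # per round
    importances: np.ndarray  # (n_rounds, n_features), rows sum to 1
    feature_names: list[str]
    params: dict
    n_rounds: int


def _sample_params(rng: np.random.Generator) -> dict:
    lo, hi = DEFAULT_HPO_SPACE["n_estimators"]
    p = {"n_estimators": int(rng.integers(lo, hi + 1))}
    lo, hi = DEFAULT_HPO_SPACE["max_depth"]
    p["max_depth"] = int(rng.integers(lo, hi + 1))
    lo, hi = DEFAULT_HPO_SPACE["learning_rate"]
    p["learning_rate"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    lo, hi = DEFAULT_HPO_SPACE["subsample"]
    p["subsample"] = float(rng.uniform(lo, hi))
    return p


def _bootstrap_rounds(X, y, train_idx, test_idx, params, n_boot, rng, collect=True):
    """Run bootstrap rounds; returns accumulated risks/concordances/importances."""
    n = len(train_idx)
    risk_sum = np.zeros(len(X))
    risk_cnt = np.zeros(len(X))
    c_val, c_test, imps = [], [], []
    time = y["time"] if "time" in y.dtype.names else y[y.dtype.names[1]]
    event = y[y.dtype.names[0]]
    for r in range(n_boot):
        sub = np.random.default_rng(rng.integers(2**31))
        for _ in range(100):
            boot = train_idx[sub.integers(0, n, n)]
            if event[boot].any():
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample containing an event")
        oob = np.setdiff1d(train_idx, boot)
        est = GradientBoostingSurvivalAnalysis(random_state=int(sub.integers(2**31)), **params)
        est.fit(X[boot], y[boot])
        if collect:
            imp = est.feature_importances_
            tot = imp.sum()
            imps.append(imp / tot if tot > 0 else np.full_like(imp, 1.0 / len(imp)))
        if oob.size:
            pred = est.predict(X[oob])
            risk_sum[oob] += pred
            risk_cnt[oob] += 1
            try:
                c_val.append(concordance_index(time[oob], event[oob], pred))
            except Exception:
                c_val.append(np.nan)
        else:
            c_val.append(np.nan)
        if test_idx.size:
            predt = est.predict(X[test_idx])
            risk_sum[test_idx] += predt
            risk_cnt[test_idx] += 1
            try:
                c_test.append(concordance_index(time[test_idx], event[test_idx], predt))
            except Exception:
                c_test.append(np.nan)
    return risk_sum, risk_cnt, np.array(c_val), np.array(c_test), np.array(imps)


def fit_risk_model(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    n_boot: int = 1000,
    test_ids: np.ndarray | list | None = None,
    test_fraction: float = 0.19,
    hpo_budget: int = 0,
    hpo_rounds: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> RiskScoreSet:
    """Gradient-boosted Cox risk scores averaged over bootstrap rounds.

    ``features`` (patients x features) and ``outcomes`` (columns ``time`` and
    ``event``) must share a row index of patient ids. Test patients are held
    out by id (``test_ids``) or by a seeded draw of ``test_fraction``; the
    remaining patients form the bootstrap training pool. Each round fits on a
    with-replacement resample of the pool and scores that round's out-of-bag
    patients (validation) and the fixed test set; per-patient risks are the
    across-round means. With ``hpo_budget`` > 0, that many random
    hyperparameter draws are first evaluated over ``hpo_rounds`` bootstrap
    rounds each and the draw with the best mean validation concordance wins.
    """
    if not features.index.equals(outcomes.index):
        raise ValueError("features and outcomes must share the same patient index")
    X = features.to_numpy(dtype=float)
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=bool)
    y = Surv.from_arrays(event=event, time=time)
    ids = np.asarray(features.index)

    rng = np.random.default_rng(seed)
    if test_ids is not None:
        test_mask = np.isin(ids, np.asarray(test_ids))
        if test_mask.sum() != len(np.asarray(test_ids)):
            raise ValueError("some test_ids not found in the feature index")
    else:
        n_test = int(round(test_fraction * len(ids)))
        test_mask = np.zeros(len(ids), dtype=bool)
        test_mask[rng.choice(len(ids), n_test, replace=False)] = True
    train_idx = np.flatnonzero(~test_mask)
    test_idx = np.flatnonzero(test_mask)
    if not event[train_idx].any():
        raise ValueError("all training outcomes are censored; Cox loss cannot be fit")

    chosen = dict(_DEFAULT_GBM_PARAMS if params is None else params)
    if hpo_budget > 0:
        best_c = -np.inf
        for _ in range(hpo_budget):
            cand = _sample_params(rng)
            _, _, c_val, _, _ = _bootstrap_rounds(
                X, y, train_idx, test_idx[:0], cand, hpo_rounds,
                np.random.default_rng(rng.integers(2**31)), collect=False)
            mc = np.nanmean(c_val) if len(c_val) else -np.inf
            if mc > best_c:
                best_c, chosen = mc, cand

    risk_sum, risk_cnt, c_val, c_test, imps = _bootstrap_rounds(
        X, y, train_idx, test_idx, chosen, n_boot,
        np.random.default_rng(rng.integers(2**31)))

    with np.errstate(invalid="ignore"):
        mean_risk = risk_sum / risk_cnt
    return RiskScoreSet(
        patient_ids=ids,
        train_ids=ids[train_idx],
        test_ids=ids[test_idx],
        val_risk=pd.Series(mean_risk[train_idx], index=ids[train_idx], name="risk"),
        test_risk=pd.Series(mean_risk[test_idx], index=ids[test_idx], name="risk"),
        val_concordance=c_val,
        test_concordance=c_test,
        importances=imps,
        feature_names=list(features.columns),
        params=chosen,
        n_rounds=n_boot,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank evaluation of averaged risks
# ---------------------------------------------------------------------------

@dataclass
class KMSplitResult:
    """Median-split survival comparison of averaged risk scores."""

    median_risk: float
    low_group: pd.Index
    high_group: pd.Index
    km_low: pd.DataFrame  # columns: time, survival, at_risk
    km_high: pd.DataFrame
    logrank_stat: float
    p_value: float
    concordance: float


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    ev = kmf.event_table
    return pd.DataFrame(
        {
            "time": kmf.survival_function_.index.values,
            "survival": kmf.survival_function_.iloc[:, 0].values,
            "at_risk": ev["at_risk"].reindex(kmf.survival_function_.index).values,
        }
    )


def km_logrank_split(risk: pd.Series, outcomes: pd.DataFrame) -> KMSplitResult:
    """Split averaged risks at the median and compare the two survival curves.

    Patients at or below the median go to the low-risk group (ties to low).
    Returns product-limit curves for both groups, the two-sample log-rank
    statistic and P-value, and the concordance index of the averaged risks.
    """
    risk = risk.dropna()
    out = outcomes.loc[risk.index]
    if risk.nunique() < 2:
        raise ValueError("all risk scores identical; median split impossible")
    med = float(np.median(risk.values))
    low = risk.index[risk.values <= med]
    high = risk.index[risk.values > med]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("median split leaves fewer than 2 patients in a group")

    kml, kmh = KaplanMeierFitter(), KaplanMeierFitter()
    kml.fit(out.loc[low, "time"], out.loc[low, "event"])
    kmh.fit(out.loc[high, "time"], out.loc[high, "event"])
    lr = logrank_test(out.loc[low, "time"], out.loc[high, "time"],
                      out.loc[low, "event"], out.loc[high, "event"])
    c = concordance_index(out["time"].values, out["event"].values, risk.values)
    return KMSplitResult(
        median_risk=med,
        low_group=low,
        high_group=high,
        km_low=_km_table(kml),
        km_high=_km_table(kmh),
        logrank_stat=float(lr.test_statistic),
        p_value=float(lr.p_value),
        concordance=c,
    )


def feature_importance_distribution(fits) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-round impurity feature importances and their summary.

    Accepts a :class:`RiskScoreSet` (importances recorded per bootstrap
    round) or a list of fitted tree ensembles. Each round's importances are
    normalized to sum to 1. Returns (samples, summary) where ``samples`` has
    one row per round and ``summary`` gives median and quartiles per feature
    for violin plotting.
    """
    if isinstance(fits, RiskScoreSet):
        imps, names = fits.importances, fits.feature_names
    else:
        rows = []
        for est in fits:
            if not hasattr(est, "feature_importances_"):
                raise TypeError("feature importances require tree-based models")
            imp = np.asarray(est.feature_importances_, dtype=float)
            tot = imp.sum()
            rows.append(imp / tot if tot > 0 else np.full_like(imp, 1.0 / len(imp)))
        imps = np.array(rows)
        names = [f"f{i}" for i in range(imps.shape[1])]
    samples = pd.DataFrame(imps, columns=names)
    summary = samples.agg(["median", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)]).T
    summary.columns = ["median", "q25", "q75"]
    return samples, summary
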