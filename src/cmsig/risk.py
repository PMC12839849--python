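"""Prognostic risk modelling on a distilled signature.

The workflow mirrors standard prognostic-signature practice: a univariate
Cox screen over the panel, a multivariate Cox fit of the survivors (Efron
tie handling, via lifelines), a linear risk score
``RS_i = sum_j beta_j * z_ij`` on training-cohort-standardized features, a
high/low cutoff at the maximum Youden index of the IPCW time-dependent ROC
at a fixed horizon, and validation by Kaplan-Meier / log-rank, group hazard
ratio, Harrell's C-index and multi-horizon AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance

from .io import ClinicalTable, ModelBundle

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass
class CoxRiskModel:
    """Fitted multivariate Cox model plus the risk-score cutoff."""

    feature_ids: list[str]
    coefficients: np.ndarray
    feature_means: np.ndarray  # training-cohort standardization parameters
    feature_sds: np.ndarray
    cutoff: float | None = None
    cutoff_horizon: float | None = None
    log_likelihood: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        k = len(self.feature_ids)
        for name, arr in (
            ("coefficients", self.coefficients),
            ("feature_means", self.feature_means),
            ("feature_sds", self.feature_sds),
        ):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per feature")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature standard deviations must be positive")

    def to_bundle(self) -> ModelBundle:
        params = {
            "feature_ids": list(self.feature_ids),
            "coefficients": self.coefficients,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "cutoff": self.cutoff,
            "cutoff_horizon": self.cutoff_horizon,
            "log_likelihood": self.log_likelihood,
        }
        return ModelBundle("cox_risk_model", params, dict(self.metadata))

    @classmethod
    def from_bundle(cls, bundle: ModelBundle) -> "CoxRiskModel":
        if bundle.stage != "cox_risk_model":
            raise ValueError(f"bundle holds {bundle.stage!r}, not a cox risk model")
        p = bundle.params
        return cls(
            list(p["feature_ids"]),
            p["coefficients"],
            p["feature_means"],
            p["feature_sds"],
            p["cutoff"],
            p["cutoff_horizon"],
            p["log_likelihood"],
            dict(bundle.metadata),
        )


@dataclass
class RiskAssignment:
    """Per-sample risk score and high/low group (high iff RS >= cutoff)."""

    sample_ids: list[str]
    risk_score: np.ndarray
    group: np.ndarray  # "high" / "low"


@dataclass
class RocCurve:
    """IPCW time-dependent ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray  # descending; classification rule is RS >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# Cox fitting


def _survival_frame(features: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    if list(features.index) != list(clinical.sample_ids):
        clinical = clinical.select(list(features.index))
    df = features.copy()
    df["time"] = clinical.time
    df["event"] = clinical.event
    return df


def univariate_cox_screen(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    alpha_keep: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Screen features one at a time by univariate Cox Wald p.

    Features are z-scored internally. Zero-variance features are skipped
    (reported with NaN p). Returns the retained feature ids (Wald
    p < ``alpha_keep``) and a per-feature report (coef, p, skipped flag).
    """
    if clinical.event.sum() == 0:
        raise ValueError("no events in the cohort; univariate screen is undefined")
    rows = []
    retained = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            rows.append({"feature": str(col), "coef": np.nan, "p": np.nan, "skipped": True})
            continue
        z = (x - x.mean()) / sd
        df = pd.DataFrame({"z": z, "time": clinical.time, "event": clinical.event})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        p = float(cph.summary.loc["z", "p"])
        rows.append(
            {"feature": str(col), "coef": float(cph.params_["z"]), "p": p, "skipped": False}
        )
        if p < alpha_keep:
            retained.append(str(col))
    report = pd.DataFrame(rows).set_index("feature")
    if not retained:
        raise ValueError("empty signature after screening")
    return retained, report


def fit_cox(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    penalizer: float = 0.0,
) -> CoxRiskModel:
    """Multivariate Cox fit (Efron ties) of the retained features.

    Features are z-scored with training-cohort parameters that are stored on
    the model so validation cohorts are scored without refitting. Requires
    more events than features.
    """
    n_events = int(clinical.event.sum())
    if n_events <= features.shape[1]:
        raise ValueError(
            f"{n_events} events for {features.shape[1]} features; "
            "reduce the feature set before fitting"
        )
    X = features.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = features.columns[np.argmax(sds == 0)]
        raise ValueError(f"zero-variance feature {bad!r} in multivariate fit")
    Z = (X - means) / sds
    df = pd.DataFrame(Z, columns=[str(c) for c in features.columns])
    df["time"] = clinical.time
    df["event"] = clinical.event
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(f"multivariate Cox did not converge: {err}") from err
    beta = cph.params_.to_numpy()
    if np.any(np.abs(beta) > 50):
        bad = features.columns[int(np.argmax(np.abs(beta)))]
        raise ValueError(f"apparent separation: coefficient diverged for {bad!r}")
    return CoxRiskModel(
        [str(c) for c in features.columns],
        beta,
        means,
        sds,
        log_likelihood=float(cph.log_likelihood_),
    )


def risk_scores(model: CoxRiskModel, features: pd.DataFrame) -> pd.Series:
    """Linear risk score ``RS_i = sum_j beta_j z_ij`` using the model's
    stored (training-cohort) standardization parameters."""
    missing = [f for f in model.feature_ids if f not in features.columns]
    if missing:
        raise ValueError(f"features missing for risk scoring: {missing}")
    X = features[model.feature_ids].to_numpy(dtype=float)
    Z = (X - model.feature_means) / model.feature_sds
    return pd.Series(Z @ model.coefficients, index=features.index, name="risk_score")


# ---------------------------------------------------------------------------
# time-dependent ROC and cutoff


def _censoring_survival(clinical: ClinicalTable):
    """KM estimate of the censoring distribution G(t) = P(C > t)."""
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, 1 - clinical.event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_left(t: np.ndarray) -> np.ndarray:
        # left limit G(t-): product over censoring times strictly < t
        idx = np.searchsorted(times, t, side="left") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out

    def g_at(t: float) -> float:
        idx = np.searchsorted(times, t, side="right") - 1
        return float(surv[idx]) if idx >= 0 else 1.0

    return g_left, g_at


def time_dependent_roc(
    rs: pd.Series | np.ndarray,
    clinical: ClinicalTable,
    horizon: float,
) -> RocCurve:
    """Cumulative-case / dynamic-control ROC at ``horizon`` with inverse
    probability of censoring weights from the KM censoring estimator.

    Cases are subjects with an observed event at or before the horizon
    (weight ``1/G(t_i-)``); controls are subjects still at risk past it
    (weight ``1/G(horizon)``). With no censoring before the horizon this
    reduces to the plain ROC of RS against the event-by-horizon indicator.
    The AUC is the trapezoidal integral of the curve.
    """
    rs = np.asarray(rs, dtype=float)
    time, event = clinical.time, clinical.event
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if case.sum() == 0:
        raise ValueError("no events before the horizon")
    if control.sum() == 0:
        raise ValueError("no subjects at risk past the horizon")

    g_left, g_at = _censoring_survival(clinical)
    w = np.zeros(len(rs))
    gc = g_left(time[case])
    gc = np.where(gc <= 0, np.nan, gc)
    w[case] = 1.0 / gc
    g_h = g_at(horizon)
    if g_h <= 0:
        raise ValueError("censoring survival vanishes at the horizon")
    w[control] = 1.0 / g_h
    w = np.nan_to_num(w, nan=0.0)

    thresholds = np.unique(rs)[::-1]  # descending
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    w_case_tot = w[case].sum()
    w_ctrl_tot = w[control].sum()
    for i, c in enumerate(thresholds):
        positive = rs >= c
        sens[i] = w[case & positive].sum() / w_case_tot
        spec[i] = w[control & ~positive].sum() / w_ctrl_tot

    # integrate over the full sweep including the (0,0) and (1,1) endpoints
    fpr = np.concatenate(([0.0], 1.0 - spec, [1.0]))
    tpr = np.concatenate(([0.0], sens, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(horizon, thresholds, sens, spec, auc)


def youden_cutoff(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward the smaller threshold (the larger high-risk group).
    Returns ``(cutoff, J)``. A constant score yields a single threshold with
    J = 0 (the degenerate, uninformative cutoff) rather than an error.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    # thresholds are descending; among maximal J pick the last (= smallest)
    best = len(j) - 1 - int(np.argmax(j[::-1] >= j.max() - 1e-12))
    return float(roc.thresholds[best]), float(j[best])


def assign_groups(model: CoxRiskModel, features: pd.DataFrame) -> RiskAssignment:
    """Score samples and dichotomize at the model's cutoff (high iff RS >= c*)."""
    if model.cutoff is None:
        raise ValueError("model has no cutoff; call fit_risk_model or set one")
    rs = risk_scores(model, features)
    group = np.where(rs.to_numpy() >= model.cutoff, HIGH, LOW).astype(object)
    return RiskAssignment(list(features.index), rs.to_numpy(), group)


def fit_risk_model(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    alpha_keep: float = 0.05,
    horizon: float = 60.0,
    penalizer: float = 0.0,
) -> tuple[CoxRiskModel, RiskAssignment, pd.DataFrame]:
    """Screen, fit, score and cut: the full training-cohort risk pipeline.

    ``horizon`` is in the clinical table's declared time unit (default 60,
    i.e. 5 years for monthly times). Returns the model (with cutoff), the
    training-cohort risk assignment, and the univariate screen report.
    """
    retained, screen_report = univariate_cox_screen(features, clinical, alpha_keep)
    model = fit_cox(features[retained], clinical, penalizer=penalizer)
    rs = risk_scores(model, features)
    roc = time_dependent_roc(rs, clinical, horizon)
    cutoff, j = youden_cutoff(roc)
    model.cutoff = cutoff
    model.cutoff_horizon = horizon
    model.metadata.update({"youden_j": j, "alpha_keep": alpha_keep})
    assignment = assign_groups(model, features)
    return model, assignment, screen_report


# ---------------------------------------------------------------------------
# evaluation statistics


@dataclass
class KmCurve:
    times: np.ndarray  # event times
    survival: np.ndarray  # product-limit estimate after each event time
    at_risk: np.ndarray
    n_events: np.ndarray


def km_curve(clinical: ClinicalTable) -> KmCurve:
    """Product-limit (Kaplan-Meier) estimate at the observed event times."""
    if len(clinical) == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, clinical.event)
    table = kmf.event_table
    is_event = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[is_event]
    surv = kmf.survival_function_.iloc[:, 0]
    survival = np.array([float(surv.loc[t]) for t in times])
    return KmCurve(
        times,
        survival,
        table["at_risk"].to_numpy(dtype=int)[is_event],
        table["observed"].to_numpy(dtype=int)[is_event],
    )


def logrank_test(clinical: ClinicalTable, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels}")
    a = groups == labels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("a group has no subjects")
    res = _ll_logrank(
        clinical.time[a], clinical.time[~a], clinical.event[a], clinical.event[~a]
    )
    return float(res.test_statistic), float(res.p_value)


def group_hazard_ratio(clinical: ClinicalTable, groups, positive=None) -> dict:
    """Univariate Cox on a two-group indicator.

    Returns ``{"hr", "ci_low", "ci_high", "p"}`` with HR = exp(beta) for
    membership of the ``positive`` group (default: the ``"high"`` risk group
    when present, else the first label in sorted order) relative to the
    other group.
    """
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"hazard ratio needs exactly 2 groups, got {labels}")
    if positive is None:
        positive = HIGH if HIGH in labels else labels[0]
    if positive not in labels:
        raise ValueError(f"positive label {positive!r} not among groups {labels}")
    ind = (groups == positive).astype(float)
    for lab in labels:
        if clinical.event[groups == lab].sum() == 0:
            raise ValueError(f"group {lab!r} has no events")
    df = pd.DataFrame({"ind": ind, "time": clinical.time, "event": clinical.event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["ind"])
    se = float(cph.standard_errors_["ind"])
    return {
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.96 * se)),
        "ci_high": float(np.exp(beta + 1.96 * se)),
        "p": float(cph.summary.loc["ind", "p"]),
    }


def concordance_index(rs, clinical: ClinicalTable) -> float:
    """Harrell's C for a risk score (higher score = earlier failure)."""
    rs = np.asarray(rs, dtype=float)
    if len(np.unique(clinical.time[clinical.event == 1])) == 0:
        raise ValueError("no comparable pairs (no events)")
    # lifelines' convention is higher prediction = longer survival
    return float(_ll_concordance(clinical.time, -rs, clinical.event))


@dataclass
class SurvivalReport:
    """Everything the validation figures show, as plain arrays."""

    km: dict  # group -> KmCurve
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: dict
    c_index: float
    auc: dict  # horizon -> AUC
    waterfall: pd.DataFrame  # RS sorted ascending with event status


def evaluate_risk(
    model: CoxRiskModel,
    features: pd.DataFrame,
    clinical: ClinicalTable,
    horizons: tuple = (24.0, 36.0, 60.0),
) -> SurvivalReport:
    """Validate a fitted risk model on a cohort (training or external)."""
    assignment = assign_groups(model, features)
    clinical = clinical.select(assignment.sample_ids)
    groups = assignment.group
    km = {}
    for lab in (HIGH, LOW):
        sel = groups == lab
        if sel.sum():
            km[lab] = km_curve(clinical.select(list(np.array(assignment.sample_ids)[sel])))
    stat, p = logrank_test(clinical, groups)
    hr = group_hazard_ratio(clinical, groups)
    c = concordance_index(assignment.risk_score, clinical)
    aucs = {}
    for horizon in horizons:
        try:
            aucs[horizon] = time_dependent_roc(assignment.risk_score, clinical, horizon).auc
        except ValueError as err:
            logger.warning("AUC at horizon %s unavailable: %s", horizon, err)
            aucs[horizon] = float("nan")
    order = np.argsort(assignment.risk_score)
    waterfall = pd.DataFrame(
        {
            "sample_id": np.array(assignment.sample_ids)[order],
            "risk_score": assignment.risk_score[order],
            "event": clinical.event[order],
            "group": groups[order],
        }
    ).reset_index(drop=True)
    return SurvivalReport(km, stat, p, hr, c, aucs, waterfall)
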