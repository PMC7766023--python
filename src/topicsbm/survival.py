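"""Clinical joins and survival analysis on topic features.

Builds patient lifetimes from vital status and follow-up fields, cleans
tumor-stage labels, engineers the binary topic up-regulation feature
(weight above the cohort median), fits a Cox proportional-hazards model
to it, and scores per-cluster five-year survival fractions against a
record-reshuffling null.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

log = logging.getLogger(__name__)

FIVE_YEARS_DAYS = 1825


def compute_lifetime(clinical: pd.DataFrame) -> pd.DataFrame:
    """Durations and event indicators from GDC-style vital-status fields.

    Expects columns ``vital_status`` (Alive/Dead), ``days_to_death`` and
    ``days_to_last_follow_up``.  Dead patients contribute
    (days_to_death, event=1); Alive patients (days_to_last_follow_up,
    event=0).  Records with a missing required field or a non-positive
    duration are dropped and logged.
    """
    required = {"vital_status", "days_to_death", "days_to_last_follow_up"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"missing clinical columns: {sorted(missing)}")
    status = clinical["vital_status"].astype(str).str.strip().str.lower()
    bad_status = ~status.isin({"alive", "dead"})
    if bad_status.any():
        raise ValueError("vital_status must be Alive or Dead")

    duration = np.where(status == "dead",
                        pd.to_numeric(clinical["days_to_death"], errors="coerce"),
                        pd.to_numeric(clinical["days_to_last_follow_up"],
                                      errors="coerce"))
    event = (status == "dead").astype(int)
    out = clinical.copy()
    out["duration_days"] = duration
    out["event"] = event
    keep = np.isfinite(duration) & (duration > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d records with missing or non-positive lifetime",
                 n_dropped)
    return out.loc[keep].reset_index(drop=True)


_STAGE_RE = re.compile(r"^\s*(?:stage\s+)?(iv|iii|ii|i)[a-z]*\s*$", re.IGNORECASE)


def clean_stage(raw_label) -> str | None:
    """Canonical tumor stage in {i, ii, iii, iv}, or None when missing.

    Trailing sub-stage letters are stripped ("stage ia" -> "i"); "nan" and
    "not reported" map to missing; unrecognized labels warn and map to
    missing.
    """
    if raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)):
        return None
    text = str(raw_label).strip().lower()
    if text in {"", "nan", "not reported", "none"}:
        return None
    match = _STAGE_RE.match(text)
    if match is None:
        warnings.warn(f"unrecognized stage label {raw_label!r}")
        return None
    return match.group(1).lower()


def upregulation_feature(topic_given_sample: pd.DataFrame, topic) -> pd.Series:
    """Binary per-sample flag: topic weight strictly above the cohort median.

    The threshold is the 50th percentile (linear interpolation between
    order statistics); values <= threshold map to 0.  A constant column
    warns and yields all zeros.
    """
    key = topic if isinstance(topic, str) else f"topic{topic}"
    if key not in topic_given_sample.columns:
        raise ValueError(f"no topic column {topic!r}")
    values = topic_given_sample[key].to_numpy(dtype=float)
    thr = np.percentile(values, 50)
    if values.max() == values.min():
        warnings.warn("constant topic column; no sample is up-regulated")
    return pd.Series((values > thr).astype(int), index=topic_given_sample.index,
                     name=f"up_{key}")


@dataclass
class CoxResult:
    """Single-covariate Cox proportional-hazards estimate."""

    coef: float
    hazard_ratio: float
    p_value: float
    n: int
    ci_lower: float
    ci_upper: float

    def to_dict(self) -> dict:
        return {"coef": self.coef, "hazard_ratio": self.hazard_ratio,
                "p_value": self.p_value, "n": self.n,
                "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}


def cox_fit(clinical: pd.DataFrame, covariate) -> CoxResult:
    """Cox proportional-hazards fit of duration/event on one covariate.

    Partial-likelihood maximization via lifelines.  The hazard ratio
    exp(coef) compares covariate value x+1 to x (for the binary
    up-regulation feature: up-regulated vs not).  Requires at least two
    events and a non-constant covariate.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.size != len(clinical):
        raise ValueError("covariate length does not match clinical table")
    if clinical["event"].sum() < 2:
        raise ValueError("need at least two events for a Cox fit")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({
        "duration": clinical["duration_days"].to_numpy(dtype=float),
        "event": clinical["event"].to_numpy(dtype=int),
        "x": cov - cov.mean(),  # mean-centered as in the hazard formula
    })
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # pragma: no cover - lifelines raises various types
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    coef = float(fitter.params_["x"])
    ci = fitter.confidence_intervals_
    return CoxResult(coef=coef,
                     hazard_ratio=float(np.exp(coef)),
                     p_value=float(fitter.summary.loc["x", "p"]),
                     n=len(df),
                     ci_lower=float(np.exp(ci.iloc[0, 0])),
                     ci_upper=float(np.exp(ci.iloc[0, 1])))


def five_year_survival(clinical: pd.DataFrame,
                       horizon_days: int = FIVE_YEARS_DAYS,
                       mode: str = "fraction") -> float:
    """Fraction of patients surviving past the horizon (default 5 years).

    ``mode='fraction'`` counts patients whose recorded duration reaches
    the horizon; patients who died or were last seen before it count as
    not surviving.  ``mode='km'`` instead evaluates the Kaplan-Meier
    estimate at the horizon, treating early censored patients as at risk.
    """
    if len(clinical) == 0:
        raise ValueError("empty cluster")
    durations = clinical["duration_days"].to_numpy(dtype=float)
    if mode == "fraction":
        return float((durations >= horizon_days).mean())
    if mode == "km":
        km = KaplanMeierFitter()
        km.fit(durations, clinical["event"].to_numpy(dtype=int))
        return float(km.predict(horizon_days))
    raise ValueError(f"unknown mode {mode!r}")


def cluster_survival_zscore(clusters, clinical: pd.DataFrame,
                            horizon_days: int = FIVE_YEARS_DAYS,
                            reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-cluster survival-fraction z-scores against a reshuffling null.

    The null reshuffles whole patient records across clusters while
    keeping cluster sizes fixed (``reps`` permutations).  For each cluster
    z = (observed fraction - null mean) / null sd; clusters whose null sd
    is zero get NaN and a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    clusters = np.asarray(list(clusters))
    if clusters.size != len(clinical):
        raise ValueError("cluster assignment length does not match table")
    rng = np.random.default_rng(seed)
    survived = (clinical["duration_days"].to_numpy(dtype=float)
                >= horizon_days).astype(float)

    ids = np.unique(clusters)
    observed = np.array([survived[clusters == c].mean() for c in ids])
    sizes = np.array([(clusters == c).sum() for c in ids])

    # indicator matrix: cluster x sample membership (sizes stay fixed under
    # the reshuffle; evaluating each cluster at its own positions keeps the
    # null exactly invariant under cluster relabeling)
    members = np.stack([(clusters == c) for c in ids]).astype(float)
    null = np.empty((reps, ids.size))
    for r in range(reps):
        shuffled = rng.permutation(survived)
        null[r] = members @ shuffled / sizes
    mean, sd = null.mean(axis=0), null.std(axis=0)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn("zero null standard deviation for some clusters; z undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(zero_sd, np.nan, (observed - mean) / sd)
    return pd.DataFrame({"cluster": ids, "n": sizes, "survival_fraction": observed,
                         "null_mean": mean, "null_sd": sd, "z": z})
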