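"""Brain-behaviour linkage: HbO-HbR responses vs estimation ability.

The central model regresses the per participant x ROI x condition
HbO-HbR difference on the three-way interaction of condition, ROI and
the participant's mean estimation error (per condition), with
recognition rate and mean enjoyment as covariates and a participant
random intercept:

    HbDiff ~ 1 + condition * ROI * error + recognition_rate
               + mean_enjoyment + (1 | participant).

Reported quantities are the per-ROI error slopes for each condition,
their condition-aggregated means, and the performed-minus-unknown slope
contrasts, each summarised by the posterior mean and 95% HPD interval.
A moderation variant adds body competence, evaluating the error slope
at 1 SD below the mean, the mean, and 1 SD above.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import HierarchicalGaussianRegression
from .behaviour import summarize_draws, zscore
from .fnirs import ROIS

__all__ = [
    "BrainBehaviourModel",
    "BodyCompetenceModerationModel",
    "fit_brain_model",
    "body_competence_moderation",
    "build_brain_records",
]

CONDITIONS = ("performed", "unknown")


def _validate_records(records: pd.DataFrame, required: set[str]) -> pd.DataFrame:
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    cells = records.groupby("participant_id")[["roi", "condition"]].apply(
        lambda g: set(map(tuple, g.to_numpy()))
    )
    full = {(r, c) for r in ROIS for c in CONDITIONS}
    problems = {pid: sorted(full - cell) for pid, cell in cells.items() if cell != full}
    if problems:
        pid, miss = next(iter(problems.items()))
        raise ValueError(
            f"incomplete ROI x condition crossing for {len(problems)} participant(s); "
            f"e.g. {pid} is missing cells {miss[:4]}"
        )
    return records.copy()


def _brain_design(records: pd.DataFrame, extra_cols: dict[str, np.ndarray] | None = None, zscore_predictors: bool = True):
    cond_u = (records["condition"] == "unknown").to_numpy(dtype=float)
    err = records["mean_estimation_error"].to_numpy(dtype=float)
    recog = records["recognition_rate"].to_numpy(dtype=float)
    enjoy = records["mean_enjoyment"].to_numpy(dtype=float)
    if zscore_predictors:
        err = zscore(err)
        recog = zscore(recog)
        enjoy = zscore(enjoy)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(records)), "cond_unknown": cond_u}
    roi = records["roi"].astype(str)
    for r in ROIS[1:]:  # ROIS[0] is the reference level
        d = (roi == r).to_numpy(dtype=float)
        cols[f"roi_{r}"] = d
    cols["error"] = err
    cols["error:cond_unknown"] = err * cond_u
    for r in ROIS[1:]:
        d = (roi == r).to_numpy(dtype=float)
        cols[f"error:roi_{r}"] = err * d
        cols[f"error:cond_unknown:roi_{r}"] = err * cond_u * d
    cols["recognition_rate"] = recog
    cols["mean_enjoyment"] = enjoy
    if extra_cols:
        cols.update(extra_cols)
    return pd.DataFrame(cols)


def _roi_slope_weights(roi: str, condition: str) -> dict[str, float]:
    """Weight vector giving the error slope in one ROI x condition cell."""
    w = {"error": 1.0}
    if condition == "unknown":
        w["error:cond_unknown"] = 1.0
    if roi != ROIS[0]:
        w[f"error:roi_{roi}"] = 1.0
        if condition == "unknown":
            w[f"error:cond_unknown:roi_{roi}"] = 1.0
    return w


class BrainBehaviourModel(HierarchicalGaussianRegression):
    """Hierarchical model of HbDiff on condition x ROI x estimation error.

    ``fit(records)`` expects one row per participant x ROI x condition
    with columns (participant_id, roi, condition, hbdiff,
    mean_estimation_error, recognition_rate, mean_enjoyment). Continuous
    predictors are z-scored across the records by default.

    Fitted attributes: ``summary_`` (all derived slope summaries),
    ``roi_table_`` (one row per ROI with the condition-aggregated slope
    and the performed-minus-unknown contrast, each with HPD and flags),
    ``slope_draws_`` (dict of per-cell posterior slope draws).
    """

    def __init__(self, zscore_predictors: bool = True, **kwargs):
        super().__init__(**kwargs)
        self.zscore_predictors = zscore_predictors

    def fit(self, records: pd.DataFrame):  # type: ignore[override]
        records = _validate_records(
            records,
            {
                "participant_id",
                "roi",
                "condition",
                "hbdiff",
                "mean_estimation_error",
                "recognition_rate",
                "mean_enjoyment",
            },
        )
        X = _brain_design(records, zscore_predictors=self.zscore_predictors)
        y = records["hbdiff"].to_numpy(dtype=float)
        super().fit(X, y, groups=records["participant_id"].to_numpy())

        slope_draws: dict[str, np.ndarray] = {}
        for r in ROIS:
            perf = self.linear_combination(_roi_slope_weights(r, "performed"))
            unk = self.linear_combination(_roi_slope_weights(r, "unknown"))
            slope_draws[f"slope[{r},performed]"] = perf
            slope_draws[f"slope[{r},unknown]"] = unk
            slope_draws[f"aggregated[{r}]"] = 0.5 * (perf + unk)
            slope_draws[f"contrast[{r}]"] = perf - unk
        self.slope_draws_ = slope_draws
        self.summary_ = summarize_draws(slope_draws)

        summ = self.summary_.set_index("parameter")
        rows = []
        for r in ROIS:
            agg = summ.loc[f"aggregated[{r}]"]
            con = summ.loc[f"contrast[{r}]"]
            rows.append(
                {
                    "roi": r,
                    "aggregated_estimate": agg["mean"],
                    "aggregated_hpd_low": agg["hpd_low"],
                    "aggregated_hpd_high": agg["hpd_high"],
                    "aggregated_substantial": agg["substantial"],
                    "aggregated_trend": agg["trend"],
                    "contrast_estimate": con["mean"],
                    "contrast_hpd_low": con["hpd_low"],
                    "contrast_hpd_high": con["hpd_high"],
                    "contrast_substantial": con["substantial"],
                    "contrast_trend": con["trend"],
                }
            )
        self.roi_table_ = pd.DataFrame(rows)
        return self


class BodyCompetenceModerationModel(HierarchicalGaussianRegression):
    """Brain model extended with a body-competence moderation term.

    Adds body_competence_z, error x body-competence and
    error x condition x body-competence terms, and reports the
    (ROI-averaged) error slope per condition evaluated at body
    competence 1 SD below the mean, at the mean, and 1 SD above, plus
    the pairwise differences between those conditional slopes.
    """

    def __init__(self, zscore_predictors: bool = True, **kwargs):
        super().__init__(**kwargs)
        self.zscore_predictors = zscore_predictors

    def fit(self, records: pd.DataFrame):  # type: ignore[override]
        records = _validate_records(
            records,
            {
                "participant_id",
                "roi",
                "condition",
                "hbdiff",
                "mean_estimation_error",
                "recognition_rate",
                "mean_enjoyment",
                "body_competence_z",
            },
        )
        bc = records["body_competence_z"].to_numpy(dtype=float)
        cond_u = (records["condition"] == "unknown").to_numpy(dtype=float)
        err = records["mean_estimation_error"].to_numpy(dtype=float)
        if self.zscore_predictors:
            err = zscore(err)
        extra = {
            "body_competence": bc,
            "error:body_competence": err * bc,
            "error:cond_unknown:body_competence": err * cond_u * bc,
        }
        X = _brain_design(records, extra_cols=extra, zscore_predictors=self.zscore_predictors)
        y = records["hbdiff"].to_numpy(dtype=float)
        super().fit(X, y, groups=records["participant_id"].to_numpy())

        # ROI-averaged error slope per condition as a function of bc level
        roi_avg = {"performed": {}, "unknown": {}}
        for cond in CONDITIONS:
            acc: dict[str, float] = {}
            for r in ROIS:
                for name, wt in _roi_slope_weights(r, cond).items():
                    acc[name] = acc.get(name, 0.0) + wt / len(ROIS)
            roi_avg[cond] = acc

        draws: dict[str, np.ndarray] = {}
        levels = {"minus1sd": -1.0, "mean": 0.0, "plus1sd": 1.0}
        for cond in CONDITIONS:
            base = self.linear_combination(roi_avg[cond])
            mod = self.linear_combination({"error:body_competence": 1.0})
            if cond == "unknown":
                mod = mod + self.linear_combination({"error:cond_unknown:body_competence": 1.0})
            for lab, zval in levels.items():
                draws[f"slope[{cond},{lab}]"] = base + zval * mod
        for cond in CONDITIONS:
            draws[f"slope_diff[{cond},plus1sd-minus1sd]"] = (
                draws[f"slope[{cond},plus1sd]"] - draws[f"slope[{cond},minus1sd]"]
            )
            draws[f"slope_diff[{cond},plus1sd-mean]"] = (
                draws[f"slope[{cond},plus1sd]"] - draws[f"slope[{cond},mean]"]
            )
            draws[f"slope_diff[{cond},mean-minus1sd]"] = (
                draws[f"slope[{cond},mean]"] - draws[f"slope[{cond},minus1sd]"]
            )
        self.conditional_slope_draws_ = draws
        self.summary_ = summarize_draws(draws)
        return self


def fit_brain_model(records: pd.DataFrame, **sampler_kwargs) -> pd.DataFrame:
    """Fit the brain-behaviour model; return the Table-shaped ROI summary."""
    return BrainBehaviourModel(**sampler_kwargs).fit(records).roi_table_


def body_competence_moderation(records: pd.DataFrame, **sampler_kwargs) -> pd.DataFrame:
    """Fit the moderation model; return the conditional-slope summary."""
    return BodyCompetenceModerationModel(**sampler_kwargs).fit(records).summary_


def build_brain_records(
    roi_estimates: pd.DataFrame,
    trials: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the model's records from pipeline outputs.

    ``roi_estimates`` needs (participant_id, roi, condition, hbdiff);
    ``trials`` the behavioural trial table; ``traits`` the raw trait
    scores (body competence is z-scored here). Recognition rate is the
    proportion of correct performed/unknown judgements per participant;
    estimation error and enjoyment are averaged per participant x
    condition (error) or participant (enjoyment).
    """
    from .behaviour import estimation_error

    t = trials.copy()
    t["error"] = estimation_error(t["measured_synchrony"], t["estimated_synchrony"])
    t["correct"] = np.where(
        t["condition"] == "performed", t["recognized"].astype(bool), ~t["recognized"].astype(bool)
    )
    err = t.groupby(["participant_id", "condition"], as_index=False)["error"].mean().rename(
        columns={"error": "mean_estimation_error"}
    )
    per_p = t.groupby("participant_id", as_index=False).agg(
        recognition_rate=("correct", "mean"), mean_enjoyment=("enjoyment", "mean")
    )
    bc = traits[["participant_id"]].copy()
    bc["body_competence_z"] = zscore(traits["body_competence"])
    records = (
        roi_estimates.merge(err, on=["participant_id", "condition"], validate="many_to_one")
        .merge(per_p, on="participant_id", validate="many_to_one")
        .merge(bc, on="participant_id", validate="many_to_one")
    )
    return records
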