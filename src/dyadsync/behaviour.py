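"""Estimation-error computation and the behavioural hierarchical models.

Estimation error D = 100*S - E compares the objectively measured
synchrony S (0-1) of a video, rescaled to the 0-100 slider range, with
an observer's estimate E; positive D means the observer underestimated
synchrony. Two Bayesian multilevel models link D to its correlates:

* the trait model regresses D on condition (performed vs unknown) and
  six z-scored personality/body traits with trait-by-condition
  interactions and a participant random intercept;
* the rating model regresses D on enjoyment, per-video movement
  complexity (each crossed with condition) and sequence recognition.

Posteriors are summarised as means with 95% highest-posterior-density
intervals; an effect is "substantial" when the HPD excludes zero and a
"trend" when less than 10% of posterior mass lies on the minority side
of zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import HierarchicalGaussianRegression

__all__ = [
    "TRAITS",
    "estimation_error",
    "zscore",
    "hpd_interval",
    "summarize_draws",
    "TraitEffectsModel",
    "RatingEffectsModel",
    "fit_trait_model",
    "fit_rating_model",
]

#: The six interindividual trait scales, in canonical order.
TRAITS: tuple[str, ...] = (
    "extraversion",
    "self_esteem",
    "body_perception",
    "body_competence",
    "empathy",
    "autistic_traits",
)

CONDITIONS: tuple[str, str] = ("performed", "unknown")


def estimation_error(measured, estimated):
    """D = 100*S - E: positive values are underestimation.

    ``measured`` is the objective synchrony on [0, 1]; ``estimated`` the
    observer's 0-100 rating. Accepts scalars or arrays.
    """
    s = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("measured synchrony must lie in [0, 1]")
    if np.any((e < 0) | (e > 100)):
        raise ValueError("estimated synchrony must lie in [0, 100]")
    d = 100.0 * s - e
    return float(d) if d.ndim == 0 else d


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, SD 1 (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples.

    Computed by scanning all windows of ceil(mass*n) consecutive order
    statistics and keeping the narrowest.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HPD interval, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize_draws(draws: dict[str, np.ndarray], mass: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: mean, HPD bounds, substantial/trend flags."""
    rows = []
    for name, d in draws.items():
        d = np.asarray(d, float).ravel()
        lo, hi = hpd_interval(d, mass)
        substantial = bool(lo > 0 or hi < 0)
        minority = min(float(np.mean(d < 0)), float(np.mean(d > 0)))
        rows.append(
            {
                "parameter": name,
                "mean": float(d.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
                "substantial": substantial,
                "trend": (not substantial) and minority < 0.10,
            }
        )
    return pd.DataFrame(rows)


def _condition_dummy(condition: pd.Series) -> np.ndarray:
    cond = condition.astype(str)
    unknown = set(cond) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    return (cond == "unknown").to_numpy(dtype=float)


class TraitEffectsModel(HierarchicalGaussianRegression):
    """Hierarchical model of estimation error vs condition and traits.

    D ~ 1 + condition + sum_k trait_k * condition + (1 | participant),
    traits z-scored at participant level across the analysed sample.

    After ``fit(trials, traits)`` the attribute ``summary_`` holds the
    posterior table with derived rows: per-condition mean error
    (intercept_performed / intercept_unknown), their contrast
    (performed - unknown), and per trait the condition-averaged slope
    plus the between-condition slope difference.
    """

    def fit(self, trials: pd.DataFrame, traits: pd.DataFrame):  # type: ignore[override]
        trials = trials.copy()
        required = {"participant_id", "measured_synchrony", "estimated_synchrony", "condition"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trials table is missing columns: {sorted(missing)}")
        missing_t = ({"participant_id", *TRAITS}) - set(traits.columns)
        if missing_t:
            raise ValueError(f"traits table is missing columns: {sorted(missing_t)}")
        unmatched = set(trials["participant_id"]) - set(traits["participant_id"])
        if unmatched:
            raise ValueError(f"participants without traits: {sorted(unmatched)[:5]}")
        if traits["participant_id"].nunique() < 2:
            raise ValueError("need at least 2 participants")

        tz = traits[["participant_id"]].copy()
        for t in TRAITS:
            tz[f"z_{t}"] = zscore(traits[t])
        df = trials.merge(tz, on="participant_id", validate="many_to_one")

        d = estimation_error(df["measured_synchrony"], df["estimated_synchrony"])
        cond_u = _condition_dummy(df["condition"])
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df)), "cond_unknown": cond_u}
        for t in TRAITS:
            cols[t] = df[f"z_{t}"].to_numpy()
            cols[f"{t}:cond_unknown"] = cols[t] * cond_u
        X = pd.DataFrame(cols)
        super().fit(X, d, groups=df["participant_id"].to_numpy())

        derived: dict[str, np.ndarray] = {}
        derived["intercept_performed"] = self.linear_combination({"Intercept": 1.0})
        derived["intercept_unknown"] = self.linear_combination({"Intercept": 1.0, "cond_unknown": 1.0})
        derived["condition_contrast"] = derived["intercept_performed"] - derived["intercept_unknown"]
        for t in TRAITS:
            perf = self.linear_combination({t: 1.0})
            unk = self.linear_combination({t: 1.0, f"{t}:cond_unknown": 1.0})
            derived[t] = 0.5 * (perf + unk)
            derived[f"{t}:condition_contrast"] = perf - unk
        self.derived_draws_ = derived
        self.summary_ = summarize_draws(derived)
        return self


class RatingEffectsModel(HierarchicalGaussianRegression):
    """Hierarchical model of estimation error vs enjoyment, complexity, recognition.

    D ~ 1 + enjoyment*condition + complexity*condition + recognized
      + (1 | participant).

    ``trials`` must carry a per-video ``complexity`` column (merged from
    the kinematic metrics). Enjoyment and complexity enter in raw units
    by default; set ``zscore_kinematics=True`` to standardise complexity.
    """

    def __init__(self, zscore_kinematics: bool = False, **kwargs):
        super().__init__(**kwargs)
        self.zscore_kinematics = zscore_kinematics

    def fit(self, trials: pd.DataFrame):  # type: ignore[override]
        required = {
            "participant_id",
            "measured_synchrony",
            "estimated_synchrony",
            "condition",
            "enjoyment",
            "complexity",
            "recognized",
        }
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trials table is missing columns: {sorted(missing)}")
        df = trials.copy()
        d = estimation_error(df["measured_synchrony"], df["estimated_synchrony"])
        cond_u = _condition_dummy(df["condition"])
        enjoy = df["enjoyment"].to_numpy(dtype=float)
        comp = df["complexity"].to_numpy(dtype=float)
        if self.zscore_kinematics:
            comp = zscore(comp)
        recog = df["recognized"].to_numpy(dtype=float)
        X = pd.DataFrame(
            {
                "Intercept": np.ones(len(df)),
                "cond_unknown": cond_u,
                "enjoyment": enjoy,
                "enjoyment:cond_unknown": enjoy * cond_u,
                "complexity": comp,
                "complexity:cond_unknown": comp * cond_u,
                "recognized": recog,
            }
        )
        super().fit(X, d, groups=df["participant_id"].to_numpy())

        derived: dict[str, np.ndarray] = {}
        for name in ("enjoyment", "complexity"):
            perf = self.linear_combination({name: 1.0})
            unk = self.linear_combination({name: 1.0, f"{name}:cond_unknown": 1.0})
            derived[name] = 0.5 * (perf + unk)
            derived[f"{name}:condition_contrast"] = perf - unk
        derived["recognized"] = self.linear_combination({"recognized": 1.0})
        self.derived_draws_ = derived
        self.summary_ = summarize_draws(derived)
        return self


def fit_trait_model(trials: pd.DataFrame, traits: pd.DataFrame, **sampler_kwargs) -> pd.DataFrame:
    """Fit the trait model and return its posterior summary table."""
    return TraitEffectsModel(**sampler_kwargs).fit(trials, traits).summary_


def fit_rating_model(trials: pd.DataFrame, **sampler_kwargs) -> pd.DataFrame:
    """Fit the enjoyment/complexity/recognition model; return the summary table."""
    return RatingEffectsModel(**sampler_kwargs).fit(trials).summary_
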