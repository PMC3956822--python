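"""Exhaustive AICc model selection and multimodel averaging.

Every subset of the candidate predictors is fitted as a PGLS model of the
response (the intercept-only model included), with one structural
constraint: whole-brain size is never combined with any individual brain
component, because the former is the sum of the latter.  Models are ranked
by AICc; each model i gets an Akaike weight

    w_i = exp(−Δ_i / 2) / Σ_m exp(−Δ_m / 2),    Δ_i = AICc_i − min AICc,

interpretable as the relative probability that model i is the best
approximating model.  Per-predictor quantities follow: the predictor weight
w(+j) (summed weight of models containing j) and the model-averaged
coefficient with an unconditional standard error that carries both
within-model sampling variance and between-model spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pgls import PGLS, PGLSResults
from .trees import PhyloCovariance

__all__ = [
    "ModelRecord", "enumerate_candidates", "fit_candidates",
    "rank_and_weight", "credibility_set", "model_average",
    "records_to_frame",
]

#: canonical short names for the study's predictor roster
DEFAULT_COMPONENTS = ("brain_stem_res", "cerebellum_res",
                      "optic_lobe_res", "forebrain_res")
DEFAULT_OTHERS = ("start_dist", "body_mass", "eye_res")
DEFAULT_WHOLE_BRAIN = "whole_brain_res"


@dataclass
class ModelRecord:
    """One candidate model with its information-theoretic scores."""

    predictors: tuple[str, ...]
    fit: PGLSResults = field(repr=False)
    aicc: float = None
    delta_aicc: float = None
    weight: float = None

    def __post_init__(self):
        if self.aicc is None:
            self.aicc = self.fit.aicc


def enumerate_candidates(components=DEFAULT_COMPONENTS, others=DEFAULT_OTHERS,
                         whole_brain=DEFAULT_WHOLE_BRAIN):
    """All admissible predictor subsets, in a deterministic order.

    Returns every subset of ``components ∪ others`` (including the empty,
    intercept-only set) plus every subset of ``others`` augmented with
    ``whole_brain`` — whole brain never co-occurs with a component.  With
    the full roster (4 components, 3 others) that is 2^7 + 2^3 = 136 sets.
    Ordered by size, then lexicographically; pass ``whole_brain=None`` to
    drop the constrained sets entirely.
    """
    free = tuple(components) + tuple(others)
    if len(set(free)) != len(free):
        raise ValueError("predictor labels must be unique")
    sets = []
    for r in range(len(free) + 1):
        sets.extend(tuple(sorted(c)) for c in combinations(free, r))
    if whole_brain is not None:
        for r in range(len(others) + 1):
            sets.extend(tuple(sorted(c + (whole_brain,)))
                        for c in combinations(tuple(others), r))
    sets.sort(key=lambda s: (len(s), s))
    return sets


def fit_candidates(data: pd.DataFrame, response: str, candidate_sets,
                   cov: PhyloCovariance, lambda_mode: str = "ml",
                   lambda_value: float | None = None):
    """Fit every candidate predictor set and return ranked ModelRecords.

    λ is re-estimated independently for every candidate model when
    ``lambda_mode="ml"`` (each model's residual errors have their own
    signal); ``"fixed1"`` reruns the whole selection under strict Brownian
    motion.  Rows with a missing value in the response or any candidate
    predictor are dropped up front so all models share the same n.
    """
    used = sorted({response} | {p for s in candidate_sets for p in s})
    complete = data[used].dropna()
    cov_aligned = cov.align(list(complete.index))
    records = []
    for preds in candidate_sets:
        model = PGLS.from_dataframe(complete, response, list(preds),
                                    cov_aligned)
        fit = model.fit(lambda_mode=lambda_mode, lambda_value=lambda_value)
        records.append(ModelRecord(predictors=tuple(preds), fit=fit))
    return rank_and_weight(records)


def rank_and_weight(records):
    """Sort by AICc (ties: fewer predictors, then lexicographic) and attach
    ΔAICc and Akaike weights, which sum to one over the candidate set."""
    records = sorted(records,
                     key=lambda r: (r.aicc, len(r.predictors), r.predictors))
    best = records[0].aicc
    rel = np.array([np.exp(-0.5 * (r.aicc - best)) for r in records])
    weights = rel / rel.sum()
    for r, w in zip(records, weights):
        r.delta_aicc = r.aicc - best
        r.weight = float(w)
    return records


def credibility_set(records, threshold: float = 2.0):
    """Models with ΔAICc below ``threshold`` (the conventional cutoff is 2)."""
    return [r for r in records if r.delta_aicc < threshold]


def best_whole_brain_model(records, whole_brain=DEFAULT_WHOLE_BRAIN):
    """Best-ranked model containing the whole-brain predictor, reported
    alongside the credibility set for the component-vs-whole comparison."""
    for r in records:
        if whole_brain in r.predictors:
            return r
    return None


def model_average(records, conditional: bool = True,
                  ci_multiplier: float = 1.959963984540054) -> pd.DataFrame:
    """Per-predictor weights, model-averaged coefficients and 95% CIs.

    For predictor j with containing-model weights w_m and estimates β_m:

    * ``w(+j)`` = Σ w_m over models containing j;
    * conditional average β̄_j = Σ w_m β_m / Σ w_m (default), or the
      full-model average with β_m = 0 substituted in non-containing models
      when ``conditional=False``;
    * unconditional SE = Σ w̃_m sqrt(se_m² + (β_m − β̄_j)²) over the same
      model set (w̃ renormalized for the conditional variant), which folds
      model-selection uncertainty into the interval;
    * CI = β̄_j ± ``ci_multiplier``·SE (1.96 ⇒ normal 95%).

    Returns a DataFrame indexed by predictor with columns
    ``weight, coef, se, ci_low, ci_high``.
    """
    predictors = sorted({p for r in records for p in r.predictors})
    total_w = sum(r.weight for r in records)
    if not np.isclose(total_w, 1.0, atol=1e-9):
        raise ValueError("Akaike weights must be normalized before averaging")
    rows = {}
    for j in predictors:
        containing = [r for r in records if j in r.predictors]
        wj = sum(r.weight for r in containing)
        betas = np.array([r.fit.params[j] for r in containing])
        ses = np.array([r.fit.bse[j] for r in containing])
        w = np.array([r.weight for r in containing])
        if conditional:
            wn = w / wj
            coef = float(wn @ betas)
            se = float(wn @ np.sqrt(ses**2 + (betas - coef) ** 2))
        else:
            coef = float(w @ betas)  # absent models contribute beta = 0
            se_terms = w * np.sqrt(ses**2 + (betas - coef) ** 2)
            # absent models: beta fixed at 0 with no sampling variance
            se = float(se_terms.sum() + (1.0 - wj) * abs(coef))
        rows[j] = {
            "weight": wj, "coef": coef, "se": se,
            "ci_low": coef - ci_multiplier * se,
            "ci_high": coef + ci_multiplier * se,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["weight", "coef", "se", "ci_low", "ci_high"]]


def records_to_frame(records) -> pd.DataFrame:
    """Ranked model table (one row per candidate) for reporting: model
    formula, ΔAICc, weight, λ and whitened-space R²."""
    rows = []
    for r in records:
        rows.append({
            "model": " + ".join(r.predictors) if r.predictors else "(intercept)",
            "n_predictors": len(r.predictors),
            "aicc": r.aicc,
            "delta_aicc": r.delta_aicc,
            "weight": r.weight,
            "lambda": r.fit.lambda_,
            "r_squared_pct": 100.0 * r.fit.rsquared,
            "loglik": r.fit.llf,
        })
    return pd.DataFrame(rows)
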