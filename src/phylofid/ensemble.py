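"""Multi-phylogeny analysis: repeat the full pipeline per tree, then pool.

Phylogenetic inference is itself uncertain, so the whole analysis — size
residuals, exhaustive AICc selection, model averaging — is repeated
independently for each supplied phylogeny (residual columns depend on the
tree, so they are recomputed every time, and each candidate model gets its
own λ).  Per-predictor weights, averaged coefficients and CI bounds are then
pooled by a plain arithmetic mean across phylogenies to give one overall
estimate of each predictor's importance and effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import selection
from .pgls import estimate_lambda
from .selection import (DEFAULT_COMPONENTS, DEFAULT_OTHERS,
                        DEFAULT_WHOLE_BRAIN)
from .traits import prepare_table
from .trees import Phylogeny, TaxonMatchError, match_taxa

__all__ = ["EnsembleSummary", "run_ensemble", "signal_report"]

#: traits whose phylogenetic signal is reported (residual organ sizes are
#: computed per tree before λ is estimated)
SIGNAL_TRAITS = ("fid", "start_dist", "body_mass", "whole_brain_res",
                 "brain_stem_res", "optic_lobe_res", "cerebellum_res",
                 "forebrain_res", "eye_res")


@dataclass
class EnsembleSummary:
    """Per-phylogeny and pooled multimodel inferences."""

    phylogeny_ids: list[str]
    mode: str
    per_tree: dict[str, pd.DataFrame]          # averaged inference per tree
    model_tables: dict[str, pd.DataFrame] = field(repr=False, default=None)
    allometry: dict[str, dict] = field(repr=False, default=None)
    pooled: pd.DataFrame = None

    def __post_init__(self):
        if self.pooled is None:
            self.pooled = pool_inferences(self.per_tree)


def pool_inferences(per_tree: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of weights, coefficients and CI bounds across trees.

    CI bounds are averaged directly, matching how a single pooled interval
    is conventionally reported, rather than re-derived from pooled
    variances."""
    frames = list(per_tree.values())
    idx = frames[0].index
    cols = ["weight", "coef", "se", "ci_low", "ci_high"]
    stacked = np.stack([f.loc[idx, cols].to_numpy(float) for f in frames])
    return pd.DataFrame(stacked.mean(axis=0), index=idx, columns=cols)


def _check_coverage(raw: pd.DataFrame, trees, species_col: str = "species"):
    species = (raw[species_col] if species_col in raw.columns
               else raw.index).astype(str)
    problems = []
    for i, tree in enumerate(trees):
        tid = tree.label or f"tree{i + 1}"
        try:
            match_taxa(tree.tips, species)
        except TaxonMatchError as exc:
            problems.append(f"[{tid}] {exc.args[0]}")
    if problems:
        raise TaxonMatchError("; ".join(problems))


def run_ensemble(raw: pd.DataFrame, trees, mode: str = "ml",
                 conditional: bool = True, ci_multiplier: float = 1.96,
                 components=DEFAULT_COMPONENTS, others=DEFAULT_OTHERS,
                 whole_brain=DEFAULT_WHOLE_BRAIN,
                 species_col: str = "species") -> EnsembleSummary:
    """Run the full analysis on each phylogeny and pool the inferences.

    ``mode="ml"`` estimates λ per candidate model; ``mode="fixed1"``
    constrains λ=1 everywhere (the independent-contrasts analysis).  Every
    tree must cover every species in the table — missing species are
    reported per tree, never pruned silently.
    """
    if mode not in ("ml", "fixed1"):
        raise ValueError(f"mode must be 'ml' or 'fixed1', got {mode!r}")
    _check_coverage(raw, trees, species_col=species_col)
    species = (raw[species_col] if species_col in raw.columns
               else raw.index).astype(str)
    candidate_sets = selection.enumerate_candidates(
        components=components, others=others, whole_brain=whole_brain)
    per_tree, model_tables, allometry = {}, {}, {}
    for i, tree in enumerate(trees):
        tid = tree.label or f"tree{i + 1}"
        cov = tree.pruned_to(species).vcv()
        analysis, meta = prepare_table(raw, cov, species_col=species_col)
        records = selection.fit_candidates(
            analysis, "fid", candidate_sets, cov.align(analysis.index),
            lambda_mode=mode if mode == "ml" else "fixed1")
        per_tree[tid] = selection.model_average(
            records, conditional=conditional, ci_multiplier=ci_multiplier)
        model_tables[tid] = selection.records_to_frame(records)
        allometry[tid] = meta["allometry"]
    return EnsembleSummary(phylogeny_ids=list(per_tree), mode=mode,
                           per_tree=per_tree, model_tables=model_tables,
                           allometry=allometry)


def signal_report(raw: pd.DataFrame, trees,
                  species_col: str = "species") -> pd.DataFrame:
    """Per-trait phylogenetic signal (λ̂ and boundary tests) per phylogeny.

    Residual organ sizes are recomputed for each tree before λ is
    estimated, since they depend on the tree.  Returns a tidy frame with
    one row per trait × phylogeny: ``lambda``, ``p_vs_0`` (against no
    signal), ``p_vs_1`` (against Brownian motion) and a
    ``significant_vs_0`` flag at α=0.05.
    """
    _check_coverage(raw, trees, species_col=species_col)
    species = (raw[species_col] if species_col in raw.columns
               else raw.index).astype(str)
    rows = []
    for i, tree in enumerate(trees):
        tid = tree.label or f"tree{i + 1}"
        cov = tree.pruned_to(species).vcv()
        analysis, _ = prepare_table(raw, cov, species_col=species_col)
        cov_aligned = cov.align(analysis.index)
        for trait in SIGNAL_TRAITS:
            if trait not in analysis.columns:
                continue
            vals = analysis[trait].dropna()
            est = estimate_lambda(vals.to_numpy(), cov_aligned.align(vals.index))
            rows.append({
                "trait": trait, "phylogeny": tid,
                "lambda": est.lambda_hat,
                "p_vs_0": est.p_vs_0, "p_vs_1": est.p_vs_1,
                "significant_vs_0": est.significant_vs_0(),
            })
    return pd.DataFrame(rows)
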