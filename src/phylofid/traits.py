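"""Trait-table preparation: component masses, log10 transform, size residuals.

The raw table carries, per species: flight-initiation distance (m), starting
distance (m), species-mean body mass (g), specimen body mass (g, the
individuals whose brains were measured), eye volume, and Portmann's
intra-cerebral indices for the four classic brain regions together with the
"chiffre basal" (the predicted brain-stem mass, in grams, of a galliform
bird of equal body mass).  Absolute component masses are index × chiffre
basal; whole brain mass is the sum of the four components.

All analysis variables are log10-transformed.  Because brain and eye size
scale strongly with body mass, organ sizes enter the regression models only
as *residual* sizes: observed log size minus the value predicted by a PGLS
regression (λ by ML) of log size on log specimen body mass.  Residuals are
returned on the observation scale, since they are used downstream as
ordinary predictor columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pgls import PGLS, PGLSResults
from .trees import PhyloCovariance

__all__ = [
    "COMPONENTS", "ORGAN_COLUMNS", "RESIDUAL_PREDICTORS",
    "component_mass", "add_component_masses", "log10_columns",
    "phylo_residual", "prepare_table",
]

#: the four classic brain regions
COMPONENTS = ("brain_stem", "optic_lobe", "cerebellum", "forebrain")

#: organs that get a body-size residual column (log-log PGLS on specimen mass)
ORGAN_COLUMNS = COMPONENTS + ("whole_brain", "eye")

#: raw-table columns log10-transformed for analysis
LOG_COLUMNS = (
    "fid_m", "start_dist_m", "body_mass_g", "specimen_mass_g", "eye_volume",
    "brain_stem_g", "optic_lobe_g", "cerebellum_g", "forebrain_g",
    "whole_brain_g",
)

#: analysis-table predictor columns produced by :func:`prepare_table`
RESIDUAL_PREDICTORS = tuple(f"{o}_res" for o in ORGAN_COLUMNS)


def component_mass(index, chiffre_basal):
    """Absolute brain-component mass (g) = intra-cerebral index × chiffre basal.

    Portmann's indices express each region's mass relative to the chiffre
    basal, so the product recovers grams.  Inputs must be positive.
    """
    index = np.asarray(index, dtype=float)
    cb = np.asarray(chiffre_basal, dtype=float)
    if np.any(index <= 0) or np.any(cb <= 0):
        raise ValueError("index and chiffre basal must be strictly positive")
    return index * cb


def add_component_masses(table: pd.DataFrame) -> pd.DataFrame:
    """Add absolute component masses and whole-brain mass to a raw table.

    Expects columns ``index_<region>`` for each region in
    :data:`COMPONENTS` plus ``chiffre_basal_g``; adds ``<region>_g`` and
    ``whole_brain_g`` (the sum of the four regions).
    """
    out = table.copy()
    for region in COMPONENTS:
        out[f"{region}_g"] = component_mass(
            out[f"index_{region}"], out["chiffre_basal_g"])
    out["whole_brain_g"] = sum(out[f"{r}_g"] for r in COMPONENTS)
    return out


def log10_columns(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Return a copy with the analysis columns replaced by their log10.

    Non-positive values are an error naming the offending species and
    column — they signal a data problem, never something to coerce.
    """
    columns = [c for c in (columns or LOG_COLUMNS) if c in table.columns]
    out = table.copy()
    for col in columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals[vals.notna() & (vals <= 0)]
        if len(bad):
            sp = bad.index[0]
            raise ValueError(
                f"cannot log10-transform {col!r}: non-positive value "
                f"{bad.iloc[0]!r} for species {sp!r}")
        out[col] = np.log10(vals)
    return out


def phylo_residual(table: pd.DataFrame, organ_col: str, mass_col: str,
                   cov: PhyloCovariance) -> tuple[pd.Series, PGLSResults]:
    """Body-size-corrected organ size: observation-scale residuals of the
    PGLS regression (λ by ML) of ``organ_col`` on ``mass_col``.

    Both columns must already be on log10 scale.  Species with a missing
    value in either column are excluded from the fit and get NaN residuals.
    Returns the residual series (aligned to ``table``) and the underlying
    fit, whose ``lambda_`` is the allometric λ worth recording.
    """
    sub = table[[organ_col, mass_col]].dropna()
    model = PGLS.from_dataframe(sub, organ_col, [mass_col],
                                cov.align(sub.index))
    fit = model.fit(lambda_mode="ml")
    resid = pd.Series(np.nan, index=table.index, dtype=float)
    resid.loc[sub.index] = fit.resid.to_numpy()
    return resid, fit


def prepare_table(raw: pd.DataFrame, cov: PhyloCovariance,
                  species_col: str = "species"):
    """Build the analysis table for one phylogeny.

    Steps: component masses from Portmann indices (if not already present),
    log10 transform, then a residual-size column per organ from its own
    independent PGLS regression on log specimen body mass.

    Returns ``(analysis, meta)`` where ``analysis`` is species-indexed with
    columns ``fid``, ``start_dist``, ``body_mass`` and
    ``<organ>_res`` for each organ, and ``meta`` records the λ and slope of
    every allometric regression plus any species excluded from organ fits.
    """
    table = raw.copy()
    if species_col in table.columns:
        table = table.set_index(species_col)
    table.index = table.index.astype(str)
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate species rows: {dupes}")
    if "whole_brain_g" not in table.columns:
        table = add_component_masses(table)
    logged = log10_columns(table)

    analysis = pd.DataFrame(index=logged.index)
    analysis["fid"] = logged["fid_m"]
    analysis["start_dist"] = logged["start_dist_m"]
    analysis["body_mass"] = logged["body_mass_g"]

    organ_source = {f"{r}": f"{r}_g" for r in COMPONENTS}
    organ_source["whole_brain"] = "whole_brain_g"
    organ_source["eye"] = "eye_volume"

    meta = {"allometry": {}, "excluded": {}}
    for organ, col in organ_source.items():
        resid, fit = phylo_residual(logged, col, "specimen_mass_g", cov)
        analysis[f"{organ}_res"] = resid
        meta["allometry"][organ] = {
            "lambda": fit.lambda_,
            "slope": float(fit.params.iloc[1]),
            "intercept": float(fit.params.iloc[0]),
            "n": fit.nobs,
        }
        dropped = sorted(analysis.index[resid.isna()])
        if dropped:
            meta["excluded"][organ] = dropped
    return analysis, meta
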