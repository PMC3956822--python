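"""Synthetic trees and trait tables with the structure the analysis assumes.

The generator emulates the study conditions end to end: a pure-birth (Yule)
ultrametric phylogeny of ~41 species; log10-scale traits evolving with
phylogenetic signal λ (a trait with signal λ and rate σ² is a single draw
from N(mean, σ²·V(λ)) with V(λ) the λ-transformed tree covariance — exact
by construction, no edge-wise Brownian increments needed); brain-component
and eye sizes tied to body mass by strong allometry (log-log slope ≈ 0.57,
small λ-structured deviations, so organ-mass correlations exceed 0.8); and
a response (flight-initiation distance) generated as a linear function of
two strong predictors (starting distance, body mass) plus a weak negative
cerebellum effect and Gaussian noise with λ-structured covariance.

Everything is reproducible: identical seed + config → identical dataset.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .trees import Phylogeny, PhyloCovariance

__all__ = ["Allometry", "ResponseModel", "SimConfig", "simulate_tree",
           "simulate_trait", "simulate_traits", "paper_shaped_fixture"]


@dataclass(frozen=True)
class Allometry:
    """Log-log scaling of an organ on body mass: log10(size) =
    intercept + slope·log10(mass) + deviation, with the deviation a
    zero-mean λ-structured Gaussian of marginal SD ``noise_sd``."""

    slope: float
    intercept: float
    noise_sd: float = 0.07
    noise_lambda: float = 0.9


@dataclass(frozen=True)
class ResponseModel:
    """Linear model generating log10 flight-initiation distance.

    Strong positive effects of log starting distance and log body mass,
    weak (here negative-cerebellum) effects of relative component sizes,
    plus residual noise with phylogenetic signal ``noise_lambda`` (default
    0: the residual-error structure the study design anticipates)."""

    intercept: float = -0.35
    beta_start_dist: float = 0.6
    beta_body_mass: float = 0.25
    beta_components: dict = field(
        default_factory=lambda: {"cerebellum": -0.3})
    noise_sd: float = 0.10
    noise_lambda: float = 0.0


def _default_allometries() -> dict:
    # intercepts put organ masses in realistic gram/mm^3 ranges for a
    # 100 g bird (brain stem ~0.4 g, forebrain ~2 g, eye ~1 cm^3)
    return {
        "brain_stem": Allometry(0.57, -1.44),
        "optic_lobe": Allometry(0.57, -1.74),
        "cerebellum": Allometry(0.57, -1.49),
        "forebrain": Allometry(0.60, -0.72),
        "eye": Allometry(0.60, 1.80, noise_sd=0.05, noise_lambda=1.0),
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the generator (log10 scale throughout).

    Defaults reproduce the shape of the real dataset: 41 species, body mass
    a Brownian (λ=1) trait spanning roughly two orders of magnitude around
    100 g, starting distance ~25 m with moderate signal, strong allometry,
    and a response driven by starting distance and body mass.
    """

    n_tips: int = 41
    birth_rate: float = 1.0
    # starting distance (log10 m): mean 1.4 ≈ 25 m
    start_dist_mean: float = 1.4
    start_dist_lambda: float = 0.8
    start_dist_rate: float = 0.02
    # body mass (log10 g): mean 2.0 = 100 g
    body_mass_mean: float = 2.0
    body_mass_lambda: float = 1.0
    body_mass_rate: float = 0.1
    #: SD of log10 specimen-vs-species mass discrepancy
    specimen_noise_sd: float = 0.02
    allometry: dict = field(default_factory=_default_allometries)
    response: ResponseModel = field(default_factory=ResponseModel)
    #: Galliform brain-stem allometry defining the chiffre basal
    chiffre_basal_slope: float = 0.52
    chiffre_basal_intercept: float = -1.45


def simulate_tree(n_tips: int = 41, birth_rate: float = 1.0,
                  seed: int | None = None, rng=None) -> Phylogeny:
    """Yule (pure-birth) ultrametric tree with ``n_tips`` extant tips."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if rng is None:
        rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        rng=rng)
    tree.is_rooted = True
    # growth stops exactly at the n-th speciation, leaving a zero-length
    # cherry; run the clock forward to just before the (n+1)-th event
    extra = rng.expovariate(n_tips * birth_rate)
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon.label = f"sp{i:03d}"
    return Phylogeny(tree, label="yule")


def simulate_trait(cov: PhyloCovariance, lambda_true: float, rate: float,
                   mean: float, rng: np.random.Generator) -> np.ndarray:
    """One trait draw: N(mean, rate · V(λ)) over the covariance's taxa.

    ``rate`` is the Brownian variance per unit branch length; λ=0 makes
    tips independent, rate=0 a constant trait.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = cov.n
    if rate == 0:
        return np.full(n, mean)
    V = rate * cov.lambda_transform(lambda_true).matrix
    return mean + rng.multivariate_normal(np.zeros(n), V, method="svd")


def _phylo_noise(cov: PhyloCovariance, lam: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero-mean λ-structured noise with marginal SD ≈ ``sd`` (rate chosen
    from the mean tip depth)."""
    if sd == 0:
        return np.zeros(cov.n)
    depth = float(np.mean(np.diag(cov.matrix)))
    return simulate_trait(cov, lam, sd**2 / depth, 0.0, rng)


def simulate_traits(tree: Phylogeny, config: SimConfig,
                    rng: np.random.Generator):
    """Raw-scale trait table plus the latent log-scale quantities.

    Returns ``(table, latents)``: ``table`` has exactly the columns the
    pipeline reads (species, fid_m, start_dist_m, body_mass_g,
    specimen_mass_g, eye_volume, index_<region>, chiffre_basal_g);
    ``latents`` holds the log-scale traits and the allometric deviations
    (the "relative sizes" the response model actually uses).
    """
    cov = tree.vcv()
    species = cov.taxa
    n = cov.n
    depth = float(np.mean(np.diag(cov.matrix)))

    log_sd = simulate_trait(cov, config.start_dist_lambda,
                            config.start_dist_rate, config.start_dist_mean,
                            rng)
    log_mass = simulate_trait(cov, config.body_mass_lambda,
                              config.body_mass_rate, config.body_mass_mean,
                              rng)
    log_spec = log_mass + rng.normal(0.0, config.specimen_noise_sd, n)

    latents = pd.DataFrame({"log_start_dist": log_sd, "log_body_mass": log_mass,
                            "log_specimen_mass": log_spec}, index=species)
    log_organ = {}
    for organ, allo in config.allometry.items():
        dev = _phylo_noise(cov, allo.noise_lambda, allo.noise_sd, rng)
        log_organ[organ] = allo.intercept + allo.slope * log_spec + dev
        latents[f"log_{organ}"] = log_organ[organ]
        latents[f"dev_{organ}"] = dev

    resp = config.response
    log_fid = (resp.intercept
               + resp.beta_start_dist * log_sd
               + resp.beta_body_mass * log_mass)
    for organ, beta in resp.beta_components.items():
        log_fid = log_fid + beta * latents[f"dev_{organ}"].to_numpy()
    log_fid = log_fid + _phylo_noise(cov, resp.noise_lambda, resp.noise_sd,
                                     rng)
    latents["log_fid"] = log_fid

    cb = 10.0 ** (config.chiffre_basal_intercept
                  + config.chiffre_basal_slope * log_spec)
    table = pd.DataFrame({
        "species": species,
        "fid_m": 10.0 ** log_fid,
        "start_dist_m": 10.0 ** log_sd,
        "body_mass_g": 10.0 ** log_mass,
        "specimen_mass_g": 10.0 ** log_spec,
        "eye_volume": 10.0 ** latents["log_eye"].to_numpy(),
        "chiffre_basal_g": cb,
    })
    for region in ("brain_stem", "optic_lobe", "cerebellum", "forebrain"):
        table[f"index_{region}"] = (10.0 ** latents[f"log_{region}"]
                                    .to_numpy()) / cb
    return table, latents


# -- tree perturbations for the multi-phylogeny fixture -----------------

def _jittered(tree: Phylogeny, rng: np.random.Generator,
              sd: float = 0.15) -> Phylogeny:
    out = Phylogeny(tree._tree.clone(depth=1), label="jitter")
    for nd in out._tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length *= float(np.exp(rng.normal(0.0, sd)))
    return out


def _consensus_like(tree: Phylogeny, rng: np.random.Generator,
                    n_collapse: int = 5) -> Phylogeny:
    """Collapse the shortest internal branches to zero (as a majority-rule
    consensus does to poorly supported splits) and re-resolve; the result
    is bifurcating with zero-length internal edges."""
    out = Phylogeny(tree._tree.clone(depth=1), label="consensus")
    internal = [nd for nd in out._tree.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()]
    internal.sort(key=lambda nd: nd.edge.length)
    for nd in internal[:n_collapse]:
        nd.edge.length = 0.0
    return out.resolve_polytomies(rng=random.Random(int(rng.integers(2**31))))


def paper_shaped_fixture(seed: int, config: SimConfig | None = None):
    """Full study-shaped dataset: one trait table and five phylogenies.

    The five trees are a base Yule tree plus four perturbations of it —
    branch-length jitter, an equal-branch-length copy, a consensus-like
    copy with collapsed-then-resolved short branches, and a uniformly
    rescaled copy — mimicking five alternative phylogenetic hypotheses for
    the same taxa.  Traits are generated once, on the base tree.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    base = simulate_tree(config.n_tips, config.birth_rate,
                         rng=random.Random(int(rng.integers(2**31))))
    base.label = "base"
    trees = [
        base,
        _jittered(base, rng),
        base.with_equal_branch_lengths(),
        _consensus_like(base, rng),
        base.scaled(2.0),
    ]
    trees[2].label = "equal"
    trees[4].label = "rescaled"
    table, latents = simulate_traits(base, config, rng)
    return table, trees, latents
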