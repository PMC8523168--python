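"""Synthetic community datasets with a known composition -> productivity ->
invasion causal structure.

The generator emulates the layout of the microcosm study the pipeline is
designed for: 680 communities, an OTU count table with planted correlated
OTU groups (clades on a generated phylogeny), 14 phenotype measurements,
and invader-survival assays for two lux-tagged invaders at three time
points in four technical replicates with left-censoring at a luminescence
detection threshold of 12 lumens.

Causal structure (all latents standardised, effects are standardised path
coefficients):

    C = standardised log mean abundance of the designated driver group
    P = beta_CP * C + e_P                        (latent productivity)
    I = beta_PI * P + beta_CI * C + e_I          (latent invasion propensity)

Cell yields (and, more weakly, respiration and ATP) load on P; the six
invader-survival endpoints load on I; enzymes are pure noise by default.
Endpoint cell densities are pushed through the inverse of the
luminescence calibration, multiplied by log-normal replicate noise, and
left-censored: luminescence below the detection threshold is replaced by
a uniform background draw on (0, threshold), mimicking sterile-blank
noise.  Every output is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data import (INVADERS, PHENOTYPE_COLUMNS, TIMEPOINTS, CalibrationModel,
                   InvasionTable, OtuTable, PhenotypeTable, TAXONOMIC_RANKS)

_NAN = float("nan")

#: Default loadings of the 14 phenotype indicators on latent productivity.
DEFAULT_PHENOTYPE_LOADINGS: dict[str, float] = {
    "cell_yield_d7": 0.8, "cell_yield_d14": 0.8,
    "respiration_d7": 0.6, "respiration_d14": 0.6,
    "atp_d7": 0.2, "atp_d14": 0.2,
    "glucosidase_d7": 0.0, "glucosidase_d14": 0.0,
    "chitinase_d7": 0.0, "chitinase_d14": 0.0,
    "xylosidase_d7": 0.0, "xylosidase_d14": 0.0,
    "phosphatase_d7": 0.0, "phosphatase_d14": 0.0,
}

#: Measurement-scale location/scale (log10 units) per phenotype family.
PHENOTYPE_SCALE: dict[str, tuple[float, float]] = {
    "cell_yield": (5.0, 0.5),      # cells/mL ~ 1e5
    "respiration": (0.3, 0.3),     # mg CO2 ~ 2
    "atp": (1.0, 0.4),             # nM ATP/mL ~ 10
    "glucosidase": (-1.0, 0.4),    # mg/mL ~ 0.1
    "chitinase": (-1.0, 0.4),
    "xylosidase": (-1.0, 0.4),
    "phosphatase": (-1.0, 0.4),
}

#: log10 cells/mL location per sampling hour (survival declines with time)
#: and scale of the endpoint map.
ENDPOINT_LOC = {24: 5.0, 96: 4.3, 168: 3.8}
ENDPOINT_SCALE = 0.8
#: putida survives less well than fluorescens in the emulated design.
INVADER_OFFSET = {"fluorescens": 0.0, "putida": -0.4}

#: Default luminescence calibrations (intercept a, slope b on the
#: log10-log10 scale).  Chosen so that the 12-lumen threshold converts to
#: detection limits near 6.3e3 (fluorescens) and 1.1e4 (putida) cells/mL.
DEFAULT_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "fluorescens": (2.178, 1.5),
    "putida": (2.299, 1.6),
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults mirror the emulated design."""

    n_communities: int = 680
    n_otus: int = 200
    n_groups: int = 10
    group_sizes: tuple[int, ...] | None = None
    library_size: int = 20000
    group_logabundance_sd: float = 1.0
    otu_logabundance_sd: float = 0.5
    within_group_sd: float = 1.0
    within_group_correlation: float = 0.8
    beta_CP: float = 0.47
    beta_PI: float = -0.33
    beta_CI: float = -0.13
    driver_weights: tuple[float, ...] | None = None
    phenotype_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_LOADINGS))
    endpoint_loading: float = 0.8
    replicate_cv: float = 0.2
    n_replicates: int = 4
    calibrations: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATIONS))
    detection_threshold_lux: float = 12.0
    driver_group: int = 0
    ultrametric_tree: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            base = self.n_otus // self.n_groups
            sizes = [base] * self.n_groups
            for i in range(self.n_otus - base * self.n_groups):
                sizes[i] += 1
            self.group_sizes = tuple(sizes)
        if sum(self.group_sizes) != self.n_otus:
            raise ValueError("group sizes must sum to n_otus")
        if self.driver_weights is None:
            # the driver group's abundance factor is the dominant
            # compositional axis; the other groups associate with it
            # weakly (sign-alternating), strongly enough to give the
            # composition features a common factor but below the
            # co-occurrence edge threshold so planted groups stay
            # separable in the network
            pattern = [0.35, -0.35, 0.3, -0.3, 0.25, -0.25]
            self.driver_weights = tuple(
                [1.0] + [pattern[i % len(pattern)]
                         for i in range(self.n_groups - 1)])
        if len(self.driver_weights) != self.n_groups:
            raise ValueError("driver_weights must have one entry per group")
        if any(abs(w) > 1 for w in self.driver_weights):
            raise ValueError("driver_weights must lie in [-1, 1]")
        if not 0.0 <= self.within_group_correlation <= 1.0:
            raise ValueError("within_group_correlation must lie in [0, 1]")
        if self.replicate_cv < 0 or self.within_group_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def resid_sd_P(self) -> float:
        v = 1.0 - self.beta_CP ** 2
        if v < 0:
            raise ValueError("|beta_CP| must be <= 1 for a standardised latent")
        return float(np.sqrt(v))

    def resid_sd_I(self) -> float:
        explained = (self.beta_PI ** 2 + self.beta_CI ** 2
                     + 2.0 * self.beta_PI * self.beta_CI * self.beta_CP)
        v = 1.0 - explained
        if v < 0:
            raise ValueError("structural coefficients imply var(I) > 1")
        return float(np.sqrt(v))


@dataclass
class GroundTruth:
    """Planted latent scores and effects of a synthetic dataset."""

    C: pd.Series
    P: pd.Series | None
    I: pd.Series | None
    beta_CP: float
    beta_PI: float
    beta_CI: float
    group_membership: dict[str, int]

    @property
    def indirect_effect(self) -> float:
        return self.beta_CP * self.beta_PI

    @property
    def total_composition_effect(self) -> float:
        return self.beta_CI + self.indirect_effect

    @property
    def proportion_mediated(self) -> float:
        """indirect / total composition effect; NaN sentinel when total = 0."""
        total = self.total_composition_effect
        if total == 0.0:
            return _NAN
        return self.indirect_effect / total

    def summary(self) -> dict:
        return {
            "beta_CP": self.beta_CP, "beta_PI": self.beta_PI,
            "beta_CI": self.beta_CI,
            "indirect_effect": self.indirect_effect,
            "total_composition_effect": self.total_composition_effect,
            "proportion_mediated": self.proportion_mediated,
        }


def ground_truth(config: SynthConfig) -> GroundTruth:
    """Planted effects implied by a configuration (no data needed)."""
    membership = {}
    k = 0
    for g, size in enumerate(config.group_sizes):
        for _ in range(size):
            membership[f"OTU_{k:04d}"] = g
            k += 1
    return GroundTruth(C=pd.Series(dtype=float), P=None, I=None,
                       beta_CP=config.beta_CP, beta_PI=config.beta_PI,
                       beta_CI=config.beta_CI, group_membership=membership)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def _coalesce(names: list[str], heights: list[float], rng: np.random.Generator,
              rate: float) -> tuple[str, float]:
    """Random sequential pairwise coalescence of named subtrees.

    ``names`` are newick fragments with tip heights ``heights``; returns
    the merged newick fragment and its height.  Merge times accumulate
    exponential waiting times, giving a coalescent-like depth profile.
    """
    names = list(names)
    heights = list(heights)
    h = max(heights)
    while len(names) > 1:
        h += rng.exponential(1.0 / (rate * len(names)))
        i, j = sorted(rng.choice(len(names), size=2, replace=False))
        bi = h - heights[i]
        bj = h - heights[j]
        merged = f"({names[i]}:{bi:.12g},{names[j]}:{bj:.12g})"
        names[i] = merged
        heights[i] = h
        del names[j], heights[j]
    return names[0], heights[0]


def generate_phylogeny(n_otus: int, n_invaders: int = 2, seed: int = 0,
                       group_sizes: tuple[int, ...] | None = None,
                       ultrametric: bool = True) -> TreeNode:
    """Random rooted tree over OTU and invader tips.

    Planted groups are clades: each group's OTUs coalesce among
    themselves before groups coalesce with each other, so group structure
    correlates with phylogeny as in real communities.  All branch lengths
    are strictly positive; in ultrametric mode all root-to-tip distances
    are equal.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)
    if group_sizes is None:
        group_sizes = (n_otus,)
    if sum(group_sizes) != n_otus:
        raise ValueError("group sizes must sum to n_otus")
    tip_heights = None if ultrametric else rng.uniform(0.0, 0.05, size=n_otus)
    clades, clade_heights = [], []
    k = 0
    for size in group_sizes:
        names = [f"OTU_{i:04d}" for i in range(k, k + size)]
        heights = [0.0 if ultrametric else float(tip_heights[i])
                   for i in range(k, k + size)]
        k += size
        if size == 1:
            clades.append(names[0])
            clade_heights.append(heights[0])
        else:
            frag, h = _coalesce(names, heights, rng, rate=2.0)
            clades.append(frag)
            clade_heights.append(h)
    backbone, root_h = _coalesce(clades, clade_heights, rng, rate=0.5)
    # invaders join above the community clade on long basal branches
    names = [backbone] + [f"INV_{INVADERS[i]}" if i < len(INVADERS) else f"INV_{i}"
                          for i in range(n_invaders)]
    heights = [root_h] + [0.0] * n_invaders
    newick, _ = _coalesce(names, heights, rng, rate=0.25)
    tree = TreeNode.read(StringIO(newick + ";"), convert_underscores=False)
    return tree


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

def generate_otu_table(config: SynthConfig) -> tuple[OtuTable, GroundTruth]:
    """Compositional counts with planted correlated OTU groups.

    Per community, each group draws a shared log-abundance factor; OTUs in
    the group mix that factor with private noise so that
    ``within_group_correlation`` controls the within-group correlation of
    log abundances.  Expected proportions are the softmax of log
    abundances; counts are multinomial at ``library_size``.  The
    composition score C is the standardised log mean expected abundance
    of the driver group.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_communities, config.n_otus
    sizes = config.group_sizes
    group_of = np.repeat(np.arange(config.n_groups), sizes)
    mu_group = rng.normal(0.0, config.group_logabundance_sd, size=config.n_groups)
    mu_otu = rng.normal(0.0, config.otu_logabundance_sd, size=m)
    rho = config.within_group_correlation
    # the driver group's factor doubles as the community-level
    # compositional axis: other groups' factors mix it in with weight
    # w_k, so group-abundance features co-vary the way a dominant
    # ecological gradient makes them do in real communities
    w = np.asarray(config.driver_weights, dtype=float)
    axis = rng.standard_normal((n, 1))
    group_noise = rng.standard_normal((n, config.n_groups))
    shared = w * axis + np.sqrt(1.0 - w ** 2) * group_noise
    private = rng.standard_normal((n, m))                   # per community x OTU
    z = (np.sqrt(rho) * shared[:, group_of] + np.sqrt(1.0 - rho) * private)
    logab = mu_group[group_of] + mu_otu + config.within_group_sd * z
    # softmax per community -> expected proportions
    logab -= logab.max(axis=1, keepdims=True)
    props = np.exp(logab)
    props /= props.sum(axis=1, keepdims=True)
    counts = np.empty((n, m), dtype=np.int64)
    for c in range(n):
        counts[c] = rng.multinomial(config.library_size, props[c])
    otu_ids = [f"OTU_{i:04d}" for i in range(m)]
    community_ids = [f"C{c:04d}" for c in range(n)]
    df = pd.DataFrame(counts, index=community_ids, columns=otu_ids)

    driver = group_of == config.driver_group
    mean_ab = props[:, driver].mean(axis=1)
    logm = np.log(mean_ab)
    C = (logm - logm.mean()) / logm.std()

    taxonomy = _synthetic_taxonomy(otu_ids, group_of)
    truth = ground_truth(config)
    truth.C = pd.Series(C, index=community_ids, name="C")
    return OtuTable(counts=df, taxonomy=taxonomy), truth


def _synthetic_taxonomy(otu_ids: list[str], group_of: np.ndarray) -> pd.DataFrame:
    """Nested labels so taxonomic aggregation has meaningful structure.

    Groups map to genera; coarser ranks merge neighbouring groups.
    """
    rows = []
    for otu, g in zip(otu_ids, group_of):
        rows.append({
            "species": f"sp_{otu}",
            "genus": f"genus_{g:02d}",
            "family": f"family_{g // 2:02d}",
            "order": f"order_{g // 3:02d}",
            "class": f"class_{g // 5:02d}",
            "phylum": f"phylum_{g // 5:02d}",
        })
    return pd.DataFrame(rows, index=pd.Index(otu_ids, name="otu_id"),
                        columns=list(TAXONOMIC_RANKS))


# ---------------------------------------------------------------------------
# Phenotypes + invasion
# ---------------------------------------------------------------------------

def generate_phenotypes_invasion(
        config: SynthConfig, C: pd.Series,
        truth: GroundTruth | None = None,
) -> tuple[PhenotypeTable, InvasionTable, GroundTruth]:
    """Latent P and I from C, observed indicators, censored replicate lux.

    Returns the phenotype table, the raw replicate-level invasion table
    (lux scale, below-detection flags set, cells not yet calibrated) and
    the completed ground truth.
    """
    if truth is None:
        truth = ground_truth(config)
    rng = np.random.default_rng(config.seed + 1)
    ids = list(C.index)
    n = len(ids)
    Cv = C.to_numpy()
    if config.beta_PI == 0 and config.beta_CI == 0:
        import warnings
        warnings.warn("beta_PI and beta_CI are both 0: proportion mediated "
                      "is undefined for recovery", stacklevel=2)
    P = config.beta_CP * Cv + config.resid_sd_P() * rng.standard_normal(n)
    I = (config.beta_PI * P + config.beta_CI * Cv
         + config.resid_sd_I() * rng.standard_normal(n))

    phen = {}
    for col in PHENOTYPE_COLUMNS:
        lam = float(config.phenotype_loadings.get(col, 0.0))
        noise_sd = np.sqrt(max(0.0, 1.0 - lam ** 2))
        z = lam * P + noise_sd * rng.standard_normal(n)
        family = col.rsplit("_", 1)[0]
        loc, scale = PHENOTYPE_SCALE[family]
        phen[col] = 10.0 ** (loc + scale * z)
    phenotypes = PhenotypeTable(pd.DataFrame(phen, index=ids))

    lam = config.endpoint_loading
    noise_sd = np.sqrt(max(0.0, 1.0 - lam ** 2))
    sigma_ln = np.sqrt(np.log1p(config.replicate_cv ** 2))
    rows = []
    for inv in INVADERS:
        a, b = config.calibrations[inv]
        for t in TIMEPOINTS:
            z = lam * I + noise_sd * rng.standard_normal(n)
            log_cells = ENDPOINT_LOC[t] + INVADER_OFFSET[inv] + ENDPOINT_SCALE * z
            lux_true = 10.0 ** ((log_cells - a) / b)
            for r in range(1, config.n_replicates + 1):
                noise = rng.lognormal(mean=-0.5 * sigma_ln ** 2, sigma=sigma_ln, size=n)
                lux = lux_true * noise
                below = lux < config.detection_threshold_lux
                lux = np.where(below,
                               rng.uniform(0.0, config.detection_threshold_lux, size=n),
                               lux)
                rows.append(pd.DataFrame({
                    "community": ids, "invader": inv, "time_h": t,
                    "replicate": r, "lux": lux, "cells": np.nan,
                    "below_detection": below,
                }))
    invasion = InvasionTable(pd.concat(rows, ignore_index=True))
    truth.C = C.copy()
    truth.P = pd.Series(P, index=ids, name="P")
    truth.I = pd.Series(I, index=ids, name="I")
    return phenotypes, invasion, truth


def calibration_models(config: SynthConfig) -> dict[str, CalibrationModel]:
    """The generator's calibrations as fitted-model objects (exact, R^2 = 1)."""
    return {inv: CalibrationModel(invader=inv, intercept=a, slope=b,
                                  r_squared=1.0, window_hours=(0.0, 0.0))
            for inv, (a, b) in config.calibrations.items()}


def generate_calibration_assay(config: SynthConfig, n_hours: int = 10,
                               noise_sd: float = 0.05) -> pd.DataFrame:
    """Growth-assay table (invader, replicate, hours, lux, cells) matching
    the configured calibrations up to log-normal measurement noise."""
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for inv, (a, b) in config.calibrations.items():
        for rep in range(1, 4):
            lux = 10.0 ** np.linspace(0.5, 4.0, n_hours)
            log_cells = a + b * np.log10(lux) + rng.normal(0, noise_sd, n_hours)
            rows.append(pd.DataFrame({
                "invader": inv, "replicate": rep,
                "hours": np.arange(n_hours, dtype=float) * 4.0,
                "lux": lux, "cells": 10.0 ** log_cells,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(config: SynthConfig):
    """Generate the complete synthetic study: OTU table, tree, phenotypes,
    raw invasion table and ground truth."""
    table, truth = generate_otu_table(config)
    tree = generate_phylogeny(config.n_otus, n_invaders=len(INVADERS),
                              seed=config.seed,
                              group_sizes=tuple(config.group_sizes),
                              ultrametric=config.ultrametric_tree)
    phenotypes, invasion, truth = generate_phenotypes_invasion(config, truth.C, truth)
    return {
        "otu_table": table,
        "tree": tree,
        "phenotypes": phenotypes,
        "invasion": invasion,
        "ground_truth": truth,
        "config": config,
    }
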