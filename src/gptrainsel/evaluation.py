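"""Predictive-ability evaluation and the method x model x size experiment grid.

Predictive ability is the Pearson correlation between observed and
predicted phenotypes in the validation set.  Abilities over independent
training-set realizations are aggregated on the Fisher z scale,
z = (1/2) ln((1+r)/(1-r)), and the mean is back-transformed with tanh; the
standard error is reported on the z scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel, TraitData
from .relatedness import KinshipMatrix, ibs_matrix, additive_relationship, loco_kinships
from .structure import (
    SubpopulationAssignment,
    assign_subpopulations,
    count_significant_components,
    pca_ibs,
)
from .sampling import (
    TrainingSplit,
    find_radius,
    sample_cd,
    sample_random,
    sample_stratified,
    sample_uniform,
)
from .models import fit_prediction_model, gwas_scan, li_ji_threshold, select_qtl

__all__ = [
    "ExperimentConfig",
    "PredictiveAbilitySummary",
    "predictive_ability",
    "fisher_aggregate",
    "within_subpop_ability",
    "run_experiment",
]

METHODS = ("U", "SU", "CD", "S", "R")


def predictive_ability(predictions: "pd.Series", trait: TraitData, ids) -> float:
    """Pearson r between observed and predicted phenotypes over ``ids``.

    Returns NaN (recorded missing, never 0) when fewer than 3 genotypes
    have both values or either side has zero variance.
    """
    ids = [str(g) for g in ids]
    usable = [g for g in ids if g in predictions.index and g in trait.values.index]
    if len(usable) < 3:
        return np.nan
    obs = trait.values.loc[usable].to_numpy()
    pred = predictions.loc[usable].to_numpy()
    if np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def fisher_aggregate(r_values) -> tuple:
    """Fisher-z mean of correlations: returns (back-transformed mean r, SE on z).

    Missing values are dropped; SE is NaN with fewer than two usable
    correlations.
    """
    r = np.asarray([v for v in r_values if v is not None and np.isfinite(v)], dtype=float)
    if r.size == 0:
        return np.nan, np.nan
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z requires |r| < 1")
    z = np.arctanh(r)
    mean_r = float(np.tanh(z.mean()))
    se = float(z.std(ddof=1) / np.sqrt(z.size)) if z.size >= 2 else np.nan
    return mean_r, se


def within_subpop_ability(predictions: "pd.Series", trait: TraitData,
                          split: TrainingSplit,
                          assignment: SubpopulationAssignment,
                          min_group: int = 3) -> "pd.Series":
    """Predictive ability per subpopulation over that group's validation members.

    Groups with fewer than ``min_group`` validation members are NaN
    (small-group flag): no reliable estimate is possible there.
    """
    groups = assignment.of(split.validation_ids)
    out = {}
    for grp in assignment.group_sizes.index:
        members = [g for g, lab in zip(split.validation_ids, groups) if lab == grp]
        out[grp] = predictive_ability(predictions, trait, members) if len(members) >= min_group else np.nan
    return pd.Series(out)


@dataclass
class ExperimentConfig:
    """Factorial experiment over sampling methods, prediction models and sizes."""

    methods: tuple = ("U", "SU", "CD", "S", "R")
    models: tuple = ("GBLUP",)
    sizes: tuple = (200,)
    n_realizations: int = 100
    seed: int = 0
    h2: float = 0.85            # drives the CD criterion's lambda
    gwas_alpha: float = 0.01    # genome-wide level for the Li-Ji threshold
    tw_alpha: float = 0.05
    forced_qtl: tuple = ()      # markers always included in QTL / QGBLUP sets

    def __post_init__(self):
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")


@dataclass
class PredictiveAbilitySummary:
    """Aggregated abilities plus raw per-realization values and split diagnostics."""

    table: "pd.DataFrame"                 # method, model, size, trait, mean_r, se_z, n
    raw: "pd.DataFrame"                   # one row per realization cell
    within: "pd.DataFrame" | None = None  # per-subpopulation means
    failures: list = field(default_factory=list)


def _draw_split(method, size, seed, k_ibs, a_ab, assignment, h2, radii):
    if method == "U":
        return sample_uniform(k_ibs, size, seed, radius=radii[("U", size)])
    if method == "SU":
        return sample_uniform(k_ibs, size, seed, strata=assignment,
                              radius=radii[("SU", size)])
    if method == "CD":
        return sample_cd(a_ab, size, h2=h2, seed=seed)
    if method == "S":
        return sample_stratified(assignment, size, seed=seed)
    return sample_random(k_ibs.genotype_ids, size, seed=seed)


def run_experiment(panel: MarkerPanel, traits: dict, config: ExperimentConfig,
                   assignment: SubpopulationAssignment | None = None) -> PredictiveAbilitySummary:
    """Run the full grid: draw splits, detect QTL where needed, fit, evaluate.

    ``traits`` maps name -> TraitData.  When no subpopulation assignment is
    given, one is derived from IBS-PCA with the Tracy-Widom group count.
    Realization seeds are config.seed + realization index so any cell is
    re-runnable in isolation.  Cell failures are logged and recorded
    missing; the run continues.
    """
    k_ibs = ibs_matrix(panel)
    a_ab = additive_relationship(panel)
    if assignment is None:
        res = pca_ibs(k_ibs)
        res.n_significant = count_significant_components(panel, alpha=config.tw_alpha)
        assignment = assign_subpopulations(res, res.n_subpops, seed=config.seed)

    needs_qtl = any(m in ("QTL", "QGBLUP") for m in config.models)
    loco = loco_kinships(panel) if needs_qtl else None

    radii = {}
    for size in config.sizes:
        if "U" in config.methods:
            radii[("U", size)] = find_radius(k_ibs, size)
        if "SU" in config.methods:
            radii[("SU", size)] = find_radius(k_ibs, size,
                                              strata=assignment.of(k_ibs.genotype_ids))

    raw_rows, within_rows, failures = [], [], []
    for trait_name, trait in traits.items():
        threshold = li_ji_threshold(panel, config.gwas_alpha) if needs_qtl else None
        for size in config.sizes:
            for method in config.methods:
                for real in range(config.n_realizations):
                    seed = config.seed + real
                    try:
                        split = _draw_split(method, size, seed, k_ibs, a_ab,
                                            assignment, config.h2, radii)
                        qtl = None
                        if needs_qtl:
                            pvals = gwas_scan(panel, trait, loco, split.training_ids)
                            qtl = select_qtl(pvals, threshold, panel,
                                             forced_markers=config.forced_qtl)
                        for model in config.models:
                            try:
                                fit = fit_prediction_model(
                                    model, trait, panel, split.training_ids,
                                    qtl=qtl, A=a_ab, tune_seed=seed)
                            except ValueError as e:
                                failures.append((trait_name, size, method, model, real, str(e)))
                                continue
                            r = predictive_ability(fit.predictions, trait,
                                                   split.validation_ids)
                            raw_rows.append((trait_name, size, method, model, real, r))
                            wr = within_subpop_ability(fit.predictions, trait,
                                                       split, assignment)
                            for grp, val in wr.items():
                                within_rows.append((trait_name, size, method, model,
                                                    real, grp, val))
                    except Exception as e:  # cell failure: record and continue
                        for model in config.models:
                            failures.append((trait_name, size, method, model, real, str(e)))

    raw = pd.DataFrame(raw_rows, columns=["trait", "size", "method", "model",
                                          "realization", "r"])
    summary_rows = []
    for (trait_name, size, method, model), grp in raw.groupby(
            ["trait", "size", "method", "model"], sort=False):
        mean_r, se = fisher_aggregate(grp["r"])
        summary_rows.append((method, model, size, trait_name, mean_r, se,
                             int(grp["r"].notna().sum())))
    table = pd.DataFrame(summary_rows, columns=["method", "model", "size", "trait",
                                                "mean_r", "se_z", "n_realizations"])
    within = pd.DataFrame(within_rows, columns=["trait", "size", "method", "model",
                                                "realization", "subpop", "r"])
    within_summary = (
        within.groupby(["trait", "size", "method", "model", "subpop"])["r"]
        .apply(lambda s: fisher_aggregate(s)[0])
        .reset_index(name="mean_r")
        if len(within) else None
    )
    return PredictiveAbilitySummary(table=table, raw=raw, within=within_summary,
                                    failures=failures)
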