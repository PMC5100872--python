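"""Synthetic structured inbred panels with known truth.

Panels follow a hierarchical Balding-Nichols model built to emulate real
diversity panels of inbred breeding material:

* ancestral allele frequencies uniform on (0.05, 0.95);
* S subpopulations drawing frequencies from Beta(p(1-F_s)/F_s,
  (1-p)(1-F_s)/F_s), with the per-subpopulation divergences F_s spread
  geometrically around the target Fst so that larger groups are more
  diverse (the pattern real panels show);
* inside each subpopulation, a mixture of unique accessions (private
  Balding-Nichols drift away from the subpopulation frequency) and sibling
  families (lines drawn from a shared near-fixed family frequency), giving
  the broad, heavy-tailed nearest-neighbour distance spectrum of real
  panels: near-duplicate sibs around distance ~0.1 and isolated singletons
  with no close relative;
* fully inbred lines (dosage = 2 x Bernoulli) unless a heterozygosity rate
  is requested.

Setting ``singleton_frac = 1`` with ``singleton_fst = 0`` and
``diversity_spread = 1`` collapses the generator to the textbook
Balding-Nichols model with exchangeable lines inside each subpopulation
(the right null for estimator-recovery checks).

Traits are a few large QTL plus a polygenic background plus noise at a
target heritability.  Because the between-subpopulation share of a
polygenic trait's variance is a ratio with only S-1 degrees of freedom, it
fluctuates wildly from draw to draw; by default the generator pins it at
its neutral expectation (the target Fst), matching panels whose predictive
ability is demonstrably not a pure population-structure artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MarkerPanel, TraitData
from .structure import SubpopulationAssignment
from .models import QTLSet

__all__ = [
    "SyntheticPanelConfig",
    "simulate_panel",
    "simulate_trait",
    "simulate_dataset",
    "write_truth",
]


@dataclass
class SyntheticPanelConfig:
    """Default panel: 250 inbred lines in 5 unequal subpopulations at Fst 0.25.

    The group sizes (95, 55, 50, 30, 20) mirror the skewed subpopulation
    sizes of real maize/wheat diversity panels; 2000 markers on 10
    chromosomes of 100 cM are a desk-scale stand-in for SNP-chip densities.
    """

    subpop_sizes: tuple = (95, 55, 50, 30, 20)
    fst: float = 0.25
    n_markers: int = 2000
    n_chromosomes: int = 10
    chrom_length_cM: float = 100.0
    #: fraction of each subpopulation that is unique accessions
    singleton_frac: float = 0.45
    #: private drift of a unique accession away from its subpopulation
    singleton_fst: float = 0.3
    #: mean sibling-family size (geometric, minimum 2)
    family_mean_size: float = 6.0
    #: drift of a family's shared frequency (near fixation within family)
    family_fst: float = 0.65
    #: ratio of largest to smallest per-subpopulation divergence
    diversity_spread: float = 2.0
    n_qtl: int = 5
    qtl_variance_fraction: float = 0.2
    h2: float = 0.7
    #: between-subpopulation share of genetic variance; None pins it at fst
    between_group_share: float | None = None
    het_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 2 for s in self.subpop_sizes):
            raise ValueError("every subpopulation needs size >= 2")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("target Fst must lie in [0, 1)")
        if not 0.0 <= self.singleton_frac <= 1.0:
            raise ValueError("singleton_frac must lie in [0, 1]")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if not 0.0 <= self.qtl_variance_fraction <= 1.0:
            raise ValueError("qtl_variance_fraction must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if self.diversity_spread < 1.0:
            raise ValueError("diversity_spread must be >= 1")

    @property
    def n_genotypes(self) -> int:
        return int(sum(self.subpop_sizes))

    def subpop_divergences(self) -> np.ndarray:
        """Per-subpopulation F_s: geometric spread, largest group most diverse."""
        s = len(self.subpop_sizes)
        if s == 1 or self.diversity_spread == 1.0 or self.fst == 0.0:
            return np.full(s, self.fst)
        ratios = np.geomspace(1.0 / np.sqrt(self.diversity_spread),
                              np.sqrt(self.diversity_spread), s)
        order = np.argsort(-np.asarray(self.subpop_sizes), kind="stable")
        c = np.empty(s)
        c[order] = ratios
        return self.fst * c / c.mean()


def _bn_freq(rng, p, f):
    """Balding-Nichols draw around frequency vector p at divergence f."""
    if f <= 0.0:
        return np.array(p, dtype=float, copy=True)
    p = np.clip(p, 1e-4, 1.0 - 1e-4)
    return rng.beta(p * (1.0 - f) / f, (1.0 - p) * (1.0 - f) / f)


def _layout(rng, cfg) -> tuple:
    """Assign every line to a drift unit (its own, or a shared sibling family)."""
    unit_of = np.empty(cfg.n_genotypes, dtype=int)
    unit_subpop, unit_f = [], []
    pos = 0
    for s, size in enumerate(cfg.subpop_sizes):
        n_sing = int(round(cfg.singleton_frac * size))
        for _ in range(n_sing):
            unit_of[pos] = len(unit_f)
            unit_subpop.append(s)
            unit_f.append(cfg.singleton_fst)
            pos += 1
        left = size - n_sing
        while left > 0:
            fam = min(max(2, int(rng.geometric(1.0 / cfg.family_mean_size))), left)
            unit = len(unit_f)
            unit_subpop.append(s)
            unit_f.append(cfg.family_fst)
            unit_of[pos:pos + fam] = unit
            pos += fam
            left -= fam
    return unit_of, np.asarray(unit_subpop), np.asarray(unit_f, dtype=float)


def _draw_block(rng, n_cols, cfg, fs, unit_of, unit_subpop, unit_f):
    """Dosage block for n_cols fresh markers under the fixed panel layout."""
    p_anc = rng.uniform(0.05, 0.95, size=n_cols)
    p_sub = np.stack([_bn_freq(rng, p_anc, f) for f in fs])
    p_unit = np.empty((unit_f.size, n_cols))
    for u in range(unit_f.size):
        p_unit[u] = _bn_freq(rng, p_sub[unit_subpop[u]], unit_f[u])
    p_line = p_unit[unit_of]
    return 2 * (rng.random((cfg.n_genotypes, n_cols)) < p_line).astype(np.int8)


def simulate_panel(cfg: SyntheticPanelConfig) -> tuple:
    """Draw a structured inbred panel; returns (MarkerPanel, SubpopulationAssignment)."""
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_genotypes, cfg.n_markers
    labels = np.repeat(np.arange(len(cfg.subpop_sizes)), cfg.subpop_sizes)
    fs = cfg.subpop_divergences()
    unit_of, unit_subpop, unit_f = _layout(rng, cfg)

    dosage = np.empty((n, k), dtype=np.int8)
    remaining = np.arange(k)
    for _ in range(50):  # resample whole-panel monomorphic markers
        dosage[:, remaining] = _draw_block(rng, remaining.size, cfg, fs,
                                           unit_of, unit_subpop, unit_f)
        col_mean = dosage[:, remaining].mean(axis=0)
        remaining = remaining[(col_mean == 0.0) | (col_mean == 2.0)]
        if remaining.size == 0:
            break
    if remaining.size:
        raise RuntimeError("could not resample monomorphic markers")
    if cfg.het_rate > 0:
        het = rng.random((n, k)) < cfg.het_rate
        dosage[het] = 1

    chrom = np.array([f"chr{1 + j % cfg.n_chromosomes}" for j in range(k)], dtype=object)
    pos = np.empty(k)
    for c in range(cfg.n_chromosomes):
        cols = np.flatnonzero(chrom == f"chr{1 + c}")
        pos[cols] = np.sort(rng.uniform(0.0, cfg.chrom_length_cM, size=cols.size))

    geno_ids = [f"g{i:04d}" for i in range(n)]
    marker_ids = [f"m{j:05d}" for j in range(k)]
    panel = MarkerPanel(geno_ids, marker_ids, chrom, pos, dosage)
    assignment = SubpopulationAssignment(pd.Series(labels, index=geno_ids))
    return panel, assignment


def simulate_trait(panel: MarkerPanel, n_qtl: int, qtl_variance_fraction: float,
                   h2: float, seed: int = 0, trait_name: str = "trait",
                   min_qtl_maf: float = 0.1,
                   assignment: SubpopulationAssignment | None = None,
                   between_group_share: float | None = None) -> tuple:
    """Simulate an additive trait; returns (TraitData, true QTLSet, genotypic values).

    QTL markers are drawn among markers with MAF >= ``min_qtl_maf`` (so a
    declared large-effect locus is actually segregating); QTL and background
    effect sizes are rescaled so the realized QTL share of the genetic
    variance matches ``qtl_variance_fraction``, and the residual variance is
    set from the realized genetic variance to hit the target heritability up
    to sampling error in the noise draw.

    When ``assignment`` and ``between_group_share`` are given, the
    between-subpopulation component of the genotypic values is rescaled to
    that exact variance share.  The realized share is a ratio with S-1
    degrees of freedom and otherwise swings from near 0 to near 1 between
    draws; pinning it at its neutral expectation keeps trait draws in the
    regime the generator is meant to emulate.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    if qtl_variance_fraction >= 1.0 and n_qtl == 0:
        raise ValueError("qtl_variance_fraction = 1 requires n_qtl > 0")
    rng = np.random.default_rng(seed)
    d = panel.dosage.astype(float)
    x = d - d.mean(axis=0)
    p = d.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf >= min_qtl_maf)
    if n_qtl > eligible.size:
        raise ValueError("not enough common markers to place the QTL")
    qtl_idx = np.sort(rng.choice(eligible, size=n_qtl, replace=False))
    bg_idx = np.setdiff1d(np.arange(panel.n_markers), qtl_idx)

    g_qtl = np.zeros(panel.n_genotypes)
    if n_qtl and qtl_variance_fraction > 0:
        g_qtl = x[:, qtl_idx] @ rng.normal(size=n_qtl)
    g_bg = x[:, bg_idx] @ rng.normal(size=bg_idx.size)

    vq, vb = np.var(g_qtl), np.var(g_bg)
    wq = np.sqrt(qtl_variance_fraction / vq) if vq > 0 else 0.0
    wb = np.sqrt((1.0 - qtl_variance_fraction) / vb) if vb > 0 else 0.0
    g = wq * g_qtl + wb * g_bg

    if assignment is not None and between_group_share is not None:
        labs = assignment.of(panel.genotype_ids)
        means = pd.Series(g).groupby(labs).transform("mean").to_numpy()
        within = g - means
        between = means - g.mean()
        realized = between.var() / (between.var() + within.var())
        if 0.0 < realized < 1.0 and 0.0 < between_group_share < 1.0:
            scale = np.var(g)
            g = (np.sqrt(between_group_share / realized) * between
                 + np.sqrt((1.0 - between_group_share) / (1.0 - realized)) * within)
            g *= np.sqrt(scale / np.var(g))

    var_g = np.var(g)
    sigma_e = np.sqrt(var_g * (1.0 - h2) / h2) if h2 < 1.0 else 0.0
    y = g + rng.normal(scale=sigma_e, size=g.size) if sigma_e > 0 else g.copy()

    trait = TraitData(trait_name, pd.Series(y, index=panel.genotype_ids))
    qtl = QTLSet(
        marker_ids=[panel.marker_ids[j] for j in qtl_idx],
        chromosomes=[str(panel.chromosome[j]) for j in qtl_idx],
        positions=[float(panel.position_cM[j]) for j in qtl_idx],
    )
    genotypic = pd.Series(g, index=panel.genotype_ids)
    return trait, qtl, genotypic


def simulate_dataset(cfg: SyntheticPanelConfig) -> tuple:
    """Panel + assignment + trait in one call, under the config's conditions.

    Returns (panel, assignment, trait, true QTLSet, true genotypic values).
    The trait uses the config's QTL count, QTL variance fraction, h2, and
    the between-group share pin (config value, defaulting to the target Fst).
    """
    panel, assignment = simulate_panel(cfg)
    share = cfg.between_group_share if cfg.between_group_share is not None else cfg.fst
    share = share if 0.0 < share < 1.0 else None
    trait, qtl, g = simulate_trait(
        panel, cfg.n_qtl, cfg.qtl_variance_fraction, cfg.h2,
        seed=cfg.seed + 1, assignment=assignment, between_group_share=share)
    return panel, assignment, trait, qtl, g


def write_truth(path, trait: TraitData, qtl: QTLSet, genotypic: "pd.Series",
                realized_h2: float | None = None) -> None:
    """Write the truth sidecar (true QTL, genotypic values, realized h2) as CSV."""
    df = pd.DataFrame({"genotype_id": genotypic.index,
                       "true_genotypic_value": genotypic.to_numpy(),
                       "phenotype": trait.values.loc[genotypic.index].to_numpy()})
    if realized_h2 is not None:
        df["realized_h2"] = realized_h2
    df["true_qtl"] = ";".join(qtl.marker_ids)
    df.to_csv(path, index=False)
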