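"""Population-structure diagnostics.

Principal component analysis of the IBS matrix, a Tracy-Widom count of
significant components (the number of subpopulations is that count plus
one), k-means subpopulation assignment on the PC scores, and the
Weir-Cockerham Fst estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .panel import MarkerPanel, MISSING
from .relatedness import KinshipMatrix

__all__ = [
    "StructureResult",
    "SubpopulationAssignment",
    "pca_ibs",
    "patterson_eigenvalues",
    "count_significant_components",
    "tracy_widom_count",
    "assign_subpopulations",
    "fst_weir_cockerham",
    "plot_pc_scatter",
]

# Tracy-Widom (TW1) critical values for the Patterson-normalized leading
# eigenvalue.
TW_CRITICAL = {0.05: 0.9793, 0.01: 2.0234}


@dataclass
class StructureResult:
    """Spectrum and scores of an IBS principal component analysis."""

    genotype_ids: list
    eigenvalues: np.ndarray          # descending, non-negative
    pct_variance: np.ndarray         # sums to 100 over retained components
    scores: np.ndarray               # genotype x component, eigvec * sqrt(eigval)
    degenerate: bool = False
    n_significant: int | None = None

    @property
    def n_subpops(self) -> int:
        if self.n_significant is None:
            raise ValueError("run tracy_widom_count first")
        return self.n_significant + 1


@dataclass
class SubpopulationAssignment:
    """Genotype -> subpopulation label map with group sizes."""

    labels: "pd.Series"  # index genotype_id, values group label

    def __post_init__(self):
        self.labels = pd.Series(self.labels)
        self.labels.index = self.labels.index.map(str)

    @property
    def S(self) -> int:
        return int(self.labels.nunique())

    @property
    def group_sizes(self) -> "pd.Series":
        return self.labels.value_counts().sort_index()

    def groups(self) -> dict:
        return {g: list(idx) for g, idx in self.labels.groupby(self.labels).groups.items()}

    def of(self, ids) -> np.ndarray:
        return self.labels.loc[[str(i) for i in ids]].to_numpy()


def pca_ibs(kinship: KinshipMatrix) -> StructureResult:
    """Eigendecompose the double-centered IBS matrix (classical MDS / Gower).

    Scores are eigenvectors scaled by sqrt(eigenvalue), so squared score
    distances reconstruct the IBS-derived squared distances.  Percent
    variance is taken over the non-negative eigenvalues.
    """
    if kinship.kind != "ibs":
        raise ValueError("pca_ibs expects an IBS kinship")
    a = kinship.values
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-12, 1e-9 * max(vals.max(), 0.0))
    total = vals[keep].sum()
    if total <= 1e-12:
        return StructureResult(kinship.genotype_ids, np.zeros(0), np.zeros(0),
                               np.zeros((n, 0)), degenerate=True)
    vals = vals[keep]
    scores = vecs[:, keep] * np.sqrt(vals)
    pct = 100.0 * vals / total
    return StructureResult(kinship.genotype_ids, vals, pct, scores)


def patterson_eigenvalues(panel: MarkerPanel) -> tuple:
    """Eigenvalues of the standardized-genotype covariance, for TW testing.

    Markers are scaled to unit variance (score minus allele frequency over
    sqrt(p(1-p))) before the eigendecomposition, so the null spectrum
    follows the Marchenko-Pastur law the Tracy-Widom edge test assumes;
    the unstandardized IBS spectrum has heterogeneous marker variances
    that inflate the leading eigenvalue under the null.  Returns
    (eigenvalues descending, number of polymorphic markers used).
    """
    x = panel.dosage.astype(float) / 2.0
    p = x.mean(axis=0)
    keep = (p > 0) & (p < 1)
    x = x[:, keep]
    p = p[keep]
    k = x.shape[1]
    if k == 0:
        raise ValueError("no polymorphic markers")
    x = (x - p) / np.sqrt(p * (1.0 - p))
    n = x.shape[0]
    cov = x @ x.T / k
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ cov @ j
    vals = np.linalg.eigvalsh((b + b.T) / 2.0)[::-1]
    return vals[vals > 1e-10], k


def count_significant_components(panel: MarkerPanel, alpha: float = 0.05) -> int:
    """Tracy-Widom count of significant PCs from the standardized spectrum."""
    vals, k = patterson_eigenvalues(panel)
    return tracy_widom_count(vals, panel.n_genotypes, k, alpha=alpha)


def _patterson_stat(eigs: np.ndarray, n_markers: int) -> float:
    """Normalize the leading of the remaining eigenvalues to the TW scale."""
    m = eigs.size
    s1, s2 = eigs.sum(), (eigs ** 2).sum()
    # moment estimator of the effective number of markers; falls back to the
    # actual marker count when the estimator is unstable
    denom = (m - 1) * s2 - s1 ** 2
    if denom > 0:
        n_eff = (m + 1) * s1 ** 2 / denom
        n_eff = float(np.clip(n_eff, m + 1, max(n_markers, m + 1)))
    else:
        n_eff = float(max(n_markers, m + 1))
    ell = m * eigs[0] / s1
    sq_n = np.sqrt(n_eff - 1.0)
    sq_m = np.sqrt(m)
    mu = (sq_n + sq_m) ** 2 / n_eff
    sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
    return (ell - mu) / sigma


def tracy_widom_count(eigenvalues, n_genotypes: int, n_markers: int,
                      alpha: float = 0.05) -> int:
    """Count of significant leading eigenvalues under sequential TW testing.

    At each step the leading remaining eigenvalue is Patterson-normalized and
    compared with the TW1 critical value; testing stops at the first
    non-significant component.
    """
    if alpha not in TW_CRITICAL:
        raise ValueError(f"alpha must be one of {sorted(TW_CRITICAL)}")
    eigs = np.asarray(eigenvalues, dtype=float)
    eigs = eigs[eigs > 0]
    if eigs.size < 3:
        raise ValueError("need at least 3 positive eigenvalues")
    crit = TW_CRITICAL[alpha]
    count = 0
    while eigs.size >= 3:
        if _patterson_stat(eigs, n_markers) <= crit:
            break
        count += 1
        eigs = eigs[1:]
    return count


def assign_subpopulations(structure: StructureResult, k: int,
                          seed: int = 0) -> SubpopulationAssignment:
    """k-means on the first max(1, k-1) PC score dimensions (25 restarts)."""
    n = len(structure.genotype_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genotypes")
    if k == 1:
        return SubpopulationAssignment(pd.Series(0, index=structure.genotype_ids))
    dims = max(1, k - 1)
    if structure.scores.shape[1] < dims:
        raise ValueError(f"need scores on >= {dims} components")
    x = structure.scores[:, :dims]
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
    return SubpopulationAssignment(pd.Series(km.labels_, index=structure.genotype_ids))


def plot_pc_scatter(structure: StructureResult,
                    assignment: "SubpopulationAssignment | None" = None,
                    components=(1, 2), ax=None):
    """Scatter of two PC score dimensions, colored by subpopulation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    i, j = components[0] - 1, components[1] - 1
    if assignment is None:
        ax.scatter(structure.scores[:, i], structure.scores[:, j], s=12)
    else:
        labels = assignment.of(structure.genotype_ids)
        for grp in pd.unique(labels):
            sel = labels == grp
            ax.scatter(structure.scores[sel, i], structure.scores[sel, j],
                       s=12, label=str(grp))
        ax.legend(title="subpopulation", fontsize="small")
    ax.set_xlabel(f"PC{components[0]} ({structure.pct_variance[i]:.1f}%)")
    ax.set_ylabel(f"PC{components[1]} ({structure.pct_variance[j]:.1f}%)")
    return ax


def fst_weir_cockerham(panel: MarkerPanel, assignment: SubpopulationAssignment,
                       haploid: bool = False) -> float:
    """Weir-Cockerham Fst (theta), ratio-of-sums over loci.

    The diploid form uses observed heterozygote frequencies (essentially
    zero for inbred lines); ``haploid=True`` treats each line as a single
    allele drawn at frequency dosage/2, dropping the within-individual
    variance component.  Loci with a zero total variance are skipped.
    """
    if assignment.S < 2:
        raise ValueError("Fst needs at least two subpopulations")
    groups = assignment.groups()
    idx = [panel.genotype_index(ids) for ids in groups.values()]
    sizes = np.array([len(ix) for ix in idx], dtype=float)
    if np.any(sizes < 2):
        raise ValueError("every subpopulation needs >= 2 genotypes")
    r = len(idx)

    d = panel.dosage.astype(float)
    d[panel.dosage == MISSING] = np.nan
    # per-group allele frequency and observed-heterozygote frequency per locus
    p_i = np.stack([np.nanmean(d[ix], axis=0) / 2.0 for ix in idx])        # r x K
    h_i = np.stack([np.nanmean(d[ix] == 1.0, axis=0) for ix in idx])       # r x K
    n_i = np.stack([np.sum(np.isfinite(d[ix]), axis=0) for ix in idx]).astype(float)

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = 0.0 if haploid else (n_i * h_i).sum(axis=0) / (r * nbar)

        if haploid:
            # haploid theta: alleles are the lines themselves
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
            c = np.zeros_like(a)
        else:
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0

    tot = a + b + c
    ok = np.isfinite(tot) & (np.abs(tot) > 1e-12)
    if not ok.any():
        raise ValueError("no informative loci for Fst (all denominators zero)")
    return float(a[ok].sum() / tot[ok].sum())
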