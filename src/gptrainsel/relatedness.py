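"""Genomic relationship and kernel matrices.

Implements the identity-by-state (IBS) proportion-of-shared-alleles matrix,
the Astle-Balding realized additive relationship, the Gaussian kernel used
by RKHS regression, leave-one-chromosome-out (LOCO) kinships for GWAS, and
the QTL-window-masked kinship used by the QGBLUP model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MarkerPanel

__all__ = [
    "KinshipMatrix",
    "ibs_matrix",
    "additive_relationship",
    "gaussian_kernel",
    "loco_kinships",
    "qtl_masked_relationship",
]

#: diagonal ridge applied transiently wherever an inverse is required;
#: never stored in a KinshipMatrix.
RIDGE = 1e-8


@dataclass
class KinshipMatrix:
    """A symmetric genotype-by-genotype relationship matrix with a kind tag."""

    genotype_ids: list
    values: np.ndarray
    kind: str  # ibs | additive_ab | additive_ab_masked | gaussian | loco
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotype_ids = list(map(str, self.genotype_ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        return np.array([lookup[str(g)] for g in ids], dtype=int)

    def submatrix(self, ids) -> np.ndarray:
        ix = self.index_of(ids)
        return self.values[np.ix_(ix, ix)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genotype_ids,
                     columns=self.genotype_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.map(str)), df.to_numpy(), kind)


def ibs_matrix(panel: MarkerPanel) -> KinshipMatrix:
    """Proportion of shared alleles, A_IBS = (GG' + G2 G2')/K.

    G holds marker scores 0/0.5/1 (homozygotes at 0 and 1, heterozygotes at
    0.5) and G2 = 1 - G.  Entries lie in [0, 1]; fully homozygous genotypes
    have unit self-IBS while a heterozygous self-entry is 0.5 (a property of
    the score-product formula, kept deliberately literal).
    """
    if panel.n_markers == 0:
        raise ValueError("panel has no markers")
    g = panel.scores()
    g2 = 1.0 - g
    a = (g @ g.T + g2 @ g2.T) / panel.n_markers
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    return KinshipMatrix(panel.genotype_ids, a, "ibs")


def _ab_values(dosage: np.ndarray, marker_ids) -> np.ndarray:
    d = dosage.astype(float)
    p = d.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = [marker_ids[j] for j in np.flatnonzero(mono)[:5]]
        raise ValueError(f"monomorphic marker(s) give a zero denominator: {bad}")
    w = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    a = w @ w.T / d.shape[1]
    return (a + a.T) / 2.0


def additive_relationship(panel: MarkerPanel, kind: str = "additive_ab") -> KinshipMatrix:
    """Realized additive relationship A_ij = (1/K) sum_k (G_ik-2p_k)(G_jk-2p_k) / (2 p_k (1-p_k)).

    G_ik is the 0/1/2 dosage and p_k the allele frequency of the panel
    actually passed in (the calibration panel, computed before any
    training/validation split).
    """
    if panel.has_missing:
        raise ValueError("panel has missing calls; impute first")
    return KinshipMatrix(panel.genotype_ids, _ab_values(panel.dosage, panel.marker_ids), kind)


def scaled_distance_matrix(panel: MarkerPanel) -> np.ndarray:
    """Squared Euclidean distance on dosage scores, scaled to unit off-diagonal mean."""
    d = panel.dosage.astype(float)
    sq = np.sum(d * d, axis=1)
    dist = sq[:, None] + sq[None, :] - 2.0 * (d @ d.T)
    np.clip(dist, 0.0, None, out=dist)
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    off_mean = dist.sum() / (n * (n - 1)) if n > 1 else 0.0
    if off_mean <= 0.0:
        raise ValueError("all genotypes identical: degenerate distance matrix")
    return dist / off_mean


def gaussian_kernel(panel: MarkerPanel, theta: float) -> KinshipMatrix:
    """RKHS kernel A* = exp(-D/theta) with D the scaled squared-distance matrix.

    Scaling D to unit mean off-diagonal distance makes the bandwidth grid
    0.05-5 transferable across panels of different sizes and marker counts.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    dist = scaled_distance_matrix(panel)
    a = np.exp(-dist / theta)
    return KinshipMatrix(panel.genotype_ids, (a + a.T) / 2.0, "gaussian",
                         meta={"theta": float(theta)})


def loco_kinships(panel: MarkerPanel) -> dict:
    """One additive relationship per chromosome, excluding that chromosome's markers.

    Returns a dict chromosome -> KinshipMatrix tagged with the excluded
    chromosome, for use as the polygenic covariance in a GWAS scan.
    """
    chroms = pd.unique(panel.chromosome)
    if len(chroms) < 2:
        raise ValueError(
            "LOCO kinships need >= 2 chromosomes; use the global additive_relationship"
        )
    out = {}
    for c in chroms:
        keep = np.flatnonzero(panel.chromosome != c)
        k = additive_relationship(panel.subset(markers=keep), kind="loco")
        k.meta["excluded_chromosome"] = str(c)
        out[str(c)] = k
    return out


def qtl_masked_relationship(panel: MarkerPanel, qtl, window_cM: float = 20.0) -> KinshipMatrix:
    """Additive relationship from all markers outside +/- window_cM of any QTL.

    ``qtl`` is a QTLSet (or anything with ``chromosomes`` and ``positions``
    sequences).  Overlapping windows are handled as a union of intervals.
    With an empty QTL set the result equals ``additive_relationship(panel)``
    exactly (up to the kind tag).
    """
    chroms = np.asarray([str(c) for c in getattr(qtl, "chromosomes", [])], dtype=object)
    poss = np.asarray(list(getattr(qtl, "positions", [])), dtype=float)
    mask = np.zeros(panel.n_markers, dtype=bool)
    windows = []
    for c, pos in zip(chroms, poss):
        lo, hi = pos - window_cM, pos + window_cM
        windows.append((c, lo, hi))
        mask |= (panel.chromosome == c) & (panel.position_cM >= lo) & (panel.position_cM <= hi)
    keep = np.flatnonzero(~mask)
    if keep.size == 0:
        raise ValueError("QTL mask removes every marker")
    k = additive_relationship(panel.subset(markers=keep), kind="additive_ab_masked")
    k.meta["masked_windows"] = windows
    return k
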