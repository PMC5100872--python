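"""Mixed-model engine: REML variance components, BLUP prediction, a mixed-model
GWAS with leave-one-chromosome-out kinship, the Li-Ji multiple-testing
threshold, and the four genomic prediction models (QTL, GBLUP, QGBLUP, RKHS).

All models share the linear mixed model y = X beta + sum_k u_k + e with
u_k ~ N(0, sigma2_k K_k) and e ~ N(0, sigma2_e I).  The single-kernel case is
solved exactly by a spectral decomposition and one-dimensional restricted
likelihood optimization over the variance ratio; multi-kernel models (QTL
terms plus a polygenic kernel) use EM-REML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .panel import MarkerPanel, TraitData
from .relatedness import (
    KinshipMatrix,
    RIDGE,
    additive_relationship,
    gaussian_kernel,
    qtl_masked_relationship,
)

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "QTLSet",
    "PredictionResult",
    "reml_fit",
    "predict_blup",
    "gwas_scan",
    "li_ji_threshold",
    "select_qtl",
    "fit_prediction_model",
    "tune_theta",
]

PREDICTION_MODELS = ("QTL", "GBLUP", "QGBLUP", "RKHS")
DEFAULT_THETA_GRID = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


@dataclass
class MixedModelSpec:
    """y = X beta + sum_k Z u_k + e with u_k ~ N(0, sigma2_k K_k)."""

    y: np.ndarray                  # training phenotypes, one record per row
    X: np.ndarray                  # fixed design (intercept first)
    Z: np.ndarray                  # record x genotype incidence
    kernels: list                  # [(label, K genotype x genotype)]
    genotype_ids: list

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X/Z row count does not match y")
        m = self.Z.shape[1]
        for label, k in self.kernels:
            if k.shape != (m, m):
                raise ValueError(f"kernel {label!r} does not match Z columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient")

    def record_kernels(self) -> list:
        """Kernels projected into record space, Z K Z'."""
        return [(label, self.Z @ k @ self.Z.T) for label, k in self.kernels]


@dataclass
class VarianceComponents:
    sigma2: dict                   # label -> variance
    sigma2_e: float
    loglik: float
    converged: bool = True
    degenerate: bool = False

    @property
    def lambda_ratio(self) -> float:
        """Residual-to-genetic variance ratio for the first genetic term."""
        sg = next(iter(self.sigma2.values()))
        return np.inf if sg <= 0 else self.sigma2_e / sg


@dataclass
class QTLSet:
    marker_ids: list = field(default_factory=list)
    chromosomes: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    pvalues: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position_cM": self.positions,
                "p_value": self.pvalues if self.pvalues else np.nan,
            }
        )


@dataclass
class PredictionResult:
    model: str
    predictions: "pd.Series"       # predicted genotypic value per calibration genotype
    vc: VarianceComponents
    theta: float | None = None
    qtl: QTLSet | None = None


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_neg2_profile(log_ratio, d, yt, xt):
    """-2 x restricted log-likelihood profiled over sigma2_e, as a function of
    log10(sigma2_g / sigma2_e) on the spectral axis."""
    gamma = 10.0 ** log_ratio
    w = gamma * d + 1.0
    n, p = xt.shape
    xw = xt / w[:, None]
    xtx = xt.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yt)
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    sigma2_e = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    return ((n - p) * (np.log(sigma2_e) + 1.0) + np.sum(np.log(w)) + logdet_xtx), sigma2_e, beta


def _fit_single_kernel(spec: MixedModelSpec) -> VarianceComponents:
    label, m = spec.record_kernels()[0]
    m = (m + m.T) / 2.0
    d, u = np.linalg.eigh(m)
    d = np.clip(d, 0.0, None)
    yt = u.T @ spec.y
    xt = u.T @ spec.X

    # aliasing: kernel indistinguishable from a multiple of the identity
    scale = np.mean(d) if np.mean(d) > 0 else 1.0
    degenerate = np.max(np.abs(d - np.mean(d))) < 1e-8 * max(scale, 1.0)

    grid = np.linspace(-6.0, 6.0, 49)
    vals = [_reml_neg2_profile(g, d, yt, xt)[0] for g in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: _reml_neg2_profile(g, d, yt, xt)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    neg2, sigma2_e, _ = _reml_neg2_profile(res.x, d, yt, xt)
    gamma = 10.0 ** float(res.x)
    return VarianceComponents(
        sigma2={label: gamma * sigma2_e},
        sigma2_e=sigma2_e,
        loglik=-0.5 * neg2,
        converged=bool(res.success),
        degenerate=bool(degenerate),
    )


def _fit_em(spec: MixedModelSpec, max_iter: int = 500, tol: float = 1e-6) -> VarianceComponents:
    kernels = [(label, (m + m.T) / 2.0) for label, m in spec.record_kernels()]
    labels = [label for label, _ in kernels]
    # identical kernels make the components unidentifiable
    degenerate = any(
        np.allclose(kernels[i][1], kernels[j][1], atol=1e-10)
        for i in range(len(kernels))
        for j in range(i + 1, len(kernels))
    )
    y, x = spec.y, spec.X
    n = y.size
    vy = float(np.var(y)) or 1.0
    sig = np.full(len(kernels), vy / (len(kernels) + 1))
    sig_e = vy / (len(kernels) + 1)
    converged = False
    loglik = -np.inf
    eye = np.eye(n)
    for _ in range(max_iter):
        v = sig_e * eye
        for s, (_, m) in zip(sig, kernels):
            v += s * m
        v[np.diag_indices(n)] += RIDGE
        try:
            f = cho_factor(v, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            v += 1e-6 * eye
            f = cho_factor(v, lower=True, check_finite=False)
        vi_x = cho_solve(f, x, check_finite=False)
        xtvix = x.T @ vi_x
        vi_y = cho_solve(f, y, check_finite=False)
        beta = np.linalg.solve(xtvix, x.T @ vi_y)
        # P y and tr(P K) for each component
        py = vi_y - vi_x @ np.linalg.solve(xtvix, vi_x.T @ y)
        vi = cho_solve(f, eye, check_finite=False)
        p_mat = vi - vi_x @ np.linalg.solve(xtvix, vi_x.T)
        new = np.empty_like(sig)
        for i, (_, m) in enumerate(kernels):
            quad = float(py @ m @ py)
            new[i] = max(sig[i] + sig[i] ** 2 * (quad - np.trace(p_mat @ m)) / n, 1e-12)
        quad_e = float(py @ py)
        new_e = max(sig_e + sig_e ** 2 * (quad_e - np.trace(p_mat)) / n, 1e-12)
        rel = np.max(np.abs(np.append(new - sig, new_e - sig_e))
                     / np.maximum(np.append(sig, sig_e), 1e-12))
        sig, sig_e = new, new_e
        if rel < tol:
            converged = True
            break
    # restricted log-likelihood at the final point
    v = sig_e * eye
    for s, (_, m) in zip(sig, kernels):
        v += s * m
    v[np.diag_indices(n)] += RIDGE
    sign, logdet_v = np.linalg.slogdet(v)
    vi_x = np.linalg.solve(v, x)
    xtvix = x.T @ vi_x
    sign2, logdet_x = np.linalg.slogdet(xtvix)
    beta = np.linalg.solve(xtvix, vi_x.T @ y)
    resid = y - x @ beta
    loglik = -0.5 * (logdet_v + logdet_x + float(resid @ np.linalg.solve(v, resid)))
    return VarianceComponents(
        sigma2=dict(zip(labels, sig.tolist())),
        sigma2_e=float(sig_e),
        loglik=float(loglik),
        converged=converged,
        degenerate=bool(degenerate),
    )


def reml_fit(spec: MixedModelSpec) -> VarianceComponents:
    """Estimate variance components by REML.

    One kernel: exact spectral path.  Several kernels: EM-REML (max 500
    iterations, relative change < 1e-6).  Non-convergence and
    unidentifiable (aliased) kernels are flagged, not raised.
    """
    if spec.y.size < 10:
        raise ValueError("REML needs at least 10 records")
    if len(spec.kernels) == 1:
        return _fit_single_kernel(spec)
    return _fit_em(spec)


def predict_blup(spec: MixedModelSpec, vc: VarianceComponents) -> "pd.Series":
    """Genotypic-value BLUPs for every calibration genotype.

    Fixed effects by GLS at the REML variance components, then
    g_hat = sum_k sigma2_k K_k Z' V^-1 (y - X beta_hat); the returned
    prediction is beta_intercept + g_hat.
    """
    n = spec.y.size
    v = vc.sigma2_e * np.eye(n)
    for (label, k_rec) in spec.record_kernels():
        v += vc.sigma2[label] * k_rec
    v[np.diag_indices(n)] += RIDGE
    try:
        f = cho_factor(v, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        v += 1e-6 * np.eye(n)
        f = cho_factor(v, lower=True, check_finite=False)
    vi_x = cho_solve(f, spec.X, check_finite=False)
    beta = np.linalg.solve(spec.X.T @ vi_x, vi_x.T @ spec.y)
    resid = spec.y - spec.X @ beta
    vi_r = cho_solve(f, resid, check_finite=False)
    g = np.zeros(spec.Z.shape[1])
    for (label, k) in spec.kernels:
        g += vc.sigma2[label] * (k @ (spec.Z.T @ vi_r))
    return pd.Series(beta[0] + g, index=[str(i) for i in spec.genotype_ids])


# ---------------------------------------------------------------------------
# GWAS and QTL selection
# ---------------------------------------------------------------------------


def _training_spec(panel: MarkerPanel, trait: TraitData, training_ids,
                   kernels) -> MixedModelSpec:
    train = [str(g) for g in training_ids]
    y = trait.aligned(train)
    gi = panel.genotype_index(train)
    z = np.zeros((len(train), panel.n_genotypes))
    z[np.arange(len(train)), gi] = 1.0
    x = np.ones((len(train), 1))
    return MixedModelSpec(y, x, z, kernels, panel.genotype_ids)


def gwas_scan(panel: MarkerPanel, trait: TraitData, loco: dict,
              training_ids) -> "pd.Series":
    """Single-marker mixed-model association scan on the training set.

    For marker k on chromosome c the model is y = mu + x_k alpha_k + G + e
    with G ~ N(0, A_loco(c) sigma2_g).  Variance components are estimated
    once per chromosome under the null model and reused for every marker on
    that chromosome; alpha_k is tested by a 1-df Wald chi-square.  Markers
    monomorphic within the training set get a missing p-value.
    """
    train = [str(g) for g in training_ids]
    y = trait.aligned(train)
    gi = panel.genotype_index(train)
    nt = len(train)
    ones = np.ones(nt)
    pvals = np.full(panel.n_markers, np.nan)
    for chrom, kin in loco.items():
        cols = np.flatnonzero(panel.chromosome == chrom)
        if cols.size == 0:
            continue
        k_tt = kin.submatrix(train)
        spec = MixedModelSpec(y, ones[:, None], np.eye(nt), [("g", k_tt)], train)
        vc = reml_fit(spec)
        sg = next(iter(vc.sigma2.values()))
        v = sg * k_tt + vc.sigma2_e * np.eye(nt)
        v[np.diag_indices(nt)] += RIDGE
        f = cho_factor(v, lower=True, check_finite=False)
        xmat = panel.dosage[np.ix_(gi, cols)].astype(float)
        poly = xmat.std(axis=0) > 0
        vi_1 = cho_solve(f, ones, check_finite=False)
        vi_y = cho_solve(f, y, check_finite=False)
        vi_x = cho_solve(f, xmat, check_finite=False)
        s11 = float(ones @ vi_1)
        s1y = float(ones @ vi_y)
        s1x = ones @ vi_x
        sxx = np.einsum("ij,ij->j", xmat, vi_x)
        sxy = xmat.T @ vi_y
        det = s11 * sxx - s1x ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = (s11 * sxy - s1x * s1y) / det
            var_alpha = s11 / det
            wald = alpha ** 2 / var_alpha
        p = stats.chi2.sf(wald, df=1)
        p[~poly] = np.nan
        pvals[cols] = p
    return pd.Series(pvals, index=panel.marker_ids)


def li_ji_threshold(panel: MarkerPanel, genomewide_alpha: float = 0.01,
                    training_ids=None) -> float:
    """Per-test p threshold from the Li-Ji effective number of tests.

    M_eff is computed per chromosome from the eigenvalues of the marker
    correlation matrix via f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)),
    summed over chromosomes; the threshold is 1 - (1 - alpha)^(1/M_eff).
    """
    if panel.n_markers < 2:
        raise ValueError("need at least 2 markers")
    if training_ids is not None:
        panel = panel.subset(genotypes=panel.genotype_index(training_ids))
    m_eff = 0.0
    for chrom in pd.unique(panel.chromosome):
        cols = np.flatnonzero(panel.chromosome == chrom)
        x = panel.dosage[:, cols].astype(float)
        sd = x.std(axis=0)
        x = x[:, sd > 0]
        if x.shape[1] == 0:
            continue
        if x.shape[1] == 1:
            m_eff += 1.0
            continue
        corr = np.corrcoef(x, rowvar=False)
        if not np.all(np.isfinite(corr)):
            raise ValueError("degenerate marker correlation matrix")
        eig = np.linalg.eigvalsh(corr)
        eig = np.round(np.clip(eig, 0.0, None), 8)
        m_eff += float(np.sum((eig >= 1.0) + (eig - np.floor(eig))))
    if m_eff <= 0:
        raise ValueError("degenerate marker correlation matrix")
    return float(1.0 - (1.0 - genomewide_alpha) ** (1.0 / m_eff))


def select_qtl(pvalues: "pd.Series", threshold: float, panel: MarkerPanel,
               peak_window_cM: float = 20.0, forced_markers=None) -> QTLSet:
    """Threshold p-values and greedily collapse peaks within a cM window.

    Within each chromosome the smallest-p significant marker is kept and
    other significant markers within +/- peak_window_cM of it are dropped,
    repeating on the remainder.  ``forced_markers`` are always included (a
    known-locus list can be supplied even when nothing reaches the
    threshold).
    """
    pos = pd.Series(panel.position_cM, index=panel.marker_ids)
    chrom = pd.Series(panel.chromosome, index=panel.marker_ids)
    sig = pvalues[pvalues.notna() & (pvalues <= threshold)]
    kept = []
    for c in pd.unique(chrom.loc[sig.index]) if len(sig) else []:
        cand = sig[chrom.loc[sig.index] == c].sort_values()
        while len(cand):
            top = cand.index[0]
            kept.append(top)
            near = np.abs(pos.loc[cand.index] - pos.loc[top]) <= peak_window_cM
            cand = cand[~near.to_numpy()]
    for m in forced_markers or []:
        m = str(m)
        if m not in pos.index:
            raise KeyError(f"forced marker {m!r} not on the panel map")
        if m not in kept:
            kept.append(m)
    return QTLSet(
        marker_ids=list(kept),
        chromosomes=[str(chrom.loc[m]) for m in kept],
        positions=[float(pos.loc[m]) for m in kept],
        pvalues=[float(pvalues.get(m, np.nan)) for m in kept],
    )


# ---------------------------------------------------------------------------
# Prediction models
# ---------------------------------------------------------------------------


def _qtl_kernels(panel: MarkerPanel, qtl: QTLSet) -> list:
    """One rank-one kernel x_q x_q' per QTL, each carrying its own variance."""
    kernels = []
    for m in qtl.marker_ids:
        j = panel.marker_ids.index(str(m))
        x = panel.dosage[:, j].astype(float)
        x = x - x.mean()
        kernels.append((f"qtl:{m}", np.outer(x, x)))
    return kernels


def fit_prediction_model(model: str, trait: TraitData, panel: MarkerPanel,
                         training_ids, qtl: QTLSet | None = None,
                         A: KinshipMatrix | None = None,
                         theta: float | None = None,
                         theta_grid=DEFAULT_THETA_GRID,
                         mask_window_cM: float = 20.0,
                         tune_seed: int = 0) -> PredictionResult:
    """Fit one of the four prediction models and predict all calibration genotypes.

    QTL: one random effect per detected QTL marker, each with its own
    variance.  GBLUP: a single additive-relationship kernel.  QGBLUP: QTL
    terms plus a polygenic kernel computed with markers within
    +/- mask_window_cM of a QTL removed.  RKHS: a Gaussian kernel with
    bandwidth theta, tuned by cross-validation inside the training set when
    not supplied.
    """
    if model not in PREDICTION_MODELS:
        raise ValueError(f"model must be one of {PREDICTION_MODELS}")
    kernels = []
    used_theta = None
    if model in ("QTL", "QGBLUP"):
        if qtl is None or len(qtl) == 0:
            if model == "QTL":
                raise ValueError(
                    "QTL model requested with an empty QTL set; "
                    "detect QTL first or drop this model for the trait"
                )
            qtl = QTLSet()
        kernels.extend(_qtl_kernels(panel, qtl))
    if model == "GBLUP":
        a = A if A is not None else additive_relationship(panel)
        kernels.append(("polygenic", a.values))
    elif model == "QGBLUP":
        if len(qtl):
            a_m = qtl_masked_relationship(panel, qtl, window_cM=mask_window_cM)
        else:
            a_m = A if A is not None else additive_relationship(panel)
        kernels.append(("polygenic", a_m.values))
    elif model == "RKHS":
        used_theta = theta if theta is not None else tune_theta(
            trait, panel, training_ids, theta_grid, seed=tune_seed)
        kernels.append(("rkhs", gaussian_kernel(panel, used_theta).values))

    spec = _training_spec(panel, trait, training_ids, kernels)
    vc = reml_fit(spec)
    preds = predict_blup(spec, vc)
    return PredictionResult(model=model, predictions=preds, vc=vc,
                           theta=used_theta, qtl=qtl if model in ("QTL", "QGBLUP") else None)


def tune_theta(trait: TraitData, panel: MarkerPanel, training_ids,
               theta_grid=DEFAULT_THETA_GRID, seed: int = 0,
               n_folds: int = 5) -> float:
    """Pick the Gaussian-kernel bandwidth by k-fold CV inside the training set.

    The theta maximizing mean fold predictive ability wins; ties go to the
    smallest theta.
    """
    grid = sorted(float(t) for t in theta_grid)
    if not grid:
        raise ValueError("theta grid is empty")
    if len(grid) == 1:
        return grid[0]
    train = [str(g) for g in training_ids]
    if len(train) < 15:
        raise ValueError("training set too small to cross-validate theta (< 15)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    folds = np.array_split(order, n_folds)
    scores = []
    for th in grid:
        kernel = gaussian_kernel(panel, th)
        rs = []
        for fold in folds:
            hold = set(int(i) for i in fold)
            sub_train = [train[i] for i in range(len(train)) if i not in hold]
            sub_valid = [train[i] for i in sorted(hold)]
            spec = _training_spec(panel, trait, sub_train, [("rkhs", kernel.values)])
            vc = reml_fit(spec)
            preds = predict_blup(spec, vc)
            obs = trait.aligned(sub_valid)
            pv = preds.loc[sub_valid].to_numpy()
            if np.std(obs) > 0 and np.std(pv) > 0:
                rs.append(float(np.corrcoef(obs, pv)[0, 1]))
        scores.append(np.mean(rs) if rs else -np.inf)
    scores = np.asarray(scores)
    best = scores.max()
    # smallest theta within numerical tie of the best
    return float(grid[int(np.flatnonzero(scores >= best - 1e-12)[0])])
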