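"""Genotype panels: loading, validation, filtering, and imputation.

The canonical dosage coding is {0, 1, 2} counts of the reference allele,
with -1 as the missing sentinel.  The {0, 0.5, 1} score matrix used by the
identity-by-state computation is obtained downstream by the fixed transform
``dosage / 2`` and is never stored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerPanel",
    "TraitData",
    "FilterReport",
    "load_panel",
    "write_panel",
    "load_traits",
    "filter_panel",
    "impute_missing",
    "allele_frequencies",
]


@dataclass
class MarkerPanel:
    """A genotype-by-marker dosage matrix with a genetic (cM) map.

    Parameters
    ----------
    genotype_ids : list of str
        Unique genotype labels, one per matrix row.
    marker_ids : list of str
        Unique marker labels, one per matrix column.
    chromosome : ndarray of str
        Linkage-group label per marker.
    position_cM : ndarray of float
        Map position per marker in centimorgans (non-negative).
    dosage : ndarray of int8
        Allele dosages in {0, 1, 2}; missing entries carry ``MISSING``.
    """

    genotype_ids: list
    marker_ids: list
    chromosome: np.ndarray
    position_cM: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.genotype_ids = list(map(str, self.genotype_ids))
        self.marker_ids = list(map(str, self.marker_ids))
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, k = self.dosage.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != k:
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("duplicate genotype ids")
        if len(set(self.marker_ids)) != k:
            raise ValueError("duplicate marker ids")
        if self.chromosome.shape != (k,) or self.position_cM.shape != (k,):
            raise ValueError("map arrays do not match marker count")
        if np.any(self.position_cM < 0) or not np.all(np.isfinite(self.position_cM)):
            raise ValueError("map positions must be finite and non-negative")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        """K, the total number of markers."""
        return len(self.marker_ids)

    @property
    def has_missing(self) -> bool:
        return bool((self.dosage == MISSING).any())

    def genotype_index(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return np.array([lookup[str(g)] for g in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"genotype {e} not in panel") from None

    def subset(self, genotypes=None, markers=None) -> "MarkerPanel":
        """Return a new panel restricted to the given genotype / marker indices."""
        gi = np.arange(self.n_genotypes) if genotypes is None else np.asarray(genotypes)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return MarkerPanel(
            [self.genotype_ids[i] for i in gi],
            [self.marker_ids[j] for j in mi],
            self.chromosome[mi],
            self.position_cM[mi],
            self.dosage[np.ix_(gi, mi)],
        )

    def scores(self) -> np.ndarray:
        """Dosages on the {0, 0.5, 1} score scale (requires an imputed panel)."""
        if self.has_missing:
            raise ValueError("panel has missing calls; impute first")
        return self.dosage.astype(float) / 2.0


@dataclass
class TraitData:
    """Adjusted-mean phenotypes for (a subset of) panel genotypes."""

    trait_name: str
    values: "pd.Series"

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.map(str)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"trait {self.trait_name!r} has non-finite values")

    def aligned(self, ids) -> np.ndarray:
        return self.values.loc[[str(i) for i in ids]].to_numpy()


@dataclass
class FilterReport:
    """Per-rule removal counts for one ``filter_panel`` pass."""

    n_genotypes_in: int
    n_markers_in: int
    removed: dict = field(default_factory=dict)
    n_genotypes_out: int = 0
    n_markers_out: int = 0

    GENOTYPE_RULES = ("genotype_missing_rate", "genotype_heterozygosity")
    MARKER_RULES = ("marker_missing_rate", "monomorphic", "maf")

    def check_conservation(self) -> bool:
        g_removed = sum(self.removed.get(r, 0) for r in self.GENOTYPE_RULES)
        m_removed = sum(self.removed.get(r, 0) for r in self.MARKER_RULES)
        return (
            self.n_genotypes_in - g_removed == self.n_genotypes_out
            and self.n_markers_in - m_removed == self.n_markers_out
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_map(map_path) -> pd.DataFrame:
    mp = pd.read_csv(map_path)
    cols = {c.lower(): c for c in mp.columns}
    for want in ("marker_id", "chromosome"):
        if want not in cols:
            raise ValueError(f"map file lacks a {want!r} column")
    pos_col = next((cols[c] for c in ("position_cm", "cm", "pos_cm") if c in cols), None)
    if pos_col is None:
        raise ValueError("map file lacks a centimorgan position column (position_cM)")
    out = pd.DataFrame(
        {
            "marker_id": mp[cols["marker_id"]].astype(str),
            "chromosome": mp[cols["chromosome"]].astype(str),
            "position_cM": mp[pos_col].astype(float),
        }
    )
    return out.set_index("marker_id")


def load_panel(path, format: str = "csv", map_path=None) -> MarkerPanel:
    """Load a genotype panel from CSV or PLINK ``.raw`` dialect.

    CSV: first column genotype id, remaining columns marker dosages.
    PLINK raw: whitespace-delimited with the standard six metadata columns;
    marker columns named ``<marker>_<allele>``.  Unknown tokens become the
    missing sentinel.  The marker map (marker_id, chromosome, position_cM)
    comes from ``map_path``.
    """
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.map(str)
        marker_ids = [str(c) for c in df.columns]
        geno_ids = list(df.index)
        raw = df.to_numpy()
    elif format == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"not a PLINK .raw file: missing {missing_meta}")
        geno_ids = df["IID"].astype(str).tolist()
        data = df.drop(columns=_PLINK_META)
        marker_ids = [c.rsplit("_", 1)[0] for c in data.columns]
        raw = data.to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")

    dosage = np.full(raw.shape, MISSING, dtype=np.int8)
    numeric = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    ok = np.isfinite(numeric) & np.isin(numeric, (0.0, 1.0, 2.0))
    dosage.ravel()[ok] = numeric[ok].astype(np.int8)

    if map_path is None:
        raise ValueError("a marker map file is required (marker_id, chromosome, position_cM)")
    mp = _read_map(map_path)
    absent = [m for m in marker_ids if m not in mp.index]
    if absent:
        raise ValueError(f"markers absent from map: {absent[:5]}{'...' if len(absent) > 5 else ''}")
    mp = mp.loc[marker_ids]
    return MarkerPanel(geno_ids, marker_ids, mp["chromosome"].to_numpy(),
                       mp["position_cM"].to_numpy(), dosage)


def write_panel(panel: MarkerPanel, path, map_path) -> None:
    """Write a panel as genotype CSV + map CSV such that write∘load is identity."""
    df = pd.DataFrame(panel.dosage, index=panel.genotype_ids, columns=panel.marker_ids)
    df = df.astype(object).where(df != MISSING, "NA")
    df.index.name = "genotype_id"
    df.to_csv(path)
    pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chromosome": panel.chromosome,
            "position_cM": panel.position_cM,
        }
    ).to_csv(map_path, index=False)


def load_traits(path) -> dict:
    """Load a phenotype CSV (genotype_id, one column per trait) into TraitData."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    out = {}
    for col in df.columns:
        vals = df[col].dropna()
        out[str(col)] = TraitData(str(col), vals)
    return out


# ---------------------------------------------------------------------------
# Allele frequencies and filtering
# ---------------------------------------------------------------------------


def allele_frequencies(panel: MarkerPanel) -> np.ndarray:
    """Per-marker reference-allele frequency on observed (non-missing) calls.

    Markers with no observed calls yield NaN.
    """
    obs = panel.dosage != MISSING
    counts = obs.sum(axis=0)
    totals = np.where(obs, panel.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, totals / np.maximum(counts, 1) / 2.0, np.nan)


def filter_panel(
    panel: MarkerPanel,
    max_geno_missing: float = 0.10,
    max_geno_het: float = 0.05,
    max_marker_missing: float = 0.25,
    maf_min: float = 0.05,
    drop_monomorphic: bool = True,
) -> tuple:
    """Apply genotype filters, then marker filters (monomorphic before MAF).

    Each rule is counted against the panel state at the time it runs, so
    the report's per-axis counts are exactly conservative.  Allele
    frequencies are recomputed on the surviving genotypes before the
    marker rules run.
    """
    for name, t in (
        ("max_geno_missing", max_geno_missing),
        ("max_geno_het", max_geno_het),
        ("max_marker_missing", max_marker_missing),
        ("maf_min", maf_min),
    ):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    report = FilterReport(panel.n_genotypes, panel.n_markers)
    miss = panel.dosage == MISSING

    # genotype rules, against the original marker set
    geno_missing_rate = miss.mean(axis=1)
    keep_g = geno_missing_rate <= max_geno_missing
    report.removed["genotype_missing_rate"] = int((~keep_g).sum())

    obs = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(obs > 0, (panel.dosage == 1).sum(axis=1) / np.maximum(obs, 1), 1.0)
    drop_het = keep_g & (het_rate > max_geno_het)
    report.removed["genotype_heterozygosity"] = int(drop_het.sum())
    keep_g &= ~drop_het

    work = panel.subset(genotypes=np.flatnonzero(keep_g))

    # marker rules, recomputed on surviving genotypes
    miss = work.dosage == MISSING
    keep_m = miss.mean(axis=0) <= max_marker_missing if work.n_genotypes else np.zeros(work.n_markers, bool)
    report.removed["marker_missing_rate"] = int((~keep_m).sum())

    p = allele_frequencies(work)
    mono = keep_m & ((p == 0.0) | (p == 1.0) | ~np.isfinite(p))
    if drop_monomorphic:
        report.removed["monomorphic"] = int(mono.sum())
        keep_m &= ~mono
    else:
        report.removed["monomorphic"] = 0

    maf = np.minimum(p, 1.0 - p)
    low = keep_m & (maf < maf_min)
    report.removed["maf"] = int(low.sum())
    keep_m &= ~low

    out = work.subset(markers=np.flatnonzero(keep_m))
    report.n_genotypes_out = out.n_genotypes
    report.n_markers_out = out.n_markers
    if out.n_markers == 0:
        raise ValueError(f"all markers removed by filtering; report: {report}")
    return out, report


def impute_missing(panel: MarkerPanel, mode: str = "expected_dosage", seed: int = 0) -> MarkerPanel:
    """Fill missing calls from per-marker allele frequencies.

    ``expected_dosage`` fills round(2*p_hat); ``bernoulli_draw`` samples
    dosage = 2*Bernoulli(p_hat), the inbred-line convention.  Both are
    deterministic under ``seed``.
    """
    if not panel.has_missing:
        return panel
    p = allele_frequencies(panel)
    miss = panel.dosage == MISSING
    fully = np.flatnonzero(~np.isfinite(p) & miss.any(axis=0))
    if fully.size:
        raise ValueError(
            f"marker(s) fully missing (filter first): {[panel.marker_ids[j] for j in fully[:5]]}"
        )
    dosage = panel.dosage.copy()
    gi, mi = np.nonzero(miss)
    if mode == "expected_dosage":
        fill = np.rint(2.0 * p[mi]).astype(np.int8)
    elif mode == "bernoulli_draw":
        rng = np.random.default_rng(seed)
        fill = (2 * rng.binomial(1, p[mi])).astype(np.int8)
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    dosage[gi, mi] = fill
    return MarkerPanel(panel.genotype_ids, panel.marker_ids, panel.chromosome,
                       panel.position_cM, dosage)
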