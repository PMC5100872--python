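"""Training-set construction: U, SU, CD, S and R sampling.

U draws genotypes one at a time at random and discards every remaining
candidate within a sampling radius r of the draw (distance = 1 - IBS), so
the training set covers the genetic space at roughly uniform density.  SU
adds strata: a candidate inside the radius survives if it belongs to a
different stratum, guaranteeing every stratum at least one entry.  CD
maximizes the mean generalized coefficient of determination of the
validation contrasts by single-genotype exchanges.  S allocates the
training set across strata proportionally to log group size; R is plain
random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .relatedness import KinshipMatrix, RIDGE
from .structure import SubpopulationAssignment

__all__ = [
    "TrainingSplit",
    "CDContext",
    "find_radius",
    "sample_uniform",
    "cd_mean",
    "sample_cd",
    "sample_stratified",
    "sample_random",
    "nearest_entry_distances",
    "representation_table",
    "plot_nearest_entry_distances",
]


@dataclass
class TrainingSplit:
    """A training/validation partition of the calibration set."""

    method: str                    # U | SU | CD | S | R
    training_ids: list
    validation_ids: list
    seed: int
    radius: float | None = None    # U / SU only
    cd_trace: list = field(default_factory=list)  # CD only

    def __post_init__(self):
        self.training_ids = [str(g) for g in self.training_ids]
        self.validation_ids = [str(g) for g in self.validation_ids]
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError("training and validation sets overlap")

    @property
    def calibration_ids(self) -> list:
        return self.training_ids + self.validation_ids

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "training") for g in self.training_ids]
        rows += [(g, "validation") for g in self.validation_ids]
        df = pd.DataFrame(rows, columns=["genotype_id", "role"])
        df["method"] = self.method
        df["seed"] = self.seed
        df["radius"] = self.radius if self.radius is not None else np.nan
        return df


def _distance(k_ibs: KinshipMatrix) -> np.ndarray:
    if k_ibs.kind != "ibs":
        raise ValueError("sampling distances are defined on an IBS kinship")
    return 1.0 - k_ibs.values


def _uniform_pass(dist: np.ndarray, r: float, rng, strata: np.ndarray | None) -> list:
    """One full U/SU pass: sample until the candidate pool is exhausted."""
    n = dist.shape[0]
    pool = np.ones(n, dtype=bool)
    chosen = []
    while pool.any():
        cand = np.flatnonzero(pool)
        pick = int(rng.choice(cand))
        chosen.append(pick)
        pool[pick] = False
        near = dist[pick] < r
        if strata is not None:
            near &= strata == strata[pick]
        pool &= ~near
    return chosen


def find_radius(k_ibs: KinshipMatrix, target_size: int, n_probe_seeds: int = 20,
                strata: np.ndarray | None = None) -> float:
    """Largest sampling radius whose expected U yield reaches target_size.

    Candidate radii are midpoints of the sorted unique pairwise-distance
    grid (plus one value below the minimum and one above the maximum
    distance); the expected yield at a radius is the median training-set
    size over ``n_probe_seeds`` probe passes.  Yield is non-increasing in
    r, so a bisection over the grid finds the largest admissible radius.
    """
    n = k_ibs.n
    if not 1 <= target_size <= n:
        raise ValueError(f"target_size must lie in [1, {n}]")
    dist = _distance(k_ibs)
    iu = np.triu_indices(n, k=1)
    uniq = np.unique(dist[iu])
    uniq = uniq[uniq > 0]
    if uniq.size == 0:
        raise ValueError("all pairwise distances are zero")
    candidates = np.concatenate([[uniq[0] / 2.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] * (1.0 + 1e-9) + 1e-12]])

    def expected_yield(r: float) -> float:
        sizes = [len(_uniform_pass(dist, r, np.random.default_rng(10_000 + s), strata))
                 for s in range(n_probe_seeds)]
        return float(np.median(sizes))

    lo, hi = 0, candidates.size - 1
    if expected_yield(candidates[hi]) >= target_size:
        return float(candidates[hi])
    # invariant: yield(candidates[lo]) >= target > yield(candidates[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_yield(candidates[mid]) >= target_size:
            lo = mid
        else:
            hi = mid
    return float(candidates[lo])


def sample_uniform(k_ibs: KinshipMatrix, target_size: int, seed: int,
                   strata: SubpopulationAssignment | None = None,
                   radius: float | None = None,
                   max_retries: int = 100) -> TrainingSplit:
    """Draw a U (or, with strata, SU) training set of exactly target_size.

    A pass samples random candidates and discards those within the radius
    (U) or within the radius and in the same stratum (SU).  A pass that
    overshoots is trimmed uniformly at random to the target; a pass that
    falls short (the radius is calibrated on median yield) is redrawn, and
    after ``max_retries`` shortfalls the radius steps down the distance
    grid.
    """
    dist = _distance(k_ibs)
    n = k_ibs.n
    if not 1 <= target_size <= n:
        raise ValueError(f"target_size must lie in [1, {n}]")
    strata_arr = None
    if strata is not None:
        strata_arr = strata.of(k_ibs.genotype_ids)
    r = find_radius(k_ibs, target_size, strata=strata_arr) if radius is None else float(radius)
    if r <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    chosen = None
    for _ in range(max_retries):
        attempt = _uniform_pass(dist, r, rng, strata_arr)
        if len(attempt) >= target_size:
            chosen = attempt
            break
    if chosen is None:
        # persistent shortfall: relax the radius one unique-distance step
        iu = np.triu_indices(n, k=1)
        uniq = np.unique(dist[iu])
        smaller = uniq[uniq < r]
        if smaller.size == 0:
            raise ValueError("cannot reach target_size even with the minimal radius")
        return sample_uniform(k_ibs, target_size, seed + 1, strata=strata,
                              radius=float(smaller[-1]) * 0.999, max_retries=max_retries)
    if len(chosen) > target_size:
        chosen = list(rng.choice(chosen, size=target_size, replace=False))
    ids = np.asarray(k_ibs.genotype_ids, dtype=object)
    train = set(int(i) for i in chosen)
    method = "U" if strata is None else "SU"
    return TrainingSplit(method, list(ids[sorted(train)]),
                         [g for i, g in enumerate(ids) if i not in train],
                         seed=seed, radius=r)


# ---------------------------------------------------------------------------
# CD criterion
# ---------------------------------------------------------------------------


@dataclass
class CDContext:
    """Fixed quantities for generalized-CD evaluation over a calibration set.

    The contrast for each validation genotype i is e_i - (1/n) 1 over all n
    calibration genotypes; lambda is the residual-to-additive variance
    ratio, (1 - h2)/h2.
    """

    A: np.ndarray                 # calibration-set additive relationship
    genotype_ids: list
    lam: float
    A_inv: np.ndarray = field(init=False)

    def __post_init__(self):
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        n = len(self.genotype_ids)
        if self.A.shape != (n, n):
            raise ValueError("A does not match the id list")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        self.A_inv = np.linalg.inv(self.A + RIDGE * np.eye(n))

    @classmethod
    def from_kinship(cls, A: KinshipMatrix, lam: float | None = None,
                     h2: float = 0.85) -> "CDContext":
        if lam is None:
            if not 0 < h2 <= 1:
                raise ValueError("h2 must lie in (0, 1]")
            lam = (1.0 - h2) / h2
        return cls(A.values.copy(), list(A.genotype_ids), float(lam))

    def index_of(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        return np.array([lookup[str(g)] for g in ids], dtype=int)


def _cd_values(ctx: CDContext, train_idx: np.ndarray, valid_idx: np.ndarray) -> np.ndarray:
    """CD(c) = diag[c'(A - lam (Z'MZ + lam A^-1)^-1) c / c'Ac] per validation contrast."""
    n = len(ctx.genotype_ids)
    t = train_idx.size
    c = -np.ones((n, valid_idx.size)) / n
    c[valid_idx, np.arange(valid_idx.size)] += 1.0

    ac = ctx.A @ c
    denom = np.einsum("ij,ij->j", c, ac)
    if ctx.lam == 0.0:
        return np.ones(valid_idx.size)

    # Z'MZ in calibration coordinates: diag(train indicator) - (1/t) z z'
    z = np.zeros(n)
    z[train_idx] = 1.0
    b = ctx.lam * ctx.A_inv + np.diag(z) - np.outer(z, z) / t
    b[np.diag_indices(n)] += RIDGE
    try:
        f = cho_factor(b, lower=True, check_finite=False)
        binv_c = cho_solve(f, c, check_finite=False)
    except np.linalg.LinAlgError:
        binv_c = np.linalg.solve(b + 1e-6 * np.eye(n), c)
    numer = denom - ctx.lam * np.einsum("ij,ij->j", c, binv_c)
    return numer / denom


def cd_mean(ctx: CDContext, training_ids, validation_ids=None) -> float:
    """Mean generalized CD over the validation contrasts."""
    train_idx = ctx.index_of(training_ids)
    if train_idx.size == 0:
        raise ValueError("training set is empty")
    if validation_ids is None:
        valid_idx = np.setdiff1d(np.arange(len(ctx.genotype_ids)), train_idx)
    else:
        valid_idx = ctx.index_of(validation_ids)
    return float(np.mean(_cd_values(ctx, train_idx, valid_idx)))


def sample_cd(A: KinshipMatrix, target_size: int, lam: float | None = None,
              h2: float = 0.85, seed: int = 0, max_sweeps: int = 800) -> TrainingSplit:
    """Exchange optimization of the mean CD over validation contrasts.

    Starts from a random training set and proposes random single
    training/validation exchanges, accepting only strict improvements;
    stops after ``max_sweeps`` proposals or when improvement stalls.
    """
    n = A.n
    if not 1 <= target_size < n:
        raise ValueError("CD needs 1 <= target_size < n")
    ctx = CDContext.from_kinship(A, lam=lam, h2=h2)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = perm[:target_size].copy()
    valid = perm[target_size:].copy()

    def objective(tr, va):
        return float(np.mean(_cd_values(ctx, np.sort(tr), np.sort(va))))

    current = objective(train, valid)
    trace = [current]
    stall_limit = max(200, 20 * n)
    stall = 0
    for _ in range(max_sweeps):
        if stall >= stall_limit:
            break
        ti = int(rng.integers(target_size))
        vi = int(rng.integers(n - target_size))
        train[ti], valid[vi] = valid[vi], train[ti]
        proposal = objective(train, valid)
        if proposal > current:
            current = proposal
            trace.append(current)
            stall = 0
        else:
            train[ti], valid[vi] = valid[vi], train[ti]
            stall += 1
    ids = np.asarray(ctx.genotype_ids, dtype=object)
    return TrainingSplit("CD", list(ids[np.sort(train)]), list(ids[np.sort(valid)]),
                         seed=seed, cd_trace=trace)


# ---------------------------------------------------------------------------
# Stratified and random sampling
# ---------------------------------------------------------------------------


def stratified_allocation(group_sizes: "pd.Series", target_size: int,
                          cap: bool = True) -> "pd.Series":
    """Log-proportional allocation n_{t,s} = n_t log(n_s) / sum_s log(n_s).

    Rounded by largest remainder so the allocation sums exactly to the
    target.  With ``cap`` (the default, required for the allocation to be
    sampleable) allocations are clipped at the group size and the overflow
    redistributed by remainder order; ``cap=False`` returns the literal
    formula's rounding even when it asks for more genotypes than a group
    holds.  The allocation is invariant to the logarithm base.  Singleton
    strata receive 0 under the literal formula (log 1 = 0).
    """
    sizes = pd.Series(group_sizes).astype(float)
    logs = np.log(sizes)
    total = logs.sum()
    if total <= 0:
        raise ValueError(
            "all strata are singletons (log sizes sum to 0); use random sampling instead"
        )
    quota = target_size * logs / total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    order = np.argsort(-remainder.to_numpy(), kind="stable")
    short = target_size - int(alloc.sum())
    for j in order[:short]:
        alloc.iloc[j] += 1
    if not cap:
        return alloc
    # cap at group size, redistribute overflow by remainder order
    for _ in range(len(sizes)):
        over = alloc - sizes.astype(int)
        excess = int(over[over > 0].sum())
        if excess == 0:
            break
        alloc = np.minimum(alloc, sizes.astype(int))
        room = sizes.astype(int) - alloc
        for j in order:
            if excess == 0:
                break
            take = min(excess, int(room.iloc[j]))
            alloc.iloc[j] += take
            excess -= take
    if int(alloc.sum()) != target_size:
        raise ValueError("target_size exceeds the calibration set")
    return alloc


def sample_stratified(assignment: SubpopulationAssignment, target_size: int,
                      seed: int = 0) -> TrainingSplit:
    """Stratified random sampling with log-proportional allocation."""
    n = len(assignment.labels)
    if target_size > n:
        raise ValueError("target_size exceeds the calibration set")
    alloc = stratified_allocation(assignment.group_sizes, target_size)
    rng = np.random.default_rng(seed)
    train = []
    for grp, ids in assignment.groups().items():
        k = int(alloc.get(grp, 0))
        if k:
            train.extend(rng.choice(np.asarray(ids, dtype=object), size=k, replace=False))
    train_set = set(map(str, train))
    valid = [g for g in assignment.labels.index if g not in train_set]
    return TrainingSplit("S", sorted(train_set), valid, seed=seed)


def sample_random(ids, target_size: int, seed: int = 0) -> TrainingSplit:
    """Uniform sampling without replacement."""
    ids = [str(g) for g in ids]
    if target_size > len(ids):
        raise ValueError("target_size exceeds the calibration set")
    rng = np.random.default_rng(seed)
    train = set(rng.choice(np.asarray(ids, dtype=object), size=target_size, replace=False))
    return TrainingSplit("R", sorted(train), [g for g in ids if g not in train], seed=seed)


# ---------------------------------------------------------------------------
# Split characterization
# ---------------------------------------------------------------------------


def nearest_entry_distances(k_ibs: KinshipMatrix, split: TrainingSplit) -> "pd.Series":
    """A-NE: distance (1 - IBS) from each validation genotype to its nearest training entry."""
    if not split.training_ids:
        raise ValueError("training set is empty")
    dist = _distance(k_ibs)
    ti = k_ibs.index_of(split.training_ids)
    vi = k_ibs.index_of(split.validation_ids)
    return pd.Series(dist[np.ix_(vi, ti)].min(axis=1), index=split.validation_ids)


def plot_nearest_entry_distances(distances_by_method: dict, bins=30, ax=None):
    """Overlaid histograms of validation-to-training distances per method.

    ``distances_by_method`` maps method name -> flat array of nearest-entry
    distances pooled over realizations.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, d in distances_by_method.items():
        ax.hist(np.asarray(d, dtype=float), bins=bins, histtype="step",
                density=True, label=method)
    ax.set_xlabel("distance to nearest training entry (1 - IBS)")
    ax.set_ylabel("density")
    ax.legend(title="method")
    return ax


def representation_table(splits_by_method: dict, assignment: SubpopulationAssignment) -> "pd.DataFrame":
    """Per-subpopulation training-set counts as % deviation from the R baseline.

    ``splits_by_method`` maps method name -> list of TrainingSplit
    realizations and must contain the "R" baseline.  Entries with a zero R
    baseline are NaN (flagged undefined).
    """
    if "R" not in splits_by_method:
        raise ValueError("representation table needs the R baseline splits")

    def mean_counts(splits):
        counts = [pd.Series(assignment.of(s.training_ids)).value_counts() for s in splits]
        return pd.DataFrame(counts).fillna(0.0).mean(axis=0)

    base = mean_counts(splits_by_method["R"])
    rows = {}
    for method, splits in splits_by_method.items():
        if method == "R":
            continue
        m = mean_counts(splits)
        dev = {}
        for grp in assignment.group_sizes.index:
            b = float(base.get(grp, 0.0))
            c = float(m.get(grp, 0.0))
            dev[grp] = np.nan if b == 0 else 100.0 * (c - b) / b
        rows[method] = dev
    return pd.DataFrame(rows).T
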