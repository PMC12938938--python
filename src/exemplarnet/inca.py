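"""Iterative NCA feature selection (INCA).

The selector works in three steps, all fitted on training data only:

1. **NCA feature weighting** — learn a non-negative relevance ``w_r**2`` per
   feature by maximising the (anchor-averaged) soft leave-one-out
   nearest-neighbour objective

       (1/N) sum_i sum_{j != i} p_ij * 1[y_i = y_j]  -  lambda * sum_r w_r**2,
       p_ij  proportional to  exp(-d_w(x_i, x_j)),
       d_w(x_i, x_j) = sum_r w_r**2 * |x_ir - x_jr|,

   by seeded stochastic gradient ascent from ``w = 1``. One iteration is a
   full pass over all N anchors in random order (one gradient step per
   anchor); ``floor(N / 2)`` iterations by default, step size 3.0 decaying as
   1/sqrt(iteration) (see docs/methods.md for the scale rationale),
   ``lambda = 1 / N``. The returned weights are the Polyak-Ruppert average of
   the iterates over the last half of the passes, which stabilises the
   ranking of weakly informative features.
2. **Ranking** — sort features by decreasing ``w_r**2`` (stable; ties keep the
   lower original index first).
3. **Iterative subset sweep** — for every subset size ``a`` in ``[iv, fv]``
   (100..1000 by default, 901 candidates) evaluate the top-``a`` ranked subset
   with a cross-validated 1-NN (L1) misclassification rate and keep the
   smallest size attaining the minimum.

The selected column indices are then *transferred* to the test matrix; nothing
is refitted on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, InputError
from .shallow import stratified_folds


# ---------------------------------------------------------------------------
# standardization (fit on train, apply anywhere)

@dataclass
class Standardizer:
    """Column means/scales fitted on training rows; zero-variance columns are
    mapped to exactly zero (scale forced to 1)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


def standardize_fit(X_train: np.ndarray) -> Standardizer:
    X = np.asarray(X_train, dtype=np.float64)
    if X.size == 0:
        raise DataError("cannot standardize an empty matrix")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)
    return Standardizer(mean=mean, scale=scale)


def standardize_apply(X: np.ndarray, stats: Standardizer) -> np.ndarray:
    return stats.transform(X)


# ---------------------------------------------------------------------------
# NCA feature weighting

@dataclass
class NCAConfig:
    iterations: int | None = None     # passes over all anchors; default floor(N / 2)
    step_size: float = 3.0            # decayed as step_size / sqrt(iteration)
    regularization: float | None = None  # lambda; default 1 / N
    iterate_averaging: bool = True    # Polyak-Ruppert: average iterates over the
                                      # last half of the passes
    seed: int = 0


@dataclass
class NCAWeights:
    w: np.ndarray
    objective_trace: np.ndarray       # per-iteration mean anchor objective
    config: NCAConfig


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    _, enc = np.unique(y, return_inverse=True)
    return enc


def nca_objective(X: np.ndarray, y, w: np.ndarray, regularization: float) -> float:
    """Brute-force anchor-averaged NCA objective at a given weight vector —
    the quantity the stochastic optimizer ascends."""
    X = np.asarray(X, dtype=np.float64)
    enc = _encode_labels(y)
    w2 = np.asarray(w, dtype=np.float64) ** 2
    n = X.shape[0]
    total = 0.0
    for i in range(n):
        d = np.abs(X - X[i]) @ w2
        d[i] = np.inf
        e = np.exp(-(d - d.min()))
        e[i] = 0.0
        p = e / e.sum()
        total += p[enc == enc[i]].sum()
    return total / n - regularization * float(w2.sum())


def nca_weights(X_train: np.ndarray, y_train, config: NCAConfig | None = None,
                ) -> NCAWeights:
    """Learn per-feature relevance weights by seeded stochastic gradient ascent."""
    X = np.asarray(X_train, dtype=np.float64)
    enc = _encode_labels(y_train)
    n, d = X.shape
    classes, counts = np.unique(enc, return_counts=True)
    if classes.size < 2:
        raise DataError("NCA requires at least 2 classes")
    if counts.min() < 2:
        raise DataError("NCA requires at least 2 samples per class")
    cfg = config or NCAConfig()
    iterations = cfg.iterations if cfg.iterations is not None else max(1, n // 2)
    lam = cfg.regularization if cfg.regularization is not None else 1.0 / n
    rng = np.random.default_rng(cfg.seed)
    w = np.ones(d, dtype=np.float64)
    trace = np.empty(iterations, dtype=np.float64)
    tail_start = iterations // 2          # Polyak-Ruppert averaging window
    w_sum = np.zeros(d, dtype=np.float64)
    n_avg = 0
    for it in range(iterations):
        alpha = cfg.step_size / np.sqrt(it + 1.0)
        obj = 0.0
        for i in rng.permutation(n):
            diff = np.abs(X - X[i])                 # (n, d)
            dist = diff @ (w * w)
            dist[i] = np.inf
            e = np.exp(-(dist - dist.min()))
            e[i] = 0.0
            p = e / e.sum()
            same = enc == enc[i]
            p_i = p[same].sum()
            # d(p_i)/d(w_r) = 2 w_r (p_i sum_j p_j |diff_jr| - sum_{j same} p_j |diff_jr|)
            grad = 2.0 * w * (p_i * (p @ diff) - (p[same] @ diff[same])) - 2.0 * lam * w
            w = w + alpha * grad
            obj += p_i
        trace[it] = obj / n - lam * float((w * w).sum())
        if it >= tail_start:
            w_sum += w
            n_avg += 1
    if cfg.iterate_averaging and n_avg:
        w = w_sum / n_avg
    if not np.all(np.isfinite(w)):
        raise DataError("NCA weights diverged to non-finite values")
    return NCAWeights(w=w, objective_trace=trace, config=cfg)


def rank_features(weights: NCAWeights | np.ndarray) -> np.ndarray:
    """0-based feature order by decreasing relevance w_r**2 (stable; ties keep
    the lower original index first)."""
    w = weights.w if isinstance(weights, NCAWeights) else np.asarray(weights)
    if not np.all(np.isfinite(w)):
        raise InputError("weights must be finite")
    return np.argsort(-(w ** 2), kind="stable")


# ---------------------------------------------------------------------------
# iterative subset sweep

@dataclass
class KNNOracleConfig:
    """Misclassification oracle: stratified k-fold CV of a kNN (L1) classifier."""

    k: int = 1
    n_folds: int = 10
    seed: int = 0


@dataclass
class INCAResult:
    iv: int
    fv: int
    mcv: np.ndarray                    # misclassification rate per subset size
    best_size: int                     # a* = argmin (smallest on ties)
    selected: np.ndarray               # first a* entries of the ranking (0-based)
    ranking: np.ndarray
    oracle_config: KNNOracleConfig = field(default_factory=KNNOracleConfig)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.iv, self.fv + 1)


def _cv_knn_error_from_dist(D: np.ndarray, enc: np.ndarray,
                            fold_of: np.ndarray, k: int) -> float:
    """Out-of-fold kNN error given a full pairwise L1 distance matrix."""
    n = D.shape[0]
    wrong = 0
    for f in np.unique(fold_of):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        sub = D[np.ix_(test, train)]
        if k == 1:
            pred = enc[train[np.argmin(sub, axis=1)]]
        else:
            kk = min(k, train.size)
            near = np.argpartition(sub, kk - 1, axis=1)[:, :kk]
            pred = np.empty(test.size, dtype=enc.dtype)
            for r in range(test.size):
                idx = near[r][np.lexsort((train[near[r]], sub[r, near[r]]))]
                labs = enc[train[idx]]
                counts = np.bincount(labs)
                best = counts.max()
                # earliest (nearest, lowest-index) neighbour among tied labels
                pred[r] = labs[np.argmax(np.isin(labs, np.flatnonzero(counts == best)))]
        wrong += int((pred != enc[test]).sum())
    return wrong / n


def iterative_selection(X_train: np.ndarray, y_train, ranking: np.ndarray,
                        iv: int = 100, fv: int = 1000,
                        oracle_config: KNNOracleConfig | None = None) -> INCAResult:
    """Sweep nested top-``a`` subsets for ``a`` in [iv, fv]; return the
    misclassification curve and the smallest size attaining its minimum.

    The pairwise L1 distance matrix is grown one ranked feature at a time, so
    the full sweep costs O((fv - iv) * N**2) rather than O(sum_a a * N**2).
    """
    X = np.asarray(X_train, dtype=np.float64)
    enc = _encode_labels(y_train)
    n, d = X.shape
    ranking = np.asarray(ranking)
    if iv < 1:
        raise ConfigurationError(f"iv must be >= 1, got {iv}")
    if iv > fv:
        raise ConfigurationError(f"iv={iv} must not exceed fv={fv}")
    if fv > d:
        raise ConfigurationError(f"fv={fv} exceeds the number of features d={d}")
    oracle = oracle_config or KNNOracleConfig()
    plan = stratified_folds(np.asarray(y_train), n_folds=oracle.n_folds,
                            seed=oracle.seed)
    fold_of = plan.assignments
    cols = X[:, ranking[:fv]]
    # pairwise L1 distances over the first iv ranked features
    D = np.zeros((n, n), dtype=np.float64)
    for j in range(iv):
        D += np.abs(cols[:, j, None] - cols[None, :, j])
    mcv = np.empty(fv - iv + 1, dtype=np.float64)
    for a in range(iv, fv + 1):
        if a > iv:
            j = a - 1
            D += np.abs(cols[:, j, None] - cols[None, :, j])
        mcv[a - iv] = _cv_knn_error_from_dist(D, enc, fold_of, oracle.k)
    ind = int(np.argmin(mcv))              # argmin returns the first minimum
    best_size = ind + iv
    return INCAResult(iv=iv, fv=fv, mcv=mcv, best_size=best_size,
                      selected=ranking[:best_size].copy(), ranking=ranking.copy(),
                      oracle_config=oracle)


def apply_selection(X: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Column subset in ``selected`` order; identical on train and test
    (pure index transfer, nothing refitted)."""
    X = np.asarray(X)
    selected = np.asarray(selected)
    if X.ndim != 2:
        raise InputError(f"expected a 2-D matrix, got shape {X.shape}")
    if selected.size and (selected.min() < 0 or selected.max() >= X.shape[1]):
        raise InputError(
            f"selected indices out of range for a matrix with {X.shape[1]} columns")
    return X[:, selected]


# ---------------------------------------------------------------------------
# selection artifact I/O (auditable plain text, 1-based indices)

def save_selection(result: INCAResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# iv {result.iv}\n# fv {result.fv}\n")
        fh.write(f"# best_size {result.best_size}\n")
        fh.write("# selected feature indices (1-based)\n")
        for idx in result.selected:
            fh.write(f"{int(idx) + 1}\n")
        fh.write("# mcv: subset_size misclassification_rate\n")
        for a, v in zip(result.sizes, result.mcv):
            fh.write(f"{int(a)} {v:.10g}\n")


def load_selection(path) -> dict:
    """Read back a selection artifact: 0-based indices plus the mcv curve."""
    meta: dict = {}
    selected: list[int] = []
    sizes: list[int] = []
    errors: list[float] = []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("iv "):
                    meta["iv"] = int(body.split()[1])
                elif body.startswith("fv "):
                    meta["fv"] = int(body.split()[1])
                elif body.startswith("best_size"):
                    meta["best_size"] = int(body.split()[1])
                elif body.startswith("selected"):
                    section = "selected"
                elif body.startswith("mcv"):
                    section = "mcv"
                continue
            if section == "selected":
                selected.append(int(line) - 1)
            elif section == "mcv":
                a, v = line.split()
                sizes.append(int(a))
                errors.append(float(v))
    meta["selected"] = np.array(selected, dtype=np.int64)
    meta["sizes"] = np.array(sizes, dtype=np.int64)
    meta["mcv"] = np.array(errors, dtype=np.float64)
    return meta
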