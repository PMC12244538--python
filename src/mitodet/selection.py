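"""Hybrid jellyfish/walrus wrapper feature selection maximizing F1.

Candidate subsets are encoded as continuous positions in [0, 1]^d and
binarized at 0.5 (a coordinate at exactly 0.5 selects its feature). Each
iteration every agent produces a jellyfish-move candidate and a walrus-move
candidate (the walrus phase cycles feeding -> migration -> escape across
iterations); with probability ``crossover_rate`` the two recombine by
per-dimension uniform crossover, otherwise the fitter candidate is taken;
with probability ``mutation_rate`` one uniformly chosen dimension is
resampled. Greedy acceptance against the incumbent closes the iteration.

Subset fitness is the pooled cross-validated F1 of a fast ridge-regularized
linear discriminant on the z-scored selected columns; the metaheuristic
minimizes ``1 - F1``. Fitness values are cached by mask so re-visited
subsets cost nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .features import FeatureRegistry
from .optimize import JSOParams, SearchBounds, time_control

__all__ = [
    "HJWOAConfig",
    "SelectionResult",
    "subset_fitness",
    "hjwoa_run",
    "selection_report",
    "exhaustive_best_subset",
    "ridge_lda_classifier",
]


@dataclass
class HJWOAConfig:
    population: int = 50
    iterations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    kappa: float = 0.5
    cv_folds: int = 3
    seed: int = 0
    stagnation_patience: int = 15
    threshold: float = 0.5
    neighborhood_mode: str = "shrinking"

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    mask: np.ndarray
    fitness: float  # best F1 found
    history: list  # per-iteration best F1, monotone non-decreasing
    n_selected: int
    category_shares: dict = field(default_factory=dict)
    n_evaluations: int = 0
    slot_names: Optional[list] = None
    config: Optional[HJWOAConfig] = None

    def to_json(self, path) -> None:
        from dataclasses import asdict

        payload = {
            "mask": self.mask.astype(int).tolist(),
            "fitness": self.fitness,
            "n_selected": self.n_selected,
            "category_shares": self.category_shares,
            "history": self.history,
            "n_evaluations": self.n_evaluations,
            "slot_names": self.slot_names,
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def ridge_lda_classifier(ridge: float = 1e-3) -> Callable:
    """A fast ridge-regularized linear discriminant.

    Returns a callable ``(X_train, y_train, X_eval) -> predictions`` using
    pooled within-class covariance with an isotropic ridge scaled to the
    mean variance, and a prior-corrected midpoint threshold.
    """

    def fit_predict(Xtr, ytr, Xev):
        m0 = Xtr[ytr == 0].mean(axis=0)
        m1 = Xtr[ytr == 1].mean(axis=0)
        X0 = Xtr[ytr == 0] - m0
        X1 = Xtr[ytr == 1] - m1
        n = Xtr.shape[0]
        cov = (X0.T @ X0 + X1.T @ X1) / max(n - 2, 1)
        lam = ridge * max(np.trace(cov) / cov.shape[0], 1e-12)
        cov[np.diag_indices_from(cov)] += lam
        w = np.linalg.solve(cov, m1 - m0)
        n1 = int((ytr == 1).sum())
        c = w @ (m0 + m1) / 2.0 - np.log(n1 / (n - n1))
        return (Xev @ w > c).astype(int)

    return fit_predict


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin per class
    after a seeded shuffle)."""
    rng = np.random.default_rng([seed, 77])
    folds = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def subset_fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: HJWOAConfig,
    classifier: Optional[Callable] = None,
    cache: Optional[dict] = None,
) -> float:
    """Cross-validated F1 of the subset selected by ``mask``.

    The selected columns are z-scored, a stratified ``cv_folds``-fold split
    (seeded from the config) is evaluated with the internal classifier, and
    validation predictions are pooled into a single F1. An empty mask
    scores 0. Results are cached by mask when a cache dict is supplied.
    """
    mask = np.asarray(mask).astype(bool)
    y = np.asarray(y)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    if y.shape[0] < 2 * config.cv_folds:
        raise ValueError("need n >= 2 * cv_folds samples")
    if not mask.any():
        return 0.0
    key = mask.tobytes() if cache is not None else None
    if key is not None and key in cache:
        return cache[key]

    Xs = X[:, mask]
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    Xs = (Xs - mu) / np.where(sd > 1e-12, sd, 1.0)

    clf = classifier or ridge_lda_classifier()
    folds = _stratified_folds(y, config.cv_folds, config.seed)
    tp = fp = fn = 0
    for f in range(config.cv_folds):
        val = folds == f
        pred = clf(Xs[~val], y[~val], Xs[val])
        tp += int(np.sum((pred == 1) & (y[val] == 1)))
        fp += int(np.sum((pred == 1) & (y[val] == 0)))
        fn += int(np.sum((pred == 0) & (y[val] == 1)))
    score = _f1(tp, fp, fn)
    if key is not None:
        cache[key] = score
    return score


# ---------------------------------------------------------------------------
# Hybrid search
# ---------------------------------------------------------------------------

def _binarize(position: np.ndarray, threshold: float) -> np.ndarray:
    return position >= threshold  # a tie at the threshold selects


def _mask_key(mask: np.ndarray):
    return tuple(np.flatnonzero(mask))


def _better(f_new, mask_new, f_old, mask_old) -> bool:
    """Tie-break between equal-fitness subsets: fewer features, then the
    lexicographically smaller mask."""
    if f_new != f_old:
        return f_new < f_old
    n_new, n_old = int(mask_new.sum()), int(mask_old.sum())
    if n_new != n_old:
        return n_new < n_old
    return _mask_key(mask_new) < _mask_key(mask_old)


def hjwoa_run(
    X: np.ndarray,
    y: np.ndarray,
    registry: Optional[FeatureRegistry] = None,
    config: Optional[HJWOAConfig] = None,
    classifier: Optional[Callable] = None,
) -> SelectionResult:
    """Run the hybrid jellyfish/walrus wrapper selection.

    Stops after ``iterations`` rounds or once the best fitness has not
    improved for ``stagnation_patience`` rounds. Deterministic given the
    config seed. Returns the best mask ever evaluated.
    """
    config = config or HJWOAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    evals = [0]

    def loss(position: np.ndarray) -> tuple:
        m = _binarize(position, config.threshold)
        before = len(cache)
        f1 = subset_fitness(m, X, y, config, classifier=classifier, cache=cache)
        evals[0] += len(cache) - before
        return 1.0 - f1, m

    jso = JSOParams(kappa=config.kappa)
    pos = rng.uniform(size=(config.population, d))
    fit = np.empty(config.population)
    masks = []
    for i in range(config.population):
        fit[i], m = loss(pos[i])
        masks.append(m)
    best_i = int(np.argmin(fit))
    best_f, best_mask = fit[best_i], masks[best_i].copy()
    for i in range(config.population):
        if _better(fit[i], masks[i], best_f, best_mask):
            best_f, best_mask = fit[i], masks[i].copy()

    bounds = SearchBounds(np.zeros(d), np.ones(d))
    history = []
    since_improve = 0
    phases = ("feed", "migrate", "escape")
    mean_pos = pos.mean(axis=0)

    for t in range(1, config.iterations + 1):
        phase = phases[(t - 1) % 3]
        improved = False
        for i in range(config.population):
            cand_j = _jso_candidate(pos, fit, i, mean_pos, best_loss_pos(pos, fit),
                                    bounds, jso, t, config.iterations, rng)
            cand_w = _waoa_candidate(pos, fit, i, best_loss_pos(pos, fit),
                                     bounds, phase, t, config.neighborhood_mode, rng)
            if rng.uniform() < config.crossover_rate:
                take_j = rng.uniform(size=d) < 0.5
                child = np.where(take_j, cand_j, cand_w)
            else:
                fj, _ = loss(cand_j)
                fw, _ = loss(cand_w)
                child = cand_j if fj <= fw else cand_w
            if rng.uniform() < config.mutation_rate:
                child = child.copy()
                child[rng.integers(d)] = rng.uniform()
            f_child, m_child = loss(child)
            if f_child < fit[i]:
                pos[i], fit[i], masks[i] = child, f_child, m_child
            if _better(f_child, m_child, best_f, best_mask):
                best_f, best_mask = f_child, m_child.copy()
                improved = True
        mean_pos = pos.mean(axis=0)
        history.append(1.0 - best_f)
        since_improve = 0 if improved else since_improve + 1
        if since_improve >= config.stagnation_patience:
            break

    shares = _category_shares(best_mask, registry)
    return SelectionResult(
        mask=best_mask.astype(np.uint8),
        fitness=1.0 - best_f,
        history=history,
        n_selected=int(best_mask.sum()),
        category_shares=shares,
        n_evaluations=evals[0],
        slot_names=(list(np.asarray(registry.names)[best_mask])
                    if registry is not None else None),
        config=config,
    )


def best_loss_pos(pos: np.ndarray, fit: np.ndarray) -> np.ndarray:
    return pos[int(np.argmin(fit))]


def _jso_candidate(pos, fit, i, mean_pos, best_pos, bounds, jso, t, t_max, rng):
    d = bounds.d
    y = pos[i]
    tcf = time_control(t, t_max, rng)
    if tcf >= jso.kappa:
        r1 = rng.uniform(size=d)
        r2 = rng.uniform(size=d)
        cand = y + r1 * (best_pos - jso.gamma_current * r2 * mean_pos)
    elif rng.uniform() > 1.0 - tcf:
        cand = y + rng.uniform(size=d) * 0.1 * bounds.span
    else:
        j = _partner(rng, pos.shape[0], i)
        r = rng.uniform(size=d)
        if fit[i] >= fit[j]:
            cand = y + r * (pos[j] - y)
        else:
            cand = y + r * (y - pos[j])
    # jellyfish boundary rule: wrap to the opposite limit
    over, under = cand > bounds.ub, cand < bounds.lb
    cand[over] = (cand[over] - bounds.ub[over]) + bounds.lb[over]
    cand[under] = (cand[under] - bounds.lb[under]) + bounds.ub[under]
    return np.clip(cand, bounds.lb, bounds.ub)


def _waoa_candidate(pos, fit, i, best_pos, bounds, phase, t, mode, rng):
    d = bounds.d
    z = pos[i]
    if phase == "feed":
        ri = rng.integers(1, 3, size=d)
        cand = z + (best_pos - ri * z) * rng.uniform(size=d)
    elif phase == "migrate":
        l = _partner(rng, pos.shape[0], i)
        ri = rng.integers(1, 3, size=d)
        r = rng.uniform(size=d)
        if fit[l] < fit[i]:
            cand = z + (pos[l] - ri * z) * r
        else:
            cand = z + (z - pos[l]) * r
    else:  # escape
        if mode == "shrinking":
            half = bounds.span / (2.0 * max(t, 1))
            lb_loc, ub_loc = -half, half
        else:
            lb_loc, ub_loc = bounds.lb, bounds.ub
        cand = z + (lb_loc + (ub_loc - lb_loc) * rng.uniform(size=d))
    return np.clip(cand, bounds.lb, bounds.ub)


def _partner(rng, n, i):
    j = int(rng.integers(n - 1))
    return j if j < i else j + 1


# ---------------------------------------------------------------------------
# Reporting and the brute-force oracle
# ---------------------------------------------------------------------------

def _category_shares(mask: np.ndarray, registry: Optional[FeatureRegistry]) -> dict:
    if registry is None:
        return {}
    cats = np.asarray(registry.categories)
    n_sel = int(mask.sum())
    shares = {}
    for cat in ("texture", "shape", "color"):
        shares[cat] = (
            float(np.sum(mask & (cats == cat)) / n_sel) if n_sel else 0.0
        )
    return shares


#: Reported bands for selected-subset composition (informational flags only).
_EXPECTED_N_RANGE = (35, 50)
_EXPECTED_SHARES = {"texture": (0.50, 0.60), "shape": (0.25, 0.30),
                    "color": (0.10, 0.15)}


def selection_report(result: SelectionResult,
                     registry: Optional[FeatureRegistry] = None) -> dict:
    """Diagnostics of a selection: size, category shares, and informational
    flags against the reported 35-50 size range and category-share bands
    (observations, not constraints)."""
    shares = result.category_shares or _category_shares(
        result.mask.astype(bool), registry
    )
    lo, hi = _EXPECTED_N_RANGE
    report = {
        "n_selected": result.n_selected,
        "fitness": result.fitness,
        "category_shares": shares,
        "n_selected_in_35_50": lo <= result.n_selected <= hi,
        "shares_in_reported_bands": {
            cat: (shares.get(cat) is not None
                  and _EXPECTED_SHARES[cat][0] <= shares[cat] <= _EXPECTED_SHARES[cat][1])
            for cat in _EXPECTED_SHARES
        } if shares else {},
        "empty_selection": result.n_selected == 0,
    }
    return report


def exhaustive_best_subset(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[HJWOAConfig] = None,
    classifier: Optional[Callable] = None,
):
    """Enumerate all 2^d - 1 non-empty masks and return
    ``(best_mask, best_f1)`` under the same fitness and tie-break rules.
    Only feasible for small d; used as the independent optimization oracle.
    """
    config = config or HJWOAConfig()
    d = X.shape[1]
    if d > 20:
        raise ValueError(f"exhaustive enumeration infeasible for d={d}")
    cache: dict = {}
    best_mask, best_f1 = None, -1.0
    for bits in range(1, 2 ** d):
        mask = np.array([(bits >> j) & 1 for j in range(d)], dtype=bool)
        f1 = subset_fitness(mask, X, y, config, classifier=classifier, cache=cache)
        if best_mask is None or _better(1 - f1, mask, 1 - best_f1, best_mask):
            best_mask, best_f1 = mask, f1
    return best_mask, best_f1
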