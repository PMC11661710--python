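"""Random survival forest: log-rank splitting, Nelson-Aalen terminal nodes,
out-of-bag ensemble prediction.

Each tree is grown on a bootstrap sample.  At every node a random subset of
``mtry`` columns is scanned; for each candidate cut point the standardized
log-rank statistic between the two daughter groups is computed over the
distinct event times i:

    numerator = sum_i ( d_Li - Y_Li * d_i / Y_i )
    variance  = sum_i ( Y_Li/Y_i * (1 - Y_Li/Y_i) * (Y_i - d_i)/(Y_i - 1) * d_i )
    statistic = |numerator| / sqrt(variance)

with Y the risk-set size, d the death count and the L subscript the left
daughter.  The cut maximizing the statistic is taken; splitting stops when a
node holds fewer than ``nodesize`` unique death times or no informative cut
exists.  Terminal nodes store the in-node Nelson-Aalen cumulative hazard
evaluated on the forest-wide event-time grid; the ensemble prediction is
S(t) = exp(-mean H(t)), averaging on the cumulative-hazard scale.  Training
rows can be scored out of bag (only by trees whose bootstrap excluded them).

The candidate scan is vectorized over cut points via suffix counts of
left-daughter membership in time-sorted order, which is what makes desk-scale
cohorts (thousands of patients, hundreds of trees) tractable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimators import SurvivalCurve, eval_cumhaz

__all__ = [
    "ForestParams",
    "SurvivalForest",
    "SurvivalTree",
    "grow_forest",
    "logrank_split_statistic",
    "predict_curve",
    "oob_concordance",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` defaults to ceil(sqrt(p)); ``nodesize`` is the minimum number
    of unique death times a node must hold to be split further;
    ``max_candidates`` caps the cut points scanned per variable per node;
    ``max_grid`` caps the shared event-time grid (a quantile grid is used
    beyond it).  ``bootstrap=False`` grows every tree on the full sample
    (no out-of-bag notion), which makes a single root-only tree reproduce
    the pooled Nelson-Aalen estimator exactly.
    """

    ntree: int = 500
    mtry: int | None = None
    nodesize: int = 15
    max_candidates: int = 32
    max_grid: int = 220
    bootstrap: bool = True


@dataclass
class SurvivalTree:
    """Array-encoded binary tree; ``feature[k] == -1`` marks a leaf and
    ``leaf_slot[k]`` indexes its cumulative-hazard row in ``leaf_H``."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_slot: np.ndarray
    leaf_H: np.ndarray  # (n_leaves, G) cumulative hazard on the forest grid

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf slot reached by every row of X."""
        idx = np.zeros(len(X), dtype=np.int32)
        active = np.flatnonzero(self.feature[idx] >= 0)
        while active.size:
            node = idx[active]
            go_left = X[active, self.feature[node]] <= self.threshold[node]
            idx[active] = np.where(go_left, self.left[node], self.right[node])
            active = active[self.feature[idx[active]] >= 0]
        return self.leaf_slot[idx]


@dataclass
class SurvivalForest:
    trees: list[SurvivalTree]
    inbag: np.ndarray  # (ntree, n_train) bool
    grid: np.ndarray  # shared event-time grid (months)
    params: ForestParams
    seed: int
    n_features: int
    train_times: np.ndarray = field(repr=False, default=None)
    train_events: np.ndarray = field(repr=False, default=None)
    oob_concordance_: float | None = None

    @property
    def ntree(self) -> int:
        return len(self.trees)

    # -- prediction ------------------------------------------------------
    def predict_cumhaz(self, X: np.ndarray, oob_rows: np.ndarray | None = None
                       ) -> np.ndarray:
        """Ensemble-average cumulative hazard, shape (n_rows, G).

        With ``oob_rows`` (training-row indices aligned with the rows of X),
        each row is averaged only over trees in which it was out of bag; a
        row in bag in every tree raises an error naming it.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"design row width {X.shape} does not match forest ({self.n_features})"
            )
        H = np.zeros((len(X), len(self.grid)))
        if oob_rows is None:
            for tree in self.trees:
                H += tree.leaf_H[tree.apply(X)]
            return H / self.ntree
        oob_rows = np.asarray(oob_rows, dtype=int)
        if oob_rows.shape != (len(X),):
            raise ValueError("oob_rows must give one training index per row")
        counts = np.zeros(len(X))
        for b, tree in enumerate(self.trees):
            use = ~self.inbag[b, oob_rows]
            if not use.any():
                continue
            H[use] += tree.leaf_H[tree.apply(X[use])]
            counts[use] += 1
        if (counts == 0).any():
            bad = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(
                f"row {oob_rows[bad]} is in bag in every tree; "
                "increase ntree for out-of-bag prediction"
            )
        return H / counts[:, None]

    def predict_survival(self, X: np.ndarray, oob_rows: np.ndarray | None = None
                         ) -> np.ndarray:
        return np.exp(-self.predict_cumhaz(X, oob_rows))

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        """Persist splits and terminal cumulative-hazard grids."""
        payload = {
            "params": self.params.__dict__,
            "seed": self.seed,
            "n_features": self.n_features,
            "grid": self.grid.tolist(),
            "oob_concordance": self.oob_concordance_,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "leaf_slot": t.leaf_slot.tolist(),
                    "leaf_H": t.leaf_H.tolist(),
                }
                for t in self.trees
            ],
            "inbag": self.inbag.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SurvivalForest":
        with open(path) as fh:
            payload = json.load(fh)
        trees = [
            SurvivalTree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                leaf_slot=np.asarray(t["leaf_slot"], dtype=np.int32),
                leaf_H=np.asarray(t["leaf_H"], dtype=float),
            )
            for t in payload["trees"]
        ]
        forest = cls(
            trees=trees,
            inbag=np.asarray(payload["inbag"], dtype=bool),
            grid=np.asarray(payload["grid"], dtype=float),
            params=ForestParams(**payload["params"]),
            seed=payload["seed"],
            n_features=payload["n_features"],
        )
        forest.oob_concordance_ = payload["oob_concordance"]
        return forest


# ---------------------------------------------------------------------------
# Log-rank machinery


def _node_tables(times: np.ndarray, events: np.ndarray):
    """Sort a node by time and tabulate its distinct-time structure.

    Returns (order, starts_all, event_time_mask, d, Y) where ``starts_all``
    are group-start indices of all distinct times in sorted order,
    ``event_time_mask`` flags the groups holding at least one death, and
    d/Y are death counts and risk-set sizes at those event times.
    """
    order = np.argsort(times, kind="stable")
    t_s = times[order]
    e_s = events[order]
    _, starts = np.unique(t_s, return_index=True)
    d_all = np.add.reduceat(e_s, starts)
    y_all = len(t_s) - starts
    ev = d_all > 0
    return order, starts, ev, d_all[ev].astype(float), y_all[ev].astype(float)


def _score_left_membership(L_sorted: np.ndarray, e_sorted: np.ndarray,
                           starts: np.ndarray, ev: np.ndarray,
                           d: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized log-rank statistic for each column of ``L_sorted``.

    ``L_sorted`` is an (m, c) left-membership matrix with rows in time-sorted
    order; zero-variance candidates score 0.
    """
    suffix = np.cumsum(L_sorted[::-1], axis=0, dtype=np.float64)[::-1]
    y_left = suffix[starts][ev]  # (k, c)
    deaths_left = np.add.reduceat(L_sorted & e_sorted[:, None], starts, axis=0)[ev]
    num = (deaths_left - y_left * (d / y)[:, None]).sum(axis=0)
    frac = y_left / y[:, None]
    cc = np.where(y > 1, (y - d) / np.maximum(y - 1.0, 1.0) * d, 0.0)
    var = (frac * (1.0 - frac) * cc[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.abs(num) / np.sqrt(var)
    return np.where(var > 0, stat, 0.0)


def logrank_split_statistic(times, events, left_mask) -> float:
    """Standardized log-rank statistic for one candidate left/right split.

    Requires both groups non-empty and at least one event; a zero-variance
    configuration scores 0 (uninformative split).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    left_mask = np.asarray(left_mask, dtype=bool)
    if left_mask.all() or not left_mask.any():
        raise ValueError("both groups must be non-empty")
    if events.sum() == 0:
        raise ValueError("at least one event is required")
    order, starts, ev, d, y = _node_tables(times, events)
    L = left_mask[order][:, None]
    return float(_score_left_membership(L, events[order].astype(bool),
                                        starts, ev, d, y)[0])


# ---------------------------------------------------------------------------
# Growing


def _grow_tree(X: np.ndarray, times: np.ndarray, events: np.ndarray,
               grid: np.ndarray, params: ForestParams, mtry: int,
               rng: np.random.Generator) -> SurvivalTree:
    feature, threshold, left, right, leaf_slot = [], [], [], [], []
    leaf_rows: list[np.ndarray] = []
    p = X.shape[1]
    # stack of (node_id, row indices into the bootstrap sample)
    stack: list[tuple[int, np.ndarray]] = []

    def _new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_slot.append(-1)
        return len(feature) - 1

    root = _new_node()
    stack.append((root, np.arange(len(X))))
    while stack:
        node, rows = stack.pop()
        t_node = times[rows]
        e_node = events[rows]
        split = None
        if len(rows) >= 2 and e_node.sum() > 0:
            order, starts, ev, d, y = _node_tables(t_node, e_node)
            if int(ev.sum()) >= params.nodesize:
                split = _best_split(X[rows], t_node, e_node, order, starts,
                                    ev, d, y, mtry, params.max_candidates, rng)
        if split is None:
            leaf_slot[node] = len(leaf_rows)
            leaf_rows.append(rows)
            continue
        f, thr = split
        go_left = X[rows, f] <= thr
        feature[node] = f
        threshold[node] = thr
        lid, rid = _new_node(), _new_node()
        left[node], right[node] = lid, rid
        stack.append((lid, rows[go_left]))
        stack.append((rid, rows[~go_left]))

    leaf_H = np.zeros((len(leaf_rows), len(grid)))
    for slot, rows in enumerate(leaf_rows):
        leaf_H[slot] = _leaf_cumhaz(times[rows], events[rows], grid)
    return SurvivalTree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        leaf_slot=np.asarray(leaf_slot, dtype=np.int32),
        leaf_H=leaf_H,
    )


def _best_split(X_node, t_node, e_node, order, starts, ev, d, y,
                mtry, max_candidates, rng):
    m, p = X_node.shape
    feats = rng.permutation(p)[:mtry]
    e_sorted = e_node[order].astype(bool)
    best = (0.0, None, None)
    for f in feats:
        x = X_node[:, f]
        u = np.unique(x)
        if u.size < 2:
            continue
        cuts = (u[:-1] + u[1:]) / 2.0
        if cuts.size > max_candidates:
            cuts = np.sort(rng.choice(cuts, size=max_candidates, replace=False))
        L = x[order][:, None] <= cuts[None, :]
        stats = _score_left_membership(L, e_sorted, starts, ev, d, y)
        j = int(np.argmax(stats))
        if stats[j] > best[0]:
            best = (float(stats[j]), int(f), float(cuts[j]))
    if best[1] is None or best[0] <= 0.0:
        return None
    return best[1], best[2]


def _leaf_cumhaz(times: np.ndarray, events: np.ndarray, grid: np.ndarray
                 ) -> np.ndarray:
    """In-node Nelson-Aalen cumulative hazard step-evaluated on the grid."""
    if events.sum() == 0:
        return np.zeros(len(grid))
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    uniq, starts = np.unique(t_s, return_index=True)
    d = np.add.reduceat(e_s, starts)
    yy = len(t_s) - starts
    keep = d > 0
    H = np.cumsum(d[keep] / yy[keep])
    return eval_cumhaz(uniq[keep], H, grid)


def _make_grid(times: np.ndarray, events: np.ndarray, max_grid: int) -> np.ndarray:
    ev_times = np.unique(times[events == 1])
    if len(ev_times) <= max_grid:
        return ev_times
    return np.unique(np.quantile(ev_times, np.linspace(0.0, 1.0, max_grid)))


def grow_forest(X, times, events, params: ForestParams = ForestParams(),
                seed: int = 0) -> SurvivalForest:
    """Grow a random survival forest on a complete-case design matrix."""
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute first")
    if events.sum() == 0:
        raise ValueError("all observations censored: no split criterion exists")
    if len(times) != n or len(events) != n:
        raise ValueError("times/events must align with the design matrix")
    mtry = params.mtry if params.mtry is not None else int(np.ceil(np.sqrt(p)))
    mtry = max(1, min(mtry, p))
    grid = _make_grid(times, events, params.max_grid)

    child_seeds = np.random.SeedSequence(seed).spawn(params.ntree)
    trees: list[SurvivalTree] = []
    inbag = np.zeros((params.ntree, n), dtype=bool)
    for b in range(params.ntree):
        rng = np.random.default_rng(child_seeds[b])
        if params.bootstrap:
            idx = rng.integers(0, n, n)
        else:
            idx = np.arange(n)
        inbag[b, np.unique(idx)] = True
        trees.append(_grow_tree(X[idx], times[idx], events[idx], grid,
                                params, mtry, rng))

    forest = SurvivalForest(trees=trees, inbag=inbag, grid=grid, params=params,
                            seed=seed, n_features=p,
                            train_times=times, train_events=events)
    if params.bootstrap:
        forest.oob_concordance_ = oob_concordance(forest, X)
    return forest


def oob_concordance(forest: SurvivalForest, X: np.ndarray) -> float:
    """Concordance of ensemble out-of-bag mortality (summed cumulative
    hazard over the grid) against the training outcomes.

    Rows that are in bag in every tree (possible at very small ntree) are
    dropped from the concordance computation.
    """
    from lifelines.utils import concordance_index

    X = np.asarray(X, dtype=float)
    H = np.zeros((len(X), len(forest.grid)))
    counts = np.zeros(len(X))
    for b, tree in enumerate(forest.trees):
        use = ~forest.inbag[b]
        if not use.any():
            continue
        H[use] += tree.leaf_H[tree.apply(X[use])]
        counts[use] += 1
    ok = counts > 0
    mortality = H[ok].sum(axis=1) / counts[ok]
    return float(concordance_index(forest.train_times[ok], -mortality,
                                   forest.train_events[ok]))


def predict_curve(forest: SurvivalForest, row: np.ndarray,
                  oob_row: int | None = None) -> SurvivalCurve:
    """Predicted survival curve for a single design row.

    ``oob_row`` gives the row's training index for out-of-bag prediction.
    """
    row = np.atleast_2d(np.asarray(row, dtype=float))
    oob = None if oob_row is None else np.asarray([oob_row])
    S = forest.predict_survival(row, oob)
    return SurvivalCurve(forest.grid, S[0])
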