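"""Bagged regression forest with explicit out-of-bag bookkeeping.

The filtering stage needs two quantities that require per-tree bootstrap
membership: the out-of-bag (OOB) percent variance explained, and raw
(unscaled) OOB permutation variable importance — the mean increase in a
tree's OOB mean squared error when one predictor's OOB values are
permuted over the OOB set.

Genotype predictors take only the three additive codes {1, 2, 3}, so the
trees are grown on a binned (histogram) representation: each predictor
is mapped to small integer bins (genotypes get 3 bins; continuous
covariates get up to 32 quantile bins) and split search scans bin
statistics instead of sorting, which makes CART split search O(n) per
predictor.  Trees use variance-reduction splits, sample
``mtry = floor(p/3)`` predictors per node (the regression-forest
convention) and stop at ``min_samples_leaf = 5`` (R randomForest's
regression ``nodesize``), all numba-compiled.

The per-tree split-gain sums double as impurity (MDI) importances for
the shadow-feature stage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFAULT_MIN_SAMPLES_LEAF = 5
MAX_BINS = 32


@njit(cache=True)
def _build_tree(xb, nbins, y, idx, mtry, min_leaf, seed,
                feature, threshold, left, right, value, imp):
    """Grow one variance-reduction tree on the bootstrap sample ``idx``.

    ``xb`` is the (n, p) uint8 bin matrix; ``idx`` indexes the bootstrap
    rows (modified in place by partitioning).  Outputs are written into
    the preallocated node arrays; returns the number of nodes used.
    ``imp`` accumulates per-feature split gains (sum-of-squares
    reductions) for impurity importances.
    """
    np.random.seed(seed)
    n_feat = xb.shape[1]
    n = idx.size
    feats = np.arange(n_feat)
    counts = np.empty(MAX_BINS, dtype=np.int64)
    sums = np.empty(MAX_BINS, dtype=np.float64)
    # node stack: (node id, start, end) into idx
    stack = np.empty((2 * n + 2, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    node_count = 1
    while top > 0:
        top -= 1
        nid = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        ns = end - start
        sum_y = 0.0
        for i in range(start, end):
            sum_y += y[idx[i]]
        value[nid] = sum_y / ns
        feature[nid] = -1
        left[nid] = -1
        right[nid] = -1
        if ns < 2 * min_leaf:
            continue
        parent_score = sum_y * sum_y / ns
        best_gain = 1e-12
        best_f = -1
        best_t = -1
        for m in range(mtry):
            r = m + np.random.randint(0, n_feat - m)
            tmp = feats[m]
            feats[m] = feats[r]
            feats[r] = tmp
            f = feats[m]
            nb = nbins[f]
            for b in range(nb):
                counts[b] = 0
                sums[b] = 0.0
            for i in range(start, end):
                b = xb[idx[i], f]
                counts[b] += 1
                sums[b] += y[idx[i]]
            cl = 0
            sl = 0.0
            for t in range(nb - 1):
                cl += counts[t]
                sl += sums[t]
                cr = ns - cl
                if cl < min_leaf or cr < min_leaf:
                    continue
                sr = sum_y - sl
                gain = sl * sl / cl + sr * sr / cr - parent_score
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_t = t
        if best_f < 0:
            continue
        # partition idx[start:end) by bin <= best_t
        i = start
        j = end - 1
        while i <= j:
            if xb[idx[i], best_f] <= best_t:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        feature[nid] = best_f
        threshold[nid] = best_t
        left[nid] = node_count
        right[nid] = node_count + 1
        imp[best_f] += best_gain
        stack[top, 0] = node_count
        stack[top, 1] = start
        stack[top, 2] = i
        top += 1
        stack[top, 0] = node_count + 1
        stack[top, 1] = i
        stack[top, 2] = end
        top += 1
        node_count += 2
    return node_count


@njit(cache=True)
def _predict(feature, threshold, left, right, value, xb, out):
    for i in range(xb.shape[0]):
        node = 0
        while left[node] != -1:
            if xb[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]


@njit(cache=True)
def _perm_sse(feature, threshold, left, right, value, xb, y, used, perms):
    """Sum of squared errors per permuted feature for one tree's OOB set."""
    n = xb.shape[0]
    out = np.empty(used.size)
    for k in range(used.size):
        f = used[k]
        sse = 0.0
        for i in range(n):
            node = 0
            while left[node] != -1:
                ft = feature[node]
                if ft == f:
                    b = xb[perms[k, i], f]
                else:
                    b = xb[i, ft]
                if b <= threshold[node]:
                    node = left[node]
                else:
                    node = right[node]
            d = y[i] - value[node]
            sse += d * d
        out[k] = sse
    return out


def _bin_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Map each column to uint8 bin indices.

    Columns with <= MAX_BINS distinct values (genotype codes, shadow
    copies) bin exactly on their sorted unique values; wider columns
    (continuous covariates) use up to MAX_BINS quantile bins.  Returns
    (bin matrix, bins-per-column, per-column cut values) where cut value
    ``c[t]`` is the largest raw value falling in bin t.
    """
    n, p = x.shape
    xb = np.empty((n, p), dtype=np.uint8)
    nbins = np.empty(p, dtype=np.int64)
    cuts: list[np.ndarray] = []
    for j in range(p):
        col = x[:, j]
        uniq = np.unique(col)
        if uniq.size > MAX_BINS:
            qs = np.quantile(col, np.linspace(0, 1, MAX_BINS + 1)[1:])
            uniq = np.unique(qs)
        # bin index = position of the smallest cut >= value
        xb[:, j] = np.clip(np.searchsorted(uniq, col, side="left"),
                           0, uniq.size - 1).astype(np.uint8)
        nbins[j] = uniq.size
        cuts.append(uniq.astype(np.float64))
    return xb, nbins, cuts


class BaggedForest:
    """Bootstrap-aggregated histogram regression trees with OOB access.

    Parameters
    ----------
    n_trees:
        Number of bootstrap trees.
    mtry:
        Predictors sampled per split; ``None`` means max(1, floor(p/3)).
    min_samples_leaf:
        Minimum samples per terminal node (default 5).
    seed:
        Seeds the bootstrap draws and per-tree split sampling.
    """

    def __init__(self, n_trees: int, mtry: int | None = None,
                 min_samples_leaf: int = DEFAULT_MIN_SAMPLES_LEAF,
                 seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.trees_: list[tuple[np.ndarray, ...]] = []
        self.oob_masks_: list[np.ndarray] = []
        self.tree_importances_: list[np.ndarray] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BaggedForest":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if x.ndim != 2 or x.shape[0] != y.size:
            raise ValueError("x must be (n, p) matching len(y)")
        n, p = x.shape
        if n < 2:
            raise ValueError("need at least 2 samples to fit a forest")
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        mtry = min(mtry, p)
        xb, nbins, cuts = _bin_columns(x)
        self._xb = xb
        self._nbins = nbins
        self._cuts = cuts
        self._y = y
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.seed)))
        self.trees_ = []
        self.oob_masks_ = []
        self.tree_importances_ = []
        max_nodes = 2 * n + 1
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            feature = np.empty(max_nodes, dtype=np.int64)
            threshold = np.zeros(max_nodes, dtype=np.int64)
            lchild = np.empty(max_nodes, dtype=np.int64)
            rchild = np.empty(max_nodes, dtype=np.int64)
            value = np.zeros(max_nodes, dtype=np.float64)
            imp = np.zeros(p, dtype=np.float64)
            used_nodes = _build_tree(
                xb, nbins, y, idx, mtry, self.min_samples_leaf,
                int(rng.integers(0, 2**31 - 1)),
                feature, threshold, lchild, rchild, value, imp,
            )
            self.trees_.append((feature[:used_nodes], threshold[:used_nodes],
                                lchild[:used_nodes], rchild[:used_nodes],
                                value[:used_nodes]))
            self.oob_masks_.append(oob)
            total = imp.sum()
            self.tree_importances_.append(imp / total if total > 0 else imp)
        return self

    def _bin_new(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        xb = np.empty(x.shape, dtype=np.uint8)
        for j in range(x.shape[1]):
            cuts = self._cuts[j]
            xb[:, j] = np.clip(np.searchsorted(cuts, x[:, j], side="left"),
                               0, cuts.size - 1).astype(np.uint8)
        return xb

    def predict(self, x: np.ndarray) -> np.ndarray:
        xb = self._bin_new(np.atleast_2d(x))
        out = np.zeros(xb.shape[0])
        tmp = np.empty(xb.shape[0])
        for tree in self.trees_:
            _predict(*tree, xb, tmp)
            out += tmp
        return out / len(self.trees_)

    def oob_predictions(self) -> np.ndarray:
        """Per-sample mean prediction over trees where the sample is OOB.

        A sample in every bootstrap (probability (1 - 1/e)^n_trees,
        negligible for the schedules used) falls back to the training mean.
        """
        n = self._xb.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        tmp = np.empty(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            x_oob = np.ascontiguousarray(self._xb[oob])
            _predict(*tree, x_oob, tmp[:x_oob.shape[0]])
            total[oob] += tmp[:x_oob.shape[0]]
            count[oob] += 1
        pred = np.full(n, self._y.mean())
        seen = count > 0
        pred[seen] = total[seen] / count[seen]
        return pred

    def feature_importances_z(self) -> np.ndarray:
        """Z-score per feature: mean / sd of per-tree impurity importances."""
        imps = np.stack(self.tree_importances_)
        mean = imps.mean(axis=0)
        sd = imps.std(axis=0, ddof=1) if imps.shape[0] > 1 else np.zeros_like(mean)
        z = np.zeros_like(mean)
        ok = sd > 0
        z[ok] = mean[ok] / sd[ok]
        return z

    def permutation_importance(self, seed: int = 0) -> np.ndarray:
        """Raw OOB permutation importance per predictor.

        For each tree: permute one predictor's values over the tree's OOB
        samples and record the increase in OOB MSE; average the increases
        over all trees (zero contribution from trees not splitting on the
        predictor).
        """
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        n, p = self._xb.shape
        importance = np.zeros(p)
        tmp = np.empty(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            n_oob = int(oob.sum())
            if n_oob == 0:
                continue
            x_oob = np.ascontiguousarray(self._xb[oob])
            y_oob = self._y[oob]
            _predict(*tree, x_oob, tmp[:n_oob])
            base_sse = float(np.sum((y_oob - tmp[:n_oob]) ** 2))
            feature = tree[0]
            used = np.unique(feature[feature >= 0])
            if used.size == 0:
                continue
            perms = np.empty((used.size, n_oob), dtype=np.int64)
            for k in range(used.size):
                perms[k] = rng.permutation(n_oob)
            sse = _perm_sse(*tree, x_oob, y_oob, used, perms)
            importance[used] += (sse - base_sse) / n_oob
        return importance / len(self.trees_)
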