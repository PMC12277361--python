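"""Gene regulatory network inference via tree-ensemble importance.

Per-species GRNs follow the GENIE3 scheme: one random-forest regression
per target gene with the transcription factors as candidate regulators;
the importance of a TF in a target's forest is the weight of the directed
TF -> target edge. Networks are thresholded to the top fraction of
non-zero-weight edges (5% by default) and edges are signed by the Pearson
correlation of TF and target expression: positive = activator, negative =
repressor.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.metrics import roc_auc_score

__all__ = ["infer_grn", "top_edges", "assign_sign", "edge_ranking_auroc"]


@njit(cache=True)
def _fast_et_importances(
    X: np.ndarray, y: np.ndarray, n_trees: int, k: int, seed: int
) -> np.ndarray:  # pragma: no cover - exercised via infer_grn
    """Extra-Trees variance-reduction importances, compiled.

    Fully grown extremely randomized regression trees (no bootstrap, one
    uniform-random threshold per candidate feature, best of k candidates
    by variance reduction); the importance of feature f is the summed
    variance reduction of its split nodes divided by n_samples, averaged
    over trees — the unnormalized tree-ensemble edge weight.
    """
    n, p = X.shape
    imp = np.zeros(p)
    idx = np.empty(n, dtype=np.int64)
    feat = np.empty(p, dtype=np.int64)
    # explicit node stack of (start, end) spans over idx
    stack = np.empty((4 * n + 8, 2), dtype=np.int64)
    buf = np.empty(n, dtype=np.int64)
    for t in range(n_trees):
        np.random.seed(seed + t)
        for i in range(n):
            idx[i] = i
        top = 0
        stack[top, 0] = 0
        stack[top, 1] = n
        top += 1
        while top > 0:
            top -= 1
            start, end = stack[top, 0], stack[top, 1]
            m = end - start
            if m < 2:
                continue
            s = 0.0
            ss = 0.0
            for i in range(start, end):
                v = y[idx[i]]
                s += v
                ss += v * v
            node_ss = ss - s * s / m
            if node_ss <= 1e-12:
                continue
            # draw k distinct candidate features (partial Fisher-Yates)
            for j in range(p):
                feat[j] = j
            kk = k if k < p else p
            best_gain = -1.0
            best_f = -1
            best_thr = 0.0
            for j in range(kk):
                r = j + np.random.randint(0, p - j)
                tmp = feat[j]
                feat[j] = feat[r]
                feat[r] = tmp
                f = feat[j]
                xmin = X[idx[start], f]
                xmax = xmin
                for i in range(start + 1, end):
                    xv = X[idx[i], f]
                    if xv < xmin:
                        xmin = xv
                    elif xv > xmax:
                        xmax = xv
                if xmax <= xmin:
                    continue
                thr = xmin + np.random.random() * (xmax - xmin)
                if thr >= xmax:  # guard against fp rounding
                    thr = xmin
                ls = 0.0
                lss = 0.0
                ln = 0
                for i in range(start, end):
                    xv = X[idx[i], f]
                    if xv <= thr:
                        v = y[idx[i]]
                        ls += v
                        lss += v * v
                        ln += 1
                if ln == 0 or ln == m:
                    continue
                rn = m - ln
                rs = s - ls
                rss = ss - lss
                gain = node_ss - (lss - ls * ls / ln) - (rss - rs * rs / rn)
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = thr
            if best_f < 0:
                continue
            imp[best_f] += best_gain / n
            # partition idx[start:end] on the chosen split
            nl = 0
            nr = 0
            for i in range(start, end):
                if X[idx[i], best_f] <= best_thr:
                    buf[nl] = idx[i]
                    nl += 1
                else:
                    buf[m - 1 - nr] = idx[i]
                    nr += 1
            for i in range(m):
                idx[start + i] = buf[i]
            stack[top, 0] = start
            stack[top, 1] = start + nl
            top += 1
            stack[top, 0] = start + nl
            stack[top, 1] = end
            top += 1
    return imp / n_trees


def infer_grn(
    expr: pd.DataFrame,
    tf_list: Sequence[str],
    n_trees: int = 1000,
    k_features: int | str = "sqrt",
    seed: int = 0,
    targets: Sequence[str] | None = None,
    method: str = "RF",
) -> pd.DataFrame:
    """Weighted TF -> target edge list from expression.

    ``expr`` is genes x samples (typically TPM restricted to the union of
    DEGs); ``tf_list`` names the regulators present in ``expr``. For each
    target the target's unit-variance-scaled profile is regressed on all
    TF profiles (excluding the target itself when it is a TF) with a
    random forest of ``n_trees`` trees and ``k_features`` candidate
    features per split (default sqrt of the regulator count); edge weight
    is the forest's variance-reduction importance. ``method`` selects the
    ensemble: "RF" (random forest, the default) or "ET" (extremely
    randomized trees, the faster published variant of the same scheme).
    Deterministic given ``seed``. Constant targets are skipped with a
    warning; constant TFs receive zero importance.
    """
    if method not in ("RF", "ET", "FAST-ET"):
        raise ValueError("method must be 'RF', 'ET' or 'FAST-ET'")
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples for GRN inference")
    tfs = [t for t in tf_list if t in expr.index]
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs present in the expression matrix")
    if targets is None:
        targets = list(expr.index)
    data = expr.T  # samples x genes
    rows = []
    skipped = []
    for i, target in enumerate(sorted(targets)):
        regulators = [t for t in tfs if t != target]
        y = data[target].to_numpy(dtype=float)
        sd = y.std()
        if sd == 0:
            skipped.append(target)
            continue
        y = (y - y.mean()) / sd
        X = data[regulators].to_numpy(dtype=float)
        if isinstance(k_features, str):
            max_features = k_features
        else:
            max_features = min(max(1, int(k_features)), len(regulators))
        if method == "FAST-ET":
            if isinstance(max_features, str):
                k = max(1, int(round(math.sqrt(len(regulators)))))
            else:
                k = max_features
            imps = _fast_et_importances(
                np.ascontiguousarray(X), y, n_trees, k, (seed + i) % (2**31 - 1)
            )
        else:
            cls = RandomForestRegressor if method == "RF" else ExtraTreesRegressor
            forest = cls(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=(seed + i) % (2**31 - 1),
                n_jobs=1,
            )
            forest.fit(X, y)
            # GENIE3's weight is the UNnormalized variance-reduction sum per
            # tree (importances normalized to sum 1 would hand a pure-noise
            # target the same total edge weight as a well-explained one)
            imps = np.mean(
                [
                    est.tree_.compute_feature_importances(normalize=False)
                    for est in forest.estimators_
                ],
                axis=0,
            )
        for tf, imp in zip(regulators, imps):
            rows.append({"tf": tf, "target": target, "weight": float(imp)})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} constant target(s)")
    return pd.DataFrame(rows, columns=["tf", "target", "weight"])


def top_edges(
    edges: pd.DataFrame, fraction: float = 0.05, scope: str = "global"
) -> pd.DataFrame:
    """Keep the top fraction of non-zero-weight edges.

    Edges are ranked by weight descending with a deterministic
    (tf, target) lexicographic tie-break; the retained count is
    ceil(fraction x n_nonzero). ``scope="per_target"`` applies the rule
    within each target's edge set instead of network-wide.
    """
    nz = edges[edges["weight"] > 0]
    if nz.empty:
        warnings.warn("no non-zero-weight edges")
        return nz.assign(rank=pd.Series(dtype=int))

    def _take(df: pd.DataFrame) -> pd.DataFrame:
        ordered = df.sort_values(
            ["weight", "tf", "target"], ascending=[False, True, True]
        )
        keep = math.ceil(fraction * len(ordered))
        return ordered.head(keep)

    if scope == "global":
        out = _take(nz)
    elif scope == "per_target":
        out = pd.concat(
            [_take(g) for _, g in nz.groupby("target", sort=True)],
            ignore_index=True,
        ).sort_values(["weight", "tf", "target"], ascending=[False, True, True])
    else:
        raise ValueError("scope must be 'global' or 'per_target'")
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def assign_sign(edges: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Sign each edge by the PCC of TF and target expression.

    pcc > 0 -> activator, pcc < 0 -> repressor, pcc = 0 (or a constant
    profile, which warns) -> unsigned.
    """
    pccs = []
    signs = []
    warned = False
    for row in edges.itertuples(index=False):
        x = expr.loc[row.tf].to_numpy(dtype=float)
        y = expr.loc[row.target].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            if not warned:
                warnings.warn("constant profile: edge(s) left unsigned")
                warned = True
            pccs.append(np.nan)
            signs.append("unsigned")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        pccs.append(r)
        signs.append("activator" if r > 0 else "repressor" if r < 0 else "unsigned")
    out = edges.copy()
    out["pcc"] = pccs
    out["sign"] = signs
    return out


def edge_ranking_auroc(
    edges: pd.DataFrame, true_edges: set[tuple[str, str]]
) -> float:
    """AUROC of the weight ranking against a set of true (tf, target) pairs.

    Scored over every TF -> target pair present in the edge list; pairs in
    ``true_edges`` are positives.
    """
    labels = [
        1 if (row.tf, row.target) in true_edges else 0
        for row in edges.itertuples(index=False)
    ]
    if len(set(labels)) < 2:
        raise ValueError("need both positive and negative pairs for AUROC")
    return float(roc_auc_score(labels, edges["weight"].to_numpy()))
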