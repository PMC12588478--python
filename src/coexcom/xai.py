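"""Shapley-value attribution of community classifiers.

Two routes to the same quantity:

* :func:`shap_exact` — the defining weighted sum over feature subsets,

      phi_j(x) = sum_{F subseteq S \\ {j}} |F|! (|S|-|F|-1)! / |S|!
                  [ f_x(F u {j}) - f_x(F) ],

  with ``f_x(F)`` the interventional value function: the model's expected
  output when features outside F are replaced by background rows.  Exponential
  in |S|, so it refuses above 12 features; it is the validation oracle.

* :func:`shap_tree` — an exact polynomial algorithm for tree ensembles under
  the same interventional value function.  For one (sample x, background row
  z, tree) triple the hybrid input follows x on features in F and z
  elsewhere; walking the tree, only nodes where x and z fall on different
  sides of the split make the leaf depend on F, so each reachable leaf
  carries a pair of disjoint requirement sets (A: features forced into F,
  B: forced out).  The Shapley sum over subsets then collapses, per leaf,
  to closed-form factorial weights depending only on (|A|, |B|), giving
  phi exactly at cost linear in the number of divergent paths.

Both explain the Random Forest's case-class probability, so attributions are
continuous.  Local accuracy (base value + sum of phis = model output) holds
to float precision by construction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

try:  # optional jit; the pure-Python path is the same source
    import numba
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

EXACT_MAX_FEATURES = 12
POSITIVE_CLASS = "case"


# ---------------------------------------------------------------------------
# weights


def shapley_weights(n_features: int) -> np.ndarray:
    """w[f] = f! (S-f-1)! / S! for f = 0..S-1, computed exactly."""
    return np.array([1.0 / (n_features * math.comb(n_features - 1, f))
                     for f in range(n_features)])


def _ps_table(n_features: int) -> np.ndarray:
    """PS[a, b] = sum_k C(m, k) w(a + k), m = S - 1 - a - b.

    The closed-form leaf weight: a leaf requiring |A| = a features present
    and |B| = b absent contributes ``+v * PS[a-1, b]`` to each feature of A
    and ``-v * PS[a, b-1]`` to each feature of B.
    """
    w = shapley_weights(n_features)
    ps = np.zeros((n_features + 1, n_features + 1))
    for a in range(n_features):
        for b in range(n_features - a):
            m = n_features - 1 - a - b
            ps[a, b] = sum(math.comb(m, k) * w[a + k] for k in range(m + 1))
    return ps


# ---------------------------------------------------------------------------
# exact enumeration oracle


def shap_exact(model_fn, x, background) -> np.ndarray:
    """Exact Shapley values by subset enumeration (interventional averaging).

    ``model_fn`` maps a 2-D array to a 1-D output vector; ``x`` is one
    feature vector; ``background`` the reference rows.  Refuses beyond
    12 features — use :func:`shap_tree` for larger models.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    if background.shape[1] != p:
        raise ValueError("background and x differ in feature count")
    if p > EXACT_MAX_FEATURES:
        raise ValueError(
            f"shap_exact enumerates 2^{p} subsets; limited to "
            f"{EXACT_MAX_FEATURES} features — use shap_tree instead")
    # value function for every subset mask
    v = np.empty(1 << p)
    for mask in range(1 << p):
        hybrid = background.copy()
        for j in range(p):
            if mask >> j & 1:
                hybrid[:, j] = x[j]
        v[mask] = float(np.mean(model_fn(hybrid)))
    w = shapley_weights(p)
    phi = np.zeros(p)
    for j in range(p):
        bit = 1 << j
        for mask in range(1 << p):
            if mask & bit:
                continue
            size = bin(mask).count("1")
            phi[j] += w[size] * (v[mask | bit] - v[mask])
    return phi


# ---------------------------------------------------------------------------
# polynomial interventional tree attribution


def _tree_shap_kernel(feature, left, right, leaf_value,
                      x_left, z_left, ps, n_features, phi):
    """Accumulate per-tree interventional Shapley values into ``phi``.

    ``x_left[node, i]`` / ``z_left[node, m]`` say whether sample i /
    background row m takes the left branch at ``node``.  Requirement sets
    are carried as bitmasks; ``phi`` has shape (n_x, n_features) and
    receives the background-averaged contribution of this tree.
    """
    n_x = x_left.shape[1]
    n_z = z_left.shape[1]
    inv_nz = 1.0 / n_z
    max_stack = 4 * (n_features + 2)
    s_node = np.empty(max_stack, dtype=np.int64)
    s_a = np.empty(max_stack, dtype=np.int64)
    s_b = np.empty(max_stack, dtype=np.int64)
    s_na = np.empty(max_stack, dtype=np.int64)
    s_nb = np.empty(max_stack, dtype=np.int64)
    for i in range(n_x):
        for m in range(n_z):
            top = 0
            s_node[0] = 0
            s_a[0] = 0
            s_b[0] = 0
            s_na[0] = 0
            s_nb[0] = 0
            top = 1
            while top > 0:
                top -= 1
                node = s_node[top]
                mask_a = s_a[top]
                mask_b = s_b[top]
                na = s_na[top]
                nb = s_nb[top]
                while left[node] != -1:
                    f = feature[node]
                    bit = np.int64(1) << f
                    xl = x_left[node, i]
                    zl = z_left[node, m]
                    if mask_a & bit:
                        node = left[node] if xl else right[node]
                    elif mask_b & bit:
                        node = left[node] if zl else right[node]
                    elif xl == zl:
                        node = left[node] if xl else right[node]
                    else:
                        # branch: x-side requires f in F, z-side requires f out
                        s_node[top] = left[node] if zl else right[node]
                        s_a[top] = mask_a
                        s_b[top] = mask_b | bit
                        s_na[top] = na
                        s_nb[top] = nb + 1
                        top += 1
                        node = left[node] if xl else right[node]
                        mask_a = mask_a | bit
                        na = na + 1
                v = leaf_value[node] * inv_nz
                if na + nb > 0:
                    for j in range(n_features):
                        bit = np.int64(1) << j
                        if mask_a & bit:
                            phi[i, j] += v * ps[na - 1, nb]
                        elif mask_b & bit:
                            phi[i, j] -= v * ps[na, nb - 1]


if _HAVE_NUMBA:
    _tree_shap_kernel_jit = numba.njit(cache=False)(_tree_shap_kernel)
else:  # pragma: no cover
    _tree_shap_kernel_jit = _tree_shap_kernel


@dataclasses.dataclass
class AttributionMatrix:
    """Per-sample, per-feature Shapley values for one explained model."""

    values: pd.DataFrame        # samples x features, phi_j(x)
    feature_values: pd.DataFrame  # samples x features, the inputs explained
    base_value: float           # expected model output over the background
    model_output: pd.Series     # f(x) per sample

    def check_local_accuracy(self, tol: float = 1e-6) -> float:
        """Max |base + sum_j phi_j - f(x)|; raises if above tolerance."""
        recon = self.base_value + self.values.sum(axis=1)
        err = float(np.max(np.abs(recon - self.model_output)))
        if err > tol:
            raise AssertionError(f"local accuracy violated: max error {err:g}")
        return err


@dataclasses.dataclass
class AttributionSummary:
    table: pd.DataFrame  # per feature: mean_abs_shap, rank, direction
    top_features: list


def _case_column(model) -> int:
    classes = list(model.classes_)
    if POSITIVE_CLASS in classes:
        return classes.index(POSITIVE_CLASS)
    return len(classes) - 1


def _leaf_probabilities(tree, case_col: int) -> np.ndarray:
    value = tree.tree_.value[:, 0, :]
    totals = value.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(totals > 0, value[:, case_col] / np.where(totals > 0, totals, 1.0), 0.0)
    return prob


def shap_tree(model, X, background) -> AttributionMatrix:
    """Interventional Shapley attribution of a tree-ensemble classifier.

    ``model`` is a fitted ``RandomForestClassifier`` (or any ensemble with
    ``estimators_`` of sklearn decision trees); ``X`` the samples to explain
    and ``background`` the reference rows, both as DataFrames (features in
    columns) or arrays over the model's training feature set.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        sample_ids = list(X.index)
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.atleast_2d(np.asarray(X, dtype=float))
        feature_names = [f"f{j}" for j in range(X_arr.shape[1])]
        sample_ids = list(range(X_arr.shape[0]))
    bg_arr = (background.to_numpy(dtype=float)
              if isinstance(background, pd.DataFrame)
              else np.atleast_2d(np.asarray(background, dtype=float)))
    if hasattr(model, "feature_names_in_"):
        expected = list(model.feature_names_in_)
        if feature_names != expected and isinstance(X, pd.DataFrame):
            offending = [f for f in feature_names if f not in expected]
            raise ValueError(
                f"feature mismatch with fitted model; unexpected: {offending[:5]}, "
                f"expected order: {expected[:5]}...")
    p = X_arr.shape[1]
    if bg_arr.shape[1] != p:
        raise ValueError("background feature count differs from X")

    case_col = _case_column(model)
    ps = _ps_table(p)
    phi = np.zeros((X_arr.shape[0], p))
    kernel = _tree_shap_kernel_jit if (_HAVE_NUMBA and p <= 62) else _tree_shap_kernel
    use_masks_as_python_ints = p > 62
    n_trees = len(model.estimators_)
    for est in model.estimators_:
        t = est.tree_
        feature = t.feature.astype(np.int64)
        left = t.children_left.astype(np.int64)
        right = t.children_right.astype(np.int64)
        leaf_value = _leaf_probabilities(est, case_col)
        thresholds = t.threshold
        internal = left != -1
        x_left = np.zeros((t.node_count, X_arr.shape[0]), dtype=np.bool_)
        z_left = np.zeros((t.node_count, bg_arr.shape[0]), dtype=np.bool_)
        idx = np.flatnonzero(internal)
        x_left[idx] = X_arr[:, feature[idx]].T <= thresholds[idx][:, None]
        z_left[idx] = bg_arr[:, feature[idx]].T <= thresholds[idx][:, None]
        tree_phi = np.zeros_like(phi)
        if use_masks_as_python_ints:
            _tree_shap_wide(feature, left, right, leaf_value, x_left, z_left,
                            ps, p, tree_phi)
        else:
            kernel(feature, left, right, leaf_value, x_left, z_left, ps, p,
                   tree_phi)
        phi += tree_phi / n_trees

    fx = model.predict_proba(X_arr if not hasattr(model, "feature_names_in_")
                             else pd.DataFrame(X_arr, columns=feature_names))[:, case_col]
    base = float(model.predict_proba(
        bg_arr if not hasattr(model, "feature_names_in_")
        else pd.DataFrame(bg_arr, columns=feature_names))[:, case_col].mean())
    attr = AttributionMatrix(
        values=pd.DataFrame(phi, index=sample_ids, columns=feature_names),
        feature_values=pd.DataFrame(X_arr, index=sample_ids, columns=feature_names),
        base_value=base,
        model_output=pd.Series(fx, index=sample_ids),
    )
    attr.check_local_accuracy()
    return attr


def _tree_shap_wide(feature, left, right, leaf_value, x_left, z_left,
                    ps, n_features, phi):
    """Arbitrary-width fallback using Python integers as bitmasks."""
    n_x = x_left.shape[1]
    n_z = z_left.shape[1]
    inv_nz = 1.0 / n_z
    for i in range(n_x):
        for m in range(n_z):
            stack = [(0, 0, 0, 0, 0)]
            while stack:
                node, mask_a, mask_b, na, nb = stack.pop()
                while left[node] != -1:
                    f = int(feature[node])
                    bit = 1 << f
                    xl = x_left[node, i]
                    zl = z_left[node, m]
                    if mask_a & bit:
                        node = left[node] if xl else right[node]
                    elif mask_b & bit:
                        node = left[node] if zl else right[node]
                    elif xl == zl:
                        node = left[node] if xl else right[node]
                    else:
                        stack.append((left[node] if zl else right[node],
                                      mask_a, mask_b | bit, na, nb + 1))
                        node = left[node] if xl else right[node]
                        mask_a |= bit
                        na += 1
                if na + nb:
                    v = leaf_value[node] * inv_nz
                    for j in range(n_features):
                        bit = 1 << j
                        if mask_a & bit:
                            phi[i, j] += v * ps[na - 1, nb]
                        elif mask_b & bit:
                            phi[i, j] -= v * ps[na, nb - 1]


def summarize(attr: AttributionMatrix, top_k: int = 20) -> AttributionSummary:
    """Rank features by mean |phi| (descending, ties by feature id).

    The direction column is the sign of the correlation between a feature's
    values and its Shapley values: negative means low feature values push the
    model toward the positive (case) class.
    """
    if attr.values.empty:
        raise ValueError("empty attribution matrix")
    mean_abs = attr.values.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda f: (-mean_abs[f], str(f)))
    directions = {}
    for f in order:
        x = attr.feature_values[f].to_numpy()
        s = attr.values[f].to_numpy()
        if np.std(x) < 1e-12 or np.std(s) < 1e-12:
            directions[f] = 0
        else:
            directions[f] = int(np.sign(np.corrcoef(x, s)[0, 1]))
    table = pd.DataFrame({
        "mean_abs_shap": [float(mean_abs[f]) for f in order],
        "rank": np.arange(1, len(order) + 1),
        "direction": [directions[f] for f in order],
    }, index=pd.Index(order, name="gene_id"))
    return AttributionSummary(table=table, top_features=order[:min(top_k, len(order))])


def write_attribution(attr: AttributionMatrix, path) -> None:
    """Long-form TSV: sample_id, gene_id, shap_value, feature_value."""
    rows = []
    for sample in attr.values.index:
        for f in attr.values.columns:
            rows.append((sample, f, attr.values.at[sample, f],
                         attr.feature_values.at[sample, f]))
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "shap_value",
                                "feature_value"]).to_csv(path, sep="\t", index=False)


def write_summary(summary: AttributionSummary, path) -> None:
    summary.table.to_csv(path, sep="\t", index_label="gene_id")
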