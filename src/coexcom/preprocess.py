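"""Expression preprocessing: controls-anchored batch adjustment, log2,
quantile normalization.

The batch step is a per-gene location--scale adjustment whose coefficients
are estimated from the CONTROL samples of each batch only (batch control
mean/SD against the pooled control mean/SD) and then applied to every sample
of the batch, case and control alike.  Anchoring on controls avoids absorbing
the case/control signal into the batch coefficients when case prevalence
differs between batches.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from coexcom.io import validate_expression, validate_metadata

logger = logging.getLogger(__name__)

#: default pipeline order; each stage name maps to its function below.
#: The location-scale batch adjustment runs on the log2 scale (the
#: empirical-Bayes convention): adjusting raw intensities can push low
#: values negative, which the later log transform cannot accept.
DEFAULT_ORDER = ("log2", "batch", "quantile")


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(value + offset)``; ids unchanged.

    Raises ``ValueError`` naming the first offending (gene, sample) if any
    shifted value is nonpositive.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    shifted = matrix.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"nonpositive value after offset at gene {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(shifted), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean-of-order-statistics reference.

    After the transform all columns share the identical sorted value vector;
    within-column ranks are preserved.  Ties receive the mean of the
    reference values over their tied rank range, which makes the operation
    exactly idempotent and permutation-equivariant.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    # keep re-application exactly idempotent: when a row of order statistics
    # is already constant its mean must be that constant, not a rounded sum
    constant_rows = (sorted_vals == sorted_vals[:, :1]).all(axis=1)
    reference[constant_rows] = sorted_vals[constant_rows, 0]

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference over each run of tied values
        start = 0
        n = col_sorted.size
        for end in range(1, n + 1):
            if end == n or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_adjust_on_controls(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, batch) affine correction estimated on control samples only.

    For each batch the per-gene shift and scale map the batch's control mean
    and SD onto the pooled control mean and SD; the correction is then
    applied to all samples of the batch.  A batch with fewer than two
    controls is an error (its SD is undefined).  Genes whose control SD in a
    batch is degenerate (< 1e-12) get scale 1 for that batch.
    """
    validate_expression(matrix)
    validate_metadata(metadata, matrix.columns)
    meta = metadata.loc[matrix.columns]
    batches = meta["batch"].unique()
    control_cols = meta.index[meta["class"] == "control"]
    if len(control_cols) < 2:
        raise ValueError("batch adjustment needs at least 2 control samples overall")
    for b in batches:
        n_ctrl = ((meta["batch"] == b) & (meta["class"] == "control")).sum()
        if n_ctrl < 2:
            raise ValueError(f"batch {b!r} has {n_ctrl} control samples; need >= 2")

    values = matrix.to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(matrix.columns)}
    ctrl_idx = np.array([col_index[s] for s in control_cols])
    pooled_mean = values[:, ctrl_idx].mean(axis=1)
    pooled_sd = values[:, ctrl_idx].std(axis=1, ddof=1)

    out = values.copy()
    for b in batches:
        batch_cols = np.array([col_index[s] for s in meta.index[meta["batch"] == b]])
        batch_ctrl = np.array([
            col_index[s]
            for s in meta.index[(meta["batch"] == b) & (meta["class"] == "control")]
        ])
        m_b = values[:, batch_ctrl].mean(axis=1)
        s_b = values[:, batch_ctrl].std(axis=1, ddof=1)
        scale = np.where((s_b < 1e-12) | (pooled_sd < 1e-12), 1.0, pooled_sd / np.where(s_b < 1e-12, 1.0, s_b))
        out[:, batch_cols] = (values[:, batch_cols] - m_b[:, None]) * scale[:, None] + pooled_mean[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_pipeline(matrix: pd.DataFrame, metadata: pd.DataFrame,
                        offset: float = 1.0,
                        order=DEFAULT_ORDER,
                        batch_adjust: bool = True) -> pd.DataFrame:
    """Run the configured preprocessing stages in order.

    Stage names: ``"batch"`` (controls-anchored adjustment, skipped when
    ``batch_adjust`` is false or only one batch is present), ``"log2"``,
    ``"quantile"``.
    """
    out = matrix
    for stage in order:
        if stage == "batch":
            if batch_adjust and metadata["batch"].nunique() > 1:
                out = batch_adjust_on_controls(out, metadata)
        elif stage == "log2":
            out = log2_transform(out, offset=offset)
        elif stage == "quantile":
            out = quantile_normalize(out)
        else:
            raise ValueError(f"unknown preprocessing stage {stage!r}")
        logger.info("preprocess stage %s done (%d genes x %d samples)",
                    stage, *out.shape)
    return out
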