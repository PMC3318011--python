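"""Normalization and empirical-Bayes batch-effect correction for virtual arrays.

Two harmonization steps run after virtual-array assembly:

* :func:`quantile_normalize` forces every sample to share one empirical
  intensity distribution (the across-sample mean of order statistics).

* :func:`fit_batch_model` / :func:`apply_batch_correction` implement the
  parametric empirical-Bayes location/scale batch model (the ComBat model).
  For gene g, sample j in batch i the model is

      y_gij = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_gij

  with additive batch effect gamma_ig ~ N(gamma_bar_i, tau2_i) and squared
  scale effect delta2_ig ~ InverseGamma(lambda_i, theta_i).  Hyperparameters
  are estimated by method of moments across genes; the conditional posterior
  means gamma*_ig and delta2*_ig are obtained by fixed-point iteration and
  used to adjust the standardized data.

* :func:`reference_anchor_check` audits the correction using shared reference
  samples (MAQC-style internal controls) carried in every batch: after a
  successful correction the references of all batches should coincide up to
  their within-batch spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .integration import VirtualArray

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "BatchModel",
    "fit_batch_model",
    "apply_batch_correction",
    "reference_anchor_check",
]


# --------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(v: VirtualArray) -> VirtualArray:
    """Quantile-normalize samples so all share one value distribution.

    After the transform, every sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample ranks are preserved
    and tied values receive the mean of the quantile values their positions
    span.  A constant sample is permitted (its values all map to the grand
    mean of the target distribution) but is logged.
    """
    X = v.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n_genes, n_samples = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    target = sorted_X.mean(axis=1)

    out = np.empty_like(X)
    for j in range(n_samples):
        idx = order[:, j]
        vals = X[idx, j]
        if vals[0] == vals[-1]:
            logger.info("quantile_normalize: sample %r is constant", v.samples[j])
        # tie groups occupy consecutive positions in the sort order and all
        # receive the mean of the target values over those positions
        starts = np.flatnonzero(np.r_[True, vals[1:] != vals[:-1]])
        sums = np.add.reduceat(target, starts)
        counts = np.diff(np.r_[starts, n_genes])
        group_means = sums / counts
        out[idx, j] = np.repeat(group_means, counts)

    values = pd.DataFrame(out, index=v.values.index, columns=v.values.columns)
    return v.with_values(values)


# --------------------------------------------------------------------------
# ComBat: model container


@dataclass
class BatchModel:
    """Fitted location/scale empirical-Bayes batch model.

    Attributes
    ----------
    batch_key, covariate_key:
        Metadata fields used for batch labels and the (optional) biological
        covariate protected during standardization.
    alpha:
        Per-gene grand mean (Series over genes).
    beta:
        Covariate effects: DataFrame (covariate level × gene); the first
        level is the reference with zero effect.
    sigma:
        Per-gene pooled residual SD.
    gamma_hat / gamma_star:
        Per-batch per-gene additive effects, raw and EB-shrunk
        (DataFrames batch × gene).
    delta2_hat / delta2_star:
        Per-batch per-gene squared scale effects, raw and EB-shrunk.
    hyper:
        Per-batch prior parameters: ``gamma_bar`` and ``tau2`` of the normal
        prior on gamma, and inverse-gamma ``shape`` (lambda) and ``scale``
        (theta) of the prior on delta².
    """

    batch_key: str
    covariate_key: Optional[str]
    batches: list[str]
    genes: list[str]
    alpha: pd.Series
    beta: pd.DataFrame
    sigma: pd.Series
    gamma_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_hat: pd.DataFrame
    delta2_star: pd.DataFrame
    hyper: dict[str, dict[str, float]]
    n_iterations: dict[str, int] = field(default_factory=dict)
    fit_sample_ids: list[str] = field(default_factory=list)

    def stand_mean_for(self, metadata: pd.DataFrame) -> pd.DataFrame:
        """Gene × sample matrix of alpha + covariate effect for given samples."""
        n = len(metadata.index)
        base = np.tile(self.alpha.to_numpy()[:, None], (1, n))
        if self.covariate_key is not None:
            for k, s in enumerate(metadata.index):
                level = str(metadata.loc[s, self.covariate_key])
                if level in self.beta.index:
                    base[:, k] += self.beta.loc[level].to_numpy()
                else:
                    raise ValueError(
                        f"sample {s!r} has covariate level {level!r} unseen during fitting"
                    )
        return pd.DataFrame(base, index=self.genes, columns=metadata.index)


def _eb_fixed_point(
    s_block: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    shape: float,
    scale: float,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means for one batch.

    ``s_block`` is the standardized data restricted to the batch (genes ×
    samples).  Returns (gamma_star, delta2_star, n_iterations).
    """
    n = s_block.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        ssq = ((s_block - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (scale + 0.5 * ssq) / (n / 2.0 + shape - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            return g_old, d_old, it
    raise RuntimeError(
        f"EB fixed-point iteration did not converge in {max_iter} iterations "
        f"(last relative change {change:.3g})"
    )


def fit_batch_model(
    v: VirtualArray,
    batch_key: str = "batch",
    covariate_key: Optional[str] = "cell_type",
    fit_on_cell_type: Optional[str] = None,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> BatchModel:
    """Fit the empirical-Bayes location/scale batch model.

    Parameters
    ----------
    v:
        Virtual array with ``batch_key`` (and optionally ``covariate_key``)
        columns in its metadata.
    covariate_key:
        Biological covariate (e.g. cell type) protected during
        standardization so real contrasts are not absorbed into batch terms.
        Pass ``None`` to fit without covariates.
    fit_on_cell_type:
        If given, batch effects are estimated **only** from samples whose
        cell_type equals this label (reference-anchored mode, for shared
        MAQC-style controls); the covariate design is dropped since the fit
        subset is biologically homogeneous.  Default: fit on all samples.

    Requires ≥2 batches with ≥2 samples each in the fitting subset.
    """
    meta = v.metadata
    if batch_key not in meta.columns:
        raise ValueError(f"metadata lacks batch field {batch_key!r}")
    if fit_on_cell_type is not None:
        mask = meta["cell_type"].astype(str) == str(fit_on_cell_type)
        if not mask.any():
            raise ValueError(f"no samples with cell_type {fit_on_cell_type!r} to anchor on")
        covariate_key = None
    else:
        mask = pd.Series(True, index=meta.index)

    sub = meta.loc[mask]
    Y = v.values.loc[:, sub.index].to_numpy(dtype=float)
    genes = v.genes
    batches = sorted(sub[batch_key].astype(str).unique())
    if len(batches) < 2:
        raise ValueError("batch correction requires at least two batches")
    batch_of = sub[batch_key].astype(str)
    counts = batch_of.value_counts()
    small = [b for b in batches if counts[b] < 2]
    if small:
        raise ValueError(f"each batch needs >=2 samples in the fitting subset; too small: {small}")

    n_samples = Y.shape[1]
    # design: batch indicators plus covariate dummies (reference level dropped)
    B = np.stack([(batch_of == b).to_numpy(dtype=float) for b in batches], axis=1)
    cov_levels: list[str] = []
    C = np.empty((n_samples, 0))
    if covariate_key is not None and covariate_key in sub.columns:
        levels = sorted(sub[covariate_key].astype(str).unique())
        if len(levels) > 1:
            cov_levels = levels
            C = np.stack(
                [(sub[covariate_key].astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]],
                axis=1,
            )
    X = np.hstack([B, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}): batch {batch_key!r} is "
            f"confounded with covariate {covariate_key!r}; cannot separate batch from biology"
        )

    # per-gene least squares for the full location model
    Bhat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_params, n_genes)
    n_batches = len(batches)
    batch_sizes = np.array([counts[b] for b in batches], dtype=float)
    grand = (batch_sizes / n_samples) @ Bhat[:n_batches]  # per-gene grand mean
    resid = Y - (X @ Bhat).T
    var_pooled = (resid ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        bad = [genes[i] for i in np.flatnonzero(var_pooled <= 0)][:5]
        raise ValueError(f"zero pooled variance for gene(s) {bad}; cannot standardize")
    sigma = np.sqrt(var_pooled)

    stand_mean = grand[:, None] + (C @ Bhat[n_batches:]).T  # genes x samples
    s_data = (Y - stand_mean) / sigma[:, None]

    gamma_hat = np.empty((n_batches, len(genes)))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    hyper: dict[str, dict[str, float]] = {}
    n_iterations: dict[str, int] = {}
    for i, b in enumerate(batches):
        cols = (batch_of == b).to_numpy()
        block = s_data[:, cols]
        gamma_hat[i] = block.mean(axis=1)
        delta2_hat[i] = block.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat[i].mean())
        tau2 = float(gamma_hat[i].var(ddof=1))
        m = float(delta2_hat[i].mean())
        s2 = float(delta2_hat[i].var(ddof=1))
        # method-of-moments inverse-gamma prior on delta^2
        shape = (2.0 * s2 + m ** 2) / s2
        scale = (m * s2 + m ** 3) / s2
        hyper[b] = {"gamma_bar": gamma_bar, "tau2": tau2, "shape": shape, "scale": scale}
        gamma_star[i], delta2_star[i], n_iterations[b] = _eb_fixed_point(
            block, gamma_hat[i], delta2_hat[i], gamma_bar, tau2, shape, scale,
            conv=conv, max_iter=max_iter,
        )

    beta = pd.DataFrame(
        np.zeros((len(cov_levels), len(genes))), index=cov_levels, columns=genes
    )
    if cov_levels:
        beta.iloc[1:] = Bhat[n_batches:]

    return BatchModel(
        batch_key=batch_key,
        covariate_key=covariate_key if cov_levels else None,
        batches=batches,
        genes=genes,
        alpha=pd.Series(grand, index=genes),
        beta=beta,
        sigma=pd.Series(sigma, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat, index=batches, columns=genes),
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=genes),
        delta2_hat=pd.DataFrame(delta2_hat, index=batches, columns=genes),
        delta2_star=pd.DataFrame(delta2_star, index=batches, columns=genes),
        hyper=hyper,
        n_iterations=n_iterations,
        fit_sample_ids=list(sub.index),
    )


def apply_batch_correction(v: VirtualArray, model: BatchModel) -> VirtualArray:
    """Remove fitted batch effects from every sample of ``v``.

    corrected = sigma * (standardized − gamma*) / sqrt(delta2*) + alpha + covariate fit.

    Every sample's batch must be known to the model.  Shape, gene order and
    sample order are preserved.
    """
    if list(v.genes) != model.genes:
        raise ValueError("virtual array genes do not match the fitted model")
    batch_of = v.metadata[model.batch_key].astype(str)
    unknown = sorted(set(batch_of) - set(model.batches))
    if unknown:
        raise ValueError(f"samples from batch(es) {unknown} absent from the fitted model")

    Y = v.values.to_numpy(dtype=float)
    sigma = model.sigma.to_numpy()
    stand_mean = model.stand_mean_for(v.metadata).to_numpy()
    s_data = (Y - stand_mean) / sigma[:, None]
    out = np.empty_like(Y)
    for b in model.batches:
        cols = (batch_of == b).to_numpy()
        if not cols.any():
            continue
        g = model.gamma_star.loc[b].to_numpy()[:, None]
        d = np.sqrt(model.delta2_star.loc[b].to_numpy())[:, None]
        out[:, cols] = (s_data[:, cols] - g) / d
    out = out * sigma[:, None] + stand_mean
    values = pd.DataFrame(out, index=v.values.index, columns=v.values.columns)
    return v.with_values(values)


# --------------------------------------------------------------------------
# MAQC-style reference anchoring audit


def reference_anchor_check(
    v_corrected: VirtualArray,
    reference_label: str = "reference",
    batch_key: str = "batch",
    flag_multiple: float = 2.0,
) -> dict:
    """Audit batch alignment using shared reference samples.

    Every batch is expected to carry replicates of one common reference
    material (MAQC-style internal control).  For each batch the report gives
    the Euclidean distance from the batch's reference centroid to the global
    reference centroid ("between") and the mean distance of its reference
    samples to their own centroid ("within").  A batch is flagged when its
    between-distance exceeds ``flag_multiple`` × the pooled within-batch
    spread — i.e. its references remain further from everyone else's than
    replicate noise explains.  Batches with no reference samples are skipped
    with a warning.
    """
    meta = v_corrected.metadata
    is_ref = meta["cell_type"].astype(str) == str(reference_label)
    if not is_ref.any():
        raise ValueError(f"no samples labelled {reference_label!r} found")
    X = v_corrected.values.loc[:, is_ref[is_ref].index].to_numpy(dtype=float).T
    ref_meta = meta.loc[is_ref]
    global_centroid = X.mean(axis=0)

    per_batch: dict[str, dict] = {}
    withins: list[float] = []
    for b in sorted(meta[batch_key].astype(str).unique()):
        rows = (ref_meta[batch_key].astype(str) == b).to_numpy()
        if not rows.any():
            logger.warning("reference_anchor_check: batch %r has no reference samples; skipped", b)
            continue
        block = X[rows]
        centroid = block.mean(axis=0)
        within = float(np.linalg.norm(block - centroid, axis=1).mean())
        between = float(np.linalg.norm(centroid - global_centroid))
        per_batch[b] = {"n_reference": int(rows.sum()), "between": between, "within": within}
        withins.append(within)

    pooled_within = float(np.mean(withins)) if withins else 0.0
    for b, rec in per_batch.items():
        rec["flagged"] = bool(rec["between"] > flag_multiple * pooled_within)
    return {
        "reference_label": reference_label,
        "pooled_within_spread": pooled_within,
        "flag_multiple": flag_multiple,
        "batches": per_batch,
        "any_flagged": any(rec["flagged"] for rec in per_batch.values()),
    }
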