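"""Normalization and covariate adjustment ahead of network inference.

Three stages: trimmed-mean-of-M-values (TMM) scaling factors for raw
count libraries, an expressed-gene filter (value >= threshold in at
least a fraction of samples), and per-gene least-squares covariate
residualization.  The TMM implementation follows the published method:
a reference library is chosen by upper-quartile closeness to the mean,
gene-wise log-ratios (M) and average log-intensities (A) are doubly
trimmed, and the factor is the precision-weighted mean of the surviving
M values, with factors rescaled to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and provenance."""

    library_sizes: pd.Series
    factors: pd.Series
    reference_sample: str
    log_ratio_trim: float
    intensity_trim: float

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")
        logf = np.log(self.factors.to_numpy(dtype=float))
        if abs(logf.mean()) > 1e-8:
            raise ValueError("factors must be rescaled to geometric mean 1")

    def normalized(self, counts: ExpressionMatrix) -> pd.DataFrame:
        """Counts divided by effective library size (libsize * factor)."""
        eff = self.library_sizes * self.factors
        return counts.values / eff


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float,
    intensity_trim: float,
) -> float:
    """Weighted trimmed mean of M values for one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) binomial variance of M
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * log_ratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * intensity_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(
    counts: ExpressionMatrix,
    log_ratio_trim: float = 0.30,
    intensity_trim: float = 0.05,
) -> NormalizationFactors:
    """Compute TMM scaling factors for a raw-count expression matrix."""
    if counts.value_kind != "counts":
        raise ValueError(f"TMM needs raw counts, got value_kind={counts.value_kind!r}")
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.values.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = [s for s, z in zip(counts.samples, zero) if z]
        raise ValueError(f"sample(s) with zero total count: {bad}")
    # reference = sample whose upper quartile of count fractions is closest
    # to the mean upper quartile
    uq = np.quantile(mat / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair(mat[:, s], ref, lib[s], lib[ref_idx], log_ratio_trim, intensity_trim)
            for s in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        library_sizes=pd.Series(lib, index=counts.samples),
        factors=pd.Series(factors, index=counts.samples),
        reference_sample=counts.samples[ref_idx],
        log_ratio_trim=log_ratio_trim,
        intensity_trim=intensity_trim,
    )


def filter_expressed(
    fpkm: ExpressionMatrix,
    min_value: float = 1.0,
    min_fraction: float = 0.10,
) -> ExpressionMatrix:
    """Keep genes with value >= min_value in >= ceil(min_fraction * n) samples.

    Defaults implement the standard "at least 1 FPKM in at least 10% of
    the samples" inclusion rule; both comparisons are inclusive.
    """
    if fpkm.value_kind != "fpkm":
        raise ValueError(f"filter expects FPKM values, got {fpkm.value_kind!r}")
    if fpkm.n_genes == 0 or fpkm.n_samples == 0:
        raise ValueError("empty expression matrix")
    need = int(np.ceil(min_fraction * fpkm.n_samples))
    hits = (fpkm.values >= min_value).sum(axis=1)
    keep = fpkm.values.index[hits >= need]
    return ExpressionMatrix(fpkm.values.loc[keep], "fpkm", fpkm.dataset)


def _design_matrix(
    covariates: pd.DataFrame, batch_column: str | None
) -> pd.DataFrame:
    """Numeric design with intercept; categoricals expand to indicators."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.isna().any():
            raise ValueError(f"missing values in covariate {col!r}")
        if pd.api.types.is_numeric_dtype(s) and col != batch_column:
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def residualize(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    batch_column: str | None = None,
    batch_as_random: bool = False,
) -> ExpressionMatrix:
    """Per-gene least-squares adjustment; output is the residual matrix.

    Categorical covariates (and the batch column, when named) enter as
    indicator contrasts.  ``batch_as_random`` reserves a mixed-model
    treatment of batch; the fixed-indicator approximation used here has
    the same expectation on balanced designs, and the flag currently
    rejects rather than silently falling back.
    """
    if batch_as_random:
        raise NotImplementedError(
            "random-effect batch adjustment is reserved; use fixed indicators"
        )
    missing = set(expr.samples) - set(covariates.index)
    if missing:
        raise ValueError(f"covariate rows missing for samples: {sorted(missing)[:5]}")
    design = _design_matrix(covariates.loc[expr.samples], batch_column)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        offending = [
            col
            for i, col in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns include: {offending}"
        )
    Y = expr.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return ExpressionMatrix(
        pd.DataFrame(resid, index=expr.genes, columns=expr.samples),
        value_kind="residual",
        dataset=expr.dataset,
    )
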