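"""Probe intensities to batch-corrected probeset expression.

The processing chain mirrors a robust-averaging microarray workflow adapted
to a dataset acquired in technical batches (operator x amplification date):

1. per-array background correction, the background being the 15th percentile
   of the tryptophan control probe intensities of that array (linear
   interpolation percentile convention), with a floor of 1.0 so the log2
   transform stays defined;
2. per-(operator, date) batch: quantile normalization of the log2 values
   followed by median-polish summarization of each probeset;
3. a two-step location/scale batch adjustment of the probeset matrix under
   the model  Y_ijg = mu_g + X beta_g + gamma_ig + delta_ig eps_ijg
   (gene-wise additive gamma and multiplicative delta batch components,
   eps ~ N(0, sigma_g)), estimated with parametric empirical-Bayes
   shrinkage: first merging amplification dates within each operator, then
   merging operators over the whole set.

All steps are deterministic; no RNG enters the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

BACKGROUND_PERCENTILE = 15.0
BACKGROUND_FLOOR = 1.0


@dataclass
class ProbeSignalMatrix:
    """Probe-by-array positive intensities plus probe metadata.

    ``probe_meta`` is indexed by probe id with columns ``probeset_id`` and
    ``is_control`` (tryptophan baseline probes used for background
    estimation only).
    """

    values: pd.DataFrame
    probe_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.values.values > 0).all():
            raise ValueError("all intensities must be positive")
        if not self.values.index.equals(self.probe_meta.index):
            raise ValueError("values and probe_meta must share the probe index")
        if not self.probe_meta["is_control"].any():
            raise ValueError("at least one tryptophan control probe is required")

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values.loc[self.probe_meta["is_control"]]

    @property
    def signal_values(self) -> pd.DataFrame:
        return self.values.loc[~self.probe_meta["is_control"]]


@dataclass
class BatchDesign:
    """Sample sheet: per-array operator, amplification date, covariate, set.

    The covariate is the single qualitative biological factor (tissue origin
    x state) protected during batch adjustment.  ``pair_id`` (optional
    column) marks matched normal/tumor samples.
    """

    sheet: pd.DataFrame

    REQUIRED = ("operator", "amp_date", "covariate", "sample_set_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.sheet.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns: {missing}")
        if self.sheet.index.has_duplicates:
            raise ValueError("duplicate array ids in sample sheet")

    @property
    def arrays(self) -> list[str]:
        return list(self.sheet.index)

    def batch_key(self) -> pd.Series:
        return self.sheet["operator"].astype(str) + "/" + self.sheet["amp_date"].astype(str)


def background_correct(matrix: ProbeSignalMatrix) -> ProbeSignalMatrix:
    """Subtract each array's tryptophan-baseline background from every probe.

    The background is the 15th percentile (linear interpolation between
    order statistics) of that array's control intensities; corrected values
    are floored at 1.0.
    """
    controls = matrix.control_values
    for array in matrix.values.columns:
        if controls[array].isna().all():
            raise ValueError(f"array {array} lacks tryptophan control values")
    background = controls.quantile(BACKGROUND_PERCENTILE / 100.0, axis=0)
    corrected = (matrix.values - background).clip(lower=BACKGROUND_FLOOR)
    return ProbeSignalMatrix(values=corrected, probe_meta=matrix.probe_meta)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    The reference distribution is the across-column mean of sorted values;
    within-column ranks are preserved and ties receive the average of the
    reference values they span.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = np.empty(arr.shape[0], dtype=int)
        ranks[order[:, j]] = np.arange(arr.shape[0])
        col = reference[ranks]
        # average reference values over tied input values
        series = pd.Series(arr[:, j])
        grouped = pd.Series(col).groupby(series).transform("mean")
        out[:, j] = grouped.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_polish(
    block: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way fit by alternating row/column median sweeps.

    Returns (overall, row_effects, col_effects, residuals).  Iteration stops
    when the largest absolute change falls below ``tol`` or after
    ``max_iter`` sweeps.
    """
    resid = np.asarray(block, dtype=float).copy()
    nr, nc = resid.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    for _ in range(max_iter):
        delta = 0.0
        row_med = np.median(resid, axis=1)
        resid -= row_med[:, None]
        row_eff += row_med
        delta = max(delta, np.abs(row_med).max(initial=0.0))
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift
        col_med = np.median(resid, axis=0)
        resid -= col_med[None, :]
        col_eff += col_med
        delta = max(delta, np.abs(col_med).max(initial=0.0))
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift
        if delta < tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(probe_block: pd.DataFrame) -> pd.Series:
    """Per-array summary of one probeset's log2 probe block.

    The summary is the overall effect plus the array (column) effect; probe
    (row) effects absorb affinity differences.  A single-probe probeset
    reduces to that probe's values.
    """
    if probe_block.shape[0] == 1:
        return probe_block.iloc[0].astype(float)
    overall, _, col_eff, _ = median_polish(probe_block.to_numpy(dtype=float))
    return pd.Series(overall + col_eff, index=probe_block.columns)


def rma_summarize(matrix: ProbeSignalMatrix, skip_quantile: bool = False) -> pd.DataFrame:
    """Quantile normalization + median polish for one batch of arrays.

    Operates on log2 of the (background-corrected) non-control probes and
    returns a probeset x array matrix on the log2 scale.
    """
    signals = np.log2(matrix.signal_values)
    if not skip_quantile and signals.shape[1] >= 2:
        signals = quantile_normalize(signals)
    meta = matrix.probe_meta.loc[~matrix.probe_meta["is_control"]]
    out = {}
    for probeset_id, probe_ids in meta.groupby("probeset_id").groups.items():
        out[probeset_id] = median_polish_summarize(signals.loc[probe_ids])
    result = pd.DataFrame(out).T
    result.index.name = "probeset_id"
    return result.loc[sorted(result.index)]


# ---------------------------------------------------------------------------
# location/scale batch adjustment with empirical-Bayes shrinkage


def _design_matrix(batch: pd.Series, covariate: pd.Series | None) -> np.ndarray:
    batches = pd.get_dummies(batch).to_numpy(dtype=float)
    blocks = [batches]
    if covariate is not None:
        cov = pd.get_dummies(covariate, drop_first=True).to_numpy(dtype=float)
        if cov.size:
            blocks.append(cov)
    design = np.hstack(blocks)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate is confounded with batch")
    return design


def combat_adjust(
    expr: pd.DataFrame,
    batches: pd.Series,
    covariate: pd.Series | None = None,
    shrink: bool = True,
) -> pd.DataFrame:
    """Remove gene-wise additive/multiplicative batch components.

    Fits the model Y_ijg = mu_g + X beta_g + gamma_ig + delta_ig eps_ijg by
    gene-wise least squares, standardizes, and estimates gamma (normal
    prior) and delta^2 (inverse-gamma prior) with parametric empirical-Bayes
    shrinkage whose hyperpriors are moment-matched across genes.  With
    ``shrink=False`` the raw per-batch location/scale estimates are used
    (useful on tiny simulations where cross-gene moments are unstable).
    A single batch is returned unchanged; a batch with fewer than two
    arrays, or a covariate confounded 1:1 with batch, is an error.
    """
    batches = batches.loc[expr.columns]
    labels = batches.unique()
    if len(labels) < 2:
        return expr.copy()
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 arrays: {list(small.index)}")
    if covariate is not None:
        covariate = covariate.loc[expr.columns]

    Y = expr.to_numpy(dtype=float)  # genes x arrays
    design = _design_matrix(batches, covariate)
    n_batch = len(labels)
    n_arrays = Y.shape[1]
    batch_onehot = pd.get_dummies(batches).to_numpy(dtype=float)
    batch_order = list(pd.get_dummies(batches).columns)

    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # params x genes
    grand = (sizes.loc[batch_order].to_numpy() / n_arrays) @ B_hat[:n_batch]
    stand_mean = np.tile(grand[:, None], (1, n_arrays))
    if design.shape[1] > n_batch:
        cov_part = design[:, n_batch:] @ B_hat[n_batch:]
        stand_mean = stand_mean + cov_part.T
    resid = Y - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((n_batch, Y.shape[0]))
    delta2_hat = np.empty((n_batch, Y.shape[0]))
    for i, label in enumerate(batch_order):
        members = batch_onehot[:, i].astype(bool)
        Zi = Z[:, members]
        gamma_hat[i] = Zi.mean(axis=1)
        delta2_hat[i] = Zi.var(axis=1, ddof=1)
    delta2_hat = np.where(delta2_hat <= 0, 1e-12, delta2_hat)

    if shrink:
        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for i, label in enumerate(batch_order):
            n_i = int(sizes.loc[label])
            g_bar = gamma_hat[i].mean()
            tau2 = gamma_hat[i].var(ddof=1)
            d_bar = delta2_hat[i].mean()
            s2 = delta2_hat[i].var(ddof=1)
            # inverse-gamma moment matching
            lam = (d_bar**2 + 2 * s2) / s2 if s2 > 0 else 2.0 + 1e6
            theta = (d_bar**3 + d_bar * s2) / s2 if s2 > 0 else d_bar * 1e6
            g_new = gamma_hat[i].copy()
            d_new = delta2_hat[i].copy()
            members = batch_onehot[:, i].astype(bool)
            Zi = Z[:, members]
            for _ in range(100):
                g_prev, d_prev = g_new.copy(), d_new.copy()
                if tau2 > 0:
                    g_new = (n_i * tau2 * gamma_hat[i] + d_new * g_bar) / (
                        n_i * tau2 + d_new
                    )
                else:
                    g_new = np.full_like(gamma_hat[i], g_bar)
                sse = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sse) / (n_i / 2.0 + lam - 1.0)
                if (
                    np.abs(g_new - g_prev).max(initial=0) < 1e-8
                    and np.abs(d_new - d_prev).max(initial=0) < 1e-8
                ):
                    break
            gamma_star[i] = g_new
            delta2_star[i] = np.where(d_new <= 0, 1e-12, d_new)
    else:
        gamma_star, delta2_star = gamma_hat, delta2_hat

    adjusted = Z.copy()
    for i in range(n_batch):
        members = batch_onehot[:, i].astype(bool)
        adjusted[:, members] = (
            Z[:, members] - gamma_star[i][:, None]
        ) / np.sqrt(delta2_star[i])[:, None]
    result = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(result, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    expression: pd.DataFrame  # probesets x arrays, log2
    log: list[str] = field(default_factory=list)


def normalize_dataset(
    matrix: ProbeSignalMatrix,
    design: BatchDesign,
    shrink: bool = True,
) -> PipelineResult:
    """Background -> per-(operator, date) RMA -> nested batch adjustment.

    The batch merge is two-step: amplification dates are merged within each
    operator first, then operators are merged over the entire set, both
    protecting the biological covariate.  Stages that are degenerate for the
    design at hand (single date within an operator, single operator) are
    skipped and logged.
    """
    missing = [a for a in matrix.values.columns if a not in design.sheet.index]
    if missing:
        raise ValueError(f"arrays missing from sample sheet: {missing}")
    extra = [a for a in design.sheet.index if a not in matrix.values.columns]
    if extra:
        raise ValueError(f"sample sheet arrays missing from signals: {extra}")

    log: list[str] = []
    corrected = background_correct(matrix)
    log.append("background: tryptophan 15th percentile subtracted, floor 1.0")

    sheet = design.sheet
    blocks = []
    for (operator, date), group in sheet.groupby(["operator", "amp_date"], sort=True):
        arrays = list(group.index)
        sub = ProbeSignalMatrix(
            values=corrected.values[arrays], probe_meta=corrected.probe_meta
        )
        skip_qn = len(arrays) < 2
        summary = rma_summarize(sub, skip_quantile=skip_qn)
        blocks.append(summary)
        log.append(
            f"rma[{operator}/{date}]: {len(arrays)} arrays"
            + (" (single array: quantile normalization skipped)" if skip_qn else "")
        )
    expr = pd.concat(blocks, axis=1)[list(sheet.index)]

    # step 1: merge amplification dates within each operator
    merged = []
    for operator, group in sheet.groupby("operator", sort=True):
        arrays = list(group.index)
        dates = group["amp_date"]
        sub = expr[arrays]
        if dates.nunique() < 2:
            log.append(f"combat-dates[{operator}]: single date, skipped")
            merged.append(sub)
            continue
        adjusted = combat_adjust(
            sub, dates, covariate=group["covariate"], shrink=shrink
        )
        log.append(f"combat-dates[{operator}]: merged {dates.nunique()} dates")
        merged.append(adjusted)
    expr = pd.concat(merged, axis=1)[list(sheet.index)]

    # step 2: merge operators over the entire chip set
    operators = sheet["operator"]
    if operators.nunique() >= 2:
        expr = combat_adjust(
            expr, operators, covariate=sheet["covariate"], shrink=shrink
        )
        log.append(f"combat-operators: merged {operators.nunique()} operators")
    else:
        log.append("combat-operators: single operator, skipped")
    return PipelineResult(expression=expr, log=log)


def aggregate_sample_sets(
    expr: pd.DataFrame, design: BatchDesign, how: str = "mean"
) -> pd.DataFrame:
    """Collapse arrays into sample sets (arithmetic mean by default).

    ``how`` may be "mean" or "median".  Every array must map to a set and
    every set must be non-empty.
    """
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    sets = design.sheet["sample_set_id"]
    missing = [a for a in expr.columns if a not in sets.index]
    if missing:
        raise ValueError(f"arrays without sample set: {missing}")
    groups = sets.loc[expr.columns]
    out = expr.T.groupby(groups).agg(how).T
    if (out.isna()).any().any():
        raise ValueError("empty sample set after aggregation")
    return out
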