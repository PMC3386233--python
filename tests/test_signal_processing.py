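"""Background correction, normalization, summarization, batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from hervarray.signal_processing import (
    BatchDesign,
    ProbeSignalMatrix,
    aggregate_sample_sets,
    background_correct,
    combat_adjust,
    median_polish,
    median_polish_summarize,
    normalize_dataset,
    quantile_normalize,
    rma_summarize,
)


def _matrix(values, n_controls=2, control_value=10.0):
    n_probes, n_arrays = values.shape
    probe_ids = [f"p{i}" for i in range(n_probes)] + [f"trp{i}" for i in range(n_controls)]
    arrays = [f"a{j}" for j in range(n_arrays)]
    full = np.vstack([values, np.full((n_controls, n_arrays), control_value)])
    meta = pd.DataFrame(
        {
            "probeset_id": [f"ps{i // 2}" for i in range(n_probes)] + ["trp"] * n_controls,
            "is_control": [False] * n_probes + [True] * n_controls,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeSignalMatrix(
        values=pd.DataFrame(full, index=meta.index, columns=arrays), probe_meta=meta
    )


class TestBackgroundCorrect:
    def test_constant_controls_subtract_exactly(self):
        m = _matrix(np.full((4, 3), 100.0), control_value=30.0)
        out = background_correct(m)
        assert (out.signal_values.to_numpy() == 70.0).all()

    def test_floor_applies_below_background(self):
        m = _matrix(np.full((4, 2), 5.0), control_value=30.0)
        out = background_correct(m)
        assert (out.signal_values.to_numpy() == 1.0).all()

    def test_percentile_follows_linear_interpolation(self):
        """20 control values 1..20 give a 15th percentile of 3.85."""
        n_controls = 20
        vals = np.full((2, 1), 50.0)
        m = _matrix(vals, n_controls=n_controls)
        m.values.loc[[f"trp{i}" for i in range(20)], "a0"] = np.arange(1.0, 21.0)
        out = background_correct(m)
        assert out.signal_values.iloc[0, 0] == pytest.approx(50.0 - 3.85)

    def test_matrix_without_controls_rejected(self):
        with pytest.raises(ValueError, match="control"):
            ProbeSignalMatrix(
                values=pd.DataFrame([[1.0]], index=["p0"], columns=["a0"]),
                probe_meta=pd.DataFrame(
                    {"probeset_id": ["ps0"], "is_control": [False]}, index=["p0"]
                ),
            )


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0, 5.0])
        df = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(quantile_normalize(df), df)

    def test_monotone_transform_collapses_to_same_column(self):
        a = np.array([0.5, 2.0, 1.0, 4.0])
        df = pd.DataFrame({"a": a, "b": 3 * a + 1})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], out["b"])

    def test_matches_sort_mean_unsort_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(5, 3))
        df = pd.DataFrame(arr)
        out = quantile_normalize(df).to_numpy()
        reference = np.sort(arr, axis=0).mean(axis=1)
        expected = np.empty_like(arr)
        for j in range(3):
            ranks = np.argsort(np.argsort(arr[:, j]))
            expected[:, j] = reference[ranks]
        assert np.allclose(out, expected)

    def test_all_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(size=(40, 6)))
        out = quantile_normalize(df).to_numpy()
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))

    def test_ties_receive_equal_values(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]


def _independent_medpolish(x, iters=200):
    """Textbook alternating-median fit, written independently of the package.

    Returns grand effect + column effects (the per-array summaries).
    """
    x = x.astype(float).copy()
    grand = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(iters):
        rm = np.median(x, axis=1)
        x -= rm[:, None]
        row += rm
        shift = np.median(col)
        col -= shift
        grand += shift
        cm = np.median(x, axis=0)
        x -= cm[None, :]
        col += cm
        shift = np.median(row)
        row -= shift
        grand += shift
    return grand + col, x


class TestMedianPolish:
    def test_additive_block_is_exact_fixed_point(self):
        r = np.array([0.0, 1.0, -1.0, 2.0])
        c = np.array([5.0, 6.0, 7.0])
        block = r[:, None] + c[None, :]
        overall, row_eff, col_eff, resid = median_polish(block)
        assert np.allclose(resid, 0.0, atol=1e-9)
        summary = overall + col_eff
        assert np.allclose(summary, c + np.median(r))

    def test_single_probe_returns_its_values(self):
        block = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        assert median_polish_summarize(block).tolist() == [1.0, 2.0, 3.0]

    def test_outlier_cell_barely_moves_summary(self):
        """With >= 5 probes one gross outlier leaves summaries unchanged."""
        rng = np.random.default_rng(2)
        r = rng.normal(size=6)
        c = rng.normal(7, 1, size=4)
        clean = pd.DataFrame(r[:, None] + c[None, :])
        dirty = clean.copy()
        dirty.iloc[2, 1] += 50.0
        s_clean = median_polish_summarize(clean)
        s_dirty = median_polish_summarize(dirty)
        assert np.allclose(s_clean, s_dirty, atol=1e-6)

    def test_residual_medians_vanish_at_convergence(self):
        rng = np.random.default_rng(3)
        block = rng.normal(size=(7, 5)) + rng.normal(size=(7, 1))
        _, _, _, resid = median_polish(block, max_iter=50)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(4)
        block = rng.normal(size=(8, 5))
        overall, row_eff, col_eff, resid = median_polish(block, max_iter=200)
        summary, _ = _independent_medpolish(block)
        assert np.allclose(overall + col_eff, summary, atol=1e-4)


def _simulated_batches(seed=0, n_genes=120, n_arrays=24, gamma=2.0, delta=3.0, beta=0.8):
    rng = np.random.default_rng(seed)
    arrays = [f"a{i}" for i in range(n_arrays)]
    half = n_arrays // 2
    batch = pd.Series(["b1"] * half + ["b2"] * half, index=arrays)
    cov = pd.Series((["x", "y"] * (half // 2)) * 2, index=arrays)
    mu = rng.normal(7, 1, size=n_genes)[:, None]
    betas = rng.normal(beta, 0.1, size=n_genes)[:, None]
    x = (cov == "y").to_numpy().astype(float)[None, :]
    g = np.where(batch == "b2", gamma, 0.0)[None, :]
    d = np.where(batch == "b2", delta, 1.0)[None, :]
    Y = mu + betas * x + g + d * rng.normal(0, 0.5, size=(n_genes, n_arrays))
    expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)], columns=arrays)
    return expr, batch, cov, betas.ravel(), x.ravel()


class TestCombatAdjust:
    def test_single_batch_is_identity(self):
        expr, batch, cov, *_ = _simulated_batches()
        one = pd.Series("b1", index=expr.columns)
        out = combat_adjust(expr, one, cov)
        assert np.allclose(out, expr, atol=1e-8)

    def test_removes_location_and_scale(self):
        """Known gamma=2 / delta=3 batch distortions are taken out."""
        rng = np.random.default_rng(1)
        n_genes, n_arrays = 200, 20
        arrays = [f"a{i}" for i in range(n_arrays)]
        batch = pd.Series(["b1"] * 10 + ["b2"] * 10, index=arrays)
        mu = rng.normal(7, 1, size=n_genes)[:, None]
        g = np.where(batch == "b2", 2.0, 0.0)[None, :]
        d = np.where(batch == "b2", 3.0, 1.0)[None, :]
        Y = mu + g + d * rng.normal(0, 0.5, size=(n_genes, n_arrays))
        expr = pd.DataFrame(Y, index=range(n_genes), columns=arrays)
        out = combat_adjust(expr, batch).to_numpy()
        b2 = (batch == "b2").to_numpy()
        mean_diff = out[:, b2].mean(axis=1) - out[:, ~b2].mean(axis=1)
        var_ratio = out[:, b2].var(axis=1, ddof=1) / out[:, ~b2].var(axis=1, ddof=1)
        assert abs(mean_diff.mean()) < 0.1
        # geometric mean: a ratio of sample variances is F-distributed with a
        # mean above 1 even under perfect adjustment
        assert 0.8 < np.exp(np.log(var_ratio).mean()) < 1.25

    def test_covariate_effect_preserved(self):
        expr, batch, cov, betas, x = _simulated_batches(seed=2)
        out = combat_adjust(expr, batch, cov)
        X = np.column_stack([np.ones(len(x)), x])
        B, *_ = np.linalg.lstsq(X, out.to_numpy().T, rcond=None)
        est = B[1]
        err = est - betas
        mc_se = err.std(ddof=1) / np.sqrt(len(err))
        assert abs(err.mean()) < 2 * mc_se + 1e-9

    def test_null_batches_barely_adjust(self):
        expr, batch, cov, *_ = _simulated_batches(seed=3, gamma=0.0, delta=1.0)
        out = combat_adjust(expr, batch, cov)
        shift = (out - expr).to_numpy()
        # adjustment stays within a few noise standard errors (sd 0.5, n=12)
        assert np.abs(shift).mean() < 3 * 0.5 / np.sqrt(12)

    def test_batch_of_one_rejected(self):
        expr, batch, cov, *_ = _simulated_batches()
        batch.iloc[0] = "b3"
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_adjust(expr, batch, cov)

    def test_confounded_covariate_rejected(self):
        expr, batch, _, *_ = _simulated_batches()
        confounded = batch.copy().rename("cov")
        with pytest.raises(ValueError, match="confounded"):
            combat_adjust(expr, batch, confounded)

    def test_matches_scanpy_reference(self):
        """Independent cross-check against scanpy's batch adjustment."""
        sc = pytest.importorskip("scanpy")
        anndata = pytest.importorskip("anndata")
        expr, batch, cov, *_ = _simulated_batches(seed=4)
        mine = combat_adjust(expr, batch, cov)
        obs = pd.DataFrame(
            {"batch": batch.values, "cov": (cov == "y").astype(float).values},
            index=batch.index,
        )
        A = anndata.AnnData(expr.T.to_numpy(), obs=obs)
        sc.pp.combat(A, key="batch", covariates=["cov"])
        theirs = A.X.T
        assert np.abs(mine.to_numpy() - theirs).max() < 0.01


def _pipeline_fixture(one_batch=False):
    from hervarray.simulate import SimConfig, make_signal_dataset
    from hervarray.probe_design import CandidateProbe, Probeset

    probes = tuple(
        CandidateProbe(sequence="ACGT" * 6 + "A", locus_id="L1", part_name="U3", offset=o)
        for o in range(4)
    )
    probesets = [
        Probeset(locus_id=f"L{i}", part_name="U3", probes=probes, ltr_role="solo")
        for i in range(1, 4)
    ]
    config = SimConfig(
        seed=9,
        operators=("op1",) if one_batch else ("op1", "op2"),
        dates_per_operator=1 if one_batch else 2,
        n_background_probesets=10,
    )
    return make_signal_dataset(config, probesets), config


class TestNormalizeDataset:
    def test_single_operator_single_date_reduces_to_rma(self):
        (matrix, design, _), _ = _pipeline_fixture(one_batch=True)
        result = normalize_dataset(matrix, design)
        expected = rma_summarize(background_correct(matrix))
        assert np.allclose(result.expression, expected[result.expression.columns])
        assert any("skipped" in line for line in result.log)

    def test_missing_array_named_in_error(self):
        (matrix, design, _), _ = _pipeline_fixture()
        trimmed = BatchDesign(sheet=design.sheet.iloc[:-1])
        with pytest.raises(ValueError, match=design.sheet.index[-1]):
            normalize_dataset(matrix, trimmed)

    def test_batch_effects_removed_on_fixture(self):
        """Implanted operator/date offsets leave no dominant batch signal."""
        (matrix, design, truth), _ = _pipeline_fixture()
        result = normalize_dataset(matrix, design)
        expr = result.expression
        batch = design.batch_key().loc[expr.columns]
        f_obs = _batch_f(expr.to_numpy(), batch.to_numpy())
        rng = np.random.default_rng(0)
        exceed = np.zeros(len(f_obs))
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(batch.to_numpy())
            exceed += _batch_f(expr.to_numpy(), perm) >= f_obs
        p_values = (exceed + 1) / (n_perm + 1)
        assert (p_values > 0.05).mean() >= 0.9


def _batch_f(values, labels):
    groups = [values[:, labels == b] for b in np.unique(labels)]
    overall = values.mean(axis=1)
    between = sum(g.shape[1] * (g.mean(axis=1) - overall) ** 2 for g in groups) / (
        len(groups) - 1
    )
    within = sum(
        ((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups
    ) / (values.shape[1] - len(groups))
    return between / np.where(within == 0, np.nan, within)


class TestAggregateSampleSets:
    def _design(self):
        sheet = pd.DataFrame(
            {
                "operator": ["o"] * 4,
                "amp_date": ["d"] * 4,
                "covariate": ["c"] * 4,
                "sample_set_id": ["s1", "s1", "s2", "s2"],
            },
            index=pd.Index(["a1", "a2", "a3", "a4"], name="array_id"),
        )
        return BatchDesign(sheet=sheet)

    def test_mean_of_member_arrays(self):
        expr = pd.DataFrame([[4.0, 6.0, 1.0, 3.0]], index=["ps"], columns=["a1", "a2", "a3", "a4"])
        out = aggregate_sample_sets(expr, self._design())
        assert out.loc["ps", "s1"] == 5.0 and out.loc["ps", "s2"] == 2.0

    def test_identical_arrays_preserve_value(self):
        expr = pd.DataFrame([[7.0] * 4], index=["ps"], columns=["a1", "a2", "a3", "a4"])
        out = aggregate_sample_sets(expr, self._design())
        assert (out.loc["ps"] == 7.0).all()

    def test_array_without_set_rejected(self):
        expr = pd.DataFrame([[1.0] * 5], index=["ps"], columns=["a1", "a2", "a3", "a4", "a5"])
        with pytest.raises(ValueError, match="a5"):
            aggregate_sample_sets(expr, self._design())
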