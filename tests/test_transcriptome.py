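"""Tests for count filtering, TMM, log-CPM, precision weights, the DE
contrast and PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from persistome import stats
from persistome import synthetic as syn
from persistome import transcriptome as rna
from persistome.errors import DesignError, FilterError

from conftest import permute_arms_within_lines

# ---------------------------------------------------------------------------
# filter_low_expression


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(
        arr, index=pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene_id"), columns=samples
    )


def _sheet_for(samples, arm="TGFB1"):
    rows = []
    for i, s in enumerate(samples):
        rows.append(
            {
                "sample_id": s,
                "cell_line": f"L{i % 3 + 1}",
                "arm": "MOCK" if i % 2 == 0 else arm,
                "timepoint": "T1",
            }
        )
    return pd.DataFrame(rows)


def test_low_expression_filter_hand_enumerable():
    # library sizes ~1e6 so counts ~ CPM
    base = np.full((6, 4), 0)
    counts = _counts(
        [
            [0, 0, 0, 0],  # removed: all zero
            [5, 5, 5, 5],  # kept: CPM ~5 everywhere
            [2, 0, 0, 0],  # removed: above cutoff in 1 sample < min_samples=2
            [2, 2, 0, 0],  # kept: above cutoff in exactly 2
            [1, 1, 1, 1],  # removed: CPM ~1 is not > min_cpm
            [1000, 1000, 1000, 1000],
        ]
    )
    filler = _counts(np.full((1, 4), 10**6 - counts.sum(axis=0).to_numpy()))
    filler.index = ["filler"]
    counts = pd.concat([counts, filler])
    sheet = _sheet_for(list(counts.columns))
    kept = rna.filter_low_expression(counts, sheet, min_cpm=1.0, min_samples=2)
    assert list(kept.index) == ["g1", "g3", "g5", "filler"]


def test_low_expression_filter_empty_result_is_error():
    counts = _counts([[1, 1], [1, 1]])
    sheet = _sheet_for(list(counts.columns))
    with pytest.raises(FilterError):
        rna.filter_low_expression(counts, sheet, min_cpm=1e9, min_samples=1)


# ---------------------------------------------------------------------------
# TMM


def oracle_tmm_pair(yk, yr, Nk, Nr):
    """Independent trimmed-mean-of-M reimplementation (naive, loop-based)."""
    records = []
    for a, b in zip(yk, yr):
        if a > 0 and b > 0:
            M = math.log2((a / Nk) / (b / Nr))
            A = 0.5 * math.log2((a / Nk) * (b / Nr))
            v = (Nk - a) / (Nk * a) + (Nr - b) / (Nr * b)
            records.append((M, A, v))
    n = len(records)
    if max(abs(r[0]) for r in records) < 1e-6:
        return 1.0
    m_rank = pd.Series([r[0] for r in records]).rank().to_numpy()
    a_rank = pd.Series([r[1] for r in records]).rank().to_numpy()
    loL, hiL = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
    loS, hiS = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
    num = den = 0.0
    for (M, A, v), rm, ra in zip(records, m_rank, a_rank):
        if loL <= rm <= hiL and loS <= ra <= hiS:
            num += M / v
            den += 1.0 / v
    return 2.0 ** (num / den)


def test_tmm_identical_columns_unit_factors():
    counts = _counts(np.tile([[10], [100], [1000], [50]], (1, 3)))
    nf = rna.tmm_normalize(counts)
    assert np.allclose(nf.factor, 1.0, atol=1e-12)


def test_tmm_pure_depth_difference_unit_factors():
    rng = np.random.default_rng(1)
    col = rng.integers(1, 1000, size=200)
    counts = _counts(np.column_stack([col, 2 * col]))
    nf = rna.tmm_normalize(counts)
    assert np.allclose(nf.factor, 1.0, atol=1e-9)


def test_tmm_composition_bias_matches_oracle():
    rng = np.random.default_rng(4)
    base = rng.integers(5, 2000, size=300).astype(float)
    spiked = base * rng.uniform(0.9, 1.1, 300)
    spiked[:30] *= 8  # 10% of genes massively up in sample 2 -> composition bias
    counts = _counts(np.column_stack([base, spiked, base * rng.uniform(0.8, 1.2, 300)]).round())
    nf = rna.tmm_normalize(counts, ref_sample="s0")
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    raw = [1.0] + [oracle_tmm_pair(Y[:, j], Y[:, 0], lib[j], lib[0]) for j in (1, 2)]
    expected = np.array(raw) / np.exp(np.mean(np.log(raw)))
    assert np.allclose(nf.factor, expected, atol=1e-9)
    # extra content inflates the spiked library and dilutes the unchanged
    # majority, so its compensating factor moves below 1
    assert raw[1] < 1.0
    assert np.exp(np.mean(np.log(nf.factor))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_nearly_invariant_to_column_rescaling():
    # M, A and the trim are exactly scale-free; only the shared-variance
    # weighting shifts slightly when one library is rescaled alone.
    rng = np.random.default_rng(2)
    counts = _counts(rng.integers(1, 500, size=(100, 3)))
    nf1 = rna.tmm_normalize(counts, ref_sample="s0")
    scaled = counts.copy()
    scaled["s1"] = scaled["s1"] * 7
    nf2 = rna.tmm_normalize(scaled, ref_sample="s0")
    assert np.allclose(nf1.factor, nf2.factor, rtol=0.02)
    # rescaling every column together is exactly neutral
    nf3 = rna.tmm_normalize(counts * 7, ref_sample="s0")
    assert np.allclose(nf1.factor, nf3.factor, atol=1e-12)


# ---------------------------------------------------------------------------
# log_cpm


def test_log_cpm_zero_counts_finite_and_scale_invariant():
    counts = _counts([[0, 10], [100, 200]])
    nf = rna.tmm_normalize(counts)
    lc = rna.log_cpm(counts, nf, prior_count=0.5)
    assert np.isfinite(lc.to_numpy()).all()
    doubled = counts * 2
    nf2 = rna.NormFactors(nf.sample_ids, nf.lib_size * 2, nf.factor)
    lc2 = rna.log_cpm(doubled, nf2, prior_count=0.5)
    pd.testing.assert_frame_equal(lc, lc2)


def test_log_cpm_hand_computed_toy():
    counts = _counts([[10, 20], [90, 180]])
    nf = rna.NormFactors(["s0", "s1"], np.array([100.0, 200.0]), np.array([1.0, 1.0]))
    lc = rna.log_cpm(counts, nf, prior_count=0.5)
    assert lc.iloc[0, 0] == pytest.approx(math.log2(10 / 100 * 1e6 + 0.5))
    assert lc.iloc[1, 1] == pytest.approx(math.log2(180 / 200 * 1e6 + 0.5))
    # monotone in y
    assert lc.iloc[1, 0] > lc.iloc[0, 0]


# ---------------------------------------------------------------------------
# precision weights


def _study_counts(seed=0, disp=0.05, n_genes=300, log_sd=1.0):
    sheet = syn.generate_design(3, ["MOCK", "TGFB1"], ["T1"], seed=0)
    cfg = syn.ExprTruthConfig(dispersion=disp, baseline_log_sd=log_sd)
    counts, _ = syn.simulate_transcriptome(
        [f"G{i:04d}" for i in range(n_genes)], sheet, cfg, seed=seed
    )
    return counts, sheet


def test_weights_positive_and_low_counts_downweighted():
    counts, sheet = _study_counts(seed=3)
    from persistome.methylome import treatment_design

    _, design = treatment_design(sheet, "TGFB1", "T1")
    kept = rna.filter_low_expression(counts, sheet)
    nf = rna.tmm_normalize(kept)
    w = rna.mean_variance_weights(kept, nf, design)
    assert w.shape == kept.shape
    assert np.isfinite(w).all() and (w > 0).all()
    # counting noise falls with abundance: mean weight of the top-expression
    # quartile exceeds that of the bottom quartile
    mean_count = kept.mean(axis=1).to_numpy()
    order = np.argsort(mean_count)
    q = len(order) // 4
    assert w[order[-q:]].mean() > w[order[:q]].mean()


def test_weights_roughly_constant_for_homoskedastic_data():
    # equal-abundance genes, enough residual df that the per-gene sd is a
    # stable estimate: the trend has nothing to explain
    rng = np.random.default_rng(8)
    n_samples = 20
    X = np.column_stack([np.ones(n_samples), np.repeat([0.0, 1.0], n_samples // 2)])
    counts = _counts(rng.poisson(5000, size=(300, n_samples)))
    nf = rna.tmm_normalize(counts)
    w = rna.mean_variance_weights(counts, nf, X)
    assert np.std(w) / np.mean(w) < 0.2


def test_weights_fall_back_to_unit_below_50_genes():
    counts, sheet = _study_counts(n_genes=20)
    from persistome.methylome import treatment_design

    _, design = treatment_design(sheet, "TGFB1", "T1")
    nf = rna.tmm_normalize(counts)
    with pytest.warns(UserWarning, match="50 genes"):
        w = rna.mean_variance_weights(counts, nf, design)
    assert (w == 1.0).all()


# ---------------------------------------------------------------------------
# de_pipeline


def test_de_noiseless_fold_two_logfc_close_to_one():
    sheet = syn.generate_design(3, ["MOCK", "TGFB1"], ["T1"], seed=0)
    cfg = syn.ExprTruthConfig(
        n_up_transient=5,
        fold=2.0,
        dispersion=0.0,
        baseline_log_mean=np.log(20000.0),
        baseline_log_sd=0.3,
        libsize_range=(1.0, 1.0),
        line_sd=0.0,
        min_planted_baseline=0.0,
    )
    counts, registry = syn.simulate_transcriptome(
        [f"G{i:04d}" for i in range(200)], sheet, cfg, seed=5
    )
    table = rna.de_pipeline(counts, sheet, "TGFB1", "T1")
    planted = registry.feature_ids(layer="expression", arm="TGFB1")
    sub = table.set_index("feature_id")
    for gene in planted:
        assert abs(sub.at[gene, "logFC"] - 1.0) < 0.05


def test_de_recovery_planted_subset_with_bounded_false_positives():
    sheet = syn.generate_design(3, ["MOCK", "TGFB1"], ["T1"], seed=0)
    cfg = syn.ExprTruthConfig(
        n_up_transient=10,
        n_down_transient=10,
        fold=2.0,
        dispersion=0.01,
        min_planted_baseline=100.0,
    )
    counts, registry = syn.simulate_transcriptome(
        [f"G{i:04d}" for i in range(500)], sheet, cfg, seed=6
    )
    table = rna.de_pipeline(counts, sheet, "TGFB1", "T1")
    calls = stats.call_features(table, 0.01, 1.5)
    planted_up = registry.feature_ids(layer="expression", arm="TGFB1", sign=1)
    planted_down = registry.feature_ids(layer="expression", arm="TGFB1", sign=-1)
    assert planted_up <= calls.up
    assert planted_down <= calls.down
    n_false = len((calls.up | calls.down) - (planted_up | planted_down))
    assert n_false <= 2 * 0.01 * len(table)


def test_de_gene_reordering_invariance():
    counts, sheet = _study_counts(seed=9)
    table = rna.de_pipeline(counts, sheet, "TGFB1", "T1")
    shuffled = counts.sample(frac=1.0, random_state=1)
    table2 = rna.de_pipeline(shuffled, sheet, "TGFB1", "T1")
    a = table.sort_values("feature_id").reset_index(drop=True)
    b = table2.sort_values("feature_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_de_null_calibration_permuted_labels():
    fractions = []
    for seed in range(5):
        counts, sheet = _study_counts(seed=200 + seed, disp=0.05)
        shuffled = permute_arms_within_lines(sheet, seed)
        table = rna.de_pipeline(counts, shuffled, "TGFB1", "T1")
        fractions.append(float((table["p_value"] < 0.01).mean()))
    assert np.mean(fractions) <= 0.02


def test_de_logfc_estimates_unbiased_and_tight_across_seeds():
    """logFC recovery over 10 seeds: unbiased at dispersion 0.05, and mean
    absolute error < 0.1 once the NB noise allows it (dispersion 0.005,
    planted baselines >= 500; the delta-method se there is ~0.09)."""
    sheet = syn.generate_design(3, ["MOCK", "TGFB1"], ["T1"], seed=0)

    def run(disp, floor):
        signed, absolute = [], []
        for seed in range(10):
            cfg = syn.ExprTruthConfig(
                n_up_transient=5, n_down_transient=5, fold=2.0, dispersion=disp,
                min_planted_baseline=floor,
            )
            counts, registry = syn.simulate_transcriptome(
                [f"G{i:04d}" for i in range(300)], sheet, cfg, seed=300 + seed
            )
            table = rna.de_pipeline(counts, sheet, "TGFB1", "T1").set_index("feature_id")
            for e in registry.select(layer="expression", arm="TGFB1"):
                err = table.at[e.feature_id, "logFC"] - e.effect
                signed.append(err)
                absolute.append(abs(err))
        return np.mean(signed), np.mean(absolute)

    bias, _ = run(0.05, 100.0)
    assert abs(bias) < 0.05  # unbiased even at realistic dispersion
    _, mae = run(0.005, 500.0)
    assert mae < 0.1


# ---------------------------------------------------------------------------
# PCA


def test_pca_degenerate_geometry():
    logcpm = _counts(
        np.column_stack([np.arange(10.0), np.arange(10.0), np.arange(10.0) + [0, 1] * 5])
    ).astype(float)
    res = rna.pca_top_features(logcpm, n_top=10)
    # PC1 separates the distinct sample from the identical pair
    assert abs(res.scores.iloc[2, 0] - res.scores.iloc[0, 0]) > 1e-6
    assert res.scores.iloc[0, 0] == pytest.approx(res.scores.iloc[1, 0], abs=1e-9)
    assert res.variance_fraction[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_matches_svd_oracle_and_is_orthogonal():
    rng = np.random.default_rng(11)
    logcpm = _counts(rng.normal(size=(40, 6))).astype(float)
    res = rna.pca_top_features(logcpm, n_top=25)
    assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(res.variance_fraction) <= 1e-12)
    assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
    # oracle: eigen-decomposition of the sample covariance of the same subset
    X = logcpm.loc[res.features].to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    gram = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(gram)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    scores = res.scores.to_numpy()
    for j in range(min(4, scores.shape[1])):
        ref = evecs[:, j] * math.sqrt(max(evals[j], 0.0))
        assert np.allclose(np.abs(scores[:, j]), np.abs(ref), atol=1e-8)
    # orthogonality of score columns
    g = scores.T @ scores
    off = g - np.diag(np.diag(g))
    assert np.allclose(off, 0.0, atol=1e-8)


def test_pca_preconditions():
    logcpm = _counts(np.random.default_rng(0).normal(size=(10, 2))).astype(float)
    with pytest.raises(DesignError):
        rna.pca_top_features(logcpm, n_top=5)
    logcpm3 = _counts(np.random.default_rng(0).normal(size=(10, 3))).astype(float)
    with pytest.warns(UserWarning, match="using all"):
        res = rna.pca_top_features(logcpm3, n_top=99)
    assert len(res.features) == 10
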