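import math

import numpy as np
import pytest
from scipy import stats

from mbcdeg import (
    CountMatrix,
    NormalizationFactors,
    SizeFactors,
    cpm_offsets,
    deges_factors,
    design_from_labels,
    library_sizes,
    offsets_for_variant,
    potential_deg_pvalues,
    simulate_counts,
    size_factors_from,
    tmm_factors,
    uq_offsets,
)
from mbcdeg.simulate import SimulationScenario

from conftest import random_count_matrix


def _cm(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=np.int64)
    G, J = values.shape
    return CountMatrix(
        tuple(gene_ids or (f"g{i}" for i in range(G))),
        tuple(sample_ids or (f"s{j}" for j in range(J))),
        values,
    )


# ---------------------------------------------------------------- library sizes


def test_library_sizes_are_column_sums():
    cm = _cm([[10, 10], [0, 0], [5, 5]])
    assert np.array_equal(library_sizes(cm), [15.0, 15.0])


def test_library_sizes_all_zero_column_names_sample():
    cm = _cm([[10, 0], [5, 0]], sample_ids=("ok", "empty"))
    with pytest.raises(ValueError, match="empty"):
        library_sizes(cm)


# ---------------------------------------------------------------- UQ / CPM


def test_uq_offsets_identical_columns_are_zero():
    cm = _cm(np.tile([[8], [4], [2], [1]], (1, 3)))
    assert np.allclose(uq_offsets(cm).values, 0.0)


def test_uq_offsets_doubled_column():
    base = np.array([[8], [4], [2], [1], [16]])
    cm = _cm(np.hstack([base, 2 * base]))
    expected = np.array([-math.log(2) / 2, math.log(2) / 2])
    assert np.allclose(uq_offsets(cm).values, expected, atol=1e-12)
    # cross-check against a direct percentile computation
    q = [np.percentile(cm.values[:, j], 75) for j in range(2)]
    direct = np.log(q) - np.mean(np.log(q))
    assert np.allclose(uq_offsets(cm).values, direct)


def test_uq_offsets_sum_to_zero():
    rng = np.random.default_rng(1)
    cm = random_count_matrix(rng, G=100, J=5)
    assert abs(uq_offsets(cm).values.sum()) < 1e-12


def test_cpm_offsets_from_library_sizes():
    cm = _cm([[500_000, 1_000_000], [500_000, 1_000_000]])
    expected = np.array([-math.log(2) / 2, math.log(2) / 2])
    assert np.allclose(cpm_offsets(cm).values, expected)
    assert abs(cpm_offsets(cm).values.sum()) < 1e-12


# ---------------------------------------------------------------- TMM


def _brute_force_tmm_pair(yj, yr, Nj, Nr):
    """Independent re-derivation of the trimmed weighted mean, no shortcuts."""
    M, A, w = [], [], []
    for a, b in zip(yj, yr):
        if a > 0 and b > 0:
            M.append(math.log2((a / Nj) / (b / Nr)))
            A.append(0.5 * math.log2((a / Nj) * (b / Nr)))
            w.append(1.0 / ((Nj - a) / (Nj * a) + (Nr - b) / (Nr * b)))
    n = len(M)

    def rank_of(vals):
        # average ranks computed by explicit pair counting
        out = []
        for x in vals:
            less = sum(1 for v in vals if v < x)
            ties = sum(1 for v in vals if v == x)
            out.append(less + (ties + 1) / 2.0)
        return out

    rM, rA = rank_of(M), rank_of(A)
    loM = math.floor(n * 0.30) + 1
    hiM = n + 1 - loM
    loA = math.floor(n * 0.05) + 1
    hiA = n + 1 - loA
    num = den = 0.0
    for k in range(n):
        if loM <= rM[k] <= hiM and loA <= rA[k] <= hiA:
            num += w[k] * M[k]
            den += w[k]
    return num / den if den > 0 else 0.0


def test_tmm_identical_columns_give_unit_factors():
    cm = _cm(np.tile([[10], [30], [5], [200]], (1, 3)))
    assert np.allclose(tmm_factors(cm).values, 1.0)


def test_tmm_pure_depth_change_gives_unit_factors():
    base = np.array([[10], [30], [5], [200], [47]])
    cm = _cm(np.hstack([base, 2 * base]))
    assert np.allclose(tmm_factors(cm).values, 1.0, atol=1e-12)


def test_tmm_matches_brute_force_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(50):
        cm = random_count_matrix(rng)
        N = cm.values.sum(axis=0).astype(float)
        if np.any(N == 0):
            continue
        nf = tmm_factors(cm, ref=0)
        log2f = np.zeros(cm.n_samples)
        for j in range(1, cm.n_samples):
            log2f[j] = _brute_force_tmm_pair(cm.values[:, j], cm.values[:, 0], N[j], N[0])
        expected = 2.0 ** log2f
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(nf.values, expected, atol=1e-10)


def test_tmm_fixed_two_sample_table_matches_oracle():
    rng = np.random.default_rng(7)
    vals = rng.poisson(60, size=(20, 2)) + 1
    cm = _cm(vals)
    N = vals.sum(axis=0).astype(float)
    lf = _brute_force_tmm_pair(vals[:, 1], vals[:, 0], N[1], N[0])
    expected = np.array([1.0, 2.0 ** lf])
    expected /= np.exp(np.mean(np.log(expected)))
    assert np.allclose(tmm_factors(cm, ref=0).values, expected, atol=1e-10)


# ---------------------------------------------------------------- DEG screen


def test_constant_gene_with_equal_exposures_has_p_near_one():
    rng = np.random.default_rng(0)
    # every gene constant across samples: equal effective library sizes
    vals = np.tile(rng.integers(5, 200, size=(50, 1)), (1, 6)).astype(np.int64)
    cm = _cm(vals)
    design = design_from_labels(["A"] * 3 + ["B"] * 3)
    p = potential_deg_pvalues(cm, design, NormalizationFactors(np.ones(6)))
    assert p[0] > 0.95


def test_null_pvalues_approximately_uniform():
    ds = simulate_counts(
        SimulationScenario(G=5000, n_a=5, n_b=6, p_deg=0.0, p_a=0.5, seed=7, dispersion=0.2)
    )
    design = design_from_labels(["A"] * 5 + ["B"] * 6)
    p = potential_deg_pvalues(ds.counts, design, tmm_factors(ds.counts))
    assert stats.kstest(p, "uniform").statistic < 0.05


def test_strong_effect_gene_detected():
    design = design_from_labels(["A"] * 5 + ["B"] * 6)
    null = simulate_counts(
        SimulationScenario(G=500, n_a=5, n_b=6, p_deg=0.0, p_a=0.5, seed=3, dispersion=0.1)
    )
    rng = np.random.default_rng(3)
    vals = null.counts.values.copy()
    r = 1 / 0.1
    vals[0, :5] = rng.negative_binomial(r, r / (r + 400), 5)
    vals[0, 5:] = rng.negative_binomial(r, r / (r + 100), 6)
    cm = _cm(vals)
    p = potential_deg_pvalues(cm, design, tmm_factors(cm))
    assert p[0] < 1e-4


def test_bh_adjustment_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    ours = stats.false_discovery_control(p, method="bh")
    theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)


def test_multigroup_design_rejected():
    cm = _cm(np.ones((10, 6), dtype=np.int64) * 5)
    design = design_from_labels(["A", "A", "B", "B", "C", "C"])
    with pytest.raises(ValueError, match="two-group"):
        potential_deg_pvalues(cm, design, NormalizationFactors(np.ones(6)))


# ---------------------------------------------------------------- DEGES


def test_deges_identical_columns_give_unit_factors():
    cm = _cm(np.tile([[10], [30], [5], [200]] * 5, (1, 6)))
    design = design_from_labels(["A"] * 3 + ["B"] * 3)
    assert np.allclose(deges_factors(cm, design).values, 1.0)


def test_deges_close_to_tmm_without_degs(design_5v6):
    ds = simulate_counts(
        SimulationScenario(G=2000, n_a=5, n_b=6, p_deg=0.0, p_a=0.5, seed=11)
    )
    f_tmm = tmm_factors(ds.counts).values
    f_deges = deges_factors(ds.counts, design_5v6).values
    assert np.max(np.abs(np.log(f_deges / f_tmm))) < 0.02


def test_deges_factors_lower_in_group_a_under_biased_degs(design_5v6):
    ds = simulate_counts(
        SimulationScenario(G=2000, n_a=5, n_b=6, p_deg=0.2, p_a=0.9, fc_a=4, fc_b=9, seed=12)
    )
    f = deges_factors(ds.counts, design_5v6).values
    assert f[:5].mean() < f[5:].mean()


# ---------------------------------------------------------------- size factors


def test_size_factors_unit_case():
    sf = size_factors_from(NormalizationFactors(np.array([1.0, 1.0])), [100.0, 100.0])
    assert np.allclose(sf.values, 1.0)


def test_size_factors_hand_computed_example():
    nf = NormalizationFactors(np.array([1.2, 0.833333]))
    sf = size_factors_from(nf, [100.0, 200.0])
    assert np.allclose(sf.values, [0.8372, 1.1628], atol=2e-4)


def test_size_factor_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        size_factors_from(NormalizationFactors(np.array([1.0, 1.0])), [100.0, 200.0, 300.0])


def test_constructor_normalization_conventions():
    rng = np.random.default_rng(9)
    for _ in range(20):
        raw = rng.lognormal(0, 0.4, size=4)
        nf = NormalizationFactors(raw)
        assert abs(np.exp(np.mean(np.log(nf.values))) - 1.0) < 1e-9
        sf = SizeFactors(raw)
        assert abs(sf.values.mean() - 1.0) < 1e-9


# ---------------------------------------------------------------- variants


def test_variant4_identical_columns_gives_zero_offsets():
    cm = _cm(np.tile([[10], [30], [5], [200]] * 5, (1, 6)))
    design = design_from_labels(["A"] * 3 + ["B"] * 3)
    assert np.allclose(offsets_for_variant(cm, design, 4).values, 0.0)
    assert abs(offsets_for_variant(cm, design, 4).values.sum()) < 1e-9


def test_variant2_offsets_sum_nonpositive(design_5v6):
    # AM-GM: mean-one size factors have non-positive mean log
    rng = np.random.default_rng(13)
    for seed in range(3):
        ds = simulate_counts(
            SimulationScenario(G=800, n_a=5, n_b=6, p_deg=0.2, p_a=0.7, seed=seed)
        )
        o = offsets_for_variant(ds.counts, design_5v6, 2)
        assert o.values.sum() <= 1e-9


def test_variant4_offsets_sum_to_zero(fig2_dataset, design_5v6):
    o = offsets_for_variant(fig2_dataset.counts, design_5v6, 4)
    assert abs(o.values.sum()) < 1e-9


def test_unknown_variant_rejected(fig2_dataset, design_5v6):
    with pytest.raises(ValueError, match="variant"):
        offsets_for_variant(fig2_dataset.counts, design_5v6, 5)


# ---------------------------------------------------------------- factor semantics


def test_size_vs_normalization_factor_ordering_under_biased_degs(design_5v6):
    """With most DEGs up in group A, size factors run high in A while
    normalization factors run low in A — the two conventions move in
    opposite directions between the groups."""
    depth = (1.1, 0.9, 1.05, 0.95, 1.0, 1.0, 1.08, 0.92, 1.02, 0.98, 1.0)
    ds = simulate_counts(
        SimulationScenario(
            G=2000, n_a=5, n_b=6, p_deg=0.2, p_a=0.9, fc_a=4, fc_b=9,
            seed=12, depth_factors=depth,
        )
    )
    nf = deges_factors(ds.counts, design_5v6)
    sf = size_factors_from(nf, library_sizes(ds.counts))
    assert sf.values[:5].mean() > sf.values[5:].mean()
    assert nf.values[:5].mean() < nf.values[5:].mean()


def test_equal_library_sizes_preserve_factor_rank_order():
    f = np.array([0.8, 1.3, 1.05, 0.95])
    nf = NormalizationFactors(f)
    sf = size_factors_from(nf, np.full(4, 1e6))
    assert np.array_equal(np.argsort(nf.values), np.argsort(sf.values))
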