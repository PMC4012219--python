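import numpy as np
import pytest

from ibshe import (GenotypeMatrix, LocusInfo, RelatednessMatrix, ar1_var_omega,
                   compute_grm, effective_marker_count, filter_relatedness,
                   ld_pair, ld_pair_from_rho, pairwise_ld_cov_oracle,
                   read_gcta_grm, simulate_ar1_genotypes, standardize,
                   write_gcta_grm, SimConfig)
from ibshe.grm import single_locus_relatedness_distribution
from ibshe.ld_math import d_bounds


def _genotypes(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix([("F", f"i{i}") for i in range(calls.shape[0])],
                          [LocusInfo(id=f"s{k}") for k in range(calls.shape[1])],
                          calls)


def test_duplicated_individual_has_relatedness_one(rng):
    calls = rng.binomial(2, 0.4, size=(50, 2000)).astype(np.int8)
    calls[1] = calls[0]  # duplicate
    G = _genotypes(calls)
    grm = compute_grm(standardize(G, np.full(2000, 0.4)))
    assert grm.omega[0, 1] == pytest.approx(grm.omega[0, 0], abs=1e-12)
    assert grm.omega[0, 1] == pytest.approx(1.0, abs=0.1)


def test_parent_offspring_relatedness_half(rng):
    """Children built from one transmitted parental haplotype show E(Omega) = 0.5."""
    m, pairs = 4000, 60
    p = 0.5
    hap = lambda n: rng.random((n, m)) < p
    pa1, pa2 = hap(pairs), hap(pairs)
    child = np.where(rng.random((pairs, m)) < 0.5, pa1, pa2).astype(np.int8) + \
        hap(pairs).astype(np.int8)
    parent = (pa1.astype(np.int8) + pa2.astype(np.int8))
    calls = np.vstack([parent, child])
    grm = compute_grm(standardize(_genotypes(calls), np.full(m, p)))
    rel = np.array([grm.omega[i, i + pairs] for i in range(pairs)])
    assert abs(rel.mean() - 0.5) < 3 * rel.std(ddof=1) / np.sqrt(pairs)


def test_single_locus_distribution_moments():
    """Exhaustive single-locus relatedness distribution: E = 0, var = 1."""
    for p in (0.5, 0.3):
        vals, probs = single_locus_relatedness_distribution(p)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.dot(vals, probs) == pytest.approx(0.0, abs=1e-12)
        assert np.dot(vals**2, probs) == pytest.approx(1.0, abs=1e-12)
    # at p = 0.5 the nine products collapse to the values -2, 0, +2
    vals, probs = single_locus_relatedness_distribution(0.5)
    np.testing.assert_allclose(vals, [-2.0, 0.0, 2.0], atol=1e-12)
    np.testing.assert_allclose(probs, [0.125, 0.75, 0.125], atol=1e-12)


def test_generic_p_distribution_matches_tabulated_form():
    """The seven distinct scores and their frequencies at a generic frequency."""
    p = 0.3
    q = 1 - p
    vals = np.array([4 * p**2, -2 * p * (q - p), -4 * p * q, (q - p) ** 2,
                     2 * q * (q - p), 4 * q**2]) / (2 * p * q)
    freqs = np.array([q**4, 4 * p * q**3, 2 * p**2 * q**2, 4 * p**2 * q**2,
                      4 * p**3 * q, p**4])
    order = np.argsort(vals)
    got_v, got_p = single_locus_relatedness_distribution(p)
    np.testing.assert_allclose(got_v, vals[order], atol=1e-12)
    np.testing.assert_allclose(got_p, freqs[order], atol=1e-12)


@pytest.mark.parametrize("p_k,p_l,frac", [
    (p_k, p_l, f)
    for p_k in (0.2, 0.5, 0.7) for p_l in (0.3, 0.5, 0.8)
    for f in (-0.8, 0.0, 0.5, 1.0)])
def test_ld_cov_oracle_equals_rho_squared(p_k, p_l, frac):
    """Exhaustive 9x9 enumeration of cov(Omega_k, Omega_l) equals rho^2."""
    lo, hi = d_bounds(p_k, p_l)
    pair = ld_pair(p_k, p_l, frac * (hi if frac >= 0 else -lo))
    assert pairwise_ld_cov_oracle(pair) == pytest.approx(pair.rho**2, abs=1e-12)


def test_ld_cov_oracle_limits():
    assert pairwise_ld_cov_oracle(ld_pair(0.4, 0.6, 0.0)) == pytest.approx(0.0, abs=1e-12)
    same = ld_pair(0.5, 0.5, 0.25)  # rho = 1: the same locus twice
    assert pairwise_ld_cov_oracle(same) == pytest.approx(1.0, abs=1e-12)
    mixed = ld_pair(0.3, 0.6, 0.05)
    assert pairwise_ld_cov_oracle(mixed) == pytest.approx(mixed.rho**2, abs=1e-12)


def test_effective_marker_count_independent_loci():
    cfg = SimConfig(n=2000, m=100, rho=0.0, seed=3)
    G = simulate_ar1_genotypes(cfg)
    grm = compute_grm(standardize(G))
    stats = effective_marker_count(grm)
    assert stats.n_pairs == 2000 * 1999 // 2
    assert abs(stats.mean_omega) < 0.01
    assert 90 < stats.me < 110


def test_effective_marker_count_ar1_ld():
    cfg = SimConfig(n=2000, m=100, rho=0.75, seed=3)
    grm = compute_grm(standardize(simulate_ar1_genotypes(cfg)))
    me = effective_marker_count(grm).me
    analytic = 1.0 / ar1_var_omega(100, 0.75)
    assert analytic == pytest.approx(28.47, abs=0.01)
    assert abs(me - analytic) < 3.0


def test_single_marker_me_is_one(rng):
    calls = rng.binomial(2, 0.5, size=(3000, 1)).astype(np.int8)
    grm = compute_grm(standardize(_genotypes(calls), np.array([0.5])))
    me = effective_marker_count(grm).me
    assert me == pytest.approx(1.0, abs=0.1)


def test_grm_invariant_to_allele_orientation(small_genotypes):
    a = compute_grm(standardize(small_genotypes))
    b = compute_grm(standardize(small_genotypes.flipped()))
    np.testing.assert_allclose(a.omega, b.omega, atol=1e-12)


def test_filter_relatedness_cases():
    base = np.zeros((5, 5))
    grm = RelatednessMatrix(omega=base.copy(), m=10)
    assert filter_relatedness(grm, 0.05).tolist() == [0, 1, 2, 3, 4]

    dup = base.copy()
    dup[0, 1] = dup[1, 0] = 0.98
    assert filter_relatedness(RelatednessMatrix(dup, m=10), 0.05).tolist() == \
        [1, 2, 3, 4]

    tri = base.copy()
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        tri[i, j] = tri[j, i] = 0.5
    kept = filter_relatedness(RelatednessMatrix(tri, m=10), 0.05)
    assert len(kept) == 3 and set([3, 4]) <= set(kept.tolist())
    # brute force: removing fewer than two of the triangle cannot clear it
    assert sum(1 for k in (0, 1, 2) if k in kept) == 1


def test_gcta_grm_round_trip(tmp_path, small_genotypes):
    grm = compute_grm(standardize(small_genotypes))
    grm.ids = list(small_genotypes.samples)
    prefix = str(tmp_path / "g")
    write_gcta_grm(grm, prefix)
    back = read_gcta_grm(prefix)
    np.testing.assert_allclose(back.omega, grm.omega, rtol=1e-9)
    assert back.m == grm.m and back.ids == grm.ids


def test_empirical_var_omega_matches_analytic():
    """Eq for var(Omega) under the AR(1) chain, middle LD level."""
    cfg = SimConfig(n=2000, m=100, rho=0.5, seed=5)
    grm = compute_grm(standardize(simulate_ar1_genotypes(cfg)))
    stats = effective_marker_count(grm)
    analytic = ar1_var_omega(100, 0.5)
    off = grm.offdiag()
    mc_se = off.std(ddof=1) ** 2 * np.sqrt(2.0 / off.size)  # approx SE of a variance
    # pairs are not independent, so allow a generous multiple
    assert abs(stats.var_omega - analytic) < max(30 * mc_se, 0.1 * analytic)
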