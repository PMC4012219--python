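import numpy as np
import pytest

from ibshe import (GenotypeMatrix, LocusInfo, PhenotypeVector, ar1_qtl_model,
                   breakeven_sample_size, compute_grm, expected_b_multi,
                   expected_b_one_marker_multi_qtl, expected_b_single,
                   he_fit, ld_pair, ld_pair_from_rho, ncp,
                   sample_size_for_power, standardize)
from ibshe.expectations import (QTLModel, expected_b_one_marker_rho_form,
                                expected_b_single_rho_form, sigma2_a_components)
from ibshe.ld_math import d_bounds, haplotype_freqs

GRID = [(p_k, p_l, f) for p_k in (0.2, 0.5, 0.8) for p_l in (0.3, 0.5, 0.6)
        for f in (-0.7, 0.0, 0.5, 1.0)]


def _pair(p_k, p_l, f):
    lo, hi = d_bounds(p_k, p_l)
    return ld_pair(p_k, p_l, f * (hi if f >= 0 else -lo))


@pytest.mark.parametrize("p_k,p_l,f", GRID)
def test_single_marker_forms_identical(p_k, p_l, f):
    """-4 tau^2 p_k q_k beta^2 and -2 rho^2 sigma_l^2 agree to 1e-12."""
    pair = _pair(p_k, p_l, f)
    beta = 0.83
    assert expected_b_single(pair, beta) == pytest.approx(
        expected_b_single_rho_form(pair, beta), abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_one_marker_multi_qtl_forms_identical(seed):
    rng = np.random.default_rng(seed)
    p_k = 0.4
    pairs = [_pair(p_k, p_l, f)
             for p_l, f in zip(rng.uniform(0.2, 0.8, 4), rng.uniform(-0.8, 0.8, 4))]
    betas = rng.standard_normal(4)
    a = expected_b_one_marker_multi_qtl(pairs, betas)
    b = expected_b_one_marker_rho_form(pairs, betas)
    assert a == pytest.approx(b, abs=1e-12)


def test_single_qtl_reduces_and_cancellation():
    pair = ld_pair_from_rho(0.5, 0.5, 0.4)
    beta = 1.2
    assert expected_b_one_marker_multi_qtl([pair], np.array([beta])) == \
        pytest.approx(expected_b_single(pair, beta), abs=1e-12)
    # two QTLs with equal |tau beta| and opposite sign cancel exactly
    p2 = ld_pair_from_rho(0.5, 0.5, 0.4)
    assert expected_b_one_marker_multi_qtl([pair, p2], np.array([beta, -beta])) \
        == pytest.approx(0.0, abs=1e-12)


def test_single_marker_reference_grid():
    """Single-marker coefficient at QTL variance 0.5: the reference grid."""
    for rho, reference, exact in [(0.25, -0.062, -0.0625), (0.5, -0.25, -0.25),
                                (0.75, -0.56, -0.5625)]:
        beta = np.sqrt(0.5 / (2 * 0.25))  # sigma_l^2 = 0.5 at p = 0.5
        e_b = expected_b_single(ld_pair_from_rho(0.5, 0.5, rho), beta)
        assert e_b == pytest.approx(exact, abs=1e-12)
        assert round(e_b, len(str(reference).split(".")[1])) == reference
    assert expected_b_single(ld_pair(0.5, 0.5, 0.0), 1.0) == 0.0


def test_expected_b_multi_perfect_tagging_lambda_one(rng):
    """Markers = QTLs gives Lambda = 1 and -E(b)/2 = h2 for standardized y."""
    beta = rng.standard_normal(50)
    model = ar1_qtl_model(50, 0.4, beta)
    res = expected_b_multi(model)
    assert res.lambda_ == pytest.approx(1.0, abs=1e-12)
    # standardized scale: divide by sigma2_y = sigma2_A_total / h2
    sigma2_y = res.sigma2_a_total / 0.5
    pred = res.predicted_h2(sigma2_y)
    assert res.e_b == pytest.approx(-2 * res.sigma2_a_within * res.lambda_
                                    + res.delta, abs=1e-12)
    # with random effects the prediction sits near the simulated truth
    assert pred == pytest.approx(0.5, abs=0.15)


def test_expected_b_multi_independent_perfect_tags():
    """Each QTL tagged perfectly by one of M independent markers: Lambda = 1."""
    m = 20
    model = QTLModel(p_marker=np.full(m, 0.5), p_qtl=np.full(m, 0.5),
                     beta=np.ones(m), rho_mq=np.eye(m), rho_mm=np.eye(m),
                     rho_qq=np.eye(m))
    res = expected_b_multi(model)
    assert res.rho2_q == pytest.approx(1 / m, abs=1e-15)
    assert res.rho2_m == pytest.approx(1 / m, abs=1e-15)
    assert res.lambda_ == pytest.approx(1.0, abs=1e-12)
    assert res.delta == pytest.approx(0.0, abs=1e-10)


def test_sorted_effects_inflate_prediction(rng):
    """Correlated (sorted) effects produce a nonzero remainder and inflation."""
    beta = np.sort(rng.standard_normal(100))
    res = expected_b_multi(ar1_qtl_model(100, 0.5, beta))
    # positive LD x sorted effects: cross-terms push E(b) further negative
    assert res.delta < 0
    sigma2_y = res.sigma2_a_total / 0.5
    assert res.predicted_h2(sigma2_y) > 0.6
    # random (unsorted) effects leave only a small remainder
    res0 = expected_b_multi(ar1_qtl_model(100, 0.5,
                                          rng.permutation(beta)))
    assert abs(res0.delta) < abs(res.delta)


def test_expectation_matches_monte_carlo_single_marker(rng):
    """Eq-form expectation vs Monte-Carlo regression, 3 QTLs on one marker."""
    from ibshe.simulate import simulate_ar1_haplotypes
    rho = 0.5
    m = 4  # marker is locus 0; QTLs are loci 1..3 on the chain
    pairs = [ld_pair_from_rho(0.5, 0.5, rho**d) for d in (1, 2, 3)]
    betas = np.array([1.0, -0.6, 0.8])
    e_b = expected_b_one_marker_multi_qtl(pairs, betas)
    n, reps = 2000, 30
    bs = []
    for _ in range(reps):
        x = (simulate_ar1_haplotypes(n, m, 0.5, rho, rng)
             + simulate_ar1_haplotypes(n, m, 0.5, rho, rng)).astype(np.int8)
        y = x[:, 1:] @ betas
        y = y - y.mean()
        s = (x[:, 0] - 1.0) / np.sqrt(0.5)  # standardized marker, true p
        iu, ju = np.triu_indices(n, k=1)
        # regression uses the raw (non-variance-normalized) phenotype
        Y = (y[iu] - y[ju]) ** 2
        O = s[iu] * s[ju]
        bs.append(np.polyfit(O, Y, 1)[0])
    sem = np.std(bs, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(bs) - e_b) < 3 * sem


def test_sigma2_a_components_closed_form():
    p = np.array([0.5, 0.5])
    beta = np.array([1.0, 2.0])
    rho_qq = np.array([[1.0, 0.6], [0.6, 1.0]])
    within, total = sigma2_a_components(p, beta, rho_qq)
    assert within == pytest.approx(0.5 * (1 + 4), abs=1e-12)
    assert total == pytest.approx(within + 2 * 0.6 * 0.5 * 1 * 2, abs=1e-12)


def test_breakeven_sample_size_full_grid():
    """All 12 reference breakeven cells: N = ceil(4 / (h2 rho^2))."""
    reference = {
        (0.005, 0.25): 12800, (0.005, 0.5): 3200, (0.005, 0.75): 1423,
        (0.01, 0.25): 6400, (0.01, 0.5): 1600, (0.01, 0.75): 712,
        (0.025, 0.25): 2560, (0.025, 0.5): 640, (0.025, 0.75): 285,
        (0.05, 0.25): 1280, (0.05, 0.5): 320, (0.05, 0.75): 143,
    }
    for (h2, rho), n in reference.items():
        assert breakeven_sample_size(h2, rho) == n
    with pytest.raises(ValueError):
        breakeven_sample_size(0.0, 0.5)


def test_ncp_ratio_at_breakeven():
    h2, rho = 0.01, 0.5
    n = round(4 / (h2 * rho**2))
    ratio = ncp(n, h2, rho, "he") / ncp(n, h2, rho, "linear")
    # linear NCP carries the (1 - h2 rho^2) correction, hence approx
    assert ratio == pytest.approx(1.0, rel=0.01)
    assert ncp(100, 1e-9, 0.5, "he") < 1e-10
    assert ncp(100, 1e-9, 0.5, "linear") < 1e-6
    with pytest.raises(ValueError):
        ncp(100, 1.5, 1.0)


def test_sample_size_solver_monotone():
    n1 = sample_size_for_power(0.01, 0.5, alpha=1e-8, power=0.8)
    n2 = sample_size_for_power(0.01, 0.5, alpha=1e-8, power=0.9)
    n3 = sample_size_for_power(0.02, 0.5, alpha=1e-8, power=0.8)
    assert n2 > n1 > n3


def test_single_marker_he_type_one_error(rng):
    """Marker in LE with the causal locus: rejection rate near alpha."""
    n, reps, alpha = 300, 400, 0.05
    from scipy import stats
    crit = stats.chi2.isf(alpha, df=1)
    se_b = np.sqrt(16.0 / (n * (n - 1)))
    hits = 0
    for _ in range(reps):
        marker = rng.binomial(2, 0.5, n)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        s = (marker - marker.mean()) / marker.std()
        iu, ju = np.triu_indices(n, k=1)
        b = np.polyfit(s[iu] * s[ju], (y[iu] - y[ju]) ** 2, 1)[0]
        hits += (b / se_b) ** 2 > crit
    rate = hits / reps
    # dependent pairs make the naive test anti-conservative; wide band
    assert rate < 0.25
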