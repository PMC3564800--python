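import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scoremr.associate import BivariateEstimate
from scoremr.errors import (
    ConfigurationError,
    InsufficientStudiesError,
    NoContrastError,
)
from scoremr.meta import (
    dersimonian_laird,
    fixed_effects,
    heterogeneity,
    meta_regression,
    multivariate_pool,
    pool,
    reml_random_effects,
)

SIX_STUDIES = [(0.12, 0.05), (0.05, 0.08), (0.30, 0.10),
               (-0.08, 0.06), (0.22, 0.12), (0.15, 0.07)]


class TestFixedEffects:
    def test_equal_weight_average(self):
        m = fixed_effects([(1.0, 1.0), (3.0, 1.0)])
        assert m.beta == pytest.approx(2.0)
        assert m.se == pytest.approx(1.0 / np.sqrt(2.0))

    def test_replication_shrinks_se_like_sqrt_k(self):
        one = fixed_effects([(0.7, 0.2), (0.7, 0.2)])
        four = fixed_effects([(0.7, 0.2)] * 8)
        assert four.beta == pytest.approx(one.beta)
        assert four.se == pytest.approx(one.se / 2.0)

    def test_consortium_snp_pair_pooling(self):
        """IVW of the two published metabolism-SNP rows (SEs from their CIs)."""
        m = fixed_effects([(0.001, 0.005357), (0.003, 0.005612)])
        assert m.beta == pytest.approx(0.0020, abs=5e-5)

    def test_matches_metafor_fe(self):
        m = fixed_effects(SIX_STUDIES)
        assert m.beta == pytest.approx(0.0906628719, abs=1e-9)
        assert m.se == pytest.approx(0.0287770814, abs=1e-9)
        assert m.Q == pytest.approx(14.9555521683, abs=1e-8)

    def test_requires_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            fixed_effects([(1.0, 1.0)])


class TestDersimonianLaird:
    def test_homogeneous_reduces_to_fixed(self):
        hom = [(0.5, 0.1)] * 4
        dl, fe = dersimonian_laird(hom), fixed_effects(hom)
        assert dl.tau2 == 0.0
        assert dl.beta == pytest.approx(fe.beta)
        assert dl.se == pytest.approx(fe.se)

    def test_hand_worked_two_study_example(self):
        """(0, se 1), (4, se 1): Q=8, tau2=(8-1)/(2-1)=7, se=sqrt(8/2)=2."""
        dl = dersimonian_laird([(0.0, 1.0), (4.0, 1.0)])
        assert dl.Q == pytest.approx(8.0)
        assert dl.tau2 == pytest.approx(7.0)
        assert dl.beta == pytest.approx(2.0)
        assert dl.se == pytest.approx(2.0)

    def test_matches_metafor_dl(self):
        dl = dersimonian_laird(SIX_STUDIES)
        assert dl.beta == pytest.approx(0.1101130507, abs=1e-9)
        assert dl.se == pytest.approx(0.0527123719, abs=1e-9)
        assert dl.tau2 == pytest.approx(0.0105442019, abs=1e-9)
        assert dl.i2 == pytest.approx(66.5676001546, abs=1e-7)

    def test_tau2_estimator_unbiased_at_truth(self):
        """Monte Carlo: true tau2=0.5, k=50, se=0.1 => mean estimate within 10%."""
        rng = np.random.default_rng(1)
        vals = [
            dersimonian_laird(
                list(zip(rng.normal(0, np.sqrt(0.51), 50), [0.1] * 50))
            ).tau2
            for _ in range(1000)
        ]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_reml_variant_matches_metafor(self):
        re = reml_random_effects(SIX_STUDIES)
        assert re.beta == pytest.approx(0.1104859004, abs=1e-6)
        assert re.se == pytest.approx(0.0534424460, abs=1e-6)
        assert re.tau2 == pytest.approx(0.0109902335, abs=1e-6)

    def test_pool_can_select_reml_branch(self):
        ests = [(0.0, 0.1), (1.0, 0.1), (2.0, 0.1)]
        m = pool(ests, tau2_estimator="reml")
        assert m.model == "random"
        assert m.tau2 > 0
        with pytest.raises(ConfigurationError):
            pool(ests, tau2_estimator="bogus")

    def test_continuity_to_fixed_as_dispersion_vanishes(self):
        base = np.array([0.1, 0.2, 0.15, 0.12])
        fe = fixed_effects(list(zip(base, [0.05] * 4)))
        spread = base - base.mean()
        for eps in (1.0, 0.1, 0.01):
            b = base.mean() + eps * spread
            dl = dersimonian_laird(list(zip(b, [0.05] * 4)))
        assert dl.beta == pytest.approx(fe.beta, abs=1e-3)
        assert dl.se == pytest.approx(fe.se, rel=1e-2)


class TestHeterogeneity:
    def test_identical_studies(self):
        q, p_q, i2 = heterogeneity([(1.0, 0.5)] * 3)
        assert q == pytest.approx(0.0)
        assert i2 == 0.0

    def test_two_study_chi_square_tail(self):
        q, p_q, i2 = heterogeneity([(0.0, 1.0), (4.0, 1.0)])
        assert q == pytest.approx(8.0)
        assert p_q == pytest.approx(stats.chi2.sf(8.0, 1), abs=1e-12)
        assert p_q == pytest.approx(0.00468, abs=2e-5)


class TestPoolSelection:
    def test_homogeneous_selects_fixed(self):
        assert pool([(0.5, 0.1)] * 4).model == "fixed"

    def test_heterogeneous_selects_random_with_larger_se(self):
        ests = [(0.0, 0.1), (1.0, 0.1), (2.0, 0.1)]
        m = pool(ests)
        assert m.model == "random"
        assert m.se > fixed_effects(ests).se

    def test_boundary_is_fixed(self):
        """p_Q == alpha_het exactly keeps the fixed-effects model."""
        ests = [(0.0, 1.0), (4.0, 1.0)]
        _, p_q, _ = heterogeneity(ests)
        assert pool(ests, alpha_het=p_q).model == "fixed"


class TestMetaRegression:
    def test_matches_metafor_continuous(self):
        res = meta_regression(SIX_STUDIES, [1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert res.terms[0].slope == pytest.approx(-0.1024818362, abs=1e-9)
        assert res.terms[0].se == pytest.approx(0.0452682689, abs=1e-9)
        assert res.terms[0].p == pytest.approx(0.0235816220, abs=1e-8)

    def test_matches_metafor_categorical(self):
        res = meta_regression(SIX_STUDIES, ["a", "a", "b", "b", "a", "b"],
                              reference="a")
        assert res.terms[0].name == "b vs a"
        assert res.terms[0].slope == pytest.approx(-0.0151354612, abs=1e-9)
        assert res.terms[0].p == pytest.approx(0.8989698368, abs=1e-8)

    def test_knapp_hartung_matches_metafor(self):
        res = meta_regression(
            SIX_STUDIES, [1.0, 2.0, 0.5, 3.0, 1.5, 2.5], knapp_hartung=True
        )
        assert res.terms[0].slope == pytest.approx(-0.1024818362, abs=1e-9)
        assert res.terms[0].se == pytest.approx(0.0430542310, abs=1e-8)
        assert res.terms[0].p == pytest.approx(0.0759647615, abs=1e-7)

    def test_type_i_error_near_nominal(self):
        """Null covariate, k=30: rejection rate at alpha=.05 within (.03,.07)."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(1000):
            se = rng.uniform(0.5, 1.5, 30)
            b = rng.normal(0, se)
            res = meta_regression(list(zip(b, se)), list(rng.normal(size=30)))
            rejections += res.terms[0].p < 0.05
        assert 0.03 < rejections / 1000 < 0.07

    def test_group_separation_limit(self):
        """Two study groups differing by delta with negligible se: slope=delta."""
        ests = [(0.0, 1e-4)] * 4 + [(0.3, 1e-4)] * 4
        res = meta_regression(ests, ["lo"] * 4 + ["hi"] * 4, reference="lo")
        assert res.terms[0].slope == pytest.approx(0.3, abs=1e-6)

    def test_recovers_injected_age_trend(self):
        """A -0.03-per-category trend across 21 studies is recovered."""
        rng = np.random.default_rng(9)
        cats = np.array([0, 1, 2] * 7)
        se = np.full(21, 0.01)
        b = 0.14 - 0.03 * cats + rng.normal(0, se)
        res = meta_regression(list(zip(b, se)), [float(c) for c in cats])
        assert abs(res.terms[0].slope - (-0.03)) < 3 * res.terms[0].se

    def test_intercept_only_reproduces_random_effects_pool(self):
        res = meta_regression(SIX_STUDIES, None)
        dl = dersimonian_laird(SIX_STUDIES)
        assert res.terms[0].slope == pytest.approx(dl.beta, abs=1e-12)
        assert res.terms[0].se == pytest.approx(dl.se, abs=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(NoContrastError):
            meta_regression(SIX_STUDIES, [1.0] * 6)

    def test_too_few_studies_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            meta_regression(SIX_STUDIES[:2], [1.0, 2.0])


def _biv(beta, cov, name="s"):
    return BivariateEstimate(beta_pair=tuple(beta), cov=np.asarray(cov),
                             cohort=name)


class TestMultivariatePool:
    def test_diagonal_covariances_decouple(self):
        bivs = [
            _biv((0.1, 0.4), np.diag([0.01, 0.04]), "a"),
            _biv((0.3, 0.2), np.diag([0.02, 0.01]), "b"),
        ]
        (c1, c2), _ = multivariate_pool(bivs)
        u1 = fixed_effects([(0.1, 0.1), (0.3, np.sqrt(0.02))])
        u2 = fixed_effects([(0.4, 0.2), (0.2, 0.1)])
        assert c1.beta == pytest.approx(u1.beta, abs=1e-12)
        assert c2.beta == pytest.approx(u2.beta, abs=1e-12)

    def test_equals_dense_stacked_gls(self):
        """Independent oracle: solve the 6x6 block system directly."""
        rng = np.random.default_rng(4)
        bivs, blocks, ys = [], [], []
        for i in range(3):
            a = rng.normal(size=(2, 2))
            cov = a @ a.T + 0.3 * np.eye(2)
            beta = rng.normal(size=2)
            bivs.append(_biv(beta, cov, f"s{i}"))
            blocks.append(cov)
            ys.append(beta)
        (c1, c2), joint_p = multivariate_pool(bivs)
        big_cov = np.zeros((6, 6))
        for i, blk in enumerate(blocks):
            big_cov[2 * i:2 * i + 2, 2 * i:2 * i + 2] = blk
        x = np.vstack([np.eye(2)] * 3)
        y = np.concatenate(ys)
        vinv = np.linalg.inv(big_cov)
        v = np.linalg.inv(x.T @ vinv @ x)
        beta = v @ (x.T @ vinv @ y)
        assert c1.beta == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
        assert c2.beta == pytest.approx(beta[1], rel=1e-10, abs=1e-12)
        assert c1.se == pytest.approx(np.sqrt(v[0, 0]), rel=1e-10)
        wald = beta @ np.linalg.solve(v, beta)
        assert joint_p == pytest.approx(stats.chi2.sf(wald, 2), rel=1e-10)

    def test_joint_null_p_uniform(self):
        """Known covariances, both effects 0: the 2-df Wald p is uniform."""
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(1000):
            bivs = []
            for i in range(3):
                a = rng.normal(size=(2, 2))
                cov = a @ a.T + 0.5 * np.eye(2)
                b = np.linalg.cholesky(cov) @ rng.normal(size=2)
                bivs.append(_biv(b, cov, f"s{i}"))
            ps.append(multivariate_pool(bivs)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_infinite_variance_component_reproduces_univariate(self):
        big = 1e8
        bivs = [
            _biv((0.1, 0.4), np.diag([0.01, big]), "a"),
            _biv((0.3, 0.2), np.diag([0.02, big]), "b"),
        ]
        (c1, _), _ = multivariate_pool(bivs)
        u1 = fixed_effects([(0.1, 0.1), (0.3, np.sqrt(0.02))])
        assert c1.beta == pytest.approx(u1.beta, rel=1e-6)
        assert c1.se == pytest.approx(u1.se, rel=1e-6)

    def test_singular_studies_dropped_then_error(self):
        good = [_biv((0.1, 0.2), np.diag([0.01, 0.01]), f"g{i}")
                for i in range(2)]
        bad = _biv((9.9, 9.9), [[0.01, 0.01], [0.01, 0.01]], "sing")
        with pytest.warns(UserWarning, match="singular"):
            (c1, _), _ = multivariate_pool(good + [bad])
        assert c1.k == 2
        with pytest.raises(InsufficientStudiesError):
            with pytest.warns(UserWarning):
                multivariate_pool([bad, bad])


@settings(derandomize=True, max_examples=100)
@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            st.floats(min_value=0.01, max_value=5, allow_nan=False),
        ),
        min_size=2, max_size=12,
    )
)
def test_pooling_invariants(data):
    """Pooled beta lies within the study range, is order-invariant, the
    fixed se never exceeds the smallest study se, random se >= fixed se,
    and I^2 stays in [0,100]."""
    fe = fixed_effects(data)
    betas = [b for b, _ in data]
    assert min(betas) - 1e-9 <= fe.beta <= max(betas) + 1e-9
    assert fe.se <= min(s for _, s in data) + 1e-12
    fe_rev = fixed_effects(list(reversed(data)))
    assert fe_rev.beta == pytest.approx(fe.beta, rel=1e-9, abs=1e-12)
    dl = dersimonian_laird(data)
    assert dl.se >= fe.se - 1e-12
    assert 0.0 <= dl.i2 <= 100.0
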