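import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, t as t_dist, truncnorm

from markertime import (
    ModelParameters,
    NoiseParams,
    PriorSettings,
    dropout_probability,
    log_joint,
    log_obs_density,
    log_prior,
    observation_variance,
    sigmoid_mean,
    transient_mean,
)
from markertime.model import LAMBDA_TRANSIENT, mean_matrix


class TestMeanFunctions:
    def test_sigmoid_half_peak_at_switch_time(self):
        assert sigmoid_mean(0.3, eta=1.0, k=5.0, t0=0.3) == pytest.approx(1.0)

    def test_sigmoid_constant_at_eta_when_strength_zero(self):
        for t in [0.0, 0.33, 0.9]:
            assert sigmoid_mean(t, eta=2.0, k=0.0, t0=0.5) == pytest.approx(2.0)

    def test_sigmoid_direct_evaluation(self):
        # 2/(1+exp(-10*(1-0.5))) = 2/(1+e^-5)
        assert sigmoid_mean(1.0, eta=1.0, k=10.0, t0=0.5) == pytest.approx(
            2.0 / (1.0 + np.exp(-5.0)), rel=1e-9
        )

    @pytest.mark.parametrize("k", [-8.0, -1.0, 2.0, 15.0])
    def test_sigmoid_strictly_monotone_direction_follows_k(self, k):
        grid = np.linspace(0, 0.999, 50)
        vals = sigmoid_mean(grid, 1.3, k, 0.4)
        diffs = np.diff(vals)
        assert np.all(diffs > 0) if k > 0 else np.all(diffs < 0)

    def test_transient_peak_value_and_flat_limit(self):
        assert transient_mean(0.6, eta=1.7, b=3.0, p=0.6) == pytest.approx(3.4)
        for t in [0.1, 0.5, 0.9]:
            assert transient_mean(t, eta=1.0, b=0.0, p=0.2) == pytest.approx(2.0)

    def test_transient_half_maximum_half_width(self):
        # closed form: mu = eta at t = p +/- sqrt(ln 2 / (lam b))
        b, p = 2.5, 0.5
        d = np.sqrt(np.log(2.0) / (LAMBDA_TRANSIENT * b))
        for t in (p - d, p + d):
            assert transient_mean(t, eta=1.0, b=b, p=p) == pytest.approx(1.0, rel=1e-9)

    def test_transient_symmetry_about_peak(self):
        for d in np.linspace(0, 0.4, 9):
            lo = transient_mean(0.5 - d, 1.2, 4.0, 0.5)
            hi = transient_mean(0.5 + d, 1.2, 4.0, 0.5)
            assert lo == pytest.approx(hi, abs=1e-12)


class TestNoiseModel:
    def test_dropout_probability_values(self):
        assert dropout_probability(5.0, 0.0, 0.0) == pytest.approx(0.5)
        assert dropout_probability(0.0, np.log(3.0), 0.0) == pytest.approx(0.75)
        assert dropout_probability(2.0, 0.0, -50.0) < 1e-20

    def test_observation_variance(self):
        assert observation_variance(1.0, 0.0, 0.01) == pytest.approx(1.01)
        assert observation_variance(0.0, 3.0, 0.01) == pytest.approx(0.01)
        assert observation_variance(2.0, 1.0, 0.01) == pytest.approx(4.01)

    def test_pure_point_mass_at_zero(self):
        assert log_obs_density(0.0, mu=1.0, pi=1.0, sigma2=1.0, nu=10) == pytest.approx(0.0)

    def test_positive_branch_matches_student_t_oracle(self):
        # independent oracle: scipy's location-scale Student-t density
        for y, mu, s2, nu in [(1.0, 1.0, 1.0, 10.0), (0.5, 2.0, 0.3, 4.0),
                              (3.0, 0.1, 2.0, 30.0)]:
            expected = t_dist.logpdf(y, df=nu, loc=mu, scale=np.sqrt(s2))
            got = log_obs_density(y, mu, 0.0, s2, nu)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_gaussian_limit_of_student_t(self):
        got = log_obs_density(1.7, mu=1.0, pi=0.0, sigma2=0.5, nu=1e6)
        assert got == pytest.approx(norm.logpdf(1.7, 1.0, np.sqrt(0.5)), abs=1e-4)

    def test_pi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            log_obs_density(1.0, 1.0, 1.5, 1.0, 10.0)

    @pytest.mark.parametrize("mu,pi,s2,nu", [
        (0.5, 0.2, 0.5, 10.0),
        (2.0, 0.05, 3.0, 5.0),
        (0.0, 0.5, 0.01, 10.0),
        (1.0, 0.9, 1.0, 30.0),
    ])
    def test_total_probability_is_one(self, mu, pi, s2, nu):
        # point mass at zero plus integral of the continuous part over y > 0
        # and y < 0 folded in: the zero-inflated density integrates to 1 when
        # the continuous component's full support is counted
        cont = integrate.quad(
            lambda y: (1 - pi) * np.exp(
                t_dist.logpdf(y, df=nu, loc=mu, scale=np.sqrt(s2))
            ),
            -np.inf, np.inf, limit=200,
        )[0]
        total = pi + cont
        assert total == pytest.approx(1.0, abs=1e-6)
        # and the implementation's positive branch matches that component
        ys = np.linspace(0.01, 8, 5)
        dens = np.exp(log_obs_density(ys, mu, pi, s2, nu))
        expect = (1 - pi) * np.exp(t_dist.logpdf(ys, df=nu, loc=mu,
                                                 scale=np.sqrt(s2)))
        assert np.allclose(dens, expect, rtol=1e-10)


def _random_params(rng, n, g, sw_mask):
    shape = np.where(sw_mask, rng.normal(0, 5, g), rng.uniform(0.5, 5, g))
    return ModelParameters(
        t=rng.uniform(0.01, 0.99, n),
        eta=rng.uniform(0.3, 2.0, g),
        shape=shape,
        time=rng.uniform(0.05, 0.95, g),
        noise=NoiseParams(rng.normal(0, 0.3), rng.normal(0, 0.3),
                          rng.uniform(0.1, 1.0)),
    )


class TestPriorAndJoint:
    def test_out_of_support_gives_neg_inf(self):
        pri = PriorSettings()
        p = ModelParameters(t=np.array([0.5, 0.5]), eta=np.array([1.0, 1.0]),
                            shape=np.array([1.0, 1.0]),
                            time=np.array([1.5, 0.5]),   # t0 outside [0,1)
                            noise=NoiseParams(0.0, 0.0, 1.0))
        lp = log_prior(p, pri, ["g1", "g2"], ["switch", "switch"])
        assert lp == -np.inf

    def test_moving_k_off_prior_mean_lowers_log_prior(self):
        pri = PriorSettings()
        base = ModelParameters(t=np.array([0.5, 0.5]), eta=np.array([1.0, 1.0]),
                               shape=np.array([pri.mu_k, 1.0]),
                               time=np.array([0.5, 0.5]),
                               noise=NoiseParams(0.0, 0.0, 1.0))
        moved = base.replace(shape=np.array([pri.mu_k + 4.0, 1.0]))
        beh = ["switch", "transient"]
        assert log_prior(moved, pri, ["g1", "g2"], beh) < log_prior(
            base, pri, ["g1", "g2"], beh
        )

    def test_log_prior_matches_per_term_oracle(self, rng):
        # independent oracle: every prior term evaluated separately via scipy
        pri = PriorSettings()
        beh = ["switch", "transient", "switch"]
        sw = np.array([True, False, True])
        p = _random_params(rng, 4, 3, sw)
        expected = truncnorm.logpdf(
            p.t, (0 - pri.t_loc) / np.sqrt(pri.t_var),
            (1 - pri.t_loc) / np.sqrt(pri.t_var), loc=pri.t_loc,
            scale=np.sqrt(pri.t_var),
        ).sum()
        expected += gamma_dist.logpdf(p.eta, pri.delta / 2, scale=2.0).sum()
        expected += norm.logpdf(p.shape[0], pri.mu_k,
                                np.sqrt(1 / pri.tau_k))
        expected += norm.logpdf(p.shape[2], pri.mu_k, np.sqrt(1 / pri.tau_k))
        sd_b = np.sqrt(1 / pri.tau_b)
        expected += truncnorm.logpdf(p.shape[1], (0 - pri.mu_b) / sd_b, np.inf,
                                     loc=pri.mu_b, scale=sd_b)
        for j, is_sw in enumerate(sw):
            loc = pri.mu_t if is_sw else pri.mu_p
            sd = np.sqrt(1 / (pri.tau_t if is_sw else pri.tau_p))
            expected += truncnorm.logpdf(p.time[j], (0 - loc) / sd,
                                         (1 - loc) / sd, loc=loc, scale=sd)
        sdb = np.sqrt(pri.beta_var)
        expected += norm.logpdf(p.noise.beta0, 0, sdb)
        expected += norm.logpdf(p.noise.beta1, 0, sdb)
        expected += gamma_dist.logpdf(p.noise.phi, pri.alpha_phi,
                                      scale=1 / pri.beta_phi)
        got = log_prior(p, pri, ["g1", "g2", "g3"], beh)
        assert got == pytest.approx(float(expected), rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_log_joint_matches_brute_force_double_loop(self, seed):
        # independent oracle: naive per-observation summation via scipy
        rng = np.random.default_rng(seed)
        n, g = 3, 2
        beh = ["switch", "transient"]
        sw = np.array([True, False])
        p = _random_params(rng, n, g, sw)
        Y = rng.gamma(1.0, 1.0, size=(n, g))
        Y[rng.random((n, g)) < 0.3] = 0.0
        pri = PriorSettings()
        brute = log_prior(p, pri, ["g1", "g2"], beh)
        for i in range(n):
            for j in range(g):
                if sw[j]:
                    mu = sigmoid_mean(p.t[i], p.eta[j], p.shape[j], p.time[j])
                else:
                    mu = transient_mean(p.t[i], p.eta[j], p.shape[j], p.time[j])
                pi = 1 / (1 + np.exp(-(p.noise.beta0 + p.noise.beta1 * mu)))
                s2 = (1 + p.noise.phi) * mu + p.noise.eps
                tdens = t_dist.pdf(Y[i, j], df=p.noise.nu, loc=mu,
                                   scale=np.sqrt(s2))
                if Y[i, j] == 0:
                    brute += np.log(pi + (1 - pi) * t_dist.pdf(
                        0.0, df=p.noise.nu, loc=mu, scale=np.sqrt(s2)))
                else:
                    brute += np.log(1 - pi) + np.log(tdens)
        got = log_joint(Y, p, pri, ["g1", "g2"], beh)
        assert got == pytest.approx(brute, rel=1e-10)

    def test_duplicating_a_cell_adds_its_likelihood_contribution(self, rng):
        beh = ["switch", "switch"]
        p = _random_params(rng, 2, 2, np.array([True, True]))
        pri = PriorSettings()
        Y = rng.gamma(1.0, 1.0, size=(2, 2))
        lj = log_joint(Y, p, pri, ["g1", "g2"], beh)
        # duplicate cell 0 (with its pseudotime); prior gains one t-term
        p3 = p.replace(t=np.concatenate([p.t, [p.t[0]]]))
        Y3 = np.vstack([Y, Y[0]])
        lj3 = log_joint(Y3, p3, pri, ["g1", "g2"], beh)
        lj_prior_extra = (
            log_prior(p3, pri, ["g1", "g2"], beh)
            - log_prior(p, pri, ["g1", "g2"], beh)
        )
        cell0_lik = (
            log_joint(Y[[0, 0]], p.replace(t=p.t[[0, 0]]), pri, ["g1", "g2"], beh)
            - log_prior(p.replace(t=p.t[[0, 0]]), pri, ["g1", "g2"], beh)
        ) / 2
        assert lj3 - lj == pytest.approx(lj_prior_extra + cell0_lik, rel=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        p = _random_params(rng, 3, 2, np.array([True, True]))
        with pytest.raises(ValueError, match="shape mismatch"):
            log_joint(np.ones((4, 2)), p, PriorSettings(), ["g1", "g2"],
                      ["switch", "switch"])


class TestEngine:
    """The vectorized unconstrained-space engine against independent routes."""

    def _engine(self, seed=3, n=12, g=4):
        from markertime._engine import ModelEngine
        from markertime import SimulationConfig, simulate_dataset
        from markertime import compute_size_factors, normalize_expression

        ds = simulate_dataset(SimulationConfig(n_cells=n, n_genes=g,
                                               frac_switch=0.5, seed=seed))
        Yn = normalize_expression(ds.Y, compute_size_factors(ds.Y))
        return ModelEngine(Yn, Yn.gene_ids, ds.true_behaviours,
                           PriorSettings()), Yn, ds

    def test_log_density_equals_log_joint_plus_jacobian(self, rng):
        eng, Yn, ds = self._engine()
        c = dict(t=rng.uniform(0.05, 0.95, eng.N),
                 eta=rng.uniform(0.5, 2, eng.G),
                 shape=np.where(eng.sw, rng.normal(0, 5, eng.G),
                                rng.uniform(0.5, 4, eng.G)),
                 time=rng.uniform(0.1, 0.9, eng.G),
                 beta0=-0.4, beta1=-0.2, phi=0.7)
        z = eng.pack(**c)
        p = ModelParameters(t=c["t"], eta=c["eta"], shape=c["shape"],
                            time=c["time"],
                            noise=NoiseParams(c["beta0"], c["beta1"], c["phi"]))
        lj = log_joint(Yn, p, PriorSettings(), Yn.gene_ids, ds.true_behaviours)
        assert eng.log_density(z) - eng.log_jacobian(eng.unpack(z)) == (
            pytest.approx(lj, rel=1e-12)
        )

    @pytest.mark.parametrize("include_likelihood", [True, False])
    def test_analytic_gradient_matches_finite_differences(self, include_likelihood):
        eng, _, _ = self._engine()
        rng = np.random.default_rng(7)
        z = rng.normal(0, 0.5, eng.D)
        _, grad = eng.log_density_and_grad(z, include_likelihood)
        h = 1e-6
        for i in range(eng.D):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (eng.log_density(zp, include_likelihood)
                  - eng.log_density(zm, include_likelihood)) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=5e-5, abs=1e-6)

    def test_pack_unpack_round_trip_preserves_support(self, rng):
        eng, _, _ = self._engine()
        c = dict(t=rng.uniform(0.01, 0.99, eng.N),
                 eta=rng.uniform(0.2, 3, eng.G),
                 shape=np.where(eng.sw, rng.normal(0, 8, eng.G),
                                rng.uniform(0.1, 6, eng.G)),
                 time=rng.uniform(0.02, 0.98, eng.G),
                 beta0=0.3, beta1=-1.1, phi=0.4)
        c2 = eng.unpack(eng.pack(**c))
        for key in ("t", "eta", "shape", "time"):
            assert np.allclose(c2[key], c[key], rtol=1e-9)
        assert np.all((c2["t"] >= 0) & (c2["t"] < 1))
        assert np.all(c2["eta"] > 0) and c2["phi"] > 0


def test_mean_matrix_dispatches_by_behaviour():
    t = np.array([0.2, 0.8])
    eta = np.array([1.0, 1.0])
    shape = np.array([10.0, 3.0])
    time = np.array([0.5, 0.5])
    mu = mean_matrix(t, eta, shape, time, np.array(["switch", "transient"],
                                                   dtype=object))
    assert mu[0, 0] == pytest.approx(sigmoid_mean(0.2, 1, 10, 0.5))
    assert mu[1, 1] == pytest.approx(transient_mean(0.8, 1, 3, 0.5))
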