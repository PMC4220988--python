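"""Marginal-likelihood engine: modes, Laplace/FOCE objectives, estimation.

The oracles are independent of the engine's code paths: dense grid search for
the inner mode, closed-form Gaussian marginals for the linear toy, and
one-dimensional numerical integration (scipy.integrate.quad and 64-node
adaptive Gauss-Hermite) for the binary toys.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit

from vpapkpd import mixed_effects as me


def linear_gaussian_spec():
    """y_ij = a + b * eta_i + eps, additive residual; FOCE/Laplace are exact."""

    def predict(theta, eta_rec, data):
        return theta[0] + theta[1] * eta_rec[:, 0]

    return me.ModelSpec(predict=predict, kind="continuous", n_eta=1,
                        residual="additive")


def binary_spec():
    def predict(theta, eta_rec, data):
        return expit(theta[0] + theta[1] * data["x"] + eta_rec[:, 0])

    return me.ModelSpec(predict=predict, kind="binary", n_eta=1)


def linear_data():
    subject = np.array([0, 0, 0, 1, 1, 3, 3, 3, 3])  # subject 2 has no data
    y = np.array([1.2, 0.8, 1.5, 2.1, 1.7, 0.2, 0.9, 0.4, 0.6])
    return {"y": y, "subject": subject}


def binary_data():
    subject = np.array([0, 0, 1, 1, 1, 2, 3, 3])
    y = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 1.0])
    x = np.array([0.5, 1.0, 0.0, 0.2, 0.9, 1.5, 0.3, 0.3])
    return {"y": y, "subject": subject, "x": x}


def closed_form_linear_m2ll(data, a, b, omega2, sigma2):
    """Exact -2 log marginal likelihood: per-subject multivariate normal."""
    total = 0.0
    for i in range(int(data["subject"].max()) + 1):
        yi = data["y"][data["subject"] == i]
        n = len(yi)
        if n == 0:
            continue
        V = sigma2 * np.eye(n) + b * b * omega2 * np.ones((n, n))
        r = yi - a
        sign, logdet = np.linalg.slogdet(2.0 * np.pi * V)
        total += logdet + float(r @ np.linalg.solve(V, r))
    return total


def quad_binary_m2ll(data, theta, omega2):
    """Brute-force integration oracle for the binary marginal likelihood."""
    total = 0.0
    n_sub = int(data["subject"].max()) + 1
    for i in range(n_sub):
        m = data["subject"] == i
        yi, xi = data["y"][m], data["x"][m]

        def joint(eta):
            p = expit(theta[0] + theta[1] * xi + eta)
            lik = np.prod(p**yi * (1 - p) ** (1 - yi))
            return lik * np.exp(-0.5 * eta**2 / omega2) / np.sqrt(2 * np.pi * omega2)

        L, _ = quad(joint, -12 * np.sqrt(omega2), 12 * np.sqrt(omega2),
                    limit=200, epsabs=1e-13, epsrel=1e-12)
        total += -2.0 * np.log(L)
    return total


class TestInnerMode:
    def test_subject_without_observations_sits_at_prior_mode(self):
        spec = linear_gaussian_spec()
        data = linear_data()
        eta, hess, flags = me.inner_mode(spec, data, np.array([1.0, 1.0]),
                                         np.array([0.5]), sigma2=0.2)
        assert eta[2, 0] == pytest.approx(0.0, abs=1e-8)
        assert not flags.any()

    def test_mode_matches_dense_grid_search(self):
        spec = binary_spec()
        data = binary_data()
        theta = np.array([-0.5, 1.0])
        omega2 = np.array([0.8])
        eta, _, _ = me.inner_mode(spec, data, theta, omega2)
        grid = np.linspace(-4.0, 4.0, 160001)
        for i in range(4):
            m = data["subject"] == i
            yi, xi = data["y"][m], data["x"][m]
            p = expit(theta[0] + theta[1] * xi[None, :] + grid[:, None])
            g = (-2.0 * (yi * np.log(p) + (1 - yi) * np.log1p(-p))).sum(axis=1)
            g = g + grid**2 / omega2[0]
            assert eta[i, 0] == pytest.approx(grid[np.argmin(g)], abs=1e-4)

    def test_vanishing_prior_variance_pins_mode_at_zero(self):
        spec = binary_spec()
        data = binary_data()
        eta, _, _ = me.inner_mode(spec, data, np.array([0.3, -0.2]),
                                  np.array([1e-9]))
        assert np.all(np.abs(eta) < 1e-4)

    def test_nonpositive_omega2_rejected(self):
        with pytest.raises(ValueError):
            me.inner_mode(binary_spec(), binary_data(), np.zeros(2), np.array([0.0]))


class TestMarginalNLL:
    def test_foce_matches_closed_form_gaussian(self):
        spec = linear_gaussian_spec()
        data = linear_data()
        a, b, omega2, sigma2 = 1.1, 0.7, 0.4, 0.09
        expected = closed_form_linear_m2ll(data, a, b, omega2, sigma2)
        for method in ("foce", "laplace"):
            got = me.marginal_nll(spec, data, np.array([a, b]), np.array([omega2]),
                                  sigma2, method=method)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_laplace_tracks_quadrature_on_binary_toys(self):
        """Small-variance regime where the Laplace expansion is accurate."""
        spec = binary_spec()
        data = binary_data()
        for theta0, theta1, omega2 in [(-0.5, 1.0, 0.05), (0.2, -0.4, 0.05),
                                       (1.0, 0.0, 0.02)]:
            theta = np.array([theta0, theta1])
            lap = me.marginal_nll(spec, data, theta, np.array([omega2]),
                                  method="laplace")
            agq = me.agq_nll(spec, data, theta, np.array([omega2]), n_nodes=64)
            assert lap == pytest.approx(agq, abs=1e-3)

    def test_agq_matches_quad_oracle(self):
        spec = binary_spec()
        data = binary_data()
        for omega2 in (0.05, 0.5, 4.0, 12.3):
            theta = np.array([-0.5, 1.0])
            agq = me.agq_nll(spec, data, theta, np.array([omega2]), n_nodes=64)
            oracle = quad_binary_m2ll(data, theta, omega2)
            assert agq == pytest.approx(oracle, abs=1e-5)

    def test_zero_variance_limit_is_fixed_effects_likelihood(self):
        spec = binary_spec()
        data = binary_data()
        theta = np.array([-0.5, 1.0])
        got = me.marginal_nll(spec, data, theta, np.array([me.OMEGA2_FLOOR]),
                              method="laplace")
        p = expit(theta[0] + theta[1] * data["x"])
        y = data["y"]
        fixed = float(np.sum(-2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))))
        assert got == pytest.approx(fixed, abs=1e-4)

    def test_invariant_to_subject_relabelling(self):
        spec = binary_spec()
        data = binary_data()
        theta = np.array([-0.5, 1.0])
        base = me.marginal_nll(spec, data, theta, np.array([0.7]))
        # swap subjects 0 and 1 and re-sort the records
        relabel = {0: 1, 1: 0, 2: 2, 3: 3}
        new_subject = np.array([relabel[s] for s in data["subject"]])
        order = np.argsort(new_subject, kind="stable")
        permuted = {k: v[order] for k, v in data.items()}
        permuted["subject"] = new_subject[order]
        assert me.marginal_nll(spec, permuted, theta, np.array([0.7])) == (
            pytest.approx(base, abs=1e-9)
        )

    def test_multidimensional_eta_laplace_matches_scalar_path(self):
        """A 2-eta model whose second effect is inert must reproduce the
        1-eta objective (generic per-subject path vs vectorised path)."""

        def predict2(theta, eta_rec, data):
            return expit(theta[0] + theta[1] * data["x"] + eta_rec[:, 0]
                         + 0.0 * eta_rec[:, 1])

        spec2 = me.ModelSpec(predict=predict2, kind="binary", n_eta=2)
        data = binary_data()
        theta = np.array([-0.5, 1.0])
        got2 = me.marginal_nll(spec2, data, theta, np.array([0.3, me.OMEGA2_FLOOR]),
                               method="laplace")
        got1 = me.marginal_nll(binary_spec(), data, theta, np.array([0.3]),
                               method="laplace")
        assert got2 == pytest.approx(got1, abs=1e-3)


class TestFit:
    def _simulate_linear(self, rng, a=1.0, b=1.0, omega2=0.25, sigma2=0.04,
                         n_sub=120, n_obs=4):
        subject = np.repeat(np.arange(n_sub), n_obs)
        eta = rng.normal(0.0, np.sqrt(omega2), n_sub)
        y = a + b * eta[subject] + rng.normal(0.0, np.sqrt(sigma2), len(subject))
        return {"y": y, "subject": subject}

    def test_recovers_linear_gaussian_truth(self):
        rng = np.random.default_rng(7)
        data = self._simulate_linear(rng)
        fit = me.fit(
            linear_gaussian_spec(), data,
            init_theta=np.array([0.0, 1.0]), theta_names=["a", "b"],
            theta_transforms=["identity", "identity"],
            init_omega2=np.array([0.1]), init_sigma2=0.1,
            fixed_omega2=None,
        )
        assert fit.converged
        assert fit.theta[0] == pytest.approx(1.0, abs=0.15)
        assert fit.sigma2 == pytest.approx(0.04, rel=0.3)

    def test_refit_from_optimum_is_fixed_point(self):
        rng = np.random.default_rng(8)
        data = self._simulate_linear(rng, n_sub=40)
        kwargs = dict(
            spec=linear_gaussian_spec(), data=data,
            theta_names=["a", "b"], theta_transforms=["identity", "identity"],
        )
        first = me.fit(init_theta=np.array([0.0, 1.0]),
                       init_omega2=np.array([0.1]), init_sigma2=0.1, **kwargs)
        second = me.fit(init_theta=first.theta, init_omega2=first.omega2,
                        init_sigma2=first.sigma2, **kwargs)
        assert abs(second.ofv - first.ofv) < 0.01

    def test_ebes_length_equals_subjects(self):
        rng = np.random.default_rng(9)
        data = self._simulate_linear(rng, n_sub=25)
        fit = me.fit(linear_gaussian_spec(), data,
                     init_theta=np.array([0.0, 1.0]), theta_names=["a", "b"],
                     theta_transforms=["identity", "identity"],
                     init_omega2=np.array([0.1]), init_sigma2=0.1)
        assert fit.ebes.shape == (25, 1)
        assert np.isfinite(fit.ofv)
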