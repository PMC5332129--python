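import numpy as np
import pytest
from scipy.special import erfcx

from conftest import draw_exgauss
from exgmerge.bayes import (
    McmcSettings,
    PosteriorChain,
    PriorBox,
    default_prior_bounds,
    ideal_intensity,
    merge_dataset,
    sample_posterior,
)
from exgmerge.distributions import ExGaussParams, exgauss_cdf, exgauss_quantile
from exgmerge.errors import InsufficientMultiplicityError
from exgmerge.formats import Observation
from exgmerge.symmetry import UnitCell, group_observations

CELL = UnitCell(57.9, 84.8, 384.3)

# Reduced chain for tests that sample many reflections; retains the
# default 1000 samples via (9000 - 4000) / 5.
FAST = dict(n_samples=9000, n_burn=4000, thin=5)


class TestSettings:
    def test_default_retained_length_is_1000(self):
        assert McmcSettings().n_retained == 1000

    def test_invalid_burn(self):
        with pytest.raises(ValueError):
            McmcSettings(n_samples=100, n_burn=100)

    def test_invalid_thin(self):
        with pytest.raises(ValueError):
            McmcSettings(thin=0)

    def test_invalid_critical_cdf(self):
        with pytest.raises(ValueError):
            McmcSettings(critical_cdf=1.0)


class TestSamplePosterior:
    def test_default_settings_retain_exactly_1000(self):
        rng = np.random.default_rng(0)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 60)
        chain = sample_posterior(x, McmcSettings(seed=1))
        assert len(chain) == 1000

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 50)
        s = McmcSettings(seed=7, **FAST)
        c1 = sample_posterior(x, s)
        c2 = sample_posterior(x, s)
        assert np.array_equal(c1.samples, c2.samples)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_samples_within_prior_bounds(self):
        rng = np.random.default_rng(1)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 50)
        s = McmcSettings(seed=3, **FAST)
        chain = sample_posterior(x, s)
        box = chain.prior
        assert np.all(chain.samples[:, 0] >= box.mu[0])
        assert np.all(chain.samples[:, 0] <= box.mu[1])
        assert np.all(chain.samples[:, 1] >= box.sigma[0])
        assert np.all(chain.samples[:, 2] <= box.tau[1])

    def test_acceptance_rate_in_tuned_band(self):
        rng = np.random.default_rng(2)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 100)
        chain = sample_posterior(x, McmcSettings(seed=5, **FAST))
        assert 0.1 < chain.acceptance_rate < 0.6

    def test_insufficient_multiplicity(self):
        with pytest.raises(InsufficientMultiplicityError):
            sample_posterior([1.0, 2.0, 3.0], McmcSettings(seed=0))

    def test_prior_widened_to_contain_mle(self, caplog):
        rng = np.random.default_rng(3)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 40)
        narrow = PriorBox(mu=(10.0, 12.0), sigma=(0.5, 2.0), tau=(1.0, 8.0))
        s = McmcSettings(seed=1, prior=narrow, **FAST)
        with caplog.at_level("WARNING"):
            chain = sample_posterior(x, s)
        assert "widening" in caplog.text
        assert chain.prior.mu[0] < 10.0

    def test_recovery_within_three_posterior_sds(self):
        rng = np.random.default_rng(11)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 200)
        chain = sample_posterior(x, McmcSettings(seed=2, n_samples=30_000, n_burn=10_000, thin=10))
        means = chain.samples.mean(axis=0)
        sds = chain.samples.std(axis=0)
        truth = np.array([0.0, 1.0, 4.0])
        assert np.all(np.abs(means - truth) < 3.0 * sds)


def _grid_posterior(x, box, n=81):
    """Brute-force posterior over a dense parameter grid (flat prior)."""
    mus = np.linspace(*box.mu, n)
    sis = np.linspace(*box.sigma, n)
    tas = np.linspace(*box.tau, n)
    M, S, T = np.meshgrid(mus, sis, tas, indexing="ij")
    total = np.zeros_like(M)
    sqrt2 = np.sqrt(2.0)
    for xi in x:
        z = (xi - M) / S
        k = S / T
        u = (k - z) / sqrt2
        pos = u >= 0
        log_erfcx = np.empty_like(u)
        log_erfcx[pos] = np.log(erfcx(u[pos]))
        un = u[~pos]
        log_erfcx[~pos] = un * un + np.log(2.0 - np.exp(-un * un) * erfcx(-un))
        total += -np.log(2.0 * T) - 0.5 * z * z + log_erfcx
    w = np.exp(total - total.max())
    w /= w.sum()
    axes = [mus, sis, tas]
    means, sds = [], []
    for i, g in enumerate(axes):
        marg = w.sum(axis=tuple(j for j in range(3) if j != i))
        m = float((marg * g).sum())
        means.append(m)
        sds.append(float(np.sqrt((marg * (g - m) ** 2).sum())))
    return np.array(means), np.array(sds)


class TestPosteriorVsGridOracle:
    def test_small_sample_grid_agreement(self):
        rng = np.random.default_rng(7)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 30)
        box = PriorBox(mu=(-4.0, 4.0), sigma=(0.2, 4.0), tau=(0.5, 15.0))
        grid_means, grid_sds = _grid_posterior(x, box)
        s = McmcSettings(n_samples=200_000, n_burn=40_000, thin=10, seed=3, prior=box)
        chain = sample_posterior(x, s)
        diff = np.abs(chain.samples.mean(axis=0) - grid_means) / grid_sds
        assert np.all(diff < 0.05)


class TestIdealIntensity:
    @staticmethod
    def _chain_of(params_list):
        samples = np.array(
            [[p.mu_exg, p.sigma_exg, p.tau_exg] for p in params_list]
        )
        return PosteriorChain(
            samples=samples,
            acceptance_rate=0.3,
            map_start=params_list[0],
            prior=PriorBox(mu=(-1e6, 1e6), sigma=(1e-6, 1e6), tau=(1e-6, 1e6)),
        )

    def test_single_sample_zero_sd(self):
        chain = self._chain_of([ExGaussParams(0.0, 1.0, 2.0)])
        rec = ideal_intensity(chain, 0.95)
        assert rec.i_ideal_sd == 0.0

    def test_degenerate_chain_matches_quantile(self):
        p = ExGaussParams(0.0, 1.0, 2.0)
        chain = self._chain_of([p] * 5)
        rec = ideal_intensity(chain, 0.95)
        assert rec.i_ideal_mean == pytest.approx(exgauss_quantile(0.95, p))
        assert rec.i_ideal_sd == 0.0

    def test_cdf_identity_for_every_sample(self):
        rng = np.random.default_rng(4)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 60)
        chain = sample_posterior(x, McmcSettings(seed=9, **FAST))
        rec = ideal_intensity(chain, 0.95)
        for j in range(0, len(chain), 25):
            p = chain.sample_params(j)
            assert float(exgauss_cdf(rec.i_ideal_samples[j], p)) == pytest.approx(
                0.95, abs=1e-9
            )

    def test_monotone_in_critical_cdf(self):
        rng = np.random.default_rng(5)
        x = draw_exgauss(rng, 0.0, 1.0, 4.0, 60)
        chain = sample_posterior(x, McmcSettings(seed=2, **FAST))
        lo = ideal_intensity(chain, 0.90)
        hi = ideal_intensity(chain, 0.99)
        assert np.all(hi.i_ideal_samples >= lo.i_ideal_samples)
        assert hi.i_ideal_mean > lo.i_ideal_mean

    def test_empty_chain_rejected(self):
        chain = self._chain_of([ExGaussParams(0.0, 1.0, 2.0)])
        chain.samples = chain.samples[:0]
        with pytest.raises(ValueError):
            ideal_intensity(chain, 0.95)


def _toy_groups(rng, n_groups=8, multiplicity=40, with_absent=True, with_small=False):
    obs = []
    hkls = [(i + 1, 2, 3 + i) for i in range(n_groups)]
    for i, hkl in enumerate(hkls):
        m = 4 if (with_small and i == 0) else multiplicity
        vals = draw_exgauss(rng, 0.0, 600.0, 2000.0, m)
        obs.extend(Observation(f"f{j}", *hkl, float(v)) for j, v in enumerate(vals))
    if with_absent:
        vals = rng.normal(0.0, 600.0, 20)
        obs.extend(Observation(f"a{j}", 0, 0, 7, float(v)) for j, v in enumerate(vals))
    return group_observations(obs, CELL)


class TestMergeDataset:
    def test_counts_and_routing(self):
        rng = np.random.default_rng(6)
        groups = _toy_groups(rng, n_groups=5, with_absent=True, with_small=True)
        result = merge_dataset(groups, McmcSettings(seed=1, **FAST))
        n_non_absent = sum(1 for g in groups if not g.is_absent)
        assert len(result.merged) == n_non_absent
        assert len(result.absent) == 1
        assert result.n_fallback == 1
        fallback = [m for m in result.merged if "fallback" in m.flags]
        assert len(fallback) == 1
        assert fallback[0].multiplicity == 4

    def test_no_fallbacks_when_multiplicity_sufficient(self):
        rng = np.random.default_rng(7)
        groups = _toy_groups(rng, n_groups=4, with_absent=False)
        result = merge_dataset(groups, McmcSettings(seed=1, **FAST))
        assert result.n_fallback == 0
        assert all("fallback" not in m.flags for m in result.merged)

    def test_end_to_end_determinism(self):
        rng1 = np.random.default_rng(8)
        rng2 = np.random.default_rng(8)
        s = McmcSettings(seed=4, **FAST)
        r1 = merge_dataset(_toy_groups(rng1, 3, with_absent=False), s)
        r2 = merge_dataset(_toy_groups(rng2, 3, with_absent=False), s)
        for a, b in zip(r1.merged, r2.merged):
            assert a.i_ideal_mean == b.i_ideal_mean
            assert a.i_ideal_sd == b.i_ideal_sd

    def test_rank_correlation_with_true_scale(self):
        # reflections with larger Bragg tails must merge to larger
        # ideal intensities
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        taus = np.geomspace(300.0, 9000.0, 15)
        obs = []
        for i, tau in enumerate(taus):
            vals = draw_exgauss(rng, 0.0, 600.0, tau, 60)
            obs.extend(
                Observation(f"f{j}", i + 1, 1, 2, float(v)) for j, v in enumerate(vals)
            )
        groups = group_observations(obs, CELL)
        result = merge_dataset(groups, McmcSettings(seed=2, **FAST))
        by_hkl = {m.asu_hkl: m.i_ideal_mean for m in result.merged}
        merged_in_order = [by_hkl[(i + 1, 1, 2)] for i in range(len(taus))]
        rho = spearmanr(merged_in_order, taus).statistic
        assert rho > 0.9


class TestDefaultPriorBounds:
    def test_contains_plausible_fits(self):
        rng = np.random.default_rng(10)
        x = draw_exgauss(rng, -500.0, 600.0, 3000.0, 100)
        box = default_prior_bounds(x)
        assert box.contains(-500.0, 600.0, 3000.0)
        assert box.sigma[0] > 0 and box.tau[0] > 0
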