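"""Nested likelihood-ratio test per reflection and resolution-shell summaries.

Twice the gap between the Gaussian and ex-Gaussian optimal negative
log-likelihoods is referred to a chi-squared distribution with one extra
degree of freedom; at a 5% criterion the cutoff is 3.84.  Because tau > 0
sits on the boundary of the parameter space the test is conservative,
which is replicated as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from exgmerge.distributions import FitResult
from exgmerge.symmetry import ReflectionGroup


def chi2_cutoff(alpha: float, dof: int = 1) -> float:
    """Upper-tail critical value of the chi-squared distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    return float(chi2.isf(alpha, dof))


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    dof: int
    cutoff: float
    prefers_exgauss: bool


def likelihood_ratio_test(
    fit_g: FitResult, fit_exg: FitResult, alpha: float = 0.05
) -> LRTResult:
    """Decide between the nested Gaussian and ex-Gaussian fits.

    chi2 = 2*(nll_gauss - nll_exgauss), clamped at zero so optimizer
    noise cannot produce a negative statistic.
    """
    if fit_g.n_obs != fit_exg.n_obs:
        raise ValueError(
            f"fits compare different data: n={fit_g.n_obs} vs n={fit_exg.n_obs}"
        )
    stat = 2.0 * (fit_g.neg_log_likelihood - fit_exg.neg_log_likelihood)
    stat = max(stat, 0.0)
    cutoff = chi2_cutoff(alpha, 1)
    return LRTResult(chi2=stat, dof=1, cutoff=cutoff, prefers_exgauss=stat > cutoff)


@dataclass
class FittedReflection:
    """A reflection group together with both fits and the LRT verdict."""

    group: ReflectionGroup
    fit_gauss: FitResult | None
    fit_exgauss: FitResult | None
    lrt: LRTResult | None

    @property
    def fitted(self) -> bool:
        return self.lrt is not None


def fit_and_test_groups(
    groups: Sequence[ReflectionGroup], alpha: float = 0.05
) -> list[FittedReflection]:
    """Run both fits and the LRT on every group that supports them.

    Groups that are too small or degenerate get partial results
    (``fit_exgauss``/``lrt`` of None) rather than raising.
    """
    from exgmerge.distributions import fit_exgauss_mle, fit_gaussian_mle
    from exgmerge.errors import DegenerateGroupError

    out: list[FittedReflection] = []
    for g in groups:
        fit_g = fit_x = lrt = None
        try:
            fit_g = fit_gaussian_mle(g.intensities)
            fit_x = fit_exgauss_mle(g.intensities)
            lrt = likelihood_ratio_test(fit_g, fit_x, alpha)
        except DegenerateGroupError:
            pass
        out.append(FittedReflection(g, fit_g, fit_x, lrt))
    return out


@dataclass(frozen=True)
class ShellStats:
    d_max: float
    d_min: float
    q_min: float
    q_max: float
    n_reflections: int
    fraction_exgauss_preferred: float
    mean_mu_g: float
    mean_mu_exg: float
    mean_sigma_exg: float
    mean_tau_exg: float


def shell_summary(
    fitted: Sequence[FittedReflection], n_shells: int = 20
) -> list[ShellStats]:
    """Equal-count resolution shells (high d first) with per-shell model
    preference fractions and mean fitted parameters.

    Systematically absent and unfitted reflections are excluded.
    """
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    usable = [f for f in fitted if f.fitted and not f.group.is_absent]
    if len(usable) < n_shells:
        raise ValueError(
            f"fewer fitted reflections ({len(usable)}) than shells ({n_shells})"
        )
    usable.sort(key=lambda f: -f.group.d_spacing)
    shells: list[ShellStats] = []
    for chunk in np.array_split(np.arange(len(usable)), n_shells):
        members = [usable[i] for i in chunk]
        d_vals = [m.group.d_spacing for m in members]
        prefs = [m.lrt.prefers_exgauss for m in members]
        shells.append(
            ShellStats(
                d_max=max(d_vals),
                d_min=min(d_vals),
                q_min=1.0 / max(d_vals) ** 2,
                q_max=1.0 / min(d_vals) ** 2,
                n_reflections=len(members),
                fraction_exgauss_preferred=float(np.mean(prefs)),
                mean_mu_g=float(np.mean([m.fit_gauss.params.mu_g for m in members])),
                mean_mu_exg=float(
                    np.mean([m.fit_exgauss.params.mu_exg for m in members])
                ),
                mean_sigma_exg=float(
                    np.mean([m.fit_exgauss.params.sigma_exg for m in members])
                ),
                mean_tau_exg=float(
                    np.mean([m.fit_exgauss.params.tau_exg for m in members])
                ),
            )
        )
    return shells
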