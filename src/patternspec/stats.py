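"""Hierarchical Gaussian comparison of slope distributions.

Spider submodel:
    slope_ij = alpha + beta_sex * male_ij + a_j + b_j * male_ij + eps_ij
with species-level (a_j, b_j) bivariate zero-mean random effects and
Gaussian residuals.  Scene submodel: slope_k = mu_region(k) + eta_k.

Priors are weakly informative: improper flat on fixed effects and region
means, half-Normal(0, 5) on all standard deviations, uniform on the
random-effect correlation.  Sampling is Metropolis-within-Gibbs: conjugate
normal draws for all location parameters and random effects, adaptive
random-walk Metropolis (log / atanh scale) for scale and correlation
parameters.  Any correct MCMC satisfies the model contract; this sampler
keeps the package dependency-free of external MCMC engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "ContrastResult",
    "fit_hierarchical_model",
    "contrast",
    "convergence_diagnostics",
]

_SD_PRIOR_SCALE = 5.0  # half-Normal prior scale for all SDs
_SIGMA_FLOOR = 1e-7  # numerical floor; guards degenerate zero-noise cohorts
_SIGMA_CEIL = 1e3
_RHO_MAX = 0.995
_MH_TARGET = 0.44


@dataclass
class ContrastResult:
    """Posterior summary of a per-draw difference a - b."""

    mean: float
    sd: float
    cri_low: float
    cri_high: float
    crosses_zero: bool


class ModelFit:
    """Posterior draws plus summaries for the hierarchical slope model.

    draws maps parameter name -> array of shape (chains, kept_iterations).
    Includes derived group means: mean_male, mean_female and (when scenes
    are present) mean_scene.
    """

    def __init__(self, draws: dict[str, np.ndarray], species: list[str]):
        self.draws = draws
        self.species = species
        self._summary: pd.DataFrame | None = None

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            diag = convergence_diagnostics(self.draws)
            rows = {}
            for name, d in self.draws.items():
                flat = d.reshape(-1)
                lo, hi = np.percentile(flat, [2.5, 97.5])
                rows[name] = {
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "cri_2.5": float(lo),
                    "cri_97.5": float(hi),
                    "rhat": float(diag.loc[name, "rhat"]),
                    "ess_bulk": float(diag.loc[name, "ess_bulk"]),
                }
            self._summary = pd.DataFrame(rows).T
        return self._summary

    @property
    def converged(self) -> bool:
        rhat = self.summary()["rhat"]
        return bool(np.all(rhat[np.isfinite(rhat)] <= 1.01)) and not rhat.isna().all()


def _halfnormal_logpdf(s: float, scale: float = _SD_PRIOR_SCALE) -> float:
    return -0.5 * (s / scale) ** 2


def _bvn_loglik(a: np.ndarray, b: np.ndarray, ta: float, tb: float, rho: float) -> float:
    """Log-likelihood of zero-mean bivariate normal effects."""
    det = ta**2 * tb**2 * (1 - rho**2)
    if det <= 0:
        return -np.inf
    q = (
        (a / ta) ** 2 - 2 * rho * (a / ta) * (b / tb) + (b / tb) ** 2
    ).sum() / (1 - rho**2)
    return -0.5 * len(a) * np.log(det) - 0.5 * q


class _AdaptiveStep:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, step: float = 0.3):
        self.log_step = np.log(step)
        self.t = 0

    def update(self, acc_prob: float) -> None:
        self.t += 1
        self.log_step += (acc_prob - _MH_TARGET) / self.t**0.6

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))


def _mh_scalar(rng, value, logpost, stepper, adapt, lo=-np.inf, hi=np.inf):
    """One random-walk Metropolis update of a scalar on an open interval."""
    prop = value + rng.normal(0.0, stepper.step)
    if prop <= lo or prop >= hi:
        acc = 0.0
        new = value
    else:
        dlp = logpost(prop) - logpost(value)
        acc = min(1.0, np.exp(min(dlp, 0.0))) if np.isfinite(dlp) else 0.0
        new = prop if rng.random() < acc else value
    if adapt:
        stepper.update(acc)
    return new


def _run_chain(y, male, sp_idx, n_species, ys, region_idx, n_regions,
               iterations, warmup, rng):
    n = len(y)
    n_j = np.bincount(sp_idx, minlength=n_species).astype(float)
    nm_j = np.bincount(sp_idx, weights=male, minlength=n_species)
    xtx = np.array([[n, male.sum()], [male.sum(), male.sum()]], dtype=float)
    xtx_inv = np.linalg.inv(xtx)
    chol_xtx_inv = np.linalg.cholesky(xtx_inv)

    # initial values, jittered per chain
    fem = y[male == 0]
    mal = y[male == 1]
    alpha = fem.mean() + rng.normal(0, 0.1)
    beta = mal.mean() - fem.mean() + rng.normal(0, 0.1)
    sigma = max(y.std(), 0.05) * np.exp(rng.normal(0, 0.2))
    tau_a = tau_b = max(0.5 * sigma, 0.05)
    rho = 0.0
    a = np.zeros(n_species)
    b = np.zeros(n_species)
    if n_regions:
        mu_r = np.array([ys[region_idx == r].mean() for r in range(n_regions)])
        sigma_s = max(ys.std(), 0.05) * np.exp(rng.normal(0, 0.2))
    steppers = {
        k: _AdaptiveStep()
        for k in ("sigma", "tau_a", "tau_b", "rho", "sigma_s",
                  "nc_tau_a", "nc_tau_b", "nc_rho")
    }

    kept = iterations - warmup
    out = {k: np.empty(kept) for k in
           ["alpha", "beta_sex", "sigma", "tau_a", "tau_b", "rho"]}
    for j in range(n_species):
        out[f"a[{j}]"] = np.empty(kept)
        out[f"b[{j}]"] = np.empty(kept)
    if n_regions:
        for r in range(n_regions):
            out[f"mu_region[{r}]"] = np.empty(kept)
        out["sigma_scene"] = np.empty(kept)

    for it in range(iterations):
        adapt = it < warmup
        s2 = sigma**2  # residual variance entering this scan

        # fixed effects | random effects (conjugate, flat prior)
        r_fix = y - a[sp_idx] - b[sp_idx] * male
        mean_fix = xtx_inv @ np.array([r_fix.sum(), (r_fix * male).sum()])
        alpha, beta = mean_fix + sigma * (chol_xtx_inv @ rng.standard_normal(2))

        # species effects | fixed effects (conjugate bivariate normal)
        resid = y - alpha - beta * male
        s0 = np.bincount(sp_idx, weights=resid, minlength=n_species)
        s1 = np.bincount(sp_idx, weights=resid * male, minlength=n_species)
        det_s = tau_a**2 * tau_b**2 * (1 - rho**2)
        si11 = tau_b**2 / det_s
        si22 = tau_a**2 / det_s
        si12 = -rho * tau_a * tau_b / det_s
        p11 = si11 + n_j / s2
        p12 = si12 + nm_j / s2
        p22 = si22 + nm_j / s2
        det_p = p11 * p22 - p12**2
        c11, c12, c22 = p22 / det_p, -p12 / det_p, p11 / det_p
        m_a = c11 * (s0 / s2) + c12 * (s1 / s2)
        m_b = c12 * (s0 / s2) + c22 * (s1 / s2)
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
        z1 = rng.standard_normal(n_species)
        z2 = rng.standard_normal(n_species)
        a = m_a + l11 * z1
        b = m_b + l21 * z1 + l22 * z2

        # recentering move: shift the random-effect means into the fixed
        # effects (likelihood-invariant; breaks the alpha <-> a_j coupling
        # that otherwise slows mixing).  Conditional of the shift given the
        # invariance is N2(mean(a, b), Sigma / J).
        sc11 = tau_a**2 / n_species
        sc22 = tau_b**2 / n_species
        sc12 = rho * tau_a * tau_b / n_species
        sl11 = np.sqrt(sc11)
        sl21 = sc12 / sl11
        sl22 = np.sqrt(max(sc22 - sl21**2, 0.0))
        w1, w2 = rng.standard_normal(2)
        d_a = a.mean() + sl11 * w1
        d_b = b.mean() + sl21 * w1 + sl22 * w2
        alpha += d_a
        beta += d_b
        a -= d_a
        b -= d_b

        # refresh residual statistics for the recentred state
        resid = y - alpha - beta * male
        s0 = np.bincount(sp_idx, weights=resid, minlength=n_species)
        s1 = np.bincount(sp_idx, weights=resid * male, minlength=n_species)

        # residual scale (adaptive MH on log sigma)
        ssr = ((resid - a[sp_idx] - b[sp_idx] * male) ** 2).sum()

        def lp_sigma(ls):
            s = np.exp(ls)
            return -n * ls - ssr / (2 * s**2) + _halfnormal_logpdf(s) + ls

        ls = _mh_scalar(rng, np.log(sigma), lp_sigma, steppers["sigma"], adapt,
                        lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL))
        sigma = np.exp(ls)

        # random-effect scales and correlation (adaptive MH)
        def lp_tau_a(lt):
            t = np.exp(lt)
            return _bvn_loglik(a, b, t, tau_b, rho) + _halfnormal_logpdf(t) + lt

        def lp_tau_b(lt):
            t = np.exp(lt)
            return _bvn_loglik(a, b, tau_a, t, rho) + _halfnormal_logpdf(t) + lt

        def lp_rho(r):
            return _bvn_loglik(a, b, tau_a, tau_b, r)

        # a few MH sweeps per scan: these scalars are cheap to evaluate and
        # mix slower than the conjugate blocks otherwise
        for _ in range(3):
            tau_a = np.exp(_mh_scalar(rng, np.log(tau_a), lp_tau_a, steppers["tau_a"],
                                      adapt, lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL)))
            tau_b = np.exp(_mh_scalar(rng, np.log(tau_b), lp_tau_b, steppers["tau_b"],
                                      adapt, lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL)))
            rho = _mh_scalar(rng, rho, lp_rho, steppers["rho"], adapt,
                             lo=-_RHO_MAX, hi=_RHO_MAX)

        # interweaved non-centered update of the same scalars (ASIS): with
        # eta = L^{-1}(a, b) held fixed the scales are informed by the data
        # likelihood directly, which breaks the tau -> 0 funnel that traps
        # the centered sampler.
        s2c = sigma**2  # sigma was just updated
        s2_tot = (resid**2).sum()

        def _ssr_of(av, bv):
            return (
                s2_tot
                - 2 * (av * s0 + bv * s1).sum()
                + (n_j * av**2 + 2 * nm_j * av * bv + nm_j * bv**2).sum()
            )

        def _recompose(ta, tb, r, e1, e2):
            return ta * e1, tb * (r * e1 + np.sqrt(1 - r**2) * e2)

        eta1 = a / tau_a
        eta2 = (b - tau_b * rho * eta1) / (tau_b * np.sqrt(1 - rho**2))

        def lp_nc_tau_a(lt):
            t = np.exp(lt)
            av, bv = _recompose(t, tau_b, rho, eta1, eta2)
            return -_ssr_of(av, bv) / (2 * s2c) + _halfnormal_logpdf(t) + lt

        def lp_nc_tau_b(lt):
            t = np.exp(lt)
            av, bv = _recompose(tau_a, t, rho, eta1, eta2)
            return -_ssr_of(av, bv) / (2 * s2c) + _halfnormal_logpdf(t) + lt

        def lp_nc_rho(r):
            av, bv = _recompose(tau_a, tau_b, r, eta1, eta2)
            return -_ssr_of(av, bv) / (2 * s2c)

        tau_a = np.exp(_mh_scalar(rng, np.log(tau_a), lp_nc_tau_a, steppers["nc_tau_a"],
                                  adapt, lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL)))
        tau_b = np.exp(_mh_scalar(rng, np.log(tau_b), lp_nc_tau_b, steppers["nc_tau_b"],
                                  adapt, lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL)))
        rho = _mh_scalar(rng, rho, lp_nc_rho, steppers["nc_rho"], adapt,
                         lo=-_RHO_MAX, hi=_RHO_MAX)
        a, b = _recompose(tau_a, tau_b, rho, eta1, eta2)

        # scene submodel
        if n_regions:
            ss2 = sigma_s**2
            for r in range(n_regions):
                sel = region_idx == r
                nr = sel.sum()
                mu_r[r] = ys[sel].mean() + rng.normal(0, np.sqrt(ss2 / nr))
            ssr_s = ((ys - mu_r[region_idx]) ** 2).sum()
            ns = len(ys)

            def lp_sigma_s(ls):
                s = np.exp(ls)
                return -ns * ls - ssr_s / (2 * s**2) + _halfnormal_logpdf(s) + ls

            sigma_s = np.exp(_mh_scalar(rng, np.log(sigma_s), lp_sigma_s,
                                        steppers["sigma_s"], adapt,
                                        lo=np.log(_SIGMA_FLOOR), hi=np.log(_SIGMA_CEIL)))

        if it >= warmup:
            k = it - warmup
            out["alpha"][k] = alpha
            out["beta_sex"][k] = beta
            out["sigma"][k] = sigma
            out["tau_a"][k] = tau_a
            out["tau_b"][k] = tau_b
            out["rho"][k] = rho
            for j in range(n_species):
                out[f"a[{j}]"][k] = a[j]
                out[f"b[{j}]"][k] = b[j]
            if n_regions:
                for r in range(n_regions):
                    out[f"mu_region[{r}]"][k] = mu_r[r]
                out["sigma_scene"][k] = sigma_s
    return out


def fit_hierarchical_model(
    cohort: pd.DataFrame,
    chains: int = 4,
    iterations: int = 5000,
    warmup: int = 2500,
    seed: int | None = None,
) -> ModelFit:
    """Fit the joint spider (sex + species random slopes) and scene model.

    cohort needs columns group ('spider'/'scene'), species, sex
    ('male'/'female'), region and slope.  Runs ``chains`` independent
    chains of ``iterations`` draws each, discarding ``warmup``; flags
    non-convergence (any split-Rhat > 1.01) with a warning but still
    returns summaries.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if not 0 < warmup < iterations:
        raise ValueError("require 0 < warmup < iterations")
    spiders = cohort[cohort["group"] == "spider"]
    scenes = cohort[cohort["group"] == "scene"]
    if spiders.empty:
        raise ValueError("cohort has no spider rows")
    if not np.isfinite(cohort["slope"]).all():
        raise ValueError("slopes must be finite")

    both = spiders.groupby("species")["sex"].nunique()
    n_both = int((both >= 2).sum())
    if n_both < 2:
        raise ValueError(
            "random-slope model needs >= 2 species observed in both sexes; "
            "use a fixed-effects model for a single-species cohort"
        )
    species = sorted(spiders["species"].unique())
    sp_map = {s: i for i, s in enumerate(species)}
    y = spiders["slope"].to_numpy(dtype=float)
    male = (spiders["sex"] == "male").to_numpy(dtype=float)
    sp_idx = spiders["species"].map(sp_map).to_numpy()

    if not scenes.empty:
        regions = sorted(scenes["region"].unique())
        rg_map = {r: i for i, r in enumerate(regions)}
        ys = scenes["slope"].to_numpy(dtype=float)
        region_idx = scenes["region"].map(rg_map).to_numpy()
        n_regions = len(regions)
    else:
        regions, ys, region_idx, n_regions = [], np.empty(0), np.empty(0, int), 0

    seeds = np.random.SeedSequence(seed).spawn(chains)
    chain_draws = [
        _run_chain(y, male, sp_idx, len(species), ys, region_idx, n_regions,
                   iterations, warmup, np.random.default_rng(s))
        for s in seeds
    ]
    draws = {
        k: np.stack([cd[k] for cd in chain_draws]) for k in chain_draws[0]
    }
    # derived group means (population level; random effects are zero-mean)
    draws["mean_female"] = draws["alpha"]
    draws["mean_male"] = draws["alpha"] + draws["beta_sex"]
    if n_regions:
        draws["mean_scene"] = np.mean(
            [draws[f"mu_region[{r}]"] for r in range(n_regions)], axis=0
        )

    fit = ModelFit(draws, species)
    if not fit.converged:
        warnings.warn(
            "MCMC convergence not reached (split-Rhat > 1.01 for some "
            "parameters); summaries emitted anyway",
            stacklevel=2,
        )
    return fit


def contrast(a: np.ndarray, b: np.ndarray) -> ContrastResult:
    """Per-draw difference a - b summarized as mean, SD and 95% CrI.

    The crosses-zero verdict is True when the equal-tailed 95% credible
    interval contains zero.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("mismatched draw counts")
    d = a - b
    lo, hi = np.percentile(d, [2.5, 97.5])
    return ContrastResult(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        cri_low=float(lo),
        cri_high=float(hi),
        crosses_zero=bool(lo <= 0.0 <= hi),
    )


def convergence_diagnostics(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rank-normalized split-Rhat and bulk ESS per parameter.

    draws maps parameter -> (chains, iterations) arrays; at least two
    chains are required.  Zero-variance (constant) chains yield NaN and are
    the caller's signal of degeneracy.
    """
    import arviz as az

    rows = {}
    for name, d in draws.items():
        d = np.asarray(d, dtype=float)
        if d.ndim != 2 or d.shape[0] < 2:
            raise ValueError("Rhat requires >= 2 chains of draws")
        if np.allclose(d, d.flat[0]):
            rows[name] = {"rhat": np.nan, "ess_bulk": np.nan}
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows[name] = {
                "rhat": float(az.rhat(d)),
                "ess_bulk": float(az.ess(d)),
            }
    return pd.DataFrame(rows).T
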