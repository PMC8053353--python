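"""Constrained two-component Gaussian mixtures for biomarker abnormality.

Each biomarker's oriented z-scores are modelled as a mixture of a *normal*
Gaussian — fixed at the non-carrier mean and SD, since non-carriers are
healthy — and an *abnormal* Gaussian estimated from mutation carriers
together with a mixing fraction pi (the fraction of carriers drawn from the
abnormal component):

    f(x) = pi * N(x; mu_ab, sd_ab) + (1 - pi) * N(x; mu_no, sd_no)

Three fit variants share this likelihood:

* standard controls-fixed fit — one mixing fraction;
* Siamese fit — a left/right biomarker pair shares both Gaussians but keeps
  independent mixing fractions pi_L, pi_R, stabilising the fit of the side
  that becomes abnormal late in an asymmetric disease;
* phenotype-shared fit — Gaussians estimated on pooled symptomatic carriers,
  mixing fractions re-estimated per clinical phenotype.

The abnormality posterior P(abnormal | x) feeds the event-ordering step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.stats import norm

_PI_LO, _PI_HI = 1e-3, 1.0 - 1e-3
#: abnormal-component SD cap, in control-SD units. On the z-scored scale the
#: abnormal component is expected to have dispersion comparable to the normal
#: one; a loose cap lets a single broad component swallow both modes (the
#: classic GMM instability of late biomarkers), which this bound excludes.
_SD_HI_FACTOR = 1.25


class MixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise MixtureError(f"component sd must be > 0, got {self.sd}")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return norm.logpdf(x, self.mean, self.sd)


@dataclass
class MixtureFit:
    """Fitted two-component mixture with one mixing fraction per context.

    Contexts are ``{"all": pi}`` for a standard fit, ``{"left","right"}`` for
    a Siamese fit, and one key per phenotype for a phenotype-shared fit. A
    context whose data were entirely missing maps to None (undefined).
    """

    normal: GaussianComponent
    abnormal: GaussianComponent
    mixing: dict
    loglik: float
    n_used: dict = field(default_factory=dict)
    converged: bool = True

    def pi(self, context: str = "all") -> float:
        if context not in self.mixing:
            raise MixtureError(f"no mixing fraction for context {context!r}")
        val = self.mixing[context]
        if val is None:
            raise MixtureError(f"mixing fraction undefined for context {context!r}")
        return val

    def to_dict(self) -> dict:
        return {
            "normal": {"mean": self.normal.mean, "sd": self.normal.sd},
            "abnormal": {"mean": self.abnormal.mean, "sd": self.abnormal.sd},
            "mixing": self.mixing,
            "loglik": self.loglik,
            "n_used": self.n_used,
            "converged": self.converged,
        }


def mixture_loglik(x: np.ndarray, normal: GaussianComponent,
                   abnormal: GaussianComponent, pi: float) -> float:
    """Exact mixture log-likelihood; handles the pi = 0 and pi = 1 boundaries."""
    x = np.asarray(x, dtype=float)
    la = abnormal.logpdf(x)
    ln = normal.logpdf(x)
    if pi <= 0:
        return float(ln.sum())
    if pi >= 1:
        return float(la.sum())
    return float(np.logaddexp(np.log(pi) + la, np.log1p(-pi) + ln).sum())


def _nll_terms(x: np.ndarray, mu_n: float, sd_n: float):
    """Pre-computed pieces of the normal-component logpdf for speed."""
    ln = norm.logpdf(x, mu_n, sd_n)
    return ln


def _neg_loglik(theta: np.ndarray, xs: list[np.ndarray],
                lns: list[np.ndarray]) -> float:
    """Negative log-likelihood for shared Gaussians and per-dataset mixing.

    theta = (mu_ab, sd_ab, pi_1, ..., pi_D) over datasets xs.
    """
    mu_a, sd_a = theta[0], theta[1]
    total = 0.0
    for d, x in enumerate(xs):
        pi = theta[2 + d]
        la = -0.5 * ((x - mu_a) / sd_a) ** 2 - np.log(sd_a) - 0.5 * np.log(2 * np.pi)
        total -= np.logaddexp(np.log(pi) + la, np.log1p(-pi) + lns[d]).sum()
    return total


def _fit_shared(xs: list[np.ndarray], mu_n: float, sd_n: float,
                maxiter: int, tol: float,
                symptomatic_mean: Optional[float] = None
                ) -> tuple[float, float, list[float], float, bool]:
    """Bounded multi-start quasi-Newton fit of (mu_ab, sd_ab, pi_1..pi_D)."""
    pooled = np.concatenate(xs)
    if pooled.std() == 0:
        raise MixtureError("all carrier values identical; mixture is degenerate")
    lns = [_nll_terms(x, mu_n, sd_n) for x in xs]

    lo_mu = mu_n + 0.1 * sd_n
    hi_mu = float(pooled.max())
    if hi_mu <= lo_mu:
        hi_mu = lo_mu + 0.1 * sd_n  # essentially no abnormal tail in the data
    bounds = [(lo_mu, hi_mu), (0.2 * sd_n, _SD_HI_FACTOR * sd_n)] + \
             [(_PI_LO, _PI_HI)] * len(xs)

    starts_mu = [float(np.percentile(pooled, 75)), mu_n + 2.0 * sd_n]
    if symptomatic_mean is not None:
        starts_mu.insert(0, float(symptomatic_mean))
    else:
        starts_mu.insert(0, float(pooled[pooled >= np.median(pooled)].mean()))

    best = None
    for mu0 in starts_mu:
        theta0 = np.array([np.clip(mu0, lo_mu, hi_mu), sd_n, *([0.5] * len(xs))])
        res = optimize.minimize(
            _neg_loglik, theta0, args=(xs, lns), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": maxiter, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise MixtureError("mixture optimisation produced no iterate")
    mu_a, sd_a = float(best.x[0]), float(best.x[1])
    pis = [float(p) for p in best.x[2:]]
    return mu_a, sd_a, pis, -float(best.fun), bool(best.success)


def fit_fixed_normal_gmm(carrier_values: np.ndarray, control_mean: float,
                         control_sd: float, maxiter: int = 500,
                         tol: float = 1e-6,
                         symptomatic_mean: Optional[float] = None) -> MixtureFit:
    """Controls-fixed GMM on carrier values of one biomarker.

    The normal component is pinned at the non-carrier statistics; only the
    abnormal mean/SD and the mixing fraction are estimated, under bound
    constraints that keep the abnormal component above the normal one.
    """
    x = np.asarray(carrier_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise MixtureError(f"need >= 10 carrier observations, got {len(x)}")
    if not control_sd > 0:
        raise MixtureError("control sd must be > 0")
    mu_a, sd_a, pis, ll, ok = _fit_shared(
        [x], control_mean, control_sd, maxiter, tol, symptomatic_mean)
    return MixtureFit(
        normal=GaussianComponent(control_mean, control_sd),
        abnormal=GaussianComponent(mu_a, sd_a),
        mixing={"all": pis[0]}, loglik=ll,
        n_used={"all": len(x)}, converged=ok,
    )


def fit_siamese_gmm(left_values: np.ndarray, right_values: np.ndarray,
                    control_mean_left: float, control_sd_left: float,
                    control_mean_right: Optional[float] = None,
                    control_sd_right: Optional[float] = None,
                    maxiter: int = 500, tol: float = 1e-6,
                    symptomatic_mean: Optional[float] = None) -> MixtureFit:
    """Joint fit of a left/right biomarker pair.

    Both hemispheres (as z-scores) share the normal and abnormal Gaussians;
    each side keeps its own mixing fraction. The shared fixed normal pools
    the per-side control statistics (identical after z-scoring).
    """
    if control_mean_right is None:
        control_mean_right = control_mean_left
    if control_sd_right is None:
        control_sd_right = control_sd_left
    xl = np.asarray(left_values, dtype=float)
    xl = xl[np.isfinite(xl)]
    xr = np.asarray(right_values, dtype=float)
    xr = xr[np.isfinite(xr)]
    if len(xl) < 10 or len(xr) < 10:
        raise MixtureError(
            f"need >= 10 carrier observations per side, got {len(xl)}/{len(xr)}")
    mu_n = 0.5 * (control_mean_left + control_mean_right)
    sd_n = float(np.sqrt(0.5 * (control_sd_left ** 2 + control_sd_right ** 2)))
    mu_a, sd_a, pis, ll, ok = _fit_shared(
        [xl, xr], mu_n, sd_n, maxiter, tol, symptomatic_mean)
    return MixtureFit(
        normal=GaussianComponent(mu_n, sd_n),
        abnormal=GaussianComponent(mu_a, sd_a),
        mixing={"left": pis[0], "right": pis[1]}, loglik=ll,
        n_used={"left": len(xl), "right": len(xr)}, converged=ok,
    )


def fit_phenotype_shared_gmm(values_by_phenotype: dict, control_mean: float,
                             control_sd: float, maxiter: int = 500,
                             tol: float = 1e-6) -> MixtureFit:
    """Gaussians fit on the pooled phenotypes; mixing fraction per phenotype.

    Phenotype samples are too small for independent mixtures, so only the
    1-D mixing fraction is re-optimised per phenotype with both Gaussians
    held at the pooled estimate. A phenotype with no observations gets an
    undefined (None) mixing fraction.
    """
    if len(values_by_phenotype) < 2:
        raise MixtureError("phenotype-shared fit needs >= 2 phenotypes")
    clean = {
        ph: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
        for ph, v in values_by_phenotype.items()
    }
    pooled = np.concatenate(list(clean.values())) if clean else np.array([])
    base = fit_fixed_normal_gmm(pooled, control_mean, control_sd, maxiter, tol)

    mixing: dict = {}
    n_used: dict = {}
    total_ll = 0.0
    for ph, x in clean.items():
        n_used[ph] = len(x)
        if len(x) == 0:
            mixing[ph] = None
            continue
        la = base.abnormal.logpdf(x)
        ln = base.normal.logpdf(x)

        def nll(pi: float) -> float:
            return -float(np.logaddexp(np.log(pi) + la,
                                       np.log1p(-pi) + ln).sum())

        res = optimize.minimize_scalar(
            nll, bounds=(_PI_LO, _PI_HI), method="bounded",
            options={"xatol": 1e-9})
        mixing[ph] = float(res.x)
        total_ll -= float(res.fun)

    return MixtureFit(normal=base.normal, abnormal=base.abnormal,
                      mixing=mixing, loglik=total_ll, n_used=n_used,
                      converged=base.converged)


def posterior_abnormality(x, fit: MixtureFit, context: str = "all"):
    """P(abnormal | x) under the fitted mixture, using the context's mixing."""
    pi = fit.pi(context)
    x = np.asarray(x, dtype=float)
    if pi <= 0:
        out = np.zeros_like(x)
    elif pi >= 1:
        out = np.ones_like(x)
    else:
        la = np.log(pi) + fit.abnormal.logpdf(x)
        ln = np.log1p(-pi) + fit.normal.logpdf(x)
        out = np.exp(la - np.logaddexp(la, ln))
    return float(out) if out.ndim == 0 else out
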