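"""Use–availability choice sets and conditional-likelihood fitting.

Each observed step contributes one stratum: the used endpoint plus M
available endpoints drawn from the availability kernel, all with covariates
attached.  Selection coefficients are estimated by maximizing the
conditional (within-stratum softmax) likelihood

    Σ_i [ η_used,i − log Σ_{j ∈ stratum i} exp(η_ij) ]

which is the conditional-logistic-regression likelihood when the linear
predictor is η = w′β (exponential selection, g = exp(w′β)).  The
residence-time selection form sets η = log g = log(1 + exp(−w′β)), from
g = 1/(δΔt) with motility on an inverse-logit link; the stratum-constant
factors Δs²/(4Δt)·Δt cancel inside the softmax, as does any intercept —
neither is estimable and neither is included.

The kernel parameters (δ̄, or the gamma baseline's shape/rate) are plug-in
estimates, not jointly estimated with β; reported uncertainty can
therefore be biased low, and fit reports carry that caveat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .kernels import sample_cartesian, sample_gamma_polar, sample_polar
from .landscape import Landscape, extract_covariates
from .motility import MotilitySeries
from .tracks import StepSeries

PLUGIN_CAVEAT = (
    "Movement-kernel parameters are plug-in estimates, not jointly "
    "estimated with the selection coefficients; reported uncertainty "
    "may be biased low."
)

FORMS = ("exponential", "ede_residence")


class FitError(RuntimeError):
    pass


class NonIdentifiableError(FitError):
    """All within-stratum covariate contrasts are zero: flat likelihood."""


# ---------------------------------------------------------------------------
# choice sets

@dataclass
class ChoiceSet:
    """One used step plus its M available alternatives."""

    stratum_id: int
    used_xy: np.ndarray        # (2,)
    used_w: np.ndarray         # (p,)
    avail_xy: np.ndarray       # (M_i, 2)
    avail_w: np.ndarray        # (M_i, p)
    dt: float
    delta_bar: float
    sigma2: float
    n_redrawn: int = 0
    n_dropped: int = 0

    @property
    def n_avail(self) -> int:
        return len(self.avail_xy)


@dataclass
class ChoiceSetCollection:
    """All strata for one track plus build bookkeeping."""

    sets: list[ChoiceSet]
    covariate_names: list[str]
    sampler: str
    M: int
    n_strata_dropped: int = 0
    n_candidates_dropped: int = 0

    def __len__(self) -> int:
        return len(self.sets)

    def to_frame(self) -> pd.DataFrame:
        """Long format interoperable with conditional-logistic tools."""
        rows = []
        for cs in self.sets:
            xy = np.vstack([cs.used_xy, cs.avail_xy])
            w = np.vstack([cs.used_w, cs.avail_w])
            case = np.zeros(len(xy), dtype=int)
            case[0] = 1
            block = pd.DataFrame(
                {
                    "stratum_id": cs.stratum_id,
                    "case": case,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "dt_h": cs.dt,
                    "sigma2": cs.sigma2,
                }
            )
            for k, name in enumerate(self.covariate_names):
                block[name] = w[:, k]
            rows.append(block)
        return pd.concat(rows, ignore_index=True)


def _draw_available(
    sampler: str,
    origin: np.ndarray,
    sigma2: float,
    M: int,
    rng: np.random.Generator,
    gamma_model=None,
) -> np.ndarray:
    if sampler in ("polar", "rayleigh"):
        return sample_polar(origin, sigma2, M, rng)
    if sampler == "cartesian":
        return sample_cartesian(origin, sigma2, M, rng)
    if sampler == "plain_diffusion":
        return sample_polar(origin, sigma2, M, rng)
    if sampler == "gamma":
        if gamma_model is None:
            raise ValueError("gamma sampler requires a fitted GammaStepModel")
        return sample_gamma_polar(origin, gamma_model.shape, gamma_model.rate, M, rng)
    raise ValueError(f"unknown sampler {sampler!r}")


def build_choice_sets(
    steps: StepSeries,
    motility: MotilitySeries | None,
    landscape: Landscape,
    M: int = 100,
    sampler: str = "polar",
    rng: np.random.Generator | int | None = None,
    gamma_model=None,
    plain_sigma2_0: float | None = None,
    max_redraw_factor: int = 10,
) -> ChoiceSetCollection:
    """Build one stratum per step with M sampled available endpoints.

    Strata start at the first step: the angle distribution is uniform, so
    no previous heading is needed and the whole track is usable.  Each
    stratum uses its own kernel scale σ² = 2δ̄(t_i)Δt_i (``polar`` /
    ``cartesian``), σ²₀·Δt_i (``plain_diffusion``), or gamma-distributed
    lengths (``gamma``).

    Out-of-bounds or NoData candidates are redrawn up to
    ``max_redraw_factor × M`` total draws, then dropped; a stratum is
    dropped when its used endpoint is out of bounds or fewer than M/2
    candidates survive.  All drops are counted on the result.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(steps)
    if n == 0:
        raise ValueError("no steps to build strata from")

    if sampler in ("polar", "rayleigh", "cartesian"):
        if motility is None:
            raise ValueError("diffusion samplers require a MotilitySeries")
        if len(motility) != n:
            raise ValueError("motility is not aligned to the steps")
        sigma2_all = motility.sigma2()
        delta_all = motility.delta_bar
    elif sampler == "plain_diffusion":
        if plain_sigma2_0 is None:
            raise ValueError("plain_diffusion requires plain_sigma2_0")
        sigma2_all = plain_sigma2_0 * steps.dt
        delta_all = np.full(n, plain_sigma2_0 / 2.0)
    elif sampler == "gamma":
        sigma2_all = np.full(n, np.nan)
        delta_all = np.full(n, np.nan)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")

    # used endpoints first: a fully disjoint landscape is an input error
    used_w_all, used_missing = extract_covariates(landscape, steps.endpoint)
    if used_missing.all():
        raise ValueError("landscape does not cover any used endpoint")

    sets: list[ChoiceSet] = []
    n_strata_dropped = 0
    n_candidates_dropped = 0
    for i in range(n):
        if used_missing[i]:
            n_strata_dropped += 1
            continue
        origin = steps.origin[i]
        sigma2 = float(sigma2_all[i])
        kept_xy: list[np.ndarray] = []
        kept_w: list[np.ndarray] = []
        n_kept = 0
        n_drawn = 0
        n_redrawn = 0
        cap = max_redraw_factor * M
        while n_kept < M and n_drawn < cap:
            want = M - n_kept
            xy = _draw_available(sampler, origin, sigma2, want, rng, gamma_model)
            n_drawn += want
            w, missing = extract_covariates(landscape, xy)
            ok = ~missing
            if ok.any():
                kept_xy.append(xy[ok])
                kept_w.append(w[ok])
                n_kept += int(ok.sum())
            n_redrawn += int(missing.sum())
        if n_kept < max(1, M // 2):
            n_strata_dropped += 1
            n_candidates_dropped += M - n_kept
            continue
        n_candidates_dropped += M - n_kept
        sets.append(
            ChoiceSet(
                stratum_id=i,
                used_xy=steps.endpoint[i].copy(),
                used_w=used_w_all[i],
                avail_xy=np.vstack(kept_xy),
                avail_w=np.vstack(kept_w),
                dt=float(steps.dt[i]),
                delta_bar=float(delta_all[i]),
                sigma2=sigma2,
                n_redrawn=n_redrawn,
                n_dropped=M - n_kept,
            )
        )
    if not sets:
        raise ValueError("every stratum was dropped; landscape coverage too poor")
    return ChoiceSetCollection(
        sets=sets,
        covariate_names=list(landscape.names),
        sampler=sampler,
        M=M,
        n_strata_dropped=n_strata_dropped,
        n_candidates_dropped=n_candidates_dropped,
    )


# ---------------------------------------------------------------------------
# conditional likelihood

@dataclass
class SelectionModel:
    """Selection-function form plus coefficients."""

    form: str
    beta: np.ndarray

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")


def _stack(sets: list[ChoiceSet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten strata: X (N, p), used row first in each stratum.

    Returns (X, starts, sizes); starts[i] indexes each stratum's used row.
    """
    blocks = [np.vstack([cs.used_w, cs.avail_w]) for cs in sets]
    sizes = np.array([b.shape[0] for b in blocks])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return np.vstack(blocks), starts, sizes


def _eta_and_grad_factor(u: np.ndarray, form: str) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor transform η(u) and dη/du for each form."""
    if form == "exponential":
        return u, np.ones_like(u)
    # ede_residence: η = log g = log(1 + exp(−u)) = softplus(−u)
    eta = np.logaddexp(0.0, -u)
    deta = -expit(-u)
    return eta, deta


def _segment_logsumexp(eta: np.ndarray, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum log-sum-exp and softmax probabilities, guarded."""
    mx = np.maximum.reduceat(eta, starts)
    rep = np.repeat(mx, np.diff(np.concatenate([starts, [len(eta)]])))
    ex = np.exp(eta - rep)
    denom = np.add.reduceat(ex, starts)
    lse = mx + np.log(denom)
    probs = ex / np.repeat(denom, np.diff(np.concatenate([starts, [len(eta)]])))
    return lse, probs


def conditional_loglik(
    sets, model: SelectionModel | None = None, *, beta=None, form: str | None = None
) -> float:
    """Conditional (within-stratum softmax) log-likelihood.

    Accepts either a :class:`SelectionModel` or ``beta=..., form=...``.
    ``sets`` may be a ChoiceSetCollection or a list of ChoiceSet.
    """
    if model is None:
        model = SelectionModel(form=form or "exponential", beta=beta)
    cs_list = sets.sets if isinstance(sets, ChoiceSetCollection) else list(sets)
    X, starts, _ = _stack(cs_list)
    return _loglik_grad(X, starts, model.beta, model.form)[0]


def _loglik_grad(
    X: np.ndarray, starts: np.ndarray, beta: np.ndarray, form: str
) -> tuple[float, np.ndarray]:
    p = X.shape[1]
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ValueError(f"beta has length {beta.size}, expected {p}")
    if np.isnan(X).any():
        raise ValueError("NaN covariates reached the likelihood; filter upstream")
    u = X @ beta
    eta, deta = _eta_and_grad_factor(u, form)
    lse, probs = _segment_logsumexp(eta, starts)
    ll = float(np.sum(eta[starts]) - np.sum(lse))
    # ∂η/∂β = deta ⊙ x; grad = Σ_i [∂η_used − Σ_j p_j ∂η_j]
    dX = X * deta[:, None]
    grad = dX[starts].sum(axis=0) - probs @ dX
    return ll, grad


def null_loglik(sets) -> float:
    """Log-likelihood at β = 0 (uniform softmax within each stratum)."""
    cs_list = sets.sets if isinstance(sets, ChoiceSetCollection) else list(sets)
    return float(-np.sum(np.log([cs.n_avail + 1 for cs in cs_list])))


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SelectionFit:
    """Fitted selection coefficients with Wald inference."""

    form: str
    covariate_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    ci_level: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    null_loglik: float
    n_strata: int
    M: int
    converged: bool
    n_iter: int
    grad_norm: float = float("nan")
    sampler: str | None = None
    notes: str = PLUGIN_CAVEAT

    @property
    def ci_width(self) -> np.ndarray:
        return self.ci_upper - self.ci_lower

    def destandardized_beta(self, standardization: dict[str, tuple[float, float]]) -> np.ndarray:
        """Coefficients on the raw covariate scale, given z-score records."""
        sds = np.array([standardization[n][1] for n in self.covariate_names])
        return self.beta / sds

    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "covariates": self.covariate_names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "cov": self.cov.tolist(),
            "ci_level": self.ci_level,
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "n_strata": self.n_strata,
            "M": self.M,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "sampler": self.sampler,
            "notes": self.notes,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SelectionFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            form=d["form"],
            covariate_names=d["covariates"],
            beta=np.asarray(d["beta"]),
            cov=np.asarray(d["cov"]),
            se=np.asarray(d["se"]),
            ci_level=d["ci_level"],
            ci_lower=np.asarray(d["ci_lower"]),
            ci_upper=np.asarray(d["ci_upper"]),
            loglik=d["loglik"],
            null_loglik=d["null_loglik"],
            n_strata=d["n_strata"],
            M=d["M"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            grad_norm=d.get("grad_norm", float("nan")),
            sampler=d.get("sampler"),
            notes=d.get("notes", PLUGIN_CAVEAT),
        )


def _check_identifiable(X: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> None:
    # within-stratum contrasts: any covariate varying inside any stratum
    for s, m in zip(starts, sizes):
        block = X[s : s + m]
        if np.any(np.ptp(block, axis=0) > 0):
            return
    raise NonIdentifiableError(
        "all within-stratum covariate contrasts are zero; the conditional "
        "likelihood is flat and beta is not identifiable"
    )


def _observed_information(
    X: np.ndarray, starts: np.ndarray, beta: np.ndarray, form: str, step: float = 1e-5
) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central differences of the gradient."""
    p = beta.size
    H = np.zeros((p, p))
    for k in range(p):
        e = np.zeros(p)
        e[k] = step
        gp = _loglik_grad(X, starts, beta + e, form)[1]
        gm = _loglik_grad(X, starts, beta - e, form)[1]
        H[:, k] = (gp - gm) / (2.0 * step)
    H = 0.5 * (H + H.T)
    return -H


def fit_ssf(
    sets,
    form: str = "exponential",
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    ci_level: float = 0.90,
    max_iter: int = 500,
) -> SelectionFit:
    """Maximize the conditional likelihood by quasi-Newton (BFGS) iteration.

    The gradient is analytic for both selection forms; the covariance is
    the inverse of the observed information, evaluated by central
    differences of the analytic gradient at the optimum.  Wald CIs at
    ``ci_level`` (default 0.90).
    """
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    collection = sets if isinstance(sets, ChoiceSetCollection) else None
    cs_list = sets.sets if collection is not None else list(sets)
    if not cs_list:
        raise ValueError("no strata to fit")
    X, starts, sizes = _stack(cs_list)
    p = X.shape[1]
    _check_identifiable(X, starts, sizes)
    x0 = np.zeros(p) if init is None else np.asarray(init, dtype=float)

    def negloglik_and_grad(b):
        ll, g = _loglik_grad(X, starts, b, form)
        return -ll, -g

    res = optimize.minimize(
        negloglik_and_grad,
        x0=x0,
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    beta_hat = np.asarray(res.x, dtype=float)
    n_iter = int(res.nit)
    ll, grad = _loglik_grad(X, starts, beta_hat, form)
    # BFGS can stop on precision loss with the gradient still above gtol;
    # polish with Newton steps using the observed information, which is
    # exact curvature at convergence
    gtol_eff = max(tol, tol * abs(ll))
    info = _observed_information(X, starts, beta_hat, form)
    for _ in range(20):
        if np.linalg.norm(grad) <= gtol_eff:
            break
        try:
            step_vec = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        ll_new, grad_new = _loglik_grad(X, starts, beta_hat + step_vec, form)
        if not np.isfinite(ll_new) or ll_new < ll - 1e-9:
            break
        beta_hat, ll, grad = beta_hat + step_vec, ll_new, grad_new
        info = _observed_information(X, starts, beta_hat, form)
        n_iter += 1
    grad_norm = float(np.linalg.norm(grad))
    converged = grad_norm <= gtol_eff
    if not converged:
        raise FitError(
            f"optimizer failed to converge after {n_iter} iterations "
            f"(|grad| = {grad_norm:.3g}); last beta = {beta_hat}"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("observed information is singular at the optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    names = collection.covariate_names if collection else [f"x{k}" for k in range(p)]
    return SelectionFit(
        form=form,
        covariate_names=list(names),
        beta=beta_hat,
        cov=cov,
        se=se,
        ci_level=ci_level,
        ci_lower=beta_hat - z * se,
        ci_upper=beta_hat + z * se,
        loglik=ll,
        null_loglik=null_loglik(cs_list),
        n_strata=len(cs_list),
        M=collection.M if collection else int(sizes.max() - 1),
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        sampler=collection.sampler if collection else None,
    )


def profile_ci(sets, fit: SelectionFit, index: int, ci_level: float | None = None,
               max_expand: float = 6.0) -> tuple[float, float]:
    """Profile-likelihood CI for one coefficient.

    Offered because reference conditional-logistic software is ambiguous
    between Wald and profile intervals; at these sample sizes the two
    nearly coincide.
    """
    level = ci_level if ci_level is not None else fit.ci_level
    cs_list = sets.sets if isinstance(sets, ChoiceSetCollection) else list(sets)
    X, starts, _ = _stack(cs_list)
    p = X.shape[1]
    crit = stats.chi2.ppf(level, df=1) / 2.0
    target = fit.loglik - crit

    def profile_ll(val: float) -> float:
        if p == 1:
            return _loglik_grad(X, starts, np.array([val]), fit.form)[0]
        free = [k for k in range(p) if k != index]

        def nll(bf):
            b = np.empty(p)
            b[index] = val
            b[free] = bf
            ll, g = _loglik_grad(X, starts, b, fit.form)
            return -ll, -g[free]

        r = optimize.minimize(nll, x0=fit.beta[free], jac=True, method="BFGS")
        return -float(r.fun)

    from scipy.optimize import brentq

    bounds = []
    for sign in (-1.0, 1.0):
        lo = fit.beta[index]
        hi = fit.beta[index] + sign * max_expand * max(fit.se[index], 1e-6)
        f = lambda v: profile_ll(v) - target
        if f(hi) > 0:  # likelihood too flat out to max_expand SEs
            bounds.append(hi)
            continue
        bounds.append(float(brentq(f, min(lo, hi), max(lo, hi), xtol=1e-8)))
    return min(bounds), max(bounds)


# ---------------------------------------------------------------------------
# fit comparison

def compare_fits(fit_a: SelectionFit, fit_b: SelectionFit,
                 labels: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Tabulate two fits side by side: estimates, CI widths, ratios.

    Raises on mismatched covariate names; flags sign disagreements.
    """
    if fit_a.covariate_names != fit_b.covariate_names:
        raise ValueError(
            f"covariate mismatch: {fit_a.covariate_names} vs {fit_b.covariate_names}"
        )
    la, lb = labels
    df = pd.DataFrame(
        {
            "covariate": fit_a.covariate_names,
            f"beta_{la}": fit_a.beta,
            f"beta_{lb}": fit_b.beta,
            f"se_{la}": fit_a.se,
            f"se_{lb}": fit_b.se,
            f"ci_width_{la}": fit_a.ci_width,
            f"ci_width_{lb}": fit_b.ci_width,
        }
    )
    df["ci_width_ratio"] = df[f"ci_width_{la}"] / df[f"ci_width_{lb}"]
    df["sign_disagrees"] = np.sign(fit_a.beta) != np.sign(fit_b.beta)
    df.attrs["loglik"] = {la: fit_a.loglik, lb: fit_b.loglik}
    df.attrs["n_strata"] = {la: fit_a.n_strata, lb: fit_b.n_strata}
    df.attrs["M"] = {la: fit_a.M, lb: fit_b.M}
    return df
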