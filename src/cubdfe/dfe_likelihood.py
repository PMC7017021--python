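"""Maximum-likelihood estimation of a categorical DFE from paired folded
4D / short-intron spectra.

The full likelihood is the product of two multinomial likelihoods over
{monomorphic, folded frequency classes}: the test (4D) spectrum under the
categorical selection model and the reference (SI) spectrum under pure
neutrality, sharing theta and the per-frequency-bin alpha corrections.
Fitting is two-stage by default: alpha (and an initial theta) on the SI
spectrum alone, then theta and the selection parameters jointly with alpha
held fixed, via multi-start Nelder-Mead in transformed coordinates that
enforce the f-simplex and gamma-bound constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .errors import DataError, DomainError
from .spectra import (
    LETHAL,
    AlphaCorrection,
    DFEClass,
    DFEModel,
    FoldedSFS,
    PopulationModel,
    default_alpha_bins,
    fold,
    _fold_kernel,
    _ratio,
    _unit_folded_neutral,
    _unit_folded_probs,
)

__all__ = [
    "FoldedSFS",
    "AlphaCorrection",
    "ModelSpec",
    "FitResult",
    "fold",
    "fit_alpha",
    "loglik_joint",
    "fit_model",
    "lrt",
    "select_best_model",
    "rank_bootstrap_ci",
    "MODEL_NAMES",
]

MODEL_NAMES = ("n", "n+l", "n+s", "n+s+l", "n+s+s")

#: null -> alt pairs accepted by the likelihood-ratio test, with degrees of
#: freedom equal to the difference in free selection-parameter counts.
#: (n+l, n+s) and (n+s+l, n+s+s) are boundary/adjacent comparisons used in
#: the nested model walk and reported at df 1.
NESTED_DF = {
    ("n", "n+l"): 1,
    ("n", "n+s"): 2,
    ("n", "n+s+l"): 3,
    ("n", "n+s+s"): 4,
    ("n+l", "n+s"): 1,
    ("n+l", "n+s+l"): 2,
    ("n+l", "n+s+s"): 3,
    ("n+s", "n+s+l"): 1,
    ("n+s", "n+s+s"): 2,
    ("n+s+l", "n+s+s"): 1,
}

#: chain used for the model-selection walk and the table layout; each model
#: is tested against its predecessor here.
CHAIN_PREDECESSOR = {"n+l": "n", "n+s": "n+l", "n+s+l": "n+s", "n+s+s": "n+s"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the five nested categorical selection models.

    ``sel_bounds`` lists |gamma| intervals (lo, hi), one per finite
    selection class; ``n_lethal`` adds a polymorphism-free class. The
    weak/strong boundary (default 10 = |Ne s|) only applies to the
    two-coefficient model.
    """

    name: str
    sel_bounds: tuple = ()
    n_lethal: int = 0

    @classmethod
    def from_name(
        cls,
        name: str,
        boundary: float = 10.0,
        gamma_cap: float = 1600.0,
        gamma_min: float = 1e-4,
    ) -> "ModelSpec":
        if boundary <= 0 or gamma_cap <= boundary or gamma_min >= boundary:
            raise DomainError("require 0 < gamma_min < boundary < gamma_cap")
        table = {
            "n": ((), 0),
            "n+l": ((), 1),
            "n+s": (((gamma_min, gamma_cap),), 0),
            "n+s+l": (((gamma_min, gamma_cap),), 1),
            "n+s+s": (((gamma_min, boundary), (boundary, gamma_cap)), 0),
        }
        if name not in table:
            raise DomainError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        sel, nl = table[name]
        return cls(name, sel, nl)

    @property
    def free_params(self) -> int:
        """Free selection parameters (theta is always fitted in addition)."""
        return 2 * len(self.sel_bounds) + self.n_lethal

    @property
    def n_classes(self) -> int:
        return len(self.sel_bounds) + self.n_lethal


@dataclass
class FitResult:
    model: ModelSpec
    dfe: DFEModel
    theta: float
    alpha: AlphaCorrection | None
    loglik: float
    converged: bool
    optima: list = field(default_factory=list)
    seeds: list = field(default_factory=list)

    def params_dict(self) -> dict:
        out = {"theta": self.theta, "loglik": self.loglik, "model": self.model.name}
        si = 0
        for c in self.dfe.classes:
            if c.is_lethal:
                out["f_lethal"] = c.f
            else:
                si += 1
                out[f"f_s{si}"] = c.f
                out[f"gamma_s{si}"] = c.gamma
        return out


# ---------------------------------------------------------------------------
# alpha fitting (stage 1)
# ---------------------------------------------------------------------------


def fit_alpha(
    si: FoldedSFS,
    ne: int = 2000,
    n_bins: int = 6,
    bins: tuple | None = None,
):
    """Maximum-likelihood frequency-bin corrections from the SI spectrum.

    Under the neutral model the folded class probabilities are
    ``theta * alpha_bin(m) * u_m`` with ``u`` the fixed neutral shape, so
    each bin's total probability is a free parameter (the singleton bin's
    alpha anchored at 1 identifies theta); the multinomial MLE therefore
    matches every bin mass exactly and is available in closed form.

    Returns ``(AlphaCorrection, theta_hat)``.
    """
    if bins is None:
        bins = default_alpha_bins(si.ns, n_bins)
    nf = si.ns // 2
    if bins[-1][1] != nf:
        raise DomainError("alpha bins must cover folded classes up to Ns//2")
    u = _unit_folded_neutral(ne, si.ns)
    L = si.L
    values = []
    theta = None
    for i, (lo, hi) in enumerate(bins):
        K = int(si.counts[lo - 1 : hi].sum())
        if K == 0:
            raise DataError(
                f"alpha bin {i + 1} (folded classes {lo}-{hi}) is empty; "
                "alpha is not identifiable"
            )
        U = float(u[lo - 1 : hi].sum())
        if i == 0:
            theta = (K / L) / U
            values.append(1.0)
        else:
            values.append((K / L) / (theta * U))
    return AlphaCorrection(tuple(bins), tuple(values)), float(theta)


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------


def _multinomial_loglik(k0: int, counts: np.ndarray, mono: float, poly: np.ndarray):
    """sum k log p over {monomorphic, folded classes}; -inf when a class with
    positive count has non-positive probability."""
    if mono <= 0.0 and k0 > 0:
        return -np.inf
    ll = k0 * np.log(mono) if k0 > 0 else 0.0
    pos = counts > 0
    if np.any(poly[pos] <= 0.0):
        return -np.inf
    ll += float(counts[pos] @ np.log(poly[pos]))
    return ll


def loglik_joint(
    dfe: DFEModel,
    theta: float,
    alpha: AlphaCorrection | None,
    sfs4d: FoldedSFS,
    sfs_si: FoldedSFS,
    model: PopulationModel,
) -> float:
    """Joint log-likelihood of the 4D spectrum under ``dfe`` and the SI
    spectrum under pure neutrality, sharing ``theta`` and ``alpha``."""
    if sfs4d.ns != sfs_si.ns:
        raise DomainError("4D and SI spectra must share the sample size")
    ne, ns = model.ne, sfs4d.ns
    alpha_vec = None if alpha is None else alpha.expand(ns // 2)
    u0 = _unit_folded_neutral(ne, ns)
    poly4 = dfe.f0 * u0.copy()
    for c in dfe.classes:
        if c.is_lethal or c.f == 0.0:
            continue
        poly4 = poly4 + c.f * _unit_folded_probs(ne, ns, c.gamma)
    poly4 = theta * poly4
    poly_si = theta * u0
    if alpha_vec is not None:
        poly4 = poly4 * alpha_vec
        poly_si = poly_si * alpha_vec
    ll4 = _multinomial_loglik(sfs4d.k0, sfs4d.counts, 1.0 - poly4.sum(), poly4)
    llsi = _multinomial_loglik(sfs_si.k0, sfs_si.counts, 1.0 - poly_si.sum(), poly_si)
    return ll4 + llsi


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------


def _unpack(x: np.ndarray, spec: ModelSpec):
    """Transformed coordinates -> (theta, [(gamma, f) per finite class], f_lethal)."""
    theta = float(np.exp(x[0]))
    i = 1
    remaining = 1.0
    sel = []
    for lo, hi in spec.sel_bounds:
        tlo, thi = np.log(lo), np.log(hi)
        gamma = -float(np.exp(tlo + (thi - tlo) * expit(x[i])))
        s = float(expit(x[i + 1]))
        f = remaining * s
        remaining -= f
        sel.append((gamma, f))
        i += 2
    f_lethal = 0.0
    if spec.n_lethal:
        s = float(expit(x[i]))
        f_lethal = remaining * s
    return theta, sel, f_lethal


def _pack(spec: ModelSpec, theta: float, sel, f_lethal: float = 0.0) -> np.ndarray:
    def _logit(p):
        return float(logit(np.clip(p, 1e-9, 1 - 1e-9)))

    x = [float(np.log(theta))]
    remaining = 1.0
    for (lo, hi), (gamma, f) in zip(spec.sel_bounds, sel):
        tlo, thi = np.log(lo), np.log(hi)
        t = (np.log(np.clip(-gamma, lo * (1 + 1e-9), hi * (1 - 1e-9))) - tlo) / (
            thi - tlo
        )
        x.append(_logit(t))
        s = f / remaining if remaining > 0 else 0.0
        x.append(_logit(s))
        remaining -= f
    if spec.n_lethal:
        s = f_lethal / remaining if remaining > 0 else 0.0
        x.append(_logit(s))
    return np.array(x)


def default_seed_grid(spec: ModelSpec, theta0: float) -> list:
    """Multi-start seeds spanning the weak and strong selection regimes."""

    def _clip_gamma(g, lo, hi):
        return -float(np.clip(-g, lo * 1.5, hi * 0.67))

    seeds = []
    if spec.name == "n":
        for t in (0.5, 1.0, 1.5):
            seeds.append((theta0 * t, [], 0.0))
    elif spec.name == "n+l":
        for fl in (0.02, 0.1, 0.3):
            seeds.append((theta0, [], fl))
    elif spec.name == "n+s":
        (lo, hi) = spec.sel_bounds[0]
        for g, f in itertools.product((-0.5, -8.0, -50.0, -300.0), (0.05, 0.2)):
            seeds.append((theta0, [(_clip_gamma(g, lo, hi), f)], 0.0))
    elif spec.name == "n+s+l":
        (lo, hi) = spec.sel_bounds[0]
        for g, fl in itertools.product((-3.0, -50.0), (0.02, 0.1)):
            seeds.append((theta0, [(_clip_gamma(g, lo, hi), 0.1)], fl))
    elif spec.name == "n+s+s":
        (lw, hw), (ls, hs) = spec.sel_bounds
        for gw, gs in itertools.product((-0.5, -3.0, -8.0), (-15.0, -50.0, -300.0)):
            seeds.append(
                (
                    theta0,
                    [(_clip_gamma(gw, lw, hw), 0.1), (_clip_gamma(gs, ls, hs), 0.1)],
                    0.0,
                )
            )
    else:
        raise DomainError(f"no default seeds for model {spec.name!r}")
    return seeds


# ---------------------------------------------------------------------------
# model fitting (stage 2)
# ---------------------------------------------------------------------------


def fit_model(
    spec: ModelSpec,
    sfs4d: FoldedSFS,
    sfs_si: FoldedSFS,
    alpha: AlphaCorrection | None,
    model: PopulationModel | None = None,
    seeds: list | None = None,
    fatol: float = 1e-6,
    xatol: float = 1e-8,
    maxiter: int | None = None,
    include_si: bool = True,
) -> FitResult:
    """Maximize the joint likelihood over theta and the model's selection
    parameters by derivative-free Nelder-Mead simplex from every seed.

    ``alpha`` is held fixed (two-stage fitting); pass ``include_si=False``
    to drop the SI term (reference already absorbed elsewhere).
    """
    if model is None:
        model = PopulationModel(ns=sfs4d.ns, theta=1e-3)
    ne, ns = model.ne, sfs4d.ns
    if sfs_si is not None and sfs_si.ns != ns:
        raise DomainError("4D and SI spectra must share the sample size")
    nf = ns // 2
    alpha_vec = None if alpha is None else alpha.expand(nf)
    u0 = _unit_folded_neutral(ne, ns)
    z, zz, Bf = _fold_kernel(ne, ns)
    k0_4, c4 = sfs4d.k0, sfs4d.counts.astype(float)
    if include_si:
        k0_s, cs = sfs_si.k0, sfs_si.counts.astype(float)
        u0_si = u0 if alpha_vec is None else u0 * alpha_vec
        usum_si = u0_si.sum()
        log_u0_si = np.where(u0_si > 0, np.log(u0_si), 0.0)
        csum_si = cs.sum()
        c_logu_si = float(cs @ log_u0_si)

    def neg_loglik(x):
        theta, sel, f_lethal = _unpack(x, spec)
        f0 = 1.0 - f_lethal - sum(f for _, f in sel)
        # the expected polymorphic spectrum is linear in the class weights,
        # so all finite selection classes collapse into one grid kernel
        shape = None
        for gamma, f in sel:
            if f > 0.0:
                s = f * _ratio(z, gamma)
                shape = s if shape is None else shape + s
        poly4 = f0 * u0 if shape is None else f0 * u0 + (shape * zz) @ Bf
        poly4 = theta * poly4
        if alpha_vec is not None:
            poly4 = poly4 * alpha_vec
        ll = _multinomial_loglik(k0_4, c4, 1.0 - poly4.sum(), poly4)
        if include_si:
            # SI term under neutrality: counts @ log(theta * u0) + k0 log(mono)
            mono_si = 1.0 - theta * usum_si
            if mono_si <= 0.0 and k0_s > 0:
                ll = -np.inf
            else:
                ll += csum_si * np.log(theta) + c_logu_si
                if k0_s > 0:
                    ll += k0_s * np.log(mono_si)
        return -ll if np.isfinite(ll) else 1e300

    if seeds is None:
        theta0 = (sfs_si.n_polymorphic / sfs_si.L / (u0.sum())) if include_si else 0.01
        theta0 = max(theta0, 1e-8)
        seeds = default_seed_grid(spec, theta0)

    optima = []
    best = None
    n_params = 1 + spec.free_params
    for seed in seeds:
        x0 = _pack(spec, *seed)
        res = minimize(
            neg_loglik,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": fatol,
                "xatol": xatol,
                "maxiter": maxiter or 400 * n_params,
                "maxfev": maxiter or 400 * n_params,
            },
        )
        theta, sel, f_lethal = _unpack(res.x, spec)
        optima.append(
            {
                "loglik": -float(res.fun),
                "theta": theta,
                "sel": sel,
                "f_lethal": f_lethal,
                "success": bool(res.success),
            }
        )
        if best is None or -res.fun > best[0]:
            best = (-float(res.fun), theta, sel, f_lethal, bool(res.success))

    if best is None or not np.isfinite(best[0]):
        raise DataError(f"no seed converged for model {spec.name}: {optima}")
    ll, theta, sel, f_lethal, success = best
    classes = [DFEClass(g, f) for g, f in sel]
    if spec.n_lethal:
        classes.append(DFEClass(LETHAL, f_lethal))
    return FitResult(
        model=spec,
        dfe=DFEModel(tuple(classes)),
        theta=theta,
        alpha=alpha,
        loglik=ll,
        converged=any(o["success"] for o in optima),
        optima=optima,
        seeds=list(seeds),
    )


# ---------------------------------------------------------------------------
# profile-likelihood fitting
# ---------------------------------------------------------------------------
#
# For fixed selection coefficients the expected polymorphic spectrum is
# linear in the scaled class weights b_j = theta * f_j, making the joint
# log-likelihood concave in b (and in theta, which enters the neutral SI
# term alone). fit_model_profile therefore runs the simplex only over the
# gamma coordinates and solves the inner weight problem with a small
# projected-Newton iteration — the same maximum as fit_model, found far
# faster and without ridge-trapping. Used for bootstrap refits and other
# bulk fitting.


def _inner_weights(vs, k0, counts, csum_si, k0_s, U, b_init, tol=1e-9, maxiter=80):
    """Maximize the concave inner objective over b >= 0 (no lethal slack).

    vs: (n_classes, nf) alpha-corrected unit spectra (row 0 = neutral);
    the 4D term uses q = b @ vs, the SI term theta = sum(b).
    Returns (b, loglik_without_constant_terms).
    """
    vs = np.asarray(vs)
    Vs = vs.sum(axis=1)
    b = np.maximum(np.asarray(b_init, dtype=float), 1e-12)

    def objective(b):
        q = b @ vs
        S = float(b @ Vs)
        theta = float(b.sum())
        if S >= 1.0 or theta * U >= 1.0 or np.any(q <= 0.0) or theta <= 0.0:
            return -np.inf
        val = k0 * np.log1p(-S) if k0 > 0 else 0.0
        pos = counts > 0
        val += float(counts[pos] @ np.log(q[pos]))
        val += csum_si * np.log(theta)
        if k0_s > 0:
            val += k0_s * np.log1p(-theta * U)
        return val

    # shrink towards feasibility if the start is invalid
    for _ in range(60):
        if np.isfinite(objective(b)):
            break
        b *= 0.5
    f_cur = objective(b)
    n = len(b)
    for _ in range(maxiter):
        q = b @ vs
        S = float(b @ Vs)
        theta = float(b.sum())
        mono4 = 1.0 - S
        mono_si = 1.0 - theta * U
        w = counts / q
        g = vs @ w - k0 * Vs / mono4 + csum_si / theta - k0_s * U / mono_si
        w2 = counts / q**2
        H = -(vs * w2) @ vs.T
        H -= np.outer(Vs, Vs) * (k0 / mono4**2)
        H -= csum_si / theta**2
        H -= k0_s * U**2 / mono_si**2
        free = (b > 1e-12) | (g > 0.0)
        if not free.any():
            break
        gf = g[free]
        Hf = H[np.ix_(free, free)]
        try:
            step = np.linalg.solve(Hf, -gf)
        except np.linalg.LinAlgError:
            step = gf / np.maximum(-np.diag(Hf), 1e-12)
        # Newton decrement ~ attainable log-likelihood gain
        if 0.5 * float(gf @ step) < tol:
            break
        def try_direction(delta):
            nonlocal b, f_cur
            alpha_step = 1.0
            neg = delta < 0
            if neg.any():
                with np.errstate(divide="ignore"):
                    cap = float(np.min(-b[neg] / delta[neg]))
                alpha_step = min(1.0, cap) if cap > 0 else 1.0
            for _ in range(50):
                cand = np.maximum(b + alpha_step * delta, 0.0)
                f_new = objective(cand)
                if f_new > f_cur:
                    b, f_cur = cand, f_new
                    return True
                alpha_step *= 0.5
            return False

        delta = np.zeros(n)
        delta[free] = step
        if not try_direction(delta):
            # Newton direction infeasible/unhelpful at the boundary:
            # fall back to a diagonally scaled gradient step
            delta = np.zeros(n)
            delta[free] = gf / np.maximum(-np.diag(Hf), 1e-30)
            if not try_direction(delta):
                break
    return b, f_cur


def fit_model_profile(
    spec: ModelSpec,
    sfs4d: FoldedSFS,
    sfs_si: FoldedSFS,
    alpha: AlphaCorrection | None,
    model: PopulationModel | None = None,
    gamma_seeds: list | None = None,
    fatol: float = 1e-8,
    xatol: float = 1e-6,
) -> FitResult:
    """Maximize the same joint likelihood as :func:`fit_model`, profiling
    out theta and the class fractions (concave given the gammas) so the
    simplex search runs only over the selection coefficients."""
    if model is None:
        model = PopulationModel(ns=sfs4d.ns, theta=1e-3)
    ne, ns = model.ne, sfs4d.ns
    nf = ns // 2
    alpha_vec = np.ones(nf) if alpha is None else alpha.expand(nf)
    u0 = _unit_folded_neutral(ne, ns)
    z, zz, Bf = _fold_kernel(ne, ns)
    v0 = u0 * alpha_vec
    U = float(v0.sum())
    k0_4, c4 = sfs4d.k0, sfs4d.counts.astype(float)
    k0_s, cs = sfs_si.k0, sfs_si.counts.astype(float)
    csum_si = float(cs.sum())
    log_v0 = np.where(v0 > 0, np.log(v0), 0.0)
    const_si = float(cs @ log_v0)  # counts @ log(alpha*u0), theta-free part
    n_sel = len(spec.sel_bounds)
    has_lethal = bool(spec.n_lethal)
    theta_si_hat = (csum_si / (csum_si + k0_s)) / U  # SI-only theta MLE

    b_guess = np.full(1 + n_sel, theta_si_hat / (1 + n_sel))

    def profiled(gammas):
        """(loglik, b, theta, f_lethal) at fixed selection coefficients."""
        if n_sel:
            rows = [v0]
            for g in gammas:
                rows.append(((_ratio(z, g) * zz) @ Bf) * alpha_vec)
            vs = np.vstack(rows)
        else:
            vs = v0[None, :]
        if has_lethal:
            # theta decouples from the 4D weights: closed-form SI theta,
            # lethal fraction takes the slack when theta >= sum(b)
            b, val4 = _inner_weights(vs, k0_4, c4, 0.0, 0, U, b_guess[: 1 + n_sel])
            theta = theta_si_hat
            if b.sum() <= theta:
                ll = val4 + csum_si * np.log(theta)
                if k0_s > 0:
                    ll += k0_s * np.log1p(-theta * U)
                return ll + const_si, b, theta, 1.0 - b.sum() / theta
        b, val = _inner_weights(vs, k0_4, c4, csum_si, k0_s, U, b_guess[: 1 + n_sel])
        theta = float(b.sum())
        return val + const_si, b, theta, 0.0

    if n_sel == 0:
        ll, b, theta, f_l = profiled(())
        classes = [DFEClass(LETHAL, f_l)] if has_lethal else []
        return FitResult(spec, DFEModel(tuple(classes)), theta, alpha, ll, True)

    bounds = spec.sel_bounds

    def unpack_g(x):
        out = []
        for xi, (lo, hi) in zip(x, bounds):
            tlo, thi = np.log(lo), np.log(hi)
            out.append(-float(np.exp(tlo + (thi - tlo) * expit(xi))))
        return tuple(out)

    def pack_g(gammas):
        out = []
        for g, (lo, hi) in zip(gammas, bounds):
            tlo, thi = np.log(lo), np.log(hi)
            t = (np.log(np.clip(-g, lo * (1 + 1e-9), hi * (1 - 1e-9))) - tlo) / (
                thi - tlo
            )
            out.append(float(logit(np.clip(t, 1e-9, 1 - 1e-9))))
        return np.array(out)

    def neg(x):
        ll = profiled(unpack_g(x))[0]
        return -ll if np.isfinite(ll) else 1e300

    if gamma_seeds is None:
        if n_sel == 1:
            (lo, hi) = bounds[0]
            grid = [-0.5, -3.0, -8.0, -50.0, -300.0]
            gamma_seeds = [
                (-float(np.clip(-g, lo * 1.5, hi * 0.67)),) for g in grid
            ]
            gamma_seeds = sorted(set(gamma_seeds))
        else:
            (lw, hw), (ls, hs) = bounds
            gamma_seeds = [
                (gw, gs)
                for gw in (-0.5, -3.0, -8.0)
                for gs in (-15.0, -50.0, -300.0)
            ]

    best = None
    optima = []
    for gseed in gamma_seeds:
        res = minimize(
            neg,
            pack_g(gseed),
            method="Nelder-Mead",
            options={"fatol": fatol, "xatol": xatol, "maxiter": 200 * n_sel + 200,
                     "maxfev": 200 * n_sel + 200},
        )
        optima.append({"loglik": -float(res.fun), "gammas": unpack_g(res.x),
                       "success": bool(res.success)})
        if best is None or -res.fun > best[0]:
            best = (-float(res.fun), res.x, bool(res.success))

    ll_best, x_best, success = best
    gammas = unpack_g(x_best)
    ll, b, theta, f_l = profiled(gammas)
    classes = [
        DFEClass(g, float(b[i + 1] / theta)) for i, g in enumerate(gammas)
    ]
    if has_lethal:
        classes.append(DFEClass(LETHAL, float(f_l)))
    return FitResult(
        model=spec,
        dfe=DFEModel(tuple(classes)),
        theta=theta,
        alpha=alpha,
        loglik=float(ll),
        converged=success,
        optima=optima,
        seeds=list(gamma_seeds),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def lrt(null: FitResult, alt: FitResult):
    """Chi-squared likelihood-ratio test of nested fits.

    Returns ``(statistic, df, p)`` with ``statistic = 2 * (ll_alt - ll_null)``
    and df the difference in free selection-parameter counts.
    """
    key = (null.model.name, alt.model.name)
    if key not in NESTED_DF:
        raise DomainError(f"models {key} are not nested")
    stat = 2.0 * (alt.loglik - null.loglik)
    df = NESTED_DF[key]
    p = float(chi2.sf(max(stat, 0.0), df))
    return stat, df, p


def select_best_model(fits: dict, threshold: float = 0.05):
    """Walk the nested chain n -> n+l -> n+s -> {n+s+l, n+s+s}, accepting a
    richer model whenever the LRT against the current best is significant.

    ``fits`` maps model name -> FitResult for all five models. Returns
    ``(best ModelSpec, report)`` where the report rows give, per model,
    the log-likelihood gain over the neutral model and the p-value against
    its chain predecessor.
    """
    missing = [m for m in MODEL_NAMES if m not in fits]
    if missing:
        raise DataError(f"fits missing for models {missing}")
    best = "n"
    report = []
    for name in MODEL_NAMES:
        row = {
            "model": name,
            "loglik": fits[name].loglik,
            "delta_ll": fits[name].loglik - fits["n"].loglik,
        }
        row.update(fits[name].params_dict())
        if name != "n":
            stat, df, p = lrt(fits[CHAIN_PREDECESSOR[name]], fits[name])
            row.update({"lrt_vs": CHAIN_PREDECESSOR[name], "lrt_df": df, "p": p})
            if (best, name) in NESTED_DF:
                _, _, p_vs_best = lrt(fits[best], fits[name])
                if p_vs_best < threshold:
                    best = name
        report.append(row)
    return fits[best].model, report


def rank_bootstrap_ci(values, ranks: tuple | None = None):
    """Confidence interval as order statistics of per-replicate estimates.

    With the default 200 matched replicates the interval is the (5th, 195th)
    rank pair; supply ``ranks=(lo, hi)`` (1-based) explicitly for other
    replicate counts.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if ranks is None:
        if n != 200:
            raise DataError(
                f"rank bootstrap expects 200 replicate values (got {n}); "
                "pass explicit ranks for other sizes"
            )
        ranks = (5, 195)
    lo, hi = ranks
    if not (1 <= lo <= hi <= n):
        raise DomainError(f"ranks {ranks} invalid for {n} values")
    return float(values[lo - 1]), float(values[hi - 1])
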