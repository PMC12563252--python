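"""EM-REML variance components, Henderson mixed-model equations and BLUP.

Model, for one trait of a multi-harvest randomized-complete-block trial
with one plant (plot) per genotype×block::

    y = X m + Z g + W p + T i + e

* ``m`` — fixed harvest×block combination effects (cell-means coding);
* ``g`` — random genotype effects,              g  ~ N(0, sigma2_g I);
* ``p`` — random permanent-plot effects,        p  ~ N(0, sigma2_perm I)
  (one level per genotype×block, shared by every harvest of that plant);
* ``i`` — random genotype×harvest interaction,  i  ~ N(0, sigma2_gm I);
* ``e`` — residual,                             e  ~ N(0, sigma2_e I).

Variance components are estimated by EM-REML: alternate a solve of the
Henderson equations (shrinkage ratios ``lambda_k = sigma2_e / sigma2_k``
on each random block) with the expectation-maximization updates

    sigma2_e = (y'y - sol'rhs) / (N - r(X))
    sigma2_k = (u_k'u_k + sigma2_e * tr(C^kk)) / n_k

where ``C^kk`` is the corresponding diagonal block of the inverse
coefficient matrix and ``n_k`` the number of levels of effect ``k``.

The coefficient matrix is solved by absorbing the (large, diagonal)
interaction block through its Schur complement, which keeps a fit of an
84-genotype × 4-block × 13-harvest trait to a few hundred dense solves
of order ~500.

The REML deviance (−2 × restricted log-likelihood) is computed from the
same factorization; differences between nested fits are the chi-square
statistics of the deviance analysis (ANADEV).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.stats import chi2

from .trial_data import TrialDataset

__all__ = [
    "ModelMatrices",
    "VarianceComponents",
    "BlupSolution",
    "FitResult",
    "DevianceTable",
    "build_design",
    "solve_mme",
    "em_reml_fit",
    "reml_deviance",
    "anadev",
    "lrt",
]

# chi-square(1) critical values printed in deviance tables
LRT_5PCT = 3.84
LRT_1PCT = 6.63

RANDOM_BLOCKS = ("g", "p", "i")


@dataclass(frozen=True)
class ModelMatrices:
    """Incidence matrices and observation vector for one trait.

    Level order is sorted label order throughout, so solutions and
    traces are reproducible across runs.
    """

    X: sp.csr_matrix
    Z: sp.csr_matrix
    W: sp.csr_matrix
    T: sp.csr_matrix
    y: np.ndarray
    fixed_levels: list[str]
    genotype_levels: list[str]
    plot_levels: list[tuple[str, str]]
    interaction_levels: list[tuple[str, str]]
    trait: str

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def rank_x(self) -> int:
        # cell-means coding: one column per observed harvest×block combination
        return self.X.shape[1]

    @property
    def mu(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variances for one trait (trait units squared)."""

    sigma2_g: float
    sigma2_perm: float
    sigma2_gm: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_perm", "sigma2_gm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_perm + self.sigma2_gm + self.sigma2_e

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {
            "g": self.sigma2_g / t,
            "perm": self.sigma2_perm / t,
            "gm": self.sigma2_gm / t,
            "e": self.sigma2_e / t,
        }

    def lambdas(self, floor: float) -> dict[str, float]:
        """Shrinkage ratios sigma2_e / sigma2_k, with components floored."""
        return {
            "g": self.sigma2_e / max(self.sigma2_g, floor),
            "p": self.sigma2_e / max(self.sigma2_perm, floor),
            "i": self.sigma2_e / max(self.sigma2_gm, floor),
        }


@dataclass(frozen=True)
class BlupSolution:
    """Solutions of the mixed-model equations for one trait."""

    m_hat: pd.Series  # fixed harvest×block combination effects
    g_hat: pd.Series  # genotype BLUPs
    p_hat: pd.Series  # permanent-plot BLUPs, index (genotype, block)
    i_hat: pd.Series  # genotype×harvest BLUPs, index (genotype, harvest)
    mu: float

    @property
    def u_plus_g(self) -> pd.Series:
        """Predicted genotypic value µ + g per genotype."""
        return (self.mu + self.g_hat).rename("u_plus_g")

    @property
    def u_plus_g_plus_gem(self) -> pd.Series:
        """Average genotypic value µ + g + mean interaction per genotype."""
        if len(self.i_hat):
            gem = self.i_hat.groupby(level=0).mean()
            gem = gem.reindex(self.g_hat.index, fill_value=0.0)
        else:
            gem = pd.Series(0.0, index=self.g_hat.index)
        return (self.mu + self.g_hat + gem).rename("u_plus_g_plus_gem")


@dataclass(frozen=True)
class FitResult:
    trait: str
    components: VarianceComponents
    blup: BlupSolution
    deviance: float
    lambdas: dict[str, float]
    traces: dict[str, float]
    n_iterations: int
    converged: bool
    degenerate: bool = False
    included: tuple[str, ...] = RANDOM_BLOCKS
    mm: ModelMatrices | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class DevianceTable:
    """Deviance analysis of the random effects of one trait.

    Rows: deviance of the full model and of each reduced model (one
    random term removed), the likelihood-ratio statistic per effect and
    its significance code at the chi-square(1) thresholds 3.84 (5%) and
    6.63 (1%).
    """

    trait: str
    deviance_full: float
    rows: pd.DataFrame  # index: effect; columns: deviance, lrt, p_value, code, reliable

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.attrs["deviance_full"] = self.deviance_full
        return out


def _indicator(labels: pd.Series, levels: list) -> sp.csr_matrix:
    codes = pd.Categorical(labels, categories=levels).codes
    n = len(labels)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes.astype(np.int64))), shape=(n, len(levels))
    )


def build_design(ds: TrialDataset, trait: str) -> ModelMatrices:
    """Assemble incidence matrices for one trait, rows in sorted
    (genotype, block, harvest) order and levels in sorted label order."""
    sub = ds.subset(trait)
    if sub["genotype"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: need at least 2 genotypes")
    if sub["harvest"].nunique() < 2:
        raise ValueError(
            f"trait {trait!r} observed in a single harvest; use a "
            "single-measurement model (not supported here)"
        )
    combo = list(zip(sub["harvest"], sub["block"]))
    fixed_levels = sorted(set(combo))
    genotype_levels = sorted(set(sub["genotype"]))
    plot = list(zip(sub["genotype"], sub["block"]))
    plot_levels = sorted(set(plot))
    inter = list(zip(sub["genotype"], sub["harvest"]))
    inter_levels = sorted(set(inter))
    return ModelMatrices(
        X=_indicator(pd.Series(combo), fixed_levels),
        Z=_indicator(sub["genotype"], genotype_levels),
        W=_indicator(pd.Series(plot), plot_levels),
        T=_indicator(pd.Series(inter), inter_levels),
        y=sub["value"].to_numpy(dtype=float),
        fixed_levels=[f"{h}:{b}" for h, b in fixed_levels],
        genotype_levels=genotype_levels,
        plot_levels=plot_levels,
        interaction_levels=inter_levels,
        trait=trait,
    )


class _HendersonSystem:
    """Precomputed cross-products of one design; solves the mixed-model
    equations for arbitrary shrinkage ratios.

    The interaction block (diagonal own-block, typically the largest) is
    absorbed via its Schur complement when present and large; the
    remaining system is solved densely by Cholesky.  Returns solutions,
    traces of the inverse-coefficient-matrix diagonal blocks, the
    log-determinant of the coefficient matrix and the residual quadratic
    form y'y − sol'rhs.
    """

    ABSORB_MIN = 50

    def __init__(self, mm: ModelMatrices, include: tuple[str, ...] = RANDOM_BLOCKS):
        self.mm = mm
        self.include = tuple(k for k in RANDOM_BLOCKS if k in include)
        blocks = {"g": mm.Z, "p": mm.W, "i": mm.T}
        self.absorb = "i" if ("i" in self.include and mm.T.shape[1] >= self.ABSORB_MIN) else None
        self.front_random = [k for k in self.include if k != self.absorb]
        mats = [mm.X] + [blocks[k] for k in self.front_random]
        A = sp.hstack(mats, format="csr")
        y = mm.y
        self.n_fixed = mm.X.shape[1]
        self.sizes = {k: blocks[k].shape[1] for k in self.include}
        # index ranges of the front (non-absorbed) random blocks
        self.ranges: dict[str, slice] = {}
        off = self.n_fixed
        for k in self.front_random:
            self.ranges[k] = slice(off, off + self.sizes[k])
            off += self.sizes[k]
        self.n_front = off
        self.C_FF0 = (A.T @ A).toarray()
        self.rhs_F = np.asarray(A.T @ y).ravel()
        self.yty = float(y @ y)
        if self.absorb:
            Ta = blocks[self.absorb]
            self.d0 = np.asarray(Ta.multiply(Ta).sum(axis=0)).ravel()  # diag counts
            C_Fa = (A.T @ Ta).tocsr()
            # small couplings go dense: cuts per-iteration overhead a lot
            self.dense_coupling = C_Fa.shape[0] * C_Fa.shape[1] <= 500_000
            self.C_Fa = C_Fa.toarray() if self.dense_coupling else C_Fa
            self.rhs_a = np.asarray(Ta.T @ y).ravel()

    def solve(self, lambdas: dict[str, float]) -> dict:
        S = self.C_FF0.copy()
        for k in self.front_random:
            r = self.ranges[k]
            S[np.arange(r.start, r.stop), np.arange(r.start, r.stop)] += lambdas[k]
        rhs = self.rhs_F.copy()
        logdet_absorbed = 0.0
        if self.absorb:
            d = self.d0 + lambdas[self.absorb]
            if self.dense_coupling:
                Cfa_dinv = self.C_Fa / d  # C_Fa * diag(1/d)
                S -= Cfa_dinv @ self.C_Fa.T
            else:
                Cfa_dinv = self.C_Fa.multiply(1.0 / d)
                S -= (Cfa_dinv @ self.C_Fa.T).toarray()
            rhs = rhs - Cfa_dinv @ self.rhs_a
            logdet_absorbed = float(np.log(d).sum())
        try:
            cF, low = sla.cho_factor(S, lower=True, check_finite=False)
        except sla.LinAlgError as exc:  # pragma: no cover - degenerate designs
            raise np.linalg.LinAlgError(
                f"singular mixed-model equations for trait {self.mm.trait!r} "
                "(confounded fixed levels?)"
            ) from exc
        sol_F = sla.cho_solve((cF, low), rhs, check_finite=False)
        logdet = 2.0 * float(np.log(np.diag(cF)).sum()) + logdet_absorbed
        # inverse of the front system via LAPACK dpotri (lower triangle)
        inv_half, info = sla.lapack.dpotri(cF, lower=True)
        if info != 0:  # pragma: no cover
            raise np.linalg.LinAlgError("dpotri failed")
        S_inv_diag_full = np.diag(inv_half)  # diag is correct from either triangle
        traces = {k: float(S_inv_diag_full[self.ranges[k]].sum()) for k in self.front_random}
        sols: dict[str, np.ndarray] = {"fixed": sol_F[: self.n_fixed]}
        for k in self.front_random:
            sols[k] = sol_F[self.ranges[k]]
        resid_qform = self.yty - float(sol_F @ self.rhs_F)
        if self.absorb:
            sol_a = (self.rhs_a - self.C_Fa.T @ sol_F) / d
            sols[self.absorb] = sol_a
            resid_qform -= float(sol_a @ self.rhs_a)
            # tr of the absorbed block of C^{-1}:
            #   diag = 1/d + rows of (D^{-1} C_aF) S^{-1} (D^{-1} C_aF)'
            S_inv = np.tril(inv_half) + np.tril(inv_half, -1).T
            if self.dense_coupling:
                M = Cfa_dinv.T  # n_a × n_front, rows m_t = C_aF_t / d_t
                traces[self.absorb] = float((1.0 / d).sum() + (M * (M @ S_inv)).sum())
            else:
                M = Cfa_dinv.T.tocsr()
                traces[self.absorb] = float((1.0 / d).sum() + M.multiply(M @ S_inv).sum())
        return {
            "solutions": sols,
            "traces": traces,
            "logdet_C": logdet,
            "resid_qform": resid_qform,
        }


def _deviance_from_solve(
    res: dict, vc_map: dict[str, float], sizes: dict[str, int], n: int, rank_x: int, sigma2_e: float
) -> float:
    """−2 × restricted log-likelihood from one Henderson solve.

    Uses the identity  ln|V| + ln|X'V⁻¹X| = (N − p) ln σ²e + ln|C_λ| − Σ n_k ln λ_k
    with C_λ the shrinkage-form coefficient matrix, plus
    y'Py = (y'y − sol'rhs)/σ²e.
    """
    log_lambda_sum = sum(
        sizes[k] * math.log(sigma2_e / vc_map[k]) for k in sizes
    )
    n_eff = n - rank_x
    return (
        n_eff * math.log(2.0 * math.pi * sigma2_e)
        + res["logdet_C"]
        - log_lambda_sum
        + res["resid_qform"] / sigma2_e
    )


def _vc_map(vc: VarianceComponents) -> dict[str, float]:
    return {"g": vc.sigma2_g, "p": vc.sigma2_perm, "i": vc.sigma2_gm}


def _blup_from_solutions(mm: ModelMatrices, sols: dict[str, np.ndarray]) -> BlupSolution:
    zeros = lambda idx: np.zeros(len(idx))
    g = sols.get("g", zeros(mm.genotype_levels))
    p = sols.get("p", zeros(mm.plot_levels))
    i = sols.get("i", zeros(mm.interaction_levels))
    return BlupSolution(
        m_hat=pd.Series(sols["fixed"], index=pd.Index(mm.fixed_levels, name="harvest:block")),
        g_hat=pd.Series(g, index=pd.Index(mm.genotype_levels, name="genotype")),
        p_hat=pd.Series(
            p, index=pd.MultiIndex.from_tuples(mm.plot_levels, names=["genotype", "block"])
        )
        if len(mm.plot_levels)
        else pd.Series(dtype=float),
        i_hat=pd.Series(
            i, index=pd.MultiIndex.from_tuples(mm.interaction_levels, names=["genotype", "harvest"])
        )
        if len(mm.interaction_levels)
        else pd.Series(dtype=float),
        mu=mm.mu,
    )


def solve_mme(mm: ModelMatrices, vc: VarianceComponents, floor: float | None = None) -> BlupSolution:
    """Solve the Henderson mixed-model equations at fixed variance
    components and return all effect estimates."""
    if floor is None:
        floor = 1e-10 * max(vc.total, 1.0)
    sys_ = _HendersonSystem(mm)
    res = sys_.solve(vc.lambdas(floor))
    return _blup_from_solutions(mm, res["solutions"])


def reml_deviance(
    mm: ModelMatrices,
    vc: VarianceComponents,
    include: tuple[str, ...] = RANDOM_BLOCKS,
    floor: float | None = None,
) -> float:
    """−2 × restricted log-likelihood of the model at ``vc``, profiled
    over the fixed effects.  Differences between nested models are the
    ANADEV chi-square statistics."""
    if floor is None:
        floor = 1e-10 * max(vc.total, 1.0)
    sys_ = _HendersonSystem(mm, include=include)
    res = sys_.solve(vc.lambdas(floor))
    vcm = {k: max(v, floor) for k, v in _vc_map(vc).items() if k in include}
    return _deviance_from_solve(res, vcm, sys_.sizes, mm.n_obs, mm.rank_x, vc.sigma2_e)


def _em_fit(
    mm: ModelMatrices,
    include: tuple[str, ...],
    tol: float,
    max_iter: int,
    floor_frac: float = 1e-10,
) -> FitResult:
    y = mm.y
    var_y = float(np.var(y, ddof=1)) if mm.n_obs > 1 else 0.0
    degenerate = var_y <= 0.0
    floor = max(floor_frac * var_y, 1e-12)
    include = tuple(k for k in RANDOM_BLOCKS if k in include)
    sys_ = _HendersonSystem(mm, include=include)
    n_comp = len(include) + 1
    start = max(var_y, floor) / n_comp
    vcm = {k: start for k in include}
    sigma2_e = start
    divisors = {"g": sys_.sizes.get("g"), "p": sys_.sizes.get("p"), "i": sys_.sizes.get("i")}
    n_eff = mm.n_obs - mm.rank_x
    if n_eff <= 0:
        raise ValueError("no residual degrees of freedom (N <= rank of fixed effects)")
    converged = False
    it = 0
    res = None
    for it in range(1, max_iter + 1):
        lambdas = {k: sigma2_e / max(vcm[k], floor) for k in include}
        res = sys_.solve(lambdas)
        new_e = max(res["resid_qform"] / n_eff, floor)
        new_vcm = {}
        for k in include:
            u = res["solutions"][k]
            new_vcm[k] = max((float(u @ u) + sigma2_e * res["traces"][k]) / divisors[k], floor)
        rel = abs(new_e - sigma2_e) / max(sigma2_e, floor)
        for k in include:
            rel = max(rel, abs(new_vcm[k] - vcm[k]) / max(vcm[k], floor))
        vcm, sigma2_e = new_vcm, new_e
        if rel < tol:
            converged = True
            break
    # final solve at the converged components
    lambdas = {k: sigma2_e / max(vcm[k], floor) for k in include}
    res = sys_.solve(lambdas)
    vc = VarianceComponents(
        sigma2_g=vcm.get("g", 0.0),
        sigma2_perm=vcm.get("p", 0.0),
        sigma2_gm=vcm.get("i", 0.0),
        sigma2_e=sigma2_e,
    )
    deviance = _deviance_from_solve(
        res, {k: max(vcm[k], floor) for k in include}, sys_.sizes, mm.n_obs, mm.rank_x, sigma2_e
    )
    return FitResult(
        trait=mm.trait,
        components=vc,
        blup=_blup_from_solutions(mm, res["solutions"]),
        deviance=float(deviance),
        lambdas=lambdas,
        traces={f"tr_C_{k}": res["traces"][k] for k in include},
        n_iterations=it,
        converged=converged or degenerate,
        degenerate=degenerate,
        included=include,
        mm=mm,
    )


def em_reml_fit(
    ds: TrialDataset,
    trait: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """Fit the full genotype + plot + genotype×harvest model for one
    trait by EM-REML.

    Iterates Henderson solves and EM variance updates until the maximum
    relative change of any component falls below ``tol``; components are
    clamped at a small positive floor so the shrinkage ratios stay
    finite.  Non-convergence is reported through ``converged=False``,
    never an exception.
    """
    mm = build_design(ds, trait)
    return _em_fit(mm, RANDOM_BLOCKS, tol=tol, max_iter=max_iter)


def lrt(dev_reduced: float, dev_full: float) -> tuple[float, float, str]:
    """Likelihood-ratio statistic, chi-square(1) p-value and the
    significance code used in deviance tables (``**`` at 1%, ``*`` at
    5%, ``ns`` otherwise; thresholds 6.63 and 3.84, inclusive)."""
    stat = dev_reduced - dev_full
    if stat < -1e-4:
        warnings.warn(
            f"negative LRT statistic {stat:.6g}: reduced fit beat the full fit "
            "(numerical non-convergence)",
            RuntimeWarning,
            stacklevel=2,
        )
    p = float(chi2.sf(max(stat, 0.0), df=1))
    eps = 1e-9  # boundary-inclusive despite float subtraction error
    if stat >= LRT_1PCT - eps:
        code = "**"
    elif stat >= LRT_5PCT - eps:
        code = "*"
    else:
        code = "ns"
    return float(stat), p, code


#: ANADEV row label → random block removed ("Environment" is the
#: permanent-plot term, the model's non-interaction environmental term).
ANADEV_ROWS = {
    "Genotype": "g",
    "Environment": "p",
    "Interaction GxM": "i",
}


def anadev(
    ds: TrialDataset,
    trait: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
    full_fit: FitResult | None = None,
) -> DevianceTable:
    """Deviance analysis: refit with each random term removed and test
    each effect by a chi-square(1) likelihood-ratio test."""
    if full_fit is None:
        full_fit = em_reml_fit(ds, trait, tol=tol, max_iter=max_iter)
    mm = full_fit.mm if full_fit.mm is not None else build_design(ds, trait)
    rows = {}
    for label, drop in ANADEV_ROWS.items():
        include = tuple(k for k in RANDOM_BLOCKS if k != drop)
        red = _em_fit(mm, include, tol=tol, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p, code = lrt(red.deviance, full_fit.deviance)
        rows[label] = {
            "deviance": red.deviance,
            "lrt": stat,
            "p_value": p,
            "code": code,
            "reliable": bool(red.converged and stat > -1e-4),
        }
    return DevianceTable(
        trait=trait,
        deviance_full=full_fit.deviance,
        rows=pd.DataFrame.from_dict(rows, orient="index"),
    )
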