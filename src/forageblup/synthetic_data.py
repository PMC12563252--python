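"""Synthetic multi-harvest forage trials with known ground truth.

Generates phenotype tables with exactly the random-effects structure the
analysis model assumes,

    y_ijk = mu + m_(harvest,block) + g_i + p_(i,block) + gm_(i,harvest) + e_ijk,

all effects Gaussian, genotype effects optionally correlated across
traits.  Ordinal score traits (growth habit 1-4, cold tolerance 1-5) are
produced by rounding a latent continuous trait onto their bounds, and
binary survival by thresholding a latent trait at a target survival
rate.

The default panel emulates a perennial-forage evaluation: 84 genotypes,
4 blocks, 13 harvests and 12 traits whose means, coefficients of
variation and variance-fraction decompositions are typical of
multi-harvest trials of a wild forage grass (tiller counts dominated by
genotype×harvest interaction, visual scores with a strong genotypic
share, survival almost entirely environmental).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_data import TraitSpec, TrialDataset, HIGHER, LOWER
from .reml_core import VarianceComponents, em_reml_fit

__all__ = [
    "TraitSimSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "default_panel",
    "default_config",
    "simulate_trial",
    "recovery_experiment",
]

FRACTION_KEYS = ("g", "perm", "gm", "e")


@dataclass(frozen=True)
class TraitSimSpec:
    """Simulation settings for one trait.

    ``mu`` is the trait mean in trait units (for binary traits, the
    survival rate in (0, 1)); ``sigma2_f`` the total phenotypic variance
    of the underlying continuous/latent trait; ``fractions`` the shares
    of genotypic, permanent-plot, genotype×harvest and residual variance
    (keys ``g, perm, gm, e``, summing to 1).
    """

    name: str
    mu: float
    sigma2_f: float
    fractions: dict[str, float]
    direction: str = HIGHER
    scale: str = "continuous"
    ordinal_bounds: tuple[int, int] | None = None
    include_in_ideotype: bool = True

    def __post_init__(self) -> None:
        fr = self.fractions
        if set(fr) != set(FRACTION_KEYS):
            raise ValueError(f"fractions must have keys {FRACTION_KEYS}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-12:
            raise ValueError(f"variance fractions must sum to 1, got {sum(fr.values())!r}")
        if self.sigma2_f <= 0:
            raise ValueError("sigma2_f must be positive")
        if self.scale == "binary" and not 0.0 < self.mu < 1.0:
            raise ValueError("binary traits interpret mu as a survival rate in (0, 1)")

    @property
    def trait_spec(self) -> TraitSpec:
        return TraitSpec(
            name=self.name,
            direction=self.direction,
            scale=self.scale,
            ordinal_bounds=self.ordinal_bounds,
            include_in_ideotype=self.include_in_ideotype,
        )

    @property
    def true_components(self) -> VarianceComponents:
        f, s = self.fractions, self.sigma2_f
        return VarianceComponents(
            sigma2_g=f["g"] * s,
            sigma2_perm=f["perm"] * s,
            sigma2_gm=f["gm"] * s,
            sigma2_e=max(f["e"] * s, 1e-300),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full design + trait panel for one simulated trial.

    ``genetic_corr`` is the genotype-effect correlation matrix across
    traits (unit diagonal, positive semi-definite), aligned to the order
    of ``traits``; ``fixed_effect_rel_sd`` scales the fixed
    harvest×block effects as a fraction of each trait's phenotypic
    standard deviation; rows are dropped independently at
    ``missing_rate``.
    """

    q: int = 84
    b: int = 4
    m: int = 13
    traits: tuple[TraitSimSpec, ...] = ()
    genetic_corr: np.ndarray | None = None
    fixed_effect_rel_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.q, self.b, self.m) < 1:
            raise ValueError("q, b, m must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.traits:
            raise ValueError("at least one trait required")
        if self.genetic_corr is not None:
            C = np.asarray(self.genetic_corr, dtype=float)
            k = len(self.traits)
            if C.shape != (k, k):
                raise ValueError(f"genetic_corr must be {k}x{k}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("genetic_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError("genetic_corr must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("genetic_corr must be positive semi-definite")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one simulated trial: true variance components
    and the realized effect vectors, keyed the way the fit reports them."""

    components: dict[str, VarianceComponents]
    g: pd.DataFrame  # genotype × trait realized genotype effects
    p: dict[str, pd.Series]  # trait → plot effects, index (genotype, block)
    gm: dict[str, pd.Series]  # trait → interaction effects, index (genotype, harvest)
    fixed: dict[str, pd.Series]  # trait → harvest×block effects
    seed: int


def _fractions(g: float, perm: float, gm: float, e: float) -> dict[str, float]:
    fr = {"g": g, "perm": perm, "gm": gm, "e": e}
    s = sum(fr.values())
    return {k: v / s for k, v in fr.items()}


def _spec(name, mu, cv_e_pct, f, **kw) -> TraitSimSpec:
    # total phenotypic variance back-derived from the residual CV:
    # sigma_e = cv_e * mu / 100, sigma2_f = sigma2_e / f_e
    base = abs(mu) if kw.get("scale") != "binary" else 0.33
    sigma2_e = (cv_e_pct * base / 100.0) ** 2
    return TraitSimSpec(name=name, mu=mu, sigma2_f=sigma2_e / f["e"], fractions=f, **kw)


def default_panel() -> tuple[TraitSimSpec, ...]:
    """Twelve-trait panel of a multi-harvest forage grass trial.

    Means, residual CVs and variance decompositions follow the typical
    pattern of such trials: biomass traits with large genotype×harvest
    interaction, visual scores (GH, CT) with sizeable genotypic and
    permanent-plot shares, and survival (FP) mostly environmental.
    """
    return (
        _spec("NT", 207.96, 11.73, _fractions(0.1553, 0.0032, 0.7718, 0.0697)),
        _spec("FM", 155.18, 21.71, _fractions(0.0965, 0.0128, 0.6711, 0.2196)),
        _spec("LDM", 62.32, 39.43, _fractions(0.0421, 0.0470, 0.4412, 0.4697)),
        _spec("SDM", 6.55, 49.13, _fractions(0.0310, 0.0100, 0.4663, 0.4927), direction=LOWER),
        _spec("IDM", 3.86, 51.45, _fractions(0.0370, 0.0030, 0.4995, 0.4605), direction=LOWER),
        _spec("TDM", 75.89, 28.73, _fractions(0.0742, 0.0200, 0.5473, 0.3585)),
        _spec("LSR", 2.93, 32.80, _fractions(0.0600, 0.0083, 0.6019, 0.3298)),
        _spec("HI", 0.82, 15.65, _fractions(0.0024, 0.1517, 0.2621, 0.5838), include_in_ideotype=False),
        _spec("CT", 3.03, 23.32, _fractions(0.1004, 0.1552, 0.1984, 0.5460), scale="ordinal", ordinal_bounds=(1, 5)),
        _spec("FP", 0.86, 34.02, _fractions(0.0037, 0.1454, 0.0601, 0.7908), scale="binary", include_in_ideotype=False),
        _spec("GH", 2.87, 15.76, _fractions(0.4538, 0.1492, 0.0969, 0.3001), scale="ordinal", ordinal_bounds=(1, 4)),
        _spec("PH", 57.02, 13.32, _fractions(0.0400, 0.1408, 0.2201, 0.5991)),
    )


def default_genetic_corr(traits: tuple[TraitSimSpec, ...]) -> np.ndarray:
    """Block correlation structure: biomass traits mutually correlated,
    morphology scores weakly correlated, the rest independent."""
    groups = {
        "biomass": ({"NT", "FM", "LDM", "SDM", "TDM", "IDM", "PH"}, 0.6),
        "scores": ({"CT", "GH", "FP"}, 0.3),
        "quality": ({"LSR", "HI"}, 0.4),
    }
    names = [t.name for t in traits]
    C = np.eye(len(names))
    for members, r in groups.values():
        idx = [i for i, n in enumerate(names) if n in members]
        for a, b in itertools.combinations(idx, 2):
            C[a, b] = C[b, a] = r
    return C


def default_config(q: int = 84, b: int = 4, m: int = 13, seed: int = 0, **kw) -> SimulationConfig:
    traits = kw.pop("traits", default_panel())
    corr = kw.pop("genetic_corr", default_genetic_corr(traits))
    return SimulationConfig(q=q, b=b, m=m, traits=traits, genetic_corr=corr, seed=seed, **kw)


def _observe(spec: TraitSimSpec, latent: np.ndarray) -> np.ndarray:
    if spec.scale == "continuous":
        return latent
    if spec.scale == "ordinal":
        lo, hi = spec.ordinal_bounds
        return np.clip(np.rint(latent), lo, hi)
    # binary: latent was centred at sigma_f * Phi^{-1}(rate); alive if > 0
    return (latent > 0.0).astype(float)


def simulate_trial(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[TrialDataset, SyntheticTruth]:
    """Draw one trial.  Same config + seed → bit-identical dataset.

    Every random effect has its own substream spawned deterministically
    from the master seed, so adding traits or changing the missingness
    rate does not scramble the realized genotype effects.
    """
    master = seed if seed is not None else cfg.seed
    q, b, m = cfg.q, cfg.b, cfg.m
    n_traits = len(cfg.traits)
    ss = np.random.SeedSequence(master)
    s_g, s_p, s_gm, s_e, s_fx, s_miss = ss.spawn(6)
    rng_g = np.random.default_rng(s_g)

    genotypes = [f"G{i + 1:03d}" for i in range(q)]
    blocks = [f"B{j + 1}" for j in range(b)]
    harvests = [f"H{k + 1:02d}" for k in range(m)]

    # genotype effects, correlated across traits
    corr = np.eye(n_traits) if cfg.genetic_corr is None else np.asarray(cfg.genetic_corr, float)
    evals, evecs = np.linalg.eigh(corr)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    g_std = rng_g.standard_normal((q, n_traits)) @ L.T
    sig_g = np.array([np.sqrt(t.fractions["g"] * t.sigma2_f) for t in cfg.traits])
    g_all = g_std * sig_g  # q × traits

    rng_p = np.random.default_rng(s_p)
    rng_gm = np.random.default_rng(s_gm)
    rng_e = np.random.default_rng(s_e)
    rng_fx = np.random.default_rng(s_fx)
    rng_miss = np.random.default_rng(s_miss)

    frames = []
    comp: dict[str, VarianceComponents] = {}
    p_truth: dict[str, pd.Series] = {}
    gm_truth: dict[str, pd.Series] = {}
    fx_truth: dict[str, pd.Series] = {}
    gi, bi, hi = np.meshgrid(np.arange(q), np.arange(b), np.arange(m), indexing="ij")
    gi, bi, hi = gi.ravel(), bi.ravel(), hi.ravel()
    for t_idx, spec in enumerate(cfg.traits):
        sf = np.sqrt(spec.sigma2_f)
        sig_p = np.sqrt(spec.fractions["perm"] * spec.sigma2_f)
        sig_gm = np.sqrt(spec.fractions["gm"] * spec.sigma2_f)
        sig_e = np.sqrt(spec.fractions["e"] * spec.sigma2_f)
        p_eff = rng_p.standard_normal((q, b)) * sig_p
        gm_eff = rng_gm.standard_normal((q, m)) * sig_gm
        fx_eff = rng_fx.standard_normal((m, b)) * (cfg.fixed_effect_rel_sd * sf)
        e_eff = rng_e.standard_normal(q * b * m) * sig_e
        centre = spec.mu if spec.scale != "binary" else sf * norm.ppf(spec.mu)
        latent = (
            centre
            + fx_eff[hi, bi]
            + g_all[gi, t_idx]
            + p_eff[gi, bi]
            + gm_eff[gi, hi]
            + e_eff
        )
        values = _observe(spec, latent)
        keep = rng_miss.random(q * b * m) >= cfg.missing_rate
        frames.append(
            pd.DataFrame(
                {
                    "genotype": np.asarray(genotypes)[gi[keep]],
                    "block": np.asarray(blocks)[bi[keep]],
                    "harvest": np.asarray(harvests)[hi[keep]],
                    "trait": spec.name,
                    "value": values[keep],
                }
            )
        )
        comp[spec.name] = spec.true_components
        p_truth[spec.name] = pd.Series(
            p_eff.ravel(),
            index=pd.MultiIndex.from_product([genotypes, blocks], names=["genotype", "block"]),
        )
        gm_truth[spec.name] = pd.Series(
            gm_eff.ravel(),
            index=pd.MultiIndex.from_product([genotypes, harvests], names=["genotype", "harvest"]),
        )
        fx_truth[spec.name] = pd.Series(
            fx_eff.ravel(),
            index=pd.MultiIndex.from_product([harvests, blocks], names=["harvest", "block"]),
        )
    data = pd.concat(frames, ignore_index=True)
    ds = TrialDataset(data=data, traits={t.name: t.trait_spec for t in cfg.traits})
    truth = SyntheticTruth(
        components=comp,
        g=pd.DataFrame(g_all, index=pd.Index(genotypes, name="genotype"), columns=cfg.trait_names),
        p=p_truth,
        gm=gm_truth,
        fixed=fx_truth,
        seed=master,
    )
    return ds, truth


def recovery_experiment(
    cfg: SimulationConfig,
    n_reps: int,
    seed: int,
    traits: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> pd.DataFrame:
    """Simulate → fit → compare, ``n_reps`` times.

    Returns one row per (trait, component) with the true variance
    fraction, the mean estimated fraction across replicates, bias and
    RMSE, plus the number of replicates whose EM fit converged.
    Non-convergent fits contribute their final components and are
    counted, never dropped silently.
    """
    traits = traits if traits is not None else list(cfg.trait_names)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    records: dict[tuple[str, str], list[float]] = {}
    conv: dict[str, int] = {t: 0 for t in traits}
    for rep in range(n_reps):
        ds, truth = simulate_trial(cfg, seed=int(seeds[rep]))
        for trait in traits:
            fit = em_reml_fit(ds, trait, tol=tol, max_iter=max_iter)
            conv[trait] += int(fit.converged)
            for key, est in fit.components.fractions.items():
                records.setdefault((trait, key), []).append(est)
    rows = []
    by_name = {t.name: t for t in cfg.traits}
    for (trait, key), ests in sorted(records.items()):
        truth_frac = by_name[trait].fractions[{"g": "g", "perm": "perm", "gm": "gm", "e": "e"}[key]]
        ests_arr = np.asarray(ests)
        rows.append(
            {
                "trait": trait,
                "component": key,
                "true_fraction": truth_frac,
                "mean_estimate": float(ests_arr.mean()),
                "bias": float(ests_arr.mean() - truth_frac),
                "rmse": float(np.sqrt(((ests_arr - truth_frac) ** 2).mean())),
                "n_reps": n_reps,
                "n_converged": conv[trait],
            }
        )
    return pd.DataFrame(rows)
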