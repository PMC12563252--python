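"""BLUP-based genotype ranking, selection gains and harmonic-mean
stability/adaptability indices.

Per-harvest genotypic values form a genotype × environment matrix
(environments = harvests)

    Vg_ij = env_mean_j + g_i + i_ij

from which the classical indices are computed:

* MHVG_i    — harmonic mean of the Vg row: productivity penalized by
  instability, in trait units;
* PRVG_i    — mean of the Vg entries expressed relative to each
  environment's mean: adaptability, dimensionless;
* MHPRVG_i  — harmonic mean of those relative values: productivity,
  stability and adaptability jointly;
* PRVG×µ and MHPRVG×µ put the relative indices back on the trait scale.

Selection gain at rank k is SG% = 100·(GS_k − µ)/µ with GS_k the mean
predicted genotypic value of the genotypes ranked 1..k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml_core import FitResult
from .trial_data import TraitSpec, TrialDataset, HIGHER

__all__ = [
    "GenotypeRanking",
    "StabilityIndices",
    "per_environment_values",
    "stability_indices",
    "rank_and_gains",
]


@dataclass(frozen=True)
class GenotypeRanking:
    trait: str
    table: pd.DataFrame  # rank-ordered: genotype, u_plus_g_plus_gem, g_hat, sg_percent
    mu: float
    gain_basis: str
    selected: list[str]
    ties: bool = False


@dataclass(frozen=True)
class StabilityIndices:
    trait: str
    table: pd.DataFrame  # per genotype: MHVG, PRVG, PRVG_x_mu, MHPRVG, MHPRVG_x_mu
    n_env: int
    mu: float


def per_environment_values(fit: FitResult, ds: TrialDataset, trait: str) -> pd.DataFrame:
    """Genotype × harvest matrix of predicted genotypic values.

    The environment mean of harvest j is the average of the fitted
    harvest×block effects of that harvest; cells with no observed
    genotype×harvest combination take interaction BLUP 0.
    """
    blup = fit.blup
    m_hat = blup.m_hat
    env = {}
    for label, val in m_hat.items():
        h, _ = label.rsplit(":", 1)
        env.setdefault(h, []).append(val)
    env_mean = pd.Series({h: float(np.mean(v)) for h, v in env.items()}).sort_index()
    genotypes = blup.g_hat.index
    i_wide = (
        blup.i_hat.unstack("harvest")
        if len(blup.i_hat)
        else pd.DataFrame(index=genotypes, columns=env_mean.index, dtype=float)
    )
    i_wide = i_wide.reindex(index=genotypes, columns=env_mean.index).fillna(0.0)
    vg = i_wide.add(blup.g_hat, axis=0).add(env_mean, axis=1)
    vg.index.name = "genotype"
    vg.columns.name = "harvest"
    return vg


def stability_indices(vg: pd.DataFrame, mu: float) -> StabilityIndices:
    """MHVG, PRVG, MHPRVG (and ×µ variants) from a Vg matrix.

    Harmonic means require strictly positive genotypic values; a
    nonpositive entry names its genotype and environment — such a trait
    is unsuited to harmonic-mean indices on its raw scale.
    """
    arr = vg.to_numpy(dtype=float)
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"nonpositive genotypic value for genotype {vg.index[i]!r} in "
            f"environment {vg.columns[j]!r}: harmonic-mean indices undefined"
        )
    n_env = arr.shape[1]
    mhvg = n_env / (1.0 / arr).sum(axis=1)
    rel = arr / arr.mean(axis=0, keepdims=True)  # value / environment mean
    prvg = rel.mean(axis=1)
    mhprvg = n_env / (1.0 / rel).sum(axis=1)
    table = pd.DataFrame(
        {
            "MHVG": mhvg,
            "PRVG": prvg,
            "PRVG_x_mu": prvg * mu,
            "MHPRVG": mhprvg,
            "MHPRVG_x_mu": mhprvg * mu,
        },
        index=vg.index,
    )
    return StabilityIndices(trait=str(vg.columns.name or ""), table=table, n_env=n_env, mu=mu)


def rank_and_gains(
    fit: FitResult,
    trait_spec: TraitSpec,
    mu: float | None = None,
    selected_n: int | None = None,
    gain_basis: str = "g",
) -> GenotypeRanking:
    """Rank genotypes on u+g+gem and attach cumulative selection gains.

    Ordering is descending for higher-is-better traits, ascending
    otherwise; ties are broken by genotype label and flagged.  The gain
    at rank k uses the cumulative mean over ranks 1..k of either the
    genotypic effects (``gain_basis="g"``, the default) or the full
    u+g+gem values (``gain_basis="g_plus_gem"``).
    """
    if gain_basis not in ("g", "g_plus_gem"):
        raise ValueError(f"unknown gain_basis {gain_basis!r}")
    blup = fit.blup
    if mu is None:
        mu = blup.mu
    upgg = blup.u_plus_g_plus_gem
    ascending = trait_spec.direction != HIGHER
    order = upgg.sort_values(ascending=ascending, kind="mergesort")
    # mergesort on values preserves the label-sorted index order for ties
    ties = bool(order.duplicated(keep=False).any())
    basis = (mu + blup.g_hat) if gain_basis == "g" else upgg
    basis = basis.loc[order.index]
    cum_mean = basis.expanding().mean()
    sg = 100.0 * (cum_mean - mu) / mu if mu != 0 else pd.Series(np.nan, index=order.index)
    table = pd.DataFrame(
        {
            "u_plus_g_plus_gem": order,
            "g_hat": blup.g_hat.loc[order.index],
            "sg_percent": sg,
        }
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    q = len(table)
    if selected_n is not None and not 1 <= selected_n <= q:
        raise ValueError(f"selected_n must be in [1, {q}]")
    n_sel = selected_n if selected_n is not None else q
    return GenotypeRanking(
        trait=fit.trait,
        table=table,
        mu=float(mu),
        gain_basis=gain_basis,
        selected=list(table.index[:n_sel]),
        ties=ties,
    )
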