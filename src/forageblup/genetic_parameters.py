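"""Genetic parameters derived from fitted variance components.

All quantities follow the standard repeated-measures RCBD definitions:

* individual broad-sense heritability     h2      = s2_g / s2_total
* individual repeatability                rho     = (s2_g + s2_perm) / s2_total
* determination of plot effects           c2_perm = s2_perm / s2_total
* determination of g×measurement effects  c2_gm   = s2_gm / s2_total
* genotypic correlation over measurements r_gmed  = s2_g / (s2_g + s2_gm)
* genotype-mean heritability  h2_mg = s2_g / (s2_g + s2_perm/b + s2_gm/m + s2_e/(b*m))
  (each non-genetic component divided by the number of independent
  realizations averaged into a genotype mean: b blocks, m harvests)
* selection accuracy                      sqrt(h2_mg)
* CVg = 100*sg/mu, CVe = 100*se/mu, CVr = CVg/CVe
* Pimentel-Gomes variation indices        VIe = CVe/sqrt(r), VIg = CVg/sqrt(r)
  with r the number of replicates (blocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .reml_core import FitResult, VarianceComponents
from .trial_data import DesignSummary, TrialDataset

__all__ = ["GeneticParameters", "derive_parameters", "parameter_table"]


@dataclass(frozen=True)
class GeneticParameters:
    h2: float
    rho: float
    c2_perm: float
    c2_gm: float
    r_gmed: float
    h2_mg: float
    accuracy: float
    mu: float
    cv_g: float  # percent; nan when mu <= 0
    cv_e: float  # percent; nan when mu <= 0
    cv_r: float  # ratio CVg/CVe
    vi_g: float  # percent
    vi_e: float  # percent
    r: int  # replicates used in the variation indices

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def derive_parameters(
    vc: VarianceComponents, design: DesignSummary, mu: float
) -> GeneticParameters:
    """Full parameter set from one trait's components and design.

    CV-based quantities require a positive grand mean; for ``mu <= 0``
    they are reported as NaN and everything else is still computed.
    """
    total = vc.total
    h2 = vc.sigma2_g / total
    rho = (vc.sigma2_g + vc.sigma2_perm) / total
    c2_perm = vc.sigma2_perm / total
    c2_gm = vc.sigma2_gm / total
    gg_gm = vc.sigma2_g + vc.sigma2_gm
    r_gmed = vc.sigma2_g / gg_gm if gg_gm > 0 else 0.0
    b, m = design.n_blocks, design.n_harvests
    denom = vc.sigma2_g + vc.sigma2_perm / b + vc.sigma2_gm / m + vc.sigma2_e / (b * m)
    h2_mg = vc.sigma2_g / denom if denom > 0 else 0.0
    r = b
    if mu > 0:
        cv_g = 100.0 * math.sqrt(vc.sigma2_g) / mu
        cv_e = 100.0 * math.sqrt(vc.sigma2_e) / mu
    else:
        cv_g = cv_e = float("nan")
    cv_r = cv_g / cv_e if cv_e and not math.isnan(cv_e) else float("nan")
    return GeneticParameters(
        h2=h2,
        rho=rho,
        c2_perm=c2_perm,
        c2_gm=c2_gm,
        r_gmed=r_gmed,
        h2_mg=h2_mg,
        accuracy=math.sqrt(h2_mg),
        mu=mu,
        cv_g=cv_g,
        cv_e=cv_e,
        cv_r=cv_r,
        vi_g=cv_g / math.sqrt(r),
        vi_e=cv_e / math.sqrt(r),
        r=r,
    )


def parameter_table(fits: dict[str, FitResult], ds: TrialDataset) -> pd.DataFrame:
    """One row of genetic parameters per fitted trait.

    Traits present in the dataset but missing from ``fits`` are omitted
    with a warning attribute on the returned frame.
    """
    rows, skipped = {}, []
    for trait in ds.trait_names:
        fit = fits.get(trait)
        if fit is None:
            skipped.append(trait)
            continue
        params = derive_parameters(fit.components, ds.design_summary(trait), fit.blup.mu)
        rows[trait] = params.as_dict()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trait"
    out.attrs["skipped"] = skipped
    return out
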