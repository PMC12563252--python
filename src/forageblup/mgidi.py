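"""Multi-trait genotype–ideotype distance index (MGIDI).

Four steps on a genotype × trait matrix of predicted genotypic values:

1. rescale each trait linearly to 0–100 so that 100 is always the
   desired end (maximum for higher-is-better traits, minimum for
   lower-is-better ones);
2. exploratory factor analysis of the rescaled matrix: principal-axis
   loadings from the trait correlation matrix, Kaiser retention
   (eigenvalue >= 1), varimax rotation, regression-method factor scores;
3. score the ideotype — 100 on every included trait — with the same
   score coefficients;
4. rank genotypes by Euclidean distance to the ideotype in factor-score
   space and select the closest at the requested intensity.

Selection differentials (mean of selected − grand mean, per trait)
summarize what the selection would change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import TraitSpec, HIGHER

__all__ = [
    "IdeotypeSpec",
    "FactorModel",
    "MgidiResult",
    "rescale_traits",
    "fit_factor_model",
    "mgidi_rank_select",
    "selection_differentials",
]


@dataclass(frozen=True)
class IdeotypeSpec:
    """Directions of the traits participating in ideotype selection."""

    directions: dict[str, str]  # trait -> higher_is_better / lower_is_better

    def __post_init__(self) -> None:
        if len(self.directions) < 2:
            raise ValueError("ideotype needs at least 2 traits")
        bad = {v for v in self.directions.values()} - {HIGHER, "lower_is_better"}
        if bad:
            raise ValueError(f"unknown directions {bad}")

    @classmethod
    def from_trait_specs(cls, specs: list[TraitSpec]) -> "IdeotypeSpec":
        return cls({s.name: s.direction for s in specs if s.include_in_ideotype})

    @property
    def traits(self) -> list[str]:
        return list(self.directions)


@dataclass(frozen=True)
class FactorModel:
    loadings: pd.DataFrame  # trait × factor, varimax-rotated
    communalities: pd.Series  # per trait
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix
    n_factors: int
    scores: pd.DataFrame  # genotype × factor
    ideotype_scores: pd.Series  # per factor
    rotation: str = "varimax"


@dataclass(frozen=True)
class MgidiResult:
    rescaled: pd.DataFrame
    factor_model: FactorModel
    distances: pd.Series  # per genotype, ascending = better
    ranking: pd.DataFrame  # rank, mgidi
    selected: list[str]
    intensity: float | None
    ties: bool


def rescale_traits(values: pd.DataFrame, spec: IdeotypeSpec) -> pd.DataFrame:
    """Linear 0–100 rescaling, direction-aware.

    For higher-is-better traits the column maximum maps to 100 and the
    minimum to 0; for lower-is-better traits the minimum maps to 100.
    A constant column has no usable range and is a hard error.
    """
    cols = [t for t in spec.traits if t in values.columns]
    missing = set(spec.traits) - set(cols)
    if missing:
        raise KeyError(f"ideotype traits absent from the value matrix: {sorted(missing)}")
    out = {}
    for trait in cols:
        col = values[trait].astype(float)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            raise ValueError(f"trait {trait!r} is constant across genotypes; drop it")
        scaled = 100.0 * (col - lo) / (hi - lo)
        if spec.directions[trait] != HIGHER:
            scaled = 100.0 - scaled
        out[trait] = scaled
    return pd.DataFrame(out, index=values.index)


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Kaiser varimax rotation of a loading matrix."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (L * (L**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new <= var_old * (1 + tol):
            break
        var_old = var_new
    return loadings @ R


def fit_factor_model(rescaled: pd.DataFrame) -> FactorModel:
    """Exploratory factor analysis of the rescaled genotype × trait matrix.

    Loadings are eigenvector × sqrt(eigenvalue) of the trait correlation
    matrix for the factors with eigenvalue >= 1 (Kaiser), varimax
    rotated, with a deterministic sign convention (the largest-magnitude
    loading of each factor is positive).  Scores use the regression
    method, B = R^{-1} L, applied to the standardized data; the ideotype
    (100 on every trait) is standardized and scored identically.
    """
    n_gen, n_traits = rescaled.shape
    if n_gen <= n_traits:
        raise ValueError(
            f"need more genotypes ({n_gen}) than traits ({n_traits}) for factor analysis"
        )
    X = rescaled.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError("constant trait column: correlation matrix undefined")
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    if not np.isfinite(R).all():
        raise ValueError("non-finite trait correlations")
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_factors = max(1, int((evals >= 1.0 - 1e-9).sum()))  # inclusive Kaiser rule
    L = evecs[:, :n_factors] * np.sqrt(np.clip(evals[:n_factors], 0.0, None))
    L = _varimax(L)
    # sign convention: dominant loading of each factor positive
    for j in range(n_factors):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    communal = (L**2).sum(axis=1)
    B = np.linalg.solve(R, L)  # regression score coefficients
    scores = Z @ B
    z_ideo = (100.0 - means) / sds
    ideo_scores = z_ideo @ B
    factors = [f"FA{j + 1}" for j in range(n_factors)]
    return FactorModel(
        loadings=pd.DataFrame(L, index=rescaled.columns, columns=factors),
        communalities=pd.Series(communal, index=rescaled.columns, name="communality"),
        eigenvalues=evals,
        n_factors=n_factors,
        scores=pd.DataFrame(scores, index=rescaled.index, columns=factors),
        ideotype_scores=pd.Series(ideo_scores, index=factors, name="ideotype"),
    )


def mgidi_rank_select(
    fm: FactorModel,
    rescaled: pd.DataFrame,
    intensity: float | None = 0.15,
    selected_n: int | None = None,
) -> MgidiResult:
    """Euclidean genotype–ideotype distance in factor space; ascending
    ranking; selection of the closest ceil(intensity·g) genotypes (or an
    explicit count).  Ties are broken by genotype label and flagged."""
    diffs = fm.scores - fm.ideotype_scores
    dist = pd.Series(
        np.sqrt((diffs.to_numpy() ** 2).sum(axis=1)), index=fm.scores.index, name="mgidi"
    )
    order = dist.sort_values(kind="mergesort")  # stable → label order on ties
    ties = bool(order.duplicated(keep=False).any())
    g = len(order)
    if selected_n is not None:
        if not 1 <= selected_n <= g:
            raise ValueError(f"selected_n must be in [1, {g}]")
        n_sel = selected_n
        intensity_used = None
    else:
        if intensity is None or not 0.0 < intensity <= 1.0:
            raise ValueError("intensity must be in (0, 1]")
        n_sel = math.ceil(intensity * g)
        intensity_used = intensity
    ranking = pd.DataFrame({"rank": np.arange(1, g + 1), "mgidi": order})
    return MgidiResult(
        rescaled=rescaled,
        factor_model=fm,
        distances=dist,
        ranking=ranking,
        selected=list(order.index[:n_sel]),
        intensity=intensity_used,
        ties=ties,
    )


def plot_ranking(res: MgidiResult, path: str) -> None:
    """Plain ranked-distance plot: genotypes by ascending MGIDI, the
    selected set highlighted and the selection cutoff drawn."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = res.ranking
    n_sel = len(res.selected)
    fig, ax = plt.subplots(figsize=(9, 4))
    colors = ["#c0392b" if i < n_sel else "#444444" for i in range(len(order))]
    ax.scatter(order["rank"], order["mgidi"], c=colors, s=14)
    ax.axvline(n_sel + 0.5, color="#c0392b", ls="--", lw=1)
    ax.set_xlabel("rank")
    ax.set_ylabel("MGIDI (distance to ideotype)")
    ax.set_title(f"{n_sel} of {len(order)} genotypes selected")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def selection_differentials(
    res: MgidiResult, raw: pd.DataFrame, spec: IdeotypeSpec
) -> pd.DataFrame:
    """Per-trait selection differentials of the MGIDI-selected set.

    Columns: grand mean, mean of the selected genotypes, differential
    (selected − all), the same as a percentage of the grand mean, and
    whether the shift is favorable given the trait's direction.
    """
    if not res.selected:
        raise ValueError("empty selected set")
    rows = {}
    for trait in spec.traits:
        col = raw[trait].astype(float)
        grand = float(col.mean())
        sel = float(col.loc[res.selected].mean())
        diff = sel - grand
        higher = spec.directions[trait] == HIGHER
        rows[trait] = {
            "grand_mean": grand,
            "selected_mean": sel,
            "differential": diff,
            "differential_pct": 100.0 * diff / grand if grand != 0 else float("nan"),
            "favorable": bool(diff > 0) == higher if diff != 0 else True,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trait"
    return out
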