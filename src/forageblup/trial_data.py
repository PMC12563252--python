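"""Data model and I/O for multi-harvest RCBD phenotype tables.

A trial is stored in long (tidy) form: one row per observed
(genotype, block, harvest, trait) cell.  Missing observations are absent
rows, never sentinel values, so unbalanced trials (dead plants, harvests
with partial coverage) are represented naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraitSpec",
    "DesignSummary",
    "TrialDataset",
    "load_trait_specs",
    "read_trial_table",
    "write_trial_table",
    "validate_design",
    "genotype_means",
]

REQUIRED_COLUMNS = ("genotype", "block", "harvest", "trait", "value")

HIGHER = "higher_is_better"
LOWER = "lower_is_better"


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of one measured trait.

    Parameters
    ----------
    name
        Trait identifier, unique within a study (e.g. ``"NT"``).
    direction
        ``"higher_is_better"`` or ``"lower_is_better"``; drives ranking
        order and ideotype construction.
    scale
        ``"continuous"``, ``"ordinal"`` (visual scores such as growth
        habit 1-4 or cold tolerance 1-5) or ``"binary"`` (survival 0/1).
    ordinal_bounds
        ``(low, high)`` integer bounds, required for ordinal traits.
    include_in_ideotype
        Whether the trait participates in multi-trait ideotype selection.
    """

    name: str
    direction: str = HIGHER
    scale: str = "continuous"
    ordinal_bounds: tuple[int, int] | None = None
    include_in_ideotype: bool = True

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.scale not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "ordinal":
            if self.ordinal_bounds is None:
                raise ValueError(f"ordinal trait {self.name!r} needs ordinal_bounds")
            lo, hi = self.ordinal_bounds
            if not lo < hi:
                raise ValueError(f"invalid ordinal_bounds {self.ordinal_bounds!r}")


@dataclass(frozen=True)
class DesignSummary:
    """Counts describing the realized design for one trait.

    ``n_plots`` counts genotype×block combinations actually observed and
    ``n_interaction_levels`` genotype×harvest combinations observed; with
    missing data these can fall below ``q*b`` and ``q*m``.  ``rank_x`` is
    the number of estimable harvest×block combination effects — the fixed
    part of the model uses cell-means coding of that combination, so its
    rank equals the number of combinations with data.
    """

    n_genotypes: int
    n_blocks: int
    n_harvests: int
    n_observations: int
    n_plots: int
    n_interaction_levels: int
    rank_x: int

    def __post_init__(self) -> None:
        q, b, m = self.n_genotypes, self.n_blocks, self.n_harvests
        if self.n_observations > q * b * m:
            raise ValueError("more observations than design cells")
        if self.n_plots > q * b or self.n_interaction_levels > q * m:
            raise ValueError("inconsistent level counts")


@dataclass(frozen=True)
class TrialDataset:
    """Long-format phenotype table plus trait declarations.

    ``data`` has exactly the columns ``genotype, block, harvest, trait,
    value``; keys are strings, values finite floats.  At most one row per
    (genotype, block, harvest, trait) key.
    """

    data: pd.DataFrame
    traits: dict[str, TraitSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("empty dataset")
        dup = df.duplicated(subset=["genotype", "block", "harvest", "trait"])
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), ["genotype", "block", "harvest", "trait"]])
            raise ValueError(f"duplicate record for key {key}")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite phenotype values")
        unknown = set(df["trait"]) - set(self.traits)
        if unknown:
            raise ValueError(f"records for undeclared traits: {sorted(unknown)}")

    @property
    def trait_names(self) -> list[str]:
        return sorted(set(self.data["trait"]))

    @property
    def genotypes(self) -> list[str]:
        return sorted(set(self.data["genotype"]))

    @property
    def blocks(self) -> list[str]:
        return sorted(set(self.data["block"]))

    @property
    def harvests(self) -> list[str]:
        return sorted(set(self.data["harvest"]))

    def subset(self, trait: str) -> pd.DataFrame:
        """Rows for one trait, sorted by (genotype, block, harvest)."""
        sub = self.data[self.data["trait"] == trait]
        if len(sub) == 0:
            raise KeyError(f"trait {trait!r} has no observations")
        return sub.sort_values(["genotype", "block", "harvest"], kind="mergesort").reset_index(
            drop=True
        )

    def design_summary(self, trait: str) -> DesignSummary:
        sub = self.subset(trait)
        combos = sub[["harvest", "block"]].drop_duplicates()
        plots = sub[["genotype", "block"]].drop_duplicates()
        inter = sub[["genotype", "harvest"]].drop_duplicates()
        return DesignSummary(
            n_genotypes=sub["genotype"].nunique(),
            n_blocks=sub["block"].nunique(),
            n_harvests=sub["harvest"].nunique(),
            n_observations=len(sub),
            n_plots=len(plots),
            n_interaction_levels=len(inter),
            rank_x=len(combos),
        )


def load_trait_specs(path: str | Path) -> list[TraitSpec]:
    """Read trait declarations from a YAML file.

    Layout::

        traits:
          - name: NT
            direction: higher_is_better
          - name: GH
            scale: ordinal
            ordinal_bounds: [1, 4]
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["traits"] if isinstance(doc, dict) else doc
    specs = []
    for entry in entries:
        entry = dict(entry)
        if "ordinal_bounds" in entry and entry["ordinal_bounds"] is not None:
            entry["ordinal_bounds"] = tuple(entry["ordinal_bounds"])
        specs.append(TraitSpec(**entry))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names in config")
    return specs


def read_trial_table(path: str | Path, trait_specs: Iterable[TraitSpec]) -> TrialDataset:
    """Read a long-format CSV (columns genotype,block,harvest,trait,value).

    Rows whose value does not parse as a finite number are rejected with
    their row numbers; duplicate keys and undeclared traits are hard
    errors raised by :class:`TrialDataset` validation.
    """
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: unparseable values at rows {rows[:20]}")
    out = df[["genotype", "block", "harvest", "trait"]].astype(str).copy()
    out["value"] = values.astype(float)
    return TrialDataset(data=out, traits={s.name: s for s in trait_specs})


def write_trial_table(ds: TrialDataset, path: str | Path) -> None:
    """Write the long table as CSV, lossless to 12 significant digits."""
    df = ds.data.copy()
    df["value"] = df["value"].map(lambda v: f"{v:.12g}")
    df.to_csv(path, index=False)


def validate_design(ds: TrialDataset) -> list[str]:
    """Report-only design checks: unbalance, ordinal bound violations,
    empty harvests.  Returns a list of human-readable findings (empty for
    a complete balanced dataset)."""
    report: list[str] = []
    genotypes, blocks, harvests = ds.genotypes, ds.blocks, ds.harvests
    for trait in ds.trait_names:
        sub = ds.data[ds.data["trait"] == trait]
        spec = ds.traits[trait]
        if spec.scale == "ordinal" and spec.ordinal_bounds is not None:
            lo, hi = spec.ordinal_bounds
            oob = sub[(sub["value"] < lo) | (sub["value"] > hi)]
            for _, row in oob.iterrows():
                report.append(
                    f"out-of-bounds: trait {trait} value {row['value']} outside "
                    f"[{lo}, {hi}] at (genotype={row['genotype']}, "
                    f"block={row['block']}, harvest={row['harvest']})"
                )
        present_harvests = set(sub["harvest"])
        for h in harvests:
            if h not in present_harvests:
                report.append(f"missing harvest: trait {trait} has no data in harvest {h}")
        n_expected = len(genotypes) * len(blocks) * len(present_harvests)
        n_missing = n_expected - len(sub)
        if n_missing > 0:
            cells = {(g, b, h) for g, b, h in zip(sub["genotype"], sub["block"], sub["harvest"])}
            examples = []
            for g in genotypes:
                g_harv = {h for (gg, _, h) in cells if gg == g}
                absent = [h for h in present_harvests if h not in g_harv]
                if absent:
                    examples.append(f"genotype {g} absent from harvests {sorted(absent)[:3]}")
                if len(examples) >= 3:
                    break
            note = "; ".join(examples)
            report.append(
                f"unbalanced: trait {trait} missing {n_missing} of {n_expected} cells"
                + (f" ({note})" if note else "")
            )
    return report


def wide_table(ds: TrialDataset, trait: str) -> pd.DataFrame:
    """Wide reporting layout for one trait: rows (genotype, block),
    one column per harvest, NaN where the cell is unobserved."""
    sub = ds.subset(trait)
    return sub.pivot(index=["genotype", "block"], columns="harvest", values="value")


def genotype_means(ds: TrialDataset, trait: str) -> tuple[pd.Series, float]:
    """Per-genotype arithmetic means across blocks and harvests, plus the
    grand mean µ (mean of all observations of the trait)."""
    sub = ds.subset(trait)
    means = sub.groupby("genotype")["value"].mean().sort_index()
    mu = float(sub["value"].mean())
    return means, mu
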