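"""Fixed- and random-effect incidence structures for animal models.

Turns a phenotype table plus a model specification into per-trait design
blocks: the response vector, a full-rank fixed-effect matrix (intercept,
one-hot contemporary groups with the first level dropped, mean-centred
covariates) and the map from records to pedigree positions.  Bivariate
models with unequal record patterns keep one block per trait; records
missing a trait are excluded from that trait's block only.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "DesignError",
    "ModelSpec",
    "TraitDesign",
    "DesignMatrices",
    "read_phenotypes",
    "flag_outliers",
    "build_design",
    "load_model_spec",
]


class DesignError(ValueError):
    """Raised for invalid model specifications or phenotype tables."""


@dataclass
class ModelSpec:
    """Names the response trait(s) and fixed effects of one model.

    ``covariates`` may be a flat sequence (applied to every trait) or a
    mapping trait -> sequence, so that e.g. slaughter age can enter the
    carcass-trait models only.
    """

    traits: tuple
    class_effects: tuple = ("slaughter_date",)
    covariates: Mapping[str, Sequence[str]] | Sequence[str] = ()

    def __post_init__(self):
        self.traits = tuple(self.traits)
        if not 1 <= len(self.traits) <= 2:
            raise DesignError("ModelSpec supports one or two traits")
        self.class_effects = tuple(self.class_effects)

    def covariates_for(self, trait: str) -> tuple:
        if isinstance(self.covariates, Mapping):
            return tuple(self.covariates.get(trait, ()))
        return tuple(self.covariates)


@dataclass
class TraitDesign:
    """Design block of one trait: y, X and the record-to-animal map."""

    trait: str
    y: np.ndarray
    X: np.ndarray
    columns: tuple
    animal_index: np.ndarray  # positions in the pedigree order
    animal_ids: tuple
    mask: np.ndarray  # over the input phenotype-table rows

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class DesignMatrices:
    traits: tuple
    blocks: Mapping[str, TraitDesign]
    trait_means: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def block(self, trait_or_pos) -> TraitDesign:
        if isinstance(trait_or_pos, int):
            trait_or_pos = self.traits[trait_or_pos]
        return self.blocks[trait_or_pos]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV (columns: animal, effects..., traits...)."""
    df = pd.read_csv(path)
    df["animal"] = df["animal"].astype(str).str.strip()
    return df


def flag_outliers(
    df: pd.DataFrame, traits: Sequence[str], k: float = 3.0
) -> pd.DataFrame:
    """Boolean frame marking values beyond ``k * IQR`` outside the quartiles.

    This is the optional screen applied before model fitting; it is off
    by default because any such rule is a judgement call.
    """
    flags = pd.DataFrame(False, index=df.index, columns=list(traits))
    for t in traits:
        x = df[t]
        q1, q3 = x.quantile([0.25, 0.75])
        iqr = q3 - q1
        flags[t] = (x < q1 - k * iqr) | (x > q3 + k * iqr)
    return flags


def build_design(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    outlier_k: float | None = None,
) -> DesignMatrices:
    """Assemble per-trait y vectors and full-rank fixed-effect matrices.

    Rows missing a trait are dropped from that trait's block only; class
    effects are one-hot encoded with the first (sorted) level as
    reference; covariates are centred at the sample mean of the block.

    Raises
    ------
    DesignError
        If a phenotyped animal is absent from the pedigree, a named
        column is missing, a covariate has zero variance, or X is rank
        deficient.
    """
    df = phenotypes
    if "animal" not in df.columns:
        raise DesignError("phenotype table needs an 'animal' column")
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise DesignError(f"phenotype table has duplicate rows for animal {dup!r}")
    for col in (*spec.traits, *spec.class_effects):
        if col not in df.columns:
            raise DesignError(f"column {col!r} not in phenotype table")
    for t in spec.traits:
        for c in spec.covariates_for(t):
            if c not in df.columns:
                raise DesignError(f"covariate column {c!r} not in phenotype table")

    if outlier_k is not None:
        flags = flag_outliers(df, spec.traits, k=outlier_k)
        df = df.copy()
        for t in spec.traits:
            df.loc[flags[t], t] = np.nan

    blocks: dict[str, TraitDesign] = {}
    means: dict[str, float] = {}
    for t in spec.traits:
        mask = df[t].notna().to_numpy()
        sub = df.loc[mask]
        if sub.empty:
            raise DesignError(f"trait {t!r} has no non-missing records")
        animals = sub["animal"].astype(str).tolist()
        idx = np.empty(len(animals), dtype=int)
        for j, a in enumerate(animals):
            if a not in ped.index:
                raise DesignError(f"phenotyped animal not in pedigree: {a!r}")
            idx[j] = ped.index[a]

        cols: list[np.ndarray] = [np.ones(len(sub))]
        names: list[str] = ["intercept"]
        for ce in spec.class_effects:
            levels = sorted(sub[ce].astype(str).unique())
            if len(levels) == 1:
                warnings.warn(
                    f"class effect {ce!r} has a single level for trait {t!r}; dropped",
                    stacklevel=2,
                )
                continue
            vals = sub[ce].astype(str).to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{ce}[{lev}]")
        for cv in spec.covariates_for(t):
            x = sub[cv].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise DesignError(f"covariate {cv!r} has missing values for trait {t!r}")
            if np.std(x) == 0:
                raise DesignError(f"covariate {cv!r} has zero variance")
            cols.append(x - x.mean())
            names.append(f"{cv} (centred)")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError(
                f"fixed-effect matrix for trait {t!r} is rank deficient "
                "(confounded effects?)"
            )
        y = sub[t].to_numpy(dtype=float)
        blocks[t] = TraitDesign(
            trait=t,
            y=y,
            X=X,
            columns=tuple(names),
            animal_index=idx,
            animal_ids=tuple(animals),
            mask=mask,
        )
        means[t] = float(y.mean())
    return DesignMatrices(traits=spec.traits, blocks=blocks, trait_means=means)


def load_model_spec(path, traits: Sequence[str] | None = None) -> ModelSpec:
    """Read a ``[model]`` table from a TOML config file.

    Keys: ``traits`` (list), ``class_effects`` (list), ``covariates``
    (list, or table mapping trait -> list), ``outlier_k`` (ignored here,
    read by the pipeline).  ``traits`` may be overridden by the caller.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    model = cfg.get("model", cfg)
    tr = tuple(traits if traits is not None else model.get("traits", ()))
    if not tr:
        raise DesignError("no traits given (config [model].traits or argument)")
    cov = model.get("covariates", ())
    return ModelSpec(
        traits=tr,
        class_effects=tuple(model.get("class_effects", ("slaughter_date",))),
        covariates=cov,
    )
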