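"""Full-study orchestration: descriptive statistics, univariate fits and
all requested pairwise bivariate fits with likelihood-ratio tests.

Mirrors the structure of a genetic-parameter study: a summary-statistics
table, a per-trait table of heritabilities and variance components
(from univariate fits), and correlation tables (genetic above, phenotypic
below the diagonal) from bivariate fits, with significance flags from
nested-model likelihood-ratio tests.  Bivariate-implied heritabilities
are kept as a diagnostic of agreement with the univariate fits.
"""

from __future__ import annotations

import itertools
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .aireml import REMLFit, fit, fit_constrained
from .design import ModelSpec, build_design
from .genpar import (LRTResult, correlation, cv_genetic, heritability,
                     lrt_correlations, se_by_sampling)
from .pedigree import Pedigree, RelationshipStructure, build_A_inverse

__all__ = [
    "DEFAULT_COMPOSITES",
    "descriptives",
    "make_composites",
    "StudyReport",
    "run_study",
]

# Composite cut groups by market value: high, medium and low value cuts.
DEFAULT_COMPOSITES: Mapping[str, tuple] = {
    "HVC": ("CHK", "SLN", "STLN", "TLN"),
    "MVC": ("BSK", "TRD", "BRD", "RB"),
    "LVC": ("FK", "SK"),
}


def descriptives(ph: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """n, mean, SE of mean (SD/sqrt(n)), min, max, SD (n-1), CV% (SD/mean)."""
    if ph.empty:
        raise ValueError("empty phenotype table")
    rows = []
    for t in traits:
        x = ph[t].dropna().to_numpy(dtype=float)
        n = len(x)
        if n == 0:
            rows.append({"trait": t, "n": 0, "mean": np.nan, "se": np.nan,
                         "min": np.nan, "max": np.nan, "sd": np.nan,
                         "cv_pct": np.nan})
            continue
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        mean = float(np.mean(x))
        rows.append({
            "trait": t,
            "n": n,
            "mean": mean,
            "se": sd / np.sqrt(n),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "sd": sd,
            "cv_pct": (sd / mean * 100.0) if mean != 0 else 0.0,
        })
    return pd.DataFrame(rows)


def make_composites(
    ph: pd.DataFrame, composites: Mapping[str, Sequence[str]] = DEFAULT_COMPOSITES
) -> pd.DataFrame:
    """Add composite columns: the sum of the member cuts where all members
    are observed, missing otherwise.  Missing member columns are skipped."""
    out = ph.copy()
    for name, members in composites.items():
        if not all(m in ph.columns for m in members):
            continue
        block = ph[list(members)]
        out[name] = block.sum(axis=1).where(block.notna().all(axis=1))
    return out


@dataclass
class StudyReport:
    """All tables of one study run, each cell traceable to a fit."""

    descriptives: pd.DataFrame
    heritability: pd.DataFrame
    pairs: pd.DataFrame
    bivariate_h2_diagnostics: pd.DataFrame
    manifest: dict
    univariate_fits: Mapping[str, REMLFit] = field(repr=False, default_factory=dict)
    bivariate_fits: Mapping[tuple, dict] = field(repr=False, default_factory=dict)

    def correlation_matrix(self, traits: Sequence[str]) -> pd.DataFrame:
        """Square table: genetic correlations above the diagonal,
        phenotypic below, unit diagonal."""
        traits = list(traits)
        M = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
        for _, row in self.pairs.iterrows():
            a, b = row["trait_x"], row["trait_y"]
            if a in traits and b in traits:
                i, j = traits.index(a), traits.index(b)
                M.iloc[min(i, j), max(i, j)] = row["r_g"]
                M.iloc[max(i, j), min(i, j)] = row["r_p"]
        return M

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.heritability.to_csv(out / "heritability.csv", index=False)
        self.pairs.to_csv(out / "correlations_pairs.csv", index=False)
        self.bivariate_h2_diagnostics.to_csv(
            out / "bivariate_h2_diagnostics.csv", index=False
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _spec_for(traits, class_effects, covariates):
    return ModelSpec(traits=tuple(traits), class_effects=class_effects,
                     covariates=covariates)


def run_study(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    *,
    carcass_traits: Sequence[str] = (),
    cut_traits: Sequence[str] = (),
    composites: Mapping[str, Sequence[str]] | None = None,
    class_effects: Sequence[str] = ("slaughter_date",),
    covariates: Mapping[str, Sequence[str]] | None = None,
    rel: RelationshipStructure | None = None,
    seed: int = 0,
    n_se_samples: int = 10_000,
    tol: float = 1e-12,
    max_iter: int = 200,
    outlier_k: float | None = None,
    n_jobs: int = 1,
) -> StudyReport:
    """Descriptives, univariate fits per trait, bivariate fits per pair.

    Pairs fitted: cut x cut, carcass x cut, and carcass x composite.
    Variance components and heritabilities are reported from the
    univariate fits; correlations and their LRT significance from the
    bivariate fits.  ``covariates`` defaults to a slaughter-age covariate
    for the carcass traits only.  Deterministic given the seed; results
    are independent of ``n_jobs``.
    """
    carcass = tuple(carcass_traits)
    cuts = tuple(cut_traits)
    if composites is None:
        composites = {
            k: v for k, v in DEFAULT_COMPOSITES.items()
            if all(m in phenotypes.columns for m in v)
        }
    ph = make_composites(phenotypes, composites) if composites else phenotypes.copy()
    comp_names = tuple(k for k in composites if k in ph.columns) if composites else ()
    all_traits = carcass + cuts + comp_names
    if not all_traits:
        raise ValueError("no traits to analyse")
    if covariates is None:
        covariates = {t: ("slaughter_age",) for t in carcass
                      if "slaughter_age" in ph.columns}
    if rel is None:
        rel = build_A_inverse(ped)

    desc = descriptives(ph, all_traits)
    desc_mean = dict(zip(desc["trait"], desc["mean"]))

    pairs = (
        list(itertools.combinations(cuts, 2))
        + [(c, t) for c in carcass for t in cuts]
        + [(c, t) for c in carcass for t in comp_names]
    )

    seeds = np.random.SeedSequence(seed).spawn(len(all_traits) + len(pairs))
    uni_seeds = dict(zip(all_traits, seeds[: len(all_traits)]))
    pair_seeds = dict(zip(pairs, seeds[len(all_traits):]))

    def fit_one(trait):
        spec = _spec_for((trait,), class_effects, covariates)
        dm = build_design(ph, ped, spec, outlier_k=outlier_k)
        f = fit(dm, rel, tol=tol, max_iter=max_iter)
        rng = np.random.default_rng(uni_seeds[trait])
        h2 = heritability(f.vc)
        h2_se = se_by_sampling(
            f, lambda G, R: G[0, 0] / (G[0, 0] + R[0, 0]),
            n_samples=n_se_samples, seed=rng,
        ).se
        se_theta = np.sqrt(np.clip(np.diag(f.theta_cov), 0, None))
        mean = desc_mean.get(trait, np.nan)
        return trait, f, {
            "trait": trait,
            "h2": h2,
            "h2_se": h2_se,
            "sigma2_g": f.vc.G[0, 0],
            "sigma2_g_se": se_theta[0],
            "sigma2_e": f.vc.R[0, 0],
            "sigma2_e_se": se_theta[1],
            "sigma2_p": f.vc.G[0, 0] + f.vc.R[0, 0],
            "cvg_pct": cv_genetic(f.vc.G[0, 0], mean) if mean > 0 else np.nan,
            "converged": f.converged,
            "n_iterations": f.n_iterations,
        }

    def fit_pair(pair):
        x, y = pair
        spec = _spec_for((x, y), class_effects, covariates)
        dm = build_design(ph, ped, spec, outlier_k=outlier_k)
        full = fit(dm, rel, tol=tol, max_iter=max_iter)
        red_g = fit_constrained(dm, rel, "zero-genetic-cov", tol=tol,
                                max_iter=max_iter)
        red_gr = fit_constrained(dm, rel, "zero-both-cov", tol=tol,
                                 max_iter=max_iter)
        lrt1 = lrt_correlations(full, red_g, df=1)
        lrt2 = lrt_correlations(full, red_gr, df=2)
        rng = np.random.default_rng(pair_seeds[pair])
        rg = correlation(full.vc, "genetic")
        rp = correlation(full.vc, "phenotypic")

        def corr_fn(kind):
            def fn(G, R):
                M = G if kind == "genetic" else G + R
                return M[0, 1] / np.sqrt(M[0, 0] * M[1, 1])
            return fn

        rg_se = se_by_sampling(full, corr_fn("genetic"),
                               n_samples=n_se_samples, seed=rng).se
        rp_se = se_by_sampling(full, corr_fn("phenotypic"),
                               n_samples=n_se_samples, seed=rng).se
        row = {
            "trait_x": x,
            "trait_y": y,
            "r_g": rg,
            "r_g_se": rg_se,
            "r_g_significant": lrt1.significant,
            "r_p": rp,
            "r_p_se": rp_se,
            "r_p_significant": lrt2.significant,
            "lrt_df1": lrt1.minus2logLambda,
            "lrt_df2": lrt2.minus2logLambda,
            "converged": full.converged and red_g.converged and red_gr.converged,
        }
        diag = [
            {"pair": f"{x}:{y}", "trait": tr,
             "h2_bivariate": heritability(full.vc, k),
             "bent": full.bent, "boundary": full.boundary}
            for k, tr in enumerate((x, y))
        ]
        return pair, {"full": full, "reduced_g": red_g, "reduced_gr": red_gr}, row, diag

    if n_jobs > 1:
        with ThreadPoolExecutor(max_workers=n_jobs) as ex:
            uni_results = list(ex.map(fit_one, all_traits))
            pair_results = list(ex.map(fit_pair, pairs))
    else:
        uni_results = [fit_one(t) for t in all_traits]
        pair_results = [fit_pair(p) for p in pairs]

    uni_fits = {t: f for t, f, _ in uni_results}
    herit = pd.DataFrame([row for _, _, row in uni_results])
    biv_fits = {p: d for p, d, _, _ in pair_results}
    pair_rows = pd.DataFrame([row for _, _, row, _ in pair_results])
    diag_rows = [r for _, _, _, dl in pair_results for r in dl]
    diag = pd.DataFrame(diag_rows)
    if not diag.empty:
        diag["h2_univariate"] = diag["trait"].map(
            dict(zip(herit["trait"], herit["h2"]))
        )
        diag["delta"] = diag["h2_bivariate"] - diag["h2_univariate"]

    manifest = {
        "pedreml_version": _version,
        "seed": seed,
        "tol": tol,
        "max_iter": max_iter,
        "n_se_samples": n_se_samples,
        "n_animals_pedigree": ped.n,
        "traits": list(all_traits),
        "n_pairs": len(pairs),
        "class_effect_levels": {
            ce: int(ph[ce].nunique()) for ce in class_effects if ce in ph.columns
        },
        "convergence": {
            **{t: bool(f.converged) for t, f in uni_fits.items()},
            **{f"{x}:{y}": bool(d["full"].converged)
               for (x, y), d in biv_fits.items()},
        },
    }
    return StudyReport(
        descriptives=desc,
        heritability=herit,
        pairs=pair_rows,
        bivariate_h2_diagnostics=diag,
        manifest=manifest,
        univariate_fits=uni_fits,
        bivariate_fits=biv_fits,
    )
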