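"""Strain-phenotype attribution and density/diversity associations.

The screen's attribution step: with a balanced subcommunity design, each
strain splits the mice into those colonized with a community containing it and
those without; a Welch t test on per-mouse phenotype values over that split
quantifies the strain's association, and Benjamini-Hochberg q-values are
reported across strains (headline ranking uses raw p, correction is the
reader's call). The module also houses the density bookkeeping: microbiota
density as DNA mass over fecal mass, paired pre/post change tests, two-group
comparisons, and simple OLS associations between density (or strain
abundance) and immune phenotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import DesignMatrix
from .errors import InputError
from .stats import (RegressionResult, TestResult, group_summary, linear_regression_f,
                    one_way_anova, paired_t_test, welch_t_test)

__all__ = [
    "strain_screen",
    "community_anova",
    "abundance_phenotype_regression",
    "microbiota_density",
    "density_change_and_association",
]


def _check_phenotypes(phenotypes: pd.DataFrame) -> None:
    required = {"mouse_id", "community_id", "value"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise InputError(f"phenotype table lacks columns {sorted(missing)!r}")


def strain_screen(design: DesignMatrix, phenotypes: pd.DataFrame,
                  unit: str = "mouse") -> pd.DataFrame:
    """Per-strain with/without association over a subcommunity screen.

    For each strain, phenotype values are pooled by whether the mouse's
    community contains the strain and compared by Welch t test (``unit='mouse'``,
    the default, pools mice; ``unit='community'`` uses community means).
    Returns one row per strain with effect (mean with - without), t, raw p,
    BH-adjusted q, group sizes and flags. Strains present in every community
    or in none have no contrast and are flagged NA; strains with identical
    design columns are perfectly confounded and flagged as such.
    """
    _check_phenotypes(phenotypes)
    X = design.X
    unknown = set(phenotypes["community_id"]) - set(X.index)
    if unknown:
        raise InputError(f"phenotype rows reference unknown communities {sorted(unknown)!r}")
    if unit not in ("mouse", "community"):
        raise InputError(f"unknown unit {unit!r}")
    if unit == "community":
        values = phenotypes.groupby("community_id")["value"].mean()
        comm_of = pd.Series(values.index, index=values.index)
        vals = values.to_numpy()
        comms = values.index.to_numpy()
    else:
        vals = phenotypes["value"].to_numpy()
        comms = phenotypes["community_id"].to_numpy()

    # confound groups: strains with identical incidence columns
    col_key = {s: tuple(X[s].tolist()) for s in X.columns}
    key_counts: dict[tuple, int] = {}
    for s, kk in col_key.items():
        key_counts[kk] = key_counts.get(kk, 0) + 1

    has_strain = {s: set(X.index[X[s] == 1]) for s in X.columns}
    rows = []
    for s in X.columns:
        with_mask = np.array([c in has_strain[s] for c in comms])
        x, y = vals[with_mask], vals[~with_mask]
        row = {"strain_id": s, "n_with": int(len(x)), "n_without": int(len(y)),
               "confounded": key_counts[col_key[s]] > 1}
        if len(x) < 2 or len(y) < 2:
            row.update({"effect": np.nan, "t": np.nan, "p": np.nan,
                        "flag": "no_contrast" if (len(x) == 0 or len(y) == 0) else "too_few"})
        else:
            res = welch_t_test(x, y)
            row.update({"effect": res.effect, "t": res.statistic, "p": res.p_value, "flag": ""})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("strain_id")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["rank"] = out["p"].rank(method="min")
    return out.sort_values(["p", "effect"], ascending=[True, False])


def community_anova(design: DesignMatrix, phenotypes: pd.DataFrame) -> TestResult:
    """One-way ANOVA of phenotype across subcommunities (>= 2 mice each)."""
    _check_phenotypes(phenotypes)
    groups = [sub["value"].to_numpy() for _, sub in phenotypes.groupby("community_id")]
    return one_way_anova(groups, label="phenotype across communities")


def abundance_phenotype_regression(abundance: pd.DataFrame | pd.Series,
                                   phenotypes: pd.DataFrame, strain_id: str | None = None,
                                   sample_col: str = "mouse_id") -> RegressionResult:
    """OLS of phenotype on a strain's (relative or absolute) abundance.

    ``abundance`` is either a samples x strains frame (then ``strain_id``
    selects the column) or an already-extracted per-sample series. Samples are
    matched to phenotype rows by ``sample_col``; mismatched ids are an error.
    """
    _check_phenotypes(phenotypes)
    if isinstance(abundance, pd.DataFrame):
        if strain_id is None or strain_id not in abundance.columns:
            raise InputError(f"strain {strain_id!r} not in abundance table")
        series = abundance[strain_id]
    else:
        series = abundance
    pheno = phenotypes.set_index(sample_col)["value"]
    common = series.index.intersection(pheno.index)
    if len(common) < 3:
        raise InputError("need >= 3 matched abundance/phenotype samples")
    if len(common) < len(pheno.index.unique()) and len(common) < len(series.index):
        raise InputError("abundance and phenotype sample ids do not match")
    x = series.loc[common].to_numpy(dtype=float)
    y = pheno.loc[common].to_numpy(dtype=float)
    label = f"phenotype ~ abundance[{strain_id}]" if strain_id else "phenotype ~ abundance"
    return linear_regression_f(x, y, label=label)


def microbiota_density(dna_mass_ng, fecal_mass_mg):
    """Fecal microbiota density: DNA mass (ng) divided by fecal mass (mg).

    Accepts scalars or aligned array-likes; masses must be strictly positive.
    """
    d = np.asarray(dna_mass_ng, dtype=float)
    m = np.asarray(fecal_mass_mg, dtype=float)
    if np.any(d <= 0) or np.any(m <= 0):
        raise InputError("masses must be positive")
    out = d / m
    return float(out) if out.ndim == 0 else out


def density_change_and_association(density: pd.DataFrame,
                                   phenotypes: pd.DataFrame | None = None,
                                   grouping: str | None = None) -> dict:
    """Density change after transplant plus optional group and phenotype analyses.

    ``density`` needs columns mouse_id, timepoint ('pre'/'post') and
    density_ng_per_mg (or dna_mass_ng + fecal_mass_mg, from which density is
    computed). Returns a dict with:

    * ``paired`` — paired t on per-mouse post-minus-pre density change;
    * ``group_summary``/``group_welch`` — when ``grouping`` names a column,
      mean +/- SE per group and (for exactly two groups) a Welch t test;
    * ``regression`` — when ``phenotypes`` is given, OLS of the phenotype on
      post-transplant density with the overall F test.
    """
    density = density.copy()
    if "density_ng_per_mg" not in density.columns:
        density["density_ng_per_mg"] = microbiota_density(
            density["dna_mass_ng"], density["fecal_mass_mg"])
    for col in ("mouse_id", "timepoint"):
        if col not in density.columns:
            raise InputError(f"density table lacks column {col!r}")
    wide = density.pivot_table(index="mouse_id", columns="timepoint",
                               values="density_ng_per_mg", aggfunc="mean")
    out: dict = {}
    paired = wide.dropna(subset=[c for c in ("pre", "post") if c in wide.columns])
    if {"pre", "post"} <= set(wide.columns) and len(paired) >= 2:
        out["paired"] = paired_t_test(paired["pre"], paired["post"],
                                      label="density change after transplant (paired t)")
    else:
        raise InputError("paired pre/post densities required (>= 2 mice with both)")
    if grouping is not None:
        if grouping not in density.columns:
            raise InputError(f"unknown grouping column {grouping!r}")
        groups = {name: sub["density_ng_per_mg"].to_numpy()
                  for name, sub in density.groupby(grouping)}
        out["group_summary"] = group_summary(groups)
        if len(groups) == 2:
            a, b = groups.values()
            names = list(groups)
            out["group_welch"] = welch_t_test(a, b, label=f"density {names[0]} vs {names[1]}")
    if phenotypes is not None:
        _check_phenotypes(phenotypes)
        post = density[density["timepoint"] == "post"].set_index("mouse_id")["density_ng_per_mg"]
        pheno = phenotypes.set_index("mouse_id")["value"]
        common = post.index.intersection(pheno.index)
        if len(common) < 3:
            raise InputError("need >= 3 matched density/phenotype mice")
        out["regression"] = linear_regression_f(post.loc[common], pheno.loc[common],
                                                label="phenotype ~ density (f-test)")
    return out
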