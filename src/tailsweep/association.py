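"""Genotype–phenotype association under three genetic models.

Each marker is tested against each phenotype by ordinary least squares
under additive (allele count 0/1/2), dominant (carrier 0/1) and recessive
(homozygote 0/1) encodings of the mutated allele, optionally adjusting for
age and sex.  "Mutated allele" means the allele whose count the table
stores — the allele enriched in the selected lineage — and must be declared
by whoever built the table; it is never inferred here.

Rows with any missing required field are dropped (complete-case analysis)
and the number of rows actually used is reported.  P-values are two-sided
t-tests on the genotype coefficient, unadjusted for multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "encode_genotype",
    "fit_association",
    "association_report",
]

MODELS = ("additive", "dominant", "recessive")


def encode_genotype(g, model: str):
    """Numeric encoding of a mutated-allele count under a genetic model:
    additive → g; dominant → 1 if g ≥ 1; recessive → 1 if g = 2.
    Missing values (NaN/None) propagate."""
    if model not in MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    arr = np.asarray(g, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    valid = np.isnan(arr) | np.isin(arr, [0.0, 1.0, 2.0])
    if not valid.all():
        bad = arr[~valid][:3]
        raise ValueError(f"genotype codes outside {{0,1,2,missing}}: {bad}")
    if model == "additive":
        out = arr
    elif model == "dominant":
        out = np.where(np.isnan(arr), np.nan, (arr >= 1).astype(float))
    else:
        out = np.where(np.isnan(arr), np.nan, (arr == 2).astype(float))
    return float(out[0]) if scalar else out


@dataclass
class RegressionResult:
    """Effect of one marker on one phenotype under one genetic model.
    ``beta`` is in phenotype units per encoded genotype unit; ``estimable``
    is False (with NaN statistics) when the encoded genotype is constant in
    the rows used."""

    marker: str
    phenotype: str
    model: str
    adjusted: bool
    beta: float
    se: float
    t: float
    p: float
    n_used: int
    estimable: bool = True

    def as_row(self) -> dict:
        return {
            "marker": self.marker,
            "phenotype": self.phenotype,
            "model": self.model,
            "adjusted": self.adjusted,
            "beta": self.beta,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "n_used": self.n_used,
            "estimable": self.estimable,
        }


def fit_association(
    table: pd.DataFrame,
    marker: str,
    phenotype: str,
    model: str = "additive",
    adjust: bool = True,
    *,
    age_col: str = "age",
    sex_col: str = "sex",
) -> RegressionResult:
    """OLS of ``phenotype`` on the encoded ``marker`` genotype, plus age and
    sex covariates when ``adjust`` is true.

    A constant encoded genotype yields an inestimable result rather than an
    exception; a rank-deficient covariate design raises, naming the
    collinear columns.
    """
    cols = [phenotype, marker] + ([age_col, sex_col] if adjust else [])
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"table lacks columns: {missing_cols}")
    data = table[cols].dropna()
    n_used = len(data)
    g = encode_genotype(data[marker].to_numpy(), model)

    if n_used > 0 and np.nanstd(g) == 0.0:
        nan = float("nan")
        return RegressionResult(
            marker, phenotype, model, adjust, nan, nan, nan, nan, n_used, estimable=False
        )

    X = pd.DataFrame({"genotype": g}, index=data.index)
    if adjust:
        X[age_col] = data[age_col].astype(float)
        X[sex_col] = data[sex_col].astype(float)
    n_params = X.shape[1] + 1  # + intercept
    if n_used < n_params + 3:
        raise ValueError(
            f"only {n_used} complete rows for {n_params} parameters; need ≥{n_params + 3}"
        )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    fit = sm.OLS(data[phenotype].astype(float), Xc).fit()
    return RegressionResult(
        marker=marker,
        phenotype=phenotype,
        model=model,
        adjusted=adjust,
        beta=float(fit.params["genotype"]),
        se=float(fit.bse["genotype"]),
        t=float(fit.tvalues["genotype"]),
        p=float(fit.pvalues["genotype"]),
        n_used=n_used,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (the dependent set)."""
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    out = []
    for col in X.columns:
        reduced = X.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(reduced) == full_rank:
            out.append(col)
    return out


def association_report(
    table: pd.DataFrame,
    markers: list[str],
    phenotypes: list[str],
    models: tuple[str, ...] = MODELS,
    adjustments: tuple[bool, ...] = (True, False),
    **kwargs,
) -> pd.DataFrame:
    """One regression per marker × phenotype × model × adjustment, as a flat
    table (the layout of a full association report)."""
    rows = []
    for marker in markers:
        for phenotype in phenotypes:
            for model in models:
                for adjust in adjustments:
                    res = fit_association(
                        table, marker, phenotype, model, adjust, **kwargs
                    )
                    rows.append(res.as_row())
    columns = [
        "marker",
        "phenotype",
        "model",
        "adjusted",
        "beta",
        "se",
        "t",
        "p",
        "n_used",
        "estimable",
    ]
    return pd.DataFrame(rows, columns=columns)
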