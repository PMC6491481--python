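"""Quantitative-genetics layer: mixed models, BLUPs, heritability.

Each trait is analysed with a linear mixed model

    y = X beta + Z g + e,    g ~ N(0, sigma_G^2 I),   e ~ N(0, sigma_R^2 I)

with a random genotype intercept and fixed effects (watering scenario always;
optionally date, device, VPD, ...).  Variance components are estimated by
REML; genotype BLUPs are the conditional means of g given the data.  Candidate
fixed-effect structures are compared on the Bayesian Information Criterion of
an ML refit of the same structure (REML likelihoods are not comparable across
fixed-effect sets); the likelihood flavour is recorded in the fit.

Broad-sense heritability on a genotype-mean basis:

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_R^2 / n)

with n the mean number of non-missing replicates per genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "ModelFit",
    "fit_mixed",
    "select_model",
    "heritability",
    "genotypic_cv",
    "DEFAULT_CANDIDATES",
]

#: Default candidate fixed-effect structures (formula right-hand sides).
DEFAULT_CANDIDATES = ("scenario", "scenario + date", "scenario + device + vpd")


@dataclass
class ModelFit:
    """One trait's mixed-model fit."""

    trait: str
    fixed_formula: str
    fixed_effects: dict
    sigma_g2: float
    sigma_r2: float
    bic: float
    blups: pd.Series  # genotype -> genetic value (deviation from intercept)
    n_replicates: float  # mean non-missing replicates per genotype
    intercept: float
    converged: bool
    boundary: bool  # sigma_G^2 pinned at (or squeezed onto) the zero boundary
    likelihood_note: str = "variance components: REML; BIC: ML refit of the same structure"
    diagnostics: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return heritability(self.sigma_g2, self.sigma_r2, self.n_replicates)


def _bic_ml(model, n_obs: int, k_fixed: int) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ml = model.fit(reml=False)
    # free parameters: fixed effects + genotype variance + residual variance
    k = k_fixed + 2
    return float(-2.0 * ml.llf + k * np.log(n_obs))


def fit_mixed(
    records: pd.DataFrame,
    fixed: str = "scenario",
    value_col: str = "value",
    genotype_col: str = "genotype",
    trait: str | None = None,
) -> ModelFit:
    """REML mixed-model fit of one trait with a random genotype intercept.

    ``fixed`` is the right-hand side of the fixed-effect formula ("1" for an
    intercept-only model).  Non-convergence and a genetic variance estimated at
    the zero boundary are flagged on the result rather than raised.
    """
    data = records.dropna(subset=[value_col]).copy()
    if data[genotype_col].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if len(data) < data[genotype_col].nunique() + 1:
        raise ValueError("need more observations than genotypes")
    for col in _formula_columns(fixed):
        if col not in data.columns:
            raise ValueError(f"fixed-effect term {col!r} is not a column of the table")
    formula = f"{value_col} ~ {fixed}"
    model = smf.mixedlm(formula, data, groups=data[genotype_col])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        # polish with a derivative-free pass: the default gradient stop leaves
        # ~1e-5 slack in the variance components
        res = model.fit(reml=True, start_params=res.params_object, method="powell")
    sigma_g2 = float(res.cov_re.iloc[0, 0])
    sigma_r2 = float(res.scale)
    boundary = sigma_g2 <= 1e-8 * max(sigma_r2, 1e-12)
    blups = pd.Series(
        {g: float(re.iloc[0]) for g, re in res.random_effects.items()}, dtype=float
    ).sort_index()
    blups.index.name = genotype_col
    n_rep = float(data.groupby(genotype_col)[value_col].count().mean())
    fe = {name: float(v) for name, v in res.fe_params.items()}
    return ModelFit(
        trait=trait or value_col,
        fixed_formula=fixed,
        fixed_effects=fe,
        sigma_g2=sigma_g2,
        sigma_r2=sigma_r2,
        bic=_bic_ml(model, len(data), len(res.fe_params)),
        blups=blups,
        n_replicates=n_rep,
        intercept=fe.get("Intercept", 0.0),
        converged=bool(res.converged),
        boundary=boundary,
        diagnostics={"n_obs": len(data), "n_genotypes": int(data[genotype_col].nunique())},
    )


def _formula_columns(fixed: str):
    import re as _re

    cols = set()
    for tok in _re.split(r"[+*:]", fixed):
        tok = tok.strip()
        m = _re.fullmatch(r"C\((\w+)\)", tok)
        if m:
            cols.add(m.group(1))
        elif tok and tok not in {"1", "0"}:
            cols.add(tok)
    return cols


def select_model(
    records: pd.DataFrame,
    candidates=DEFAULT_CANDIDATES,
    value_col: str = "value",
    genotype_col: str = "genotype",
    trait: str | None = None,
):
    """Fit every candidate fixed-effect structure; return (best fit, BIC table).

    The winner has the lowest BIC.  Candidates that fail (missing columns,
    non-convergence errors) are recorded in the table with a NaN BIC; if all
    fail, the collected errors are raised together.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate model")
    rows, fits, errors = [], {}, {}
    for fixed in candidates:
        try:
            fit = fit_mixed(records, fixed, value_col, genotype_col, trait)
            fits[fixed] = fit
            rows.append({"fixed": fixed, "bic": fit.bic, "converged": fit.converged})
        except Exception as exc:  # noqa: BLE001 - aggregate and rethrow below
            errors[fixed] = str(exc)
            rows.append({"fixed": fixed, "bic": float("nan"), "converged": False})
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError(f"all candidate models failed: {errors}")
    best = min(fits.values(), key=lambda f: f.bic)
    return best, table


def heritability(sigma_g2: float, sigma_r2: float, n: float) -> float:
    """Broad-sense heritability on a genotype-mean basis:
    H^2 = sigma_G^2 / (sigma_G^2 + sigma_R^2 / n)."""
    if sigma_g2 < 0 or sigma_r2 < 0:
        raise ValueError("variance components must be >= 0")
    if n < 1:
        raise ValueError("n (replicates per genotype) must be >= 1")
    if sigma_g2 == 0 and sigma_r2 == 0:
        raise ValueError("H^2 undefined when both variance components are 0")
    return float(sigma_g2 / (sigma_g2 + sigma_r2 / n))


def genotypic_cv(genetic_values, grand_mean: float | None = None) -> float:
    """Genotypic coefficient of variation: sample SD of genotypic values
    divided by the mean on the trait scale.

    ``genetic_values`` may be BLUP deviations (then ``grand_mean`` must carry
    the intercept) or already on the trait scale (``grand_mean`` omitted).
    """
    v = np.asarray(genetic_values, dtype=float)
    if grand_mean is not None:
        v = v + grand_mean
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    return float(np.std(v, ddof=1) / mean)
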