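"""Environmental distinctness of sectors via multinomial logit models.

For each bioregion (with at least two well-populated sectors), the sector
label of a cell is regressed on environmental covariates with a softmax
(multinomial logistic) model and compared against an intercept-only null.
Evidence of environmentally distinct sectors requires the null's corrected
AIC to exceed the model's by more than 10.  Fit quality is summarized by
McFadden's pseudo-R^2 = 1 - lnL_model / lnL_null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MultinomFit:
    """A fitted multinomial logit (or its intercept-only null)."""

    loglike: float
    n_obs: int
    n_classes: int
    n_params: int
    aicc: float
    pseudo_r2: float
    converged: bool
    coef: np.ndarray | None = None
    row_index: tuple | None = None  # identity of the rows used


def _aicc(loglike: float, k: int, n: int) -> float:
    aic = -2.0 * loglike + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def eligible_regions(
    sector_sizes: pd.DataFrame,
    min_cells: int = 15,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Screen regions for the multinomial analysis.

    ``sector_sizes`` has columns region, sector, n_cells.  A sector is
    retained when it holds strictly more than ``min_cells`` cells; a region
    is eligible when it keeps at least two retained sectors covering at
    least ``min_coverage`` of all its cells.
    Returns columns: region, retained_sectors, coverage, eligible.
    """
    rows = []
    for reg, grp in sector_sizes.groupby("region"):
        total = grp["n_cells"].sum()
        keep = grp[grp["n_cells"] > min_cells]
        coverage = keep["n_cells"].sum() / total if total else 0.0
        eligible = len(keep) >= 2 and coverage >= min_coverage
        rows.append((reg, sorted(keep["sector"].tolist()), float(coverage), bool(eligible)))
    return pd.DataFrame(rows, columns=["region", "retained_sectors", "coverage", "eligible"])


def fit_sector_multinomial(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    null: bool = False,
    maxiter: int = 500,
) -> MultinomFit:
    """Maximum-likelihood softmax regression of sector on covariates.

    ``data`` needs a ``sector`` column plus the covariate columns.
    Covariates are standardized internally (a constant covariate is zeroed
    out, contributing nothing).  The largest sector is the reference class.
    With ``null=True`` an intercept-only model is fitted instead.
    """
    if "sector" not in data.columns:
        raise ValidationError("data needs a 'sector' column")
    classes = data["sector"].value_counts()
    if len(classes) < 2:
        raise ValidationError("need at least 2 sector classes")
    n = len(data)
    # reference class = largest sector: relabel so it gets code 0
    order = list(classes.index)  # sorted by decreasing size
    code = data["sector"].map({s: i for i, s in enumerate(order)}).to_numpy()
    K = len(order)

    if null or not covariates:
        X = np.ones((n, 1))
        p_terms = 1
    else:
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise ValidationError(f"missing covariates: {missing}")
        if data[covariates].isna().any().any():
            raise ValidationError("missing covariate values")
        Z = data[covariates].to_numpy(float)
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (Z - mu) / sd_safe
        Z[:, sd == 0] = 0.0  # constant covariate carries no information
        X = np.column_stack([np.ones(n), Z])
        p_terms = X.shape[1]

    k_params = (K - 1) * p_terms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(code, X)
        try:
            res = model.fit(method="bfgs", maxiter=maxiter, disp=False, gtol=1e-8)
            llf = float(res.llf)
            coef = np.asarray(res.params)
            opt_converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # noqa: BLE001 - surfaced via flag
            logger.warning("multinomial fit failed: %s", exc)
            llf, coef, opt_converged = np.nan, None, False

    converged = bool(np.isfinite(llf))
    # null log-likelihood has a closed form: class frequencies
    freq = classes.to_numpy(float) / n
    llnull = float(n * np.sum(freq * np.log(freq)))
    if null or not covariates:
        llf = llnull if not np.isfinite(llf) else max(llf, llnull)
        coef = None
        converged = True
    elif converged and llf < llnull:
        # the saturated model nests the null; never report a worse likelihood
        llf = llnull
    pseudo_r2 = 1.0 - llf / llnull if converged and llnull != 0 else (0.0 if null else np.nan)
    if null or not covariates:
        pseudo_r2 = 0.0
    return MultinomFit(
        loglike=llf,
        n_obs=n,
        n_classes=K,
        n_params=k_params,
        aicc=_aicc(llf, k_params, n) if converged else np.nan,
        pseudo_r2=float(pseudo_r2) if pseudo_r2 == pseudo_r2 else np.nan,
        converged=converged and opt_converged if not null else True,
        coef=coef,
        row_index=tuple(data.index),
    )


def compare_to_null(
    fit: MultinomFit, null_fit: MultinomFit, threshold: float = 10.0
) -> dict:
    """AICc verdict: significant iff AICc_null - AICc_model > threshold."""
    if fit.row_index != null_fit.row_index:
        raise ValidationError("model and null were fitted on different rows")
    delta = null_fit.aicc - fit.aicc
    return {
        "delta_aicc": float(delta),
        "significant": bool(np.isfinite(delta) and delta > threshold),
        "pseudo_r2": fit.pseudo_r2,
    }


def region_environment_tests(
    assignment: pd.DataFrame,
    env: pd.DataFrame,
    covariates: list[str],
    min_cells: int = 15,
    min_coverage: float = 0.9,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Run the eligibility screen and model comparison for every region.

    ``assignment`` has columns cell_id, region, sector; ``env`` is indexed
    by cell_id.  Returns one row per eligible region with delta AICc,
    pseudo-R^2 and the verdict; ineligible regions appear with a reason.
    """
    sizes = (
        assignment.groupby(["region", "sector"]).size()
        .rename("n_cells").reset_index()
    )
    elig = eligible_regions(sizes, min_cells=min_cells, min_coverage=min_coverage)
    rows = []
    for rec in elig.itertuples(index=False):
        if not rec.eligible:
            rows.append((rec.region, np.nan, np.nan, False, "ineligible region"))
            continue
        sub = assignment[
            (assignment["region"] == rec.region)
            & (assignment["sector"].isin(rec.retained_sectors))
        ]
        data = sub.join(env, on="cell_id")[["sector", *covariates]].dropna()
        data = data.reset_index(drop=True)
        fit = fit_sector_multinomial(data, covariates)
        if not np.isfinite(fit.loglike):
            rows.append((rec.region, np.nan, np.nan, False, "non-convergent fit"))
            logger.info("region %s excluded from summaries: non-convergent", rec.region)
            continue
        null_fit = fit_sector_multinomial(data, covariates, null=True)
        verdict = compare_to_null(fit, null_fit, threshold=threshold)
        rows.append((
            rec.region, verdict["delta_aicc"], verdict["pseudo_r2"],
            verdict["significant"], "",
        ))
    return pd.DataFrame(
        rows, columns=["region", "delta_aicc", "pseudo_r2", "significant", "reason"]
    )
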