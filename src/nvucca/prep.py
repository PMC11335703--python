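"""Neuropsychological score preparation and CCA input-matrix construction.

Raw timed scores are turned into interference scores, "higher = worse"
columns are inverted, scores are transformed to sample-based z-scores, and
optional covariate residualization is applied, yielding the aligned,
standardized matrix pair that enters canonical correlation analysis.

Missing cognitive tests are handled by listwise deletion by default (the
effective n is carried alongside the matrices); mean imputation is available
as an alternative.  Cognitive-domain compound scores average the z-scores of
the tests in a domain, tolerating a single missing test; with more than one
test missing the compound is undefined for that subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import datadict as dd

__all__ = [
    "StandardizedMatrixPair",
    "tmt_interference",
    "scwt_interference",
    "invert_scores",
    "zscore",
    "domain_composite",
    "residualize",
    "build_matrices",
]


@dataclass(frozen=True)
class StandardizedMatrixPair:
    """Aligned, complete, column-standardized CCA inputs."""

    X: np.ndarray
    Y: np.ndarray
    x_names: list[str]
    y_names: list[str]
    n_effective: int
    subject_ids: list[str] | None = None


def _check_positive(*args) -> None:
    for a in args:
        arr = np.asarray(a, dtype=float)
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError("timed scores must be positive")


def tmt_interference(time_b, time_a):
    """Trail Making Test interference: time of part B minus time of part A."""
    _check_positive(time_b, time_a)
    return np.asarray(time_b, dtype=float) - np.asarray(time_a, dtype=float) \
        if np.ndim(time_b) else float(time_b) - float(time_a)


def scwt_interference(time_3, time_1, time_2):
    """Stroop interference: time of part 3 minus the mean of parts 1 and 2."""
    _check_positive(time_3, time_1, time_2)
    t3 = np.asarray(time_3, dtype=float)
    t12 = (np.asarray(time_1, dtype=float) + np.asarray(time_2, dtype=float)) / 2.0
    out = t3 - t12
    return out if np.ndim(time_3) else float(out)


def invert_scores(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Negate the columns where a higher raw score means worse performance.

    Default column list: TMT interference, SCWT interference, TMT A,
    SCWT I, SCWT II.  Returns a new table; applying twice is the identity.
    """
    cols = dd.INVERTED_VARS if columns is None else list(columns)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"unknown columns: {missing}")
    out = table.copy()
    out[cols] = -out[cols]
    return out


def zscore(values) -> np.ndarray:
    """Sample-based z-scores, skipping missing entries.

    Uses the n-1 (sample) SD denominator; missing entries stay missing.
    """
    v = np.asarray(values, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size < 2:
        raise ValueError("need at least 2 observed values")
    sd = obs.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero variance: z-scores undefined")
    return (v - obs.mean()) / sd


def domain_composite(
    z_table: pd.DataFrame,
    domain_map: dict[str, str] | None = None,
    max_missing: int = 1,
) -> pd.DataFrame:
    """Cognitive-domain compound scores from per-test z-scores.

    Per subject and domain, the mean of the available test z-scores; with at
    most ``max_missing`` tests missing the remaining tests are averaged, with
    more the compound is NaN (no reliable domain score).
    """
    dmap = dd.DOMAIN_MAP if domain_map is None else domain_map
    unmapped = [c for c in z_table.columns if c not in dmap]
    if unmapped:
        raise KeyError(f"tests not covered by domain map: {unmapped}")
    domains: dict[str, list[str]] = {}
    for test, domain in dmap.items():
        if test in z_table.columns:
            domains.setdefault(domain, []).append(test)
    out = pd.DataFrame(index=z_table.index)
    for domain, tests in domains.items():
        block = z_table[tests]
        n_missing = block.isna().sum(axis=1)
        comp = block.mean(axis=1, skipna=True)
        comp[n_missing > max_missing] = np.nan
        out[domain] = comp
    return out


def residualize(
    table: pd.DataFrame,
    covariate_names: list[str],
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Replace each analysis variable by its OLS residual on the covariates.

    Each listed column is regressed on an intercept plus ``covariate_names``
    (ordinary least squares, fitted on its non-missing rows); the fitted
    values are subtracted.  With an empty covariate list this mean-centres
    the columns.  Residuals are re-standardized downstream.
    """
    cols = columns if columns is not None else [
        c for c in dd.NVU_VARS + dd.COG_VARS if c in table.columns
    ]
    out = table.copy()
    design_cols = list(covariate_names)
    Z = table[design_cols].to_numpy(dtype=float) if design_cols else np.empty((len(table), 0))
    if np.isnan(Z).any():
        raise ValueError("covariates must be complete")
    design = sm.add_constant(Z, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design matrix")
    for c in cols:
        y = table[c].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        fit = sm.OLS(y[obs], design[obs]).fit()
        resid = np.full_like(y, np.nan)
        resid[obs] = fit.resid
        out[c] = resid
    return out


def build_matrices(
    table: pd.DataFrame,
    mode: str = "tests13",
    adjust: list[str] | None = None,
    missing: str = "listwise",
) -> StandardizedMatrixPair:
    """Assemble the standardized (X, Y) pair that enters CCA.

    Steps, in order: drop artefact-flagged subjects; optional covariate
    residualization; for ``mode='domains3'``, per-test z-scoring followed by
    domain compounding; missing-data rule (listwise deletion or mean
    imputation); z-scoring of every retained column.

    Parameters
    ----------
    table : prepared cohort (interference computed, inversion applied).
    mode : "tests13" (13 individual tests) or "domains3" (3 domain scores).
    adjust : covariate names to residualize on, or None/[] for unadjusted.
    missing : "listwise" or "mean_impute".
    """
    if mode not in ("tests13", "domains3"):
        raise ValueError("mode must be 'tests13' or 'domains3'")
    if missing not in ("listwise", "mean_impute"):
        raise ValueError("missing must be 'listwise' or 'mean_impute'")

    df = table.copy()
    if "excluded" in df.columns:
        df = df.loc[df["excluded"] == 0].copy()

    if adjust:
        df = residualize(df, list(adjust))

    x_names = list(dd.NVU_VARS)
    if mode == "tests13":
        y_names = list(dd.COG_VARS)
        ydf = df[y_names]
    else:
        z = pd.DataFrame(
            {c: zscore(df[c].to_numpy()) for c in dd.COG_VARS}, index=df.index
        )
        ydf = domain_composite(z)
        y_names = list(ydf.columns)

    frame = pd.concat([df[["subject_id"]], df[x_names], ydf], axis=1)
    if missing == "mean_impute":
        for c in x_names + y_names:
            frame[c] = frame[c].fillna(frame[c].mean())
    frame = frame.dropna(subset=x_names + y_names)

    n_eff = len(frame)
    if n_eff <= len(x_names) + len(y_names):
        raise ValueError(
            f"only {n_eff} complete subjects for {len(x_names) + len(y_names)} "
            "variables: CCA is ill-posed"
        )
    X = np.column_stack([zscore(frame[c].to_numpy()) for c in x_names])
    Y = np.column_stack([zscore(frame[c].to_numpy()) for c in y_names])
    return StandardizedMatrixPair(
        X=X, Y=Y, x_names=x_names, y_names=y_names,
        n_effective=n_eff, subject_ids=frame["subject_id"].tolist(),
    )
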