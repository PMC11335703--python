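"""End-to-end analysis pipeline: cohort -> prepared matrices -> CCA -> report.

A :class:`RunConfig` (loadable from YAML or JSON) fully determines a run:
input source (a cohort CSV or the synthetic generator), ROI, cognition mode
(13 tests or 3 domain scores), covariate-adjustment set, permutation count
and seed.  :func:`run_pipeline` executes preparation, CCA and permutation
inference, writes a JSON report plus a loadings TSV, and logs subject counts
at every filtering step.  Identical config + seed reproduces the report
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import datadict as dd
from .cca import CanonicalCorrelation
from .prep import build_matrices, invert_scores
from .simulate import LatentStructureSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_cohort_csv"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    source: str = "synthetic"            # "synthetic" or a cohort CSV path
    latent_spec: dict = field(default_factory=dict)  # LatentStructureSpec overrides
    roi: str = "nawm"                    # "nawm" | "wmh"
    cognition_mode: str = "tests13"      # "tests13" | "domains3"
    adjustment: str = "none"             # key of datadict.ADJUSTMENT_SETS
    missing: str = "listwise"            # "listwise" | "mean_impute"
    n_permutations: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.roi not in ("nawm", "wmh"):
            raise ValueError(f"roi must be 'nawm' or 'wmh', got {self.roi!r}")
        if self.cognition_mode not in ("tests13", "domains3"):
            raise ValueError("cognition_mode must be 'tests13' or 'domains3'")
        if self.adjustment not in dd.ADJUSTMENT_SETS:
            raise ValueError(
                f"adjustment must be one of {sorted(dd.ADJUSTMENT_SETS)}"
            )
        if self.missing not in ("listwise", "mean_impute"):
            raise ValueError("missing must be 'listwise' or 'mean_impute'")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.source != "synthetic" and not Path(self.source).exists():
            raise FileNotFoundError(self.source)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV and check the documented schema."""
    df = pd.read_csv(path)
    required = ["subject_id"] + dd.NVU_VARS + dd.COG_VARS + dd.COVARIATES + ["excluded"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("subject_id must be unique")
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``; return the report."""
    config.validate()

    if config.source == "synthetic":
        spec = LatentStructureSpec(
            **{"roi": config.roi, "seed": config.seed, **config.latent_spec}
        )
        table, _truth = generate_cohort(spec)
        logger.info("generated synthetic cohort: %d subjects", len(table))
    else:
        table = load_cohort_csv(config.source)
        logger.info("loaded cohort %s: %d subjects", config.source, len(table))

    n_total = len(table)
    n_excluded = int(table["excluded"].sum())
    logger.info("artefact exclusions: %d of %d flagged", n_excluded, n_total)

    prepared = invert_scores(table)
    covariates = dd.ADJUSTMENT_SETS[config.adjustment]
    pair = build_matrices(
        prepared,
        mode=config.cognition_mode,
        adjust=covariates,
        missing=config.missing,
    )
    logger.info(
        "prepared matrices: n_effective=%d, X %s, Y %s",
        pair.n_effective, pair.X.shape, pair.Y.shape,
    )

    model = CanonicalCorrelation(
        pair.X, pair.Y, x_names=pair.x_names, y_names=pair.y_names
    )
    results = model.fit()
    perm = results.permutation_test(
        n_permutations=config.n_permutations, seed=config.seed
    )
    logger.info(
        "CCA: %d modes, r1=%.3f, p1=%.4f",
        results.n_modes, results.r[0], perm.p_values[0],
    )

    report = {
        "settings": {
            "source": config.source,
            "roi": config.roi,
            "cognition_mode": config.cognition_mode,
            "adjustment": config.adjustment,
            "missing": config.missing,
            "n_permutations": config.n_permutations,
            "seed": config.seed,
        },
        "counts": {
            "n_input": n_total,
            "n_excluded": n_excluded,
            "n_effective": pair.n_effective,
        },
        "cca": results.to_dict(),
    }
    _check_identities(report["cca"])

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        results.loadings_frame().to_csv(out / "loadings.tsv", sep="\t", index=False)
        logger.info("report written to %s", out)
    return report


def _check_identities(cca: dict, tol: float = 1e-10) -> None:
    """Internal consistency of the reported quantities, checked at write time."""
    r = cca["canonical_correlations"]
    for k, (rk, sv) in enumerate(zip(r, cca["shared_variance"])):
        if abs(sv - rk**2) > tol:
            raise AssertionError(f"shared variance identity violated at mode {k + 1}")
    for which in ("x_given_y", "y_given_x"):
        ve = cca[f"variance_extracted_{which[0]}"]
        rd = cca[f"redundancy_{which}"]
        for k in range(len(r)):
            if abs(rd[k] - ve[k] * r[k] ** 2) > tol:
                raise AssertionError(f"redundancy identity violated at mode {k + 1}")
        total = cca[f"total_redundancy_{which[0]}"]
        if abs(total - sum(rd)) > tol:
            raise AssertionError("total redundancy is not the sum over modes")
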