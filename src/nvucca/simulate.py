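"""Synthetic cohorts and ground-truth MRI signal curves.

The cohort generator plants a known latent structure between the five
neurovascular-unit (NVU) measures and the thirteen cognitive test scores so
that the canonical correlations of the *population* generating process equal
a requested vector ``rho`` exactly.  Construction: with within-set
covariances ``Sxx = Lx Lx' + diag(noise_x^2)`` (likewise ``Syy``), the
latent-to-observed loading matrices are whitened and orthonormalised to
``Qx, Qy`` and the cross-covariance is set to

    Sxy = Sxx^{1/2} Qx diag(rho) Qy' Syy^{1/2},

so ``Sxx^{-1/2} Sxy Syy^{-1/2} = Qx diag(rho) Qy'`` has singular values
``rho`` by construction.  Subjects are drawn jointly Gaussian from the full
covariance and rescaled column-wise to the requested marginal moments (a
diagonal transform, which leaves canonical correlations untouched).

Raw-score orientation is preserved: timed tests (TMT, Stroop) are generated
on their natural "higher = slower = worse" scale; sign flips during
preparation do not change canonical correlations.

Signal-level generators produce Patlak-kinetics DCE concentration curves and
triexponential IVIM decay curves with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from . import datadict as dd
from ._linalg import polar_orthonormal, sym_inv_sqrt, sym_sqrt
from .mri import ConcentrationCurve, DWSignal, ivim_signal

__all__ = [
    "LatentStructureSpec",
    "SyntheticTruth",
    "DCESimSpec",
    "IVIMSimSpec",
    "PROTOCOL_BVALUES",
    "generate_cohort",
    "sample_latent_pair",
    "simulate_dce_curve",
    "simulate_ivim_signal",
    "default_loadings",
]

#: The 15-point diffusion-weighting scheme (s/mm^2) of the reference protocol.
PROTOCOL_BVALUES: tuple[float, ...] = (
    0, 5, 7, 10, 15, 20, 30, 40, 50, 60, 100, 200, 400, 700, 1000,
)


def default_loadings(K: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Default latent-to-observed loading matrices (NVU p=5, cognition q=13).

    NVU: one common factor with equal loadings on all five measures.
    Cognition: a general factor on every test plus three domain factors
    (memory / executive / speed) carrying within-domain correlation only.
    """
    p, q = len(dd.NVU_VARS), len(dd.COG_VARS)
    Lx = np.zeros((p, K))
    Lx[:, 0] = dd.NVU_G_LOADING
    Ly = np.zeros((q, K))
    Ly[:, 0] = dd.COG_G_LOADING
    for d, domain in enumerate(dd.DOMAINS):
        col = d + 1
        if col >= K:
            break
        for j, test in enumerate(dd.COG_VARS):
            if dd.DOMAIN_MAP[test] == domain:
                Ly[j, col] = dd.COG_DOMAIN_LOADING
    return Lx, Ly


@dataclass
class LatentStructureSpec:
    """Specification of a synthetic cohort with planted canonical structure.

    Defaults reproduce the reference study conditions: 80 recruited subjects
    of whom 7 carry an artefact-exclusion flag, a first canonical correlation
    of 0.73 between the NVU and cognition sets, marginal moments from the
    reference cohort table, and sporadic missing cognitive tests.
    """

    n_subjects: int = 80
    rho: tuple[float, ...] = dd.DEFAULT_RHO
    loadings_x: np.ndarray | None = None
    loadings_y: np.ndarray | None = None
    noise_sd_x: np.ndarray | None = None
    noise_sd_y: np.ndarray | None = None
    marginal_means: dict[str, float] | None = None
    marginal_sds: dict[str, float] | None = None
    roi: str = "nawm"
    missing_rate: float = 0.01
    n_excluded: int = 7
    seed: int = 0

    def resolve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Validate and return (rho, Lx, Ly, noise_sd_x, noise_sd_y)."""
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 1 or rho.size == 0:
            raise ValueError("rho must be a non-empty vector")
        if np.any(rho < 0) or np.any(rho >= 1):
            raise ValueError("all rho must lie in [0, 1)")
        if np.any(np.diff(rho) > 1e-12):
            raise ValueError("rho must be non-increasing")
        K = rho.size
        Lx, Ly = self.loadings_x, self.loadings_y
        if Lx is None or Ly is None:
            dLx, dLy = default_loadings(K)
            Lx = dLx if Lx is None else np.asarray(Lx, dtype=float)
            Ly = dLy if Ly is None else np.asarray(Ly, dtype=float)
        else:
            Lx = np.asarray(Lx, dtype=float)
            Ly = np.asarray(Ly, dtype=float)
        if Lx.shape[1] != K or Ly.shape[1] != K:
            raise ValueError("loadings must have one column per planted mode")
        if K > min(Lx.shape[0], Ly.shape[0]):
            raise ValueError("more planted modes than min(p, q)")

        def _noise(ns, L, label):
            if ns is None:
                resid = 1.0 - np.sum(L**2, axis=1)
                if np.any(resid <= 0):
                    raise ValueError(f"{label} loadings imply non-positive residual variance")
                return np.sqrt(resid)
            ns = np.asarray(ns, dtype=float)
            if ns.shape != (L.shape[0],) or np.any(ns <= 0):
                raise ValueError(f"{label} noise SDs must be positive, one per variable")
            return ns

        nsx = _noise(self.noise_sd_x, Lx, "X")
        nsy = _noise(self.noise_sd_y, Ly, "Y")
        if not 0 <= self.n_excluded <= self.n_subjects:
            raise ValueError("n_excluded must lie in [0, n_subjects]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.roi not in dd.NVU_MARGINALS:
            raise ValueError(f"unknown roi {self.roi!r}")
        return rho, Lx, Ly, nsx, nsy


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted in a generated cohort."""

    rho: np.ndarray                    # planted canonical correlations
    loadings_x: np.ndarray             # population X loadings (corr with variate)
    loadings_y: np.ndarray             # population Y loadings
    mri_params: pd.DataFrame           # per-subject natural-unit MRI truth

    def to_json(self, path) -> None:
        import json

        payload = {
            "rho": self.rho.tolist(),
            "loadings_x": self.loadings_x.tolist(),
            "loadings_y": self.loadings_y.tolist(),
            "mri_params": self.mri_params.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _population_blocks(rho, Lx, Ly, nsx, nsy):
    """Full joint covariance with exact planted canonical correlations."""
    Sxx = Lx @ Lx.T + np.diag(nsx**2)
    Syy = Ly @ Ly.T + np.diag(nsy**2)
    Qx = polar_orthonormal(sym_inv_sqrt(Sxx) @ Lx)
    Qy = polar_orthonormal(sym_inv_sqrt(Syy) @ Ly)
    Sxy = sym_sqrt(Sxx) @ Qx @ np.diag(rho) @ Qy.T @ sym_sqrt(Syy)
    return Sxx, Syy, Sxy, Qx, Qy


def sample_latent_pair(
    n: int,
    rho,
    Lx: np.ndarray,
    Ly: np.ndarray,
    noise_sd_x: np.ndarray,
    noise_sd_y: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Y) from the planted-structure Gaussian, unit-diagonal scale.

    The population canonical correlations between X and Y equal ``rho``
    exactly; each column is standardised to population mean 0, SD 1.
    """
    rho = np.asarray(rho, dtype=float)
    p, q = Lx.shape[0], Ly.shape[0]
    Sxx, Syy, Sxy, _, _ = _population_blocks(rho, Lx, Ly, noise_sd_x, noise_sd_y)
    Sigma = np.block([[Sxx, Sxy], [Sxy.T, Syy]])
    Z = rng.multivariate_normal(np.zeros(p + q), Sigma, size=n, method="eigh")
    Z /= np.sqrt(np.diag(Sigma))
    return Z[:, :p], Z[:, p:]


def population_loadings(rho, Lx, Ly, nsx, nsy) -> tuple[np.ndarray, np.ndarray]:
    """Population canonical loadings implied by a planted structure."""
    Sxx, Syy, _, Qx, Qy = _population_blocks(
        np.asarray(rho, float), Lx, Ly, nsx, nsy
    )
    Lpop_x = (sym_sqrt(Sxx) @ Qx) / np.sqrt(np.diag(Sxx))[:, None]
    Lpop_y = (sym_sqrt(Syy) @ Qy) / np.sqrt(np.diag(Syy))[:, None]
    return Lpop_x, Lpop_y


def generate_cohort(spec: LatentStructureSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a subject-level cohort table plus its planted ground truth.

    Returns a DataFrame with columns ``subject_id``, the five NVU measures,
    the thirteen cognitive test scores (raw orientation, sporadically
    missing), the five covariates, and an ``excluded`` artefact flag; and a
    :class:`SyntheticTruth` carrying the planted canonical structure and the
    per-subject natural-unit MRI parameters.
    """
    rho, Lx, Ly, nsx, nsy = spec.resolve()
    if Lx.shape[0] != len(dd.NVU_VARS) or Ly.shape[0] != len(dd.COG_VARS):
        raise ValueError(
            "cohort generation requires p=5 NVU and q=13 cognitive variables; "
            "use sample_latent_pair for other shapes"
        )
    n = spec.n_subjects
    rng = np.random.default_rng(spec.seed)

    X, Y = sample_latent_pair(n, rho, Lx, Ly, nsx, nsy, rng)

    means = dict(dd.NVU_MARGINALS[spec.roi])
    means.update(dd.COG_MARGINALS)
    if spec.marginal_means:
        for k, v in spec.marginal_means.items():
            means[k] = (v, means[k][1])
    if spec.marginal_sds:
        for k, v in spec.marginal_sds.items():
            means[k] = (means[k][0], v)

    table = pd.DataFrame({"subject_id": [f"S{i:03d}" for i in range(1, n + 1)]})
    for j, name in enumerate(dd.NVU_VARS):
        mu, sd = means[name]
        table[name] = mu + sd * X[:, j]
    for j, name in enumerate(dd.COG_VARS):
        mu, sd = means[name]
        table[name] = mu + sd * Y[:, j]

    # Covariates: drawn independently of the planted structure, so covariate
    # adjustment is a no-op in expectation (the robustness setting emulated).
    cp = dd.COVARIATE_PARAMS
    table["age"] = cp["age"]["mean"] + cp["age"]["sd"] * rng.standard_normal(n)
    table["sex"] = (rng.random(n) < cp["sex"]["p_female"]).astype(int)
    edu = np.rint(cp["education"]["mean"] + cp["education"]["sd"] * rng.standard_normal(n))
    table["education"] = np.clip(edu, cp["education"]["lo"], cp["education"]["hi"]).astype(int)
    table["rel_brain_vol"] = (
        cp["rel_brain_vol"]["mean"] + cp["rel_brain_vol"]["sd"] * rng.standard_normal(n)
    )
    table["rel_wmh_vol"] = np.exp(
        cp["rel_wmh_vol"]["log_median"] + cp["rel_wmh_vol"]["log_sd"] * rng.standard_normal(n)
    )

    # Sporadic missing cognitive tests (completely at random).
    if spec.missing_rate > 0:
        miss = rng.random((n, len(dd.COG_VARS))) < spec.missing_rate
        for j, name in enumerate(dd.COG_VARS):
            table.loc[miss[:, j], name] = np.nan

    table["excluded"] = 0
    if spec.n_excluded:
        flagged = rng.choice(n, size=spec.n_excluded, replace=False)
        table.loc[flagged, "excluded"] = 1

    # Natural-unit MRI ground truth per subject (reporting-scale -> SI-ish).
    mri = pd.DataFrame(
        {
            "Ki": table["ki"].to_numpy() * 1e-4,       # min^-1
            "vp": np.full(n, 0.01),
            "f": table["f"].to_numpy() / 100.0,
            "Dstar": table["dstar"].to_numpy() * 1e-2,  # mm^2/s
            "f_int": table["f_int"].to_numpy() / 100.0,
            "D_int": np.full(n, 2.5e-3),
            "D_par": np.full(n, 0.7e-3),
        },
        index=table.index,
    )
    Lpx, Lpy = population_loadings(rho, Lx, Ly, nsx, nsy)
    truth = SyntheticTruth(rho=rho, loadings_x=Lpx, loadings_y=Lpy, mri_params=mri)
    return table, truth


# ---------------------------------------------------------------------------
# DCE simulation
# ---------------------------------------------------------------------------

def _default_times() -> np.ndarray:
    return np.linspace(0.0, 25.0, 126)  # minutes, 12 s sampling


#: Parametric vascular input function: gamma-style saturating rise at bolus
#: arrival multiplied by a biexponential washout.  Amplitude in mM, times in
#: minutes.
DEFAULT_VIF_PARAMS: dict[str, float] = {
    "amplitude": 6.0,
    "arrival_time": 0.5,
    "rise_time": 0.15,
    "frac_fast": 0.6,
    "decay_fast": 1.5,
    "decay_slow": 0.03,
}


def vascular_input_function(t: np.ndarray, params: dict[str, float] | None = None) -> np.ndarray:
    p = dict(DEFAULT_VIF_PARAMS)
    if params:
        p.update(params)
    t = np.asarray(t, dtype=float)
    dt = t - p["arrival_time"]
    rise = np.where(dt > 0, 1.0 - np.exp(-np.clip(dt, 0, None) / p["rise_time"]), 0.0)
    washout = p["frac_fast"] * np.exp(-p["decay_fast"] * np.clip(dt, 0, None)) + (
        1.0 - p["frac_fast"]
    ) * np.exp(-p["decay_slow"] * np.clip(dt, 0, None))
    return p["amplitude"] * rise * washout


@dataclass
class DCESimSpec:
    """Ground-truth Patlak kinetics for one voxel/ROI concentration curve."""

    times: np.ndarray = field(default_factory=_default_times)   # minutes
    vif_params: dict[str, float] | None = None
    Ki: float = 3.3e-4       # min^-1
    vp: float = 0.01
    noise_sd: float = 0.0    # mM, additive Gaussian on Ct
    seed: int | None = None

    def validate(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 3 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 3 samples")
        if self.Ki < 0:
            raise ValueError("Ki must be non-negative")
        if not 0.0 <= self.vp < 1.0:
            raise ValueError("vp must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_dce_curve(spec: DCESimSpec) -> ConcentrationCurve:
    """Simulate a tissue concentration curve under Patlak kinetics.

    ``Ct(t) = vp*Cp(t) + Ki * integral_0^t Cp`` (trapezoid rule), plus
    optional additive Gaussian noise.
    """
    spec.validate()
    t = np.asarray(spec.times, dtype=float)
    cp = vascular_input_function(t, spec.vif_params)
    ct = spec.vp * cp + spec.Ki * cumulative_trapezoid(cp, t, initial=0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ct = ct + spec.noise_sd * rng.standard_normal(t.size)
    return ConcentrationCurve(t=t, Ct=ct, Cp=cp)


# ---------------------------------------------------------------------------
# IVIM simulation
# ---------------------------------------------------------------------------

@dataclass
class IVIMSimSpec:
    """Ground-truth three-component IVIM decay for one voxel/ROI.

    Defaults are normal-appearing white matter magnitudes: perfusion volume
    fraction 1.1%, intermediate volume fraction 9.3%, microvascular
    diffusivity 0.10 mm^2/s.
    """

    bvalues: tuple[float, ...] = PROTOCOL_BVALUES     # s/mm^2
    f: float = 0.011
    f_int: float = 0.093
    Dstar: float = 0.10      # mm^2/s
    D_int: float = 2.5e-3    # mm^2/s
    D_par: float = 0.7e-3    # mm^2/s
    S0: float = 1.0
    snr: float = np.inf      # signal-to-noise at b=0; inf = noiseless
    noise_model: str = "gaussian"   # or "rician"
    seed: int | None = None

    def validate(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if np.any(b < 0) or 0.0 not in b:
            raise ValueError("b-values must be non-negative and include 0")
        if self.f < 0 or self.f_int < 0 or self.f + self.f_int >= 1:
            raise ValueError("need f >= 0, f_int >= 0, f + f_int < 1")
        if not self.Dstar > self.D_int > self.D_par > 0:
            raise ValueError("diffusivity ordering Dstar > D_int > D_par > 0 violated")
        if self.S0 <= 0 or self.snr <= 0:
            raise ValueError("S0 and snr must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def simulate_ivim_signal(spec: IVIMSimSpec) -> DWSignal:
    """Simulate a triexponential diffusion-weighted decay curve."""
    spec.validate()
    b = np.asarray(spec.bvalues, dtype=float)
    s = ivim_signal(b, spec.S0, spec.f, spec.f_int, spec.Dstar, spec.D_int, spec.D_par)
    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = spec.S0 / spec.snr
        if spec.noise_model == "rician":
            s = np.sqrt(
                (s + sigma * rng.standard_normal(b.size)) ** 2
                + (sigma * rng.standard_normal(b.size)) ** 2
            )
        else:
            s = s + sigma * rng.standard_normal(b.size)
    return DWSignal(b=b, S=s)
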