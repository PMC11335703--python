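"""Quantitative-MRI parameter estimation for neurovascular-unit function.

Three estimators operate on per-voxel (or per-ROI) signal curves:

* :func:`patlak_fit` — graphical Patlak analysis of dynamic contrast-enhanced
  (DCE) concentration-time curves, yielding the blood-brain-barrier leakage
  rate ``Ki`` (min^-1) and the plasma volume fraction ``vp``.
* :func:`leakage_volume` — histogram method: the fraction of voxels whose Ki
  exceeds a noise threshold estimated from the mirrored negative-Ki tail.
* :func:`fit_ivim_3c` — three-component intravoxel-incoherent-motion (IVIM)
  fit of diffusion-weighted decay curves, separating microvascular
  pseudo-diffusion (``f``, ``D*``), an intermediate interstitial/perivascular
  compartment (``f_int``, ``D_int``) and parenchymal diffusion (``D_par``).

ROI summaries use :func:`roi_mean`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "ConcentrationCurve",
    "DWSignal",
    "PatlakFit",
    "LeakageVolume",
    "IVIMFit",
    "patlak_fit",
    "leakage_volume",
    "fit_ivim_3c",
    "roi_mean",
    "ivim_signal",
    "IVIM_BOUNDS",
]


# ---------------------------------------------------------------------------
# Signal containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationCurve:
    """Paired tissue/plasma concentration-time curves from DCE-MRI.

    Attributes
    ----------
    t : time in minutes, strictly increasing.
    Ct : tissue contrast-agent concentration (mM).
    Cp : plasma concentration (mM), the vascular input function.
    """

    t: np.ndarray
    Ct: np.ndarray
    Cp: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "Ct", "Cp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.Ct.shape == self.Cp.shape):
            raise ValueError("t, Ct, Cp must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "Ct": self.Ct, "Cp": self.Cp}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationCurve":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["Ct"].to_numpy(), df["Cp"].to_numpy())


@dataclass(frozen=True)
class DWSignal:
    """Diffusion-weighted signal versus b-value (s/mm^2)."""

    b: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        if self.b.shape != self.S.shape:
            raise ValueError("b and S must have equal lengths")
        if np.any(self.b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(self.S <= 0):
            raise ValueError("signal must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"b": self.b, "S": self.S}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DWSignal":
        df = pd.read_csv(path)
        return cls(df["b"].to_numpy(), df["S"].to_numpy())


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatlakFit:
    Ki: float          # leakage rate, min^-1
    vp: float          # plasma volume fraction (intercept)
    fit_r2: float      # R^2 of the Patlak-space linear fit

    def __post_init__(self) -> None:
        if not -1e-12 <= self.fit_r2 <= 1 + 1e-12:
            raise ValueError("fit_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class LeakageVolume:
    VL: float          # fraction of leaking voxels, in [0, 1]
    threshold: float   # Ki cut-off used (min^-1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.VL <= 1.0:
            raise ValueError("VL must lie in [0, 1]")


@dataclass(frozen=True)
class IVIMFit:
    f: float
    f_int: float
    Dstar: float       # mm^2/s
    D_int: float       # mm^2/s
    D_par: float       # mm^2/s
    S0: float
    converged: bool
    rss: float


# ---------------------------------------------------------------------------
# Patlak
# ---------------------------------------------------------------------------

_CP_TOL = 1e-12  # plasma concentrations at or below this are unusable


def patlak_fit(curve: ConcentrationCurve, fit_window: slice | np.ndarray | None = None) -> PatlakFit:
    """Graphical Patlak analysis of a DCE concentration-time curve.

    Regresses ``Ct/Cp`` on the normalised cumulative plasma exposure
    ``(integral of Cp)/Cp`` by ordinary least squares; the slope is the
    leakage rate ``Ki`` (min^-1) and the intercept the plasma volume
    fraction ``vp``.  The cumulative integral uses the trapezoid rule, and
    the fit window should exclude the early bolus phase where the Patlak
    quasi-equilibrium assumption fails.

    Parameters
    ----------
    curve : ConcentrationCurve
    fit_window : slice, index array, or None
        Samples to fit; default is all samples with ``Cp > 0``.
    """
    t, Ct, Cp = curve.t, curve.Ct, curve.Cp
    cum_cp = cumulative_trapezoid(Cp, t, initial=0.0)

    idx = np.arange(t.size)
    if fit_window is not None:
        idx = idx[fit_window]
    usable = idx[Cp[idx] > _CP_TOL]
    if len(usable) < len(idx):
        raise ValueError("Cp must be positive throughout the fit window")
    if len(usable) < 3:
        raise ValueError("need at least 3 usable points for a Patlak fit")

    x = cum_cp[usable] / Cp[usable]
    y = Ct[usable] / Cp[usable]
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)

    resid = y - design @ np.array([slope, intercept])
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 1e-30 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return PatlakFit(Ki=float(slope), vp=float(intercept), fit_r2=r2)


# ---------------------------------------------------------------------------
# Histogram leakage volume
# ---------------------------------------------------------------------------

def leakage_volume(
    ki_values: np.ndarray,
    quantile: float = 0.95,
    on_no_noise: str = "error",
) -> LeakageVolume:
    """Fraction of voxels with detectable leakage (histogram method).

    Negative Patlak slopes can only arise from noise; mirroring them about
    zero gives an estimate of the symmetric noise distribution.  The
    threshold is the ``quantile`` (default 0.95) of that distribution and
    ``VL`` is the fraction of voxels whose Ki exceeds it.

    Parameters
    ----------
    ki_values : voxel-wise Ki estimates (min^-1).
    quantile : upper quantile of the mirrored-noise distribution.
    on_no_noise : {"error", "zero_threshold"}
        Behaviour when no negative Ki exists to estimate noise from:
        raise, or count every strictly positive voxel (threshold 0).
    """
    ki = np.asarray(ki_values, dtype=float).ravel()
    if ki.size == 0:
        raise ValueError("empty Ki vector")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    neg = ki[ki < 0]
    if neg.size == ki.size:
        raise ValueError("all Ki negative: input looks inverted")
    if neg.size == 0:
        if on_no_noise == "zero_threshold":
            thr = 0.0
        else:
            raise ValueError(
                "no negative Ki values to estimate the noise distribution from; "
                "pass on_no_noise='zero_threshold' to count all positive voxels"
            )
    else:
        mirrored = np.concatenate([neg, -neg])
        thr = float(np.quantile(mirrored, quantile))
    vl = float(np.mean(ki > thr))
    return LeakageVolume(VL=vl, threshold=thr)


# ---------------------------------------------------------------------------
# Three-component IVIM
# ---------------------------------------------------------------------------

#: Default parameter box (lower, upper) per parameter; the non-overlapping
#: diffusivity boxes enforce the compartment ordering D* >= D_int >= D_par.
IVIM_BOUNDS: dict[str, tuple[float, float]] = {
    "S0": (0.5, 1.5),
    "f": (0.0, 0.3),
    "f_int": (0.0, 0.5),
    "Dstar": (5e-3, 1.0),       # mm^2/s
    "D_int": (1.5e-3, 5e-3),    # mm^2/s
    "D_par": (1e-4, 1.5e-3),    # mm^2/s
}

_IVIM_ORDER = ["S0", "f", "f_int", "Dstar", "D_int", "D_par"]


def ivim_signal(b, S0, f, f_int, Dstar, D_int, D_par) -> np.ndarray:
    """Triexponential IVIM model: normalised signal at b-values ``b``."""
    b = np.asarray(b, dtype=float)
    return S0 * (
        f * np.exp(-b * Dstar)
        + f_int * np.exp(-b * D_int)
        + (1.0 - f - f_int) * np.exp(-b * D_par)
    )


def fit_ivim_3c(
    signal: DWSignal,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 10,
    seed: int | None = 0,
) -> IVIMFit:
    """Constrained multi-start nonlinear least-squares fit of the 3C-IVIM model.

    Starts are drawn from a Latin hypercube inside the parameter box (the
    midpoint is always included); the solution with the lowest residual sum
    of squares is returned.  Identical seed implies an identical fit.
    """
    b, S = signal.b, signal.S
    if 0.0 not in b:
        raise ValueError("b=0 must be acquired to anchor S0")
    if np.unique(b).size < 7:
        raise ValueError("need at least 7 distinct b-values")
    box = dict(IVIM_BOUNDS)
    if bounds:
        box.update(bounds)
    lo = np.array([box[k][0] for k in _IVIM_ORDER])
    hi = np.array([box[k][1] for k in _IVIM_ORDER])

    s0_obs = float(S[b == 0].mean())
    S_norm = S / s0_obs  # fit in normalised units; rescale S0 afterwards

    def residuals(theta):
        return ivim_signal(b, *theta) - S_norm

    starts = [0.5 * (lo + hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(_IVIM_ORDER), seed=seed)
        unit = sampler.random(n=n_starts - 1)
        starts.extend(lo + unit * (hi - lo))

    best = None
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                x_scale=np.maximum(hi - lo, 1e-12), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        any_success = any_success or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))
    if best is None:
        raise RuntimeError("IVIM fit failed from every start")

    rss, theta, _ = best
    s0, f, f_int, dstar, d_int, d_par = theta
    return IVIMFit(
        f=float(f), f_int=float(f_int), Dstar=float(dstar),
        D_int=float(d_int), D_par=float(d_par), S0=float(s0 * s0_obs),
        converged=any_success, rss=rss,
    )


# ---------------------------------------------------------------------------
# ROI summary
# ---------------------------------------------------------------------------

def roi_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``values`` over the voxels selected by ``mask``."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must have equal lengths")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    return float(values[mask].mean())
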