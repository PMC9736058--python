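"""Spectrophotometric pKa determination by sigmoidal titration fitting.

Absorbance at a fixed wavelength is recorded across a series of buffered pH
values; as the compound deprotonates, absorbance moves between an acid-form
plateau and a base-form plateau. Under a single deprotonation with Hill
slope 1 the curve is the Henderson-Hasselbalch sigmoid

    A(pH) = A_acid + (A_base - A_acid) * 10^(pH - pKa) / (1 + 10^(pH - pKa))

whose inflection point is the pKa. :func:`fit_pka` performs unweighted
nonlinear least squares; initialization uses the first/last absorbance as
plateau guesses and the pH nearest the half-height as the pKa guess, which
removes starting-value sensitivity for any data that actually bracket the
transition. The reported uncertainty is the asymptotic +/-1 standard error
from the fit covariance (not a replicate spread).

A free-Hill-slope variant is available (``hill=True``) but is off by
default: a fitted slope absorbs cooperativity or instrument drift that a
single-site acid cannot have, at the price of one more parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateCurveError, FitError, SchemaError

__all__ = [
    "TitrationCurve",
    "TitrationFit",
    "sigmoid_model",
    "fit_pka",
    "simulate_curve",
    "read_titration_csv",
]

MIN_POINTS = 5


@dataclass(frozen=True)
class TitrationCurve:
    """Absorbance vs pH at one wavelength for one compound."""

    ph: np.ndarray
    absorbance: np.ndarray
    wavelength: float | None = None  # nm
    label: str = ""

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ph.shape != ab.shape or ph.ndim != 1:
            raise SchemaError(
                f"ph and absorbance must be equal-length 1-D arrays, "
                f"got {ph.shape} vs {ab.shape}"
            )
        if not (np.all(np.isfinite(ph)) and np.all(np.isfinite(ab))):
            raise SchemaError("pH and absorbance values must be finite")
        order = np.argsort(ph, kind="stable")
        ph, ab = ph[order], ab[order]
        if np.any(np.diff(ph) <= 0):
            raise SchemaError("pH values must be distinct")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return len(self.ph)


@dataclass(frozen=True)
class TitrationFit:
    """Fitted sigmoid parameters; pka_stderr is the asymptotic 1-SE."""

    pka: float
    pka_stderr: float
    a_acid: float
    a_base: float
    residual_rms: float
    converged: bool
    hill: float = 1.0
    in_span: bool = True  # pKa inside the observed pH window


def sigmoid_model(ph, pka, a_acid, a_base, hill: float = 1.0):
    """Henderson-Hasselbalch sigmoid; equals the plateau midpoint at ph=pka."""
    ph = np.asarray(ph, dtype=float)
    frac = 1.0 / (1.0 + 10.0 ** (-hill * (ph - pka)))
    return a_acid + (a_base - a_acid) * frac


def _initial_guess(curve: TitrationCurve) -> tuple[float, float, float]:
    a0, a1 = float(curve.absorbance[0]), float(curve.absorbance[-1])
    half = 0.5 * (a0 + a1)
    k = int(np.argmin(np.abs(curve.absorbance - half)))
    return float(curve.ph[k]), a0, a1


def fit_pka(curve: TitrationCurve, hill: bool = False) -> TitrationFit:
    """Unweighted nonlinear least-squares sigmoid fit of a titration curve.

    Raises :class:`DegenerateCurveError` when the data carry no transition
    (plateau difference indistinguishable from noise) and :class:`FitError`
    on non-convergence.
    """
    if len(curve) < MIN_POINTS:
        raise SchemaError(f"need >= {MIN_POINTS} points to fit, got {len(curve)}")
    ab = curve.absorbance
    # noise scale from second differences (a smooth sigmoid contributes
    # little curvature at titration-grid spacing); the transition amplitude
    # is measured on a moving average so uncorrelated noise cannot fake a span
    if len(ab) >= 3:
        noise = float(np.std(np.diff(ab, 2)) / math.sqrt(6.0))
    else:
        noise = 0.0
    if len(ab) >= 9:
        smooth = np.convolve(ab, np.full(5, 0.2), mode="valid")
    else:
        smooth = ab
    span = float(smooth.max() - smooth.min())
    if span == 0.0 or span < 5.0 * noise:
        raise DegenerateCurveError(
            f"no resolvable transition: absorbance span {span:.4g} AU vs "
            f"noise scale {noise:.4g} AU"
        )

    pka0, a0, a1 = _initial_guess(curve)
    if hill:
        model = sigmoid_model
        p0 = [pka0, a0, a1, 1.0]
    else:
        def model(ph, pka, a_acid, a_base):
            return sigmoid_model(ph, pka, a_acid, a_base, hill=1.0)

        p0 = [pka0, a0, a1]
    try:
        popt, pcov = curve_fit(model, curve.ph, ab, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    resid = ab - model(curve.ph, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    stderr = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    pka = float(popt[0])
    return TitrationFit(
        pka=pka,
        pka_stderr=stderr,
        a_acid=float(popt[1]),
        a_base=float(popt[2]),
        residual_rms=rms,
        converged=True,
        hill=float(popt[3]) if hill else 1.0,
        in_span=bool(curve.ph[0] <= pka <= curve.ph[-1]),
    )


def simulate_curve(
    pka: float,
    a_acid: float,
    a_base: float,
    ph_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength: float | None = None,
    label: str = "synthetic",
) -> TitrationCurve:
    """Sigmoid evaluated on ``ph_grid`` plus seeded Gaussian noise."""
    if noise_sd < 0:
        raise SchemaError(f"noise_sd must be >= 0, got {noise_sd}")
    ph = np.asarray(ph_grid, dtype=float)
    ab = sigmoid_model(ph, pka, a_acid, a_base)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(scale=noise_sd, size=ph.shape)
    return TitrationCurve(ph=ph, absorbance=ab, wavelength=wavelength, label=label)


def read_titration_csv(path) -> TitrationCurve:
    """Read a titration CSV with columns ph,absorbance (wavelength_nm optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty titration CSV") from exc
    missing = {"ph", "absorbance"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    wavelength = None
    if "wavelength_nm" in df.columns and df["wavelength_nm"].notna().any():
        wavelength = float(df["wavelength_nm"].dropna().iloc[0])
    return TitrationCurve(
        ph=df["ph"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        wavelength=wavelength,
        label=path.stem,
    )
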