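"""One-site ligand-binding fits to fluorescence anisotropy titrations.

The model is the single-site saturation isotherm A = A_max [L] / (K_D + [L]),
with A the baseline-corrected anisotropy, [L] the titrated protein
concentration (µM) and K_D the dissociation constant.  Fitting is unweighted
nonlinear least squares over (A_max, K_D); standard errors come from the
Gauss-Newton approximation of the Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

KD_BOUNDS = (1e-6, 1e3)  # µM


class BindingFitError(RuntimeError):
    """Non-convergence or a K_D driven to the box bounds."""


def one_site(L, a_max, kd):
    """A = A_max [L] / (K_D + [L])."""
    L = np.asarray(L, dtype=float)
    return a_max * L / (kd + L)


def correct_baseline(a_raw, a_baseline):
    """Subtract the RNA-alone anisotropy (scalar or per-point vector)."""
    a_raw = np.asarray(a_raw, dtype=float)
    base = np.asarray(a_baseline, dtype=float)
    if base.ndim > 0 and base.shape != a_raw.shape:
        raise ValueError("baseline length does not match the data")
    return a_raw - base


@dataclass
class BindingSeries:
    """A titration: concentrations (µM) and corrected anisotropies."""

    L: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.L.shape != self.A.shape:
            raise ValueError("L and A must have equal length")
        if np.any(self.L < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.L[self.L > 0])) < 4:
            raise ValueError("need at least 4 distinct nonzero concentrations")

    @classmethod
    def from_raw(cls, L, a_raw, a_baseline=0.0) -> "BindingSeries":
        return cls(L, correct_baseline(a_raw, a_baseline))


@dataclass
class BindingFit:
    """Fitted one-site parameters with curvature standard errors."""

    kd: float          # µM
    a_max: float
    rss: float
    se_kd: float
    se_a_max: float
    n: int

    def predict(self, L):
        return one_site(L, self.a_max, self.kd)

    def as_dict(self) -> dict:
        return {
            "kd_uM": self.kd, "a_max": self.a_max, "rss": self.rss,
            "se_kd_uM": self.se_kd, "se_a_max": self.se_a_max, "n": self.n,
        }


def _initial_guess(L, A):
    """A_max from the plateau; K_D from the concentration at half-maximum by
    linear interpolation along the titration."""
    a0 = float(np.max(A))
    if a0 <= 0:
        a0 = max(float(np.abs(A).max()), 1e-6)
    order = np.argsort(L)
    Ls, As = L[order], A[order]
    half = a0 / 2.0
    kd0 = None
    for i in range(1, len(Ls)):
        if As[i - 1] < half <= As[i] and As[i] > As[i - 1]:
            frac = (half - As[i - 1]) / (As[i] - As[i - 1])
            kd0 = Ls[i - 1] + frac * (Ls[i] - Ls[i - 1])
            break
    if kd0 is None or kd0 <= 0:
        kd0 = float(np.median(Ls[Ls > 0]))
    return a0, kd0


def fit_one_site(series: BindingSeries, max_iter: int = 500) -> BindingFit:
    """Least-squares fit of (A_max, K_D); raises BindingFitError on failure.

    Zero-concentration points stay in the fit (the model pins A(0) = 0).
    """
    L, A = series.L, series.A
    p0 = _initial_guess(L, A)
    try:
        popt, pcov = curve_fit(
            one_site, L, A, p0=p0,
            bounds=([0.0, KD_BOUNDS[0]], [np.inf, KD_BOUNDS[1]]),
            xtol=1e-10, ftol=1e-12, max_nfev=max_iter * 3,
        )
    except RuntimeError as exc:
        raise BindingFitError(f"fit did not converge: {exc}") from exc
    a_max, kd = float(popt[0]), float(popt[1])
    min_l, max_l = float(np.min(L[L > 0])), float(np.max(L))
    if (
        kd <= KD_BOUNDS[0] * 1.01
        or kd >= KD_BOUNDS[1] * 0.99
        or kd < min_l / 50
        or kd > max_l * 50
    ):
        raise BindingFitError(
            f"K_D={kd:.3g} µM lies outside the range the titration "
            f"({min_l:.3g}-{max_l:.3g} µM) can constrain"
        )
    resid = A - one_site(L, a_max, kd)
    se = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=kd, a_max=a_max, rss=float(np.dot(resid, resid)),
        se_kd=float(se[1]), se_a_max=float(se[0]), n=len(L),
    )


def serial_dilution(top: float = 52.81, n_points: int = 12, factor: float = 2.0,
                    include_zero: bool = True) -> np.ndarray:
    """Concentration ladder of a serial dilution from ``top`` µM downward."""
    L = top / factor ** np.arange(n_points - int(include_zero))
    if include_zero:
        L = np.append(L, 0.0)
    return np.sort(L)


def bootstrap_se(series: BindingSeries, n_boot: int = 500, seed: int = 0):
    """Case-resampling bootstrap SEs for (K_D, A_max), for small titrations."""
    rng = np.random.default_rng(seed)
    kds, amaxes = [], []
    n = len(series.L)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            f = fit_one_site(BindingSeries(series.L[idx], series.A[idx]))
        except (BindingFitError, ValueError):
            continue
        kds.append(f.kd)
        amaxes.append(f.a_max)
    if len(kds) < n_boot // 2:
        raise BindingFitError("bootstrap failed on most resamples")
    return float(np.std(kds, ddof=1)), float(np.std(amaxes, ddof=1))
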