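"""Two-site chemical-exchange 19F line shapes and dissociation-rate fitting.

A ligand exchanging between a free state (resonance ``delta_free``, intrinsic
transverse relaxation ``r2_free``) and a receptor-bound state (``delta_bound``,
``r2_bound``) with fraction bound ``p_b`` and dissociation rate ``k_off``
produces the steady-state Bloch-McConnell absorption line shape

    I(w) = Re[ 1^T A(w)^-1 p ],       p = (1 - p_b, p_b)

    A(w) = diag(r2_free + i(w - w_f),  r2_bound + i(w - w_b)) + K

    K = [[ k_fb, -k_off],
         [-k_fb,  k_off]],            k_fb = k_off * p_b / (1 - p_b)

where ``k_fb`` is the pseudo-first-order free->bound rate that balances
detailed balance at equilibrium (K p = 0).  In the slow-exchange regime
(2*pi*|d_bound - d_free| >> k_ex) the two states give separate peaks and the
free line is exchange-broadened by k_fb, i.e. its full width at half maximum is

    FWHM_free = (r2_free + k_off * p_b / (1 - p_b)) / pi      [Hz]

so a titration that raises p_b at fixed k_off raises the free linewidth
linearly in p_b/(1-p_b) with slope k_off/pi.  ``fit_koff`` inverts this: it
fits the free-resonance region of every titration point jointly, sharing
(delta_free, r2_free, k_off) across points with p_b fixed per point, and also
exposes the analytic broadening regression as a fast path and initializer.

Frequencies are offset Hz relative to the carrier throughout; the absolute
field never enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

MIN_SPECTRUM_POINTS = 64


@dataclass(frozen=True)
class ExchangeSystem:
    """Spectroscopic parameters of one two-site free/bound ligand."""

    delta_free: float  # Hz
    delta_bound: float  # Hz
    r2_free: float  # s^-1
    r2_bound: float  # s^-1
    k_off: float  # s^-1
    p_b: float  # fraction bound

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_b <= 1.0:
            raise ValueError(f"p_b must be in [0, 1], got {self.p_b}")
        for attr in ("r2_free", "r2_bound", "k_off"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.p_b == 1.0 and self.k_off > 0:
            raise ValueError(
                "p_b = 1 with k_off > 0: free-state lifetime undefined"
            )

    @property
    def delta_delta(self) -> float:
        """Free/bound shift separation in Hz."""
        return self.delta_bound - self.delta_free

    @property
    def k_fb(self) -> float:
        """Pseudo-first-order free->bound rate k_off * p_b / (1 - p_b)."""
        if self.p_b >= 1.0:
            return 0.0
        return self.k_off * self.p_b / (1.0 - self.p_b)


@dataclass(frozen=True)
class Spectrum:
    """One 1-D absorption spectrum on a uniform, strictly increasing Hz axis."""

    axis: np.ndarray  # Hz
    intensity: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or axis.size < MIN_SPECTRUM_POINTS:
            raise ValueError(f"axis must be 1-D with >= {MIN_SPECTRUM_POINTS} points")
        if intensity.shape != axis.shape:
            raise ValueError("axis and intensity must have the same length")
        step = np.diff(axis)
        if not np.all(step > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.allclose(step, step[0], rtol=1e-4, atol=0.0):
            raise ValueError("axis must be uniform")

    @property
    def dx(self) -> float:
        return float(self.axis[1] - self.axis[0])


@dataclass
class TitrationSeries:
    """Ordered titration points for one ligand: spectra with known p_b.

    ``p_b`` holds the fraction bound at each point (from concentrations and
    K_d, or from sidecar ground truth).  ``meta`` carries provenance such as
    concentrations and the generating scenario.
    """

    spectra: list[Spectrum]
    p_b: np.ndarray
    ligand_total: float | None = None
    receptor_site_totals: np.ndarray | None = None
    name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p_b = np.asarray(self.p_b, dtype=float)
        if len(self.spectra) != self.p_b.size:
            raise ValueError("one p_b per spectrum required")
        if np.any((self.p_b < 0) | (self.p_b > 1)):
            raise ValueError("p_b values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class LineshapeFit:
    """Result of a dissociation-rate fit across a titration."""

    k_off_hat: float  # s^-1
    k_off_se: float  # s^-1
    widths_hz: np.ndarray  # fitted free-line FWHM per titration point
    residual_norm: float
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_off_hat < 0 or self.k_off_se < 0:
            raise ValueError("k_off_hat and k_off_se must be >= 0")


def simulate_spectrum(sys: ExchangeSystem, axis) -> Spectrum:
    """Steady-state two-site exchange absorption line shape on ``axis`` (Hz).

    Closed-form inverse of the 2x2 complex matrix A(w), vectorized over the
    axis.  The integral of the returned intensity over w (rad/s) equals pi
    regardless of k_off (conservation of total magnetization).
    """
    axis = np.asarray(axis, dtype=float)
    w = 2.0 * np.pi * axis
    wf = 2.0 * np.pi * sys.delta_free
    wb = 2.0 * np.pi * sys.delta_bound
    pf, pb = 1.0 - sys.p_b, sys.p_b
    k_fb = sys.k_fb

    a11 = sys.r2_free + 1j * (w - wf) + k_fb
    a22 = sys.r2_bound + 1j * (w - wb) + sys.k_off
    a12 = -sys.k_off
    a21 = -k_fb
    det = a11 * a22 - a12 * a21
    x1 = (a22 * pf - a12 * pb) / det
    x2 = (a11 * pb - a21 * pf) / det
    return Spectrum(axis=axis, intensity=np.real(x1 + x2))


def integrated_intensity(spec: Spectrum) -> float:
    """Trapezoidal integral of intensity over angular frequency (rad/s)."""
    return float(np.trapezoid(spec.intensity, spec.axis) * 2.0 * np.pi)


def fwhm(spec: Spectrum, window: tuple[float, float] | None = None) -> float:
    """Full width at half maximum (nu_0.5, Hz) by linear interpolation.

    ``window`` restricts the search to an axis sub-range (e.g. the
    free-resonance region of a two-peak spectrum).  The peak must be a unique
    interior maximum with the half-maximum level bracketed on both sides.
    """
    x, y = spec.axis, spec.intensity
    if window is not None:
        mask = (x >= window[0]) & (x <= window[1])
        if mask.sum() < 5:
            raise ValueError("window too narrow for width estimation")
        x, y = x[mask], y[mask]
    i_max = int(np.argmax(y))
    if i_max == 0 or i_max == len(y) - 1:
        raise ValueError("peak maximum at axis edge; axis (or window) too narrow")
    half = y[i_max] / 2.0

    left = np.nonzero(y[:i_max] <= half)[0]
    right = np.nonzero(y[i_max:] <= half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("half maximum not bracketed; axis (or window) too narrow")
    i = left[-1]  # y[i] <= half < y[i+1]
    x_left = x[i] + (x[i + 1] - x[i]) * (half - y[i]) / (y[i + 1] - y[i])
    j = i_max + right[0]  # y[j-1] > half >= y[j]
    x_right = x[j - 1] + (x[j] - x[j - 1]) * (y[j - 1] - half) / (y[j - 1] - y[j])
    return float(x_right - x_left)


def free_window(init: ExchangeSystem, fraction: float = 0.45) -> tuple[float, float]:
    """Axis window centred on the free resonance, excluding the bound peak."""
    half = fraction * abs(init.delta_delta)
    if half <= 0:
        raise ValueError("delta_free and delta_bound coincide; no free window")
    return (init.delta_free - half, init.delta_free + half)


def initial_guess(series: TitrationSeries, k_off: float = 1.0) -> ExchangeSystem:
    """Data-driven starting guess for :func:`fit_koff`.

    The free resonance and its width are read off the lowest-p_b spectrum
    (global maximum; at p_b ~ 0 it is a pure Lorentzian of width r2_free/pi);
    the bound resonance and width come from the highest-p_b spectrum after
    masking the neighbourhood of the free peak.  The bound width slightly
    overestimates r2_bound (it includes the k_off broadening of the bound
    line), which is harmless: the bound state enters the free-window fit only
    through the exchange terms.
    """
    i_free = int(np.argmin(series.p_b))
    i_bound = int(np.argmax(series.p_b))
    s0 = series.spectra[i_free]
    d_free = float(s0.axis[np.argmax(s0.intensity)])

    s1 = series.spectra[i_bound]
    span = s1.axis[-1] - s1.axis[0]
    mask = np.abs(s1.axis - d_free) > 0.15 * span
    if not np.any(mask):
        raise ValueError("cannot locate bound resonance: axis too narrow")
    masked = np.where(mask, s1.intensity, -np.inf)
    d_bound = float(s1.axis[np.argmax(masked)])
    half = 0.45 * abs(d_bound - d_free)

    w_free = fwhm(s0, (max(d_free - half, s0.axis[0]), min(d_free + half, s0.axis[-1])))
    try:
        w_bound = fwhm(
            s1, (max(d_bound - half, s1.axis[0]), min(d_bound + half, s1.axis[-1]))
        )
    except ValueError:
        w_bound = w_free
    return ExchangeSystem(
        delta_free=d_free,
        delta_bound=d_bound,
        r2_free=np.pi * w_free,
        r2_bound=np.pi * w_bound,
        k_off=k_off,
        p_b=float(series.p_b[i_free]),
    )


def _broadening_regression(
    series: TitrationSeries, init: ExchangeSystem, window: tuple[float, float]
):
    """Weighted linear regression of pi*FWHM_i on x_i = p_b/(1-p_b).

    Slope = k_off, intercept = r2_free (slow-exchange limit).  Returns
    (k_off, k_off_se, r2_free, widths).
    """
    x = series.p_b / (1.0 - series.p_b)
    widths = np.array([fwhm(s, window) for s in series.spectra])
    res = stats.linregress(x, np.pi * widths)
    k_off = max(float(res.slope), 0.0)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return k_off, se, float(res.intercept), widths


def fit_koff(
    series: TitrationSeries,
    init: ExchangeSystem,
    method: str = "matrix",
    window: tuple[float, float] | None = None,
    fit_pb: bool = False,
) -> LineshapeFit:
    """Estimate k_off from the free-resonance region of a titration.

    Parameters
    ----------
    series
        Titration points with per-point fraction bound fixed (or, with
        ``fit_pb=True``, used as starting values and co-fitted).
    init
        Starting guess; ``delta_bound`` and ``r2_bound`` are taken from it and
        held fixed (in slow exchange they influence the free line only through
        the exchange terms).
    method
        ``"matrix"`` (default): global nonlinear least squares of the full
        Bloch-McConnell shape over the free window, sharing (delta_free,
        r2_free, k_off) across points, with per-point amplitude and constant
        baseline solved linearly at each step.  ``"analytic"``: weighted linear
        regression of the excess free linewidth, pi*(FWHM_i) = r2_free +
        k_off * p_b_i/(1-p_b_i).
    window
        Free-resonance axis window in Hz; defaults to +/-45% of |d_bound -
        d_free| around the free shift.

    Notes
    -----
    k_off is parameterized as log(k_off) to enforce positivity; the standard
    error comes from the Jacobian-based covariance at the solution.
    """
    if len(series) < 2 or np.unique(np.round(series.p_b, 12)).size < 2:
        raise ValueError("need >= 2 titration points with distinct p_b")
    if np.all(series.p_b < 0.01):
        raise ValueError("all p_b ~ 0: k_off is unidentifiable from this series")
    if np.any(series.p_b >= 1.0):
        raise ValueError("p_b = 1 point cannot constrain the free resonance")
    lo_ax = max(s.axis[0] for s in series.spectra)
    hi_ax = min(s.axis[-1] for s in series.spectra)
    if lo_ax >= hi_ax:
        raise ValueError("titration spectra have non-overlapping axes")
    if window is None:
        raw = free_window(init)
        window = (max(raw[0], lo_ax), min(raw[1], hi_ax))
        if not window[0] < init.delta_free < window[1]:
            raise ValueError("axes do not cover the free resonance")
    elif window[0] < lo_ax or window[1] > hi_ax:
        raise ValueError("free window not covered by every spectrum's axis")

    try:
        k0, se0, intercept0, widths0 = _broadening_regression(series, init, window)
    except ValueError:
        k0, se0, intercept0, widths0 = init.k_off, 0.0, np.pi * init.r2_free, None

    if method == "analytic":
        if widths0 is None:
            raise ValueError("analytic fit requires measurable free-line widths")
        r2_free = max(intercept0, 1e-6)
        return LineshapeFit(
            k_off_hat=k0,
            k_off_se=se0,
            widths_hz=(r2_free + k0 * series.p_b / (1 - series.p_b)) / np.pi,
            residual_norm=float("nan"),
            method="analytic",
            params={"r2_free": r2_free, "delta_free": init.delta_free},
        )
    if method != "matrix":
        raise ValueError(f"unknown method {method!r}")

    masks = [(s.axis >= window[0]) & (s.axis <= window[1]) for s in series.spectra]
    axes = [s.axis[m] for s, m in zip(series.spectra, masks)]
    ys = [s.intensity[m] for s, m in zip(series.spectra, masks)]
    n_pts = len(series)
    # per-spectrum noise from first differences (robust MAD); the noise floor
    # varies across titration points, so residuals are whitened per spectrum
    weights = []
    for s in series.spectra:
        mad = float(np.median(np.abs(np.diff(s.intensity))))
        sigma = mad / (np.sqrt(2.0) * 0.6744897501960817)
        weights.append(1.0 / sigma if sigma > 0 else 1.0)
    scale = max(w for w in weights)
    weights = [w / scale for w in weights]

    k_init = k0 if k0 > 1e-4 else max(init.k_off, 1e-4)
    r2_init = max(intercept0 if widths0 is not None else init.r2_free, 1.0)
    theta0 = [np.log(k_init), init.delta_free, np.log(r2_init)]
    lo = [np.log(1e-8), init.delta_free - abs(window[1] - window[0]), np.log(1e-3)]
    hi = [np.log(1e8), init.delta_free + abs(window[1] - window[0]), np.log(1e6)]
    if fit_pb:
        pb0 = np.clip(series.p_b, 1e-6, 1 - 1e-6)
        theta0 += list(np.log(pb0 / (1 - pb0)))  # logit
        lo += [-30.0] * n_pts
        hi += [30.0] * n_pts
    theta0 = np.asarray(theta0)

    def model_shapes(theta):
        k_off = np.exp(theta[0])
        d_free = theta[1]
        r2_free = np.exp(theta[2])
        if fit_pb:
            pbs = 1.0 / (1.0 + np.exp(-theta[3 : 3 + n_pts]))
        else:
            pbs = series.p_b
        shapes = []
        for ax, pb in zip(axes, pbs):
            sys_i = ExchangeSystem(
                delta_free=d_free,
                delta_bound=init.delta_bound,
                r2_free=r2_free,
                r2_bound=init.r2_bound,
                k_off=k_off,
                p_b=float(pb),
            )
            shapes.append(simulate_spectrum(sys_i, ax).intensity)
        return shapes, k_off, r2_free, pbs

    def residuals(theta):
        shapes, *_ = model_shapes(theta)
        res = []
        for m, y, w in zip(shapes, ys, weights):
            # per-point amplitude and baseline solved linearly (variable projection)
            design = np.column_stack([m, np.ones_like(m)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            res.append(w * (y - design @ coef))
        return np.concatenate(res)

    sol = optimize.least_squares(
        residuals, theta0, bounds=(lo, hi), method="trf", x_scale="jac"
    )
    shapes, k_hat, r2_hat, pbs = model_shapes(sol.x)

    m, p = sol.fun.size, sol.x.size
    if m > p:
        sigma2 = float(sol.fun @ sol.fun) / (m - p)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = sigma2 * np.linalg.inv(jtj)
            se_logk = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            se_logk = float("nan")
    else:
        se_logk = float("nan")
    k_se = k_hat * se_logk if np.isfinite(se_logk) else 0.0

    widths = (r2_hat + k_hat * pbs / (1.0 - pbs)) / np.pi
    return LineshapeFit(
        k_off_hat=float(k_hat),
        k_off_se=float(k_se),
        widths_hz=np.asarray(widths, dtype=float),
        residual_norm=float(np.linalg.norm(sol.fun)),
        method="matrix",
        params={
            "delta_free": float(sol.x[1]),
            "r2_free": float(r2_hat),
            "p_b": np.asarray(pbs, dtype=float),
            "window": window,
            "init_k_off": float(k_init),
            "analytic_k_off": float(k0),
            "analytic_k_off_se": float(se0),
        },
    )
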