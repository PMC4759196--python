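"""Worm-like-chain polymer mechanics.

Implements the Marko–Siggia interpolation for the entropic elasticity of an
unfolded polypeptide,

    F(x) = (kBT/p) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

its numeric inversion, the force balance between a stretched chain and a
Hookean cantilever, and least-squares fitting of a rising force-extension
edge with the persistence length held fixed.  Holding p fixed and fitting
only the contour length Lc is the standard AFM protocol: it makes the
contour-length increment between two fits (delta Lc) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .constants import KBT_ROOM, thermal_energy
from .errors import FitError, InputError


@dataclass(frozen=True)
class WlcParams:
    """Worm-like-chain parameters.

    Parameters
    ----------
    persistence_length : float
        Persistence length p in nm (> 0).
    contour_length : float
        Contour length Lc in nm (> 0).
    temperature : float, optional
        Temperature in K.  When omitted, room temperature is assumed and
        kBT = 4.11 pN nm is used directly.
    """

    persistence_length: float
    contour_length: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise InputError("persistence_length must be > 0 nm")
        if self.contour_length <= 0:
            raise InputError("contour_length must be > 0 nm")
        if self.temperature is not None and self.temperature <= 0:
            raise InputError("temperature must be > 0 K")

    @property
    def kbt(self) -> float:
        """Thermal energy in pN nm."""
        if self.temperature is None:
            return KBT_ROOM
        return thermal_energy(self.temperature)


def _ms_force(x, contour_length: float, persistence_length: float, kbt: float):
    """Marko–Siggia force (vector-safe); no domain checking."""
    u = np.asarray(x, dtype=float) / contour_length
    return (kbt / persistence_length) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)


def _ms_stiffness(x, contour_length: float, persistence_length: float, kbt: float):
    """dF/dx of the Marko–Siggia law (vector-safe)."""
    u = np.asarray(x, dtype=float) / contour_length
    return (kbt / persistence_length) * (0.5 / (1.0 - u) ** 3 + 1.0) / contour_length


def wlc_force(extension: float, params: WlcParams) -> float:
    """Force (pN) of a worm-like chain stretched to ``extension`` nm.

    Raises
    ------
    InputError
        If extension is negative or >= the contour length (the chain cannot
        be stretched beyond its backbone length).
    """
    if extension < 0:
        raise InputError("extension must be >= 0 nm")
    if extension >= params.contour_length:
        raise InputError(
            f"extension {extension} nm >= contour length {params.contour_length} nm"
        )
    return float(_ms_force(extension, params.contour_length,
                           params.persistence_length, params.kbt))


def wlc_extension(force: float, params: WlcParams) -> float:
    """Extension (nm) at which the chain exerts ``force`` pN.

    Unique by monotonicity of the force law; solved to |dF| < 1e-6 pN.
    """
    if force < 0:
        raise InputError("force must be >= 0 pN")
    if force == 0:
        return 0.0
    lc = params.contour_length

    def g(x: float) -> float:
        return float(_ms_force(x, lc, params.persistence_length, params.kbt)) - force

    return float(brentq(g, 0.0, lc * (1.0 - 1e-12), xtol=1e-12, rtol=8.9e-16))


def solve_force_balance(stage_position: float, params: WlcParams,
                        spring_constant: float) -> tuple[float, float]:
    """Tip-sample extension and force for a chain in series with a cantilever.

    Solves F = k_c (z - x) = F_wlc(x) for the unique crossing; the cantilever
    deflection is z - x.  Returns ``(extension nm, force pN)``.
    """
    if stage_position < 0:
        raise InputError("stage_position must be >= 0 nm")
    if spring_constant <= 0:
        raise InputError("spring_constant must be > 0 pN/nm")
    z = stage_position
    if z == 0.0:
        return 0.0, 0.0
    lc, p, kbt = params.contour_length, params.persistence_length, params.kbt
    hi = min(z, lc * (1.0 - 1e-12))

    def g(x: float) -> float:
        return spring_constant * (z - x) - float(_ms_force(x, lc, p, kbt))

    if g(hi) >= 0.0:  # chain slack relative to stage: deflection ~ 0
        x = hi
    else:
        x = brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return float(x), float(spring_constant * (z - x))


def solve_force_balance_array(stage_positions: np.ndarray, contour_length: float,
                              persistence_length: float, kbt: float,
                              spring_constant: float, iters: int = 64
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised force balance along a stage ramp at fixed contour length.

    Bisection on g(x) = k_c (z - x) - F_wlc(x), which is strictly decreasing
    in x; ``iters`` halvings give machine-level accuracy.  Used by the
    pulling simulator where one branch of the sawtooth shares a single Lc.
    """
    z = np.asarray(stage_positions, dtype=float)
    lo = np.zeros_like(z)
    hi = np.minimum(np.maximum(z, 0.0), contour_length * (1.0 - 1e-12))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = spring_constant * (z - mid) - _ms_force(mid, contour_length,
                                                    persistence_length, kbt)
        take = g > 0.0
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    x = 0.5 * (lo + hi)
    return x, spring_constant * (z - x)


def fit_wlc_segment(points, persistence_length: float,
                    kbt: float = KBT_ROOM, search_span: float = 500.0,
                    spring_constant: float | None = None
                    ) -> tuple[float, float]:
    """Least-squares contour length of one rising force-extension edge.

    ``points`` is an (n, 2) array-like of (extension nm, force pN).  The
    persistence length is held fixed; only Lc is optimised, over a bounded
    interval that keeps every data point below the fitted contour length.

    When the extension was derived from the cantilever deflection
    (x = z - F/k_c), force noise leaks into the extension coordinate and the
    force residuals are amplified by (1 + k_wlc/k_c) where the chain is
    stiff.  Passing ``spring_constant`` applies the corresponding inverse
    weights so every sample contributes at its true information content.

    Returns ``(contour_length nm, rms weighted force residual pN)``.

    Raises
    ------
    FitError
        Fewer than 5 points, a flat/degenerate segment, or a segment whose
        force does not rise with extension.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be an (n, 2) array of (extension, force)")
    if pts.shape[0] < 5:
        raise FitError(f"segment underdetermined: {pts.shape[0]} points (< 5)")
    x, f = pts[:, 0], pts[:, 1]
    if np.ptp(x) < 1e-9 or np.ptp(f) < 1e-9:
        raise FitError("degenerate segment: no spread in extension or force")
    slope = np.polyfit(x, f, 1)[0]
    if slope <= 0:
        raise FitError("segment is not a rising edge (force does not grow with extension)")

    xmax = float(np.max(x))
    lo = xmax * (1.0 + 1e-6) + 1e-9
    hi = xmax + search_span

    def sse(lc: float) -> float:
        r = _ms_force(x, lc, persistence_length, kbt) - f
        if spring_constant is not None:
            k_wlc = _ms_stiffness(x, lc, persistence_length, kbt)
            r = r / (1.0 + k_wlc / spring_constant)
        return float(np.dot(r, r))

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    lc_hat = float(res.x)
    rms = float(np.sqrt(res.fun / pts.shape[0]))
    return lc_hat, rms
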