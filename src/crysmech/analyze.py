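"""Trace analysis: peaks, WLC fits, event classification, EKF, gating.

A sawtooth force-extension recording is reduced to an ordered table of
unfolding events: rupture peaks are located on a lightly smoothed force
signal, each rising edge is fitted with a fixed-persistence worm-like chain
to estimate its contour length, and the increment between consecutive fits
is the contour length released by the rupture (delta Lc).  Events are
classified by a joint (force, delta Lc) window table, and recordings are
gated on the I27 fingerprint: a trace counts as a verified single-molecule
recording only when the number of high-force I27-class events equals the
construct's I27 count.

An extended Kalman filter over the instantaneous contour length provides a
real-time alternative to segment fitting: the state is Lc, the observation
model is the worm-like-chain force at the measured extension, and sustained
innovation failures mark a rupture, whose size is the filter's contour
length jump.  This recovers weak low-force steps (the ~35 pN swapped-state
rupture) whose short rising edges make windowed fits noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .constants import DEFAULT_PERSISTENCE_NM, KBT_ROOM
from .constructs import ConstructTopology
from .errors import ConfigError, FilterError, FitError, InputError
from .simulate import ForceExtensionTrace
from .wlc import _ms_force, fit_wlc_segment


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class UnfoldingEvent:
    """One rupture: peak force, contour lengths before/after, class label."""
    index: int
    rupture_force: float
    Lc_before: float
    Lc_after: float
    delta_Lc: float
    class_label: str = "unknown"
    fit_residual: float = float("nan")
    peak_sample: int = -1

    @property
    def resolved(self) -> bool:
        return np.isfinite(self.delta_Lc)


@dataclass(frozen=True)
class GateResult:
    """Outcome of the I27 fingerprint gate."""
    accepted: bool
    n_fingerprint_events: int
    reason: str = ""


@dataclass
class EkfState:
    """Extended-Kalman-filter output: the Lc track and detected steps."""
    Lc_estimate: np.ndarray
    estimate_variance: np.ndarray
    detected_steps: list[tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class ClassWindow:
    """One classification window in the (force, delta Lc) plane."""
    label: str
    f_min: float = 0.0
    f_max: float = float("inf")
    dlc_min: float = 0.0
    dlc_max: float = float("inf")
    priority: int = 0

    def contains(self, force: float, delta_Lc: float) -> bool:
        return (self.f_min <= force < self.f_max
                and self.dlc_min <= delta_Lc < self.dlc_max)

    def overlaps(self, other: "ClassWindow") -> bool:
        f_overlap = self.f_min < other.f_max and other.f_min < self.f_max
        d_overlap = self.dlc_min < other.dlc_max and other.dlc_min < self.dlc_max
        return f_overlap and d_overlap


#: Default event classes: boundaries sit between the measured force
#: distributions (Ctd ~96, Ntd ~136, I27 ~252 pN); below 60 pN the contour
#: increment separates the weak swapped-state rupture (>= 20 nm) from the
#: ~8 nm Ctd intermediate.
DEFAULT_WINDOWS = (
    ClassWindow("I27", f_min=180.0),
    ClassWindow("Ntd", f_min=110.0, f_max=180.0),
    ClassWindow("Ctd", f_min=60.0, f_max=110.0),
    ClassWindow("swap-weak", f_max=60.0, dlc_min=20.0),
    ClassWindow("intermediate", f_max=60.0, dlc_max=20.0),
)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_peaks(trace: ForceExtensionTrace, min_drop: float = 20.0,
                 min_force: float = 25.0, smooth_samples: int = 11,
                 drop_window: int = 200) -> np.ndarray:
    """Indices of rupture peaks in the force signal.

    A rupture is a local force maximum of at least ``min_force`` pN followed
    by a drop of at least ``min_drop`` pN before the force exceeds it again.
    The drop criterion (rather than peak prominence) is what keeps the
    ~35 pN weak swapped-state peak: it rises from an elevated trough, so its
    prominence is small even though the rupture drop after it is large.
    Noise is rejected by the ``smooth_samples``-point moving average and the
    ``min_drop`` depth; ``drop_window`` bounds how far after the final peak
    the drop may occur.
    """
    if len(trace.force) == 0:
        raise InputError("empty trace")
    f = uniform_filter1d(np.asarray(trace.force, dtype=float),
                         size=max(1, smooth_samples))
    n = f.size
    cands, _ = find_peaks(f, height=min_force)
    kept: list[int] = []
    active = -1
    for c in cands:
        if active < 0:
            active = int(c)
            continue
        if np.min(f[active: c + 1]) <= f[active] - min_drop:
            kept.append(active)      # rupture drop occurred before this peak
            active = int(c)
        elif f[c] >= f[active]:
            active = int(c)          # same rupture region, higher maximum
    if active >= 0:
        tail = f[active: min(active + drop_window, n)]
        if np.min(tail) <= f[active] - min_drop:
            kept.append(active)
    return np.asarray(kept, dtype=int)


def smoothed_force(trace: ForceExtensionTrace, smooth_samples: int = 11) -> np.ndarray:
    return uniform_filter1d(np.asarray(trace.force, dtype=float),
                            size=max(1, smooth_samples))


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

def _segment_bounds(f_smooth: np.ndarray, peaks: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs of the rising edge preceding each peak, plus
    the trailing segment after the final peak (if any)."""
    bounds = []
    prev = 0
    for pk in peaks:
        trough = prev + int(np.argmin(f_smooth[prev: pk + 1])) if pk > prev else prev
        bounds.append((trough, pk))
        prev = pk + 1
    if peaks.size:
        last = peaks[-1] + 1
        if last < f_smooth.size:
            trough = last + int(np.argmin(f_smooth[last:]))
            bounds.append((trough, f_smooth.size - 1))
    return bounds


def _fit_segment(trace: ForceExtensionTrace, f_smooth: np.ndarray,
                 start: int, end: int, persistence_length: float,
                 f_min_fit: float, max_points: int,
                 trim: int = 0) -> tuple[float, float]:
    # trim the rupture itself out of the fit window: around the (smoothed)
    # peak the raw signal may already contain post-rupture samples
    end = max(start, end - trim)
    sel = slice(start, end + 1)
    mask = f_smooth[sel] >= f_min_fit
    kc = trace.metadata.get("spring_constant_pN_nm")
    if kc:
        # rebuild the extension from the noise-free stage ramp and the
        # *smoothed* deflection: the raw deflection noise otherwise leaks
        # into the extension coordinate and biases the fit on stiff branches
        x = (np.asarray(trace.stage_position[sel], dtype=float)
             - f_smooth[sel] / kc)[mask]
        weights_kc = None
    else:
        x = np.asarray(trace.extension[sel], dtype=float)[mask]
        weights_kc = None
    f = np.asarray(trace.force[sel], dtype=float)[mask]
    if x.size > max_points:
        stride = int(np.ceil(x.size / max_points))
        x, f = x[::stride], f[::stride]
    return fit_wlc_segment(np.column_stack([x, f]), persistence_length,
                           spring_constant=weights_kc)


def extract_events(trace: ForceExtensionTrace, peaks: np.ndarray,
                   persistence_length: float = DEFAULT_PERSISTENCE_NM,
                   windows: tuple[ClassWindow, ...] = DEFAULT_WINDOWS,
                   f_min_fit: float = 8.0, max_fit_points: int = 400,
                   smooth_samples: int = 11) -> list[UnfoldingEvent]:
    """Fit every rising edge and build the ordered event table.

    Each peak yields one event with ``Lc_before`` from the edge leading into
    it and ``Lc_after`` from the next edge; ``delta_Lc`` is their difference.
    When the edge *between* two peaks cannot be fitted (a rupture cascade too
    fast to resolve, e.g. an intermediate breaking right after its parent
    domain), the two peaks are merged into a single event carrying their
    combined increment.  Other unfittable edges (leading/trailing) leave the
    event flagged ``unknown`` rather than dropping it.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise InputError("no peaks supplied")
    f_smooth = smoothed_force(trace, smooth_samples)

    def fit_all(pks):
        bounds = _segment_bounds(f_smooth, pks)
        fits = []
        for start, end in bounds:
            try:
                fits.append(_fit_segment(trace, f_smooth, start, end,
                                         persistence_length, f_min_fit,
                                         max_fit_points,
                                         trim=smooth_samples))
            except FitError:
                fits.append((float("nan"), float("nan")))
        return fits

    fits = fit_all(peaks)
    # merge peak pairs separated by an unfittable edge (indices 1..n-1 of the
    # fit list correspond to inter-peak edges)
    while peaks.size > 1:
        bad = [i for i in range(1, peaks.size)
               if not np.isfinite(fits[i][0])]
        if not bad:
            break
        i = bad[0]
        drop = i if f_smooth[peaks[i]] < f_smooth[peaks[i - 1]] else i - 1
        peaks = np.delete(peaks, drop)
        fits = fit_all(peaks)
    events = []
    for i, pk in enumerate(peaks):
        lc_before, resid = fits[i]
        lc_after = fits[i + 1][0] if i + 1 < len(fits) else float("nan")
        delta = lc_after - lc_before
        force = float(f_smooth[pk])
        ev = UnfoldingEvent(index=i, rupture_force=force, Lc_before=lc_before,
                            Lc_after=lc_after, delta_Lc=delta,
                            fit_residual=resid, peak_sample=int(pk))
        ev.class_label = classify_event(ev, windows) if np.isfinite(delta) \
            else "unknown"
        events.append(ev)
    return events


def analyze_trace(trace: ForceExtensionTrace,
                  persistence_length: float = DEFAULT_PERSISTENCE_NM,
                  windows: tuple[ClassWindow, ...] = DEFAULT_WINDOWS,
                  **peak_kwargs) -> list[UnfoldingEvent]:
    """Convenience pipeline: detect peaks, then extract classified events.
    Returns an empty list when no peaks are found."""
    peaks = detect_peaks(trace, **peak_kwargs)
    if peaks.size == 0:
        return []
    return extract_events(trace, peaks, persistence_length, windows)


# ---------------------------------------------------------------------------
# Classification and gating
# ---------------------------------------------------------------------------

def validate_windows(windows: tuple[ClassWindow, ...]) -> None:
    """Reject window tables with same-priority overlaps (ambiguous rules)."""
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            if a.priority == b.priority and a.overlaps(b):
                raise ConfigError(
                    f"class windows {a.label!r} and {b.label!r} overlap at "
                    "equal priority; set explicit precedence")


def classify_event(event: UnfoldingEvent,
                   windows: tuple[ClassWindow, ...] = DEFAULT_WINDOWS) -> str:
    """Class label of one event from the (force, delta Lc) window table;
    highest-priority match wins, ``unknown`` if nothing matches."""
    validate_windows(windows)
    if not np.isfinite(event.delta_Lc):
        return "unknown"
    matches = [w for w in windows
               if w.contains(event.rupture_force, event.delta_Lc)]
    if not matches:
        return "unknown"
    return max(matches, key=lambda w: w.priority).label


def fingerprint_gate(events: list[UnfoldingEvent],
                     construct: ConstructTopology) -> GateResult:
    """Accept a recording only if the I27 fingerprint is complete.

    The construct's flanking I27 modules certify that a single, fully
    tethered molecule was pulled; the trace passes when the number of
    I27-class events equals the construct's I27 count.
    """
    expected = construct.i27_count
    n = sum(1 for ev in events if ev.class_label == "I27")
    if n == expected:
        return GateResult(True, n, "")
    if n < expected:
        return GateResult(False, n,
                          f"fingerprint incomplete: {n}/{expected} I27 events")
    return GateResult(False, n,
                      f"surplus I27-class events: {n} > {expected}")


# ---------------------------------------------------------------------------
# Extended Kalman filter contour-length tracker
# ---------------------------------------------------------------------------

def _invert_lc(extension: float, force: float, persistence_length: float,
               kbt: float, lc_max: float = 1e4) -> float:
    """Contour length at which a WLC at ``extension`` exerts ``force``."""
    lo = extension * (1.0 + 1e-9) + 1e-9

    def g(lc: float) -> float:
        return float(_ms_force(extension, lc, persistence_length, kbt)) - force

    if g(lc_max) > 0:  # even a nearly slack chain exceeds the force
        return lc_max
    return float(brentq(g, lo, lc_max, xtol=1e-10))


def ekf_contour_length(trace: ForceExtensionTrace,
                       persistence_length: float = DEFAULT_PERSISTENCE_NM,
                       process_noise: float = 1e-4,
                       obs_noise: float | None = None,
                       gate_threshold: float = 2.0,
                       m_consecutive: int = 10,
                       f_track_min: float = 8.0,
                       kbt: float = KBT_ROOM) -> EkfState:
    """Track the instantaneous contour length with an extended Kalman filter.

    State: Lc (nm); random walk with per-sample variance ``process_noise``
    (nm^2).  Observation: the measured force, predicted from the (noise-free)
    stage position by solving the chain/cantilever force balance at the
    current Lc; the Jacobian is dF/dLc damped by the stiffness ratio
    k_c/(k_c + k_wlc).  Predicting from the stage rather than from the
    deflection-derived extension keeps the innovations independent and
    Gaussian.  ``obs_noise`` is the force noise sd (pN); by default read
    from the trace metadata.

    Rupture detection: the mean normalised innovation over the last
    ``m_consecutive`` samples beyond ``gate_threshold`` declares a step (for
    white noise that mean has sd 1/sqrt(m), so the default 2.0 over 10
    samples is a ~6.3 sigma test yet still catches the sustained ~2.5 sigma
    offset left by a weak ~30 pN rupture).  The filter then rolls Lc back to
    the pre-break buffer, re-initialises by averaging a short batch of
    post-break samples, and records the contour-length jump (the difference
    of the converged estimates on the adjacent branches) at the rupture
    time.

    Samples with force below ``f_track_min`` carry almost no information
    about Lc and are coasted over (prediction only).
    """
    if obs_noise is None:
        obs_noise = float(trace.metadata.get("force_noise_sd_pN", 0.0)) or 1.0
    if obs_noise <= 0:
        raise InputError("obs_noise must be > 0 pN")
    r_var = obs_noise ** 2
    kc = trace.metadata.get("spring_constant_pN_nm")
    if not kc:
        raise InputError(
            "trace metadata must carry spring_constant_pN_nm: the filter "
            "predicts force from the stage ramp through the cantilever")
    kc = float(kc)
    z_arr = np.asarray(trace.stage_position, dtype=float)
    f_arr = np.asarray(trace.force, dtype=float)
    t_arr = np.asarray(trace.time, dtype=float)
    n = z_arr.size
    if n == 0:
        raise InputError("empty trace")
    c_elastic = kbt / persistence_length

    def balance(z: float, lc: float, x_guess: float) -> float:
        """Equilibrium extension for stage z at contour length lc (Newton,
        warm-started; g is strictly decreasing so iteration is stable)."""
        x = min(max(x_guess, 0.0), min(z, lc * (1 - 1e-9)))
        for _ in range(40):
            u = x / lc
            f_ch = c_elastic * (0.25 / (1 - u) ** 2 - 0.25 + u)
            g = kc * (z - x) - f_ch
            if abs(g) < 1e-9:
                break
            k_wlc = c_elastic * (0.5 / (1 - u) ** 3 + 1.0) / lc
            x = min(max(x + g / (kc + k_wlc), 0.0), lc * (1 - 1e-9))
        return x

    lc_track = np.full(n, np.nan)
    p_track = np.full(n, np.nan)
    steps: list[tuple[float, float]] = []

    lc = None
    p_var = 25.0
    lc_before_break = None
    settle_var = 0.25  # record a pending step once the estimate re-converges
    # (re)acquisition averages several samples, so a modest threshold
    # already rules out noise excursions
    f_acquire = max(f_track_min, 1.5 * obs_noise)

    pending_t = None  # sample index of the break a pending step belongs to
    x_eq = 0.0        # warm start for the balance solver
    w_acq = 40        # batch length for (re)acquisition averaging
    break_t = -1      # last break sample; acquisition must not look past it
    z_window: list[float] = []   # last m normalised innovations
    lc_buffer: list[tuple[float, float]] = []  # (lc, P) m samples back
    hard_gate = 2.0 * gate_threshold  # skip single-sample outliers entirely

    def finalize_pending() -> None:
        nonlocal lc_before_break, pending_t
        if lc_before_break is not None:
            jump = lc - lc_before_break
            if jump > 0:
                steps.append((float(t_arr[pending_t]), float(jump)))
            lc_before_break = None
            pending_t = None

    for t in range(n):
        z, f_obs = z_arr[t], f_arr[t]
        if lc is None:
            # (re)acquire from a post-break batch average: the mean of w_acq
            # samples beats any single noisy inversion, and the implied
            # prior variance is the averaged information content
            lo_w = max(break_t + 1, t - w_acq + 1)
            if t - lo_w + 1 >= w_acq:
                f_recent = float(np.mean(f_arr[lo_w: t + 1]))
                z_recent = float(np.mean(z_arr[lo_w: t + 1]))
                x_impl = z_recent - f_recent / kc
                if f_recent >= f_acquire and x_impl > 5.0:
                    lc = _invert_lc(x_impl, f_recent, persistence_length, kbt)
                    x_eq = x_impl
                    p_var = 25.0
                    # replay the batch as ordinary updates: this removes the
                    # curvature bias of inverting at the batch mean and
                    # leaves an honest (small) posterior variance
                    for tb in range(lo_w, t + 1):
                        x_eq = balance(z_arr[tb], lc, x_eq)
                        ub = min(x_eq / lc, 1.0 - 1e-9)
                        kwb = c_elastic * (0.5 / (1 - ub) ** 3 + 1.0) / lc
                        hb = -c_elastic * (x_eq / lc ** 2) \
                            * (0.5 / (1 - ub) ** 3 + 1.0) * kc / (kc + kwb)
                        sb = hb * hb * p_var + r_var
                        gb = p_var * hb / sb
                        lc = lc + gb * (f_arr[tb] - kc * (z_arr[tb] - x_eq))
                        p_var = (1.0 - gb * hb) * p_var
            lc_track[t], p_track[t] = (lc if lc is not None else np.nan), p_var
            continue

        p_var += process_noise
        if p_var > 1e9 or not np.isfinite(p_var):
            raise FilterError(f"variance overflow at sample {t}: P={p_var:.3g}")

        x_eq = balance(z, lc, x_eq)
        u = min(x_eq / lc, 1.0 - 1e-9)
        f_pred = kc * (z - x_eq)
        if f_pred < f_track_min and f_obs < f_track_min:
            lc_track[t], p_track[t] = lc, p_var
            z_window.clear()
            continue
        k_wlc = c_elastic * (0.5 / (1 - u) ** 3 + 1.0) / lc
        # dF/dLc through the force balance: the bare WLC sensitivity damped
        # by the stiffness divider of chain and cantilever in series
        h = -c_elastic * (x_eq / lc ** 2) * (0.5 / (1 - u) ** 3 + 1.0) \
            * kc / (kc + k_wlc)
        s_var = h * h * p_var + r_var
        nu = f_obs - f_pred
        zscore = nu / np.sqrt(s_var)
        z_window.append(float(zscore))
        if len(z_window) > m_consecutive:
            z_window.pop(0)
        if (len(z_window) == m_consecutive
                and abs(np.mean(z_window)) > gate_threshold):
            # rupture: flush any step still settling, roll Lc back to
            # the pre-break buffer, then re-acquire from the data
            finalize_pending()
            if lc_buffer:
                lc, p_var = lc_buffer[0]
            if p_var < 4 * settle_var:
                lc_before_break = lc
                pending_t = t - m_consecutive + 1
            lc = None
            lc_buffer.clear()
            z_window.clear()
            break_t = t
            lc_track[t], p_track[t] = np.nan, p_var
            continue
        if abs(zscore) <= hard_gate:
            gain = p_var * h / s_var
            lc = lc + gain * nu
            p_var = (1.0 - gain * h) * p_var
        else:
            p_var -= process_noise  # outlier: no update, freeze variance
        lc_buffer.append((lc, p_var))
        if len(lc_buffer) > m_consecutive:
            lc_buffer.pop(0)
        lc_track[t], p_track[t] = lc, p_var

    if lc is not None:
        finalize_pending()  # last pending step, using the final estimate
    return EkfState(Lc_estimate=lc_track, estimate_variance=p_track,
                    detected_steps=steps)
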