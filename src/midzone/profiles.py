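"""Gaussian models of axial spindle intensity profiles and their fits.

The midzone crosslinker distribution along the pole-to-pole axis is modelled
as a single Gaussian in metaphase and, in anaphase, as a sum of one central
Gaussian peak with two equidistant side peaks of identical height and width:

    f(x) = b + A_c G(x; x0, s_c) + A_s [G(x; x0 - d, s_s) + G(x; x0 + d, s_s)]

with G(x; m, s) = exp(-(x - m)^2 / (2 s^2)).  Two derived lengths summarise
the spindle geometry:

* antiparallel overlap length  L = FWHM of the central peak = 2*sqrt(2 ln 2)*s_c
* total profile width          W = 2 d + FWHM of the side peaks

The DNA (chromosome) distribution is two spatially displaced but otherwise
identical Gaussians; their separation measures chromosome segregation.

All fits are non-linear least squares (scipy.optimize.curve_fit) with
inverse-variance weights when per-point SEMs are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .core import IntensityProfile

#: FWHM of a Gaussian divided by its sigma: 2*sqrt(2 ln 2).
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class FitError(RuntimeError):
    """A least-squares fit could not be performed at all."""


def gaussian(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    """Peak-height parameterised Gaussian (no baseline)."""
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass
class GaussianPeak:
    """One Gaussian peak: height, centre (um) and width sigma (um)."""

    amplitude: float
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return gaussian(x, self.amplitude, self.center, self.sigma)


@dataclass
class AnaphaseProfileModel:
    """Central peak plus two identical, equidistant side peaks and a baseline."""

    amp_central: float
    center: float
    sigma_central: float
    amp_side: float
    side_offset: float  # distance d from the centre to each side-peak centre
    sigma_side: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.side_offset > 0) and not np.isnan(self.side_offset):
            raise ValueError("side_offset must be positive")
        for name in ("sigma_central", "sigma_side"):
            v = getattr(self, name)
            if not (v > 0) and not np.isnan(v):
                raise ValueError(f"{name} must be positive")

    @property
    def overlap_length(self) -> float:
        """Central-peak FWHM: the antiparallel microtubule overlap length."""
        return FWHM_FACTOR * self.sigma_central

    @property
    def total_width(self) -> float:
        """Side-peak separation plus one side-peak FWHM: total spindle width."""
        return 2.0 * self.side_offset + FWHM_FACTOR * self.sigma_side

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.baseline + gaussian(x, self.amp_central, self.center, self.sigma_central)
        if self.amp_side and not np.isnan(self.side_offset):
            out = out + gaussian(x, self.amp_side, self.center - self.side_offset, self.sigma_side)
            out = out + gaussian(x, self.amp_side, self.center + self.side_offset, self.sigma_side)
        return out

    @classmethod
    def from_widths(
        cls,
        overlap_length_um: float,
        total_width_um: float,
        amp_central: float = 5.0,
        amp_side: float = 1.0,
        sigma_side_um: float = 0.9,
        center_um: float = 0.0,
        baseline: float = 0.0,
    ) -> "AnaphaseProfileModel":
        """Solve (sigma_central, side_offset) from the two derived lengths."""
        sigma_c = overlap_length_um / FWHM_FACTOR
        d = 0.5 * (total_width_um - FWHM_FACTOR * sigma_side_um)
        if d <= 0:
            raise ValueError("total width too small for the requested side sigma")
        return cls(amp_central, center_um, sigma_c, amp_side, d, sigma_side_um, baseline)


@dataclass
class DnaProfileModel:
    """Two spatially displaced, otherwise identical Gaussians plus baseline."""

    amplitude: float
    midpoint: float
    separation: float  # distance between the two means (um)
    sigma: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        half = 0.5 * self.separation
        return (
            self.baseline
            + gaussian(x, self.amplitude, self.midpoint - half, self.sigma)
            + gaussian(x, self.amplitude, self.midpoint + half, self.sigma)
        )


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------


@dataclass
class MetaphaseFit:
    peak: GaussianPeak
    baseline: float
    errors: dict[str, float]
    converged: bool = True

    @property
    def fwhm(self) -> float:
        return self.peak.fwhm

    @property
    def fwhm_se(self) -> float:
        return FWHM_FACTOR * self.errors.get("sigma", float("nan"))


@dataclass
class AnaphaseFit:
    model: AnaphaseProfileModel
    errors: dict[str, float]
    reliable: bool
    degenerate: bool = False
    converged: bool = True

    @property
    def overlap_length(self) -> float:
        return self.model.overlap_length

    @property
    def overlap_length_se(self) -> float:
        return FWHM_FACTOR * self.errors.get("sigma_central", float("nan"))

    @property
    def total_width(self) -> float:
        return self.model.total_width

    @property
    def total_width_se(self) -> float:
        vd = self.errors.get("side_offset", float("nan")) ** 2
        vs = self.errors.get("sigma_side", float("nan")) ** 2
        cov = self.errors.get("cov_side_offset_sigma_side", 0.0)
        var = 4.0 * vd + FWHM_FACTOR**2 * vs + 4.0 * FWHM_FACTOR * cov
        return math.sqrt(max(var, 0.0))


@dataclass
class DnaFit:
    model: DnaProfileModel
    errors: dict[str, float]
    resolved: bool

    @property
    def separation(self) -> float:
        return self.model.separation

    @property
    def separation_se(self) -> float:
        return self.errors.get("separation", float("nan"))


def _weights(profile: IntensityProfile) -> np.ndarray | None:
    if profile.sem is None:
        return None
    sem = np.asarray(profile.sem, dtype=float)
    if np.all(sem > 0):
        return sem
    return None


def _se_dict(names: list[str], pcov: np.ndarray | None) -> dict[str, float]:
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {n: float("nan") for n in names}
    return {n: float(math.sqrt(max(pcov[i, i], 0.0))) for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def fit_metaphase_profile(profile: IntensityProfile) -> MetaphaseFit:
    """Fit a single Gaussian plus constant baseline to a metaphase profile.

    The FWHM of the fitted peak is the metaphase spindle length as labelled
    by the crosslinker.
    """
    x, y = profile.x_um, profile.intensity
    if len(x) < 6:
        raise ValueError("need at least 6 points to fit a Gaussian + baseline")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile intensities must be finite")

    span = x[-1] - x[0]
    b0 = float(np.min(y))
    yc = np.clip(y - b0, 0, None)
    tot = yc.sum()
    x0 = float((x * yc).sum() / tot) if tot > 0 else float(x.mean())
    var = float(((x - x0) ** 2 * yc).sum() / tot) if tot > 0 else (span / 4) ** 2
    sig0 = max(math.sqrt(max(var, 1e-12)), span / 100)
    a0 = max(float(np.max(y) - b0), 1e-12)

    def model(xv, a, c, s, b):
        return b + gaussian(xv, a, c, s)

    dx = float(np.min(np.diff(x)))
    bounds = ([0, x[0], dx / 2, -np.inf], [np.inf, x[-1], span, np.inf])
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[a0, x0, sig0, b0], sigma=_weights(profile),
            bounds=bounds, maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, pcov, converged = [a0, x0, sig0, b0], None, False

    errs = _se_dict(["amplitude", "center", "sigma", "baseline"], pcov)
    peak = GaussianPeak(float(popt[0]), float(popt[1]), float(popt[2]))
    return MetaphaseFit(peak, float(popt[3]), errs, converged)


def _anaphase_init(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Heuristic start: centroid centre, second-moment central sigma,
    side offset from the outer local maxima of a lightly smoothed profile."""
    span = x[-1] - x[0]
    dx = float(np.min(np.diff(x)))
    b0 = float(np.min(y))
    yc = np.clip(y - b0, 0, None)
    tot = yc.sum()
    x0 = float((x * yc).sum() / tot) if tot > 0 else float(x.mean())

    # central third
    third = np.abs(x - x0) <= span / 6
    ycen = yc[third]
    xcen = x[third]
    if ycen.sum() > 0:
        var_c = float(((xcen - x0) ** 2 * ycen).sum() / ycen.sum())
        sc0 = max(math.sqrt(max(var_c, 1e-12)), dx)
    else:
        sc0 = span / 10

    ys = gaussian_filter1d(yc, sigma=2.0)
    # prominence guard: tail noise must not masquerade as a side peak
    peaks, _ = signal.find_peaks(ys, prominence=0.02 * float(np.max(ys)))
    left = [p for p in peaks if x[p] < x0 - sc0]
    right = [p for p in peaks if x[p] > x0 + sc0]
    if left and right:
        lbest = max(left, key=lambda p: ys[p])
        rbest = max(right, key=lambda p: ys[p])
        d0 = 0.5 * ((x0 - x[lbest]) + (x[rbest] - x0))
        as0 = 0.5 * (ys[lbest] + ys[rbest])
    else:
        d0 = span / 4
        as0 = 0.3 * float(np.max(yc))
    d0 = float(np.clip(d0, dx, span / 2))
    ac0 = max(float(np.max(yc)), 1e-12)
    as0 = float(np.clip(as0, 1e-3 * ac0, None))
    ss0 = max(sc0, dx * 2)
    return [ac0, x0, sc0, as0, d0, ss0, b0]


_ANA_NAMES = ["amp_central", "center", "sigma_central", "amp_side",
              "side_offset", "sigma_side", "baseline"]


def fit_anaphase_profile(
    profile: IntensityProfile,
    rel_se_max: float = 0.5,
) -> AnaphaseFit:
    """Constrained central + two-identical-side Gaussian fit (7 parameters).

    Returns the fitted model with derived overlap length L (central FWHM)
    and total width W (2d + side FWHM).  A reliability flag marks whether L
    can be trusted: relative SE of sigma_central below ``rel_se_max``, a
    central peak narrower than the side-peak offset, and a central peak
    taller than the side peaks.  Degenerate fits (vanishing side peaks or a
    central peak wider than the side offset) fall back to the single-Gaussian
    metaphase model with L marked unreliable.
    """
    x, y = profile.x_um, profile.intensity
    if len(x) < 10:
        raise ValueError("need at least 10 points spanning both shoulders")

    span = x[-1] - x[0]
    dx = float(np.min(np.diff(x)))
    p0 = _anaphase_init(x, y)
    lower = [0, x[0], dx / 2, 0, dx / 2, dx / 2, -np.inf]
    upper = [np.inf, x[-1], span, np.inf, span / 2, span, np.inf]

    def model(xv, ac, c, sc, a_s, d, ss, b):
        return (
            b
            + gaussian(xv, ac, c, sc)
            + gaussian(xv, a_s, c - d, ss)
            + gaussian(xv, a_s, c + d, ss)
        )

    rng = np.random.default_rng(0)  # multi-start perturbations, deterministic
    popt = pcov = None
    for attempt in range(6):
        start = list(p0)
        if attempt > 0:
            fac = rng.uniform(0.6, 1.6, size=7)
            start = [v * f for v, f in zip(p0, fac)]
            start = [float(np.clip(v, lo if np.isfinite(lo) else v,
                                   hi if np.isfinite(hi) else v))
                     for v, lo, hi in zip(start, lower, upper)]
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, sigma=_weights(profile),
                bounds=(lower, upper), maxfev=40000,
            )
            break
        except RuntimeError:
            popt = None
    if popt is None:
        raise FitError("anaphase profile fit failed to converge (6 starts)")

    ac, c, sc, a_s, d, ss, b = (float(v) for v in popt)
    errs = _se_dict(_ANA_NAMES, pcov)
    if pcov is not None and np.all(np.isfinite(pcov)):
        errs["cov_side_offset_sigma_side"] = float(pcov[4, 5])

    degenerate = (a_s <= 1e-3 * max(ac, 1e-300)) or (sc >= d)
    if degenerate:
        mono = fit_metaphase_profile(profile)
        model_out = AnaphaseProfileModel(
            mono.peak.amplitude, mono.peak.center, mono.peak.sigma,
            0.0, float("nan"), float("nan"), mono.baseline,
        )
        errs = {
            "amp_central": mono.errors["amplitude"],
            "center": mono.errors["center"],
            "sigma_central": mono.errors["sigma"],
            "baseline": mono.errors["baseline"],
        }
        return AnaphaseFit(model_out, errs, reliable=False, degenerate=True)

    model_out = AnaphaseProfileModel(ac, c, sc, a_s, d, ss, b)
    se_sc = errs.get("sigma_central", float("nan"))
    rel_se_ok = np.isfinite(se_sc) and sc > 0 and (se_sc / sc) < rel_se_max
    # noiseless fits have ~zero covariance; treat nan/zero SE as precise
    if not np.isfinite(se_sc) or se_sc == 0.0:
        rel_se_ok = True
    reliable = bool(rel_se_ok and sc < d and ac > a_s)
    return AnaphaseFit(model_out, errs, reliable=reliable)


def fit_dna_profile(profile: IntensityProfile) -> DnaFit:
    """Fit two identical, displaced Gaussians to a DNA (chromosome) profile.

    Returns the separation between the two means.  Unresolved masses
    (separation below one sigma) are flagged and their SE inflated.
    """
    x, y = profile.x_um, profile.intensity
    if len(x) < 8:
        raise ValueError("need at least 8 points")

    span = x[-1] - x[0]
    dx = float(np.min(np.diff(x)))
    b0 = float(np.min(y))
    yc = np.clip(y - b0, 0, None)
    tot = yc.sum()
    m0 = float((x * yc).sum() / tot) if tot > 0 else float(x.mean())
    var = float(((x - m0) ** 2 * yc).sum() / tot) if tot > 0 else (span / 4) ** 2
    std = math.sqrt(max(var, 1e-12))

    ys = gaussian_filter1d(yc, sigma=2.0)
    peaks, _ = signal.find_peaks(ys)
    if len(peaks) >= 2:
        order = np.argsort(ys[peaks])[::-1]
        two = np.sort(x[peaks[order[:2]]])
        s0 = float(two[1] - two[0])
        sig0 = max(std / 2, dx)
    else:
        s0 = std
        sig0 = max(std / 2, dx)
    a0 = max(float(np.max(yc)), 1e-12)

    def model(xv, a, m, s, sig, b):
        half = 0.5 * s
        return b + gaussian(xv, a, m - half, sig) + gaussian(xv, a, m + half, sig)

    bounds = ([0, x[0], 0, dx / 2, -np.inf], [np.inf, x[-1], span, span, np.inf])
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[a0, m0, max(s0, dx), sig0, b0],
            sigma=_weights(profile), bounds=bounds, maxfev=40000,
        )
    except RuntimeError as exc:
        raise FitError(f"DNA two-Gaussian fit failed: {exc}") from exc

    a, m, s, sig, b = (float(v) for v in popt)
    errs = _se_dict(["amplitude", "midpoint", "separation", "sigma", "baseline"], pcov)
    resolved = s >= sig
    # Guard against degenerate optima: a component centre outside the data
    # window, or a two-Gaussian fit that is no better than a single Gaussian
    # (coincident masses), means the separation is not identified.
    if resolved:
        in_window = (x[0] <= m - 0.5 * s) and (m + 0.5 * s <= x[-1])
        if not in_window:
            resolved = False
        else:
            yhat = model(x, a, m, s, sig, b)
            rss_two = float(np.sum((y - yhat) ** 2))
            try:
                mono = fit_metaphase_profile(profile)
                yhat1 = mono.baseline + gaussian(
                    x, mono.peak.amplitude, mono.peak.center, mono.peak.sigma)
                rss_one = float(np.sum((y - yhat1) ** 2))
                if rss_two > rss_one:
                    resolved = False
            except (FitError, ValueError):
                pass
    if not resolved:
        # overlapping masses: separation is poorly identified
        se = errs.get("separation", float("nan"))
        errs["separation"] = 3.0 * se if np.isfinite(se) else float("nan")
    return DnaFit(DnaProfileModel(a, m, s, sig, b), errs, resolved)


def max_peak_intensity(profile: IntensityProfile | np.ndarray) -> float:
    """Mean of the five samples centred on the profile maximum.

    The window is clipped at the profile boundaries; a clipped (shorter)
    window triggers a warning.
    """
    y = profile.intensity if isinstance(profile, IntensityProfile) else np.asarray(profile, float)
    if len(y) < 5:
        raise ValueError("need at least 5 points")
    i = int(np.argmax(y))
    lo, hi = max(0, i - 2), min(len(y), i + 3)
    if hi - lo < 5:
        warnings.warn("max-intensity window clipped at profile boundary", stacklevel=2)
    return float(np.mean(y[lo:hi]))


# ---------------------------------------------------------------------------
# Time course over mitosis
# ---------------------------------------------------------------------------


@dataclass
class OverlapTimecourse:
    """Spindle geometry and intensity metrics versus time.

    Times are minutes relative to anaphase onset (t = 0 at onset).  The
    overlap length column is NaN wherever the anaphase fit was not flagged
    reliable, mirroring that the central-peak width cannot be extracted
    early in anaphase.
    """

    times_min: np.ndarray
    total_width_um: np.ndarray
    total_width_se: np.ndarray
    overlap_fwhm_um: np.ndarray
    overlap_fwhm_se: np.ndarray
    max_intensity: np.ndarray
    dna_separation_um: np.ndarray = field(default=None)
    dna_separation_se: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.times_min)
        for name in ("total_width_um", "total_width_se", "overlap_fwhm_um",
                     "overlap_fwhm_se", "max_intensity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if self.dna_separation_um is None:
            self.dna_separation_um = np.full(n, np.nan)
            self.dna_separation_se = np.full(n, np.nan)


@dataclass
class OverlapDecayFit:
    """Mono-exponential decay of the overlap length toward an asymptote:

    L(t) = L_inf + (L0 - L_inf) * exp(-(t - t_ref) / tau_min)
    """

    length_initial_um: float  # L at the reference time t_ref
    length_final_um: float    # asymptote
    tau_min: float
    t_ref_min: float
    errors: dict[str, float]
    flat: bool = False

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        if self.flat:
            return np.full_like(t, self.length_final_um)
        return self.length_final_um + (
            self.length_initial_um - self.length_final_um
        ) * np.exp(-(t - self.t_ref_min) / self.tau_min)


def fit_overlap_decay(
    times_min: np.ndarray | OverlapTimecourse,
    lengths_um: np.ndarray | None = None,
    sems: np.ndarray | None = None,
) -> OverlapDecayFit:
    """Fit a mono-exponential decay to the reliable overlap-length points.

    Accepts either an :class:`OverlapTimecourse` (NaN rows dropped) or raw
    (times, lengths) arrays.  The reference time is the first reliable
    point.  A flat series (no measurable decay) is returned with
    ``flat=True`` and tau undefined.
    """
    if isinstance(times_min, OverlapTimecourse):
        tc = times_min
        keep = np.isfinite(tc.overlap_fwhm_um)
        t = tc.times_min[keep]
        y = tc.overlap_fwhm_um[keep]
        sems = tc.overlap_fwhm_se[keep]
        if sems is not None and not np.all(np.isfinite(sems) & (sems > 0)):
            sems = None
    else:
        t = np.asarray(times_min, dtype=float)
        y = np.asarray(lengths_um, dtype=float)
        keep = np.isfinite(y)
        t, y = t[keep], y[keep]
        if sems is not None:
            sems = np.asarray(sems, dtype=float)[keep]
    if len(t) < 4:
        raise ValueError("need at least 4 reliable overlap-length points")

    t_ref = float(t[0])
    spread = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.mean(y))), 1e-12)
    if spread <= 1e-6 * scale:
        return OverlapDecayFit(float(y[0]), float(np.mean(y)), float("nan"),
                               t_ref, {}, flat=True)

    def model(tv, l0, linf, tau):
        return linf + (l0 - linf) * np.exp(-(tv - t_ref) / tau)

    span_t = max(float(t[-1] - t[0]), 1e-9)
    p0 = [float(y[0]), float(y[-1]), span_t / 3]
    bounds = ([0, 0, 1e-6], [np.inf, np.inf, 100 * span_t])
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, sigma=sems,
                               bounds=bounds, maxfev=40000)
    except RuntimeError as exc:
        raise FitError(f"overlap decay fit failed: {exc}") from exc
    errs = _se_dict(["length_initial_um", "length_final_um", "tau_min"], pcov)
    return OverlapDecayFit(float(popt[0]), float(popt[1]), float(popt[2]),
                           t_ref, errs)


def build_timecourse(
    protein_kymo,
    dna_kymo=None,
    window: int = 1,
) -> OverlapTimecourse:
    """Assemble W(t), L(t), Imax(t) and chromosome separation from an
    averaged kymograph.

    Rows before anaphase onset (t < 0) are fitted with the single-Gaussian
    metaphase model (its FWHM reported as the total width); rows at and
    after onset use the constrained three-Gaussian anaphase model.  Fit
    failures leave NaN gaps instead of aborting the series.
    """
    from .kymograph import extract_profile  # local import avoids a cycle

    times_s = protein_kymo.times_s
    n = len(times_s)
    W = np.full(n, np.nan)
    Wse = np.full(n, np.nan)
    L = np.full(n, np.nan)
    Lse = np.full(n, np.nan)
    Imax = np.full(n, np.nan)
    S = np.full(n, np.nan)
    Sse = np.full(n, np.nan)

    for i in range(n):
        try:
            prof = extract_profile(protein_kymo, i, window=window)
        except Exception:
            continue
        try:
            if times_s[i] < 0:
                fit = fit_metaphase_profile(prof)
                W[i] = fit.fwhm
                Wse[i] = fit.fwhm_se
            else:
                afit = fit_anaphase_profile(prof)
                if not afit.degenerate:
                    W[i] = afit.total_width
                    Wse[i] = afit.total_width_se
                if afit.reliable:
                    L[i] = afit.overlap_length
                    Lse[i] = afit.overlap_length_se
            Imax[i] = max_peak_intensity(prof)
        except (FitError, ValueError):
            continue
        if dna_kymo is not None:
            try:
                dprof = extract_profile(dna_kymo, i, window=window)
                dfit = fit_dna_profile(dprof)
                S[i] = dfit.separation
                Sse[i] = dfit.separation_se
            except (FitError, ValueError):
                pass

    return OverlapTimecourse(
        times_min=times_s / 60.0,
        total_width_um=W, total_width_se=Wse,
        overlap_fwhm_um=L, overlap_fwhm_se=Lse,
        max_intensity=Imax,
        dna_separation_um=S, dna_separation_se=Sse,
    )
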