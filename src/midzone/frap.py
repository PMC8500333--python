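"""FRAP recovery analysis: normalization, bleach correction, stage
classification, curve averaging, and mono-exponential recovery fits.

A normalized recovery curve is fitted with

    I(t) = I0 + Ia * (1 - exp(-t / tau))

where t = 0 at the bleach frame.  Derived quantities are the plateau
IE = I0 + Ia and the recovery fraction (mobile pool) mf = Ia / (1 - I0).
The bleach frame itself (the first frame after the bleach pulse, showing
the intensity drop to ~I0) is excluded from the fit and only seeds the
initial guess for I0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .profiles import AnaphaseFit, DnaFit, FitError, MetaphaseFit

STAGES = ("metaphase", "early anaphase", "mid anaphase", "late anaphase",
          "telophase")


@dataclass
class FrapRecord:
    """One cell's FRAP region-of-interest time series.

    ``bleach_index`` is the index of the first frame after the bleach pulse
    (the frame showing the intensity drop); at least four pre-bleach frames
    must precede it.
    """

    times_s: np.ndarray
    roi_intensity: np.ndarray
    bleach_index: int
    reference_intensity: np.ndarray | None = None
    roi_radius_um: float = 0.6
    stage: str = "unknown"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        if self.times_s.shape != self.roi_intensity.shape:
            raise ValueError("times and intensities must match in length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bleach_index < 4:
            raise ValueError("need at least 4 pre-bleach time points")
        if self.reference_intensity is not None:
            self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
            if self.reference_intensity.shape != self.times_s.shape:
                raise ValueError("reference series length mismatch")

    @property
    def n_post(self) -> int:
        return len(self.times_s) - self.bleach_index - 1


@dataclass
class FrapFit:
    """Fitted recovery parameters with standard errors."""

    i0: float
    ia: float
    tau_s: float
    errors: dict[str, float]
    window_limited: bool = False
    converged: bool = True

    @property
    def plateau(self) -> float:
        """Final intensity after recovery, IE = I0 + Ia."""
        return self.i0 + self.ia

    @property
    def recovery_fraction(self) -> float:
        """Mobile fraction mf = Ia / (1 - I0)."""
        return self.ia / (1.0 - self.i0)

    @property
    def recovery_fraction_se(self) -> float:
        """Delta-method SE of mf from the (I0, Ia) covariance."""
        se_i0 = self.errors.get("i0", float("nan"))
        se_ia = self.errors.get("ia", float("nan"))
        cov = self.errors.get("cov_i0_ia", 0.0)
        g = 1.0 - self.i0
        d_ia = 1.0 / g
        d_i0 = self.ia / g**2
        var = d_ia**2 * se_ia**2 + d_i0**2 * se_i0**2 + 2 * d_ia * d_i0 * cov
        return math.sqrt(max(var, 0.0))

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        return self.i0 + self.ia * (1.0 - np.exp(-t / self.tau_s))


@dataclass
class StageAverageCurve:
    """Pointwise mean of normalized recovery curves for one mitotic stage."""

    times_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: int
    bleach_index: int
    stage: str = "unknown"


def _prebleach_mean(values: np.ndarray, bleach_index: int) -> float:
    return float(np.mean(values[bleach_index - 4:bleach_index]))


def normalize_frap(record: FrapRecord) -> FrapRecord:
    """Divide the ROI series by the mean of the last four pre-bleach points.

    Idempotent: the four reference points average exactly 1 afterwards.
    """
    ref = _prebleach_mean(record.roi_intensity, record.bleach_index)
    if not (ref > 0):
        raise ValueError("pre-bleach mean must be positive")
    return replace(record, roi_intensity=record.roi_intensity / ref,
                   normalized=True)


def bleach_correct(record: FrapRecord,
                   reference_series: np.ndarray | None = None) -> FrapRecord:
    """Correct acquisition photobleaching with a distant reference region.

    The reference series is first normalized to its own pre-bleach mean, the
    ROI series is divided by it pointwise, and the result is renormalized.
    """
    ref = reference_series if reference_series is not None else record.reference_intensity
    if ref is None:
        raise ValueError("no reference series available")
    ref = np.asarray(ref, dtype=float)
    if ref.shape != record.times_s.shape:
        raise ValueError("reference series length mismatch")
    if np.any(ref <= 0):
        raise ValueError("reference intensities must be strictly positive")
    ref_norm = ref / _prebleach_mean(ref, record.bleach_index)
    corrected = replace(record, roi_intensity=record.roi_intensity / ref_norm)
    return normalize_frap(corrected)


def fit_recovery(curve: FrapRecord | StageAverageCurve,
                 window_limit_factor: float = 0.5) -> FrapFit:
    """Least-squares fit of I0 + Ia(1 - exp(-t/tau)) to post-bleach samples.

    t = 0 at the bleach frame; the bleach frame is excluded from the fit but
    provides the I0 starting value.  Fits whose tau exceeds
    ``window_limit_factor`` times the post-bleach observation window are
    flagged window-limited (the plateau is barely constrained and the
    reported SEs are correspondingly wide).
    """
    times = curve.times_s
    intens = curve.mean if isinstance(curve, StageAverageCurve) else curve.roi_intensity
    bi = curve.bleach_index
    t0 = times[bi]
    t_fit = times[bi + 1:] - t0
    y_fit = intens[bi + 1:]
    if len(t_fit) < 6:
        raise ValueError("need at least 6 post-bleach samples")

    dt = float(np.min(np.diff(times)))
    window = float(t_fit[-1])
    i0_guess = float(np.clip(intens[bi], 0.0, 1.0))
    ia_guess = float(np.clip(np.median(y_fit[-4:]) - i0_guess, 1e-3, 1.5))
    tau_guess = float(np.clip(window / 5, dt, 10 * window))

    def model(t, i0, ia, tau):
        return i0 + ia * (1.0 - np.exp(-t / tau))

    bounds = ([0.0, 0.0, dt], [1.0, 1.5, 10 * window])
    converged = True
    try:
        popt, pcov = curve_fit(model, t_fit, y_fit,
                               p0=[i0_guess, ia_guess, tau_guess],
                               bounds=bounds, maxfev=40000)
    except RuntimeError as exc:
        raise FitError(f"recovery fit failed: {exc}") from exc

    i0, ia, tau = (float(v) for v in popt)
    if np.all(np.isfinite(pcov)):
        errs = {
            "i0": math.sqrt(max(pcov[0, 0], 0.0)),
            "ia": math.sqrt(max(pcov[1, 1], 0.0)),
            "tau_s": math.sqrt(max(pcov[2, 2], 0.0)),
            "cov_i0_ia": float(pcov[0, 1]),
        }
    else:
        errs = {"i0": float("nan"), "ia": float("nan"), "tau_s": float("nan"),
                "cov_i0_ia": 0.0}
    at_bound = tau <= dt * 1.0001 or tau >= 10 * window * 0.9999
    if at_bound:
        converged = False
    window_limited = tau > window_limit_factor * window
    return FrapFit(i0, ia, tau, errs, window_limited=window_limited,
                   converged=converged)


def average_curves(records: list[FrapRecord], stage: str | None = None
                   ) -> StageAverageCurve:
    """Pointwise mean, SD and SEM over normalized curves of one stage.

    Records must be normalized; curves on different grids are linearly
    interpolated onto the grid of the first record.
    """
    if stage is not None:
        records = [r for r in records if r.stage == stage]
    if not records:
        raise ValueError(f"no records for stage {stage!r}")
    if not all(r.normalized for r in records):
        raise ValueError("records must be normalized before averaging")

    base = records[0]
    grid = base.times_s
    rows = []
    for r in records:
        if r.times_s.shape == grid.shape and np.allclose(r.times_s, grid):
            rows.append(r.roi_intensity)
        else:
            rows.append(np.interp(grid, r.times_s, r.roi_intensity))
    arr = np.vstack(rows)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    sem = sd / math.sqrt(n)
    return StageAverageCurve(grid.copy(), mean, sd, sem, n,
                             base.bleach_index,
                             stage or base.stage)


def classify_stage(
    protein_fit: MetaphaseFit | AnaphaseFit,
    dna_fit: DnaFit,
    time_since_mitosis_s: float | None = None,
    plateau_pole_distance_um: float = 20.0,
    metaphase_separation_um: float = 1.0,
    telophase_fwhm_um: float = 2.5,
    telophase_amp_ratio: float = 3.0,
) -> str:
    """Deterministic rule-based mitotic stage label.

    Rules (chromosome separation s from the DNA fit, plateau pole distance
    P): metaphase if s below ``metaphase_separation_um``; anaphase split
    into early/mid/late by thirds of P; telophase if s is in the last third
    AND the central protein peak is compact (FWHM below
    ``telophase_fwhm_um``) with a dominant central peak (A_c/A_s above
    ``telophase_amp_ratio``).  Conflicting evidence returns "unknown".
    """
    s = dna_fit.separation
    is_ana_model = isinstance(protein_fit, AnaphaseFit)

    if s < metaphase_separation_um:
        # a well-resolved three-peak midzone profile contradicts unseparated DNA
        if is_ana_model and protein_fit.reliable and not protein_fit.degenerate:
            if protein_fit.model.amp_side > 0.5 * protein_fit.model.amp_central:
                return "unknown"
        if time_since_mitosis_s is not None and time_since_mitosis_s > 15 * 60:
            return "unknown"
        return "metaphase"

    third = plateau_pole_distance_um / 3.0
    if s < third:
        return "early anaphase"
    if s < 2 * third:
        return "mid anaphase"
    if is_ana_model and not protein_fit.degenerate:
        m = protein_fit.model
        ratio = m.amp_central / m.amp_side if m.amp_side > 0 else np.inf
        if m.overlap_length < telophase_fwhm_um and ratio > telophase_amp_ratio:
            return "telophase"
    return "late anaphase"
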