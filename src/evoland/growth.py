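"""Growth-rate estimation from turbidostat OD600 traces.

A turbidostat holds a culture in exponential growth between two optical-density
setpoints by diluting it whenever the upper setpoint is crossed.  The OD trace
is therefore a sawtooth whose rising segments are single exponentials.  The
estimator here splits a trace into dilution cycles (or fixed-length windows
when no dilution occurred), fits ln(OD) against time by ordinary least squares
within each cycle, and reports the median of the per-cycle rates with a
bootstrap confidence interval.

Slow-growing, cofactor-starved strains show three phases after transfer into
selective medium: fast growth on residual intracellular cofactor, a decline as
fragile cells lyse, and steady slow growth once endogenous synthesis is the
only cofactor source.  :func:`detect_growth_phases` segments such traces so
that the final steady phase alone can be used for the rate estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ODTrace",
    "DilutionCycle",
    "GrowthRateEstimate",
    "PhaseSegmentation",
    "TurbidostatGrowthEstimator",
    "segment_cycles",
    "fit_cycle_mu",
    "estimate_mu",
    "detect_growth_phases",
    "cfu_from_od",
    "fold_change",
]

#: CFU per mL per unit OD600 (empirical linear calibration)
CFU_PER_OD = 3.52e8


@dataclass
class ODTrace:
    """Timestamped OD600 series from one turbidostat vial."""

    times: np.ndarray  # h, strictly increasing
    od: np.ndarray  # OD600, > 0
    vial_id: str = "vial"
    medium: str = "M9/glucose"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if self.times.size < 3:
            raise ValueError("trace needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD values must be positive")


@dataclass(frozen=True)
class DilutionCycle:
    """Half-open index range [start, end) of one fitted cycle."""

    start: int
    end: int
    reason: str  # "dilution-event" | "fixed-interval"

    def __post_init__(self) -> None:
        if self.end - self.start < 3:
            raise ValueError("cycle must contain at least 3 points")


@dataclass
class GrowthRateEstimate:
    mu: float  # h^-1, median over cycles
    n_cycles: int
    per_cycle_mu: np.ndarray
    ci95: tuple[float, float]


@dataclass
class PhaseSegmentation:
    boundaries: list[int]  # start index of each phase
    phase_labels: list[str]  # "fast" | "decline" | "steady"


# ---------------------------------------------------------------------------


def segment_cycles(
    trace: ODTrace, drop_fraction: float = 0.05, max_interval: float = 2.0
) -> list[DilutionCycle]:
    """Split a trace into dilution cycles and fixed-interval windows.

    A new cycle starts after any between-sample relative OD decrease larger
    than ``drop_fraction``.  A segment that ends at a dilution event is one
    cycle regardless of length; a dilution-free stretch (the tail of the
    trace, or the whole trace when no dilution occurred) is cut into windows
    of at most ``max_interval`` hours.  Windows with fewer than three points
    are discarded.
    """
    t, od = trace.times, trace.od
    rel = np.diff(od) / od[:-1]
    breaks = [0, *(int(i) + 1 for i in np.nonzero(rel < -drop_fraction)[0]), t.size]

    cycles: list[DilutionCycle] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a < 2:
            continue
        if b < t.size:  # segment terminated by a dilution event
            if b - a >= 3:
                cycles.append(DilutionCycle(a, b, "dilution-event"))
            continue
        span = t[b - 1] - t[a]
        if span <= max_interval and len(breaks) > 2:
            # short tail after the last dilution of a diluted trace
            if b - a >= 3:
                cycles.append(DilutionCycle(a, b, "dilution-event"))
            continue
        # split the dilution-free stretch into fixed windows
        edges = np.arange(t[a], t[b - 1], max_interval)
        edges = np.append(edges, t[b - 1] + 1e-12)
        idx_all = np.arange(t.size)
        for lo, hi in zip(edges[:-1], edges[1:]):
            idx = np.nonzero((t >= lo) & (t < hi) & (idx_all >= a) & (idx_all < b))[0]
            if idx.size >= 3:
                cycles.append(
                    DilutionCycle(int(idx[0]), int(idx[-1]) + 1, "fixed-interval")
                )
    return cycles


def fit_cycle_mu(times, od) -> tuple[float, float]:
    """Single-exponential fit of one cycle: OLS slope of ln(OD) vs time.

    Returns ``(mu, r_squared)`` of the log-linear fit.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 points to fit a cycle")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    y = np.log(od)
    slope, intercept = np.polyfit(times, y, 1)
    resid = y - (slope * times + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def estimate_mu(
    trace: ODTrace,
    drop_fraction: float = 0.05,
    max_interval: float = 2.0,
    phase_filter: bool = False,
    min_r2: float = 0.9,
    n_boot: int = 2000,
    random_state: int | None = 0,
) -> GrowthRateEstimate:
    """Median-of-cycles growth rate with a bootstrap CI (functional API)."""
    est = TurbidostatGrowthEstimator(
        drop_fraction=drop_fraction,
        max_interval=max_interval,
        phase_filter=phase_filter,
        min_r2=min_r2,
        n_boot=n_boot,
        random_state=random_state,
    ).fit(trace)
    return GrowthRateEstimate(
        mu=est.mu_, n_cycles=est.n_cycles_, per_cycle_mu=est.per_cycle_mu_, ci95=est.ci95_
    )


def _window_mus(
    trace: ODTrace, window_h: float, drop_fraction: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Log-linear slope in consecutive windows of at most ``window_h`` hours.

    Windows never span a dilution event, and long segments (including long
    dilution cycles) are always subdivided so that phase structure within
    them is visible.
    """
    t, od = trace.times, trace.od
    rel = np.diff(od) / od[:-1]
    breaks = [0, *(int(i) + 1 for i in np.nonzero(rel < -drop_fraction)[0]), t.size]
    mus, starts = [], []
    idx_all = np.arange(t.size)
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a < 3:
            continue
        edges = np.arange(t[a], t[b - 1], window_h)
        edges = np.append(edges, t[b - 1] + 1e-12)
        for lo, hi in zip(edges[:-1], edges[1:]):
            idx = np.nonzero((t >= lo) & (t < hi) & (idx_all >= a) & (idx_all < b))[0]
            if idx.size >= 3:
                mu, _ = fit_cycle_mu(t[idx], od[idx])
                mus.append(mu)
                starts.append(int(idx[0]))
    return np.asarray(mus), starts


def detect_growth_phases(
    trace: ODTrace,
    window_h: float = 2.0,
    smooth: int = 5,
    decline_threshold: float = 0.0,
) -> PhaseSegmentation:
    """Segment a trace into fast / decline / steady growth phases.

    The trace is cut into windows and each window's log-linear slope computed;
    the slope sequence is smoothed with a centred moving average of length
    ``smooth``.  A sustained negative stretch separates an initial "fast"
    phase from a final "steady" phase.  A trace with no sustained decline is
    returned as a single phase.
    """
    mus, starts = _window_mus(trace, window_h)
    if mus.size == 0:
        raise ValueError("trace too short to segment into phases")
    if mus.size >= smooth > 1:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(mus, kernel, mode="same")
    else:
        sm = mus
    neg = sm < decline_threshold
    if not neg.any():
        return PhaseSegmentation(boundaries=[0], phase_labels=["steady"])
    first_neg = int(np.argmax(neg))
    after = np.nonzero(~neg & (np.arange(neg.size) > first_neg))[0]
    boundaries, labels = [], []
    if first_neg > 0:
        boundaries.append(0)
        labels.append("fast")
    boundaries.append(starts[first_neg])
    labels.append("decline")
    if after.size:
        boundaries.append(starts[int(after[0])])
        labels.append("steady")
    return PhaseSegmentation(boundaries=boundaries, phase_labels=labels)


def cfu_from_od(od600: float, cfu_per_od: float = CFU_PER_OD) -> float:
    """Viable-cell count per mL from OD600 via the linear calibration."""
    od600 = np.asarray(od600, dtype=float)
    if np.any(od600 < 0):
        raise ValueError("OD600 cannot be negative")
    out = cfu_per_od * od600
    return float(out) if out.ndim == 0 else out


def fold_change(
    mu_numerator: float,
    mu_denominator: float,
    per_cycle_numerator=None,
    per_cycle_denominator=None,
    n_boot: int = 2000,
    random_state: int | None = 0,
) -> tuple[float, tuple[float, float] | None]:
    """Ratio of two growth rates, optionally with a bootstrap CI.

    The CI resamples the two per-cycle rate lists and takes the ratio of
    medians; it is ``None`` when per-cycle rates are not supplied.
    """
    if mu_denominator <= 0:
        raise ValueError("denominator growth rate must be positive")
    ratio = mu_numerator / mu_denominator
    ci = None
    if per_cycle_numerator is not None and per_cycle_denominator is not None:
        rng = np.random.default_rng(random_state)
        a = np.asarray(per_cycle_numerator, dtype=float)
        b = np.asarray(per_cycle_denominator, dtype=float)
        boots = np.median(
            rng.choice(a, size=(n_boot, a.size)), axis=1
        ) / np.median(rng.choice(b, size=(n_boot, b.size)), axis=1)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return ratio, ci


# ---------------------------------------------------------------------------


class TurbidostatGrowthEstimator(BaseEstimator):
    """Median-of-cycles growth-rate estimator for turbidostat traces.

    Parameters
    ----------
    drop_fraction : relative OD decrease that marks a dilution event.
    max_interval : h; dilution-free stretches are cut into windows this long.
    phase_filter : restrict the estimate to the final steady growth phase.
    min_r2 : cycles whose log-linear fit has R^2 below this are excluded.
    min_cycles_warn : warn when fewer cycles than this survive (the
        experimental protocol used more than 6 cycles per vial).
    n_boot, random_state : bootstrap settings for the CI on the median.

    Attributes
    ----------
    mu_ : median growth rate (h^-1)
    per_cycle_mu_ : rates of the retained cycles
    n_cycles_ : number of retained cycles
    ci95_ : bootstrap 95% CI on the median
    cycles_ : the retained :class:`DilutionCycle` windows
    phases_ : phase segmentation (only when ``phase_filter``)
    """

    def __init__(
        self,
        drop_fraction: float = 0.05,
        max_interval: float = 2.0,
        phase_filter: bool = False,
        min_r2: float = 0.9,
        min_cycles_warn: int = 7,
        n_boot: int = 2000,
        random_state: int | None = 0,
    ) -> None:
        self.drop_fraction = drop_fraction
        self.max_interval = max_interval
        self.phase_filter = phase_filter
        self.min_r2 = min_r2
        self.min_cycles_warn = min_cycles_warn
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, trace: ODTrace, y=None) -> "TurbidostatGrowthEstimator":
        if not isinstance(trace, ODTrace):
            raise TypeError("fit expects an ODTrace")
        work = trace
        if self.phase_filter:
            phases = detect_growth_phases(trace, window_h=self.max_interval)
            self.phases_ = phases
            steadies = [
                i for i, lab in enumerate(phases.phase_labels) if lab != "decline"
            ]
            if phases.phase_labels == ["decline"] or not steadies:
                raise ValueError("no positive-growth cycle: trace only declines")
            last = steadies[-1]
            start = phases.boundaries[last]
            end = (
                phases.boundaries[last + 1]
                if last + 1 < len(phases.boundaries)
                else trace.times.size
            )
            work = ODTrace(
                times=trace.times[start:end],
                od=trace.od[start:end],
                vial_id=trace.vial_id,
                medium=trace.medium,
            )
        cycles = segment_cycles(work, self.drop_fraction, self.max_interval)
        kept, mus = [], []
        for c in cycles:
            mu, r2 = fit_cycle_mu(work.times[c.start : c.end], work.od[c.start : c.end])
            if r2 < self.min_r2:
                warnings.warn(
                    f"cycle [{c.start},{c.end}) excluded: log-linear R^2={r2:.3f}"
                )
                continue
            kept.append(c)
            mus.append(mu)
        if not kept:
            raise ValueError("no valid dilution cycle in trace")
        if len(kept) < self.min_cycles_warn:
            warnings.warn(
                f"only {len(kept)} cycles (<{self.min_cycles_warn}); "
                "median may be unstable"
            )
        mus_arr = np.asarray(mus)
        rng = np.random.default_rng(self.random_state)
        boots = np.median(
            rng.choice(mus_arr, size=(self.n_boot, mus_arr.size)), axis=1
        )
        self.cycles_ = kept
        self.per_cycle_mu_ = mus_arr
        self.n_cycles_ = len(kept)
        self.mu_ = float(np.median(mus_arr))
        self.ci95_ = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        return self

    def predict(self, trace: ODTrace | None = None) -> float:
        """Return the fitted growth rate (h^-1)."""
        return self.mu_
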