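"""Vitamin B6 quantification: standard curves, per-cfu content, accumulation rate.

Total B6 vitamers in cell lysates and spent medium are measured by converting
all vitamers to the fluorescent 4-pyridoxolactone (4-PLA) and reading the
signal against a standard curve (linear for 4-PLA, quadratic for the DNA and
protein assays).  Concentrations are back-corrected through an explicit
dilution ledger — the ordered multiplicative factors introduced by each
reagent addition — converted to absolute pmol via the processed volumes, and
normalised per 10^9 cfu.

Assuming the cell's B6 pool must double once per division, the per-cfu content
divided by the doubling time (ln 2 / mu) gives the B6 accumulation rate in
pmol/(10^9 cfu * h), the statistic used to compare strains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StandardCurveModel",
    "B6Content",
    "AccumulationRate",
    "PROTOCOL_LEDGERS",
    "fit_standard_curve",
    "invert_curve",
    "apply_ledger",
    "back_correct",
    "total_b6_per_cfu",
    "accumulation_rate",
]

#: Per-protocol dilution ledgers: ordered (step, multiplicative factor) pairs.
#: Factors are cumulative volume ratios of the successive reagent additions
#: (e.g. adding 20 uL to 200 uL of lysate dilutes by 220/200), so the product
#: of a ledger converts a measured concentration back to the original sample.
PROTOCOL_LEDGERS: dict[str, tuple[tuple[str, float], ...]] = {
    "lysate": (
        ("digestion_mix", 220 / 200),
        ("pmsf", 225 / 220),
        ("conversion_mix", 390 / 225),
        ("pldh", 450 / 390),
        ("proteinase_k", 470 / 450),
    ),
    "spent_medium": (
        ("edta", 217 / 195),
        ("naoh", 225 / 217),
        ("conversion_mix", 390 / 225),
        ("pldh", 450 / 390),
        ("proteinase_k", 470 / 450),
    ),
}


# ---------------------------------------------------------------------------
# standard curves


class StandardCurveModel(RegressorMixin, BaseEstimator):
    """Linear or quadratic calibration curve with monotone inversion.

    Parameters
    ----------
    model : "linear" or "quadratic".

    Attributes
    ----------
    coefficients_ : polynomial coefficients, highest degree first.
    r_squared_ : coefficient of determination of the fit.
    concentration_range_ : (lo, hi) of the fitted standards.
    response_range_ : (lo, hi) of predicted responses over that range.
    """

    def __init__(self, model: str = "linear") -> None:
        self.model = model

    # -- fitting ------------------------------------------------------------

    def fit(self, concentrations, responses) -> "StandardCurveModel":
        conc = np.asarray(concentrations, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if self.model not in ("linear", "quadratic"):
            raise ValueError("model must be 'linear' or 'quadratic'")
        degree = 1 if self.model == "linear" else 2
        if conc.size < degree + 2:
            raise ValueError(
                f"{self.model} curve needs at least {degree + 2} standards"
            )
        if np.any(conc < 0):
            raise ValueError("standard concentrations must be non-negative")
        if np.ptp(resp) == 0:
            raise ValueError("constant responses: zero-slope curve cannot be inverted")
        coefs = np.polyfit(conc, resp, degree)
        lo, hi = float(conc.min()), float(conc.max())
        deriv = np.polyder(coefs)
        grid = np.linspace(lo, hi, 257)
        dvals = np.polyval(deriv, grid)
        if np.any(dvals > 0) and np.any(dvals < 0):
            raise ValueError("fitted curve is not monotone over the standard range")
        fitted = np.polyval(coefs, conc)
        ss_res = float(((resp - fitted) ** 2).sum())
        ss_tot = float(((resp - resp.mean()) ** 2).sum())
        self.coefficients_ = coefs
        self.r_squared_ = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
        self.concentration_range_ = (lo, hi)
        ends = np.polyval(coefs, [lo, hi])
        self.response_range_ = (float(min(ends)), float(max(ends)))
        self.increasing_ = bool(ends[1] >= ends[0])
        return self

    def predict(self, concentrations) -> np.ndarray:
        conc = np.asarray(concentrations, dtype=float)
        return np.polyval(self.coefficients_, conc)

    # -- inversion ----------------------------------------------------------

    def inverse_predict(self, responses, clip_blank: bool = True) -> np.ndarray:
        """Concentration(s) producing the given response(s).

        Responses below the blank (the response at the low end of the curve)
        are clipped to the low concentration with a warning when
        ``clip_blank``; responses above the invertible range raise.
        """
        resp = np.atleast_1d(np.asarray(responses, dtype=float))
        lo, hi = self.concentration_range_
        rlo, rhi = self.response_range_
        blank = rlo if self.increasing_ else rhi
        out = np.empty_like(resp)
        for i, r in enumerate(resp):
            below = r < rlo - 1e-9 * max(1.0, abs(rlo))
            above = r > rhi + 1e-9 * max(1.0, abs(rhi))
            under_blank = (r < blank) if self.increasing_ else (r > blank)
            if under_blank and clip_blank:
                warnings.warn(
                    f"response {r!r} below the blank; concentration clipped to {lo}"
                )
                out[i] = lo
                continue
            if below or above:
                raise ValueError(
                    f"response {r!r} outside the invertible range "
                    f"[{rlo:.6g}, {rhi:.6g}]"
                )
            out[i] = self._invert_one(r, lo, hi)
        return out if np.ndim(responses) else float(out[0])

    def _invert_one(self, r: float, lo: float, hi: float) -> float:
        coefs = self.coefficients_.copy()
        if self.model == "linear":
            a, b = coefs
            return (r - b) / a
        roots = np.roots(coefs - np.array([0.0, 0.0, r]))
        real = sorted(
            float(x.real)
            for x in roots
            if abs(x.imag) < 1e-9 * max(1.0, abs(x.real))
        )
        tol = 1e-9 * max(1.0, hi - lo)
        in_range = [x for x in real if lo - tol <= x <= hi + tol]
        if not in_range:
            raise ValueError(f"no root of the quadratic within [{lo}, {hi}] for {r!r}")
        return float(np.clip(in_range[0], lo, hi))  # ties -> smaller concentration


def fit_standard_curve(concentrations, responses, model: str = "linear") -> StandardCurveModel:
    """Fit a calibration curve (functional wrapper over the estimator)."""
    return StandardCurveModel(model=model).fit(concentrations, responses)


def invert_curve(curve: StandardCurveModel, response):
    """Back-calculate concentration(s) from response(s) on a fitted curve."""
    return curve.inverse_predict(response)


# ---------------------------------------------------------------------------
# dilution ledger


def _ledger_factor(ledger) -> float:
    if ledger is None:
        raise ValueError(
            "missing dilution ledger: pass an explicit (possibly empty) ledger "
            "or a protocol preset name"
        )
    if isinstance(ledger, str):
        try:
            ledger = PROTOCOL_LEDGERS[ledger]
        except KeyError:
            raise ValueError(
                f"unknown protocol preset {ledger!r}; known: {sorted(PROTOCOL_LEDGERS)}"
            ) from None
    factor = 1.0
    for entry in ledger:
        name, f = entry
        if not np.isfinite(f) or f <= 0:
            raise ValueError(f"ledger step {name!r} has invalid factor {f!r}")
        factor *= f
    return factor


def apply_ledger(concentration: float, ledger) -> float:
    """Concentration after the ledger's dilution steps are applied."""
    return concentration / _ledger_factor(ledger)


def back_correct(concentration: float, ledger) -> float:
    """Original concentration given the measured (diluted) one."""
    return concentration * _ledger_factor(ledger)


# ---------------------------------------------------------------------------
# content and accumulation rate


@dataclass
class B6Content:
    """Total B6 vitamers per 10^9 cfu, split into lysate and medium parts."""

    content: float  # pmol per 1e9 cfu
    lysate_component: float
    medium_component: float
    dilution_ledger: dict = field(default_factory=dict)


@dataclass
class AccumulationRate:
    rate: float  # pmol / (1e9 cfu * h)
    doubling_time: float  # h
    ci95: tuple[float, float] | None = None


def total_b6_per_cfu(
    lysate_conc: float,
    medium_conc: float,
    lysate_volume_ml: float,
    medium_volume_ml: float,
    cfu: float,
    lysate_ledger="lysate",
    medium_ledger="spent_medium",
) -> B6Content:
    """Combine lysate and spent-medium 4-PLA concentrations into per-cfu content.

    Concentrations are in nM (= pmol/mL) as measured in the final assay
    mixtures; each is back-corrected through its dilution ledger, converted to
    absolute pmol via the processed volume, summed, and normalised to 10^9 cfu.
    """
    if cfu <= 0:
        raise ValueError("cfu must be positive")
    if lysate_volume_ml <= 0 or medium_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    if lysate_conc < 0 or medium_conc < 0:
        raise ValueError("concentrations cannot be negative")
    lys_factor = _ledger_factor(lysate_ledger)
    med_factor = _ledger_factor(medium_ledger)
    scale = 1e9 / cfu
    lys = lysate_conc * lys_factor * lysate_volume_ml * scale
    med = medium_conc * med_factor * medium_volume_ml * scale
    return B6Content(
        content=lys + med,
        lysate_component=lys,
        medium_component=med,
        dilution_ledger={"lysate": lys_factor, "spent_medium": med_factor},
    )


def accumulation_rate(
    content,
    mu: float,
    content_ci: tuple[float, float] | None = None,
    mu_ci: tuple[float, float] | None = None,
) -> AccumulationRate:
    """B6 accumulation rate: per-cfu content divided by the doubling time.

    ``content`` may be a :class:`B6Content` or a plain pmol/1e9-cfu value.
    The doubling time is ln 2 / mu.  When CIs on content and mu are given,
    the CI on the rate is propagated assuming independent relative errors.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    c = content.content if isinstance(content, B6Content) else float(content)
    if c < 0:
        raise ValueError("content cannot be negative")
    doubling = math.log(2) / mu
    rate = c / doubling
    ci = None
    if content_ci is not None or mu_ci is not None:
        rel_var = 0.0
        if content_ci is not None and c > 0:
            rel_var += ((content_ci[1] - content_ci[0]) / (2 * 1.96 * c)) ** 2
        if mu_ci is not None:
            rel_var += ((mu_ci[1] - mu_ci[0]) / (2 * 1.96 * mu)) ** 2
        half = 1.96 * rate * math.sqrt(rel_var)
        ci = (max(rate - half, 0.0), rate + half)
    return AccumulationRate(rate=rate, doubling_time=doubling, ci95=ci)
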