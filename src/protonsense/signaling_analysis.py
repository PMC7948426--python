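"""Quantitative readouts of receptor signaling: yeast fluorescence
normalization, deep-variant-profiling (DVP) fold-change scoring, netBRET, and
four-parameter-logistic (4PL) pH titration fits.

In the yeast reporter platform, receptor activity drives expression of a
fluorescent reporter; raw fluorescence scales with culture density, so each
strain's readout is the fluorescence extrapolated to a standard optical
density (A600 = 1.0) from a linear fluorescence-vs-A600 fit.  Variant effects
are scored as log2 fold change against the matched wild type, with calls of
increase / no change / decrease at a configurable threshold (0.5 for the pH
5.0 screen; 2.0 for GPR4 and GPR68 and 0.5 for GPR65 at pH 7.0).

In the BRET mini-G-protein assay, coupling is read as the acceptor/donor
emission ratio minus a donor-only baseline (netBRET).  pH titrations are fit
with a 4PL in pH; the midpoint pH50 is the proton analogue of -log EC50, and
a variant's ΔpH50 = pH50(mutant) - pH50(WT) measures how far its proton
activation is shifted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy import stats

NONFUNCTIONAL = float("-inf")  # sentinel fold change for dead strains

DVP_CALLS = ("increase", "no_change", "decrease", "nonfunctional")


@dataclass
class GrowthSeries:
    """Fluorescence vs culture density observations for one strain replicate."""

    strain_id: str
    replicate: int
    observations: list[tuple[float, float]]  # (A600, fluorescence)


@dataclass
class ExtrapolatedFluorescence:
    """Fluorescence standardized to A600 = 1.0 via an OLS line."""

    value: float  # slope + intercept, i.e. the line at A600 = 1.0
    slope: float
    intercept: float
    slope_stderr: float


@dataclass
class BretReading:
    acceptor_intensity: float  # 520 nm channel
    donor_intensity: float  # 482 nm channel
    donor_only_ratio: float  # acceptor/donor baseline of donor-only cells


@dataclass
class TitrationFit:
    """4PL parameters for one pH-response curve, with standard errors."""

    bottom: float
    top: float
    ph50: float
    hill_slope: float
    bottom_stderr: float
    top_stderr: float
    ph50_stderr: float
    hill_slope_stderr: float
    residual_ss: float
    converged: bool
    extrapolated: bool  # pH50 outside the data range extended by 1 pH unit

    def predict(self, ph: np.ndarray) -> np.ndarray:
        return four_parameter_logistic(
            np.asarray(ph, float), self.bottom, self.top, self.ph50, self.hill_slope
        )


def normalize_fluorescence(series: GrowthSeries) -> ExtrapolatedFluorescence:
    """Extrapolate fluorescence to A600 = 1.0 from a linear growth series.

    Fits fluorescence = slope * A600 + intercept by ordinary least squares and
    evaluates the line at A600 = 1.0; the slope standard error is reported.
    """
    if len(series.observations) < 2:
        raise ValueError("at least 2 observations required")
    a600 = np.array([o[0] for o in series.observations], float)
    fluor = np.array([o[1] for o in series.observations], float)
    if np.any(a600 <= 0):
        raise ValueError("A600 values must be positive")
    if np.ptp(a600) < 1e-12:
        raise ValueError("all A600 values identical; line is undefined")
    fit = stats.linregress(a600, fluor)
    return ExtrapolatedFluorescence(
        value=float(fit.slope + fit.intercept),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_stderr=float(fit.stderr) if len(a600) > 2 else float("nan"),
    )


def log2_fc(mutant_f: float, wt_f: float) -> float:
    """log2 fold change of mutant vs wild-type normalized fluorescence.

    A mutant fluorescence of zero returns the nonfunctional sentinel (-inf).
    """
    if wt_f <= 0:
        raise ValueError("wild-type fluorescence must be positive")
    if mutant_f < 0:
        raise ValueError("mutant fluorescence must be non-negative")
    if mutant_f == 0:
        return NONFUNCTIONAL
    return math.log2(mutant_f / wt_f)


def call_dvp(fc: float, threshold: float = 0.5) -> str:
    """Score a log2 fold change as increase / no_change / decrease.

    The band |fc| ≤ threshold (inclusive) is no change; the nonfunctional
    sentinel maps to 'nonfunctional'.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if fc == NONFUNCTIONAL:
        return "nonfunctional"
    if not np.isfinite(fc):
        raise ValueError(f"non-finite fold change {fc!r}")
    if fc > threshold:
        return "increase"
    if fc < -threshold:
        return "decrease"
    return "no_change"


def is_functional(fluorescence: float, control_mean: float, control_sd: float) -> bool:
    """A strain signals detectably when its fluorescence exceeds the matched
    no-receptor control mean by more than 2 SD."""
    return fluorescence > control_mean + 2.0 * control_sd


@dataclass
class SummedFoldChange:
    total: float
    n_included: int
    excluded_count: int  # nonfunctional sentinels left out of the sum


def sum_fc(fold_changes: list[float]) -> SummedFoldChange:
    """Sum of a mutant's log2 fold changes across its strains.

    Nonfunctional sentinels are excluded from the sum and counted.
    """
    finite = [fc for fc in fold_changes if np.isfinite(fc)]
    excluded = sum(1 for fc in fold_changes if fc == NONFUNCTIONAL)
    if len(finite) + excluded != len(fold_changes):
        raise ValueError("fold changes must be finite or the nonfunctional sentinel")
    if not finite:
        raise ValueError("no finite fold changes to sum")
    return SummedFoldChange(float(np.sum(finite)), len(finite), excluded)


def net_bret(reading: BretReading, flip_sign: bool = False) -> float:
    """netBRET: acceptor/donor emission ratio minus the donor-only baseline.

    The sign convention makes netBRET positive when coupling exceeds the
    baseline; ``flip_sign`` yields the literal baseline-minus-ratio reading.
    """
    if reading.donor_intensity <= 0:
        raise ValueError("donor intensity must be positive")
    value = reading.acceptor_intensity / reading.donor_intensity - reading.donor_only_ratio
    return -value if flip_sign else value


def four_parameter_logistic(
    ph: np.ndarray, bottom: float, top: float, ph50: float, hill_slope: float
) -> np.ndarray:
    """4PL in pH: response = bottom + (top - bottom) / (1 + 10^(slope*(pH - pH50))).

    With hill_slope > 0 the response decreases as pH rises (acid-activated):
    top is the low-pH plateau, bottom the high-pH plateau, pH50 the midpoint.
    """
    return bottom + (top - bottom) / (1.0 + np.power(10.0, hill_slope * (ph - ph50)))


_SLOPE_STARTS = (0.5, 1.0, 2.0)
_PH50_PERCENTILES = (20.0, 50.0, 80.0)


def fit_titration(
    curve: list[tuple[float, float]], direction: str = "acid_activated"
) -> TitrationFit:
    """Fit a pH-response curve with the four-parameter logistic.

    Requires at least 5 points spanning at least 1 pH unit with non-zero
    response variance.  Initialization is a fixed multistart grid: bottom/top
    from the data min/max, pH50 at the 20th/50th/80th percentile pH, slope in
    {0.5, 1, 2}; the start with the lowest residual sum of squares wins.
    For acid-activated curves the Hill slope is constrained positive.
    """
    if direction != "acid_activated":
        raise ValueError("only acid_activated curves are supported")
    ph = np.array([c[0] for c in curve], float)
    resp = np.array([c[1] for c in curve], float)
    if len(ph) < 5:
        raise ValueError("at least 5 (pH, response) points required")
    if np.ptp(ph) < 1.0:
        raise ValueError("pH values must span at least 1 pH unit")
    if np.ptp(resp) < 1e-12 or np.std(resp) == 0:
        raise ValueError("zero variance in responses; nothing to fit")

    model = Model(four_parameter_logistic, independent_vars=["ph"])
    span = float(np.ptp(resp))
    best = None
    for ph50_start in np.percentile(ph, _PH50_PERCENTILES):
        for slope_start in _SLOPE_STARTS:
            params = model.make_params(
                bottom=float(resp.min()),
                top=float(resp.max()),
                ph50=float(ph50_start),
                hill_slope=slope_start,
            )
            params["hill_slope"].set(min=1e-3, max=50.0)
            params["top"].set(min=float(resp.min()) - 10 * span)
            params["bottom"].set(max=float(resp.max()) + 10 * span)
            try:
                result = model.fit(resp, params, ph=ph)
            except Exception:
                continue
            if best is None or result.chisqr < best.chisqr:
                best = result
    if best is None:
        raise RuntimeError("4PL fit failed from every start")

    def _stderr(name: str) -> float:
        err = best.params[name].stderr
        return float(err) if err is not None else float("nan")

    ph50 = float(best.params["ph50"].value)
    extrapolated = not (ph.min() - 1.0 <= ph50 <= ph.max() + 1.0)
    return TitrationFit(
        bottom=float(best.params["bottom"].value),
        top=float(best.params["top"].value),
        ph50=ph50,
        hill_slope=float(best.params["hill_slope"].value),
        bottom_stderr=_stderr("bottom"),
        top_stderr=_stderr("top"),
        ph50_stderr=_stderr("ph50"),
        hill_slope_stderr=_stderr("hill_slope"),
        residual_ss=float(best.chisqr),
        converged=bool(best.success),
        extrapolated=extrapolated,
    )


@dataclass
class DeltaPh50:
    value: float  # mutant pH50 - WT pH50; positive = right-shifted
    stderr: float  # propagated in quadrature


def delta_ph50(mutant: TitrationFit, wt: TitrationFit) -> DeltaPh50:
    """ΔpH50 = mutant pH50 - wild-type pH50, with quadrature-propagated SE."""
    if not (mutant.converged and wt.converged):
        raise ValueError("both fits must have converged")
    se = math.sqrt(
        (0.0 if math.isnan(mutant.ph50_stderr) else mutant.ph50_stderr) ** 2
        + (0.0 if math.isnan(wt.ph50_stderr) else wt.ph50_stderr) ** 2
    )
    return DeltaPh50(value=mutant.ph50 - wt.ph50, stderr=se)
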