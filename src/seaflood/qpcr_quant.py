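"""Absolute qPCR quantification: standard curve, Cq to copies per g dry soil.

A dilution series of known template amounts (here 10^1–10^7 copies) gives a
standard curve Cq = intercept + slope·log10(copies); the amplification
efficiency is 10^(−1/slope) − 1 (slope −3.3219 ⇔ perfect doubling).  Sample
Cq values (duplicates averaged on the Cq scale) are inverted through the
curve to copies per reaction, then normalised through the extraction chain —
reaction → extract → dry soil — with every dilution factor an explicit
input (template volume, elution volume, wet mass, water content).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

#: Duplicates further apart than this (Cq units) are flagged discordant.
DUPLICATE_DISCORDANCE_CQ = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution series for one gene."""

    gene: str
    slope: float              # Cq per log10 copies, < 0
    intercept: float          # Cq at 1 copy
    r_squared: float
    efficiency: float         # 10^(-1/slope) - 1
    dynamic_range: tuple[float, float]   # copies, (min, max) of standards

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_from_copies(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Duplicate Cq values for one sample/gene plus the normalisation chain."""

    sample_id: str
    gene: str
    cq_values: tuple[float, ...]
    template_uL: float
    elution_uL: float
    wet_mass_g: float
    water_content: float

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cq_values):
            raise InputError("Cq values must be > 0")
        if self.template_uL <= 0 or self.elution_uL <= 0:
            raise InputError("volumes must be > 0")
        if not (0.0 <= self.water_content < 1.0):
            raise InputError(f"water_content must be in [0,1), got {self.water_content}")
        if self.wet_mass_g * (1.0 - self.water_content) <= 0:
            raise InputError("dry mass must be > 0")


@dataclass(frozen=True)
class QuantResult:
    """Copies per gram dry soil with quality flags and a duplicate-based CI."""

    sample_id: str
    gene: str
    mean_cq: float
    copies_per_reaction: float
    copies_per_g_dry: float
    ci_low: float             # nan when < 2 replicates
    ci_high: float
    duplicate_spread_cq: float
    extrapolated: bool        # mean Cq outside the curve's dynamic range
    below_quantification: bool
    discordant_duplicates: bool


def fit_standard_curve(standards: list[tuple[float, float]], gene: str = "",
                       ) -> StandardCurve:
    """OLS of Cq on log10(copies) over a dilution series.

    Requires at least 3 points spanning at least 2 decades; a positive slope
    means the dilution series is inverted and is an error.
    """
    if len(standards) < 3:
        raise InputError("standard curve needs >= 3 dilution points")
    copies = np.array([c for c, _ in standards], float)
    cq = np.array([q for _, q in standards], float)
    if (copies <= 0).any():
        raise InputError("standard copies must be > 0")
    logc = np.log10(copies)
    if np.ptp(logc) < 2.0:
        raise InputError("standards must span >= 2 decades of copies")
    res = stats.linregress(logc, cq)
    if res.slope >= 0:
        raise InputError(f"positive standard-curve slope ({res.slope:.3g}): "
                         "inverted standards")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(gene=gene, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2,
                         efficiency=float(efficiency),
                         dynamic_range=(float(copies.min()), float(copies.max())))


def quantify(m: QpcrMeasurement, curve: StandardCurve) -> QuantResult:
    """Copies per g dry soil from duplicate Cq values through the curve.

    Duplicates are averaged on the Cq scale.  The normalisation is
    copies/reaction × (elution/template) / (wet mass × (1 − water content)).
    The confidence interval propagates the duplicate spread through the
    curve with a t interval on the mean Cq (df = n − 1).  Values below the
    lowest standard are reported but flagged below quantification.
    """
    cq = np.array(m.cq_values, float)
    mean_cq = float(cq.mean())
    spread = float(np.ptp(cq))
    copies_rxn = curve.copies_from_cq(mean_cq)
    dry_mass = m.wet_mass_g * (1.0 - m.water_content)
    factor = (m.elution_uL / m.template_uL) / dry_mass
    copies_g = copies_rxn * factor

    if len(cq) >= 2:
        se = float(cq.std(ddof=1)) / math.sqrt(len(cq))
        tcrit = stats.t.ppf(0.975, df=len(cq) - 1)
        lo_cq, hi_cq = mean_cq - tcrit * se, mean_cq + tcrit * se
        # copies decrease with Cq, so the interval flips
        ci_low = curve.copies_from_cq(hi_cq) * factor
        ci_high = curve.copies_from_cq(lo_cq) * factor
    else:
        ci_low = ci_high = math.nan

    lo, hi = curve.dynamic_range
    extrapolated = not (lo <= copies_rxn <= hi)
    return QuantResult(
        sample_id=m.sample_id, gene=m.gene, mean_cq=mean_cq,
        copies_per_reaction=float(copies_rxn), copies_per_g_dry=float(copies_g),
        ci_low=float(ci_low), ci_high=float(ci_high),
        duplicate_spread_cq=spread, extrapolated=extrapolated,
        below_quantification=bool(copies_rxn < lo),
        discordant_duplicates=bool(spread > DUPLICATE_DISCORDANCE_CQ))
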