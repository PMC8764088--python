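"""Coverage-weighted basin upscaling of per-forest-type flux estimates.

Per-type geometric-mean fluxes (with 95% CI bounds) are combined into a
basin-wide average weighted by forest-cover fractions — lowland 90.6%,
swamp 6.8%, montane 2.6% for the Congo Basin humid forest.  The swamp
type is itself a composite of inundated and non-inundated regimes,
mixed by the inundated area fraction f (default 0.5, the value that
reconciles the printed basin-wide CH₄ and N₂O averages).

CI bounds are combined bound-wise (weighted sum of lower bounds, of
upper bounds), which is validated against the published basin intervals;
a quadrature option is provided for callers who prefer independent-error
propagation of the half-widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

FOREST_TYPES = ("lowland", "swamp", "montane")


@dataclass(frozen=True)
class CoverageWeights:
    """Forest-cover area fractions plus the inundated share of swamp area."""

    lowland: float = 0.906
    swamp: float = 0.068
    montane: float = 0.026
    inundated_fraction: float = 0.5

    def __post_init__(self) -> None:
        w = (self.lowland, self.swamp, self.montane)
        if any(x < 0 for x in w):
            raise ValueError("coverage weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"coverage weights must sum to 1, got {sum(w)}")
        if not 0.0 <= self.inundated_fraction <= 1.0:
            raise ValueError("inundated_fraction must be in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"lowland": self.lowland, "swamp": self.swamp, "montane": self.montane}


@dataclass(frozen=True)
class TypeEstimate:
    """Point estimate and 95% CI for one forest type [kg element ha⁻¹ yr⁻¹]."""

    forest_type: str
    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError(
                f"{self.forest_type}: CI [{self.ci_low}, {self.ci_high}] "
                f"must bracket the point {self.point}"
            )


def swamp_composite(
    inundated: TypeEstimate, non_inundated: TypeEstimate, f: float = 0.5
) -> TypeEstimate:
    """Area-weighted mix of the inundated and non-inundated swamp regimes.

    Point and each CI bound combine as f·inundated + (1−f)·non_inundated.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"inundated fraction must be in [0, 1], got {f}")
    mix = lambda a, b: f * a + (1.0 - f) * b
    return TypeEstimate(
        forest_type="swamp",
        point=mix(inundated.point, non_inundated.point),
        ci_low=mix(inundated.ci_low, non_inundated.ci_low),
        ci_high=mix(inundated.ci_high, non_inundated.ci_high),
    )


def basin_weighted_mean(
    estimates: dict[str, TypeEstimate],
    weights: CoverageWeights = CoverageWeights(),
    ci_method: str = "boundwise",
) -> TypeEstimate:
    """Coverage-weighted basin-wide flux from the three forest-type estimates.

    ``estimates`` must contain lowland, swamp (already composited) and
    montane, all in the same units.  CI bounds combine bound-wise by
    default; ``ci_method="quadrature"`` instead propagates half-widths
    as √Σ(wᵢ·hᵢ)² about the weighted point.
    """
    missing = [t for t in FOREST_TYPES if t not in estimates]
    if missing:
        raise ValueError(f"missing forest type estimate(s): {missing}")
    w = weights.as_dict()
    point = sum(w[t] * estimates[t].point for t in FOREST_TYPES)
    if ci_method == "boundwise":
        lo = sum(w[t] * estimates[t].ci_low for t in FOREST_TYPES)
        hi = sum(w[t] * estimates[t].ci_high for t in FOREST_TYPES)
    elif ci_method == "quadrature":
        half_lo = math.sqrt(
            sum((w[t] * (estimates[t].point - estimates[t].ci_low)) ** 2 for t in FOREST_TYPES)
        )
        half_hi = math.sqrt(
            sum((w[t] * (estimates[t].ci_high - estimates[t].point)) ** 2 for t in FOREST_TYPES)
        )
        lo, hi = point - half_lo, point + half_hi
    else:
        raise ValueError(f"ci_method must be 'boundwise' or 'quadrature', got {ci_method!r}")
    return TypeEstimate(forest_type="basin", point=point, ci_low=lo, ci_high=hi)


def relative_difference(value: float, reference: float) -> float:
    """Percent difference of ``value`` relative to ``reference``.

    (value − reference)/|reference| · 100; report-rounding to integer
    precision is left to :func:`round_half_away`.
    """
    if reference == 0:
        raise ValueError("reference flux must be nonzero")
    return (value - reference) / abs(reference) * 100.0


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed report values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
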