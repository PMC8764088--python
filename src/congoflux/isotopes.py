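"""N₂O stable-isotope analytics.

Chamber closures are sampled for isotopes at the start (t₁) and end
(t₄); the flux-source δ value follows from a two-source (Keeling-type)
mixing model: the end-of-closure headspace is a mixture of background
air (c_start, δ_start) and soil-emitted N₂O, so

    δ_flux = (c_end·δ_end − c_start·δ_start) / (c_end − c_start).

Because the inversion amplifies measurement error when the
concentration build-up is small, signatures with ΔN₂O < 31 ppb are
flagged invalid (kept in outputs, never dropped).

Site preference SP = δ¹⁵Nα − δ¹⁵Nβ (central minus terminal N of the
linear N-N-O molecule) diagnoses the microbial production pathway;
positions in the (δ¹⁵N, δ¹⁸O) plane are interpreted against literature
endmember boxes and an empirical reduction vector of slope ≈ 2.4 along
which residual N₂O is enriched as denitrifiers reduce it to N₂.

Dissolved-phase δ values measured in an equilibrated vial headspace are
corrected for equilibrium fractionation α_eq = R_headspace/R_dissolved
(0.99925 for ¹⁵N, 0.99894 for ¹⁸O).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Minimum chamber N₂O build-up [ppb] for a trustworthy mixing-model inversion.
#: Valid iff ΔN₂O ≥ 31 (records below are flagged, not removed).
DELTA_N2O_THRESHOLD = 31.0

#: Equilibrium fractionation factors R_headspace / R_dissolved.
ALPHA_EQ = {"15N": 0.99925, "18O": 0.99894}

#: Tropospheric N₂O isotopic composition (δ¹⁵N vs air-N₂, δ¹⁸O vs VSMOW, ‰),
#: the reference point anchoring the reduction vector.
TROPOSPHERIC_N2O = (6.3, 44.4)


@dataclass(frozen=True)
class IsotopePair:
    """t₁/t₄ N₂O mole fractions [ppb] with bulk and per-position δ values [‰]."""

    chamber_id: str
    c_start: float
    c_end: float
    d15n_start: float
    d15n_end: float
    d18o_start: float
    d18o_end: float
    d15n_alpha_start: float | None = None
    d15n_alpha_end: float | None = None
    d15n_beta_start: float | None = None
    d15n_beta_end: float | None = None

    def __post_init__(self) -> None:
        if not (self.c_start > 0 and self.c_end > 0):
            raise ValueError("mole fractions must be > 0 ppb")


@dataclass(frozen=True)
class SourceSignature:
    """Mixing-model flux-source δ values for one chamber closure.

    ``valid`` is False when ΔN₂O < 31 ppb or the inversion is undefined
    (no concentration change); δ fields are NaN in that case and
    ``reason`` says why.  Invalid signatures are retained so discard
    counts remain auditable.
    """

    chamber_id: str
    delta_n2o: float
    d15n_flux: float
    d18o_flux: float
    sp_flux: float
    valid: bool
    reason: str = ""


def _mix(c0: float, d0: float, c1: float, d1: float) -> float:
    return (c1 * d1 - c0 * d0) / (c1 - c0)


def two_source_mixing(
    pair: IsotopePair, threshold: float = DELTA_N2O_THRESHOLD
) -> SourceSignature:
    """Invert the two-pool mixing model for the source δ of one closure.

    Site preference of the flux is computed from per-position mixing
    when δ¹⁵Nα/δ¹⁵Nβ are supplied, else NaN.
    """
    dc = pair.c_end - pair.c_start
    if dc == 0:
        return SourceSignature(
            chamber_id=pair.chamber_id,
            delta_n2o=0.0,
            d15n_flux=math.nan,
            d18o_flux=math.nan,
            sp_flux=math.nan,
            valid=False,
            reason="no concentration change (c_end == c_start)",
        )
    d15n = _mix(pair.c_start, pair.d15n_start, pair.c_end, pair.d15n_end)
    d18o = _mix(pair.c_start, pair.d18o_start, pair.c_end, pair.d18o_end)
    if None not in (
        pair.d15n_alpha_start,
        pair.d15n_alpha_end,
        pair.d15n_beta_start,
        pair.d15n_beta_end,
    ):
        alpha = _mix(pair.c_start, pair.d15n_alpha_start, pair.c_end, pair.d15n_alpha_end)
        beta = _mix(pair.c_start, pair.d15n_beta_start, pair.c_end, pair.d15n_beta_end)
        sp = site_preference(alpha, beta)
    else:
        sp = math.nan
    valid = dc >= threshold
    reason = "" if valid else f"delta N2O {dc:g} ppb below {threshold:g} ppb threshold"
    if valid:
        return SourceSignature(pair.chamber_id, dc, d15n, d18o, sp, True)
    return SourceSignature(pair.chamber_id, dc, math.nan, math.nan, math.nan, False, reason)


def site_preference(d15n_alpha: float, d15n_beta: float) -> float:
    """SP = δ¹⁵Nα − δ¹⁵Nβ [‰]; positive values point toward nitrification/fungal pathways."""
    return d15n_alpha - d15n_beta


def dissolved_delta_correction(delta_headspace: float, isotope: str) -> float:
    """Convert a vial-headspace δ to the dissolved-phase δ [‰].

    δ_dissolved = ((δ_hs/1000 + 1)/α_eq − 1)·1000 with
    α_eq = R_headspace/R_dissolved.
    """
    try:
        alpha = ALPHA_EQ[isotope]
    except KeyError:
        raise ValueError(f"isotope must be one of {sorted(ALPHA_EQ)}, got {isotope!r}") from None
    if delta_headspace <= -1000.0:
        raise ValueError("delta must be > -1000 permil (non-physical isotope ratio)")
    return ((delta_headspace / 1000.0 + 1.0) / alpha - 1.0) * 1000.0


@dataclass(frozen=True)
class ReductionVector:
    """Direction in (δ¹⁵N, δ¹⁸O) space along which N₂O reduction enriches the residue.

    ``slope`` is the δ¹⁸O-per-δ¹⁵N enrichment ratio (empirically ≈ 2.4);
    ``anchor`` defaults to the tropospheric N₂O reference point.
    """

    slope: float = 2.4
    anchor: tuple[float, float] = TROPOSPHERIC_N2O

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("reduction-vector slope must be > 0")


def reduction_projection(
    point: tuple[float, float], vector: ReductionVector = ReductionVector()
) -> tuple[float, float]:
    """Orthogonal decomposition of a (δ¹⁵N, δ¹⁸O) point onto the reduction vector.

    Returns (progress, residual): progress is the signed distance along
    the unit vector (1, slope)/√(1+slope²) from the anchor; residual is
    the signed perpendicular distance, positive above the line.
    """
    dx = point[0] - vector.anchor[0]
    dy = point[1] - vector.anchor[1]
    norm = math.hypot(1.0, vector.slope)
    progress = (dx + dy * vector.slope) / norm
    residual = (-dx * vector.slope + dy) / norm
    return progress, residual


#: Non-normative literature-style endmember rectangles in (δ¹⁵N, δ¹⁸O) [‰];
#: real applications should supply ranges from the mapping literature via config.
DEFAULT_ENDMEMBER_BOXES = {
    "nitrification": (-65.0, -45.0, 15.0, 40.0),
    "denitrification": (-45.0, -10.0, 5.0, 35.0),
}


@dataclass(frozen=True)
class EndmemberBoxes:
    """Named rectangles (x_min, x_max, y_min, y_max) in (δ¹⁵N, δ¹⁸O) space."""

    boxes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENDMEMBER_BOXES)
    )

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("endmember box set must not be empty")
        for name, (x0, x1, y0, y1) in self.boxes.items():
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"box {name!r} must have min < max on both axes")


def classify_endmember(
    point: tuple[float, float], boxes: EndmemberBoxes = EndmemberBoxes()
) -> str:
    """Label a (δ¹⁵N, δ¹⁸O) point by endmember-box membership.

    Returns the box name for unique membership, "ambiguous" for
    overlapping membership, "outside" otherwise.
    """
    hits = [
        name
        for name, (x0, x1, y0, y1) in boxes.boxes.items()
        if x0 <= point[0] <= x1 and y0 <= point[1] <= y1
    ]
    if not hits:
        return "outside"
    if len(hits) == 1:
        return hits[0]
    return "ambiguous"
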