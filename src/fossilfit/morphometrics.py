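"""Measurement standardisation and quantitative fossil–extant comparisons.

All raw measurements are millimetres. Sizes are standardised as percentages
of a body reference — standard length (SL) or, for incomplete fossils, body
length (BL: posterior opercle margin to posterior hypural margin). Reported
values follow the field's printing conventions (ratios and size factors to
one decimal, percentages to whole numbers); internal arithmetic is always
full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up rounding (1.25 -> 1.3), the convention of printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

__all__ = [
    "RelativeSize",
    "SpecimenMeasurements",
    "standardize",
    "scale_ratio",
    "size_factor",
    "size_factor_range",
    "specimen_scale_stats",
    "classify_tooth",
    "ToothClassification",
]


@dataclass(frozen=True)
class RelativeSize:
    value: float  # percent of the basis
    basis: str  # "SL" | "BL" | "HL"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("relative size must be positive")


@dataclass
class SpecimenMeasurements:
    specimen_id: str
    SL: float | None = None
    BL: float | None = None
    HL: float | None = None
    lacrimal_depth: float | None = None
    scales: list = field(default_factory=list)  # {site, length, width}
    teeth: list = field(default_factory=list)  # {crown_width, row}

    def __post_init__(self) -> None:
        for name in ("SL", "BL", "HL", "lacrimal_depth"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.SL is not None and self.BL is not None and self.SL < self.BL:
            raise ValueError("SL must be >= BL for a complete specimen")


def standardize(measurement: float, reference: float, basis: str) -> RelativeSize:
    """Express a measurement as a percentage of a body reference length."""
    if reference <= 0:
        raise ValueError("reference length must be positive")
    return RelativeSize(value=100.0 * measurement / reference, basis=basis)


def scale_ratio(width: float, length: float):
    """Scale width/length ratio: (full precision, 1-decimal display value)."""
    if length <= 0:
        raise ValueError("scale length must be positive")
    r = width / length
    return r, _round_half_up(r, 1)


def size_factor(extant: RelativeSize, fossil: RelativeSize):
    """How many times larger the extant relative size is than the fossil's."""
    if extant.basis != fossil.basis:
        raise ValueError(f"basis mismatch: {extant.basis} vs {fossil.basis}")
    f = extant.value / fossil.value
    return f, _round_half_up(f, 1)


def size_factor_range(extant_values, fossil: RelativeSize):
    """Min–max of per-species size factors, as printed ranges are assembled."""
    factors = [size_factor(e, fossil)[0] for e in extant_values]
    return (_round_half_up(min(factors), 1), _round_half_up(max(factors), 1))


def specimen_scale_stats(specimen: SpecimenMeasurements, site: str) -> dict:
    """Mean scale length/width/ratio over a specimen's normal scales at a site."""
    recs = [s for s in specimen.scales if s["site"] == site]
    if not recs:
        raise ValueError(f"no {site!r} scales for specimen {specimen.specimen_id}")
    lengths = np.array([s["length"] for s in recs], dtype=float)
    widths = np.array([s["width"] for s in recs], dtype=float)
    out = {
        "length_mm": float(lengths.mean()),
        "width_mm": float(widths.mean()),
        "wl_ratio": float((widths / lengths).mean()),
    }
    for basis in ("SL", "BL"):
        ref = getattr(specimen, basis)
        if ref:
            out[f"length_pct_{basis}"] = standardize(out["length_mm"], ref, basis).value
            out[f"width_pct_{basis}"] = standardize(out["width_mm"], ref, basis).value
    return out


# ---------------------------------------------------------------------------
# Tooth crown-width classification
# ---------------------------------------------------------------------------

@dataclass
class ToothClassification:
    label: str  # "inner" | "outer" | "ambiguous"
    residuals: dict  # class -> absolute residual of the query from its trend line
    degenerate: list = field(default_factory=list)  # classes that fell back to means


def _fit_line(x, y):
    """Least squares line y = a + b*x; returns (a, b, degenerate)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(x) == 0:
        return float(y.mean()), 0.0, True
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b), False


def classify_tooth(
    crown_width: float, body_size: float, references: pd.DataFrame
) -> ToothClassification:
    """Assign a tooth to the inner or outer row by trend-line residual.

    ``references`` needs columns ``crown_width``, ``body_size`` and ``row``
    ("inner"/"outer"), each class with >= 2 points. A least-squares line of
    crown width on body size is fitted per class and the query goes to the
    class with the smaller absolute residual; exact ties are reported as
    ambiguous. A class whose reference points all share one body size is
    degenerate — its prediction falls back to the class mean crown width.
    """
    residuals, degenerate = {}, []
    for label in ("inner", "outer"):
        cls = references[references["row"] == label]
        if len(cls) < 2:
            raise ValueError(f"need >= 2 reference points for class {label!r}")
        a, b, fell_back = _fit_line(cls["body_size"], cls["crown_width"])
        if fell_back:
            degenerate.append(label)
        residuals[label] = abs(crown_width - (a + b * body_size))
    if np.isclose(residuals["inner"], residuals["outer"], rtol=1e-9, atol=1e-12):
        label = "ambiguous"
    else:
        label = min(residuals, key=residuals.get)
    return ToothClassification(label=label, residuals=residuals, degenerate=degenerate)
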