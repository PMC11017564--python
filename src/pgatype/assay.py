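"""Ninhydrin-assay quantification of gamma-PGA.

Free glutamate released by acid hydrolysis is read at 570 nm against a
linear standard curve; polymer content follows from the glutamate-per-mass
ratio of a hydrolysed gamma-PGA standard, and volumetric yield divides by
the fermentation volume.

Two content-formula variants are shipped because published forms of this
calculation are not mutually consistent: the dimensionally coherent
``mass_ratio`` conversion (default) and the ``literal`` percent form.
Every result records which variant produced it.  The unit of the standard
mass W must be declared by the caller; nothing is guessed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PgatypeError, ValidationError

_UG_PER = {"ug": 1.0, "mg": 1e3, "g": 1e6}


def _to_ug(value: float, unit: str) -> float:
    try:
        return value * _UG_PER[unit]
    except KeyError:
        raise PgatypeError(f"unknown mass unit {unit!r}; use one of {sorted(_UG_PER)}") from None


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("standard curve needs >= 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares fit of response on concentration."""
    if len(points) < 2:
        raise PgatypeError("need at least 2 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise PgatypeError("degenerate design: all concentrations equal")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(float(res.slope), float(res.intercept), max(min(r2, 1.0), 0.0), len(x))


def glutamate_from_response(curve: StandardCurve, response: float) -> float:
    """Invert the standard curve: concentration = (response - b) / m.

    Negative results are returned as-is (flagged by the caller); they mean
    the response fell below the blank.
    """
    if curve.slope == 0:
        raise PgatypeError("standard curve has zero slope")
    return (response - curve.intercept) / curve.slope


@dataclasses.dataclass(frozen=True)
class YieldResult:
    content_g: float
    yield_g_per_l: float
    provenance: str

    def __post_init__(self) -> None:
        # yield * volume == content is enforced where volume is known
        pass


def pga_content(
    glutamate_ug: float,
    standard_glutamate_ug: float,
    standard_mass: float,
    standard_mass_unit: str = "g",
    variant: str = "mass_ratio",
    conversion_factor: float = 1.0,
) -> tuple[float, str]:
    """Polymer mass (grams) from sample glutamate and the standard's
    glutamate/mass ratio.

    ``mass_ratio`` (default): content = glutamate * W / G — the standard's
    G micrograms of glutamate correspond to W grams of polymer, so sample
    glutamate converts by the same ratio.  ``literal``: the percent form
    content = glutamate / ((G / W) * 100), evaluated with W in micrograms.
    ``conversion_factor`` multiplies the result (declared dilution or
    recovery correction; default 1).  Returns (grams, provenance tag).
    """
    if glutamate_ug <= 0 or standard_glutamate_ug <= 0 or standard_mass <= 0:
        raise PgatypeError("assay inputs must be positive")
    w_ug = _to_ug(standard_mass, standard_mass_unit)
    if variant == "mass_ratio":
        content_ug = glutamate_ug * w_ug / standard_glutamate_ug
    elif variant == "literal":
        content_ug = glutamate_ug / ((standard_glutamate_ug / w_ug) * 100.0)
    else:
        raise PgatypeError(f"unknown content variant {variant!r}")
    content_g = content_ug * conversion_factor / 1e6
    tag = f"{variant}(factor={conversion_factor:g})"
    return content_g, tag


def volumetric_yield(content_g: float, volume_l: float) -> float:
    """Yield in g/L: polymer mass over culture volume."""
    if volume_l <= 0:
        raise PgatypeError("volume must be positive")
    return content_g / volume_l


def yield_result(content_g: float, volume_l: float, provenance: str = "reported") -> YieldResult:
    return YieldResult(content_g, volumetric_yield(content_g, volume_l), provenance)


def process_assay_table(
    samples: pd.DataFrame,
    curve: StandardCurve | None,
    standard_glutamate_ug: float,
    standard_mass: float,
    standard_mass_unit: str,
    volume_l: float,
    variant: str = "mass_ratio",
    conversion_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-sample quantification table.

    ``samples`` columns: strain; then either ``response`` (curve units,
    converted through ``curve``) or ``glutamate_ug`` directly; optional
    ``od600`` is carried through untouched (it enters no formula).
    """
    rows = []
    for _, s in samples.iterrows():
        if "glutamate_ug" in s and not pd.isna(s.get("glutamate_ug")):
            glut = float(s["glutamate_ug"])
        elif curve is not None and "response" in s:
            glut = glutamate_from_response(curve, float(s["response"]))
        else:
            raise PgatypeError(f"sample {s.get('strain')}: no glutamate_ug or response")
        content, tag = pga_content(
            glut, standard_glutamate_ug, standard_mass, standard_mass_unit,
            variant, conversion_factor,
        )
        rows.append(
            {
                "strain": s.get("strain"),
                "od600": s.get("od600", float("nan")),
                "glutamate_ug": glut,
                "content_g": content,
                "yield_g_per_l": volumetric_yield(content, volume_l),
                "provenance": tag,
            }
        )
    return pd.DataFrame(rows)
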