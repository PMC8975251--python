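"""Age transformations used as the dependent variable of clock regressions.

Three transforms are supported:

``identity``
    Chronological age in years, untransformed. Used for single-species
    (pure NMR) clocks.
``loglinear``
    Logarithmic below a species' age of sexual maturity ``m``, linear
    above it, with value and first derivative matched at the junction::

        f(a) = ln((a + k) / (m + k))   for a <= m
        f(a) = (a - m) / (m + k)       for a > m

    so f(m) = 0 and f'(m) = 1/(m+k) from both sides. The offset ``k``
    (years) keeps f finite at age zero and lets the inverse reach
    slightly negative ages (prenatal-equivalent estimates). Used for
    dual-species chronological-age clocks.
``relative``
    Age divided by the species' maximum recorded lifespan ``L``
    (relative age = age / maxLifespan), in [0, 1] for ages within the
    lifespan. Reference lifespans: human 122.5 yr, naked mole-rat 37 yr.

All transforms are strictly increasing in age and have exact inverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesParams",
    "TransformSpec",
    "relative_age",
    "loglinear",
    "inverse_loglinear",
    "apply_transform",
    "invert_transform",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species life-history constants used by the transforms.

    max_lifespan_years: maximum recorded lifespan L (relative transform).
    maturity_years: age of sexual maturity m (loglinear junction).
    offset_years: loglinear offset k, default 1.
    """

    max_lifespan_years: float
    maturity_years: float = 1.0
    offset_years: float = 1.0

    def __post_init__(self) -> None:
        if self.max_lifespan_years <= 0:
            raise ValueError("max_lifespan_years must be > 0")
        if self.maturity_years <= 0:
            raise ValueError("maturity_years must be > 0")
        if self.offset_years <= 0:
            raise ValueError("offset_years must be > 0")


_KINDS = ("identity", "loglinear", "relative")


@dataclass(frozen=True)
class TransformSpec:
    """An age transform plus the per-species parameters it needs."""

    kind: str = "identity"
    species: dict[str, SpeciesParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; expected one of {_KINDS}")

    def params_for(self, species: str) -> SpeciesParams:
        try:
            return self.species[species]
        except KeyError:
            raise KeyError(
                f"species {species!r} has no parameters in this TransformSpec "
                f"(known: {sorted(self.species)})"
            ) from None

    # -- serialization (embedded in ClockModel JSON) ------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "species": {
                name: {
                    "max_lifespan_years": p.max_lifespan_years,
                    "maturity_years": p.maturity_years,
                    "offset_years": p.offset_years,
                }
                for name, p in self.species.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(
            kind=d["kind"],
            species={name: SpeciesParams(**p) for name, p in d.get("species", {}).items()},
        )


def relative_age(age_years, max_lifespan_years):
    """Relative age = age / maxLifespan; in [0, 1] whenever age <= L."""
    if np.any(np.asarray(max_lifespan_years) <= 0):
        raise ValueError("max_lifespan_years must be > 0")
    return np.asarray(age_years, dtype=float) / max_lifespan_years


def loglinear(age_years, maturity_years, offset_years):
    """Log-linear transform: ln((a+k)/(m+k)) below maturity, (a-m)/(m+k) above."""
    m, k = float(maturity_years), float(offset_years)
    if m <= 0 or k <= 0:
        raise ValueError("maturity_years and offset_years must be > 0")
    a = np.asarray(age_years, dtype=float)
    out = np.where(a <= m, np.log((a + k) / (m + k)), (a - m) / (m + k))
    return out if out.ndim else float(out)


def inverse_loglinear(t, maturity_years, offset_years):
    """Exact inverse of :func:`loglinear`.

    Negative t maps back through the log branch and can yield negative
    (prenatal-equivalent) ages down to, but never below, -k.
    """
    m, k = float(maturity_years), float(offset_years)
    if m <= 0 or k <= 0:
        raise ValueError("maturity_years and offset_years must be > 0")
    tt = np.asarray(t, dtype=float)
    out = np.where(tt <= 0, (m + k) * np.exp(tt) - k, m + tt * (m + k))
    return out if out.ndim else float(out)


def _species_vector(spec: TransformSpec, species_labels) -> list[SpeciesParams]:
    return [spec.params_for(s) for s in species_labels]


def apply_transform(spec: TransformSpec, sheet) -> np.ndarray:
    """Transform each sample's age with its own species' parameters.

    ``sheet`` is a SampleSheet (or any DataFrame-like with ``age_years``
    and ``species`` columns). Returns a float vector aligned to sheet
    row order.
    """
    df = sheet.frame if hasattr(sheet, "frame") else pd.DataFrame(sheet)
    ages = np.asarray(df["age_years"], dtype=float)
    if spec.kind == "identity":
        return ages.copy()
    params = _species_vector(spec, df["species"])
    if spec.kind == "relative":
        L = np.array([p.max_lifespan_years for p in params])
        return ages / L
    m = np.array([p.maturity_years for p in params])
    k = np.array([p.offset_years for p in params])
    return np.where(ages <= m, np.log((ages + k) / (m + k)), (ages - m) / (m + k))


def invert_transform(spec: TransformSpec, t, species_labels) -> np.ndarray:
    """Map transformed values back to years, per sample species."""
    tt = np.asarray(t, dtype=float)
    if spec.kind == "identity":
        return tt.copy()
    params = _species_vector(spec, species_labels)
    if spec.kind == "relative":
        L = np.array([p.max_lifespan_years for p in params])
        return tt * L
    m = np.array([p.maturity_years for p in params])
    k = np.array([p.offset_years for p in params])
    return np.where(tt <= 0, (m + k) * np.exp(tt) - k, m + tt * (m + k))
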