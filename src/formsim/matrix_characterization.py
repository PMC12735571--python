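"""Hydrophilic-matrix tablet characterization: hydration, erosion, and gel
strength from raw gravimetric and texture-analyzer measurements.

Hydration% = 100*(wet - dry)/dry measures water uptake of the swollen matrix;
Erosion% = 100*(initial - dry)/initial measures polymer/drug mass loss; gel
strength G (MPa) converts a probe penetration force F (grams-force) at depth
x (mm) with probe radius rp (mm) via the gram-force-to-newton factor 0.0098:

    G = 0.0098 * F / (x * rp)

An alternative reading of the gel-strength expression (force normalized by
depth times probe *area* factor) is selectable via ``variant`` because the
published arithmetic is ambiguous; the default preserves the stated
force-per-displacement semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "TabletMassRecord",
    "GelProbeMeasurement",
    "hydration_pct",
    "erosion_pct",
    "gel_strength",
    "characterize_mass_table",
    "characterize_gel_table",
]

GRAM_FORCE_TO_NEWTON = 0.0098  # N per gram-force

#: default probe radius, mm
DEFAULT_PROBE_RADIUS_MM = 7.0


@dataclass(frozen=True)
class TabletMassRecord:
    """One tablet's weights (g) at a sampling time under given agitation."""

    initial_weight: float
    wet_weight: float
    dry_weight: float
    time: float = float("nan")  # hours
    agitation: float = float("nan")  # rpm

    def __post_init__(self):
        if min(self.initial_weight, self.wet_weight, self.dry_weight) <= 0:
            raise InvalidParameterError("weights must be positive")
        if self.dry_weight > self.wet_weight:
            raise InvalidParameterError("dry weight cannot exceed wet weight")


@dataclass(frozen=True)
class GelProbeMeasurement:
    """Texture-analyzer reading: force (g) at penetration depth (mm)."""

    force: float
    penetration_depth: float
    probe_radius: float = DEFAULT_PROBE_RADIUS_MM

    def __post_init__(self):
        if self.force < 0:
            raise InvalidParameterError("force must be >= 0")
        if self.penetration_depth <= 0 or self.probe_radius <= 0:
            raise InvalidParameterError("depth and probe radius must be positive")


def hydration_pct(rec: TabletMassRecord) -> float:
    """Percent water uptake relative to the dried matrix mass."""
    return 100.0 * (rec.wet_weight - rec.dry_weight) / rec.dry_weight


def erosion_pct(rec: TabletMassRecord) -> float:
    """Percent dry-mass loss relative to the initial tablet weight.

    A dry weight above the initial weight (e.g. salt uptake artifact) yields a
    negative value and a warning rather than an error.
    """
    if rec.dry_weight > rec.initial_weight:
        warnings.warn("dry weight exceeds initial weight; erosion is negative "
                      "(weight-gain artifact)", stacklevel=2)
    return 100.0 * (rec.initial_weight - rec.dry_weight) / rec.initial_weight


def gel_strength(m: GelProbeMeasurement, variant: str = "force_per_depth") -> float:
    """Gel strength in MPa from a single probe penetration point.

    variant="force_per_depth" (default): G = 0.0098*F/(x*rp).
    variant="force_per_area_depth": additionally divides by pi*rp, i.e. the
    force is normalized toward the probe cross-section.
    """
    g = GRAM_FORCE_TO_NEWTON * m.force / (m.penetration_depth * m.probe_radius)
    if variant == "force_per_depth":
        return g
    if variant == "force_per_area_depth":
        return g / (np.pi * m.probe_radius)
    raise InvalidParameterError(f"unknown gel-strength variant {variant!r}")


# ----------------------------------------------------------------------------
# Tabular convenience wrappers
# ----------------------------------------------------------------------------

def characterize_mass_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append hydration_pct / erosion_pct columns to a weights table.

    Expects columns: formulation_id, time_h, rpm, initial_g, wet_g, dry_g.
    """
    required = {"initial_g", "wet_g", "dry_g"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"need columns {sorted(required)}")
    out = df.copy()
    recs = [TabletMassRecord(initial_weight=r.initial_g, wet_weight=r.wet_g,
                             dry_weight=r.dry_g)
            for r in df.itertuples()]
    out["hydration_pct"] = [hydration_pct(r) for r in recs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["erosion_pct"] = [erosion_pct(r) for r in recs]
    return out


def characterize_gel_table(df: pd.DataFrame,
                           probe_radius: float = DEFAULT_PROBE_RADIUS_MM) -> pd.DataFrame:
    """Append a gel_strength_mpa column to a texture table.

    Expects columns: formulation_id, time_h, force_g, depth_mm.
    """
    required = {"force_g", "depth_mm"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"need columns {sorted(required)}")
    out = df.copy()
    out["gel_strength_mpa"] = [
        gel_strength(GelProbeMeasurement(force=r.force_g, penetration_depth=r.depth_mm,
                                         probe_radius=probe_radius))
        for r in df.itertuples()
    ]
    return out
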