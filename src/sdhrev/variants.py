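"""Catalog of the parameter variants behind every simulated curve.

Each electrode-potential curve and fumarate titration corresponds to one
override of the substrate binding/release rate constants of reactions 10,
12, 14 and 16, with the dependent equilibrium constants re-derived through
the detailed-balance cycles:

* fumarate on-rate scans (k10 = k12 down from 1 to 1e-4 1/(uM s), off-rate
  fixed at 50 1/s);
* fumarate off-rate scans (k-10 = k-12 up from 50 to 5e4 1/s, on-rate fixed);
* succinate off-rate scans (k14 = k16 down from 10 to 1e-3 1/s, on-rate
  fixed at 0.04 1/(uM s)) -- the mechanism that produces the tunnel-diode
  drop at experimentally observed threshold potentials;
* succinate on-rate scans (k-14 = k-16 up from 0.04 to 4e4 1/(uM s)).

The catalog maps (figure, panel, curve) to a variant label and its
overrides; several figures reuse the same variants (flux decompositions,
redox profiles, ROS scans and fumarate titrations are different readouts of
the same parameter sets).
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet, build_base_parameters, make_variant

__all__ = [
    "CurveVariant",
    "variant_catalog",
    "build_catalog_parameter_sets",
    "variant_by_label",
    "SCAN_DEFINITIONS",
]

#: The four one-parameter scans, as (override names, list of values,
#: label stem).  The first value of each scan is the basal configuration.
SCAN_DEFINITIONS: dict[str, tuple[tuple[str, str], tuple[float, ...]]] = {
    "fum_on": (("k10", "k12"), (1.0, 0.1, 0.01, 1e-3, 1e-4)),
    "fum_off": (("kminus10", "kminus12"), (50.0, 500.0, 5e3, 5e4)),
    "suc_off": (("k14", "k16"), (10.0, 1.0, 0.1, 0.01, 1e-3)),
    "suc_on": (("kminus14", "kminus16"), (0.04, 40.0, 400.0, 4e3, 4e4)),
}

# (figure, panel) -> (scan name, curve numbers present in that panel).
# Panels of the succinate-flux decompositions (figs 3-6), the redox profiles
# (fig 7), the ROS scans (fig 8) and the fumarate titrations (fig 9) reuse
# the four scans of fig 2.
_PANEL_MAP: dict[tuple[int, str], tuple[str, tuple[int, ...]]] = {
    (2, "A"): ("fum_on", (1, 2, 3, 4, 5)),
    (2, "B"): ("fum_off", (1, 2, 3, 4)),
    (2, "C"): ("suc_off", (1, 2, 3, 4, 5)),
    (2, "D"): ("suc_on", (1, 2, 3, 4, 5)),
    (3, "A"): ("suc_off", (1,)),
    (3, "B"): ("suc_off", (2,)),
    (3, "C"): ("suc_off", (3,)),
    (3, "D"): ("suc_off", (4,)),
    (4, "A"): ("suc_on", (1,)),
    (4, "B"): ("suc_on", (2,)),
    (4, "C"): ("suc_on", (3,)),
    (4, "D"): ("suc_on", (4,)),
    (5, "A"): ("fum_on", (1,)),
    (5, "B"): ("fum_on", (3,)),
    (5, "C"): ("fum_on", (4,)),
    (5, "D"): ("fum_on", (5,)),
    (6, "A"): ("fum_off", (1,)),
    (6, "B"): ("fum_off", (2,)),
    (6, "C"): ("fum_off", (3,)),
    (6, "D"): ("fum_off", (4,)),
    (7, "A"): ("fum_on", (1, 2, 3, 4, 5)),
    (7, "B"): ("suc_off", (1, 2, 3, 4, 5)),
    (7, "C"): ("fum_on", (1, 2, 3, 4, 5)),
    (7, "D"): ("suc_off", (1, 2, 3, 4, 5)),
    (7, "E"): ("fum_on", (1,)),
    (7, "F"): ("fum_on", (1,)),
    (8, "A"): ("fum_on", (1, 2, 3, 4, 5)),
    (8, "B"): ("fum_off", (1, 2, 3, 4)),
    (8, "C"): ("suc_off", (1, 2, 3, 4)),
    (8, "D"): ("suc_on", (1, 2, 3, 4, 5)),
    (9, "A"): ("suc_off", (1,)),
    (9, "B"): ("suc_off", (2,)),
    (9, "C"): ("suc_off", (3,)),
    (9, "D"): ("suc_off", (4,)),
}


@dataclass(frozen=True)
class CurveVariant:
    """One captioned curve: its variant label and parameter overrides."""

    figure: int
    panel: str
    curve: int
    label: str
    overrides: dict[str, float]

    @property
    def is_basal(self) -> bool:
        return not self.overrides


def _scan_variant(scan: str, curve: int) -> tuple[str, dict[str, float]]:
    names, values = SCAN_DEFINITIONS[scan]
    value = values[curve - 1]
    label = f"{scan}_{curve}"
    first = values[0]
    overrides = {} if value == first else {n: value for n in names}
    return label, overrides


def variant_catalog() -> list[CurveVariant]:
    """Every captioned curve of the simulated figures, one entry per curve."""
    rows = []
    for (fig, panel), (scan, curves) in sorted(_PANEL_MAP.items()):
        for curve in curves:
            label, overrides = _scan_variant(scan, curve)
            rows.append(CurveVariant(fig, panel, curve, label, overrides))
    return rows


def build_catalog_parameter_sets(
    base: ParameterSet | None = None,
) -> dict[str, ParameterSet]:
    """Distinct, detailed-balance-consistent parameter sets of the catalog."""
    base = base or build_base_parameters()
    out: dict[str, ParameterSet] = {}
    for scan, (names, values) in SCAN_DEFINITIONS.items():
        for i, value in enumerate(values, start=1):
            label = f"{scan}_{i}"
            overrides = {} if value == values[0] else {n: value for n in names}
            out[label] = make_variant(base, overrides, label=label)
    return out


def variant_by_label(label: str, base: ParameterSet | None = None) -> ParameterSet:
    """Build a single catalog variant (or the basal set for label 'basal')."""
    base = base or build_base_parameters()
    if label == "basal":
        return base
    sets = build_catalog_parameter_sets(base)
    if label not in sets:
        raise KeyError(f"unknown variant label {label!r}")
    return sets[label]
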