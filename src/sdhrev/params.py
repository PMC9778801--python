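"""Thermodynamically consistent parameter sets for the reverse-direction SDHA/SDHB model.

The kinetic network couples one-electron transfers through the [3Fe-4S] ->
[4Fe-4S] -> [2Fe-2S] cluster chain to fumarate reduction at the flavin site,
plus ROS side reactions.  Every equilibrium constant is either an independent
input (midpoint-potential derived or directly measured) or is recomputed from
the four detailed-balance cycle relations so that the product of equilibrium
constants around each closed thermodynamic cycle is exactly 1.

Units are fixed throughout the package: concentrations in uM, time in s,
potentials in mV.  Equilibrium constants carry the reaction-specific unit
implied by the mass-action law (dimensionless, uM or 1/uM); the proton enters
trimolecular laws as a dimensionless activity.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "InvalidConstantError",
    "ConfigurationError",
    "PhysicalConstants",
    "RedoxCouple",
    "ReactionParams",
    "ParameterSet",
    "nernst_keq",
    "build_base_parameters",
    "derive_dependent_keqs",
    "make_variant",
    "zero_ros_variant",
    "cycle_residuals",
    "MIDPOINT_POTENTIALS",
    "DEPENDENT_KEQS",
    "N_REACTIONS",
]

N_REACTIONS = 22

#: Equilibrium constants that are always recomputed from the cycle relations.
DEPENDENT_KEQS = (5, 6, 7, 13, 15)

#: Two-electron Nernst factor linking the fumarate/succinate couple (0 mV at
#: pH 7) to the bound-flavin FAD/FADH2 couple (-79 mV): exp(2*79/25) = 555.6.
FUM_SUC_FAD_FACTOR_MV = 79.0


class InvalidConstantError(ValueError):
    """A physical or rate constant is outside its admissible range."""


class ConfigurationError(ValueError):
    """A parameter override or configuration key is not recognized."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical conventions shared by every model configuration.

    ``thermal_voltage_mV`` is RT/F expressed in mV.  The model fixes it at
    25 mV (not 25.69): this convention uniquely reproduces every printed
    Nernst-derived equilibrium constant, e.g. exp(60/25) = 11.023.

    ``flux_conversion`` converts a volumetric rate in uM/s into a specific
    rate in pmol/min/mg mitochondrial protein.  ``conc_per_content`` converts
    an enzyme content in nmol/mg protein into a local concentration in uM in
    the inner-membrane volume: 273 uM per (nmol/mg) referenced to the whole
    mitochondrial volume, divided by the membrane volume fraction W_imb.
    """

    thermal_voltage_mV: float = 25.0
    alpha: float = 0.5
    flux_conversion: float = 220.0
    mito_conc_per_content: float = 273.0
    W_imb: float = 0.24

    def __post_init__(self) -> None:
        if self.thermal_voltage_mV <= 0:
            raise InvalidConstantError(
                f"thermal voltage must be positive, got {self.thermal_voltage_mV}"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidConstantError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.flux_conversion <= 0:
            raise InvalidConstantError("flux_conversion must be positive")

    @property
    def conc_per_content(self) -> float:
        """uM of enzyme per (nmol/mg protein), inner-membrane volume basis."""
        return self.mito_conc_per_content / self.W_imb


@dataclass(frozen=True)
class RedoxCouple:
    """A redox couple with its midpoint potential (mV) at the quoted pH."""

    name: str
    Em: float
    n_electrons: int = 1
    pH_of_Em: float = 7.0

    def __post_init__(self) -> None:
        if self.n_electrons not in (1, 2):
            raise InvalidConstantError(
                f"n_electrons must be 1 or 2, got {self.n_electrons}"
            )


#: Midpoint potentials (mV) used to cross-check the independent equilibrium
#: constants.  Cluster potentials quoted at pH 7.4, flavin/oxygen at pH 7.
MIDPOINT_POTENTIALS: dict[str, RedoxCouple] = {
    c.name: c
    for c in (
        RedoxCouple("3Fe-4S", 60.0, 1, 7.4),
        RedoxCouple("4Fe-4S", -260.0, 1, 7.4),
        RedoxCouple("2Fe-2S", 0.0, 1, 7.4),
        RedoxCouple("FAD/FADH.", -127.0, 1, 7.0),
        RedoxCouple("FADH./FADH2", -31.0, 1, 7.0),
        RedoxCouple("FAD/FADH2", -79.0, 2, 7.0),
        RedoxCouple("fum/suc", 0.0, 2, 7.0),
        RedoxCouple("O2/O2.-", -160.0, 1, 7.0),
        RedoxCouple("O2/H2O2", 690.0, 2, 7.0),
    )
}


@dataclass(frozen=True)
class ReactionParams:
    """Forward rate constant and equilibrium constant for one reaction.

    ``unit_k`` / ``unit_Keq`` record the reaction-specific units implied by
    the mass-action law; ``derived`` marks Keq values recomputed from a
    detailed-balance cycle relation rather than taken as inputs.
    """

    reaction_id: int
    k_forward: float
    Keq: float | None
    unit_k: str = "1/s"
    unit_Keq: str = ""
    derived: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.reaction_id <= N_REACTIONS:
            raise InvalidConstantError(f"reaction_id out of range: {self.reaction_id}")
        if self.k_forward < 0:
            raise InvalidConstantError(
                f"k{self.reaction_id} must be nonnegative, got {self.k_forward}"
            )
        if self.reaction_id <= 20 and (self.Keq is None or self.Keq <= 0):
            raise InvalidConstantError(
                f"Keq{self.reaction_id} must be positive for a reversible reaction"
            )


# (unit_k, unit_Keq) per reaction; trimolecular electron transfers carry the
# dimensionless proton activity, so their k is 1/(uM^2 s) but Keq is 1/uM.
_REACTION_UNITS: dict[int, tuple[str, str]] = {
    1: ("1/s", ""),
    2: ("1/(uM s)", ""),
    3: ("1/(uM s)", ""),
    4: ("1/(uM s)", "1/uM"),
    5: ("1/(uM^2 s)", "1/uM"),
    6: ("1/(uM^2 s)", "1/uM"),
    7: ("1/s", ""),
    8: ("1/s", "uM"),
    9: ("1/(uM^2 s)", "1/uM"),
    10: ("1/(uM s)", "1/uM"),
    11: ("1/(uM^2 s)", "1/uM"),
    12: ("1/(uM s)", "1/uM"),
    13: ("1/(uM^2 s)", "1/uM"),
    14: ("1/s", "uM"),
    15: ("1/(uM^2 s)", "1/uM"),
    16: ("1/s", "uM"),
    17: ("1/(uM s)", ""),
    18: ("1/(uM s)", ""),
    19: ("1/(uM s)", ""),
    20: ("1/(uM s)", ""),
    21: ("uM/s", ""),
    22: ("1/s", ""),
}

#: Reactions whose forward/reverse rate-constant pair defines the Keq used in
#: the figure variants: Keq_i = k_i / k_-i.
_PAIRED_REACTIONS = (10, 12, 14, 16)


def nernst_keq(delta_Em: float, n_electrons: int, vT: float = 25.0) -> float:
    """Equilibrium constant of an n-electron transfer from a midpoint-potential gap.

    Parameters
    ----------
    delta_Em : potential difference acceptor-minus-donor, mV.
    n_electrons : 1 or 2.
    vT : thermal voltage RT/F, mV.

    Returns
    -------
    exp(n_electrons * delta_Em / vT), the dimensionless Nernstian core of the
    equilibrium constant (reaction-specific concentration units are carried
    separately).
    """
    if vT <= 0:
        raise InvalidConstantError(f"thermal voltage must be positive, got {vT}")
    if n_electrons not in (1, 2):
        raise InvalidConstantError(f"n_electrons must be 1 or 2, got {n_electrons}")
    return math.exp(n_electrons * delta_Em / vT)


@dataclass(frozen=True)
class ParameterSet:
    """One complete, detailed-balance-consistent model configuration.

    ``keq`` and ``k`` map reaction id (1-20) to the equilibrium constant and
    forward rate constant; ``k_rev`` holds the reverse rate constants of the
    four substrate binding/release steps whose forward/reverse pair defines
    the Keq that the variants move.  Superoxide dismutation (reaction 21) is
    Michaelis-Menten with ``sod_Vmax21``/``sod_Km21``; hydrogen-peroxide
    efflux (22) is first order with ``k22``.
    """

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    keq: dict[int, float] = field(default_factory=dict)
    k: dict[int, float] = field(default_factory=dict)
    k_rev: dict[int, float] = field(default_factory=dict)
    pool_totals: dict[str, float] = field(
        default_factory=lambda: {
            "3Fe-4S": 235.0,
            "4Fe-4S": 235.0,
            "2Fe-2S": 235.0,
            "FAD": 235.0,
        }
    )
    sod_Vmax21: float = 5.6e4
    sod_Km21: float = 50.0
    k22: float = 30.0
    label: str = "basal"

    def __post_init__(self) -> None:
        for name, total in self.pool_totals.items():
            if total <= 0:
                raise InvalidConstantError(f"pool total {name} must be positive")
        if self.sod_Vmax21 < 0 or self.sod_Km21 <= 0 or self.k22 < 0:
            raise InvalidConstantError("reaction 21/22 constants out of range")

    # -- views -------------------------------------------------------------

    @property
    def reactions(self) -> tuple[ReactionParams, ...]:
        """All 22 reactions as ReactionParams records."""
        recs = []
        for i in range(1, 21):
            uk, ukeq = _REACTION_UNITS[i]
            recs.append(
                ReactionParams(i, self.k[i], self.keq[i], uk, ukeq, i in DEPENDENT_KEQS)
            )
        recs.append(ReactionParams(21, self.sod_Vmax21, None, "uM/s", ""))
        recs.append(ReactionParams(22, self.k22, None, "1/s", ""))
        return tuple(recs)

    def digest(self) -> str:
        """Stable hash of every numeric parameter, for provenance headers."""
        payload = {
            "keq": {str(i): self.keq[i] for i in sorted(self.keq)},
            "k": {str(i): self.k[i] for i in sorted(self.k)},
            "k_rev": {str(i): self.k_rev[i] for i in sorted(self.k_rev)},
            "pools": dict(sorted(self.pool_totals.items())),
            "sod": [self.sod_Vmax21, self.sod_Km21, self.k22],
            "const": [
                self.constants.thermal_voltage_mV,
                self.constants.alpha,
                self.constants.flux_conversion,
            ],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _two_electron_factor(vT: float) -> float:
    """exp(2*(E(fum/suc) - E(FAD/FADH2))/vT) = exp(2*79/25) = 555.6."""
    return math.exp(2.0 * FUM_SUC_FAD_FACTOR_MV / vT)


def derive_dependent_keqs(base: ParameterSet) -> ParameterSet:
    """Recompute the five dependent equilibrium constants from the cycles.

    The four closed thermodynamic cycles of the flavin-site network fix
    Keq5, Keq6, Keq7, Keq13 and Keq15 once the independent constants are
    chosen:

        Keq7  = 555.6 / (Keq8 * Keq12)        (fum/suc vs FAD/FADH2 Nernst)
        Keq6  = Keq11 * Keq12 / Keq10
        Keq5  = 1 / (Keq4 * Keq6 * Keq7 * Keq8)
        Keq13 = Keq8 * Keq9 / Keq14
        Keq15 = 1 / (Keq7 * Keq12 * Keq13 * Keq16)

    After this every cycle product equals 1 exactly (to roundoff).
    """
    keq = dict(base.keq)
    for i in (1, 2, 3, 4, 8, 9, 10, 11, 12, 14, 16):
        if keq.get(i, 0) is None or keq.get(i, 0) <= 0:
            raise InvalidConstantError(f"independent Keq{i} must be positive")
    vT = base.constants.thermal_voltage_mV
    keq[7] = _two_electron_factor(vT) / (keq[8] * keq[12])
    keq[6] = keq[11] * keq[12] / keq[10]
    keq[5] = 1.0 / (keq[4] * keq[6] * keq[7] * keq[8])
    keq[13] = keq[8] * keq[9] / keq[14]
    keq[15] = 1.0 / (keq[7] * keq[12] * keq[13] * keq[16])
    return replace(base, keq=keq)


def build_base_parameters(
    constants: PhysicalConstants | None = None,
) -> ParameterSet:
    """The basal model configuration.

    Independent equilibrium constants take their printed experimental values
    (the Nernst-derived ones are reproduced by :func:`nernst_keq` with the
    25 mV thermal voltage); the five dependent constants are then recomputed
    from the cycle relations, which reproduces the printed Keq5 = 0.03 1/uM,
    Keq7 = 2778 and Keq13 = 2.4e-4 1/uM.
    """
    constants = constants or PhysicalConstants()
    keq: dict[int, float] = {
        1: 11.023,       # e- + [3Fe-4S], Em = +60 mV
        2: 2.78e-6,      # [3Fe-4S]- -> [4Fe-4S], Em gap -320 mV
        3: 3.29e4,       # [4Fe-4S]- -> [2Fe-2S], Em gap +260 mV
        4: 4.17e-3,      # fumarate binding to oxidized FAD, 1/uM
        9: 0.006,        # [2Fe-2S]- -> free FAD, 1/uM
        10: 0.02,        # fumarate binding to FADH., 1/uM
        11: 0.289,       # [2Fe-2S]- -> FADH., 1/uM
        12: 0.02,        # fumarate binding to FADH2, 1/uM
        14: 250.0,       # succinate release from FADH..suc, uM
        16: 250.0,       # succinate release from FADH2.suc, uM
        8: 10.0,         # succinate release from FAD.suc, uM
        17: 5.2e26,      # FADH2 + O2 -> FAD + H2O2, Em gap 2*769 mV
        18: 6e-3,        # FADH2 + O2 -> FADH. + O2.-
        19: 0.267,       # FADH. + O2 -> FAD + O2.-
        20: 1.5e-4,      # [3Fe-4S]- + O2 -> O2.-
    }
    k: dict[int, float] = {
        1: 1e3,
        2: 1e4,
        3: 1e4,
        4: 1.0,
        5: 1e3,
        6: 1e3,
        7: 2.78e6,
        8: 0.5,
        9: 1e3,
        10: 1.0,
        11: 1e3,
        12: 1.0,
        13: 1e3,
        14: 10.0,
        15: 1e3,
        16: 10.0,
        17: 0.01,
        18: 0.01,
        19: 0.1,
        20: 1e-3,
    }
    k_rev = {i: k[i] / keq[i] for i in _PAIRED_REACTIONS}
    ps = ParameterSet(constants=constants, keq=keq, k=k, k_rev=k_rev, label="basal")
    return derive_dependent_keqs(ps)


_FORWARD_OVERRIDE = {f"k{i}": i for i in range(1, 21)}
_REVERSE_OVERRIDE = {f"kminus{i}": i for i in _PAIRED_REACTIONS}
_OTHER_OVERRIDE = ("sod_Vmax21", "sod_Km21", "k22")


def make_variant(
    base: ParameterSet, changes: dict[str, float], label: str | None = None
) -> ParameterSet:
    """Apply rate-constant overrides and re-derive the dependent constants.

    ``changes`` maps names like ``"k14"`` or ``"kminus16"`` to new values.
    For the four substrate binding/release pairs (reactions 10, 12, 14, 16)
    the equilibrium constant is recomputed as k/k_rev before detailed-balance
    propagation, so e.g. k14 = k16 = 1e-2 1/s with the basal k_rev = 0.04
    gives Keq14 = Keq16 = 0.25 uM and, through the cycles, Keq13 = 0.24 1/uM.
    Overrides outside that expected set are applied but flagged with a
    warning, since they change the basal thermodynamics.
    """
    keq = dict(base.keq)
    k = dict(base.k)
    k_rev = dict(base.k_rev)
    extra: dict[str, float] = {}
    expected = {f"k{i}" for i in _PAIRED_REACTIONS} | set(_REVERSE_OVERRIDE)
    for name, value in changes.items():
        if name in _FORWARD_OVERRIDE:
            k[_FORWARD_OVERRIDE[name]] = value
        elif name in _REVERSE_OVERRIDE:
            k_rev[_REVERSE_OVERRIDE[name]] = value
        elif name in _OTHER_OVERRIDE:
            extra[name] = value
        else:
            raise ConfigurationError(f"unknown rate-constant override: {name!r}")
        if name not in expected and name not in _OTHER_OVERRIDE:
            warnings.warn(
                f"override {name!r} is outside the substrate binding/release set; "
                "basal thermodynamics will change",
                stacklevel=2,
            )
    for i in _PAIRED_REACTIONS:
        if k_rev[i] <= 0:
            raise InvalidConstantError(f"kminus{i} must be positive")
        keq[i] = k[i] / k_rev[i]
    new_label = label if label is not None else (base.label if not changes else None)
    if new_label is None:
        parts = [f"{n}={v:g}" for n, v in sorted(changes.items())]
        new_label = ",".join(parts)
    ps = replace(base, keq=keq, k=k, k_rev=k_rev, label=new_label, **extra)
    return derive_dependent_keqs(ps)


def zero_ros_variant(ps: ParameterSet) -> ParameterSet:
    """Copy of a parameter set with every ROS channel switched off.

    Zeroes the rate constants of the flavin/cluster oxygen reactions
    (17-20); the mainstream electron-transfer thermodynamics is untouched,
    so detailed balance still holds.  Used for the anaerobic steady-state
    identities V1 = V2 = V3 = V_rev_tot = 2*V_suc_tot.
    """
    k = dict(ps.k)
    for i in (17, 18, 19, 20):
        k[i] = 0.0
    return replace(ps, k=k, label=f"{ps.label}+ros_off")


def cycle_residuals(ps: ParameterSet) -> tuple[float, float, float, float]:
    """Products of equilibrium constants around the four closed cycles.

    Each equals 1 for a thermodynamically consistent set:
      cycle 1: reactions 4-8          Keq4*Keq5*Keq6*Keq7*Keq8
      cycle 2: reactions 6,10,11,12   Keq6*Keq10/(Keq11*Keq12)
      cycle 3: reactions 8,9,13,14    Keq8*Keq9/(Keq13*Keq14)
      cycle 4: reactions 7,12,13,15,16  Keq7*Keq12*Keq13*Keq15*Keq16
    """
    q = ps.keq
    return (
        q[4] * q[5] * q[6] * q[7] * q[8],
        q[6] * q[10] / (q[11] * q[12]),
        q[8] * q[9] / (q[13] * q[14]),
        q[7] * q[12] * q[13] * q[15] * q[16],
    )
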