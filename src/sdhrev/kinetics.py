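"""State, rate laws and ODE right-hand side of the reverse-direction model.

The dynamic state holds the 13 integrated species (uM).  The oxidized forms
of the three iron-sulfur clusters and the free oxidized flavin are never
integrated: they are reconstructed from the four moiety-conservation
relations, which enforces conservation exactly along any trajectory of the
reduced system.

Reaction 1 is the electrode (Butler-Volmer) step: electron exchange between
the graphite electrode at potential E_out and the [3Fe-4S] cluster, with
transfer coefficient alpha.  Reactions 2-16 are mass-action electron
transfers and substrate binding/release steps; 17-20 are the ROS side
reactions (H2O2 by FADH2; superoxide by FADH2, FADH. and the reduced
[3Fe-4S] cluster); 21 is Michaelis-Menten superoxide dismutation and 22 the
first-order H2O2 efflux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "SPECIES",
    "COMPLEMENTS",
    "N_SPECIES",
    "ClampedEnvironment",
    "RateVector",
    "StateValidityError",
    "default_initial_state",
    "complements",
    "electrode_rate",
    "reaction_rates",
    "rate_vector",
    "ode_rhs",
    "ode_jacobian",
    "full_state",
    "ode_rhs_full",
    "ode_jacobian_full",
    "flux_to_specific_rate",
    "protein_to_concentration",
    "STOICHIOMETRY",
    "FULL_STOICHIOMETRY",
]

#: The 13 dynamic species, in state-vector order.
SPECIES = (
    "fes3_red",     # [3Fe-4S]-
    "fes4_red",     # [4Fe-4S]-
    "fes2_red",     # [2Fe-2S]-
    "fad_fum",      # FAD.fum
    "fadh_fum",     # FADH..fum
    "fadh2_fum",    # FADH2.fum
    "fad_suc",      # FAD.suc
    "fadh_suc",     # FADH..suc
    "fadh2_suc",    # FADH2.suc
    "fadh",         # FADH. (unoccupied site)
    "fadh2",        # FADH2 (unoccupied site)
    "superoxide",   # O2.-
    "h2o2",         # H2O2
)
N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Conserved complements, reconstructed from the pool totals.
COMPLEMENTS = ("fes3_ox", "fes4_ox", "fes2_ox", "fad")

#: Indices of the flavin-moiety members among the dynamic species; together
#: with free oxidized FAD they form the nine-state flavin pool.
_FAD_MEMBERS = tuple(range(_IDX["fad_fum"], _IDX["fadh2"] + 1))

NEG_TOL = 1e-9  # uM; tolerated numerical undershoot below zero


class StateValidityError(ValueError):
    """A state violates nonnegativity or moiety conservation beyond tolerance."""


#: Default proton value: the pH-7.4 hydrogen-ion concentration expressed on
#: the uM scale (10^-1.4 = 0.0398).  The trimolecular electron-transfer laws
#: carry this factor explicitly; it shifts the potential at which each
#: reduction step engages by vT*ln(1/H) ~ -81 mV, and with it the simulated
#: tunnel-diode thresholds onto the experimentally observed values.
DEFAULT_HPLUS = 10.0**-1.4


@dataclass(frozen=True)
class ClampedEnvironment:
    """Clamped concentrations and the electrode potential.

    fum, suc, O2 in uM; Hplus enters the trimolecular rate laws as a bare
    multiplicative factor (default: pH-7.4 concentration on the uM scale);
    E_out in mV.  O2 defaults to an air-saturated 240 uM; electrode sweeps
    that emulate anaerobic voltammetry override it to 0.
    """

    fum: float = 1000.0
    suc: float = 50.0
    Hplus: float = DEFAULT_HPLUS
    O2: float = 240.0
    E_out: float = 0.0

    def __post_init__(self) -> None:
        if self.fum < 0 or self.suc < 0 or self.O2 < 0:
            raise ValueError("clamped concentrations must be nonnegative")


def default_initial_state(ps: ParameterSet) -> np.ndarray:
    """Fully oxidized pools: every dynamic species zero (all flavin free FAD)."""
    return np.zeros(N_SPECIES)


def complements(y: np.ndarray, ps: ParameterSet) -> dict[str, float]:
    """Oxidized cluster forms and free FAD from moiety conservation."""
    t = ps.pool_totals
    bound = float(np.sum(y[list(_FAD_MEMBERS)]))
    return {
        "fes3_ox": t["3Fe-4S"] - float(y[0]),
        "fes4_ox": t["4Fe-4S"] - float(y[1]),
        "fes2_ox": t["2Fe-2S"] - float(y[2]),
        "fad": t["FAD"] - bound,
    }


def _validate_state(y: np.ndarray, ps: ParameterSet) -> None:
    if np.any(np.asarray(y) < -NEG_TOL):
        i = int(np.argmin(y))
        raise StateValidityError(f"species {SPECIES[i]} negative: {y[i]:.3e} uM")
    comp = complements(np.asarray(y), ps)
    for name, value in comp.items():
        if value < -NEG_TOL:
            raise StateValidityError(f"complement {name} negative: {value:.3e} uM")


def electrode_rate(ox: float, red: float, E_out: float, ps: ParameterSet) -> float:
    """Butler-Volmer rate of the electrode -> [3Fe-4S] electron exchange.

    V1 = k1*(ox*exp(-alpha*E/vT) - red*exp((1-alpha)*E/vT)/Keq1).  The rate
    vanishes at the Nernstian ratio red/ox = Keq1*exp(-E/vT).
    """
    a = ps.constants.alpha
    vT = ps.constants.thermal_voltage_mV
    return ps.k[1] * (
        ox * np.exp(-a * E_out / vT)
        - red * np.exp((1.0 - a) * E_out / vT) / ps.keq[1]
    )


def reaction_rates(
    y: np.ndarray,
    env: ClampedEnvironment,
    ps: ParameterSet,
    validate: bool = True,
    explicit_complements: tuple | None = None,
) -> np.ndarray:
    """Instantaneous rates V1..V22 (uM/s), index i-1 holding reaction i.

    Works on real, complex, long-double and object (arbitrary-precision)
    arrays, so everything stays in plain arithmetic.  When
    ``explicit_complements`` is given as (fes3_ox, fes4_ox, fes2_ox, fad),
    those values are used instead of the pool-total subtraction -- the
    redundant 17-species formulation relies on this.
    """
    y = np.asarray(y)
    if validate and not np.iscomplexobj(y):
        _validate_state(y, ps)
    if explicit_complements is not None:
        fes3, fes4, fes2, fad = explicit_complements
    else:
        t = ps.pool_totals
        fes3, fes4, fes2 = (
            t["3Fe-4S"] - y[0],
            t["4Fe-4S"] - y[1],
            t["2Fe-2S"] - y[2],
        )
        fad = t["FAD"] - (y[3] + y[4] + y[5] + y[6] + y[7] + y[8] + y[9] + y[10])
    fum, suc, H, O2 = env.fum, env.suc, env.Hplus, env.O2
    k, q = ps.k, ps.keq
    a = ps.constants.alpha
    vT = ps.constants.thermal_voltage_mV
    E = env.E_out

    V = np.zeros(22, dtype=np.result_type(y.dtype, float))
    V[0] = k[1] * (
        fes3 * np.exp(-a * E / vT) - y[0] * np.exp((1 - a) * E / vT) / q[1]
    )
    V[1] = k[2] * (fes4 * y[0] - y[1] * fes3 / q[2])
    V[2] = k[3] * (fes2 * y[1] - y[2] * fes4 / q[3])
    V[3] = k[4] * (fad * fum - y[3] / q[4])
    V[4] = k[5] * (y[3] * y[2] * H - y[4] * fes2 / q[5])
    V[5] = k[6] * (y[4] * y[2] * H - y[5] * fes2 / q[6])
    V[6] = k[7] * (y[5] - y[6] / q[7])
    V[7] = k[8] * (y[6] - fad * suc / q[8])
    V[8] = k[9] * (fad * y[2] * H - y[9] * fes2 / q[9])
    V[9] = k[10] * (y[9] * fum - y[4] / q[10])
    V[10] = k[11] * (y[9] * y[2] * H - y[10] * fes2 / q[11])
    V[11] = k[12] * (y[10] * fum - y[5] / q[12])
    V[12] = k[13] * (y[6] * y[2] * H - y[7] * fes2 / q[13])
    V[13] = k[14] * (y[7] - y[9] * suc / q[14])
    V[14] = k[15] * (y[7] * y[2] * H - y[8] * fes2 / q[15])
    V[15] = k[16] * (y[8] - y[10] * suc / q[16])
    V[16] = k[17] * (y[10] * O2 - fad * y[12] / q[17])
    V[17] = k[18] * (y[10] * O2 - y[9] * y[11] * H / q[18])
    V[18] = k[19] * (y[9] * O2 - fad * y[11] * H / q[19])
    V[19] = k[20] * (y[0] * O2 - fes3 * y[11] / q[20])
    V[20] = ps.sod_Vmax21 * y[11] / (ps.sod_Km21 + y[11])
    V[21] = ps.k22 * y[12]
    return V


# Net stoichiometry of the 13 dynamic species (rows) in the 22 reactions
# (columns); d y / dt = S @ V.
STOICHIOMETRY = np.zeros((N_SPECIES, 22))
_S = {
    "fes3_red": {1: 1, 2: -1, 20: -1},
    "fes4_red": {2: 1, 3: -1},
    "fes2_red": {3: 1, 5: -1, 6: -1, 9: -1, 11: -1, 13: -1, 15: -1},
    "fad_fum": {4: 1, 5: -1},
    "fadh_fum": {5: 1, 10: 1, 6: -1},
    "fadh2_fum": {6: 1, 12: 1, 7: -1},
    "fad_suc": {7: 1, 8: -1, 13: -1},
    "fadh_suc": {13: 1, 14: -1, 15: -1},
    "fadh2_suc": {15: 1, 16: -1},
    "fadh": {9: 1, 14: 1, 10: -1, 11: -1, 18: 1, 19: -1},
    "fadh2": {11: 1, 16: 1, 12: -1, 17: -1, 18: -1},
    "superoxide": {18: 1, 19: 1, 20: 1, 21: -2},
    "h2o2": {17: 1, 21: 1, 22: -1},
}
for _name, _cols in _S.items():
    for _rxn, _coef in _cols.items():
        STOICHIOMETRY[_IDX[_name], _rxn - 1] = _coef

# Full 17-species stoichiometry (dynamic species + the four complements),
# used by the SBML export and by conservation-drift checks.
FULL_STOICHIOMETRY = np.zeros((N_SPECIES + 4, 22))
FULL_STOICHIOMETRY[:N_SPECIES] = STOICHIOMETRY
for _cname, _cols in {
    "fes3_ox": {1: -1, 2: 1, 20: 1},
    "fes4_ox": {2: -1, 3: 1},
    "fes2_ox": {3: -1, 5: 1, 6: 1, 9: 1, 11: 1, 13: 1, 15: 1},
    "fad": {4: -1, 8: 1, 9: -1, 17: 1, 19: 1},
}.items():
    for _rxn, _coef in _cols.items():
        FULL_STOICHIOMETRY[N_SPECIES + COMPLEMENTS.index(_cname), _rxn - 1] = _coef


def ode_rhs(
    t: float,
    y: np.ndarray,
    env: ClampedEnvironment,
    ps: ParameterSet,
    validate: bool = False,
) -> np.ndarray:
    """Time derivatives (uM/s) of the 13 dynamic species."""
    return STOICHIOMETRY @ reaction_rates(y, env, ps, validate=validate)


def ode_jacobian(
    t: float, y: np.ndarray, env: ClampedEnvironment, ps: ParameterSet
) -> np.ndarray:
    """13x13 Jacobian of the right-hand side, by complex-step differentiation.

    Every rate law is analytic in the state, so the complex step is exact to
    machine precision and free of subtractive cancellation.
    """
    y = np.asarray(y, dtype=float)
    h = 1e-200
    J = np.empty((N_SPECIES, N_SPECIES))
    for j in range(N_SPECIES):
        yc = y.astype(complex)
        yc[j] += 1j * h
        J[:, j] = (STOICHIOMETRY @ reaction_rates(yc, env, ps, validate=False)).imag / h
    return J


def full_state(y: np.ndarray, ps: ParameterSet) -> np.ndarray:
    """17-component state: dynamic species followed by the four complements."""
    comp = complements(np.asarray(y), ps)
    return np.concatenate([y, [comp[name] for name in COMPLEMENTS]])


def ode_rhs_full(
    t: float, z: np.ndarray, env: ClampedEnvironment, ps: ParameterSet
) -> np.ndarray:
    """Right-hand side of the redundant 17-species system.

    Integrating this form does not enforce conservation by construction; it
    exists to verify that the explicit stoichiometry conserves each moiety
    (every conserved sum has zero net production) and to mirror the SBML
    export semantics.
    """
    z = np.asarray(z)
    V = reaction_rates(
        z[:N_SPECIES], env, ps, validate=False,
        explicit_complements=tuple(z[N_SPECIES:]),
    )
    return FULL_STOICHIOMETRY @ V


def ode_jacobian_full(
    t: float, z: np.ndarray, env: ClampedEnvironment, ps: ParameterSet
) -> np.ndarray:
    """17x17 Jacobian of the redundant system, by complex step."""
    z = np.asarray(z, dtype=float)
    h = 1e-200
    n = z.size
    J = np.empty((n, n))
    for j in range(n):
        zc = z.astype(complex)
        zc[j] += 1j * h
        J[:, j] = ode_rhs_full(t, zc, env, ps).imag / h
    return J


def flux_to_specific_rate(v: float, ps: ParameterSet | None = None) -> float:
    """Convert a volumetric rate (uM/s) to pmol/min/mg mitochondrial protein."""
    factor = ps.constants.flux_conversion if ps is not None else 220.0
    return v * factor


def protein_to_concentration(content: float, ps: ParameterSet | None = None) -> float:
    """Convert an enzyme content (nmol/mg protein) to uM in the inner membrane.

    0.209 nmol/mg -> 0.209 * 273 / 0.24 = 237.7 uM (rounded to the 235 uM
    pool totals used as defaults).
    """
    if content < 0:
        raise ValueError("content must be nonnegative")
    c = ps.constants if ps is not None else None
    factor = c.conc_per_content if c is not None else 273.0 / 0.24
    return content * factor


@dataclass(frozen=True)
class RateVector:
    """Named view of the 22 rates with the aggregate fluxes of interest."""

    V: np.ndarray  # shape (22,), V[i-1] is reaction i, uM/s

    def __post_init__(self) -> None:
        if np.asarray(self.V).shape != (22,):
            raise ValueError("RateVector requires 22 rates")
        if not np.all(np.isfinite(self.V)):
            raise ValueError("rates must be finite")

    def __getitem__(self, reaction_id: int) -> float:
        return float(self.V[reaction_id - 1])

    @property
    def v_rev_tot(self) -> float:
        """Total reverse electron flux: [2Fe-2S]- oxidation in 5,6,9,11,13,15."""
        return float(self.V[[4, 5, 8, 10, 12, 14]].sum())

    @property
    def v_suc_tot(self) -> float:
        """Total free-succinate release: reactions 8, 14, 16."""
        return float(self.V[[7, 13, 15]].sum())

    @property
    def v_h2o2(self) -> float:
        """Total H2O2 production: flavin reaction 17 plus dismutation 21."""
        return float(self.V[16] + self.V[20])


def rate_vector(
    y: np.ndarray, env: ClampedEnvironment, ps: ParameterSet, validate: bool = True
) -> RateVector:
    """Evaluate all rates on a state and wrap them with the aggregates."""
    return RateVector(reaction_rates(y, env, ps, validate=validate))
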