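"""Sweep and titration drivers that regenerate the steady-state analyses.

Every driver returns a tidy pandas DataFrame keyed by (variant label, swept
value) with one converged steady state per row: the 13 dynamic species, the
four conserved complements, all 22 rates, the aggregate fluxes in uM/s and
as specific rates in pmol/min/mg protein, and convergence diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import (
    COMPLEMENTS,
    SPECIES,
    ClampedEnvironment,
    complements,
)
from .params import ParameterSet
from .steady_state import ConvergenceError, find_steady_state

__all__ = [
    "DEFAULT_EOUT_GRID",
    "TITRATION_EOUT_SET",
    "ThresholdReport",
    "eout_sweep",
    "threshold_detect",
    "flux_decomposition",
    "redox_profile",
    "ros_scan",
    "fumarate_titration",
]

#: Default electrode-potential grid: +100 to -400 mV at 2 mV spacing, fine
#: enough that the quadratic threshold refinement is limited by the model,
#: not the grid.
DEFAULT_EOUT_GRID = np.arange(100.0, -400.0 - 1e-9, -2.0)

#: Electrode potentials of the fumarate titrations.
TITRATION_EOUT_SET = (0.0, -50.0, -100.0, -150.0, -200.0)


def _row(
    label: str,
    env: ClampedEnvironment,
    ps: ParameterSet,
    swept: dict[str, float],
) -> dict:
    row: dict = {"label": label, **swept}
    try:
        res = find_steady_state(ps, env)
        y = np.asarray(res.state, float)
        row.update({name: y[i] for i, name in enumerate(SPECIES)})
        row.update({k: float(v) for k, v in complements(y, ps).items()})
        V = np.asarray(res.rates.V, float)
        row.update({f"V{i + 1}": V[i] for i in range(22)})
        factor = ps.constants.flux_conversion
        row["V_rev_tot"] = res.rates.v_rev_tot
        row["V_suc_tot"] = res.rates.v_suc_tot
        row["VH2O2"] = res.rates.v_h2o2
        row["V_suc_tot_specific"] = res.rates.v_suc_tot * factor
        row["VH2O2_specific"] = res.rates.v_h2o2 * factor
        row["residual_norm"] = res.residual_norm
        row["converged"] = True
    except ConvergenceError as err:
        row["residual_norm"] = err.residual
        row["converged"] = False
    return row


def eout_sweep(
    ps_variants: list[ParameterSet] | ParameterSet,
    env_template: ClampedEnvironment | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Steady states over an electrode-potential grid, per parameter variant.

    The environment template fixes fumarate at 1000 uM and succinate at
    50 uM unless overridden, and defaults to anaerobic conditions (O2 = 0,
    the regime of the protein-film voltammetry experiments these sweeps
    emulate).  Each grid point is solved independently from the fully
    oxidized initial condition (no continuation), so any initial-condition
    dependence would surface as a cross-check failure rather than as
    imported hysteresis.
    """
    if isinstance(ps_variants, ParameterSet):
        ps_variants = [ps_variants]
    env_template = env_template or ClampedEnvironment(O2=0.0)
    grid = DEFAULT_EOUT_GRID if grid is None else np.asarray(grid, float)
    if grid.size < 1:
        raise ValueError("E_out grid must contain at least one point")
    rows = []
    for ps in ps_variants:
        for E in grid:
            env = ClampedEnvironment(
                fum=env_template.fum,
                suc=env_template.suc,
                Hplus=env_template.Hplus,
                O2=env_template.O2,
                E_out=float(E),
            )
            rows.append(_row(ps.label, env, ps, {"E_out": float(E)}))
    return pd.DataFrame(rows)


class ThresholdReport(dict):
    """Threshold of the tunnel-diode drop for one variant.

    The threshold is operationalized as the electrode potential of the
    interior maximum of the chosen steady-state flux, refined by a quadratic
    fit through the three bracketing grid points; a monotone curve (maximum
    on the grid boundary) reports ``None``.  Keys: label, E_threshold_mV,
    peak_rate, grid_spacing_mV, reliable.
    """


def threshold_detect(
    sweep: pd.DataFrame, flux_column: str = "V_rev_tot"
) -> list[ThresholdReport]:
    """Locate the interior maximum of a flux curve for every variant."""
    reports = []
    for label, sub in sweep.groupby("label", sort=False):
        sub = sub.sort_values("E_out", ascending=False).reset_index(drop=True)
        E = sub["E_out"].to_numpy()
        spacing = float(np.max(np.abs(np.diff(E)))) if len(E) > 1 else np.nan
        f = sub[flux_column].to_numpy()
        conv = sub["converged"].to_numpy()
        rep = ThresholdReport(
            label=label,
            E_threshold_mV=None,
            peak_rate=float(np.nanmax(f)) if len(f) else np.nan,
            grid_spacing_mV=spacing,
            reliable=True,
        )
        if len(f) < 3:
            reports.append(rep)
            continue
        i = int(np.nanargmax(f))
        if i == 0 or i == len(f) - 1:
            reports.append(rep)  # boundary maximum: monotone, no threshold
            continue
        if not conv[i - 1 : i + 2].all():
            rep["reliable"] = False
        # Quadratic refinement on the bracketing triple (non-uniform safe).
        x0, x1, x2 = E[i - 1], E[i], E[i + 1]
        y0, y1, y2 = f[i - 1], f[i], f[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        E_star = float(-b / (2 * a)) if a != 0 else float(x1)
        rep["E_threshold_mV"] = E_star
        rep["peak_rate"] = float(y1)
        reports.append(rep)
    return reports


def flux_decomposition(sweep: pd.DataFrame) -> pd.DataFrame:
    """Succinate-release decomposition V8, V14, V16 and their sum, per row."""
    cols = ["label"] + [c for c in ("E_out", "fum") if c in sweep.columns]
    out = sweep[cols].copy()
    out["V8"] = sweep["V8"]
    out["V14"] = sweep["V14"]
    out["V16"] = sweep["V16"]
    out["V_suc_tot"] = sweep["V8"] + sweep["V14"] + sweep["V16"]
    return out


def redox_profile(sweep: pd.DataFrame) -> pd.DataFrame:
    """ROS-relevant redox centers per row: FADH., FADH2 and both cluster states.

    Reduced and oxidized cluster concentrations are both reported; the
    conservation bound (each <= its pool total) holds by construction.
    """
    cols = ["label"] + [c for c in ("E_out", "fum") if c in sweep.columns]
    keep = ["fadh", "fadh2", "fes3_red", "fes2_red", "fes3_ox", "fes2_ox"]
    return pd.concat([sweep[cols], sweep[keep]], axis=1)


def ros_scan(
    ps_variants: list[ParameterSet] | ParameterSet,
    env_template: ClampedEnvironment | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """E_out sweep focused on H2O2 production, in both unit systems.

    VH2O2 = V17 + V21 equals the efflux V22 at steady state; the specific
    rate column applies the 220 (pmol/min/mg)/(uM/s) conversion.  Unlike the
    anaerobic flux sweeps, the ROS scan keeps the aerobic default O2 = 240
    uM unless the template overrides it.
    """
    env_template = env_template or ClampedEnvironment()
    return eout_sweep(ps_variants, env_template, grid)


def fumarate_titration(
    ps_variants: list[ParameterSet] | ParameterSet,
    suc: float = 50.0,
    fum_grid: np.ndarray | None = None,
    eout_set: tuple[float, ...] = TITRATION_EOUT_SET,
    env_template: ClampedEnvironment | None = None,
) -> pd.DataFrame:
    """Succinate-production rate vs fumarate, per (variant, E_out).

    The default fumarate grid spans 1 uM to 100 mM logarithmically (five
    decades), wide enough to resolve both the hyperbolic rise and the
    saturating plateau at every electrode potential of the titration set.
    """
    if isinstance(ps_variants, ParameterSet):
        ps_variants = [ps_variants]
    if fum_grid is None:
        fum_grid = np.logspace(0, 5, 26)
    fum_grid = np.asarray(fum_grid, float)
    if fum_grid.size >= 2:
        span = fum_grid.max() / max(fum_grid.min(), 1e-300)
        if span < 100.0:
            raise ValueError("fumarate grid must span at least two decades")
    env_template = env_template or ClampedEnvironment(O2=0.0)
    rows = []
    for ps in ps_variants:
        for E in eout_set:
            for fum in fum_grid:
                env = ClampedEnvironment(
                    fum=float(fum),
                    suc=suc,
                    Hplus=env_template.Hplus,
                    O2=env_template.O2,
                    E_out=float(E),
                )
                rows.append(
                    _row(ps.label, env, ps, {"E_out": float(E), "fum": float(fum)})
                )
    return pd.DataFrame(rows)
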