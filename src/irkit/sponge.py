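"""Kinetic model of intron-retaining transcripts as miRNA sponges.

Mass-action competing-endogenous-RNA (ceRNA) system: a target mRNA T and
a sponge transcript S (an intron-retaining transcript carrying
``n_sites_S`` miRNA binding sites) compete for a shared miRNA M through
reversible complex formation; complexes decay either stoichiometrically
(miRNA degraded with the complex) or catalytically (miRNA recycled).
Raising sponge transcription titrates miRNA away from the target and
derepresses it.

State: (T, S, M, C_TM, C_SM), all in molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class SpongeParams:
    k_T: float = 10.0  # target transcription, molecules/time
    k_S: float = 10.0  # sponge transcription
    k_M: float = 20.0  # miRNA transcription
    d_T: float = 0.1  # free-species degradation, 1/time
    d_S: float = 0.1
    d_M: float = 0.05
    d_complex: float = 0.5  # complex decay
    a_TM: float = 0.01  # association, 1/(molecules*time)
    a_SM: float = 0.01
    u_TM: float = 0.02  # dissociation, 1/time
    u_SM: float = 0.02
    n_sites_S: int = 4  # miRNA sites per sponge transcript
    catalytic: bool = False  # recycle miRNA on complex decay

    def validate(self) -> None:
        for name in (
            "k_T", "k_S", "k_M", "d_T", "d_S", "d_M", "d_complex",
            "a_TM", "a_SM", "u_TM", "u_SM",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites_S < 1:
            raise ValueError("n_sites_S must be >= 1")


STATE_NAMES = ("T", "S", "M", "C_TM", "C_SM")


def derivatives(state, params: SpongeParams) -> np.ndarray:
    """Mass-action right-hand side d(state)/dt."""
    T, S, M, C_TM, C_SM = state
    p = params
    bind_T = p.a_TM * T * M
    bind_S = p.a_SM * p.n_sites_S * S * M
    recycle = p.d_complex * (C_TM + C_SM) if p.catalytic else 0.0
    dT = p.k_T - p.d_T * T - bind_T + p.u_TM * C_TM
    dS = p.k_S - p.d_S * S - bind_S + p.u_SM * C_SM
    dM = (
        p.k_M
        - p.d_M * M
        - bind_T
        - bind_S
        + p.u_TM * C_TM
        + p.u_SM * C_SM
        + recycle
    )
    dC_TM = bind_T - p.u_TM * C_TM - p.d_complex * C_TM
    dC_SM = bind_S - p.u_SM * C_SM - p.d_complex * C_SM
    return np.array([dT, dS, dM, dC_TM, dC_SM])


def simulate(
    params: SpongeParams,
    init=(0.0, 0.0, 0.0, 0.0, 0.0),
    t_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
):
    """Integrate the system with a stiff-safe adaptive solver (LSODA).

    Returns (t, states array of shape (len(t), 5)). Trajectories are
    clipped at exact zero to remove solver-scale negative round-off.
    """
    params.validate()
    if t_grid is None:
        t_grid = np.linspace(0, 500.0, 501)
    t_grid = np.asarray(t_grid, float)
    sol = solve_ivp(
        lambda t, y: derivatives(y, params),
        (t_grid[0], t_grid[-1]),
        np.asarray(init, float),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, None)


def steady_state(params: SpongeParams, t_max: float = 5000.0,
                 tol: float = 1e-9) -> np.ndarray:
    """Steady state by integration until the relative derivative vanishes."""
    params.validate()
    y = np.zeros(5)
    t_span = t_max
    for _ in range(8):
        _, traj = simulate(
            params, init=y, t_grid=np.linspace(0, t_span, 11),
            rtol=1e-10, atol=1e-10,
        )
        y = traj[-1]
        d = derivatives(y, params)
        scale = np.maximum(np.abs(y), 1.0)
        if np.max(np.abs(d) / scale) < tol:
            return y
        t_span *= 2
    return y


def sponge_dose_response(params: SpongeParams, k_S_grid) -> dict:
    """Steady-state free target T* as a function of sponge transcription.

    Reports the full curve plus the derepression ratio
    T*(k_S_max) / T*(k_S = 0).
    """
    k_S_grid = np.asarray(k_S_grid, float)
    curve = np.array(
        [steady_state(replace(params, k_S=float(ks)))[0] for ks in k_S_grid]
    )
    base = steady_state(replace(params, k_S=0.0))[0]
    return {
        "k_S": k_S_grid,
        "free_target": curve,
        "derepression_ratio": float(curve[-1] / base) if base > 0 else float("inf"),
    }


def closed_system_invariants(state0, params: SpongeParams):
    """Conserved totals in the closed variant (no production or decay):
    T + C_TM, S + C_SM, M + C_TM + C_SM."""
    T, S, M, C_TM, C_SM = state0
    return np.array([T + C_TM, S + C_SM, M + C_TM + C_SM])


def make_closed(params: SpongeParams) -> SpongeParams:
    return replace(
        params, k_T=0.0, k_S=0.0, k_M=0.0, d_T=0.0, d_S=0.0, d_M=0.0,
        d_complex=0.0,
    )
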