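"""Equilibrium analysis, parameter-space exploration and the activity calculator.

Under constant post-ZGA rates the per-division methylation map (replication,
repair, active demethylation) is affine in (X, Y, Z) and contracts to a
unique fixed point for all non-degenerate rate combinations. With no active
demethylation (zeta = 0) and full repair resolution (alpha + delta = 1) the
equilibrium homomethylation level has the closed form

    X* = beta / (1 - alpha + beta),

which ties a gamete's global methylation level to the balance between
maintenance failure (1 - alpha) and de novo methylation (beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GrowthConfig,
    InvalidParameterError,
    InvalidStateError,
    MethylState,
    RateSet,
    active_demethylate,
    repair,
    replicate,
)
from .lifecycle import GenerationRecord

__all__ = [
    "FixedPointResult",
    "ParamSpaceResult",
    "ActivityMeasure",
    "NotConvergedError",
    "fixed_point",
    "divisions_to_equilibrium",
    "zga_onset",
    "cell_count_equilibrium_division",
    "explore_parameter_space",
    "methylation_activity",
    "default_start_state",
]


class NotConvergedError(RuntimeError):
    """The iterated division map failed to reach a fixed point."""


@dataclass(frozen=True)
class FixedPointResult:
    """Equilibrium proportions of the constant-rate per-division map."""

    X_star: float
    Y_star: float
    Z_star: float
    converged: bool
    iterations: int

    def as_state(self) -> MethylState:
        return MethylState(self.X_star, self.Y_star, self.Z_star)


@dataclass
class ParamSpaceResult:
    """Grid triples (alpha, beta, delta) whose equilibrium matches a target level."""

    target_X: float
    accuracy: float
    grid_step: float
    table: pd.DataFrame  # columns: alpha, beta, delta, X_star[, divisions_to_equilibrium]

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0


@dataclass(frozen=True)
class ActivityMeasure:
    """Net enzymatic (de-)methylation speed between two developmental stages."""

    X_S0: float
    X_S1: float
    L_n: float
    H: int
    T_d: float
    A: float


def _one_division(state: MethylState, rates: RateSet, rho_c: float) -> MethylState:
    return active_demethylate(
        repair(replicate(state), rates.alpha, rates.beta, rates.delta, rho_c),
        rates.zeta,
    )


def fixed_point(
    alpha: float,
    beta: float,
    delta: float,
    zeta: float = 0.0,
    rho_c: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> FixedPointResult:
    """Fixed point of the constant-rate division map.

    Uses the closed form ``X* = beta/(1 - alpha + beta)`` when ``zeta = 0``
    and ``alpha + rho_c*delta = 1`` (the hemimethylated pool then empties in
    a single division); otherwise iterates the map to ``tol``. The map is
    affine and contracting except at the degenerate perfect-maintenance
    corner (alpha = 1, beta = delta = zeta = 0), where every level is a
    fixed point and an error is raised.
    """
    rates = RateSet(alpha=alpha, beta=beta, delta=delta, zeta=zeta)
    if not 0.0 <= rho_c <= 1.0:
        raise InvalidParameterError(f"rho_c = {rho_c!r} outside [0, 1]")
    if alpha + rho_c * delta > 1.0 + 1e-9:
        raise InvalidParameterError("alpha + rho_c*delta exceeds 1")
    if zeta == 0.0 and abs(alpha + rho_c * delta - 1.0) <= 1e-12:
        denom = 1.0 - alpha + beta
        if denom == 0.0:
            raise InvalidParameterError(
                "degenerate rates (alpha = 1, beta = 0): every level is a fixed point"
            )
        x = beta / denom
        return FixedPointResult(x, 0.0, 1.0 - x, True, 0)
    if alpha == 1.0 and beta == 0.0 and delta * rho_c == 0.0 and zeta == 0.0:
        raise InvalidParameterError(
            "degenerate rates (alpha = 1, beta = 0): every level is a fixed point"
        )
    state = MethylState(1.0, 0.0, 0.0)
    for it in range(1, max_iter + 1):
        nxt = _one_division(state, rates, rho_c)
        if (
            abs(nxt.X - state.X) <= tol
            and abs(nxt.Y - state.Y) <= tol
            and abs(nxt.Z - state.Z) <= tol
        ):
            return FixedPointResult(nxt.X, nxt.Y, nxt.Z, True, it)
        state = nxt
    raise NotConvergedError(f"no fixed point within {max_iter} iterations")


def divisions_to_equilibrium(
    trajectory: GenerationRecord | pd.DataFrame | np.ndarray,
    sex: str | None = None,
    target: float = 0.0,
    tol: float = 0.005,
) -> int | None:
    """First division from which X stays within ``tol`` of ``target``.

    Accepts a generation record (with ``sex``), a trajectory table, or a bare
    array of per-division X values indexed from division 1. Returns ``None``
    when the trajectory never settles inside the tolerance band.
    """
    xs = _x_series(trajectory, sex)
    ok = np.abs(xs - target) < tol
    if not ok[-1]:
        return None
    bad = np.nonzero(~ok)[0]
    return int(bad[-1]) + 2 if len(bad) else 1


def _x_series(
    trajectory: GenerationRecord | pd.DataFrame | np.ndarray, sex: str | None
) -> np.ndarray:
    if isinstance(trajectory, GenerationRecord):
        if sex is None:
            raise InvalidParameterError("sex is required with a GenerationRecord")
        return trajectory.sex_series(sex, "X").to_numpy()
    if isinstance(trajectory, pd.DataFrame):
        sub = trajectory[trajectory["sex"] == sex] if sex is not None else trajectory
        return sub.sort_values("division")["X"].to_numpy()
    return np.asarray(trajectory, dtype=float)


def zga_onset(record: GenerationRecord, sex: str = "male") -> int | None:
    """First division at which the rate transition crosses its midpoint.

    Operationally: the first division whose start-of-division repressor level
    satisfies ``rho_power*rho0/rho >= 1/nu_t``. Returns ``None`` when the
    threshold is never crossed within the generation.
    """
    cfg = record.growth
    if cfg.rho0 <= 0:
        raise InvalidStateError("ZGA onset via the repressor ratio requires rho0 > 0")
    rho = record.sex_series(sex, "rho").to_numpy()
    crossed = cfg.rho_power * cfg.rho0 / rho >= 1.0 / cfg.nu_t
    idx = np.nonzero(crossed)[0]
    return int(idx[0]) + 1 if len(idx) else None


def cell_count_equilibrium_division(record: GenerationRecord, sex: str = "male") -> int | None:
    """First division after which the cell count rounds to K (N >= K - 0.5)."""
    return record.cell_equilibrium_division[sex]


def default_start_state() -> MethylState:
    """Generation-2 zygotic state at the default rates.

    The average of the two default-sex equilibria (0.8 and 0.909091), i.e.
    the zygote produced by fertilization after a fully converged generation 1.
    """
    xm = fixed_point(0.99, 0.04, 0.01).X_star
    xf = fixed_point(0.99, 0.1, 0.01).X_star
    x = (xm + xf) / 2.0
    return MethylState(x, 0.0, 1.0 - x)


def _grid_fixed_points(
    alpha: np.ndarray, beta: np.ndarray, delta: np.ndarray
) -> np.ndarray:
    """Vectorized equilibrium X for zeta = 0, rho_c = 1 (closed form).

    Writing W for the equilibrium hemimethylation source ``X + Y/2``, the
    affine map gives ``W = beta / (beta + (1 - alpha + delta)/2)`` and
    ``X* = beta + W*(alpha - beta)``. Degenerate triples (denominator zero)
    yield NaN.
    """
    denom = beta + (1.0 - alpha + delta) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, beta / np.where(denom > 0, denom, 1.0), np.nan)
    return beta + W * (alpha - beta)


def _simulate_grid_trajectories(
    alpha: np.ndarray,
    beta: np.ndarray,
    delta: np.ndarray,
    cfg: GrowthConfig,
    start: MethylState,
) -> np.ndarray:
    """Full-model X trajectories for many post-ZGA triples at once.

    Vectorizes the per-division update (pre-ZGA rates {1,0,0,0}, logistic
    rate transition, repressor-gated repair demethylation, zeta = 0) across
    triples; growth/repressor dynamics are shared. Returns (n_triples, D).
    """
    n = len(alpha)
    X = np.full(n, start.X)
    Y = np.full(n, start.Y)
    Z = np.full(n, start.Z)
    rho = cfg.rho0
    out = np.empty((n, cfg.D))
    for d in range(cfg.D):
        rho_c = (cfg.rho0 - rho) / cfg.rho0 if cfg.rho0 > 0 else 1.0
        arg = cfg.rho_power * cfg.rho0 / rho - 1.0 / cfg.nu_t if cfg.rho0 > 0 else None
        if arg is None:
            raise InvalidStateError("grid simulation requires rho0 > 0")

        def _rate(pre: float, post: np.ndarray, Q: float) -> np.ndarray:
            t = -Q * arg
            if t >= 700.0:
                return np.full(n, pre)
            if t <= -700.0:
                return np.asarray(post, dtype=float)
            return pre + (post - pre) / (1.0 + np.exp(t))

        al = _rate(1.0, alpha, cfg.Q_alpha)
        be = _rate(0.0, beta, cfg.Q_beta)
        de = _rate(0.0, delta, cfg.Q_delta)
        # replicate
        Yd = X + Y / 2.0
        Zd = Z + Y / 2.0
        # repair
        X = al * Yd + be * Zd
        Y = (1.0 - al - rho_c * de) * Yd
        Z = (1.0 - be) * Zd + rho_c * de * Yd
        out[:, d] = X
        rho = rho * (1.0 - cfg.rho_deg)
    return out


def explore_parameter_space(
    target_X: float,
    accuracy: float = 0.01,
    grid_step: float = 0.01,
    compute_divisions: bool = True,
    growth: GrowthConfig | None = None,
    start_state: MethylState | None = None,
    tol: float = 0.005,
) -> ParamSpaceResult:
    """Scan the (alpha, beta, delta) grid for triples matching a target level.

    Evaluates the zeta = 0 equilibrium of every feasible grid triple
    (``alpha + delta <= 1``) analytically and retains those whose equilibrium
    X lies within ``accuracy`` of ``target_X``. For retained triples the
    number of divisions to (sustained) equilibrium is then measured by
    simulating the full model from the standard generation-2 zygotic state.
    """
    if not 0.0 <= target_X <= 1.0:
        raise InvalidParameterError(f"target_X = {target_X!r} outside [0, 1]")
    vals = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 12)
    A, B, Dl = (g.ravel() for g in np.meshgrid(vals, vals, vals, indexing="ij"))
    feasible = A + Dl <= 1.0 + 1e-12
    A, B, Dl = A[feasible], B[feasible], Dl[feasible]
    X_star = _grid_fixed_points(A, B, Dl)
    keep = np.isfinite(X_star) & (np.abs(X_star - target_X) <= accuracy + 1e-12)
    table = pd.DataFrame(
        {"alpha": A[keep], "beta": B[keep], "delta": Dl[keep], "X_star": X_star[keep]}
    ).reset_index(drop=True)
    if compute_divisions and len(table):
        cfg = growth if growth is not None else GrowthConfig()
        start = start_state if start_state is not None else default_start_state()
        traj = _simulate_grid_trajectories(
            table["alpha"].to_numpy(),
            table["beta"].to_numpy(),
            table["delta"].to_numpy(),
            cfg,
            start,
        )
        # NaN marks triples that do not settle within D divisions
        divs = np.empty(len(table))
        x_stars = table["X_star"].to_numpy()
        for i in range(len(table)):
            d = divisions_to_equilibrium(traj[i], target=x_stars[i], tol=tol)
            divs[i] = np.nan if d is None else d
        table["divisions_to_equilibrium"] = divs
    return ParamSpaceResult(
        target_X=target_X, accuracy=accuracy, grid_step=grid_step, table=table
    )


def methylation_activity(
    X_S0: float, X_S1: float, L_n: float, H: int = 2, T_d: float = 1.0
) -> ActivityMeasure:
    """Net (de-)methylation speed between two developmental stages.

    ``A = (X_S1 - X_S0) * L_n * H / T_d`` converts the change in the global
    homomethylation proportion into CpG sites converted per unit of ``T_d``
    (cell divisions or time). Positive A means net methylation, negative net
    demethylation.
    """
    if not (0.0 <= X_S0 <= 1.0 and 0.0 <= X_S1 <= 1.0):
        raise InvalidParameterError("stage methylation proportions must lie in [0, 1]")
    if L_n <= 0:
        raise InvalidParameterError(f"L_n = {L_n!r} must be positive")
    if H < 1:
        raise InvalidParameterError(f"H = {H!r} must be >= 1")
    if T_d <= 0:
        raise InvalidParameterError(f"T_d = {T_d!r} must be positive")
    A = (X_S1 - X_S0) * L_n * H / T_d
    return ActivityMeasure(X_S0=X_S0, X_S1=X_S1, L_n=L_n, H=H, T_d=T_d, A=A)
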