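"""Domain types and per-division operators of the three-state methylation model.

The model tracks the genome-wide proportions of homomethylated (``X``),
hemimethylated (``Y``) and unmethylated (``Z``) CpG sites in an embryo whose
cell number follows discrete logistic growth. Each cell division applies three
sequential events to the methylation state:

1. semiconservative DNA replication, which converts every homomethylated site
   into a hemimethylated one and splits hemimethylated sites evenly between
   the hemi- and unmethylated pools;
2. repair (maintenance) methylation/demethylation, which resolves
   hemimethylated sites to homo- (rate ``alpha``) or unmethylated (rate
   ``delta``) and de-novo methylates unmethylated sites (rate ``beta``);
3. active demethylation of homomethylated sites (rate ``zeta``).

The four rates switch from pre-ZGA values (perfect maintenance, everything
else off) to lineage-specific post-ZGA values through a logistic transition
driven by the decay of a maternally loaded repressor ``rho``, whose threshold
is tied to the nucleocytoplasmic ratio ``nu = 1/N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "InvalidParameterError",
    "InvalidStateError",
    "MethylState",
    "RateSet",
    "SexConfig",
    "GrowthConfig",
    "EmbryoState",
    "update_cell_count",
    "realized_division_rate",
    "decay_repressor",
    "repressor_effect",
    "nucleocytoplasmic_ratio",
    "transition_rate",
    "replicate",
    "repair",
    "active_demethylate",
    "instantaneous_rates",
    "division_step",
    "SEXES",
]

SEXES = ("male", "female")

# Tolerance for validating proportions/rates supplied by users or produced by
# long chains of floating-point updates.
_TOL = 1e-9
# Logistic arguments beyond this magnitude return the asymptote exactly, so
# saturated rates equal pre/post to the last bit (no overflow, no residual).
_SATURATION = 700.0


class InvalidParameterError(ValueError):
    """A parameter is outside its admissible range."""


class InvalidStateError(ValueError):
    """An operation was applied to a state that cannot occur in a valid run."""


def _snap_unit(v: float, what: str) -> float:
    """Validate a proportion/rate, snapping float dust just outside [0, 1]."""
    if not (-_TOL <= v <= 1.0 + _TOL):
        raise InvalidParameterError(f"{what} = {v!r} is outside [0, 1]")
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@dataclass(frozen=True)
class MethylState:
    """Proportions of homo- (X), hemi- (Y) and un-methylated (Z) CpG sites.

    The three states are mutually exclusive and exhaustive, so the components
    must sum to 1.
    """

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", _snap_unit(self.X, "X"))
        object.__setattr__(self, "Y", _snap_unit(self.Y, "Y"))
        object.__setattr__(self, "Z", _snap_unit(self.Z, "Z"))
        total = self.X + self.Y + self.Z
        if abs(total - 1.0) > _TOL:
            raise InvalidParameterError(
                f"methylation proportions sum to {total!r}, expected 1"
            )

    @property
    def methylation_level(self) -> float:
        """Global methylation level ``X + Y`` (sites methylated on >= 1 strand)."""
        return self.X + self.Y

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.X, self.Y, self.Z)


@dataclass(frozen=True)
class RateSet:
    """The four (de-)methylation rates acting at one instant in one sex.

    ``alpha + delta <= 1`` is required so that the repair step cannot drive
    the hemimethylated pool negative for any repressor effect in [0, 1].
    """

    alpha: float
    beta: float
    delta: float
    zeta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta", "zeta"):
            object.__setattr__(self, name, _snap_unit(getattr(self, name), name))
        if self.alpha + self.delta > 1.0 + _TOL:
            raise InvalidParameterError(
                f"alpha + delta = {self.alpha + self.delta!r} exceeds 1"
            )


#: Pre-ZGA rates: perfect maintenance methylation, all other processes off,
#: which keeps the zygotic methylation level constant across early divisions.
PRE_ZGA_RATES = RateSet(alpha=1.0, beta=0.0, delta=0.0, zeta=0.0)


@dataclass(frozen=True)
class SexConfig:
    """One sex's pre/post-ZGA rates and environmental-perturbation ranges."""

    sex_label: str
    post_zga: RateSet
    pre_zga: RateSet = PRE_ZGA_RATES
    alpha_env_range: tuple[float, float] = (-0.01, 0.01)
    delta_env_range: tuple[float, float] = (-0.01, 0.01)

    def __post_init__(self) -> None:
        if self.sex_label not in SEXES:
            raise InvalidParameterError(
                f"sex_label must be one of {SEXES}, got {self.sex_label!r}"
            )
        for name in ("alpha_env_range", "delta_env_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise InvalidParameterError(f"{name} = {(lo, hi)!r} is not a valid interval")
            object.__setattr__(self, name, (float(lo), float(hi)))


@dataclass(frozen=True)
class GrowthConfig:
    """Embryo growth, repressor and rate-transition parameters.

    Defaults are the canonical simulation scenario: 250 divisions per
    generation, intrinsic division rate 0.1 up to K = 1024 cells, repressor
    starting at 1.0 (twofold initial speed-up) decaying 10% per division, and
    a sharp (slope 100) rate transition anchored at nucleocytoplasmic
    threshold 0.01.
    """

    r: float = 0.1
    K: float = 1024.0
    rho0: float = 1.0
    rho_deg: float = 0.1
    rho_power: float = 1.0
    nu_t: float = 0.01
    Q_alpha: float = 100.0
    Q_beta: float = 100.0
    Q_delta: float = 100.0
    Q_zeta: float = 100.0
    D: int = 250
    N0: float = 1.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise InvalidParameterError(f"r = {self.r!r} must be positive")
        if self.K < 1:
            raise InvalidParameterError(f"K = {self.K!r} must be >= 1")
        if not 0.0 <= self.rho_deg <= 1.0:
            raise InvalidParameterError(f"rho_deg = {self.rho_deg!r} outside [0, 1]")
        if self.rho0 < 0:
            raise InvalidParameterError(f"rho0 = {self.rho0!r} must be >= 0")
        if not 0.0 < self.nu_t <= 1.0:
            raise InvalidParameterError(f"nu_t = {self.nu_t!r} outside (0, 1]")
        for name in ("Q_alpha", "Q_beta", "Q_delta", "Q_zeta"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.D < 1:
            raise InvalidParameterError(f"D = {self.D!r} must be >= 1")
        if not 1.0 <= self.N0 <= self.K:
            raise InvalidParameterError(f"N0 = {self.N0!r} outside [1, K]")


@dataclass(frozen=True)
class EmbryoState:
    """Cell count, repressor and derived quantities at the start of a division."""

    N: float
    rho: float
    rho0: float
    mu: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidParameterError(f"N = {self.N!r} must be >= 1")
        if self.rho < -_TOL or self.rho0 < 0:
            raise InvalidParameterError("repressor amounts must be nonnegative")
        if self.rho < 0.0:
            object.__setattr__(self, "rho", 0.0)

    @property
    def nu(self) -> float:
        """Nucleocytoplasmic ratio, 1/N under conserved cytoplasmic volume."""
        return 1.0 / self.N

    @classmethod
    def initial(cls, cfg: GrowthConfig) -> "EmbryoState":
        return cls(N=cfg.N0, rho=cfg.rho0, rho0=cfg.rho0,
                   mu=realized_division_rate(cfg.rho0, cfg.r))


# ---------------------------------------------------------------------------
# growth / repressor operators
# ---------------------------------------------------------------------------

def update_cell_count(N: float, mu: float, K: float) -> float:
    """One step of discrete logistic growth: ``N + mu*N*(1 - N/K)``."""
    if not 1.0 <= N <= K:
        raise InvalidParameterError(f"N = {N!r} outside [1, K={K!r}]")
    if not 0.0 < mu <= 1.0:
        raise InvalidParameterError(f"mu = {mu!r} outside (0, 1]")
    return N + mu * N * (1.0 - N / K)


def realized_division_rate(rho: float, r: float) -> float:
    """Division rate ``(1 + rho)*r``: the repressor speeds up early cleavage."""
    if rho < 0 or r <= 0:
        raise InvalidParameterError("rho must be >= 0 and r > 0")
    return (1.0 + rho) * r


def decay_repressor(rho: float, rho_deg: float) -> float:
    """Geometric decay ``rho*(1 - rho_deg)`` of the parental repressor."""
    if rho < 0:
        raise InvalidParameterError(f"rho = {rho!r} must be >= 0")
    if not 0.0 <= rho_deg <= 1.0:
        raise InvalidParameterError(f"rho_deg = {rho_deg!r} outside [0, 1]")
    return rho * (1.0 - rho_deg)


def repressor_effect(rho: float, rho0: float) -> float:
    """Repressing effect ``rho_c = (rho0 - rho)/rho0`` (1 when ``rho0 = 0``).

    Grows from 0 at the start of a generation to 1 as the repressor degrades.
    """
    if rho < 0 or rho0 < 0:
        raise InvalidParameterError("repressor amounts must be nonnegative")
    if rho0 == 0.0:
        return 1.0
    if rho > rho0 * (1.0 + _TOL):
        raise InvalidStateError(f"rho = {rho!r} exceeds rho0 = {rho0!r}")
    return (rho0 - min(rho, rho0)) / rho0


def nucleocytoplasmic_ratio(N: float) -> float:
    """Ratio ``nu = 1/N`` (cytoplasmic volume is conserved across cleavages)."""
    if N < 1:
        raise InvalidParameterError(f"N = {N!r} must be >= 1")
    return 1.0 / N


def transition_rate(
    pre: float,
    post: float,
    Q: float,
    rho_power: float,
    rho0: float,
    rho: float,
    nu_t: float,
    nu: float | None = None,
) -> float:
    """Logistic interpolation between the pre- and post-ZGA value of one rate.

    The transition argument is ``rho_power*rho0/rho - 1/nu_t``: the rate sits
    at ``pre`` while the repressor is abundant and switches to ``post`` once
    ``rho`` has decayed to ``rho_power*rho0*nu_t``. Saturated arguments
    (|Q * arg| >= 700) return the asymptote exactly rather than overflowing.

    When ``rho0 = 0`` the repressor ratio is undefined; the transition then
    degrades to a step function of the nucleocytoplasmic ratio (``pre`` while
    ``nu > nu_t``, ``post`` once ``nu <= nu_t``), which must be supplied via
    ``nu``.
    """
    if Q <= 0 or nu_t <= 0:
        raise InvalidParameterError("Q and nu_t must be positive")
    if rho0 == 0.0:
        if nu is None:
            raise InvalidParameterError("nu is required when rho0 = 0")
        return post if nu <= nu_t else pre
    if rho <= 0.0:
        raise InvalidStateError("rho = 0 with rho0 > 0: transition argument undefined")
    t = -Q * (rho_power * rho0 / rho - 1.0 / nu_t)
    if t >= _SATURATION:
        return pre
    if t <= -_SATURATION:
        return post
    return pre + (post - pre) / (1.0 + math.exp(t))


# ---------------------------------------------------------------------------
# methylation sub-steps
# ---------------------------------------------------------------------------

def replicate(state: MethylState) -> MethylState:
    """Semiconservative replication.

    Homomethylated sites all become hemimethylated; hemimethylated sites split
    evenly into hemi- and unmethylated daughters; unmethylated sites stay
    unmethylated. The homomethylated pool is exactly empty afterwards.
    """
    return MethylState(
        X=0.0,
        Y=state.X + state.Y / 2.0,
        Z=state.Z + state.Y / 2.0,
    )


def repair(
    state: MethylState, alpha: float, beta: float, delta: float, rho_c: float
) -> MethylState:
    """Repair/maintenance methylation and demethylation, plus de novo methylation.

    Hemimethylated sites resolve to homomethylated at rate ``alpha`` or to
    unmethylated at rate ``rho_c*delta`` (repair demethylation is gated by the
    repressor effect); unmethylated sites are de-novo methylated at ``beta``.
    Requires the post-replication precondition ``X = 0``.
    """
    if state.X != 0.0:
        raise InvalidStateError(
            "repair must be applied to a post-replication state (X = 0)"
        )
    out = alpha + rho_c * delta
    if out > 1.0 + _TOL:
        raise InvalidParameterError(
            f"alpha + rho_c*delta = {out!r} exceeds 1: hemimethylated pool would go negative"
        )
    return MethylState(
        X=alpha * state.Y + beta * state.Z,
        Y=(1.0 - alpha - rho_c * delta) * state.Y,
        Z=(1.0 - beta) * state.Z + rho_c * delta * state.Y,
    )


def active_demethylate(state: MethylState, zeta: float) -> MethylState:
    """Active demethylation of homomethylated sites at rate ``zeta``."""
    if not 0.0 <= zeta <= 1.0:
        raise InvalidParameterError(f"zeta = {zeta!r} outside [0, 1]")
    return MethylState(
        X=(1.0 - zeta) * state.X,
        Y=state.Y,
        Z=state.Z + zeta * state.X,
    )


# ---------------------------------------------------------------------------
# composed per-division update
# ---------------------------------------------------------------------------

def instantaneous_rates(
    embryo: EmbryoState, cfg: GrowthConfig, sex: SexConfig
) -> RateSet:
    """The four rates in force at the current repressor level."""
    pre, post = sex.pre_zga, sex.post_zga
    kw = dict(rho_power=cfg.rho_power, rho0=embryo.rho0, rho=embryo.rho,
              nu_t=cfg.nu_t, nu=embryo.nu)
    return RateSet(
        alpha=transition_rate(pre.alpha, post.alpha, cfg.Q_alpha, **kw),
        beta=transition_rate(pre.beta, post.beta, cfg.Q_beta, **kw),
        delta=transition_rate(pre.delta, post.delta, cfg.Q_delta, **kw),
        zeta=transition_rate(pre.zeta, post.zeta, cfg.Q_zeta, **kw),
    )


def division_step(
    state: MethylState,
    embryo: EmbryoState,
    cfg: GrowthConfig,
    sex: SexConfig,
) -> tuple[MethylState, EmbryoState, RateSet]:
    """Advance one cell division.

    The repressor effect and the four instantaneous rates are evaluated from
    the repressor level at the *start* of the division; the three methylation
    sub-steps (replication, repair, active demethylation) are then applied in
    order, and finally the cell count and repressor are advanced. Returns the
    post-division methylation state, the embryo state for the next division,
    and the rates that were in force.
    """
    rho_c = repressor_effect(embryo.rho, embryo.rho0)
    rates = instantaneous_rates(embryo, cfg, sex)
    new_state = active_demethylate(
        repair(replicate(state), rates.alpha, rates.beta, rates.delta, rho_c),
        rates.zeta,
    )
    mu = realized_division_rate(embryo.rho, cfg.r)
    new_embryo = EmbryoState(
        N=update_cell_count(embryo.N, mu, cfg.K),
        rho=decay_repressor(embryo.rho, cfg.rho_deg),
        rho0=embryo.rho0,
        mu=mu,
    )
    return new_state, new_embryo, rates
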