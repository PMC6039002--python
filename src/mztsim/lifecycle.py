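"""Generation loop, fertilization and multi-generation simulation.

A generation runs one embryo (two parallel sex lineages sharing the same
zygotic methylation state) through ``D`` cell divisions, then fertilization
averages the two parental methylation states into the next generation's
zygote and resets the cell count and repressor. Between generations the
post-ZGA methylation/demethylation rates can drift under a sex-specific
environmental model, which is how transgenerational epigenetic effects enter
the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    SEXES,
    EmbryoState,
    GrowthConfig,
    InvalidParameterError,
    InvalidStateError,
    MethylState,
    SexConfig,
    division_step,
    repressor_effect,
)

__all__ = [
    "ConfigurationError",
    "EnvModel",
    "GenerationRecord",
    "run_generation",
    "fertilize",
    "perturb_rates",
    "run_simulation",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

ENV_MODES = ("none", "random", "directional")

#: Fixed column order of per-division trajectory rows.
TRAJECTORY_COLUMNS = [
    "generation", "division", "sex", "N", "nu", "rho", "rho_c", "mu",
    "alpha", "beta", "delta", "zeta", "X", "Y", "Z",
]


class ConfigurationError(ValueError):
    """A configuration cannot produce a valid simulation."""


@dataclass
class EnvModel:
    """Environmental variation of post-ZGA rates across generations.

    ``random`` adds an independent uniform draw from the configured intervals
    to alpha and delta of each flagged sex at the end of every generation;
    ``directional`` adds a constant shift instead. With ``accumulate`` the
    perturbation walks on the current rates (drift); without it each
    generation perturbs the original base rates (i.i.d. environment).
    """

    mode: str = "none"
    sexes: tuple[str, ...] = SEXES
    alpha_interval: tuple[float, float] = (-0.01, 0.01)
    delta_interval: tuple[float, float] = (-0.01, 0.01)
    alpha_shift: float = 0.0
    delta_shift: float = 0.0
    accumulate: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ENV_MODES:
            raise ConfigurationError(f"env mode must be one of {ENV_MODES}, got {self.mode!r}")
        for s in self.sexes:
            if s not in SEXES:
                raise ConfigurationError(f"unknown sex {s!r} in env model")
        self.sexes = tuple(self.sexes)
        for name in ("alpha_interval", "delta_interval"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} = {(lo, hi)!r} is not a valid interval")
            setattr(self, name, (float(lo), float(hi)))


@dataclass
class GenerationRecord:
    """Per-division trajectory of one generation (both sexes) plus summaries."""

    generation_index: int
    table: pd.DataFrame
    final_states: dict[str, MethylState]
    final_embryos: dict[str, EmbryoState]
    cell_equilibrium_division: dict[str, int | None]
    growth: GrowthConfig
    sex_configs: dict[str, SexConfig]
    fertilization_state: MethylState | None = None

    def sex_series(self, sex: str, column: str = "X") -> pd.Series:
        """One column of one sex's trajectory, indexed by division 1..D."""
        sub = self.table[self.table["sex"] == sex]
        return pd.Series(sub[column].to_numpy(), index=sub["division"].to_numpy())


def _as_per_sex(zygote: MethylState | Mapping[str, MethylState]) -> dict[str, MethylState]:
    if isinstance(zygote, MethylState):
        return {s: zygote for s in SEXES}
    out = dict(zygote)
    if set(out) != set(SEXES):
        raise InvalidParameterError(f"per-sex zygote mapping must have keys {SEXES}")
    return out


def run_generation(
    zygote: MethylState | Mapping[str, MethylState],
    cfg: GrowthConfig,
    sexes: Mapping[str, SexConfig],
    generation_index: int = 1,
) -> GenerationRecord:
    """Run both sex lineages through ``cfg.D`` divisions from a zygotic state.

    Each trajectory row records the embryo quantities (N, nu, rho, rho_c, mu)
    and rates in force at the *start* of division ``d`` together with the
    methylation state *after* that division. Growth dynamics are tracked per
    sex even though they coincide at default (sex-independent) parameters.
    """
    zygotes = _as_per_sex(zygote)
    rows: list[tuple] = []
    final_states: dict[str, MethylState] = {}
    final_embryos: dict[str, EmbryoState] = {}
    cell_eq: dict[str, int | None] = {}
    for sex_label in SEXES:
        sex = sexes[sex_label]
        state = zygotes[sex_label]
        embryo = EmbryoState.initial(cfg)
        reached: int | None = None
        for d in range(1, cfg.D + 1):
            rho_c = repressor_effect(embryo.rho, embryo.rho0)
            N, nu, rho = embryo.N, embryo.nu, embryo.rho
            state, embryo, rates = division_step(state, embryo, cfg, sex)
            if reached is None and embryo.N >= cfg.K - 0.5:
                reached = d
            rows.append((
                generation_index, d, sex_label, N, nu, rho, rho_c, embryo.mu,
                rates.alpha, rates.beta, rates.delta, rates.zeta,
                state.X, state.Y, state.Z,
            ))
        final_states[sex_label] = state
        final_embryos[sex_label] = embryo
        cell_eq[sex_label] = reached
    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    logger.info(
        "generation %d: final X male=%.6f female=%.6f",
        generation_index, final_states["male"].X, final_states["female"].X,
    )
    return GenerationRecord(
        generation_index=generation_index,
        table=table,
        final_states=final_states,
        final_embryos=final_embryos,
        cell_equilibrium_division=cell_eq,
        growth=cfg,
        sex_configs=dict(sexes),
    )


def fertilize(
    male: MethylState,
    female: MethylState,
    *,
    divisions_completed: int | None = None,
    required_divisions: int | None = None,
) -> MethylState:
    """Average the parental methylation states into the next zygote.

    When both ``divisions_completed`` and ``required_divisions`` are given,
    fertilization is gated on the generation having run its full course
    (the Boolean threshold on ``d = D``).
    """
    if divisions_completed is not None and required_divisions is not None:
        if divisions_completed != required_divisions:
            raise InvalidStateError(
                f"fertilization requires d = D ({required_divisions}), "
                f"got d = {divisions_completed}"
            )
    return MethylState(
        X=(male.X + female.X) / 2.0,
        Y=(male.Y + female.Y) / 2.0,
        Z=(male.Z + female.Z) / 2.0,
    )


def perturb_rates(
    sex: SexConfig,
    env: EnvModel,
    rng: np.random.Generator,
    base: SexConfig | None = None,
) -> SexConfig:
    """Apply one generation's environmental perturbation to post-ZGA rates.

    Only alpha (maintenance methylation) and delta (repair demethylation) are
    perturbed; pre-ZGA rates are structurally fixed. Random draws that violate
    the rate invariants are redrawn (up to 100 times) so the accepted draw is
    uniform on the feasible set; a directional shift is clamped to [0, 1] per
    rate but rejected if the pair becomes infeasible.
    """
    if env.mode == "none" or sex.sex_label not in env.sexes:
        return sex
    src = sex if (base is None or env.accumulate) else base
    post = src.post_zga
    if env.mode == "directional":
        a = min(max(post.alpha + env.alpha_shift, 0.0), 1.0)
        d = min(max(post.delta + env.delta_shift, 0.0), 1.0)
        if a + d > 1.0:
            raise ConfigurationError(
                f"directional shift yields infeasible rates alpha={a}, delta={d}"
            )
        return replace(sex, post_zga=replace(post, alpha=a, delta=d))
    for _ in range(100):
        a = post.alpha + rng.uniform(*env.alpha_interval)
        d = post.delta + rng.uniform(*env.delta_interval)
        if 0.0 <= a <= 1.0 and 0.0 <= d <= 1.0 and a + d <= 1.0:
            return replace(sex, post_zga=replace(post, alpha=a, delta=d))
    raise ConfigurationError(
        f"could not draw feasible perturbed rates for {sex.sex_label} "
        f"from alpha={post.alpha}, delta={post.delta} after 100 attempts"
    )


def run_simulation(
    cfg: GrowthConfig,
    sexes: Mapping[str, SexConfig],
    env: EnvModel | None = None,
    n_generations: int = 1,
    initial_state: MethylState | Mapping[str, MethylState] | None = None,
    fertilize_at: str = "D",
    equilibrium_tol: float = 0.005,
) -> list[GenerationRecord]:
    """Chain generations: run, fertilize, perturb.

    Generation ``g + 1`` starts (both sexes) from the average of generation
    ``g``'s two final states; the cell count and repressor reset at each
    fertilization. With ``fertilize_at="equilibrium"`` the state passed on is
    taken at the earliest division where both sexes have settled (sustained,
    within ``equilibrium_tol``) at their analytic equilibrium levels instead
    of at division ``D``; the full D-division trajectory is still recorded.
    """
    if n_generations < 1:
        raise InvalidParameterError("n_generations must be >= 1")
    if fertilize_at not in ("D", "equilibrium"):
        raise InvalidParameterError("fertilize_at must be 'D' or 'equilibrium'")
    env = env if env is not None else EnvModel()
    rng = np.random.default_rng(env.seed)
    current: dict[str, SexConfig] = {s: sexes[s] for s in SEXES}
    base = dict(current)
    zygote = initial_state if initial_state is not None else MethylState(1.0, 0.0, 0.0)
    records: list[GenerationRecord] = []
    for g in range(1, n_generations + 1):
        rec = run_generation(zygote, cfg, current, generation_index=g)
        parents = _fertilization_inputs(rec, fertilize_at, equilibrium_tol)
        rec.fertilization_state = fertilize(
            parents["male"], parents["female"],
            divisions_completed=cfg.D if fertilize_at == "D" else None,
            required_divisions=cfg.D if fertilize_at == "D" else None,
        )
        records.append(rec)
        zygote = rec.fertilization_state
        if env.mode != "none" and g < n_generations:
            current = {
                s: perturb_rates(current[s], env, rng, base=base[s]) for s in SEXES
            }
    return records


def _fertilization_inputs(
    rec: GenerationRecord, fertilize_at: str, tol: float
) -> dict[str, MethylState]:
    if fertilize_at == "D":
        return rec.final_states
    # gamete states taken at the first division where both sexes have settled
    from .analysis import divisions_to_equilibrium, fixed_point

    divisions: list[int] = []
    for s in SEXES:
        post = rec.sex_configs[s].post_zga
        fp = fixed_point(post.alpha, post.beta, post.delta, post.zeta)
        d = divisions_to_equilibrium(rec, sex=s, target=fp.X_star, tol=tol)
        if d is None:
            raise InvalidStateError(
                f"{s} lineage never reached its equilibrium within {tol}"
            )
        divisions.append(d)
    d_fert = max(divisions)
    out: dict[str, MethylState] = {}
    for s in SEXES:
        row = rec.table[(rec.table["sex"] == s) & (rec.table["division"] == d_fert)]
        out[s] = MethylState(
            float(row["X"].iloc[0]), float(row["Y"].iloc[0]), float(row["Z"].iloc[0])
        )
    return out
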