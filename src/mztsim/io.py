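"""Tabular run output: long-format trajectory, per-generation summary, metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .analysis import (
    cell_count_equilibrium_division,
    divisions_to_equilibrium,
    fixed_point,
    zga_onset,
)
from .config import Scenario, scenario_to_dict
from .core import SEXES
from .lifecycle import TRAJECTORY_COLUMNS, GenerationRecord

__all__ = [
    "RunOutput",
    "build_run_output",
    "write_trajectory",
    "write_summary",
    "write_metadata",
    "write_run",
    "read_trajectory",
]

SUMMARY_COLUMNS = [
    "generation", "sex", "final_X", "final_Y", "final_Z",
    "zga_onset", "divisions_to_equilibrium", "cell_equilibrium_division",
]


@dataclass
class RunOutput:
    trajectory: pd.DataFrame
    summary: pd.DataFrame
    metadata: dict


def build_run_output(
    records: Sequence[GenerationRecord],
    scenario: Scenario,
    seed: int | None = None,
) -> RunOutput:
    """Assemble trajectory/summary tables and reproducibility metadata.

    The summary's divisions-to-equilibrium is detected against each sex's
    analytic equilibrium rounded to two decimals (the levels' reporting
    accuracy of 0.01), with half-width 0.005.
    """
    trajectory = pd.concat([r.table for r in records], ignore_index=True)
    rows = []
    for rec in records:
        for sex in SEXES:
            post = rec.sex_configs[sex].post_zga
            target = round(fixed_point(post.alpha, post.beta, post.delta, post.zeta).X_star, 2)
            final = rec.final_states[sex]
            rows.append({
                "generation": rec.generation_index,
                "sex": sex,
                "final_X": final.X,
                "final_Y": final.Y,
                "final_Z": final.Z,
                "zga_onset": zga_onset(rec, sex) if rec.growth.rho0 > 0 else None,
                "divisions_to_equilibrium": divisions_to_equilibrium(
                    rec, sex=sex, target=target, tol=0.005
                ),
                "cell_equilibrium_division": cell_count_equilibrium_division(rec, sex),
            })
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    metadata = {
        "package": "mztsim",
        "version": __version__,
        "seed": seed,
        "scenario": scenario_to_dict(scenario),
        "trajectory_columns": TRAJECTORY_COLUMNS,
        "n_generations": len(records),
    }
    return RunOutput(trajectory=trajectory, summary=summary, metadata=metadata)


def write_trajectory(output: RunOutput, path: str | Path) -> None:
    """Write the long-format trajectory as TSV (floats at 10 significant digits)."""
    output.trajectory.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_summary(output: RunOutput, path: str | Path) -> None:
    output.summary.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_metadata(output: RunOutput, path: str | Path) -> None:
    Path(path).write_text(json.dumps(output.metadata, indent=2, sort_keys=True) + "\n")


def write_run(output: RunOutput, outdir: str | Path) -> dict[str, Path]:
    """Write trajectory.tsv, summary.tsv and metadata.json into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / "trajectory.tsv",
        "summary": outdir / "summary.tsv",
        "metadata": outdir / "metadata.json",
    }
    write_trajectory(output, paths["trajectory"])
    write_summary(output, paths["summary"])
    write_metadata(output, paths["metadata"])
    return paths


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
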