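"""End-to-end model reproduction: one call turns a kinetic parameter table
and a run manifest into the full dominance picture — rate curves across the
concentration range, the predicted dominant type per run, the crossover
concentration(s), and cycle-by-cycle competition trajectories at each run's
aerobic phosphate level.  Deterministic: identical inputs give identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .competition import CompetitionTrajectory, ReactorConfig, simulate_competition
from .io import RunManifest
from .kinetics import (
    DegenerateCurvesError,
    KineticParams,
    RateCurve,
    crossover_concentrations,
    dominant_label,
    rate_curve,
)

__all__ = ["ModelReport", "reproduce_model_figures"]


@dataclass(frozen=True)
class ModelReport:
    """Everything the dominance model predicts for one parameter table."""

    curve: RateCurve
    dominance: Mapping[str, str]  # run_id -> predicted dominant label (or "tie")
    crossovers: tuple[float, ...]  # rate-equality concentrations, mg P L^-1
    trajectories: Mapping[str, CompetitionTrajectory]

    def dominance_frame(self, manifest: RunManifest):
        import pandas as pd

        return pd.DataFrame(
            {
                "run_id": list(manifest.run_ids),
                "aerobic_p": list(manifest.aerobic_p),
                "dominant": [self.dominance[r] for r in manifest.run_ids],
            }
        )


def reproduce_model_figures(
    params_set: Sequence[KineticParams],
    manifest: RunManifest | None = None,
    grid=None,
    tie_tol: float = 1e-3,
    n_cycles: int = 200,
    washout_fraction: float = 0.1,
) -> ModelReport:
    """Compute rate curves, per-run dominance, crossovers and trajectories.

    ``grid`` defaults to 200 log-spaced points on 0.01-1000 mg P L^-1.
    With a single population the dominance and crossover outputs are empty
    (there is nothing to compare).
    """
    if manifest is None:
        manifest = RunManifest()
    if grid is None:
        grid = np.geomspace(0.01, 1000.0, 200)
    curve = rate_curve(params_set, grid)

    dominance: dict[str, str] = {}
    trajectories: dict[str, CompetitionTrajectory] = {}
    crossovers: tuple[float, ...] = ()
    if len(params_set) >= 2:
        for run_id, s in zip(manifest.run_ids, manifest.aerobic_p):
            dominance[run_id] = dominant_label(params_set, s, tie_tol)
            config = ReactorConfig(aerobic_s=s, washout_fraction=washout_fraction)
            init = np.full(len(params_set), 1.0 / len(params_set))
            trajectories[run_id] = simulate_competition(
                params_set, config, init, n_cycles
            )
        roots: list[float] = []
        for i in range(len(params_set)):
            for j in range(i + 1, len(params_set)):
                try:
                    roots.extend(
                        crossover_concentrations(params_set[i], params_set[j])
                    )
                except DegenerateCurvesError:
                    continue
        crossovers = tuple(sorted(roots))
    return ModelReport(
        curve=curve,
        dominance=dominance,
        crossovers=crossovers,
        trajectories=trajectories,
    )
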