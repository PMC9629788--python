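"""High-level orchestration: trajectories -> coupled parameters -> datasets."""

from __future__ import annotations

from typing import Sequence

from .coupling import RTMParams, couple
from .geometry import observation_geometry
from .trajectory import CropState, TrajectoryConfig, simulate_campaign

__all__ = ["coupled_campaign", "couple_states"]

#: phenotyping times of day considered (apparent solar time, decimal hours)
DEFAULT_AST_LEVELS = (10.0, 12.0, 14.0)


def couple_states(
    states: Sequence[CropState],
    latitude: float,
    sowing_doy: int,
    ast_levels: Sequence[float] = DEFAULT_AST_LEVELS,
    trajectory_id: int = 0,
) -> tuple[list[RTMParams], list[dict]]:
    """Couple every canopy state at each observation time.

    The day of year of each record is the sowing day plus its days after
    sowing (wrapped on a 365-day calendar); one coupled record is produced
    per (state, apparent-solar-time) combination.
    """
    params: list[RTMParams] = []
    meta: list[dict] = []
    for s in states:
        if s.LAI_total <= 0:
            continue
        doy = (sowing_doy + s.das - 1) % 365 + 1
        for ast in ast_levels:
            geom = observation_geometry(latitude, doy, ast)
            params.append(couple(s, geom))
            meta.append(dict(trajectory=trajectory_id, das=s.das, doy=doy, ast=ast))
    return params, meta


def coupled_campaign(
    config: TrajectoryConfig,
    n_trajectories: int,
    ast_levels: Sequence[float] = DEFAULT_AST_LEVELS,
) -> tuple[list[RTMParams], list[dict]]:
    """Simulate a campaign of trajectories and couple every record."""
    params: list[RTMParams] = []
    meta: list[dict] = []
    for tid, traj in enumerate(simulate_campaign(config, n_trajectories)):
        p, m = couple_states(
            traj, config.latitude, config.sowing_doy, ast_levels, trajectory_id=tid
        )
        params.extend(p)
        meta.extend(m)
    return params, meta
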