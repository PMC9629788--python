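"""Synthetic wheat growth trajectories and crop-model report ingestion.

A trajectory is a fortnightly-sampled series of :class:`CropState` records
emulating the seasonal pattern of a wheat crop as a process-based crop model
would simulate it: green leaf area rises logistically to a flag-leaf maximum,
total LAI then declines while the dead-leaf fraction rises; leaf dry weight
and canopy nitrogen co-vary with LAI through a specific leaf area and a leaf
nitrogen concentration drawn once per trajectory. No weather, water or
nitrogen process is modelled — only the co-variation structure among the
state variables that downstream coupling relies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError

__all__ = [
    "CropState",
    "TrajectoryConfig",
    "simulate_trajectory",
    "simulate_campaign",
    "read_crop_report",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "CSV_COLUMNS",
]

#: canonical column names of the trajectory CSV schema
CSV_COLUMNS = ("das", "zadok", "lai_total", "lai_dead", "ldw_g_m2", "cnc_g_m2")


@dataclass(frozen=True)
class CropState:
    """One day of crop-model output.

    Attributes
    ----------
    das : int
        Days after sowing (>= 0).
    Zs : float
        Decimal Zadok growth-stage score (0-100), non-decreasing in time.
    LAI_total : float
        Total (green + dead) leaf area index, m2 m-2.
    LAI_dead : float
        Senesced leaf area index, m2 m-2; 0 <= LAI_dead <= LAI_total.
    LDW : float
        Leaf dry weight per unit ground area, g m-2.
    CNC : float
        Canopy nitrogen content per unit ground area, g m-2.
    """

    das: int
    Zs: float
    LAI_total: float
    LAI_dead: float
    LDW: float
    CNC: float

    def validate(self) -> None:
        if self.das < 0:
            raise ValueError(f"das must be >= 0, got {self.das}")
        if not 0.0 <= self.Zs <= 100.0:
            raise ValueError(f"Zs must be in [0, 100], got {self.Zs}")
        if self.LAI_total < 0 or self.LDW < 0 or self.CNC < 0:
            raise ValueError("LAI_total, LDW and CNC must be non-negative")
        if not 0.0 <= self.LAI_dead <= self.LAI_total:
            raise ValueError(
                f"LAI_dead={self.LAI_dead} outside [0, LAI_total={self.LAI_total}]"
            )
        if self.LAI_total > 0 and self.LDW <= 0:
            raise ValueError("LDW must be > 0 whenever LAI_total > 0")

    @property
    def f_dead(self) -> float:
        """Dead-leaf fraction LAI_dead / LAI_total (0 for a bare state)."""
        return self.LAI_dead / self.LAI_total if self.LAI_total > 0 else 0.0


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of the synthetic trajectory generator.

    Defaults describe a spring wheat season at a subtropical southern-
    hemisphere site (sowing on 1 May, ~160-day season, flag-leaf LAI ~6),
    sampled fortnightly.
    """

    latitude: float = -27.54
    sowing_doy: int = 121
    season_length: int = 160
    peak_lai: float = 6.0
    peak_das: int = 100
    senescence_onset_das: int = 110
    sla_range: tuple[float, float] = (0.15, 0.30)  # cm2 mg-1
    lnc_range: tuple[float, float] = (1.0, 2.5)  # g m-2 leaf area
    max_dead_fraction: float = 0.85
    sampling_interval: int = 14
    seed: int = 0

    def validate(self) -> None:
        if self.season_length < 0:
            raise ConfigurationError(f"season_length must be >= 0, got {self.season_length}")
        if self.season_length > 0 and not self.peak_das < self.season_length:
            raise ConfigurationError(
                f"peak_das={self.peak_das} must be < season_length={self.season_length}"
            )
        if self.senescence_onset_das > self.season_length:
            raise ConfigurationError(
                f"senescence_onset_das={self.senescence_onset_das} exceeds "
                f"season_length={self.season_length}"
            )
        if self.sampling_interval < 1:
            raise ConfigurationError(
                f"sampling_interval must be >= 1, got {self.sampling_interval}"
            )
        for name in ("sla_range", "lnc_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lower <= upper, got ({lo}, {hi})")
        if not 0.0 < self.max_dead_fraction < 1.0:
            raise ConfigurationError(
                f"max_dead_fraction must be in (0, 1), got {self.max_dead_fraction}"
            )
        if not 1 <= self.sowing_doy <= 365:
            raise ConfigurationError(f"sowing_doy must be in 1..365, got {self.sowing_doy}")
        if abs(self.latitude) > 90:
            raise ConfigurationError(f"latitude must be in [-90, 90], got {self.latitude}")


def _green_lai(t: np.ndarray, peak_lai: float, peak_das: float, season_length: float) -> np.ndarray:
    """Logistic rise to the flag-leaf peak, exponential decline after."""
    k = 8.0 / peak_das
    rise = peak_lai / (1.0 + np.exp(-k * (t - 0.55 * peak_das)))
    at_peak = peak_lai / (1.0 + math.exp(-k * 0.45 * peak_das))
    post = season_length - peak_das
    decay = math.log(1.0 / 0.15) / max(post, 1.0)
    fall = at_peak * np.exp(-decay * (t - peak_das))
    return np.where(t <= peak_das, rise, fall)


def _dead_fraction(t: np.ndarray, onset: float, season_length: float, f_max: float) -> np.ndarray:
    """0 before senescence onset, saturating monotone rise toward f_max after."""
    tau = max((season_length - onset) / 2.0, 1.0)
    f = f_max * np.tanh(np.clip(t - onset, 0.0, None) / tau)
    return np.where(t < onset, 0.0, f)


def _zadok(t: np.ndarray, peak_das: float, season_length: float) -> np.ndarray:
    """Piecewise-linear decimal Zadok schedule.

    Emergence (~10) at 7 d, stem elongation (30) at 0.4*peak, flag leaf (39)
    at the LAI peak, ripening (90) at season end. Only a monotone proxy is
    needed: the water-content transform is the sole consumer.
    """
    xp = [0.0, 7.0, 0.4 * peak_das, float(peak_das), float(season_length)]
    fp = [0.0, 10.0, 30.0, 39.0, 90.0]
    # guard against degenerate breakpoints for very short seasons
    xp = np.maximum.accumulate(np.asarray(xp))
    return np.interp(t, xp, fp)


def simulate_trajectory(config: TrajectoryConfig) -> list[CropState]:
    """Generate one synthetic trajectory sampled at ``config.sampling_interval``.

    Records start at emergence (first sampled day with green leaf area) and
    run to the end of the season. Identical configs (including seed) produce
    bitwise-identical output.
    """
    config.validate()
    if config.season_length == 0:
        return []
    rng = np.random.default_rng(config.seed)
    sla0 = rng.uniform(*config.sla_range)
    lnc0 = rng.uniform(*config.lnc_range)

    days = np.arange(0, config.season_length + 1, config.sampling_interval)
    lai = _green_lai(days.astype(float), config.peak_lai, config.peak_das, config.season_length)
    f_dead = _dead_fraction(
        days.astype(float), config.senescence_onset_das, config.season_length,
        config.max_dead_fraction,
    )
    zs = np.maximum.accumulate(_zadok(days.astype(float), config.peak_das, config.season_length))

    # small day-to-day wobble on SLA and LNC, clipped back into their ranges
    sla = np.clip(sla0 * (1.0 + 0.02 * rng.standard_normal(days.size)), *config.sla_range)
    lnc = np.clip(lnc0 * (1.0 + 0.02 * rng.standard_normal(days.size)), *config.lnc_range)

    emerged = lai > 0.05  # pre-emergence days carry no canopy
    states: list[CropState] = []
    for i, das in enumerate(days):
        if not emerged[i]:
            continue
        lai_t = float(lai[i])
        states.append(
            CropState(
                das=int(das),
                Zs=float(zs[i]),
                LAI_total=lai_t,
                LAI_dead=float(f_dead[i] * lai_t),
                LDW=lai_t * 10.0 / float(sla[i]),
                CNC=float(lnc[i]) * lai_t,
            )
        )
    for s in states:
        s.validate()
    return states


def simulate_campaign(
    base: TrajectoryConfig, n_trajectories: int
) -> list[list[CropState]]:
    """Generate ``n_trajectories`` trajectories with jittered seasonal shapes.

    Peak LAI, peak timing and senescence onset are varied around the base
    config (as site/season/cultivar variation would), each trajectory with
    its own derived seed. Deterministic in ``base.seed``.
    """
    base.validate()
    rng = np.random.default_rng(base.seed)
    out: list[list[CropState]] = []
    for i in range(n_trajectories):
        peak_lai = base.peak_lai * rng.uniform(0.45, 1.1)
        peak_das = int(base.peak_das * rng.uniform(0.85, 1.1))
        season = max(base.season_length, peak_das + 20)
        onset = int(peak_das + rng.uniform(0.05, 0.25) * (season - peak_das))
        cfg = replace(
            base,
            peak_lai=peak_lai,
            peak_das=peak_das,
            season_length=season,
            senescence_onset_das=min(onset, season),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(simulate_trajectory(cfg))
    return out


def read_crop_report(
    path, column_map: Mapping[str, str] | None = None
) -> list[CropState]:
    """Read crop-model report output (delimited columnar text) as CropStates.

    Parameters
    ----------
    path : str or file-like
        Whitespace-, comma- or tab-delimited text with a header row.
    column_map : mapping, optional
        File header name -> canonical name (``das, zadok, lai_total,
        lai_dead, ldw_g_m2, cnc_g_m2``). Canonical headers need no mapping.

    Rows violating the CropState invariants are dropped with a warning that
    reports the 0-based row index; unparsable numerics raise
    :class:`ParseError` naming row and column.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed file structure
        raise ParseError(f"could not read report file {path!r}: {exc}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"report file missing mapped column(s): {missing}")

    states: list[CropState] = []
    for idx, row in df.iterrows():
        vals = {}
        for col in CSV_COLUMNS:
            raw = row[col]
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {idx}, column {col!r}: cannot parse {raw!r} as a number"
                ) from exc
        state = CropState(
            das=int(vals["das"]),
            Zs=vals["zadok"],
            LAI_total=vals["lai_total"],
            LAI_dead=vals["lai_dead"],
            LDW=vals["ldw_g_m2"],
            CNC=vals["cnc_g_m2"],
        )
        try:
            state.validate()
        except ValueError as exc:
            warnings.warn(f"row {idx} rejected: {exc}", stacklevel=2)
            continue
        states.append(state)
    return states


def _frame(trajectories: Sequence[Sequence[CropState]]) -> pd.DataFrame:
    rows = []
    for tid, traj in enumerate(trajectories):
        for s in traj:
            rows.append(
                dict(trajectory=tid, das=s.das, zadok=s.Zs, lai_total=s.LAI_total,
                     lai_dead=s.LAI_dead, ldw_g_m2=s.LDW, cnc_g_m2=s.CNC)
            )
    return pd.DataFrame(rows, columns=["trajectory", *CSV_COLUMNS])


def write_trajectory_csv(trajectories: Sequence[Sequence[CropState]], path) -> None:
    """Write trajectories to CSV (UTF-8, '.' decimal, one header row)."""
    _frame(trajectories).to_csv(path, index=False)


def read_trajectory_csv(path) -> list[list[CropState]]:
    """Read a CSV written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory CSV missing column(s): {missing}")
    if "trajectory" not in df.columns:
        df["trajectory"] = 0
    out: list[list[CropState]] = []
    for _, grp in df.groupby("trajectory", sort=True):
        traj = [
            CropState(das=int(r.das), Zs=float(r.zadok), LAI_total=float(r.lai_total),
                      LAI_dead=float(r.lai_dead), LDW=float(r.ldw_g_m2), CNC=float(r.cnc_g_m2))
            for r in grp.itertuples()
        ]
        out.append(traj)
    return out
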