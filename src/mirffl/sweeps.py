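"""Parameter sweeps and the noise-buffering summary tables.

The comparative analyses vary one coefficient at a time around the default
set: the TF half-saturation of the miRNA gene (hs), the TF translation
rate (kq), the maximal miRNA transcription rate (ks), and the
mechanism-specific miRNA-strength coefficient (hp for the Stop model, hg
for Target degradation, krs for Dual degradation).  For each loop a table
is assembled with one (mean epsilon, n-positive) cell per mechanism x
coefficient value, each cell re-deriving its own steady state and
half-steady initial condition under the swept value.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integrate import SimulationSettings, Trajectory, simulate
from .models import ConfigurationError, Mechanism, ParameterSet, Topology
from .noise import EpsilonSummary, run_noise_experiment
from .steady import steady_state

__all__ = [
    "SweepGrid",
    "TableCell",
    "DEFAULT_GRIDS",
    "STRENGTH_PARAM",
    "cell_seed",
    "sweep_deterministic",
    "build_noise_table",
    "table_to_frame",
    "steady_state_report",
]

#: the default one-at-a-time sweep grids
DEFAULT_GRIDS: dict[str, tuple[float, ...]] = {
    "hs": (1.0, 100.0, 200.0, 400.0),
    "kq": (0.02, 0.04, 0.08, 0.16),
    "ks": (0.01, 0.25, 0.50, 0.75),
    "hp": (30.0, 60.0, 120.0, 240.0),
    "hg": (30.0, 60.0, 120.0, 240.0),
    "krs": (1e-5, 2e-5, 4e-5, 8e-5),
}

_SWEEPABLE = ("hs", "kq", "ks", "kr", "hp", "hg", "krs")

#: the miRNA-action-strength coefficient of each mechanism
STRENGTH_PARAM = {
    Mechanism.STOP: "hp",
    Mechanism.TARGET_DEG: "hg",
    Mechanism.DUAL_DEG: "krs",
}


@dataclass(frozen=True)
class SweepGrid:
    """One-coefficient sweep: the varied name, its values, the fixed rest."""

    param: str
    values: tuple[float, ...]
    fixed: ParameterSet = field(default_factory=ParameterSet)

    def __post_init__(self) -> None:
        if self.param not in _SWEEPABLE:
            raise ConfigurationError(
                f"sweep parameter must be one of {_SWEEPABLE}, got {self.param!r}"
            )
        if len(self.values) == 0:
            raise ConfigurationError("sweep values must be nonempty")
        if any(v < 0 for v in self.values):
            raise ConfigurationError("sweep values must be >= 0")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def parameter_sets(self) -> list[ParameterSet]:
        return [self.fixed.replace(**{self.param: v}) for v in self.values]


@dataclass(frozen=True)
class TableCell:
    """One noise-table entry: loop x mechanism x coefficient value."""

    loop: str
    mechanism: str
    param: str
    value: float
    eps_mean: float
    n_positive: int
    seed: int


def cell_seed(master_seed: int, loop: Topology, mechanism: Mechanism,
              param: str, value: float) -> int:
    """Stable, order-independent per-cell seed below 2**31."""
    key = f"{master_seed}|{loop.label}|{mechanism.name}|{param}|{value!r}"
    return zlib.crc32(key.encode()) % (2**31)


def sweep_deterministic(
    mechanism: Mechanism,
    topology: Topology,
    grid: SweepGrid,
    settings: SimulationSettings | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """One deterministic run per grid value, from its own half-steady init.

    Returns the trajectories and a table with the swept value, the
    steady-state counts (s*, r*, p*) and the protein count at t_end.
    """
    settings = settings or SimulationSettings()
    trajectories: list[Trajectory] = []
    rows = []
    for value, params in zip(grid.values, grid.parameter_sets()):
        star = steady_state(mechanism, topology, params).state
        traj = simulate(mechanism, topology, params, settings)
        trajectories.append(traj)
        rows.append(
            {
                "param": grid.param,
                "value": value,
                "s_star": star.s,
                "r_star": star.r,
                "p_star": star.p,
                "p_end": traj.final_state.p,
            }
        )
    return trajectories, pd.DataFrame(rows)


def build_noise_table(
    loop: Topology,
    master_seed: int = 0,
    grids: dict[str, Sequence[float]] | None = None,
    params: ParameterSet | None = None,
    n_rep: int = 100,
    amplitude: float = 0.10,
    settings: SimulationSettings | None = None,
    mechanisms: Sequence[Mechanism] = tuple(Mechanism),
) -> list[TableCell]:
    """The noise-buffering table of one loop.

    Rows are the four coefficient families (hs, kq, ks, and the
    mechanism-specific strength coefficient); columns are the three
    mechanisms; every cell reports the 100-replicate mean epsilon and the
    count of non-buffered replicates.  Cell seeds are derived from
    ``master_seed`` independently of evaluation order.
    """
    params = params or ParameterSet()
    base_grids = dict(DEFAULT_GRIDS)
    if grids:
        base_grids.update({k: tuple(v) for k, v in grids.items()})
    families: list[str] = ["hs", "kq", "ks", "strength"]
    cells: list[TableCell] = []
    for family in families:
        for mech in mechanisms:
            pname = STRENGTH_PARAM[mech] if family == "strength" else family
            for value in base_grids[pname]:
                seed = cell_seed(master_seed, loop, mech, pname, float(value))
                summary = run_noise_experiment(
                    mech,
                    loop,
                    params.replace(**{pname: value}),
                    n_rep=n_rep,
                    amplitude=amplitude,
                    master_seed=seed,
                    settings=settings,
                )
                cells.append(
                    TableCell(
                        loop=loop.label,
                        mechanism=mech.name,
                        param=pname,
                        value=float(value),
                        eps_mean=round(summary.mean, 2),
                        n_positive=summary.n_positive,
                        seed=seed,
                    )
                )
    return cells


def table_to_frame(cells: Sequence[TableCell]) -> pd.DataFrame:
    """Tidy DataFrame form of a noise table (one cell per row)."""
    return pd.DataFrame(
        {
            "loop": [c.loop for c in cells],
            "model": [c.mechanism for c in cells],
            "param": [c.param for c in cells],
            "value": [c.value for c in cells],
            "eps_mean": [c.eps_mean for c in cells],
            "n_positive": [c.n_positive for c in cells],
            "seed": [c.seed for c in cells],
        }
    )


def steady_state_report(params: ParameterSet | None = None) -> pd.DataFrame:
    """Algebraic steady states of all 12 mechanism x topology variants."""
    params = params or ParameterSet()
    rows = []
    for mech in Mechanism:
        for topo in Topology:
            res = steady_state(mech, topo, params)
            st = res.state
            rows.append(
                {
                    "model": mech.name,
                    "loop": topo.label,
                    "w_star": st.w,
                    "q_star": st.q,
                    "s_star": st.s,
                    "r_star": st.r,
                    "p_star": st.p,
                    "residual": res.residual,
                }
            )
    return pd.DataFrame(rows)
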