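"""Empirical calibration sweep of energy-term weights and the screening factor.

Protocol: for one energy-term weight family at a time, the weight is varied
from 1 to 10 in steps of 1 while all other weights stay at 1; for each
weight value, κ runs over the 11-point grid 0.0 … 1.0.  Every (weight, κ,
dp) cell is simulated from the extended conformation, and the trajectory
mean end-to-end distance and radius of gyration are scored as percentage
errors against a packaged experimental reference table.  The production
protocol used one trajectory per cell; a ``reps`` argument averages several
seeds instead.

The packaged reference table ships only the experimental dp12 EED (60 Å);
the remaining dp slots are present but empty and can be filled from a user
CSV (``ReferenceTable.from_csv``) — no invented reference numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import compute_observables, percentage_error
from .dynamics import RunConfig, Trajectory, run_simulation
from .electrolyte import kappa_grid
from .errors import ParameterError
from .params import CGParameters, Weights
from .topology import build_chain

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceEntry",
    "ReferenceTable",
    "CalibrationCell",
    "default_reference_table",
    "sweep",
    "rank_combinations",
    "preset_combinations",
    "PresetCombination",
]

#: Chain lengths with published experimental EED/Rg series.
REFERENCE_DPS = (6, 12, 18, 24, 30, 32, 36, 48, 68)

#: Weight families varied in the sweep, by Weights field.
WEIGHT_FAMILIES = (
    "w_bond", "w_ang", "w_tor", "w_GBerne", "w_polGB",
    "w_pol", "w_caviso", "w_cavtail", "w_vdw", "w_eel",
)


@dataclass
class ReferenceEntry:
    eed: float | None = None     # Å
    rg: float | None = None      # Å
    source: str = ""


@dataclass
class ReferenceTable:
    """Experimental EED/Rg per degree of polymerization."""

    entries: dict = field(default_factory=dict)  # dp -> ReferenceEntry

    def __post_init__(self):
        for dp, e in self.entries.items():
            for v in (e.eed, e.rg):
                if v is not None and v <= 0:
                    raise ParameterError(f"reference values must be > 0 (dp={dp})")

    def get(self, dp: int) -> ReferenceEntry | None:
        return self.entries.get(dp)

    def covers(self, dp: int) -> bool:
        e = self.entries.get(dp)
        return e is not None and (e.eed is not None or e.rg is not None)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        """Load a user table with columns dp, eed, rg[, source]."""
        df = pd.read_csv(path)
        entries = {}
        for _, row in df.iterrows():
            entries[int(row["dp"])] = ReferenceEntry(
                eed=None if pd.isna(row.get("eed")) else float(row["eed"]),
                rg=None if pd.isna(row.get("rg")) else float(row["rg"]),
                source=str(row.get("source", "")),
            )
        return cls(entries=entries)


def default_reference_table() -> ReferenceTable:
    """Packaged reference values.

    Only the dp12 experimental EED of 60 Å is shipped; all other slots are
    user-fillable placeholders.
    """
    entries = {dp: ReferenceEntry() for dp in REFERENCE_DPS}
    entries[12] = ReferenceEntry(
        eed=60.0, rg=None, source="sedimentation/SAXS heparin oligomer series"
    )
    return ReferenceTable(entries=entries)


@dataclass
class CalibrationCell:
    """One grid point of the sweep."""

    weight_name: str
    weight_value: float
    kappa: float
    dp: int
    mean_eed: float
    mean_rg: float
    pe_eed: float | None    # unsigned %, None without a reference value
    pe_rg: float | None
    seed: int

    def __post_init__(self):
        for pe in (self.pe_eed, self.pe_rg):
            if pe is not None and pe < 0:
                raise ParameterError("percentage errors must be >= 0")


def _normalize_family(name: str) -> str:
    cand = name if name.startswith("w_") else "w_" + name
    aliases = {"w_angle": "w_ang", "w_torsion": "w_tor", "w_gberne": "w_GBerne", "w_eel": "w_eel"}
    cand = aliases.get(cand, cand)
    if cand not in WEIGHT_FAMILIES:
        raise ParameterError(f"unknown weight family {name!r}")
    return cand


def sweep(
    dp_list,
    base_config: RunConfig,
    params: CGParameters | None = None,
    weight_families=("w_eel",),
    weight_values=tuple(range(1, 11)),
    kappas=None,
    reference: ReferenceTable | None = None,
    reps: int = 1,
    equilibration: float = 0.1,
) -> list:
    """Run the weight × κ × dp calibration grid.

    One cell per (family, weight value, κ, dp): all other weights stay at 1.
    dp values missing from the reference table are skipped with a warning.
    ``reps`` repeats each cell with seeds ``base_config.seed + r`` and
    averages the observables.
    """
    params = params or CGParameters()
    reference = reference or default_reference_table()
    kappas = kappa_grid() if kappas is None else list(kappas)
    cells = []
    for dp in dp_list:
        if not reference.covers(dp):
            logger.warning("no reference values for dp=%d: skipping", dp)
            continue
        ref = reference.get(dp)
        chain = build_chain(dp, params)
        for family in (_normalize_family(f) for f in weight_families):
            for wval in weight_values:
                weights = Weights(**{family: float(wval)})
                for kap in kappas:
                    eeds, rgs = [], []
                    for r in range(reps):
                        cfg = replace(
                            base_config,
                            weights=weights,
                            kappa=float(kap),
                            seed=base_config.seed + r,
                        )
                        obs = compute_observables(
                            run_simulation(chain, params, cfg), equilibration
                        )
                        eeds.append(obs.eed_mean)
                        rgs.append(obs.rg_mean)
                    mean_eed = float(np.mean(eeds))
                    mean_rg = float(np.mean(rgs))
                    cells.append(
                        CalibrationCell(
                            weight_name=family,
                            weight_value=float(wval),
                            kappa=float(kap),
                            dp=int(dp),
                            mean_eed=mean_eed,
                            mean_rg=mean_rg,
                            pe_eed=(
                                percentage_error(mean_eed, ref.eed).percent
                                if ref.eed is not None else None
                            ),
                            pe_rg=(
                                percentage_error(mean_rg, ref.rg).percent
                                if ref.rg is not None else None
                            ),
                            seed=base_config.seed,
                        )
                    )
    return cells


def rank_combinations(cells, metric: str = "eed", top_n: int = 10) -> list:
    """Best (weight, κ) combinations, ascending by percentage error.

    Deterministic tie-break: lower κ first, then lower weight value, then
    weight name.  Cells without the requested reference value are dropped.
    """
    if metric not in ("eed", "rg"):
        raise ParameterError(f"metric must be 'eed' or 'rg', got {metric!r}")
    key = "pe_eed" if metric == "eed" else "pe_rg"
    scored = [c for c in cells if getattr(c, key) is not None]
    scored.sort(
        key=lambda c: (getattr(c, key), c.kappa, c.weight_value, c.weight_name)
    )
    return scored[:top_n]


def cells_to_frame(cells) -> pd.DataFrame:
    """Long-format table of sweep cells (heatmap-ready: weight × κ axes)."""
    return pd.DataFrame(
        [
            {
                "weight_name": c.weight_name,
                "weight_value": c.weight_value,
                "kappa": c.kappa,
                "dp": c.dp,
                "mean_eed": c.mean_eed,
                "mean_rg": c.mean_rg,
                "pe_eed": c.pe_eed,
                "pe_rg": c.pe_rg,
                "seed": c.seed,
            }
            for c in cells
        ]
    )


@dataclass
class PresetCombination:
    """A named production (κ, weights) combination."""

    name: str
    kappa: float
    weights: Weights


def preset_combinations() -> list:
    """The three production parameter combinations.

    (κ=0.2, w_eel=7) fitted on short chains, (κ=0.7, w_eel=7) on
    medium/universal, and (κ=0.7, w_bond=4) on long chains; all other
    weights 1.
    """
    return [
        PresetCombination("kappa2_weel7", 0.2, Weights(w_eel=7.0)),
        PresetCombination("kappa7_weel7", 0.7, Weights(w_eel=7.0)),
        PresetCombination("kappa7_wbond4", 0.7, Weights(w_bond=4.0)),
    ]
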