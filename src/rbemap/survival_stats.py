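"""Plating efficiency, surviving fractions and the limit of detection.

The surviving fraction of a well is its colony count normalised by the
expected number of colonies in an unirradiated well, ``cells_seeded * PE``,
where the plating efficiency PE is pooled over all control wells of the
experiment.  The smallest surviving fraction the assay can resolve is one
colony per well, ``1 / (cells_seeded * PE)``; condition/dose combinations
whose mean SF falls below that limit are flagged and excluded from
downstream fitting, mirroring how published tables mark such entries.
Individual wells are never dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .plate_io import BeamColumnCondition, PlateExperiment


class SurvivalError(ValueError):
    """Raised when survival quantities cannot be computed."""


@dataclass(frozen=True)
class PlatingEfficiency:
    """Pooled plating efficiency from the sham-irradiated control plates."""

    pe: float
    n_control_wells: int
    cells_seeded: int

    def __post_init__(self) -> None:
        if not 0 < self.pe <= 1:
            raise SurvivalError(f"plating efficiency {self.pe} outside (0, 1]")

    @property
    def expected_colonies_per_well(self) -> float:
        return self.pe * self.cells_seeded


@dataclass(frozen=True)
class SurvivalPoint:
    """Mean surviving fraction of the replicate wells at one condition/dose."""

    condition: Optional[BeamColumnCondition]
    column_index: int
    dose: float
    sf_mean: float
    sf_sem: float
    n_replicates: int
    below_lod: bool


def pool_plating_efficiency(experiment: PlateExperiment) -> PlatingEfficiency:
    """Pool all control-plate wells into one plating efficiency.

    PE = (sum of control counts) / (number of control wells x cells seeded),
    i.e. the count-weighted pooled fraction -- invariant to how control
    wells are split across plates.
    """
    counts = experiment.control_counts()
    if not counts:
        raise SurvivalError("no control wells with counts; cannot pool PE")
    total = sum(counts)
    if total == 0:
        raise SurvivalError("all control counts are zero; PE undefined")
    pe = total / (len(counts) * experiment.cells_seeded_per_well)
    return PlatingEfficiency(
        pe=pe,
        n_control_wells=len(counts),
        cells_seeded=experiment.cells_seeded_per_well,
    )


def limit_of_detection(pe: PlatingEfficiency, cells_seeded: Optional[int] = None) -> float:
    """Smallest resolvable surviving fraction: one colony per well.

    Returns ``1 / (cells_seeded * PE)``.  At 100 cells/well this gives 0.02
    for PE 0.5 and 0.03 for PE 1/3.
    """
    n = cells_seeded if cells_seeded is not None else pe.cells_seeded
    if n <= 0:
        raise SurvivalError("cells_seeded must be positive")
    return 1.0 / (n * pe.pe)


def surviving_fractions(
    experiment: PlateExperiment,
    pe: Optional[PlatingEfficiency] = None,
    include_controls: bool = True,
) -> list[SurvivalPoint]:
    """Per-condition/dose mean surviving fractions with SEM and LOD flags.

    Each well's SF is ``count / (cells_seeded * PE)``; replicate wells at the
    same (column, dose) are averaged, SEM is the sample standard deviation
    (n-1 denominator) over replicate wells divided by sqrt(n).  ``below_lod``
    is set when the mean SF is strictly below the limit of detection.
    """
    if pe is None:
        pe = pool_plating_efficiency(experiment)
    lod = limit_of_detection(pe)
    denom = pe.expected_colonies_per_well
    points: list[SurvivalPoint] = []
    cond_map = experiment.condition_map()
    columns = sorted(cond_map) or sorted(
        {col for (_pid, _row, col) in experiment.wells}
    )
    for col in columns:
        pairs = experiment.column_wells(col, include_controls=include_controls)
        if not pairs:
            warnings.warn(f"column {col}: no scoreable wells, omitted", stacklevel=2)
            continue
        by_dose: dict[float, list[int]] = {}
        for dose, count in pairs:
            by_dose.setdefault(dose, []).append(count)
        for dose in sorted(by_dose):
            sfs = np.asarray(by_dose[dose], dtype=float) / denom
            n = sfs.size
            sem = float(sfs.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            mean = float(sfs.mean())
            points.append(
                SurvivalPoint(
                    condition=cond_map.get(col),
                    column_index=col,
                    dose=dose,
                    sf_mean=mean,
                    sf_sem=sem,
                    n_replicates=int(n),
                    below_lod=mean < lod,
                )
            )
    return points


def survival_table(points: list[SurvivalPoint]) -> pd.DataFrame:
    """Tidy DataFrame of survival points (one row per condition/dose)."""
    return pd.DataFrame(
        {
            "ion": [p.condition.ion if p.condition else None for p in points],
            "column": [p.column_index for p in points],
            "y_d": [p.condition.y_d if p.condition else None for p in points],
            "let_d": [p.condition.let_d if p.condition else None for p in points],
            "dose_Gy": [p.dose for p in points],
            "sf_mean": [p.sf_mean for p in points],
            "sf_sem": [p.sf_sem for p in points],
            "n": [p.n_replicates for p in points],
            "below_lod": [p.below_lod for p in points],
        }
    )
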