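"""Litterbag experiment design: treatments × tanks × bags × sampling days.

The default design mirrors a 119-day ex situ kelp-detritus decomposition
experiment: four treatments (darkness at 15 °C and subcompensating light at
15, 20 and 25 °C), four flow-through tanks per treatment, seven mesh bags per
tank, destructive sampling of one bag per tank after 6, 13, 27, 37, 82 and
119 days, plus five day-0 laterals measured before allocation to tanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TREATMENTS = ("dark", "15C", "20C", "25C")
DEFAULT_SAMPLING_DAYS = (6, 13, 27, 37, 82, 119)


@dataclass(frozen=True)
class ExperimentDesign:
    """Fully specified litterbag design.

    Parameters
    ----------
    treatments
        Treatment labels (temperature/light combinations).
    tanks_per_treatment
        Number of replicate tanks per treatment.
    bags_per_tank
        Mesh bags placed in each tank. Bags beyond the number of sampling
        days are spares that are never measured.
    sampling_days
        Strictly increasing positive detrital ages (days) at which one bag
        per tank is sampled destructively.
    n_initial
        Day-0 laterals measured before tank allocation (outside the tank
        hierarchy).
    """

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    tanks_per_treatment: int = 4
    bags_per_tank: int = 7
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    n_initial: int = 5

    def __post_init__(self) -> None:
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment is required")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if self.tanks_per_treatment < 1 or self.bags_per_tank < 1:
            raise ValueError("counts must be >= 1")
        if self.n_initial < 0:
            raise ValueError("n_initial must be >= 0")
        days = np.asarray(self.sampling_days)
        if days.size == 0:
            raise ValueError("sampling_days must be non-empty")
        if np.any(days <= 0):
            raise ValueError("sampling days must be positive")
        if np.any(np.diff(days) <= 0):
            raise ValueError("sampling days must be strictly increasing")
        if self.bags_per_tank < len(self.sampling_days):
            raise ValueError(
                "bags_per_tank must be >= number of sampling days "
                "(one bag sampled per tank per day)"
            )

    @property
    def n_tanks(self) -> int:
        return len(self.treatments) * self.tanks_per_treatment

    @property
    def n_bags(self) -> int:
        return self.n_tanks * self.bags_per_tank

    def tank_labels(self) -> list[str]:
        return [
            f"{tr}.{i + 1}"
            for tr in self.treatments
            for i in range(self.tanks_per_treatment)
        ]


def generate_design(design: ExperimentDesign | None = None, **kwargs) -> pd.DataFrame:
    """Enumerate the bag registry for a design.

    Each bag is assigned to a treatment, a tank within the treatment and a
    sampling day; bags in excess of the sampling days are spares with missing
    sampling day. Day-0 laterals appear first, with no treatment or tank.

    Returns a DataFrame with columns ``sample_id``, ``treatment``, ``tank``,
    ``sampling_day``, ``is_initial``. Deterministic given the design.
    """
    if design is None:
        design = ExperimentDesign(**kwargs)
    elif kwargs:
        raise TypeError("pass either a design object or keyword fields, not both")

    rows: list[dict] = []
    for i in range(design.n_initial):
        rows.append(
            {
                "sample_id": f"initial.{i + 1}",
                "treatment": None,
                "tank": None,
                "sampling_day": 0,
                "is_initial": True,
            }
        )
    days = list(design.sampling_days)
    for tr in design.treatments:
        for t in range(design.tanks_per_treatment):
            tank = f"{tr}.{t + 1}"
            for b in range(design.bags_per_tank):
                day = days[b] if b < len(days) else None
                rows.append(
                    {
                        "sample_id": f"{tank}.bag{b + 1}",
                        "treatment": tr,
                        "tank": tank,
                        "sampling_day": day,
                        "is_initial": False,
                    }
                )
    frame = pd.DataFrame(rows)
    frame["sampling_day"] = frame["sampling_day"].astype("Float64")
    return frame
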