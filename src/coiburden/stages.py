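"""Disease-stage state space and stage-indexed vectors.

The model tracks nine mutually exclusive states: fibrosis grades F0-F3,
compensated cirrhosis (F4CC), decompensated cirrhosis (DCC), hepatocellular
carcinoma (HCC), liver transplant (LT) and death within the base year
(DEATH).  Every stage-resolved quantity in the package -- populations,
probabilities, unit costs, disability weights -- is carried as a
:class:`StageVector` aligned to this fixed order.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd


class Stage(str, Enum):
    """Ordered disease states, F0 through death in the base year."""

    F0 = "F0"
    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4CC = "F4CC"
    DCC = "DCC"
    HCC = "HCC"
    LT = "LT"
    DEATH = "DEATH"


#: Canonical stage order, as plain strings.
STAGES: tuple[str, ...] = tuple(s.value for s in Stage)

#: Stages a living person can occupy in the base year.
LIVING_STAGES: tuple[str, ...] = STAGES[:-1]

#: Fibrosis stages with a sub-certain probability of diagnosis.
FIBROSIS_STAGES: tuple[str, ...] = ("F0", "F1", "F2", "F3")

#: End-stage liver disease: decompensated cirrhosis through transplant.
ESLD_STAGES: tuple[str, ...] = ("DCC", "HCC", "LT")

#: Stages carrying a per-person annual health-cost schedule (LT is costed
#: separately via initial/subsequent transplant-year amounts).
COSTED_STAGES: tuple[str, ...] = ("F0", "F1", "F2", "F3", "F4CC", "DCC", "HCC")


class StageVector:
    """A real-valued quantity indexed over the nine disease states.

    Units are context dependent (persons, GBP, probabilities, weights).
    The vector is immutable; arithmetic returns new instances.

    Parameters
    ----------
    values :
        A mapping from stage name to value, an iterable of nine numbers in
        canonical stage order, or another ``StageVector``.  Mappings may
        omit stages; omitted entries default to ``fill``.
    fill :
        Default for stages absent from a mapping (default 0.0).  Pass
        ``numpy.nan`` to mark stages as unset (e.g. productivity weeks that
        must be extrapolated from F4CC).
    """

    __slots__ = ("_data",)

    def __init__(
        self,
        values: Union["StageVector", Mapping[str, float], Iterable[float]],
        fill: float = 0.0,
    ) -> None:
        if isinstance(values, StageVector):
            arr = values._data.copy()
        elif isinstance(values, Mapping):
            unknown = set(values) - set(STAGES)
            if unknown:
                raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
            arr = np.full(len(STAGES), float(fill))
            for i, s in enumerate(STAGES):
                if s in values:
                    arr[i] = float(values[s])
        else:
            arr = np.asarray(list(values), dtype=float)
            if arr.shape != (len(STAGES),):
                raise ValueError(
                    f"expected {len(STAGES)} values in stage order, got {arr.shape}"
                )
        arr.flags.writeable = False
        self._data = arr

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """Read-only array aligned to :data:`STAGES`."""
        return self._data

    def __getitem__(self, stage: Union[str, Stage]) -> float:
        key = stage.value if isinstance(stage, Stage) else stage
        return float(self._data[STAGES.index(key)])

    def as_series(self) -> pd.Series:
        return pd.Series(self._data, index=list(STAGES), dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {s: float(v) for s, v in zip(STAGES, self._data)}

    def replace(self, **updates: float) -> "StageVector":
        d = self.to_dict()
        for k, v in updates.items():
            if k not in d:
                raise ValueError(f"unknown stage name: {k}")
            d[k] = float(v)
        return StageVector(d)

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> np.ndarray:
        if isinstance(other, StageVector):
            return other._data
        return np.asarray(other, dtype=float)

    def __add__(self, other) -> "StageVector":
        return StageVector(self._data + self._coerce(other))

    def __sub__(self, other) -> "StageVector":
        return StageVector(self._data - self._coerce(other))

    def __mul__(self, other) -> "StageVector":
        return StageVector(self._data * self._coerce(other))

    __rmul__ = __mul__

    def sum(self) -> float:
        return float(np.nansum(self._data))

    def total(self) -> float:
        return self.sum()

    # -- validation helpers ------------------------------------------------
    def is_probability(self) -> bool:
        vals = self._data[~np.isnan(self._data)]
        return bool(np.all((vals >= 0.0) & (vals <= 1.0)))

    def require_probability(self, name: str = "stage vector") -> "StageVector":
        if not self.is_probability():
            raise ValueError(f"{name}: entries must lie in [0, 1]")
        return self

    def __eq__(self, other) -> bool:
        if not isinstance(other, StageVector):
            return NotImplemented
        return np.array_equal(self._data, other._data, equal_nan=True)

    def __hash__(self) -> int:  # immutable by construction
        return hash(self._data.tobytes())

    def __repr__(self) -> str:
        inner = ", ".join(f"{s}={v:g}" for s, v in zip(STAGES, self._data))
        return f"StageVector({inner})"


def stage_index(stage: Union[str, Stage]) -> int:
    key = stage.value if isinstance(stage, Stage) else stage
    return STAGES.index(key)
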