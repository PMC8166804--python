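"""Age-band x sex x stage containers.

Adults are partitioned into five-year age bands 18-19, 20-24, ..., 85-89,
90+.  Age-threshold rules (transplant eligibility, working age) compare the
band's *lower bound* against the threshold, a deterministic convention that
avoids interpolating within bands.  Annuity horizons (forgone income) use
the band midpoint as the expected age within the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import STAGES, StageVector

#: Adult five-year age bands.
AGE_BANDS: tuple[str, ...] = ("18-19",) + tuple(
    f"{lo}-{lo + 4}" for lo in range(20, 90, 5)
) + ("90+",)

SEXES: tuple[str, ...] = ("female", "male")

_CELL_INDEX = pd.MultiIndex.from_product(
    [AGE_BANDS, SEXES], names=["age_band", "sex"]
)


def band_lower(band: str) -> int:
    """Lower bound of an age band ('90+' -> 90)."""
    return int(band.rstrip("+").split("-")[0])


def band_midpoint(band: str) -> float:
    """Midpoint of an age band; '90+' is taken as 92.5."""
    if band.endswith("+"):
        return band_lower(band) + 2.5
    lo, hi = band.split("-")
    return (int(lo) + int(hi) + 1) / 2.0


def cell_index() -> pd.MultiIndex:
    """The canonical (age_band, sex) MultiIndex."""
    return _CELL_INDEX.copy()


@dataclass(frozen=True)
class DemographicTable:
    """Adult population counts by age band and sex.

    ``counts`` is a Series on the canonical (age_band, sex) index; all
    entries must be present and non-negative.
    """

    counts: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        counts = self.counts.reindex(_CELL_INDEX)
        if counts.isna().any():
            missing = counts[counts.isna()].index.tolist()
            raise ValueError(f"demographics missing cells: {missing[:4]}...")
        if (counts < 0).any():
            raise ValueError("demographic counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(float))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DemographicTable":
        """Build from a long table with columns age_band, sex, count."""
        s = frame.set_index(["age_band", "sex"])["count"]
        return cls(counts=s)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def age_sex_distribution(self) -> pd.Series:
        """Population shares by (age_band, sex); sums to one."""
        return self.counts / self.total

    def scale(self, k: float) -> "DemographicTable":
        return DemographicTable(counts=self.counts * k)

    def to_frame(self) -> pd.DataFrame:
        return self.counts.rename("count").reset_index()


class CohortTable:
    """Counts (or money) indexed by age band x sex x disease state.

    Internally a dense DataFrame with the canonical (age_band, sex) row
    index and the nine stages as columns.  Arithmetic is element-wise and
    returns new tables.
    """

    __slots__ = ("data",)

    def __init__(self, data: pd.DataFrame) -> None:
        df = data.reindex(index=_CELL_INDEX, columns=list(STAGES)).fillna(0.0)
        self.data = df.astype(float)

    @classmethod
    def zeros(cls) -> "CohortTable":
        return cls(pd.DataFrame(0.0, index=_CELL_INDEX, columns=list(STAGES)))

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "CohortTable":
        """Build from a long table with columns age_band, sex, stage, value."""
        wide = frame.pivot_table(
            index=["age_band", "sex"], columns="stage", values="value",
            aggfunc="sum", fill_value=0.0,
        )
        return cls(wide)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack().rename("value").reset_index()
        long.columns = ["age_band", "sex", "stage", "value"]
        return long

    # -- aggregation -------------------------------------------------------
    def stage_totals(self) -> StageVector:
        return StageVector(self.data.sum(axis=0).to_numpy())

    def total(self) -> float:
        return float(self.data.to_numpy().sum())

    def by_age_sex(self) -> pd.Series:
        return self.data.sum(axis=1)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "CohortTable") -> "CohortTable":
        return CohortTable(self.data + other.data)

    def __sub__(self, other: "CohortTable") -> "CohortTable":
        return CohortTable(self.data - other.data)

    def scale(self, k: float) -> "CohortTable":
        return CohortTable(self.data * k)

    def mul_stage(self, v: StageVector) -> "CohortTable":
        """Multiply each stage column by the corresponding entry of ``v``."""
        return CohortTable(self.data * v.values)

    def mul_cells(self, weights: pd.Series) -> "CohortTable":
        """Multiply each (age_band, sex) row by a per-cell weight."""
        w = weights.reindex(_CELL_INDEX).fillna(0.0)
        return CohortTable(self.data.mul(w, axis=0))

    def clip_lower(self, lo: float = 0.0) -> "CohortTable":
        return CohortTable(self.data.clip(lower=lo))

    def restrict_age(self, max_lower_bound: int) -> "CohortTable":
        """Zero all rows whose band lower bound is >= ``max_lower_bound``."""
        mask = np.array(
            [band_lower(b) < max_lower_bound for b, _ in _CELL_INDEX]
        )
        return CohortTable(self.data.mul(mask.astype(float), axis=0))

    def allclose(self, other: "CohortTable", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.data.to_numpy(), other.data.to_numpy(), rtol=rtol, atol=atol)
        )

    def __repr__(self) -> str:
        t = self.stage_totals()
        return f"CohortTable(total={self.total():,.1f}, stages={t.to_dict()})"
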