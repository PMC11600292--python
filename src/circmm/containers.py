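"""Shared in-memory containers for count data and sample annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

FEATURE_META_COLUMNS = ["kind", "length_bp", "excluded_from_tpm", "host_gene"]


@dataclass
class ExpressionMatrix:
    """Features x samples raw counts with per-feature metadata.

    ``values`` is a features-by-samples DataFrame of non-negative counts.
    ``feature_meta`` is indexed by feature id and carries at least:
    ``kind`` ("circular" or "linear"), ``length_bp`` (positive for linear
    features; may be NA for circular ones), ``excluded_from_tpm`` (bool) and
    ``host_gene``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids are not unique")
        if not self.values.index.equals(self.feature_meta.index):
            # allow meta to be a superset; align strictly
            missing = self.values.index.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(f"feature metadata missing for: {list(missing)[:5]}")
            self.feature_meta = self.feature_meta.loc[self.values.index]
        lin = self.feature_meta["kind"] == "linear"
        lengths = pd.to_numeric(self.feature_meta.loc[lin, "length_bp"], errors="coerce")
        if (lengths <= 0).any() or lengths.isna().any():
            raise ValueError("linear features require positive length_bp")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset_kind(self, kind: str) -> "ExpressionMatrix":
        mask = self.feature_meta["kind"] == kind
        return ExpressionMatrix(self.values.loc[mask], self.feature_meta.loc[mask])


@dataclass
class SampleRecord:
    """One cohort member: clinical annotations plus simulation truth hooks."""

    sample_id: str
    cohort: str  # whole_bm | purified_pc
    diagnosis: str  # MM | HC
    pc_fraction: float
    os_months: float
    event: int
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if np.isfinite(self.os_months) and self.os_months <= 0:
            raise ValueError("survival time must be positive")


def samples_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "cohort": s.cohort,
            "diagnosis": s.diagnosis,
            "pc_fraction": s.pc_fraction,
            "os_months": s.os_months,
            "event": s.event,
            "purity": s.purity if s.purity is not None else np.nan,
        }
        for s in samples
    ]
    return pd.DataFrame(rows).set_index("sample_id", drop=False)
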