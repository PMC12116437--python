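"""Aggregation of raw per-slide bilateral counts into subject × region densities.

For each (subject, region, slide) the two hemisphere counts are pooled and
divided by the pooled hemisphere area; for regions imaged on several slides
the per-slide densities are then averaged (mean of slide densities, not
pooled counts over pooled area).  Midline nuclei may appear with a single
hemisphere record per slide; the available hemisphere is used as-is.
Subjects lacking any record for a region get an explicit missing value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DensityTable", "compute_density"]


class DensityError(ValueError):
    pass


@dataclass
class DensityTable:
    """Subject × region c-Fos density matrix (cells/mm²) with row metadata."""

    densities: pd.DataFrame  # index: subject_id, columns: regions, NaN = missing
    meta: pd.DataFrame  # index: subject_id, columns: group, litter_id

    def restrict_group(self, group: str) -> "DensityTable":
        keep = self.meta.index[self.meta["group"] == group]
        return DensityTable(self.densities.loc[keep], self.meta.loc[keep])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.meta["group"]))

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.densities], axis=1)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityTable":
        df = pd.read_csv(path, index_col="subject_id")
        meta = df[["group", "litter_id"]]
        dens = df.drop(columns=["group", "litter_id"])
        return cls(dens, meta)


def compute_density(records: pd.DataFrame) -> DensityTable:
    """Collapse a tidy count table to per-subject, per-region densities.

    Raises a labeled error on duplicate (subject, region, hemisphere, slide)
    keys or nonpositive areas; missing subject-region combinations are NaN.
    """
    required = {"subject_id", "group", "litter_id", "region", "hemisphere",
                "slide_index", "count", "area_mm2"}
    missing = required - set(records.columns)
    if missing:
        raise DensityError(f"count table lacks columns: {sorted(missing)}")
    bad_area = records["area_mm2"] <= 0
    if bad_area.any():
        where = records.loc[bad_area, ["subject_id", "region"]].iloc[0]
        raise DensityError(
            f"nonpositive ROI area for subject {where.subject_id!r}, "
            f"region {where.region!r}"
        )
    if (records["count"] < 0).any():
        raise DensityError("negative c-Fos counts present")
    key = ["subject_id", "region", "hemisphere", "slide_index"]
    dup = records.duplicated(subset=key)
    if dup.any():
        where = records.loc[dup, key].iloc[0]
        raise DensityError(f"duplicate count record for {tuple(where)}")

    per_slide = (
        records.groupby(["subject_id", "region", "slide_index"], sort=False)
        .agg(count=("count", "sum"), area=("area_mm2", "sum"))
        .reset_index()
    )
    per_slide["density"] = per_slide["count"] / per_slide["area"]
    per_subject = (
        per_slide.groupby(["subject_id", "region"], sort=False)["density"]
        .mean()
        .reset_index()
    )
    densities = per_subject.pivot(
        index="subject_id", columns="region", values="density"
    )
    # keep first-appearance order of subjects and regions
    subj_order = list(dict.fromkeys(records["subject_id"]))
    region_order = list(dict.fromkeys(records["region"]))
    densities = densities.reindex(index=subj_order, columns=region_order)
    densities.columns.name = None

    meta = (
        records.drop_duplicates("subject_id")
        .set_index("subject_id")[["group", "litter_id"]]
        .reindex(subj_order)
    )
    return DensityTable(densities, meta)
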