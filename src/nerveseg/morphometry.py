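"""Per-fiber morphometry records and summary tables.

Fiber diameters are circular-equivalent (perimeter / pi), the convention
used when mapping traced cross-sections onto cable-model fibers.  The
g-ratio of a myelinated fiber is the inner (axon) to outer (fiber incl.
myelin) diameter ratio; myelin-ring contours with exactly one hole are
paired automatically.  Summary SDs use the n-1 sample denominator since
the summaries parameterize distribution-based nerve generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .contours import Contour, ContourSet, circularity, estimate_diameter


@dataclass
class FiberRecord:
    id: int
    tissue_class: str
    diameter_um: float
    area_um2: float
    circularity: float
    centroid_um: Tuple[float, float]
    g_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter must be positive")
        if self.g_ratio is not None and not 0 < self.g_ratio < 1:
            raise ValueError("g-ratio must lie in (0, 1)")


@dataclass
class MorphometryTable:
    records: List[FiberRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "tissue_class": r.tissue_class,
                    "diameter_um": r.diameter_um,
                    "area_um2": r.area_um2,
                    "circularity": r.circularity,
                    "centroid_x_um": r.centroid_um[0],
                    "centroid_y_um": r.centroid_um[1],
                    "g_ratio": r.g_ratio,
                }
                for r in self.records
            ],
            columns=["id", "tissue_class", "diameter_um", "area_um2",
                     "circularity", "centroid_x_um", "centroid_y_um",
                     "g_ratio"],
        )

    def summaries(self) -> pd.DataFrame:
        """Per-class count, mean and sample SD of diameter and g-ratio."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(
                columns=["tissue_class", "count", "diameter_mean_um",
                         "diameter_sd_um", "g_ratio_mean", "g_ratio_sd"])
        g = df.groupby("tissue_class")
        out = g.agg(
            count=("id", "size"),
            diameter_mean_um=("diameter_um", "mean"),
            diameter_sd_um=("diameter_um", lambda s: s.std(ddof=1)),
            g_ratio_mean=("g_ratio", "mean"),
            g_ratio_sd=("g_ratio", lambda s: s.std(ddof=1)),
        ).reset_index()
        return out


def g_ratio(inner: Contour, outer: Contour, pixel_size_um: float = 1.0) -> float:
    """Inner / outer circular-equivalent diameter, in (0, 1)."""
    di = estimate_diameter(inner, pixel_size_um)
    do = estimate_diameter(outer, pixel_size_um)
    if di >= do:
        raise ValueError("inner diameter must be smaller than outer")
    return di / do


def build_table(
    class_contours: Dict[str, ContourSet],
    pixel_size_um: float,
    myelin_class: str = "myelin",
) -> MorphometryTable:
    """One record per fiber from per-class contour sets.

    Contours of ``myelin_class`` with exactly one hole become myelinated
    fiber records: the outer boundary gives the fiber diameter, the hole
    the axon diameter, and their ratio the g-ratio.  All diameters are
    raw morphometry; any export-time size capping happens downstream in
    geometry construction, never here.
    """
    records: List[FiberRecord] = []
    for cls, cs in class_contours.items():
        for c in cs.top_level():
            if c.perimeter <= 0:
                continue
            holes = cs.holes_of(c.id)
            gr = None
            if cls == myelin_class and len(holes) == 1 and holes[0].perimeter > 0:
                try:
                    gr = g_ratio(holes[0], c, pixel_size_um)
                except ValueError:
                    gr = None
            cx, cy = c.centroid()
            records.append(
                FiberRecord(
                    id=c.id,
                    tissue_class=("myelinated fiber" if gr is not None else cls),
                    diameter_um=estimate_diameter(c, pixel_size_um),
                    area_um2=c.area * pixel_size_um ** 2,
                    circularity=circularity(c),
                    centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                    g_ratio=gr,
                )
            )
    return MorphometryTable(records)


def write_csv(table: MorphometryTable, records_path, summaries_path=None) -> None:
    table.to_frame().to_csv(records_path, index=False)
    if summaries_path is not None:
        table.summaries().to_csv(summaries_path, index=False)
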