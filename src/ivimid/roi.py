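"""Region-of-interest aggregation and perivascular-space grading.

Voxelwise IVIM parameter maps are reduced to one value per atlas region
by averaging over voxels that are both inside the region and flagged
valid by the fit-time exclusion rule.  The same validity mask is applied
to all three parameter maps.

Enlarged perivascular spaces (EPVS) are scored per site (basal ganglia
or centrum semiovale) on the ordinal 0-4 Potter scale, from the counted
number of spaces, taking the worse hemisphere when the two differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegionAtlas", "EPVSRating", "aggregate_roi", "epvs_grade", "hemisphere_max"]

EPVS_SITES = ("basal_ganglia", "centrum_semiovale")


@dataclass(frozen=True)
class RegionAtlas:
    """Integer label volume plus a label -> region-name map.

    Label 0 is background and never aggregated; every nonzero label must
    be named.
    """

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        present = set(int(v) for v in np.unique(labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"unnamed atlas labels: {sorted(unnamed)}")


@dataclass(frozen=True)
class EPVSRating:
    site: str
    grade: int

    def __post_init__(self) -> None:
        if self.site not in EPVS_SITES:
            raise ValueError(f"site must be one of {EPVS_SITES}")
        if self.grade not in range(5):
            raise ValueError("grade must be an integer in 0..4")


def aggregate_roi(
    param_map: np.ndarray,
    validity: np.ndarray,
    atlas: RegionAtlas,
) -> pd.DataFrame:
    """Mean parameter value per atlas region over valid voxels.

    Returns a table with columns ``label``, ``region``, ``n_voxels``,
    ``n_valid`` and ``mean``; a region with no valid voxel gets NaN and
    a warning.
    """
    param_map = np.asarray(param_map, dtype=float)
    validity = np.asarray(validity, dtype=bool)
    labels = np.asarray(atlas.labels)
    if not (param_map.shape == validity.shape == labels.shape):
        raise ValueError("param map, validity map and atlas shapes must match")

    rows = []
    for lab in sorted(atlas.names):
        in_region = labels == lab
        usable = in_region & validity & np.isfinite(param_map)
        n_valid = int(usable.sum())
        if n_valid == 0:
            warnings.warn(f"region {atlas.names[lab]} (label {lab}) has no valid voxels")
            mean = np.nan
        else:
            mean = float(param_map[usable].mean())
        rows.append(
            {
                "label": lab,
                "region": atlas.names[lab],
                "n_voxels": int(in_region.sum()),
                "n_valid": n_valid,
                "mean": mean,
            }
        )
    return pd.DataFrame(rows)


def epvs_grade(count: int) -> int:
    """Ordinal 0-4 EPVS grade from a per-hemisphere count.

    Bands: 0 -> 0; 1-10 -> 1; 11-20 -> 2; 21-40 -> 3; >40 -> 4.  The
    published band edges overlap at 10 and 20 and leave 40 ambiguous;
    this implementation keeps the bands disjoint, assigning each shared
    edge to the lower band (so exactly 40 is grade 3).
    """
    count = int(count)
    if count < 0:
        raise ValueError("EPVS count must be non-negative")
    if count == 0:
        return 0
    if count <= 10:
        return 1
    if count <= 20:
        return 2
    if count <= 40:
        return 3
    return 4


def hemisphere_max(left: EPVSRating, right: EPVSRating) -> EPVSRating:
    """Overall site score: the higher of the two hemisphere grades."""
    if left.site != right.site:
        raise ValueError(f"site mismatch: {left.site} vs {right.site}")
    return EPVSRating(site=left.site, grade=max(left.grade, right.grade))
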