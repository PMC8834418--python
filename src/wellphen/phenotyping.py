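"""Per-well phenotype parameters.

Five quantities summarize one well:

* size ``S = (N_w / N_t) * L_m * W_m`` in um^2, with ``L_m = 250`` and
  ``W_m = 150`` um the fixed well length and width;
* thickness proxy ``nGV``: mean gray value over the cluster footprint
  divided by a robust per-well maximum (99.5th percentile of the well
  interior), so that imaging gain cancels; nGV near 0 means thick;
* roughness ``SD_GV`` (population SD of gray values over the cluster) and
  its normalized form ``nSD_GV = SD_GV / GV_max``;
* thickness-per-area ``RGVS = nGV / area_fraction`` (dimensionless);
* ``RGVSD = nGV / nSD_GV``, the best healthy-vs-patient discriminator.

Ratios are reported as missing (NaN), never 0, when their denominator is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cluster_segmentation import ClusterMask
from .well_detection import WellImage

#: Percentile of well-interior gray values used as the robust per-well
#: maximum; resists hot pixels better than the literal max.
GV_MAX_PERCENTILE = 99.5


@dataclass(frozen=True)
class WellGeometry:
    """Fixed microwell footprint: length L_m and width W_m in micrometres."""

    L_m_um: float = 250.0
    W_m_um: float = 150.0

    def __post_init__(self):
        if self.L_m_um <= 0 or self.W_m_um <= 0:
            raise ValueError("well dimensions must be positive")


@dataclass
class PhenotypeRecord:
    sample_id: str
    well_id: str
    cohort: str = "unknown"  # healthy | patient | unknown
    treatment_cycle: int | None = None
    t_stage: str | None = None
    n_stage: str | None = None
    m_stage: str | None = None
    cancer_stage: str | None = None
    S_um2: float = math.nan
    area_fraction: float = math.nan
    nGV: float = math.nan
    SD_GV: float = math.nan
    nSD_GV: float = math.nan
    RGVS: float = math.nan
    RGVSD: float = math.nan
    no_cluster: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def compute_size(N_w: int, N_t: int, geom: WellGeometry = WellGeometry()) -> float:
    """Cluster size in um^2 from the pixel fraction and the well footprint."""
    if N_t <= 0:
        raise ValueError("N_t must be positive")
    if not (0 <= N_w <= N_t):
        raise ValueError("need 0 <= N_w <= N_t")
    return (N_w / N_t) * geom.L_m_um * geom.W_m_um


def compute_nGV(well: WellImage, mask: ClusterMask) -> tuple[float, float]:
    """Normalized gray value and the per-well robust maximum.

    ``GV_max`` is the 99.5th percentile of gray values over the well
    interior.  An empty cluster mask yields ``nGV = 1.0`` (fully
    transmitting well); callers should carry a "no cluster" flag alongside.
    """
    gv_max = float(np.percentile(well.pixels[well.well_mask], GV_MAX_PERCENTILE))
    if gv_max <= 0:
        raise ValueError("all-black well: GV_max is zero")
    if mask.n_white == 0:
        return 1.0, gv_max
    mean_gv = float(well.pixels[mask.mask].mean())
    return float(np.clip(mean_gv / gv_max, 0.0, 1.0)), gv_max


def compute_roughness(
    well: WellImage, mask: ClusterMask, GV_max: float
) -> tuple[float, float]:
    """Population SD of cluster gray values, raw and normalized by GV_max.

    Fewer than 2 cluster pixels -> roughness is missing (NaN, NaN).
    """
    if mask.n_white < 2:
        return math.nan, math.nan
    sd = float(well.pixels[mask.mask].std(ddof=0))
    return sd, sd / GV_max


def compute_RGVS(nGV: float, area_fraction: float) -> float:
    """Thickness-per-area: nGV divided by the cluster area fraction."""
    if area_fraction == 0 or math.isnan(area_fraction):
        return math.nan
    return nGV / area_fraction


def compute_RGVSD(nGV: float, nSD_GV: float) -> float:
    """Ratio of normalized gray value to normalized gray-value SD."""
    if nSD_GV == 0 or math.isnan(nSD_GV):
        return math.nan
    return nGV / nSD_GV


def phenotype_well(
    well: WellImage,
    mask: ClusterMask,
    geom: WellGeometry = WellGeometry(),
    **metadata,
) -> PhenotypeRecord:
    """Assemble the full per-well record from a crop and its cluster mask."""
    n_w, n_t = mask.n_white, mask.n_total
    area_fraction = n_w / n_t
    nGV, gv_max = compute_nGV(well, mask)
    sd_gv, nsd_gv = compute_roughness(well, mask, gv_max)
    return PhenotypeRecord(
        sample_id=well.sample_id,
        well_id=well.well_id,
        S_um2=compute_size(n_w, n_t, geom),
        area_fraction=area_fraction,
        nGV=nGV,
        SD_GV=sd_gv,
        nSD_GV=nsd_gv,
        RGVS=compute_RGVS(nGV, area_fraction),
        RGVSD=compute_RGVSD(nGV, nsd_gv),
        no_cluster=(n_w == 0),
        **metadata,
    )
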