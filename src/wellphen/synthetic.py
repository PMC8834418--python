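"""Seeded synthetic microwell scenes with ground truth.

The generator emulates the assay's optics well enough to exercise every
pipeline stage: a bright background (0.85) under a radial vignette, dark
elliptical well rims (intensity 0.25, 3 px wide, drawn just outside the
nominal 250 x 150 um well interior), and in-well clusters rendered as

    pixel = local_background * (transmittance + texture noise)

so that the downstream normalized gray value recovers the transmittance
and the normalized gray-value SD recovers the texture amplitude.  Additive
Gaussian sensor noise is applied to the whole frame.

Cohort presets mirror the published healthy/patient statistics: healthy
clusters are thin and smooth (nGV 0.68 +/- 0.07, nSD_GV 0.054 +/- 0.013),
patient clusters thick and rough (0.62 +/- 0.05, 0.085 +/- 0.017), with
per-sample parameters drawn from truncated Gaussians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image_correction import RawImage

BACKGROUND = 0.85
RIM_INTENSITY = 0.25
RIM_WIDTH_PX = 3


@dataclass(frozen=True)
class ClusterSpec:
    """Ground-truth description of one in-well cluster.

    ``roughness_sd_true`` is the texture SD relative to the local
    background (i.e. the target nSD_GV); the rendered raw-intensity SD is
    approximately ``roughness_sd_true * background``.
    """

    area_fraction_true: float
    transmittance_true: float
    roughness_sd_true: float = 0.0
    shape: str = "disk"  # disk | blob
    cohort_label: str = "unknown"

    def __post_init__(self):
        if not (0 <= self.area_fraction_true < 1):
            raise ValueError("area_fraction_true must be in [0, 1)")
        if not (0 < self.transmittance_true <= 1):
            raise ValueError("transmittance_true must be in (0, 1]")
        if self.roughness_sd_true < 0:
            raise ValueError("roughness_sd_true must be >= 0")
        if self.shape not in ("disk", "blob"):
            raise ValueError(f"unknown cluster shape {self.shape!r}")


@dataclass(frozen=True)
class SyntheticScene:
    """Layout and imaging parameters of one rendered frame."""

    grid_rows: int = 1
    grid_cols: int = 1
    pixel_size_um: float = 2.0
    major_um: float = 250.0
    minor_um: float = 150.0
    pitch_major_um: float = 400.0  # center-to-center along the major axis
    pitch_minor_um: float = 280.0
    vignette_strength: float = 0.0
    noise_sd: float = 0.0
    clusters: tuple = ()  # one ClusterSpec or None per well, raster order
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1 x 1")
        if not (0 <= self.vignette_strength <= 0.5):
            raise ValueError("vignette_strength must be in [0, 0.5]")
        a_px = self.major_um / self.pixel_size_um
        b_px = self.minor_um / self.pixel_size_um
        if (
            self.pitch_major_um / self.pixel_size_um < a_px + 2 * RIM_WIDTH_PX + 4
            or self.pitch_minor_um / self.pixel_size_um < b_px + 2 * RIM_WIDTH_PX + 4
        ):
            raise ValueError("wells overlap at the requested pitch")


@dataclass(frozen=True)
class WellTruth:
    well_index: int
    grid_row: int
    grid_col: int
    center_x_px: float
    center_y_px: float
    semi_major_px: float
    semi_minor_px: float
    cluster_mask: np.ndarray | None  # full-frame boolean mask, None if empty well
    well_mask: np.ndarray
    spec: ClusterSpec | None

    @property
    def area_fraction_rasterized(self) -> float:
        if self.cluster_mask is None:
            return 0.0
        return float(self.cluster_mask.sum() / self.well_mask.sum())


def truth_frame(truths: list[WellTruth]) -> pd.DataFrame:
    """Tabular view of the per-well ground truth."""
    rows = []
    for t in truths:
        spec = t.spec
        rows.append(
            {
                "well_index": t.well_index,
                "grid_row": t.grid_row,
                "grid_col": t.grid_col,
                "center_x_px": t.center_x_px,
                "center_y_px": t.center_y_px,
                "semi_major_px": t.semi_major_px,
                "semi_minor_px": t.semi_minor_px,
                "area_fraction_true": spec.area_fraction_true if spec else 0.0,
                "area_fraction_rasterized": t.area_fraction_rasterized,
                "transmittance_true": spec.transmittance_true if spec else math.nan,
                "roughness_sd_true": spec.roughness_sd_true if spec else math.nan,
                "shape": spec.shape if spec else "",
                "cohort_label": spec.cohort_label if spec else "unknown",
            }
        )
    return pd.DataFrame(rows)


def _ellipse(yy, xx, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2


def _cluster_footprint(yy, xx, cx, cy, a_int, b_int, spec, rng):
    """Rasterize the cluster footprint inside the well interior."""
    f = spec.area_fraction_true
    if f <= 0:
        return None
    target_area = f * math.pi * a_int * b_int
    margin = 2.0
    r = math.sqrt(target_area / math.pi)
    # circular disk when it fits; otherwise a well-shaped ellipse of equal area
    if r <= b_int - margin:
        ra = rb = r
    else:
        rb = b_int - margin
        ra = target_area / (math.pi * rb)
    if spec.shape == "disk":
        return _ellipse(yy, xx, cx, cy, ra, rb) <= 1.0
    # blob: radial wobble around the equal-area ellipse, renormalized so the
    # expected area is preserved
    amp1, amp2 = 0.12, 0.08
    norm = math.sqrt(1 + (amp1 ** 2 + amp2 ** 2) / 2)
    ph1, ph2 = rng.uniform(0, 2 * math.pi, size=2)
    theta = np.arctan2((yy - cy) / rb, (xx - cx) / ra)
    wobble = (1 + amp1 * np.sin(3 * theta + ph1) + amp2 * np.sin(5 * theta + ph2)) / norm
    return _ellipse(yy, xx, cx, cy, ra, rb) <= wobble ** 2


def render_scene(spec: SyntheticScene) -> tuple[RawImage, list[WellTruth]]:
    """Render a frame and return it with the per-well ground truth."""
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size_um
    a_int = spec.major_um / 2.0 / ps  # well-interior semi-axes
    b_int = spec.minor_um / 2.0 / ps
    pitch_x = spec.pitch_major_um / ps
    pitch_y = spec.pitch_minor_um / ps
    width = int(round(spec.grid_cols * pitch_x))
    height = int(round(spec.grid_rows * pitch_y))
    height, width = max(height, 64), max(width, 64)

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cx0, cy0 = width / 2.0, height / 2.0
    d2 = ((xx - cx0) ** 2 + (yy - cy0) ** 2) / (cx0 ** 2 + cy0 ** 2)
    vignette = 1.0 - spec.vignette_strength * d2
    img = BACKGROUND * vignette

    clusters = list(spec.clusters)
    n_wells = spec.grid_rows * spec.grid_cols
    if not clusters:
        clusters = [None] * n_wells
    if len(clusters) != n_wells:
        raise ValueError(
            f"expected {n_wells} cluster specs (or none), got {len(clusters)}"
        )

    truths = []
    idx = 0
    for gr in range(spec.grid_rows):
        for gc in range(spec.grid_cols):
            cx = (gc + 0.5) * pitch_x
            cy = (gr + 0.5) * pitch_y
            e_in = _ellipse(yy, xx, cx, cy, a_int, b_int)
            e_out = _ellipse(yy, xx, cx, cy, a_int + RIM_WIDTH_PX, b_int + RIM_WIDTH_PX)
            rim = (e_in > 1.0) & (e_out <= 1.0)
            img[rim] = RIM_INTENSITY
            well_mask = e_in <= 1.0

            cspec = clusters[idx]
            cmask = None
            if cspec is not None and cspec.area_fraction_true > 0:
                cmask = _cluster_footprint(yy, xx, cx, cy, a_int, b_int, cspec, rng)
                if cmask is not None:
                    cmask &= well_mask
                    vals = img[cmask] * (
                        cspec.transmittance_true
                        + rng.normal(0.0, cspec.roughness_sd_true, size=int(cmask.sum()))
                    )
                    img[cmask] = vals
            truths.append(
                WellTruth(
                    well_index=idx,
                    grid_row=gr,
                    grid_col=gc,
                    center_x_px=cx,
                    center_y_px=cy,
                    semi_major_px=a_int,
                    semi_minor_px=b_int,
                    cluster_mask=cmask,
                    well_mask=well_mask,
                    spec=cspec,
                )
            )
            idx += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    raw = RawImage(pixels=img, pixel_size_um=ps, source_path="")
    return raw, truths


# ---------------------------------------------------------------------------
# cohort fixtures
# ---------------------------------------------------------------------------

#: Published cohort statistics (mean, SD) of the normalized phenotypes, plus
#: the package's area-fraction presets (patient mean 0.18 puts RGVS =
#: nGV / f near the reported pretreatment level of ~3.4; healthy monolayers
#: are looser and cover more footprint).
COHORT_PRESETS = {
    "healthy": {
        "transmittance": (0.68, 0.07),
        "roughness": (0.054, 0.013),
        "area_fraction": (0.30, 0.08),
    },
    "patient": {
        "transmittance": (0.62, 0.05),
        "roughness": (0.085, 0.017),
        "area_fraction": (0.18, 0.06),
    },
}

_TRUNC = {
    "transmittance": (0.30, 0.95),
    "roughness": (0.010, 0.200),
    "area_fraction": (0.05, 0.55),
}


def _draw(rng, cohort, key):
    mean, sd = COHORT_PRESETS[cohort][key]
    lo, hi = _TRUNC[key]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_cluster_spec(rng, cohort: str, shape: str = "disk") -> ClusterSpec:
    """Draw one cluster's parameters from a cohort preset (truncated Gaussian)."""
    return ClusterSpec(
        area_fraction_true=_draw(rng, cohort, "area_fraction"),
        transmittance_true=_draw(rng, cohort, "transmittance"),
        roughness_sd_true=_draw(rng, cohort, "roughness"),
        shape=shape,
        cohort_label=cohort,
    )


#: Relative SD of the within-sample area-fraction jitter: wells of one
#: sample are biological replicates of the same culture.
WITHIN_SAMPLE_AREA_CV = 0.10


def sample_well_specs(rng, cohort: str, n_wells: int, shape: str = "disk"):
    """Draw correlated replicate wells for one sample.

    The sample's thickness-per-area ratio (transmittance / area fraction)
    is a property of the cultured material and is held fixed across its
    wells: each well draws its own area fraction and scales transmittance
    proportionally, so size and nGV fluctuate together while RGVS stays
    stable within the sample -- the robustness property of the assay.
    """
    base = sample_cluster_spec(rng, cohort, shape)
    specs = []
    for _ in range(n_wells):
        f = float(
            np.clip(
                rng.normal(
                    base.area_fraction_true,
                    WITHIN_SAMPLE_AREA_CV * base.area_fraction_true,
                ),
                *_TRUNC["area_fraction"],
            )
        )
        t = float(
            np.clip(
                base.transmittance_true * f / base.area_fraction_true,
                *_TRUNC["transmittance"],
            )
        )
        r = float(
            np.clip(
                rng.normal(base.roughness_sd_true, 0.1 * base.roughness_sd_true),
                *_TRUNC["roughness"],
            )
        )
        specs.append(ClusterSpec(f, t, r, shape, cohort))
    return specs


def make_cohort_fixture(
    n_healthy: int = 5,
    n_patient: int = 4,
    seed: int = 0,
    wells_per_sample: int = 4,
    noise_sd: float = 0.01,
    vignette_strength: float = 0.15,
    out_dir: str | Path | None = None,
):
    """Generate a two-cohort image set with a matching sample sheet.

    Default cohort sizes mirror the published study (5 healthy donors, 4
    pretreatment patients).  Returns ``(scenes, sample_sheet)`` where
    ``scenes`` is a list of ``(sample_id, RawImage, truths)``; when
    ``out_dir`` is given, TIFFs plus ``samples.csv`` and ``truth.csv`` are
    also written there.
    """
    if n_healthy < 0 or n_patient < 0 or n_healthy + n_patient < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    grid = _grid_for(wells_per_sample)
    scenes, sheet_rows, truth_rows = [], [], []
    roster = [("healthy", i) for i in range(n_healthy)] + [
        ("patient", i) for i in range(n_patient)
    ]
    for cohort, i in roster:
        sample_id = f"{cohort[0].upper()}{i + 1:02d}"
        specs = tuple(sample_well_specs(rng, cohort, grid[0] * grid[1]))
        scene = SyntheticScene(
            grid_rows=grid[0],
            grid_cols=grid[1],
            vignette_strength=vignette_strength,
            noise_sd=noise_sd,
            clusters=specs,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        raw, truths = render_scene(scene)
        scenes.append((sample_id, raw, truths))
        sheet_rows.append(
            {
                "sample_id": sample_id,
                "cohort": cohort,
                "treatment_cycle": 0 if cohort == "patient" else "",
                "t_stage": "",
                "n_stage": "",
                "m_stage": "",
                "cancer_stage": "",
            }
        )
        tf = truth_frame(truths)
        tf.insert(0, "sample_id", sample_id)
        truth_rows.append(tf)
    sample_sheet = pd.DataFrame(sheet_rows)

    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample_id, raw, _ in scenes:
            tifffile.imwrite(
                str(out / f"{sample_id}.tif"),
                (raw.pixels * 65535.0 + 0.5).astype(np.uint16),
            )
        sample_sheet.to_csv(out / "samples.csv", index=False)
        pd.concat(truth_rows, ignore_index=True).to_csv(out / "truth.csv", index=False)
    return scenes, sample_sheet


def _grid_for(n_wells: int) -> tuple[int, int]:
    rows = int(math.floor(math.sqrt(n_wells)))
    while n_wells % rows:
        rows -= 1
    return rows, n_wells // rows
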