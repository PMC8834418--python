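import numpy as np
import pytest

from wellphen import (
    crop_well,
    detect_wells,
    flatfield_correct,
    phenotype_well,
    segment_cluster,
)
from wellphen.synthetic import ClusterSpec, SyntheticScene, render_scene
from wellphen.well_detection import WellImage, make_roi


def run_wells(spec: SyntheticScene):
    """Render a scene and push it through the full pipeline.

    Returns a list of (WellImage, ClusterMask, PhenotypeRecord, WellTruth)
    in raster order; asserts that every well was detected.
    """
    raw, truths = render_scene(spec)
    corrected = flatfield_correct(raw)
    rois = detect_wells(corrected)
    assert len(rois) == len(truths), f"detected {len(rois)} of {len(truths)} wells"
    out = []
    for i, (roi, truth) in enumerate(zip(rois, truths)):
        well = crop_well(corrected, roi, sample_id="S", well_id=f"w{i}")
        mask = segment_cluster(well)
        rec = phenotype_well(well, mask)
        out.append((well, mask, rec, truth))
    return out


def grid_scene(seed, clusters=None, rows=2, cols=2, vignette=0.15, noise=0.01):
    n = rows * cols
    if clusters is None:
        clusters = ()
    elif isinstance(clusters, ClusterSpec):
        clusters = tuple([clusters] * n)
    return SyntheticScene(
        grid_rows=rows,
        grid_cols=cols,
        vignette_strength=vignette,
        noise_sd=noise,
        clusters=clusters,
        seed=seed,
    )


def direct_well(disk_radius=None, contrast=0.4, noise_sd=0.02, seed=0,
                background=0.85, a=62.5, b=37.5):
    """Build a WellImage directly (no detection), optionally with a centred
    dark disk of the given radius and contrast; returns (well, disk_mask)."""
    cx, cy = 70.0, 45.0
    shape = (91, 141)
    roi = make_roi(cx, cy, a, b, 0.0, shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    ell = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    px = np.full(shape, background)
    px[ell > 1] = 0.25  # rim shadow outside the interior
    disk = np.zeros(shape, dtype=bool)
    if disk_radius is not None:
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= disk_radius ** 2
        px[disk] = background - contrast
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        px = px + rng.normal(0.0, noise_sd, px.shape)
    px = np.clip(px, 0.0, 1.0)
    well = WellImage(pixels=px, roi=roi, well_mask=ell <= 1.0)
    return well, disk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
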