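"""Placental section morphometry: zone areas, stereology, cell counting.

Quantities estimated here mirror standard placental quantification on label
masks:

* absolute and relative areas of the decidua, junctional zone and labyrinth
  zone from low-magnification section masks (median over >= 3 sections per
  implantation site);
* area fractions of labyrinth-zone compartments (maternal blood space,
  fetal blood space, tissue, nuclei clump) by point-count stereology with a
  systematic uniform random grid of 400 points, with tissue and nuclei
  pooled for analysis;
* absolute compartment areas by multiplying stereological fractions by the
  zone area measured at low magnification;
* cell counts and densities from binary nuclei masks via
  distance-transform watershed.

A synthetic generator produces blobby label masks with exactly known pixel
fractions, so every estimator can be validated against planted truth.
Input masks are assumed pre-segmented; raw-fluorescence segmentation is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "ZONE_NAMES",
    "COMPARTMENT_NAMES",
    "LabeledSection",
    "CompartmentMask",
    "ZoneAreas",
    "StereologyResult",
    "synth_section",
    "zone_areas",
    "stereology_fractions",
    "pool_stereology",
    "compartment_total_area",
    "count_cells",
    "synth_nuclei",
]

#: zone label values in a LabeledSection (0 is background)
ZONE_NAMES = {1: "decidua", 2: "junctional_zone", 3: "labyrinth_zone"}
#: compartment label values in a CompartmentMask (every pixel is labeled)
COMPARTMENT_NAMES = ("maternal_blood", "fetal_blood", "tissue", "nuclei_clump")


@dataclass
class LabeledSection:
    """Low-magnification zone mask: 0 background, 1 decidua, 2 JZ, 3 LZ."""

    labels: np.ndarray
    pixel_size_um: float
    site_id: str = "site"
    section_id: str = "s1"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if not np.isin(self.labels, [0, 1, 2, 3]).all():
            raise ValueError("zone labels must be in {0,1,2,3}")


@dataclass
class CompartmentMask:
    """High-magnification labyrinth compartment mask, labels 0..3 mapping to
    maternal blood, fetal blood, tissue, nuclei clump; every pixel labeled."""

    labels: np.ndarray
    pixel_size_um: float
    magnification: str = "40x"
    image_id: str = "img"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if not np.isin(self.labels, range(len(COMPARTMENT_NAMES))).all():
            raise ValueError("compartment labels must be in 0..3")

    def pixel_fractions(self) -> np.ndarray:
        counts = np.bincount(self.labels.ravel(), minlength=len(COMPARTMENT_NAMES))
        return counts / counts.sum()


@dataclass
class ZoneAreas:
    """Per-site zone areas (mm^2) and relative fractions."""

    site_id: str
    per_section_mm2: pd.DataFrame  # rows sections, cols zone names
    median_mm2: dict[str, float]
    mean_mm2: dict[str, float]
    relative_fraction: dict[str, float]  # from medians, sums to 1
    relative_fraction_mean: dict[str, float]


@dataclass
class StereologyResult:
    """Point-count estimate of compartment area fractions."""

    n_points: int
    counts: dict[str, int]
    fractions: dict[str, float]
    se: dict[str, float]
    pooled_tissue_fraction: float
    pooled_tissue_se: float
    grid: str = "sur"

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_points


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / f.std()


def _quantile_labels(field: np.ndarray, fractions, mask=None) -> np.ndarray:
    """Split pixels (optionally inside a mask) into classes whose realized
    pixel fractions match ``fractions`` to within one pixel, by rank."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    out = np.zeros(field.shape, dtype=np.int32)
    idx = np.flatnonzero(np.ones_like(field, dtype=bool) if mask is None else mask)
    order = idx[np.argsort(field.ravel()[idx], kind="stable")]
    bounds = np.round(np.cumsum(fractions) * order.size).astype(int)
    start = 0
    for klass, stop in enumerate(bounds):
        out.ravel()[order[start:stop]] = klass
        start = stop
    return out


def _mosaic_labels(shape, sigma, fractions, rng, tol=0.005, max_iter=300):
    """Blobby mosaic of len(fractions) classes with calibrated fractions.

    Labels are the argmax over independent smoothed Gaussian fields plus
    per-class offsets; the offsets are iteratively adjusted until every
    realized pixel fraction is within ``tol`` of its request.  Unlike
    nested level sets of a single field, the mosaic's class indicators
    decorrelate at the blob scale, which matters for validating
    point-count sampling error.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    k = fractions.size
    if np.any(fractions == 1.0):
        lab = np.full(shape, int(np.argmax(fractions)), dtype=np.int32)
        return lab, fractions.copy()
    fields = np.stack([_smooth_field(shape, sigma, rng) for _ in range(k)])
    offsets = np.zeros(k)
    step = 3.0
    for it in range(max_iter):
        lab = np.argmax(fields + offsets[:, None, None], axis=0)
        realized = np.bincount(lab.ravel(), minlength=k) / lab.size
        err = fractions - realized
        if np.max(np.abs(err)) < tol:
            return lab.astype(np.int32), realized
        offsets += step * err
        step = max(step * 0.98, 0.5)
    raise RuntimeError(
        "mosaic fractions did not converge within tolerance; geometry "
        "unreachable for the requested fractions"
    )


def synth_section(zone_fractions=(0.3, 0.2, 0.5),
                  compartment_fractions=(0.35, 0.25, 0.3, 0.1),
                  shape=(256, 256), pixel_size_um=10.0, blob_sigma=8.0,
                  comp_shape=(512, 512), comp_sigma=4.0,
                  seed: int | None = None, site_id: str = "site",
                  section_id: str = "s1"):
    """Generate one synthetic implantation-site section pair with truth.

    The low-mag mask is an elliptical placental disc whose interior is
    split into the three zones; the high-mag mask covers the whole frame
    with the four labyrinth compartments.  Both are carved from smoothed
    Gaussian random fields by rank thresholding, which makes blobby
    regions whose realized pixel fractions match the request to within one
    pixel; the returned truth holds the realized fractions.  The high-mag
    blob scale (``comp_sigma``) is kept below the spacing of a 400-point
    grid so that point-count samples are effectively independent, the
    sampling regime whose standard error is sqrt(p(1-p)/n).

    Returns ``(LabeledSection, CompartmentMask, truth)`` where truth is a
    dict with ``zone_fractions`` and ``compartment_fractions`` (realized,
    ordered as the label values).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (((yy - h / 2) / (0.42 * h)) ** 2 + ((xx - w / 2) / (0.45 * w)) ** 2) <= 1.0

    zfield = _smooth_field(shape, blob_sigma, rng)
    zlab = np.zeros(shape, dtype=np.int32)
    zlab[disc] = _quantile_labels(zfield, zone_fractions, mask=disc)[disc] + 1
    section = LabeledSection(zlab, pixel_size_um, site_id, section_id)

    clab, _ = _mosaic_labels(comp_shape, comp_sigma, compartment_fractions, rng)
    comp = CompartmentMask(clab, pixel_size_um / 10.0, image_id=f"{site_id}-40x")

    n_disc = int(disc.sum())
    truth = {
        "zone_fractions": [float((zlab == k).sum() / n_disc) for k in (1, 2, 3)],
        "compartment_fractions": [
            float((clab == k).sum() / clab.size)
            for k in range(len(COMPARTMENT_NAMES))
        ],
    }
    return section, comp, truth


def zone_areas(sections, pixel_size_um: float | None = None) -> ZoneAreas:
    """Zone areas per section and per-site medians, means and fractions.

    Area = pixel count x (um/px)^2, reported in mm^2.  A zone missing from
    a section contributes area 0.  Relative fractions divide each zone's
    per-site median (or mean) by the summed medians (means); the three
    fractions sum to 1.
    """
    if not sections:
        raise ValueError("need at least one section")
    rows = {}
    for sec in sections:
        px = pixel_size_um if pixel_size_um is not None else sec.pixel_size_um
        scale = (px / 1000.0) ** 2
        rows[sec.section_id] = {
            name: float((sec.labels == k).sum() * scale)
            for k, name in ZONE_NAMES.items()
        }
    per = pd.DataFrame(rows).T
    med = per.median().to_dict()
    mean = per.mean().to_dict()

    def _rel(d):
        total = sum(d.values())
        if total == 0:
            raise ValueError("all zone areas are zero")
        return {k: v / total for k, v in d.items()}

    return ZoneAreas(
        site_id=sections[0].site_id, per_section_mm2=per,
        median_mm2=med, mean_mm2=mean,
        relative_fraction=_rel(med), relative_fraction_mean=_rel(mean),
    )


def _grid_shape(n_points: int, w: int, h: int) -> tuple[int, int]:
    """Factor pair (nx, ny) of n_points whose aspect best matches the image."""
    best = None
    for nx in range(1, n_points + 1):
        if n_points % nx:
            continue
        ny = n_points // nx
        cost = abs(np.log((nx / ny) / (w / h)))
        if best is None or cost < best[0]:
            best = (cost, nx, ny)
    return best[1], best[2]


def stereology_fractions(mask: CompartmentMask, n_points: int = 400,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         grid: str = "sur") -> StereologyResult:
    """Point-count area fractions over a compartment mask.

    Lays exactly ``n_points`` on a regular lattice spanning the image; with
    ``grid="sur"`` (systematic uniform random, the default) the lattice gets
    a random offset uniform over one grid cell, which makes the fraction
    estimator unbiased; ``grid="fixed"`` centres the points for exact
    reproducibility.  Each point is classified by the label of the pixel
    beneath it; the binomial standard error sqrt(p(1-p)/n) is attached to
    every fraction.  Tissue and nuclei-clump fractions are also pooled.
    """
    h, w = mask.labels.shape
    if n_points > mask.labels.size:
        raise ValueError("more points than pixels")
    if rng is None:
        rng = np.random.default_rng(seed)
    nx, ny = _grid_shape(n_points, w, h)
    if grid == "sur":
        ox, oy = rng.random(), rng.random()
    elif grid == "fixed":
        ox = oy = 0.5
    else:
        raise ValueError("grid must be 'sur' or 'fixed'")
    xs = ((np.arange(nx) + ox) * (w / nx)).astype(int).clip(0, w - 1)
    ys = ((np.arange(ny) + oy) * (h / ny)).astype(int).clip(0, h - 1)
    pts = mask.labels[np.repeat(ys, nx), np.tile(xs, ny)]
    counts = np.bincount(pts, minlength=len(COMPARTMENT_NAMES))

    fr = counts / n_points
    se = np.sqrt(fr * (1 - fr) / n_points)
    pooled = float(fr[2] + fr[3])
    return StereologyResult(
        n_points=n_points,
        counts={n: int(c) for n, c in zip(COMPARTMENT_NAMES, counts)},
        fractions={n: float(f) for n, f in zip(COMPARTMENT_NAMES, fr)},
        se={n: float(s) for n, s in zip(COMPARTMENT_NAMES, se)},
        pooled_tissue_fraction=pooled,
        pooled_tissue_se=float(np.sqrt(pooled * (1 - pooled) / n_points)),
        grid=grid,
    )


def pool_stereology(results) -> dict[str, float]:
    """Average fractions over replicate images of the same site (e.g. the
    six 40x labyrinth images)."""
    if not results:
        raise ValueError("no results to pool")
    out = {n: float(np.mean([r.fractions[n] for r in results]))
           for n in COMPARTMENT_NAMES}
    out["pooled_tissue"] = float(np.mean([r.pooled_tissue_fraction for r in results]))
    return out


def compartment_total_area(result: StereologyResult, zone_area_mm2: float) -> dict[str, float]:
    """Absolute compartment areas: stereological fraction x zone area.

    The returned areas sum to the zone area exactly (fractions sum to 1).
    """
    if zone_area_mm2 < 0:
        raise ValueError("zone area must be >= 0")
    return {n: result.fractions[n] * zone_area_mm2 for n in COMPARTMENT_NAMES}


def count_cells(nuclei_mask: np.ndarray, pixel_size_um: float,
                min_size_px: int = 20, min_distance_px: int = 5):
    """Count cells in a binary nuclei mask via distance-transform watershed.

    Touching nuclei are split at watershed lines seeded from the maxima of
    the smoothed Euclidean distance transform (minimum seed separation
    ``min_distance_px``); objects below ``min_size_px`` pixels are
    discarded.  Returns ``(count, density_per_mm2)`` with density relative
    to the full frame area.
    """
    mask = np.asarray(nuclei_mask, dtype=bool)
    if not mask.any():
        return 0, 0.0
    dist = ndi.gaussian_filter(ndi.distance_transform_edt(mask), 1.0)
    coords = peak_local_max(dist, min_distance=min_distance_px, labels=mask)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, seeds, mask=mask)
    sizes = np.bincount(labels.ravel())[1:]
    count = int(np.sum(sizes >= min_size_px))
    frame_mm2 = mask.size * (pixel_size_um / 1000.0) ** 2
    return count, count / frame_mm2


def synth_nuclei(n_cells: int = 50, shape=(512, 512), radius: float = 8.0,
                 radius_jitter: float = 1.5, min_center_dist: float | None = None,
                 seed: int | None = None):
    """Binary mask of roughly circular nuclei with known count.

    Centres are drawn by rejection sampling with a minimum separation
    (default 1.6 x radius, allowing mild overlap); returns ``(mask,
    centers)``.  Raises if the requested packing cannot be placed.
    """
    rng = np.random.default_rng(seed)
    if min_center_dist is None:
        min_center_dist = 1.6 * radius
    h, w = shape
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place nuclei at requested density")
        margin = radius + radius_jitter + 2
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 >= min_center_dist ** 2
               for a, b in centers):
            centers.append(c)
    mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        r = radius + rng.uniform(-radius_jitter, radius_jitter)
        rr, cc = disk((cy, cx), r, shape=shape)
        mask[rr, cc] = True
    return mask, np.asarray(centers)
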