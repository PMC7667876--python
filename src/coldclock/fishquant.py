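"""Single-molecule RNA-FISH spot counting per nuclear/cytoplasmic area.

Deconvolved z-stacks are collapsed to a 2D maximum-intensity projection, the
nucleus is outlined from the DAPI channel and the whole cell from the diffuse
background signal of the FISH channel itself, and transcript spots are
counted with a noise-tolerance maxima detector: a local maximum counts only
if it stands at least ``tolerance`` above the highest saddle connecting it to
any higher maximum (the behavioural contract of ImageJ's Find Maxima). Spot
tallies per compartment area give per-image transcript densities; condition
means are compared with Tukey's HSD after ANOVA.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters
from skimage.morphology import h_maxima


def max_project(stack: np.ndarray, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel maximum over a half-open z-slice range (default: all planes)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack (z, y, x)")
    if z_range is None:
        z_range = (0, stack.shape[0])
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= stack.shape[0]):
        raise ValueError(f"z_range {z_range} outside stack depth {stack.shape[0]}")
    return stack[z0:z1].max(axis=0)


def find_maxima(img: np.ndarray, noise_tolerance: float) -> np.ndarray:
    """Spot coordinates (row, col) of maxima with prominence >= tolerance.

    Implemented with the h-maxima transform: maxima whose height above the
    highest connecting saddle is below ``noise_tolerance`` are suppressed,
    surviving plateaus collapse to their centroid. Invariant to adding a
    constant to the whole image.
    """
    if noise_tolerance <= 0:
        raise ValueError("noise tolerance must be positive")
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return np.empty((0, 2))
    hm = h_maxima(img, noise_tolerance)
    lab, n = ndimage.label(hm)
    if n == 0:
        return np.empty((0, 2))
    coords = ndimage.center_of_mass(hm, lab, index=np.arange(1, n + 1))
    return np.asarray(coords, dtype=float).reshape(-1, 2)


@dataclass
class CompartmentMasks:
    """Nuclear and whole-cell masks with areas in physical units."""

    nucleus: np.ndarray
    cell: np.ndarray
    pixel_area_um2: float = 1.0

    def __post_init__(self):
        # the nucleus is by construction part of the cell
        self.cell = self.cell | self.nucleus

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.cell & ~self.nucleus

    @property
    def nuclear_area_um2(self) -> float:
        return float(self.nucleus.sum() * self.pixel_area_um2)

    @property
    def cytoplasmic_area_um2(self) -> float:
        return float(self.cytoplasm.sum() * self.pixel_area_um2)


def compartment_masks(
    dapi_img: np.ndarray,
    fish_img: np.ndarray,
    pixel_area_um2: float = 1.0,
    dapi_threshold: float | None = None,
    cell_threshold: float | None = None,
    smooth_sigma: float = 2.0,
) -> CompartmentMasks:
    """Outline nucleus (DAPI) and cell (diffuse FISH background) by thresholding.

    Otsu thresholds by default with manual overrides; both masks are
    hole-filled after light Gaussian smoothing.
    """
    masks = []
    for img, thr in ((dapi_img, dapi_threshold), (fish_img, cell_threshold)):
        sm = ndimage.gaussian_filter(np.asarray(img, dtype=float), smooth_sigma)
        t = filters.threshold_otsu(sm) if thr is None else thr
        m = ndimage.binary_fill_holes(sm > t)
        masks.append(m)
    return CompartmentMasks(nucleus=masks[0], cell=masks[1], pixel_area_um2=pixel_area_um2)


@dataclass
class SpotCounts:
    nuclear: int
    cytoplasmic: int
    outside: int
    nuclear_area_um2: float
    cytoplasmic_area_um2: float

    @property
    def nuclear_density(self) -> float:
        return self.nuclear / self.nuclear_area_um2

    @property
    def cytoplasmic_density(self) -> float:
        return self.cytoplasmic / self.cytoplasmic_area_um2


def count_by_compartment(spots: np.ndarray, masks: CompartmentMasks) -> SpotCounts:
    """Assign each spot to nucleus, cytoplasm or outside-cell by mask membership.

    Spots on the nuclear boundary belong to the nucleus (the nuclear mask is
    checked first). Counts conserve: nuclear + cytoplasmic + outside = total.
    """
    spots = np.asarray(spots, dtype=float).reshape(-1, 2)
    nuc = cyt = out = 0
    shape = masks.nucleus.shape
    for r, c in np.round(spots).astype(int):
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            out += 1
        elif masks.nucleus[r, c]:
            nuc += 1
        elif masks.cell[r, c]:
            cyt += 1
        else:
            out += 1
    return SpotCounts(
        nuclear=nuc,
        cytoplasmic=cyt,
        outside=out,
        nuclear_area_um2=masks.nuclear_area_um2,
        cytoplasmic_area_um2=masks.cytoplasmic_area_um2,
    )


def condition_summary(densities_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean spot density and SEM per condition across images."""
    rows = []
    for cond, d in densities_by_condition.items():
        d = np.asarray(d, dtype=float)
        rows.append(
            {
                "condition": cond,
                "mean": float(d.mean()),
                "sem": float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else np.nan,
                "n_images": int(d.size),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Tukey HSD comparisons of per-image densities across conditions."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    res = stats.tukey_hsd(*[np.asarray(groups[n], dtype=float) for n in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)
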