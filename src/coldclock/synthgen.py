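"""Seeded generators for every synthetic input the pipeline consumes.

Each generator emulates the statistical structure of one experimental data
type and returns machine-readable ground truth alongside the data, so every
downstream operation can be scored by parameter recovery:

* :func:`simulate_reads` -- strand-aware read 3'-end positions near annotated
  polyA sites, negative-binomially dispersed per gene, for a human library
  with a fly spike-in mixed at a known cell ratio;
* :func:`simulate_plate` -- damped, noisy ~24 h bioluminescence oscillations
  for plate wells synchronized at staggered phases, with a masked cold window
  followed by a programmable phase delay and amplitude change;
* :func:`simulate_nucleus` -- a 3D nucleus phantom with a 7-level chromatin
  density field (optional peripheral thickening), ordered class intensities,
  and two marker centroid sets (envelope-bound and interior);
* :func:`simulate_fish_image` -- Gaussian spots over textured background.

All generators are bit-reproducible under a fixed integer seed; sub-streams
are derived deterministically from it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .circadian import WellProfile
from .nucleome import CentroidSet, ClassMap, VoxelGrid
from .pasquant import PasSite

# ---------------------------------------------------------------------------
# 3'-end read simulation


@dataclass
class ReadSimConfig:
    """Configuration for the dual-species 3'-end read generator.

    ``mixing_ratio`` is fly cells : human cells (1:4 -> 0.25, 5:4 -> 1.25).
    ``weights`` (genes x samples, rows matching catalog gene_ids) are
    normalized per species per sample; None means uniform. ``dispersion`` is
    the NB dispersion shared by all genes (0 -> Poisson-free multinomial
    draw). ``background_frac`` of reads fall outside every extended window.
    """

    pas_catalog: list[PasSite]
    n_human_reads: int = 10_000
    n_fly_reads: int = 2_500
    mixing_ratio: float = 0.25
    weights: pd.DataFrame | None = None
    dispersion: float = 0.1
    background_frac: float = 0.0
    max_offset_5: int = 200
    max_offset_3: int = 20
    samples: tuple[str, ...] = ("sample_1",)
    seed: int = 0

    def __post_init__(self):
        if not self.pas_catalog:
            raise ValueError("pas_catalog must not be empty")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing_ratio must be positive")
        if not 0 <= self.background_frac < 1:
            raise ValueError("background_frac must be in [0, 1)")


def simulate_reads(cfg: ReadSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate read 3'-end positions and return them with true gene counts.

    Per sample and species, per-gene read counts are drawn around the target
    expression weights with gamma-Poisson (NB) noise at the configured
    dispersion, then each read's 3' end is placed uniformly within the
    extension window of one of the gene's sites (so a correctly configured
    counter recovers the truth exactly when ``background_frac`` is 0). The
    stated fraction of background reads falls outside every window.
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = pd.DataFrame(
        {
            "chrom": [s.chrom for s in cfg.pas_catalog],
            "strand": [s.strand for s in cfg.pas_catalog],
            "pos": [s.cleavage_pos for s in cfg.pas_catalog],
            "gene_id": [s.gene_id for s in cfg.pas_catalog],
            "species": [s.species for s in cfg.pas_catalog],
        }
    )
    genes = catalog[["gene_id", "species"]].drop_duplicates().set_index("gene_id")

    truth = pd.DataFrame(0, index=genes.index, columns=list(cfg.samples), dtype=np.int64)
    rows = []
    n_by_species = {"human": cfg.n_human_reads, "fly": cfg.n_fly_reads}
    for sample in cfg.samples:
        for species, n_reads in n_by_species.items():
            gids = genes.index[genes["species"] == species]
            if gids.empty or n_reads == 0:
                continue
            if cfg.weights is not None:
                w = cfg.weights.loc[gids, sample].to_numpy(dtype=float)
            else:
                w = np.ones(gids.size)
            w = w / w.sum()
            target = w * n_reads * (1.0 - cfg.background_frac)
            if cfg.dispersion > 0:
                lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * target)
                counts = rng.poisson(lam)
            else:
                counts = rng.multinomial(
                    int(round(n_reads * (1.0 - cfg.background_frac))), w
                )
            truth.loc[gids, sample] = counts

            by_gene = {g: grp for g, grp in catalog.groupby("gene_id", sort=False)}
            for gid, cnt in zip(gids, counts):
                if cnt == 0:
                    continue
                sites = by_gene[gid]
                pick = rng.integers(0, len(sites), size=cnt)
                strands = sites["strand"].to_numpy()[pick]
                pos = sites["pos"].to_numpy()[pick]
                chroms = sites["chrom"].to_numpy()[pick]
                off = np.where(
                    strands == "+",
                    rng.integers(-cfg.max_offset_5, cfg.max_offset_3 + 1, cnt),
                    rng.integers(-cfg.max_offset_3, cfg.max_offset_5 + 1, cnt),
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chroms,
                            "strand": strands,
                            "pos_3prime": np.maximum(0, pos + off),
                            "sample": sample,
                        }
                    )
                )
            # background reads well beyond any window
            n_bg = int(round(n_reads * cfg.background_frac))
            if n_bg:
                sp = catalog[catalog["species"] == species]
                far = int(sp["pos"].max()) + 1_000_000
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": rng.choice(sp["chrom"].unique(), n_bg),
                            "strand": rng.choice(["+", "-"], n_bg),
                            "pos_3prime": far + rng.integers(0, 1_000_000, n_bg),
                            "sample": sample,
                        }
                    )
                )
    if rows:
        reads = pd.concat(rows, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=["chrom", "strand", "pos_3prime", "sample"])
    reads["pos_3prime"] = reads["pos_3prime"].astype(np.int64)
    return reads, truth


# ---------------------------------------------------------------------------
# bioluminescence plate simulation


@dataclass
class OscillatorConfig:
    """Damped-cosine model of a synchronized bioluminescence well.

    Post-cold wells resume with phase delayed by
    ``post_cold_phase_delay_frac`` of the period and amplitude multiplied by
    ``post_cold_amp_factor``; samples inside ``cold_window`` are masked as
    missing (plates leave the readers), never zeroed. When
    ``post_cold_reset_phase_h`` is set, every cold-exposed well resumes at
    that single common phase regardless of its group -- the clock-resetting
    scenario in which previously staggered profiles collapse together.
    """

    period_h: float = 24.0
    damping_rate: float = 0.005  # per hour
    baseline_drift: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.1
    phase_offsets_h: tuple[float, ...] = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0)
    cold_window: tuple[float, float] = (72.0, 96.0)
    post_cold_phase_delay_frac: float = 0.0
    post_cold_amp_factor: float = 1.0
    post_cold_reset_phase_h: float | None = None
    amplitude: float = 1.0
    total_h: float = 168.0
    sampling_interval_h: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.period_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("period and sampling interval must be positive")
        if self.cold_window[0] >= self.cold_window[1]:
            raise ValueError("cold window start must precede its end")
        if self.post_cold_amp_factor <= 0:
            raise ValueError("amplitude factor must be positive")


def _well_signal(
    t: np.ndarray, cfg: OscillatorConfig, phase_h: float, cold: bool
) -> np.ndarray:
    drift = np.polyval(cfg.baseline_drift[::-1], t)
    env = cfg.amplitude * np.exp(-cfg.damping_rate * t)
    phase = np.full_like(t, phase_h)
    amp = np.ones_like(t)
    if cold:
        after = t >= cfg.cold_window[1]
        if cfg.post_cold_reset_phase_h is not None:
            phase[after] = cfg.post_cold_reset_phase_h
        phase[after] += cfg.post_cold_phase_delay_frac * cfg.period_h
        amp[after] = cfg.post_cold_amp_factor
    return drift + env * amp * np.cos(2 * np.pi * (t - phase) / cfg.period_h)


def simulate_plate(
    cfg: OscillatorConfig, n_wells_per_group: int = 10
) -> tuple[list[WellProfile], dict]:
    """Simulate cold-exposed wells plus paired 37 C controls for each phase group.

    Returns the wells and a ground-truth record (injected delay as % of
    period, injected log2 amplitude factor, per-group phase offsets).
    """
    if n_wells_per_group < 1:
        raise ValueError("need at least one well per group")
    t = np.arange(0.0, cfg.total_h + 1e-9, cfg.sampling_interval_h)
    if cfg.cold_window[0] <= t[0] or cfg.cold_window[1] >= t[-1]:
        raise ValueError("cold window must lie strictly inside the recording span")
    rng = np.random.default_rng(cfg.seed)
    masked = (t >= cfg.cold_window[0]) & (t < cfg.cold_window[1])

    wells: list[WellProfile] = []
    for gi, phase in enumerate(cfg.phase_offsets_h):
        group = chr(ord("a") + gi)
        for w in range(n_wells_per_group):
            for is_control in (False, True):
                y = _well_signal(t, cfg, phase, cold=not is_control)
                y = y + rng.normal(0.0, cfg.noise_sd, size=t.size)
                if not is_control:
                    y = np.where(masked, np.nan, y)
                wells.append(
                    WellProfile(
                        well_id=f"{group}{w + 1}{'c' if is_control else ''}",
                        time_h=t,
                        signal=y,
                        phase_group=group,
                        cold_window=None if is_control else cfg.cold_window,
                        is_control=is_control,
                    )
                )
    truth = {
        "phase_shift_pct": cfg.post_cold_phase_delay_frac * 100.0,
        "log2_amp_fc": float(np.log2(cfg.post_cold_amp_factor)),
        "period_h": cfg.period_h,
        "phase_offsets_h": cfg.phase_offsets_h,
    }
    return wells, truth


# ---------------------------------------------------------------------------
# nucleus phantom


@dataclass
class NucleusPhantomConfig:
    """Ellipsoidal nucleus phantom with a 7-level chromatin density field."""

    grid_shape: tuple[int, int, int] = (32, 64, 64)
    voxel_size: tuple[float, float, float] = (0.125, 0.04, 0.04)
    class_fractions: tuple[float, ...] = (0.5, 0.14, 0.1, 0.09, 0.08, 0.06, 0.03)
    peripheral_thickening_um: float = 0.0
    centroid_counts: tuple[int, int] = (150, 300)  # (surface marker, interior marker)
    interior_class_bias: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    class_intensity_means: tuple[float, ...] = (20, 45, 70, 95, 120, 145, 170)
    intensity_sd: float = 4.0
    quality_score_dist: tuple[float, float] = (12.0, 3.0)
    field_smoothness_vox: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.peripheral_thickening_um < 0:
            raise ValueError("shell width must be >= 0")
        if len(self.interior_class_bias) != len(self.class_fractions):
            raise ValueError("class bias must give a weight for every class")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    c = [(s - 1) / 2.0 for s in shape]
    r = [0.42 * s for s in shape]
    return ((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + (
        (xx - c[2]) / r[2]
    ) ** 2 <= 1.0


def simulate_nucleus(
    cfg: NucleusPhantomConfig,
) -> tuple[VoxelGrid, ClassMap, dict[str, CentroidSet]]:
    """Generate a DAPI-like stack, its true class map, and marker centroid sets.

    The density field is a smoothed Gaussian random field rank-sliced into
    classes at the configured volume fractions. Peripheral thickening adds a
    bump within a shell of the given width from the nuclear surface before
    slicing, concentrating the dense classes at the periphery (and pushing
    the interchromatin space inward). Surface-marker centroids sit on mask
    surface voxels; interior-marker centroids sample voxels with the
    configured per-class bias. Voxel intensities have strictly ordered class
    means. Deterministic given the seed.
    """
    n_classes = len(cfg.class_fractions)
    rng = np.random.default_rng(cfg.seed)
    mask = _ellipsoid_mask(cfg.grid_shape)
    if not mask.any():
        raise ValueError("ellipsoid mask does not fit the grid")

    fld = ndimage.gaussian_filter(
        rng.standard_normal(cfg.grid_shape), cfg.field_smoothness_vox
    )
    if cfg.peripheral_thickening_um > 0:
        dist_in = ndimage.distance_transform_edt(mask, sampling=cfg.voxel_size)
        shell = np.clip(1.0 - dist_in / cfg.peripheral_thickening_um, 0.0, 1.0)
        fld = fld + 3.0 * fld.std() * shell * mask

    # rank-slice the field inside the mask at cumulative class fractions
    vals = fld[mask]
    dense_rank = np.argsort(np.argsort(vals))
    quantile = (dense_rank + 0.5) / vals.size
    edges = np.cumsum(cfg.class_fractions)
    labels_in = np.searchsorted(edges, quantile, side="right") + 1
    labels_in = np.clip(labels_in, 1, n_classes)
    labels = np.zeros(cfg.grid_shape, dtype=np.int16)
    labels[mask] = labels_in
    cmap = ClassMap(labels=labels, mask=mask, voxel_size=cfg.voxel_size, n_classes=n_classes)

    means = np.asarray(cfg.class_intensity_means, dtype=float)
    if np.any(np.diff(means) <= 0):
        raise ValueError("class intensity means must be strictly increasing")
    img = rng.normal(2.0, cfg.intensity_sd / 2.0, size=cfg.grid_shape)  # dim background
    img[mask] = rng.normal(means[labels_in - 1], cfg.intensity_sd)
    dapi = VoxelGrid(img, cfg.voxel_size, channel="dapi")

    # surface marker: voxels of the one-voxel-thick mask rim
    eroded = ndimage.binary_erosion(mask)
    surface_idx = np.argwhere(mask & ~eroded)
    n_surf, n_int = cfg.centroid_counts
    if n_surf > len(surface_idx):
        raise ValueError("not enough surface voxels for requested centroids")
    pick = rng.choice(len(surface_idx), size=n_surf, replace=False)
    surf_pts = surface_idx[pick] * np.array(cfg.voxel_size)

    bias = np.asarray(cfg.interior_class_bias, dtype=float)
    if bias.sum() <= 0:
        raise ValueError("interior class bias must have positive total weight")
    w = bias[labels_in - 1]
    w = w / w.sum()
    in_idx = np.argwhere(mask)
    pick = rng.choice(len(in_idx), size=n_int, replace=True, p=w)
    int_pts = in_idx[pick] * np.array(cfg.voxel_size)

    qmean, qsd = cfg.quality_score_dist
    centroids = {
        "surface": CentroidSet(
            surf_pts, np.clip(rng.normal(qmean, qsd, n_surf), 0, None), marker="surface"
        ),
        "interior": CentroidSet(
            int_pts, np.clip(rng.normal(qmean, qsd, n_int), 0, None), marker="interior"
        ),
    }
    return dapi, cmap, centroids


# ---------------------------------------------------------------------------
# FISH image simulation


def simulate_fish_image(
    k_spots: int,
    amplitude: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    spot_sigma: float = 1.5,
    background: float = 10.0,
    region_mask: np.ndarray | None = None,
    n_planes: int = 1,
    min_separation: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian spots over a textured background; returns (image, true coords).

    Spots are placed by rejection sampling with pairwise separation
    >= ``min_separation`` (default 4 x ``spot_sigma``; spots closer than
    about 2 sigma merge into a single intensity maximum and would not be
    countable even in principle), optionally restricted to ``region_mask``.
    With ``n_planes`` > 1 a 3D stack is returned in which each spot lives on
    one plane, exercising maximum-intensity projection. Truth is the
    (row, col) array of planted spot centres; ``k_spots`` = 0 yields a flat
    noise image and empty truth.
    """
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 4.0 * spot_sigma
    pts: list[tuple[float, float]] = []
    margin = 4 * spot_sigma
    attempts = 0
    while len(pts) < k_spots:
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if region_mask is not None and not region_mask[int(r), int(c)]:
            continue
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation**2 for r0, c0 in pts):
            pts.append((r, c))
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place spots with the required separation")
    coords = np.asarray(pts, dtype=float).reshape(-1, 2)

    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), 8.0)
    base = background + background * 0.2 * texture

    yy, xx = np.indices(shape, dtype=float)
    planes = np.zeros((n_planes,) + shape)
    planes[:] = base
    for i, (r, c) in enumerate(coords):
        z = int(rng.integers(0, n_planes))
        planes[z] += amplitude * np.exp(
            -(((yy - r) ** 2 + (xx - c) ** 2) / (2 * spot_sigma**2))
        )
    planes = planes + rng.normal(0.0, noise_sd, planes.shape)
    img = planes[0] if n_planes == 1 else planes
    return img, coords


def simulate_fish_scene(
    n_nuclear: int,
    n_cyto: int,
    amplitude: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    spot_sigma: float = 1.5,
) -> dict:
    """A cell-shaped FISH scene with spots split between nucleus and cytoplasm.

    Builds a circular cell with a concentric nuclear disk, plants
    ``n_nuclear`` spots inside the nucleus and ``n_cyto`` in the cytoplasmic
    ring, and returns the FISH image, a DAPI-like image, the true masks and
    the per-compartment truth coordinates -- enough to score compartment
    assignment and density ratios end to end.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape, dtype=float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cell = r2 <= (0.45 * min(shape)) ** 2
    nucleus = r2 <= (0.22 * min(shape)) ** 2

    img_nuc, pts_nuc = simulate_fish_image(
        n_nuclear, amplitude, 0.0, seed=int(rng.integers(2**31)), shape=shape,
        spot_sigma=spot_sigma, background=0.0, region_mask=nucleus,
    )
    img_cyt, pts_cyt = simulate_fish_image(
        n_cyto, amplitude, 0.0, seed=int(rng.integers(2**31)), shape=shape,
        spot_sigma=spot_sigma, background=0.0, region_mask=cell & ~nucleus,
    )
    background = 5.0 + 30.0 * cell  # diffuse signal outlines the cell
    fish = background + img_nuc + img_cyt + rng.normal(0.0, noise_sd, shape)
    dapi = 5.0 + 60.0 * nucleus + rng.normal(0.0, noise_sd, shape)
    return {
        "fish": fish,
        "dapi": dapi,
        "cell_mask": cell,
        "nuclear_mask": nucleus,
        "spots_nuclear": pts_nuc,
        "spots_cyto": pts_cyt,
    }
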