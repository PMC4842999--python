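"""Synthetic synaptic scenes and their renderings.

The generator produces fields of postsynaptic densities (PSDs), each composed
of 1-4 elliptical PSD95 nanoclusters (NCs), with the statistical structure the
downstream analysis assumes: NC short/long axes log-normal around configurable
medians, within-PSD NC separations confined to a spacing interval, and PSD
counts Poisson in the field area.  Scenes are rendered three ways:

* :func:`render_image` — pixel raster seen through an isotropic Gaussian PSF
  (confocal ~240 nm FWHM, gated-STED ~85 nm FWHM, 20 nm pixels);
* :func:`simulate_palm` — a single-molecule localisation table with Gaussian
  localisation error (~40 nm precision) and uniform false localisations;
* :func:`simulate_two_channel` — a registered pre/post-synaptic puncta pair
  for object-based juxtaposition analysis.

Every stochastic operation takes an explicit integer seed; identical
(config, seed) pairs reproduce scenes, images and tables exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import RenderedImage, fwhm_to_sigma

__all__ = [
    "NanoclusterTruth",
    "PSDTruth",
    "SyntheticScene",
    "SimulationConfig",
    "sample_scene",
    "render_image",
    "simulate_palm",
    "simulate_two_channel",
    "scene_to_json",
    "scene_from_json",
]


# --------------------------------------------------------------------------
# ground-truth containers
# --------------------------------------------------------------------------

@dataclass
class NanoclusterTruth:
    """One elliptical nanocluster: centre (x, y) nm, full axis lengths in nm."""

    centre: tuple[float, float]
    long_axis: float
    short_axis: float
    orientation: float  # radians, of the long axis
    molecule_count: int

    def __post_init__(self) -> None:
        if not (0 < self.short_axis <= self.long_axis):
            raise ValueError("need 0 < short_axis <= long_axis")
        if self.molecule_count < 1:
            raise ValueError("molecule_count must be >= 1")

    @property
    def area_nm2(self) -> float:
        return np.pi * (self.long_axis / 2.0) * (self.short_axis / 2.0)

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area (geometric-mean axis)."""
        return float(np.sqrt(self.long_axis * self.short_axis))


@dataclass
class PSDTruth:
    """A PSD as the set of its nanoclusters."""

    nanoclusters: list[NanoclusterTruth]

    @property
    def subtype_truth(self) -> int:
        return len(self.nanoclusters)

    @property
    def centre(self) -> tuple[float, float]:
        xs = [nc.centre[0] for nc in self.nanoclusters]
        ys = [nc.centre[1] for nc in self.nanoclusters]
        return float(np.mean(xs)), float(np.mean(ys))


@dataclass
class SyntheticScene:
    field_width: float
    field_height: float
    psds: list[PSDTruth]
    rng_seed: int

    @property
    def nanoclusters(self) -> list[NanoclusterTruth]:
        return [nc for psd in self.psds for nc in psd.nanoclusters]


@dataclass
class SimulationConfig:
    """Generative settings for synthetic fields.

    Defaults describe a CA1 stratum oriens-like field: 19.2 PSDs per 20 um^2,
    subtype mixture 63.7/24.3/11.9% (the open 3+ bin split 9.0/2.9% between
    3 and 4 NCs), NC axes log-normal with medians 86 x 189 nm, NC separations
    100-300 nm, confocal/STED PSF FWHM 240/85 nm on a 20 nm pixel grid, and
    ~40 nm localisation precision for the pointillist modality.
    """

    field_width_nm: float = 20_000.0
    field_height_nm: float = 20_000.0
    psd_density: float = 19.2               # PSDs per 20 um^2
    subtype_mixture: tuple[float, float, float, float] = (0.637, 0.243, 0.090, 0.029)
    nc_axis_medians: tuple[float, float] = (86.0, 189.0)   # (short, long) nm
    nc_axis_dispersion: float = 0.25        # log-scale sigma
    spacing_interval: tuple[float, float] = (100.0, 300.0)
    psf_fwhm_confocal: float = 240.0
    psf_fwhm_sted: float = 85.0
    pixel_size: float = 20.0
    localisation_precision: float = 40.0
    localisations_per_nc: float = 150.0
    background_rate: float = 0.1            # false localisations per um^2
    noise_poisson_gain: float = 0.0         # photons per intensity unit; 0 = off
    noise_gaussian_read_sigma: float = 0.0  # additive read noise; 0 = off
    nc_profile: str = "uniform"             # or "gaussian"
    edge_margin_nm: float = 600.0           # keep PSDs off the border
    n_frames: int = 18_000
    supersample: int = 4

    def __post_init__(self) -> None:
        mix = np.asarray(self.subtype_mixture, dtype=float)
        if mix.size != 4 or (mix < 0).any() or mix.sum() <= 0:
            raise ValueError("subtype_mixture must be 4 non-negative weights")
        self.subtype_mixture = tuple(mix / mix.sum())
        lo, hi = self.spacing_interval
        if not (0 < lo < hi):
            raise ValueError("spacing_interval must satisfy 0 < min < max")
        for name in ("field_width_nm", "field_height_nm", "pixel_size",
                     "nc_axis_dispersion", "localisations_per_nc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        s, l = self.nc_axis_medians
        if not (0 < s <= l):
            raise ValueError("nc_axis_medians must be (short, long) with short <= long")
        if self.nc_profile not in ("uniform", "gaussian"):
            raise ValueError("nc_profile must be 'uniform' or 'gaussian'")


# --------------------------------------------------------------------------
# scene sampling
# --------------------------------------------------------------------------

_MAX_PLACEMENT_RETRIES = 10_000


def _draw_axes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Log-normal axes preserving the configured medians exactly at sigma -> 0."""
    s_med, l_med = cfg.nc_axis_medians
    short = float(np.exp(np.log(s_med) + cfg.nc_axis_dispersion * rng.standard_normal()))
    long = float(np.exp(np.log(l_med) + cfg.nc_axis_dispersion * rng.standard_normal()))
    if short > long:
        short, long = long, short
    return short, long


def _place_nc_centres(n: int, anchor: tuple[float, float],
                      cfg: SimulationConfig, rng: np.random.Generator,
                      psd_index: int) -> list[tuple[float, float]]:
    """Sequential rejection sampling: every pairwise distance in the spacing interval."""
    lo, hi = cfg.spacing_interval
    margin = cfg.edge_margin_nm
    centres = [anchor]
    for _ in range(n - 1):
        for attempt in range(_MAX_PLACEMENT_RETRIES):
            base = centres[rng.integers(len(centres))]
            r = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = (base[0] + r * np.cos(theta), base[1] + r * np.sin(theta))
            if not (margin <= cand[0] <= cfg.field_width_nm - margin
                    and margin <= cand[1] <= cfg.field_height_nm - margin):
                continue
            dists = [np.hypot(cand[0] - c[0], cand[1] - c[1]) for c in centres]
            if all(lo <= d <= hi for d in dists):
                centres.append(cand)
                break
        else:
            raise RuntimeError(
                f"PSD {psd_index}: could not place {n} nanoclusters with all "
                f"pairwise separations in [{lo}, {hi}] nm "
                f"(gave up after {_MAX_PLACEMENT_RETRIES} retries)")
    return centres


def sample_scene(config: SimulationConfig, seed: int) -> SyntheticScene:
    """Draw a ground-truth field of PSDs.

    The PSD count is Poisson with mean ``psd_density x field area / 20 um^2``;
    each PSD's NC count is drawn from the subtype mixture, NC centres are
    placed so every pairwise separation lies in the spacing interval, and NC
    axes are log-normal around the configured medians.
    """
    rng = np.random.default_rng(seed)
    area_um2 = (config.field_width_nm / 1000.0) * (config.field_height_nm / 1000.0)
    n_psds = int(rng.poisson(config.psd_density * area_um2 / 20.0))
    margin = config.edge_margin_nm
    if (config.field_width_nm <= 2 * margin or config.field_height_nm <= 2 * margin):
        raise ValueError("field smaller than twice the edge margin")

    mixture = np.asarray(config.subtype_mixture)
    psds: list[PSDTruth] = []
    for i in range(n_psds):
        anchor = (float(rng.uniform(margin, config.field_width_nm - margin)),
                  float(rng.uniform(margin, config.field_height_nm - margin)))
        nc_count = int(rng.choice(4, p=mixture)) + 1
        centres = _place_nc_centres(nc_count, anchor, config, rng, psd_index=i)
        ncs = []
        for c in centres:
            short, long = _draw_axes(config, rng)
            ncs.append(NanoclusterTruth(
                centre=c,
                long_axis=long,
                short_axis=short,
                orientation=float(rng.uniform(0.0, np.pi)),
                molecule_count=max(1, int(rng.poisson(config.localisations_per_nc))),
            ))
        psds.append(PSDTruth(nanoclusters=ncs))
    return SyntheticScene(field_width=config.field_width_nm,
                          field_height=config.field_height_nm,
                          psds=psds, rng_seed=int(seed))


# --------------------------------------------------------------------------
# raster rendering
# --------------------------------------------------------------------------

def _paint_ellipses(scene: SyntheticScene, pixel_size: float, ss: int,
                    profile: str) -> np.ndarray:
    """Supersampled raster where each NC carries total mass = molecule_count."""
    sub = pixel_size / ss
    h = int(round(scene.field_height / pixel_size)) * ss
    w = int(round(scene.field_width / pixel_size)) * ss
    img = np.zeros((h, w), dtype=np.float64)
    for nc in scene.nanoclusters:
        cx, cy = nc.centre
        a = nc.long_axis / 2.0
        b = nc.short_axis / 2.0
        # bounding box in subpixels (generous: half-diagonal)
        r = a if profile == "uniform" else a * 3.0
        x0 = max(0, int(np.floor((cx - r) / sub)))
        x1 = min(w, int(np.ceil((cx + r) / sub)) + 1)
        y0 = max(0, int(np.floor((cy - r) / sub)))
        y1 = min(h, int(np.ceil((cy + r) / sub)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = (np.arange(x0, x1) + 0.5) * sub - cx
        ys = (np.arange(y0, y1) + 0.5) * sub - cy
        dx, dy = np.meshgrid(xs, ys)
        ct, st = np.cos(nc.orientation), np.sin(nc.orientation)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        q2 = u * u + v * v
        if profile == "uniform":
            mask = q2 <= 1.0
            n_in = mask.sum()
            if n_in == 0:  # sub-subpixel NC: dump mass into nearest subpixel
                iy = min(h - 1, max(0, int(cy / sub)))
                ix = min(w - 1, max(0, int(cx / sub)))
                img[iy, ix] += nc.molecule_count
                continue
            img[y0:y1, x0:x1][mask] += nc.molecule_count / n_in
        else:  # gaussian profile with the ellipse axes as 2-sigma extents
            g = np.exp(-2.0 * q2)
            img[y0:y1, x0:x1] += nc.molecule_count * g / g.sum()
    return img


def render_image(scene: SyntheticScene, psf_fwhm: float, pixel_size: float,
                 noise: dict | None = None, *, supersample: int = 4,
                 nc_profile: str = "uniform", channel: str = "",
                 seed: int | None = None) -> RenderedImage:
    """Render a scene through an isotropic Gaussian PSF onto a pixel grid.

    Each NC is a uniform-intensity filled ellipse (or a Gaussian profile) whose
    integrated intensity equals its ``molecule_count``; the PSF is normalised
    to unit mass so the noiseless image conserves total intensity.
    ``psf_fwhm = 0`` skips the blur entirely.

    Parameters
    ----------
    noise:
        ``None`` for a noiseless render, else a mapping with optional keys
        ``poisson_gain`` (photons per intensity unit; shot noise) and
        ``gaussian_read_sigma`` (additive read noise in intensity units).
    seed:
        Required when ``noise`` requests any stochastic corruption.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if psf_fwhm < 0:
        raise ValueError("psf_fwhm must be >= 0")
    ss = int(supersample)
    img = _paint_ellipses(scene, pixel_size, ss, nc_profile)
    if psf_fwhm > 0:
        sigma_px = fwhm_to_sigma(psf_fwhm) / (pixel_size / ss)
        img = ndimage.gaussian_filter(img, sigma=sigma_px, mode="constant")
    # bin down: sum over ss x ss blocks preserves total mass
    h, w = img.shape
    img = img.reshape(h // ss, ss, w // ss, ss).sum(axis=(1, 3))

    if noise:
        gain = float(noise.get("poisson_gain", 0.0))
        read = float(noise.get("gaussian_read_sigma", 0.0))
        if gain > 0 or read > 0:
            if seed is None:
                raise ValueError("noisy rendering requires a seed")
            rng = np.random.default_rng(seed)
            if gain > 0:
                img = rng.poisson(np.clip(img, 0, None) * gain).astype(np.float64) / gain
            if read > 0:
                img = img + rng.normal(0.0, read, size=img.shape)
    return RenderedImage(data=img, pixel_size=float(pixel_size), channel=channel,
                         meta={"psf_fwhm": float(psf_fwhm)})


def render_scene_pair(scene: SyntheticScene, config: SimulationConfig,
                      seed: int | None = None) -> tuple[RenderedImage, RenderedImage]:
    """Convenience: registered (confocal, STED) channel pair of one scene."""
    noise = None
    if config.noise_poisson_gain > 0 or config.noise_gaussian_read_sigma > 0:
        noise = {"poisson_gain": config.noise_poisson_gain,
                 "gaussian_read_sigma": config.noise_gaussian_read_sigma}
        if seed is None:
            raise ValueError("config requests noise; pass a seed")
    confocal = render_image(scene, config.psf_fwhm_confocal, config.pixel_size,
                            noise=noise, supersample=config.supersample,
                            nc_profile=config.nc_profile, channel="confocal",
                            seed=None if seed is None else seed * 2 + 1)
    sted = render_image(scene, config.psf_fwhm_sted, config.pixel_size,
                        noise=noise, supersample=config.supersample,
                        nc_profile=config.nc_profile, channel="sted",
                        seed=None if seed is None else seed * 2 + 2)
    return confocal, sted


# --------------------------------------------------------------------------
# localisation-table rendering (PALM-like)
# --------------------------------------------------------------------------

def _uniform_in_ellipse(nc: NanoclusterTruth, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """n points uniform in the NC's ellipse, shape (n, 2) in nm."""
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    u = r * np.cos(phi) * nc.long_axis / 2.0
    v = r * np.sin(phi) * nc.short_axis / 2.0
    ct, st = np.cos(nc.orientation), np.sin(nc.orientation)
    x = nc.centre[0] + u * ct - v * st
    y = nc.centre[1] + u * st + v * ct
    return np.column_stack([x, y])


def simulate_palm(scene: SyntheticScene, config: SimulationConfig,
                  seed: int) -> pd.DataFrame:
    """Simulate a single-molecule localisation table for a scene.

    Per NC, ``Poisson(localisations_per_nc)`` events are drawn uniformly
    inside the NC ellipse and displaced by isotropic Gaussian localisation
    error with ``sigma = precision / 2.355`` (precision quoted as a FWHM-like
    width).  Uniform false localisations are added at ``background_rate`` per
    um^2.  Every event carries its true parent NC id (-1 for background) for
    recovery scoring.

    Returns a DataFrame with columns
    ``x_nm, y_nm, frame, precision_nm, intensity, truth_nc_id``.
    """
    rng = np.random.default_rng(seed)
    sigma = config.localisation_precision / 2.355
    rows_xy, rows_id = [], []
    nc_id = 0
    for psd in scene.psds:
        for nc in psd.nanoclusters:
            n = int(rng.poisson(config.localisations_per_nc))
            if n > 0:
                pts = _uniform_in_ellipse(nc, n, rng)
                if sigma > 0:
                    pts = pts + rng.normal(0.0, sigma, pts.shape)
                rows_xy.append(pts)
                rows_id.append(np.full(n, nc_id, dtype=np.int64))
            nc_id += 1
    area_um2 = (scene.field_width / 1000.0) * (scene.field_height / 1000.0)
    n_bg = int(rng.poisson(config.background_rate * area_um2))
    if n_bg > 0:
        bg = np.column_stack([rng.uniform(0.0, scene.field_width, n_bg),
                              rng.uniform(0.0, scene.field_height, n_bg)])
        rows_xy.append(bg)
        rows_id.append(np.full(n_bg, -1, dtype=np.int64))
    if rows_xy:
        xy = np.concatenate(rows_xy)
        ids = np.concatenate(rows_id)
    else:
        xy = np.empty((0, 2))
        ids = np.empty(0, dtype=np.int64)
    n_ev = len(ids)
    table = pd.DataFrame({
        "x_nm": xy[:, 0] if n_ev else np.array([], dtype=float),
        "y_nm": xy[:, 1] if n_ev else np.array([], dtype=float),
        "frame": rng.integers(0, config.n_frames, n_ev),
        "precision_nm": np.full(n_ev, config.localisation_precision),
        "intensity": rng.gamma(2.0, 500.0, n_ev) if n_ev else np.array([], dtype=float),
        "truth_nc_id": ids,
    })
    # events blown outside the field by localisation error are clipped back in
    table["x_nm"] = table["x_nm"].clip(0.0, np.nextafter(scene.field_width, 0.0))
    table["y_nm"] = table["y_nm"].clip(0.0, np.nextafter(scene.field_height, 0.0))
    return table


# --------------------------------------------------------------------------
# two-channel juxtaposition fields
# --------------------------------------------------------------------------

def simulate_two_channel(scene: SyntheticScene, config: SimulationConfig,
                         seed: int, *, offset_nm: float = 200.0,
                         fraction_paired: float = 0.5,
                         unpaired_density: float = 4.0,
                         min_unpaired_clearance: float = 1_000.0,
                         punctum_fwhm: float = 300.0,
                         render: bool = True,
                         ) -> tuple[RenderedImage | None, RenderedImage | None,
                                    pd.DataFrame]:
    """Build a registered pre/post-synaptic puncta pair.

    Channel A holds the scene's PSD puncta.  A ``fraction_paired`` subset of
    them receives a channel-B punctum at the A centre plus a fixed-length
    offset in a random direction; additional unpaired B puncta (density per
    20 um^2) are dropped at least ``min_unpaired_clearance`` from every A
    centre.  Returns both rendered channels plus a truth table with the A
    centres, pairing flags, and B centres.  ``render=False`` skips the pixel
    rendering (images returned as None) for centre-based analyses.
    """
    if not 0.0 <= fraction_paired <= 1.0:
        raise ValueError("fraction_paired must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a_centres = np.array([psd.centre for psd in scene.psds], dtype=float)
    n_a = len(a_centres)
    # exactly round(fraction * n) puncta paired, so the realised pairing
    # fraction carries no binomial noise on top of the configured one
    paired = np.zeros(n_a, dtype=bool)
    paired[rng.permutation(n_a)[:int(round(fraction_paired * n_a))]] = True
    theta = rng.uniform(0.0, 2.0 * np.pi, n_a)
    b_centres = a_centres + offset_nm * np.column_stack([np.cos(theta), np.sin(theta)])
    b_list = [b_centres[paired]]
    area_um2 = (scene.field_width / 1000.0) * (scene.field_height / 1000.0)
    n_unpaired = int(rng.poisson(unpaired_density * area_um2 / 20.0))
    placed = 0
    guard = 0
    extra = []
    while placed < n_unpaired and guard < 100 * max(1, n_unpaired):
        guard += 1
        cand = np.array([rng.uniform(0, scene.field_width),
                         rng.uniform(0, scene.field_height)])
        if n_a == 0 or np.min(np.hypot(*(a_centres - cand).T)) >= min_unpaired_clearance:
            extra.append(cand)
            placed += 1
    if extra:
        b_list.append(np.array(extra))
    b_all = np.concatenate([b for b in b_list if len(b)]) if any(len(b) for b in b_list) \
        else np.empty((0, 2))

    def _point_scene(centres: np.ndarray) -> SyntheticScene:
        psds = [PSDTruth(nanoclusters=[NanoclusterTruth(
            centre=(float(x), float(y)), long_axis=2.0, short_axis=2.0,
            orientation=0.0, molecule_count=100)]) for x, y in centres]
        return SyntheticScene(scene.field_width, scene.field_height, psds, scene.rng_seed)

    img_a = img_b = None
    if render:
        img_a = render_image(_point_scene(a_centres), punctum_fwhm,
                             config.pixel_size, channel="psd")
        img_b = render_image(_point_scene(b_all), punctum_fwhm,
                             config.pixel_size, channel="presynaptic")
    truth = pd.DataFrame({
        "a_x_nm": a_centres[:, 0] if n_a else np.array([], dtype=float),
        "a_y_nm": a_centres[:, 1] if n_a else np.array([], dtype=float),
        "paired": paired if n_a else np.array([], dtype=bool),
        "b_x_nm": np.where(paired, b_centres[:, 0], np.nan) if n_a else np.array([]),
        "b_y_nm": np.where(paired, b_centres[:, 1], np.nan) if n_a else np.array([]),
    })
    truth.attrs["b_centres"] = b_all
    return img_a, img_b, truth


# --------------------------------------------------------------------------
# serialisation of ground truth
# --------------------------------------------------------------------------

def scene_to_json(scene: SyntheticScene) -> str:
    """Serialise a scene (nm coordinates) to a JSON string."""
    doc = {
        "field_width": scene.field_width,
        "field_height": scene.field_height,
        "rng_seed": scene.rng_seed,
        "psds": [{
            "nanoclusters": [asdict(nc) for nc in psd.nanoclusters],
        } for psd in scene.psds],
    }
    return json.dumps(doc, indent=1)


def scene_from_json(text: str) -> SyntheticScene:
    doc = json.loads(text)
    psds = [PSDTruth(nanoclusters=[
        NanoclusterTruth(centre=tuple(nc["centre"]), long_axis=nc["long_axis"],
                         short_axis=nc["short_axis"], orientation=nc["orientation"],
                         molecule_count=nc["molecule_count"])
        for nc in psd["nanoclusters"]]) for psd in doc["psds"]]
    return SyntheticScene(field_width=doc["field_width"],
                          field_height=doc["field_height"],
                          psds=psds, rng_seed=doc["rng_seed"])
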