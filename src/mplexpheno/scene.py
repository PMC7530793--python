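"""Ground-truthed synthetic tissue scenes and their multichannel images.

The simulator emulates the structure that drives the pipeline's analyses:

* cells with a nuclear disc and a membrane annulus, carrying per-marker
  abundances in exposure-normalized "counts" (positives calibrated to the
  20-25 count signal-balance window, nothing above 30);
* dense lymphoid hot spots (germinal-centre-like clusters, CD20-dominant
  for MP1) against a sparse background with a minimum cell separation;
* dense-region artefacts: a nonspecific CD20->CD8 co-stain inside hot spots
  (coefficient ``nu``), segmentation-level spillover of membrane signal
  between touching neighbours (coefficient ``kappa``), and masking of the
  weaker co-located membrane marker in crowded pixels;
* thickness-scaled autofluorescence (factor ``tau``) with a low-frequency
  spatial texture;
* linear mixing into filter channels with per-channel exposure times and
  Gaussian read noise.

All randomness derives from one seed fanned out to labelled substreams, so
identical configurations reproduce bit-identical scenes and images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk

from . import panels, spectral
from ._rng import substream
from .errors import ConfigurationError, GenerationError
from .image import MultichannelImage

__all__ = [
    "MarkerLevel",
    "PhenotypeProfile",
    "HotspotSpec",
    "SceneConfig",
    "SceneTruth",
    "default_profiles",
    "simulate_scene",
    "render_truth_planes",
    "mix_to_channels",
    "acquire",
]

SPARSE = "sparse"
HOTSPOT = "hotspot"

#: Calibrated positive-marker mean abundance (counts): inside the ideal
#: 20-25 signal window once annulus rasterization is averaged in.
POSITIVE_MEAN_COUNTS = 23.0
DAPI_MEAN_COUNTS = 26.0
DEFAULT_LOGNORMAL_SIGMA = 0.25


@dataclass(frozen=True)
class MarkerLevel:
    compartment: str  # "nucleus" | "membrane"
    mean_counts: float
    sigma: float = DEFAULT_LOGNORMAL_SIGMA

    def __post_init__(self) -> None:
        if self.compartment not in ("nucleus", "membrane"):
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        if self.mean_counts < 0:
            raise ConfigurationError("abundance must be nonnegative")


@dataclass
class PhenotypeProfile:
    """One cell phenotype: marker abundances plus per-context frequency."""

    label: str
    marker_levels: dict[str, MarkerLevel]
    frequency: dict[str, float]  # tissue context -> fraction of cells

    def markers(self) -> list[str]:
        return list(self.marker_levels)


def _check_frequencies(profiles: list[PhenotypeProfile]) -> None:
    contexts = set()
    for p in profiles:
        contexts.update(p.frequency)
    for ctx in contexts:
        total = sum(p.frequency.get(ctx, 0.0) for p in profiles)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"profile frequencies for context {ctx!r} sum to {total}, not 1"
            )


def default_profiles(panel: str) -> list[PhenotypeProfile]:
    """Shipped phenotype tables for the two panels.

    Every profile expresses nuclear DAPI.  Membrane markers sit on the
    membrane annulus; FOXP3 is nuclear.  Hot-spot context for MP1 is
    germinal-centre-like: dominated by CD20+ B cells with admixed T cells.
    MP1 includes a CD3-positive, CD4/CD8-null T-cell population.
    """
    panels.check_panel(panel)
    dapi = MarkerLevel("nucleus", DAPI_MEAN_COUNTS, 0.10)

    def lv(marker: str, mean: float = POSITIVE_MEAN_COUNTS) -> MarkerLevel:
        return MarkerLevel(panels.MARKER_COMPARTMENT[marker], mean)

    if panel == panels.MP1:
        rows = [
            ("negative", {}, {SPARSE: 0.30, HOTSPOT: 0.05}),
            ("CK+", {"CK": lv("CK")}, {SPARSE: 0.25, HOTSPOT: 0.00}),
            ("CD3+/CD4+", {"CD3": lv("CD3"), "CD4": lv("CD4")}, {SPARSE: 0.18, HOTSPOT: 0.15}),
            ("CD3+/CD8+", {"CD3": lv("CD3"), "CD8": lv("CD8")}, {SPARSE: 0.12, HOTSPOT: 0.10}),
            ("CD3+", {"CD3": lv("CD3")}, {SPARSE: 0.05, HOTSPOT: 0.05}),
            ("CD20+", {"CD20": lv("CD20")}, {SPARSE: 0.10, HOTSPOT: 0.65}),
        ]
    else:
        rows = [
            ("negative", {}, {SPARSE: 0.30, HOTSPOT: 0.10}),
            ("CK+", {"CK": lv("CK")}, {SPARSE: 0.25, HOTSPOT: 0.05}),
            ("CD68+", {"CD68": lv("CD68")}, {SPARSE: 0.15, HOTSPOT: 0.15}),
            ("CD4+", {"CD4": lv("CD4")}, {SPARSE: 0.15, HOTSPOT: 0.30}),
            ("CD4+/FOXP3+", {"CD4": lv("CD4"), "FOXP3": lv("FOXP3")}, {SPARSE: 0.10, HOTSPOT: 0.25}),
            ("FOXP3+", {"FOXP3": lv("FOXP3")}, {SPARSE: 0.05, HOTSPOT: 0.15}),
        ]
    profiles = [
        PhenotypeProfile(label, {"DAPI": dapi, **levels}, dict(freq))
        for label, levels, freq in rows
    ]
    _check_frequencies(profiles)
    return profiles


@dataclass(frozen=True)
class HotspotSpec:
    count: int = 1
    radius_px: float = 55.0
    density_multiplier: float = 4.0
    # phenotype mix inside hot spots comes from the profiles' HOTSPOT frequencies


@dataclass
class SceneConfig:
    panel: str = panels.MP1
    shape: tuple[int, int] = (512, 512)
    n_cells: int = 300
    hotspots: HotspotSpec | None = None
    nu: float = 0.0  # nonspecific CD20->CD8 co-stain inside hot spots
    kappa: float = 0.0  # neighbour spillover / masking coefficient
    tau: float = 1.0  # tissue-thickness factor scaling autofluorescence
    exposures_ms: dict[str, float] | None = None  # channel -> ms (None: defaults)
    noise_sigma: float = 0.0  # read-noise sd per sqrt(ms)
    seed: int = 0
    nucleus_radius_range: tuple[int, int] = (4, 7)
    membrane_width_px: int = 2
    min_separation_px: float = 20.0
    af_baseline_counts: float = 2.0
    af_texture_amplitude: float = 0.8
    af_texture_scale_px: float = 40.0

    def __post_init__(self) -> None:
        panels.check_panel(self.panel)
        if self.tau < 0:
            raise ConfigurationError("tau must be >= 0")
        for name, v in (("kappa", self.kappa), ("nu", self.nu)):
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.hotspots is not None:
            margin = 2.0 * (self.hotspots.radius_px + 10.0)
            if margin > min(self.shape):
                raise ConfigurationError("hotspot radius does not fit in the image")

    def to_json(self) -> str:
        d = asdict(self)
        d["hotspots"] = asdict(self.hotspots) if self.hotspots else None
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SceneTruth:
    """Simulated cells: geometry, context, phenotype and true abundances.

    ``cells`` columns: id, y, x, radius, phenotype, context, and one
    ``ab_<marker>`` column per panel marker (0 where not expressed).
    """

    cells: pd.DataFrame
    panel: str
    hotspot_centres: list[tuple[float, float, float]] = field(default_factory=list)  # (y, x, r)

    def __post_init__(self) -> None:
        if len(self.cells) and self.cells["id"].duplicated().any():
            raise ConfigurationError("cell ids must be unique")

    @property
    def markers(self) -> list[str]:
        return [c[3:] for c in self.cells.columns if c.startswith("ab_")]

    def abundance(self, marker: str) -> np.ndarray:
        return self.cells[f"ab_{marker}"].to_numpy()

    def write_csv(self, path, config: SceneConfig | None = None) -> None:
        self.cells.to_csv(path, index=False)
        if config is not None:
            sidecar = str(path) + ".config.json"
            with open(sidecar, "w") as fh:
                fh.write(config.to_json())


def _truth_columns(markers: list[str]) -> list[str]:
    return ["id", "y", "x", "radius", "phenotype", "context"] + [f"ab_{m}" for m in markers]


def simulate_scene(config: SceneConfig, profiles: list[PhenotypeProfile] | None = None) -> SceneTruth:
    """Place cells (dense inside hot spots, min-separated outside), assign
    phenotypes by context, and draw per-cell marker abundances."""
    if profiles is None:
        profiles = default_profiles(config.panel)
    _check_frequencies(profiles)
    markers = panels.panel_markers(config.panel)
    for p in profiles:
        for m in p.marker_levels:
            if m not in markers:
                raise ConfigurationError(f"profile {p.label!r} uses marker {m!r} not in panel")

    H, W = config.shape
    if config.n_cells == 0:
        return SceneTruth(pd.DataFrame(columns=_truth_columns(markers)), config.panel)

    rng_place = substream(config.seed, "placement")
    rng_pheno = substream(config.seed, "phenotypes")
    rng_ab = substream(config.seed, "abundances")

    r_lo, r_hi = config.nucleus_radius_range
    margin = r_hi + config.membrane_width_px + 1

    # hot-spot centres: mutually separated, away from borders
    centres: list[tuple[float, float, float]] = []
    if config.hotspots is not None and config.hotspots.count > 0:
        hr = config.hotspots.radius_px
        for _ in range(config.hotspots.count):
            for _attempt in range(2000):
                cy = rng_place.uniform(hr + margin, H - hr - margin)
                cx = rng_place.uniform(hr + margin, W - hr - margin)
                if all(np.hypot(cy - y0, cx - x0) >= 2 * hr + 20 for y0, x0, _ in centres):
                    centres.append((cy, cx, hr))
                    break
            else:
                raise GenerationError("could not place non-overlapping hot spots")

    hot_area = sum(np.pi * r * r for _, _, r in centres)
    sparse_area = H * W - hot_area
    mult = config.hotspots.density_multiplier if config.hotspots else 1.0
    w_hot = mult * hot_area
    n_hot = int(round(config.n_cells * w_hot / (w_hot + sparse_area))) if hot_area else 0
    n_sparse = config.n_cells - n_hot
    sep_hot = config.min_separation_px / np.sqrt(max(mult, 1.0))

    def in_hotspot(y: float, x: float) -> bool:
        return any(np.hypot(y - cy, x - cx) <= r for cy, cx, r in centres)

    ys, xs, contexts = [], [], []
    placed = np.empty((0, 2))

    def place(n: int, sampler, sep: float, where: str) -> None:
        nonlocal placed
        attempts_budget = 400 * max(n, 1)
        done = 0
        while done < n:
            if attempts_budget <= 0:
                raise GenerationError(
                    f"cannot place {n} cells at min separation {sep:.1f}px in "
                    f"{where} region; density infeasible"
                )
            attempts_budget -= 1
            y, x = sampler()
            want_hot = where == HOTSPOT
            if in_hotspot(y, x) != want_hot:
                continue
            if len(placed):
                d = np.min(np.hypot(placed[:, 0] - y, placed[:, 1] - x))
                # local separation: the stricter (sparse) radius applies to
                # sparse placements; hot-spot placements use the reduced one
                if d < sep:
                    continue
            ys.append(y)
            xs.append(x)
            contexts.append(where)
            placed = np.vstack([placed, [y, x]])
            done += 1

    def sample_sparse():
        return (
            rng_place.uniform(margin, H - margin),
            rng_place.uniform(margin, W - margin),
        )

    def sample_hot():
        i = rng_place.integers(len(centres))
        cy, cx, r = centres[i]
        rad = r * np.sqrt(rng_place.uniform())
        ang = rng_place.uniform(0, 2 * np.pi)
        return cy + rad * np.sin(ang), cx + rad * np.cos(ang)

    if n_hot:
        place(n_hot, sample_hot, sep_hot, HOTSPOT)
    place(n_sparse, sample_sparse, config.min_separation_px, SPARSE)

    n = len(ys)
    radii = rng_place.integers(r_lo, r_hi + 1, size=n)

    # phenotype per cell by context frequency
    labels = np.empty(n, dtype=object)
    by_ctx = {}
    for ctx in (HOTSPOT, SPARSE):
        probs = np.array([p.frequency.get(ctx, 0.0) for p in profiles])
        by_ctx[ctx] = probs
    prof_labels = [p.label for p in profiles]
    for i in range(n):
        labels[i] = rng_pheno.choice(prof_labels, p=by_ctx[contexts[i]])

    prof_by_label = {p.label: p for p in profiles}
    ab = {m: np.zeros(n) for m in markers}
    for i in range(n):
        prof = prof_by_label[labels[i]]
        for m, level in prof.marker_levels.items():
            z = rng_ab.standard_normal()
            # lognormal with the stated mean: E[a] = mean_counts
            ab[m][i] = level.mean_counts * np.exp(level.sigma * z - level.sigma**2 / 2)

    cells = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "y": ys,
            "x": xs,
            "radius": radii,
            "phenotype": labels,
            "context": contexts,
            **{f"ab_{m}": ab[m] for m in markers},
        }
    )
    return SceneTruth(cells, config.panel, centres)


# ---------------------------------------------------------------------------
# rendering


def _cell_geometry(truth: SceneTruth, config: SceneConfig, scale: float):
    H = int(round(config.shape[0] * scale))
    W = int(round(config.shape[1] * scale))
    width = config.membrane_width_px * scale
    nuclei, annuli = [], []
    for row in truth.cells.itertuples():
        c = (row.y * scale, row.x * scale)
        r = row.radius * scale
        nuc = draw_disk(c, r + 0.5, shape=(H, W))
        outer = draw_disk(c, r + width + 0.5, shape=(H, W))
        inner = set(zip(nuc[0].tolist(), nuc[1].tolist()))
        ann_mask = [
            (yy, xx) for yy, xx in zip(outer[0].tolist(), outer[1].tolist()) if (yy, xx) not in inner
        ]
        ann = (
            np.array([p[0] for p in ann_mask], dtype=int),
            np.array([p[1] for p in ann_mask], dtype=int),
        )
        nuclei.append(nuc)
        annuli.append(ann)
    return (H, W), nuclei, annuli


def _ownership(shape, pixel_sets, centres):
    """Assign contested pixels to the nearest cell centroid (lower id wins ties)."""
    owner = np.full(shape, -1, dtype=int)
    best = np.full(shape, np.inf)
    coverage = np.zeros(shape, dtype=np.int16)
    for i, (yy, xx) in enumerate(pixel_sets):
        if len(yy) == 0:
            continue
        coverage[yy, xx] += 1
        cy, cx = centres[i]
        d = (yy - cy) ** 2 + (xx - cx) ** 2
        closer = d < best[yy, xx]
        owner[yy[closer], xx[closer]] = i
        best[yy[closer], xx[closer]] = d[closer]
    return owner, coverage


def render_truth_planes(
    truth: SceneTruth,
    config: SceneConfig,
    scale: float = 1.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Paint per-marker abundance planes and the autofluorescence plane.

    Nuclear markers fill the nucleus disc; membrane markers fill the annulus.
    Where annuli of neighbouring cells touch, each contested pixel belongs to
    the nearest centroid, the weaker co-located membrane markers at crowded
    pixels are attenuated by (1 - kappa/2) (steric masking), and every cell
    whose annulus overlaps a neighbour's receives that neighbour's membrane
    abundances at weight kappa over its own annulus (segmentation-level
    spillover).  Inside hot spots the CD8 plane additionally receives
    nu x the CD20 plane (nonspecific co-stain).  The autofluorescence plane
    is tau x (baseline + low-frequency texture), so it scales exactly
    linearly with section thickness.
    """
    markers = panels.panel_markers(config.panel)
    (H, W), nuclei, annuli = _cell_geometry(truth, config, scale)
    planes = {m: np.zeros((H, W)) for m in markers}
    n = len(truth.cells)
    compart = panels.MARKER_COMPARTMENT
    membrane_markers = [m for m in markers if compart[m] == "membrane"]

    if n:
        centres = [(row.y * scale, row.x * scale) for row in truth.cells.itertuples()]
        nuc_owner, _ = _ownership((H, W), nuclei, centres)
        ann_owner, ann_cov = _ownership((H, W), annuli, centres)
        ab = {m: truth.abundance(m) for m in markers}

        own_pixels = []
        for i in range(n):
            yy, xx = annuli[i]
            if len(yy):
                keep = ann_owner[yy, xx] == i
                own_pixels.append((yy[keep], xx[keep]))
            else:
                own_pixels.append((yy, xx))

        for m in markers:
            vals = ab[m]
            plane = planes[m]
            for i in range(n):
                if vals[i] <= 0:
                    continue
                if compart[m] == "nucleus":
                    yy, xx = nuclei[i]
                    keep = nuc_owner[yy, xx] == i
                    plane[yy[keep], xx[keep]] += vals[i]
                else:
                    yy, xx = own_pixels[i]
                    plane[yy, xx] += vals[i]

        # steric masking: at crowded pixels the weaker membrane markers lose
        # (kappa/2) of their signal to the dominant one
        if config.kappa > 0 and membrane_markers:
            crowded = np.where(ann_cov >= 2)
            if len(crowded[0]):
                stack = np.stack([planes[m][crowded] for m in membrane_markers])
                dominant = np.argmax(stack, axis=0)
                atten = np.full(stack.shape, 1.0 - config.kappa / 2.0)
                atten[dominant, np.arange(stack.shape[1])] = 1.0
                stack *= atten
                for k, m in enumerate(membrane_markers):
                    planes[m][crowded] = stack[k]

        # spillover: overlapping neighbours contaminate each other's annulus
        if config.kappa > 0 and n > 1:
            pts = np.array(centres)
            radii = truth.cells["radius"].to_numpy() * scale
            reach = radii + config.membrane_width_px * scale
            tree = cKDTree(pts)
            pairs = tree.query_pairs(r=2 * reach.max(), output_type="ndarray")
            for i, j in pairs:
                d = np.hypot(*(pts[i] - pts[j]))
                if d >= reach[i] + reach[j]:
                    continue
                for a_idx, b_idx in ((i, j), (j, i)):
                    yy, xx = own_pixels[a_idx]
                    if not len(yy):
                        continue
                    for m in membrane_markers:
                        contrib = ab[m][b_idx]
                        if contrib > 0:
                            planes[m][yy, xx] += config.kappa * contrib

        # nonspecific CD20->CD8 co-stain inside hot spots
        if config.nu > 0 and "CD8" in planes and "CD20" in planes and truth.hotspot_centres:
            mask = np.zeros((H, W), dtype=bool)
            for cy, cx, r in truth.hotspot_centres:
                yy, xx = draw_disk((cy * scale, cx * scale), r * scale, shape=(H, W))
                mask[yy, xx] = True
            planes["CD8"][mask] += config.nu * planes["CD20"][mask]

    af = np.full((H, W), float(config.af_baseline_counts))
    if config.af_texture_amplitude > 0:
        rng = substream(config.seed, "af-texture")
        noise = rng.standard_normal((H, W))
        smooth = gaussian_filter(noise, sigma=config.af_texture_scale_px * scale)
        lo, hi = smooth.min(), smooth.max()
        if hi > lo:
            af = af + config.af_texture_amplitude * (smooth - lo) / (hi - lo)
    af = config.tau * af
    return planes, af


# ---------------------------------------------------------------------------
# mixing into acquisition channels


def mix_to_channels(
    planes: dict[str, np.ndarray],
    af_plane: np.ndarray,
    library: spectral.SpectralLibrary,
    filters: spectral.FilterSet,
    exposures_ms: dict[str, float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    marker_fluorophores: dict[str, str] | None = None,
) -> MultichannelImage:
    """Linear forward model: channel c = sum_f A0[c,f] * abundance_f * exposure_c
    plus Gaussian read noise with sd = noise_sigma * sqrt(exposure_c), clipped
    at zero.  ``planes`` is keyed by marker; ``marker_fluorophores`` maps each
    marker onto its paired fluorophore (identity if omitted)."""
    if marker_fluorophores is None:
        marker_fluorophores = {m: m for m in planes}
    fluors = library.fluorophore_names
    for m in planes:
        if m not in marker_fluorophores:
            raise ConfigurationError(f"marker {m!r} has no fluorophore assignment")
        if marker_fluorophores[m] not in fluors:
            raise ConfigurationError(
                f"fluorophore {marker_fluorophores[m]!r} for marker {m!r} not in library"
            )
    shape = af_plane.shape
    fluor_ab = {f: np.zeros(shape) for f in fluors}
    for m, plane in planes.items():
        fluor_ab[marker_fluorophores[m]] += plane

    A0 = spectral.sensing_matrix(library, filters)  # unit exposure
    channels = filters.channels
    expo = np.array([exposures_ms[c] for c in channels], dtype=float)
    names = library.endmember_names
    stack = np.zeros((len(channels), *shape))
    for j, name in enumerate(names):
        ab = af_plane if name == spectral.AF_NAME else fluor_ab[name]
        stack += A0[:, j][:, None, None] * ab[None, :, :]
    stack *= expo[:, None, None]
    if noise_sigma > 0:
        rng = substream(seed, "read-noise")
        sd = noise_sigma * np.sqrt(expo)
        stack = stack + sd[:, None, None] * rng.standard_normal(stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return MultichannelImage(stack, channels, {c: float(e) for c, e in zip(channels, expo)})


def acquire(
    truth: SceneTruth,
    config: SceneConfig,
    library: spectral.SpectralLibrary | None = None,
    filters: spectral.FilterSet | None = None,
    scale: float = 1.0,
) -> MultichannelImage:
    """Render and mix a scene with the panel's default pairings and filters."""
    if filters is None:
        filters = spectral.motif7()
    pairing = panels.panel_fluorophores(config.panel)
    if library is None:
        library = spectral.synthetic_library(sorted(set(pairing.values()), key=list(spectral.NOMINAL_PEAKS_NM).index))
    exposures = config.exposures_ms or panels.default_exposures(filters.channels)
    planes, af = render_truth_planes(truth, config, scale=scale)
    return mix_to_channels(
        planes,
        af,
        library,
        filters,
        exposures,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
        marker_fluorophores=pairing,
    )
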