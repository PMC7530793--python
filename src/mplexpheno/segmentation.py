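"""Nucleus detection on the DAPI plane, cell expansion and measurement.

Detection is the classical watershed approach: Gaussian smoothing,
global thresholding of the nuclear counterstain ("auto" uses the triangle
method, which is robust when foreground is sparse), removal of
sub-nuclear specks, then splitting of touching blobs by a watershed on the
distance transform.  Detected nuclei are expanded by a fixed radius without
crossing a neighbour's expansion to form the cell outline; the membrane
ring is the expanded cell minus its nucleus.  Per-cell mean intensities are
measured per compartment on the unmixed abundance planes, so they are in
exposure-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_triangle
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

from . import panels
from .errors import ConfigurationError, IntegrityError
from .image import UnmixedImage

__all__ = [
    "SegmentationParams",
    "detect_nuclei",
    "expand_cells",
    "measure_cells",
    "segment_and_measure",
    "match_to_truth",
]


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 1.0
    dapi_threshold: float | str = "auto"  # counts, or "auto" for triangle
    min_nucleus_area: int = 12  # px^2
    watershed_split: bool = True
    expansion_radius: int = 2  # px
    peak_min_distance: int = 5  # px between watershed seeds (~nucleus radius)

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ConfigurationError("smoothing sigma must be >= 0")
        if self.min_nucleus_area < 1:
            raise ConfigurationError("min nucleus area must be >= 1")
        if self.expansion_radius < 1:
            raise ConfigurationError("expansion radius must be >= 1")

    def scaled(self, factor: float) -> "SegmentationParams":
        """Parameters for an image rendered at `factor` x the pixel scale."""
        return SegmentationParams(
            smoothing_sigma=self.smoothing_sigma * factor,
            dapi_threshold=self.dapi_threshold,
            min_nucleus_area=max(1, int(round(self.min_nucleus_area * factor**2))),
            watershed_split=self.watershed_split,
            expansion_radius=max(1, int(round(self.expansion_radius * factor))),
            peak_min_distance=max(1, int(round(self.peak_min_distance * factor))),
        )


def detect_nuclei(dapi_plane: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Label image of detected nuclei (0 = background). Deterministic."""
    if params is None:
        params = SegmentationParams()
    plane = np.asarray(dapi_plane, dtype=float)
    if np.any(plane < 0):
        raise ConfigurationError("DAPI plane must be nonnegative")
    if plane.max() <= 0:
        return np.zeros(plane.shape, dtype=np.int32)
    smooth = gaussian(plane, sigma=params.smoothing_sigma, preserve_range=True)
    if params.dapi_threshold == "auto":
        # triangle picks up the sparse foreground; cutting at half its mean
        # height then places the boundary at the half-maximum of the blurred
        # nuclear disc, i.e. at the true edge, instead of the blur skirt
        t0 = threshold_triangle(smooth)
        foreground = smooth[smooth > t0]
        thr = 0.5 * float(foreground.mean()) if foreground.size else t0
    else:
        thr = float(params.dapi_threshold)
    mask = smooth > thr
    if not mask.any():
        return np.zeros(plane.shape, dtype=np.int32)
    mask = remove_small_objects(mask, max_size=params.min_nucleus_area - 1)
    if not params.watershed_split:
        labels, _ = ndimage.label(mask)
        return labels.astype(np.int32)
    distance = ndimage.distance_transform_edt(mask)
    # smoothing flattens plateau ridges so each nucleus yields one seed
    seed_map = ndimage.gaussian_filter(distance, sigma=1.0)
    coords = peak_local_max(
        seed_map, min_distance=params.peak_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(plane.shape, dtype=np.int32)
    for k, (yy, xx) in enumerate(coords, start=1):
        markers[yy, xx] = k
    labels = watershed(-distance, markers, mask=mask)
    # relabel consecutively for stable ids
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new_id
    return out


def expand_cells(labels: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand nuclei into cells; return (cell labels, membrane ring labels).

    Expansion is geodesic: contested pixels go to the nearest nucleus; exact
    ties resolve deterministically. No pixel carries two labels.
    """
    if radius < 1:
        raise ConfigurationError("expansion radius must be >= 1")
    labels = np.asarray(labels)
    cells = expand_labels(labels, distance=radius)
    rings = np.where(labels > 0, 0, cells)
    return cells, rings


def measure_cells(
    cell_labels: np.ndarray,
    ring_labels: np.ndarray,
    unmixed: UnmixedImage,
    marker_fluorophores: dict[str, str],
) -> pd.DataFrame:
    """Per-cell per-marker mean counts in nucleus, membrane ring, whole cell.

    Column naming is stable: ``<marker>_<compartment>_mean`` with
    compartment in {nucleus, membrane, cell}; the whole-cell value is the
    area-weighted mean of nucleus and ring.  Sorted by cell id.
    """
    if cell_labels.shape != unmixed.shape:
        raise ConfigurationError("label image dimensions do not match unmixed image")
    nucleus_labels = np.where(ring_labels > 0, 0, cell_labels)
    ids = np.unique(cell_labels[cell_labels > 0])
    if len(ids) == 0:
        cols = ["cell_id", "y", "x", "nucleus_area"]
        for m in marker_fluorophores:
            cols += [f"{m}_nucleus_mean", f"{m}_membrane_mean", f"{m}_cell_mean"]
        return pd.DataFrame(columns=cols)

    index = np.arange(1, ids.max() + 1)
    nuc_area = ndimage.sum_labels(np.ones_like(cell_labels), nucleus_labels, index=index)
    ring_area = ndimage.sum_labels(np.ones_like(cell_labels), ring_labels, index=index)
    present = np.isin(index, ids)
    if np.any((nuc_area[present] == 0)):
        empty = index[present & (nuc_area == 0)]
        raise IntegrityError(f"cells {empty.tolist()} have empty nucleus masks")

    centroids = {p.label: p.centroid for p in regionprops(nucleus_labels.astype(np.int32))}
    rows: dict[str, np.ndarray] = {}
    for marker, fluor in marker_fluorophores.items():
        plane = unmixed.plane(fluor)
        nuc_sum = ndimage.sum_labels(plane, nucleus_labels, index=index)
        ring_sum = ndimage.sum_labels(plane, ring_labels, index=index)
        with np.errstate(invalid="ignore", divide="ignore"):
            nuc_mean = np.where(nuc_area > 0, nuc_sum / nuc_area, 0.0)
            ring_mean = np.where(ring_area > 0, ring_sum / ring_area, 0.0)
            cell_mean = np.where(
                nuc_area + ring_area > 0, (nuc_sum + ring_sum) / (nuc_area + ring_area), 0.0
            )
        rows[f"{marker}_nucleus_mean"] = nuc_mean
        rows[f"{marker}_membrane_mean"] = ring_mean
        rows[f"{marker}_cell_mean"] = cell_mean

    sel = present
    table = pd.DataFrame(
        {
            "cell_id": index[sel],
            "y": [centroids.get(i, (np.nan, np.nan))[0] for i in index[sel]],
            "x": [centroids.get(i, (np.nan, np.nan))[1] for i in index[sel]],
            "nucleus_area": nuc_area[sel],
            **{k: v[sel] for k, v in rows.items()},
        }
    )
    return table.sort_values("cell_id").reset_index(drop=True)


def match_to_truth(
    truth_cells: pd.DataFrame,
    measured: pd.DataFrame,
    max_dist: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Mutual-nearest-centroid matching of detected cells to ground truth.

    A pair matches when each is the other's nearest centroid and their
    distance is at most `max_dist` (default: the true cell's nucleus
    radius).  Returns a table (truth_id, cell_id, distance).
    """
    from scipy.spatial import cKDTree

    t_xy = truth_cells[["y", "x"]].to_numpy(dtype=float)
    m_xy = measured[["y", "x"]].to_numpy(dtype=float)
    if len(t_xy) == 0 or len(m_xy) == 0:
        return pd.DataFrame(columns=["truth_id", "cell_id", "distance"])
    if max_dist is None:
        max_dist = truth_cells["radius"].to_numpy(dtype=float)
    max_dist = np.broadcast_to(np.asarray(max_dist, dtype=float), (len(t_xy),))
    t_tree = cKDTree(t_xy)
    m_tree = cKDTree(m_xy)
    d_tm, nearest_m = m_tree.query(t_xy)  # for each truth, nearest measured
    _, nearest_t = t_tree.query(m_xy)  # for each measured, nearest truth
    rows = []
    for ti, (mi, d) in enumerate(zip(nearest_m, d_tm)):
        if nearest_t[mi] == ti and d <= max_dist[ti]:
            rows.append(
                {
                    "truth_id": truth_cells["id"].iloc[ti],
                    "cell_id": measured["cell_id"].iloc[mi],
                    "distance": float(d),
                }
            )
    return pd.DataFrame(rows, columns=["truth_id", "cell_id", "distance"])


def segment_and_measure(
    unmixed: UnmixedImage,
    panel: str,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Convenience: detect nuclei on DAPI, expand, measure all panel markers."""
    if params is None:
        params = SegmentationParams()
    pairing = panels.panel_fluorophores(panel)
    dapi = unmixed.plane(pairing["DAPI"])
    labels = detect_nuclei(dapi, params)
    cells, rings = expand_cells(labels, params.expansion_radius)
    return measure_cells(cells, rings, unmixed, pairing)
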