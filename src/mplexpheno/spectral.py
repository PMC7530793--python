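"""Spectral libraries, sensing matrices, unmixing and spectral QC.

The acquisition model is linear: each filter channel integrates the product
of fluorophore emission and the channel's passband over wavelength, scaled
by the channel's exposure time.  Collecting the per-fluorophore band
integrals into a sensing matrix ``A`` (channels x endmembers, with tissue
autofluorescence as one extra endmember), a pixel's raw channel vector is
``y = A @ x`` where ``x`` holds per-fluorophore abundances in counts.
Unmixing inverts this per pixel under a nonnegativity constraint
(abundances are physical concentrations), which also separates and removes
the autofluorescence contribution.

Emission curves for the tyramide-signal-amplification (Opal) dyes are not
published as tables, so a parametric stand-in is used: a Gaussian in
wavelength with unit peak at the dye's nominal emission wavelength.  A
library can instead be *measured* from singleplex-stained images (one per
fluorophore plus an autofluorescence-only slide), in which case the
channel-space signatures are estimated directly from the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import ConfigurationError, LibraryError, UnmixingError
from .image import MultichannelImage, UnmixedImage

__all__ = [
    "EmissionSpectrum",
    "SpectralLibrary",
    "FilterSet",
    "QCResult",
    "default_grid",
    "parametric_spectrum",
    "autofluorescence_spectrum",
    "synthetic_library",
    "build_library_from_singleplex",
    "standard5",
    "motif7",
    "sensing_matrix",
    "unmix",
    "crosstalk_matrix",
    "qc_autofluorescence",
]

AF_NAME = "AF"

#: Nominal emission peaks (nm).  Opal dyes are keyed by their product names;
#: the numeric part of the name is the nominal emission wavelength.
NOMINAL_PEAKS_NM = {
    "DAPI": 461.0,
    "Opal480": 480.0,
    "Opal520": 520.0,
    "Opal570": 570.0,
    "Opal620": 620.0,
    "Opal650": 650.0,
    "Opal690": 690.0,
    "Opal780": 780.0,
}

DEFAULT_FWHM_NM = {"DAPI": 60.0}
_OPAL_FWHM = 40.0


def default_grid(low: float = 400.0, high: float = 800.0, step: float = 2.0) -> np.ndarray:
    """Uniform wavelength grid in nm (default 400-800 nm, 2 nm step)."""
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


@dataclass
class EmissionSpectrum:
    """Relative emission intensity on a uniform ascending wavelength grid."""

    name: str
    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ConfigurationError("wavelength grid and intensities must align")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ConfigurationError("wavelength grid must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ConfigurationError("intensities must be nonnegative")
        peak = self.intensities.max()
        if peak <= 0:
            raise ConfigurationError(f"spectrum {self.name!r} is identically zero")
        self.intensities = self.intensities / peak  # unit maximum

    def band_integral(self, low_nm: float, high_nm: float) -> float:
        """Trapezoid integral of the spectrum over [low_nm, high_nm]."""
        wl, it = self.wavelengths_nm, self.intensities
        inside = (wl >= low_nm) & (wl <= high_nm)
        if not inside.any():
            return 0.0
        return float(np.trapezoid(it[inside], wl[inside]))


def parametric_spectrum(
    name: str,
    peak_nm: float,
    fwhm_nm: float,
    grid: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Gaussian emission curve with unit peak at `peak_nm`."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if fwhm_nm <= 0:
        raise ConfigurationError("fwhm must be positive")
    if not (grid[0] <= peak_nm <= grid[-1]):
        raise ConfigurationError(f"peak {peak_nm} nm outside grid [{grid[0]}, {grid[-1]}]")
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    curve = np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    return EmissionSpectrum(name, grid, curve)


def autofluorescence_spectrum(grid: np.ndarray | None = None) -> EmissionSpectrum:
    """Broad formalin-fixed-tissue autofluorescence stand-in.

    FFPE autofluorescence is spectrally wide and featureless relative to the
    dyes; a single wide Gaussian centred in the green is used, matching the
    single "representative" spectrum approach of the subtraction step.
    """
    if grid is None:
        grid = default_grid()
    return parametric_spectrum(AF_NAME, 530.0, 260.0, grid)


@dataclass
class SpectralLibrary:
    """Fluorophore endmembers plus one autofluorescence endmember.

    Two provenances exist: a *synthetic* library holds parametric emission
    spectra; a *measured* library holds channel-space signatures estimated
    from singleplex images (exposure-free, unit-maximum vectors tied to a
    specific filter set).
    """

    spectra: list[EmissionSpectrum] = field(default_factory=list)
    autofluorescence: EmissionSpectrum | None = None
    provenance: str = "synthetic"
    # measured-library representation
    signatures: dict[str, np.ndarray] | None = None
    signature_channels: list[str] | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = self.fluorophore_names
        if len(set(names)) != len(names):
            raise ConfigurationError("fluorophore names must be unique")
        if len(self.endmember_names) < 2:
            raise ConfigurationError("library needs at least two members")

    @property
    def fluorophore_names(self) -> list[str]:
        if self.signatures is not None:
            return [n for n in self.signatures if n != AF_NAME]
        return [s.name for s in self.spectra]

    @property
    def endmember_names(self) -> list[str]:
        return self.fluorophore_names + [AF_NAME]


def synthetic_library(
    fluorophores: list[str],
    grid: np.ndarray | None = None,
    fwhm_nm: float | dict[str, float] | None = None,
) -> SpectralLibrary:
    """Parametric library for named fluorophores (DAPI and Opal dyes)."""
    if grid is None:
        grid = default_grid()
    spectra = []
    for name in fluorophores:
        if name not in NOMINAL_PEAKS_NM:
            raise ConfigurationError(f"unknown fluorophore {name!r}")
        if isinstance(fwhm_nm, dict):
            width = fwhm_nm.get(name, DEFAULT_FWHM_NM.get(name, _OPAL_FWHM))
        elif fwhm_nm is not None:
            width = fwhm_nm
        else:
            width = DEFAULT_FWHM_NM.get(name, _OPAL_FWHM)
        spectra.append(parametric_spectrum(name, NOMINAL_PEAKS_NM[name], width, grid))
    return SpectralLibrary(
        spectra=spectra,
        autofluorescence=autofluorescence_spectrum(grid),
        provenance="synthetic",
    )


# ---------------------------------------------------------------------------
# filter sets


@dataclass
class FilterSet:
    """Named acquisition passbands; bands may overlap across channels."""

    name: str
    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for ch, (low, high) in self.bands.items():
            if low >= high:
                raise ConfigurationError(f"band {ch!r}: low must be < high")

    @property
    def channels(self) -> list[str]:
        return list(self.bands)


def standard5() -> FilterSet:
    """The five standard epifluorescence filters."""
    return FilterSet(
        "standard-5",
        {
            "DAPI": (417.0, 477.0),
            "FITC": (490.0, 550.0),
            "Cy3": (550.0, 610.0),
            "TexasRed": (600.0, 660.0),
            "Cy5": (650.0, 720.0),
        },
    )


def motif7() -> FilterSet:
    """Seven-colour whole-slide unmixing filters with spectrally distant bands."""
    return FilterSet(
        "motif-7",
        {
            "DAPI": (435.0, 485.0),
            "Opal480": (465.0, 505.0),
            "Opal520": (505.0, 545.0),
            "Opal570": (550.0, 590.0),
            "Opal620": (600.0, 640.0),
            "Opal690": (670.0, 710.0),
            "Opal780": (760.0, 800.0),
        },
    )


def filterset_by_name(name: str) -> FilterSet:
    if name in ("standard-5", "standard5"):
        return standard5()
    if name in ("motif-7", "motif7"):
        return motif7()
    raise ConfigurationError(f"unknown filter set {name!r}")


# ---------------------------------------------------------------------------
# sensing matrix


def sensing_matrix(
    library: SpectralLibrary,
    filters: FilterSet,
    exposures_ms: dict[str, float] | None = None,
) -> np.ndarray:
    """(channels x endmembers) acquisition matrix.

    Entry [c, f] is the band integral of endmember f's emission over channel
    c's passband, multiplied by channel c's exposure (1 ms if omitted).
    Column order is ``library.endmember_names`` (autofluorescence last).
    Records a warning on the library if the result is rank-deficient.
    """
    channels = filters.channels
    names = library.endmember_names
    A = np.zeros((len(channels), len(names)))
    if library.signatures is not None:
        if library.signature_channels != channels:
            raise ConfigurationError(
                "measured library signatures were estimated for a different filter set"
            )
        for j, name in enumerate(names):
            A[:, j] = library.signatures[name]
    else:
        members = {s.name: s for s in library.spectra}
        members[AF_NAME] = library.autofluorescence
        for j, name in enumerate(names):
            spec = members[name]
            for i, ch in enumerate(channels):
                low, high = filters.bands[ch]
                A[i, j] = spec.band_integral(low, high)
    if exposures_ms is not None:
        expo = np.array([exposures_ms[c] for c in channels], dtype=float)
        A = A * expo[:, None]
    if np.linalg.matrix_rank(A) < A.shape[1]:
        msg = f"sensing matrix rank-deficient for filter set {filters.name!r}"
        if msg not in library.warnings:
            library.warnings.append(msg)
    return A


# ---------------------------------------------------------------------------
# unmixing


def _nnls_rows(A: np.ndarray, Y: np.ndarray, X: np.ndarray, tol: float) -> np.ndarray:
    """Replace rows of the unconstrained solution X that went negative."""
    bad = np.where(X.min(axis=1) < -tol)[0]
    for i in bad:
        X[i], _ = scipy.optimize.nnls(A, Y[i])
    X[X < 0] = 0.0
    return X


def unmix(
    image: MultichannelImage,
    library: SpectralLibrary,
    filters: FilterSet,
) -> UnmixedImage:
    """Per-pixel nonnegative least-squares unmixing with AF separation.

    Exposure times are part of the sensing matrix, so the solution is
    expressed directly in exposure-normalized counts.  The unconstrained
    least-squares solution is used wherever it is already nonnegative (the
    two coincide in that case); pixels with negative components are re-solved
    under the nonnegativity constraint.
    """
    if image.channel_names != filters.channels:
        raise UnmixingError(
            f"image channels {image.channel_names} do not match filter set "
            f"{filters.channels}"
        )
    A = sensing_matrix(library, filters, image.exposures_ms)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise UnmixingError("sensing matrix is rank-deficient; unmixing is ill-posed")
    names = library.endmember_names
    C, H, W = image.planes.shape
    Y = image.planes.reshape(C, -1).T  # (N, C)
    X = Y @ np.linalg.pinv(A).T  # (N, endmembers)
    scale = max(float(np.abs(X).max()), 1.0)
    X = _nnls_rows(A, Y, X, tol=1e-9 * scale)
    X[X < 1e-9 * scale] = 0.0  # snap numerical dust to exact zero
    resid = Y - X @ A.T
    expo = image.exposure_vector
    residual = np.sqrt(((resid / expo) ** 2).sum(axis=1)).reshape(H, W)
    abundances = {
        name: X[:, j].reshape(H, W) for j, name in enumerate(names) if name != AF_NAME
    }
    af = X[:, names.index(AF_NAME)].reshape(H, W)
    return UnmixedImage(
        abundances=abundances,
        autofluorescence=af,
        residual=residual,
        meta={"library_provenance": library.provenance, "filters": filters.name},
    )


# ---------------------------------------------------------------------------
# measured library construction


def build_library_from_singleplex(
    singleplex_images: dict[str, MultichannelImage],
    autofluorescence_image: MultichannelImage,
    filters: FilterSet,
    top_quantile: float = 0.98,
) -> SpectralLibrary:
    """Estimate channel-space signatures from single-fluorophore slides.

    For each fluorophore the mean channel vector over the brightest pixel
    quantile is taken, the autofluorescence contribution (estimated from the
    dim background pixels of the same slide) is subtracted, exposures are
    divided out, and the result is normalized to unit maximum.  The
    autofluorescence signature comes from the no-stain slide the same way.
    """

    def _exposure_free(img: MultichannelImage) -> np.ndarray:
        if img.channel_names != filters.channels:
            raise ConfigurationError("singleplex image channels must match filter set")
        return (img.planes.reshape(len(img.channel_names), -1).T) / img.exposure_vector

    def _top_mean(vectors: np.ndarray, q: float) -> np.ndarray:
        norms = np.linalg.norm(vectors, axis=1)
        cut = np.quantile(norms, q)
        sel = vectors[norms >= cut]
        return sel.mean(axis=0)

    af_vectors = _exposure_free(autofluorescence_image)
    af_sig = _top_mean(af_vectors, top_quantile)
    if not np.any(af_sig > 0):
        raise LibraryError("autofluorescence image is degenerate (all zeros)")

    signatures: dict[str, np.ndarray] = {}
    for name, img in singleplex_images.items():
        vectors = _exposure_free(img)
        norms = np.linalg.norm(vectors, axis=1)
        if norms.max() <= 0:
            raise LibraryError(f"singleplex image for {name!r} is degenerate (all zeros)")
        bright = _top_mean(vectors, top_quantile)
        # background = pixels below the median norm: fluorophore-free, AF only
        background = vectors[norms <= np.quantile(norms, 0.5)].mean(axis=0)
        sig = bright - background
        sig[sig < 0] = 0.0
        if sig.max() <= 0:
            raise LibraryError(f"no fluorophore signal above background for {name!r}")
        signatures[name] = sig / sig.max()
    signatures[AF_NAME] = af_sig / af_sig.max()
    return SpectralLibrary(
        provenance="measured",
        signatures=signatures,
        signature_channels=filters.channels,
    )


# ---------------------------------------------------------------------------
# crosstalk and QC


def crosstalk_matrix(
    singleplex_scenes: dict[str, MultichannelImage],
    library: SpectralLibrary,
    filters: FilterSet,
    normalize: bool = True,
    support_fraction: float = 0.05,
):
    """Fluorophore-to-fluorophore signal leakage under a given library.

    Entry [f, g] is the total abundance assigned to g in the singleplex
    scene where only f is stained, normalized (by default) by the total
    assigned to f itself; the diagonal is then 1 by definition.  Totals are
    accumulated over the stained-pixel support — pixels whose own-fluorophore
    abundance exceeds `support_fraction` of its maximum — so the statistic
    measures misassignment of real signal rather than the background noise
    floor.  Rows for empty scenes (no abundance assigned to the scene's own
    fluorophore) are left NaN-flagged under normalization.  With
    ``normalize=False`` the raw totals are returned (the dropout-control
    reading: an unstained fluorophore's row totals sit at noise level).
    """
    import pandas as pd

    fluors = library.fluorophore_names
    mat = pd.DataFrame(np.full((len(fluors), len(fluors)), np.nan), index=fluors, columns=fluors)
    for f, img in singleplex_scenes.items():
        if f not in fluors:
            raise ConfigurationError(f"scene fluorophore {f!r} not in library")
        um = unmix(img, library, filters)
        own_plane = um.abundances[f]
        peak = own_plane.max()
        support = own_plane > support_fraction * peak if peak > 0 else np.ones_like(own_plane, bool)
        totals = {g: float(um.abundances[g][support].sum()) for g in fluors}
        own = totals[f]
        if not normalize:
            for g in fluors:
                mat.loc[f, g] = totals[g]
            continue
        if own <= 0:
            continue  # undefined row stays NaN
        for g in fluors:
            mat.loc[f, g] = totals[g] / own
        mat.loc[f, f] = 1.0
    return mat


# ---------------------------------------------------------------------------
# spectra I/O


def write_spectrum_csv(path, spectrum: EmissionSpectrum) -> None:
    """Two-column CSV: wavelength_nm, intensity."""
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum_csv(path, name: str | None = None) -> EmissionSpectrum:
    import pandas as pd
    from pathlib import Path

    df = pd.read_csv(path)
    if name is None:
        name = Path(path).stem
    return EmissionSpectrum(name, df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def library_to_json(library: SpectralLibrary) -> str:
    """Library manifest: provenance plus spectra or channel signatures."""
    import json

    payload: dict = {"provenance": library.provenance, "warnings": library.warnings}
    if library.signatures is not None:
        payload["signature_channels"] = library.signature_channels
        payload["signatures"] = {k: v.tolist() for k, v in library.signatures.items()}
    else:
        payload["spectra"] = [
            {
                "name": s.name,
                "wavelengths_nm": s.wavelengths_nm.tolist(),
                "intensities": s.intensities.tolist(),
            }
            for s in [*library.spectra, library.autofluorescence]
        ]
    return json.dumps(payload, indent=2, sort_keys=True)


def library_from_json(text: str) -> SpectralLibrary:
    import json

    payload = json.loads(text)
    if "signatures" in payload:
        return SpectralLibrary(
            provenance=payload["provenance"],
            signatures={k: np.asarray(v) for k, v in payload["signatures"].items()},
            signature_channels=payload["signature_channels"],
            warnings=list(payload.get("warnings", [])),
        )
    spectra = [
        EmissionSpectrum(s["name"], np.asarray(s["wavelengths_nm"]), np.asarray(s["intensities"]))
        for s in payload["spectra"]
    ]
    af = next(s for s in spectra if s.name == AF_NAME)
    return SpectralLibrary(
        spectra=[s for s in spectra if s.name != AF_NAME],
        autofluorescence=af,
        provenance=payload["provenance"],
        warnings=list(payload.get("warnings", [])),
    )


@dataclass
class QCResult:
    passed: bool
    reason: str | None
    af_upper_quartile_mean: float
    residual_upper_quartile_mean: float


def _upper_quartile_mean(plane: np.ndarray) -> float:
    cut = np.quantile(plane, 0.75)
    return float(plane[plane >= cut].mean())


def qc_autofluorescence(
    unmixed: UnmixedImage,
    max_af_counts: float = 6.0,
    max_residual: float = 1.0,
) -> QCResult:
    """Exclude images whose residual autofluorescence or unmixing error is high.

    Sections cut too thick fluoresce beyond the range the single AF spectrum
    can absorb, leaving incomplete unmixing; such images must not reach
    segmentation.  The test statistic is the upper-quartile mean of the AF
    plane (and of the residual plane), compared against fixed bounds in
    counts.
    """
    af_uq = _upper_quartile_mean(unmixed.autofluorescence)
    res_uq = _upper_quartile_mean(unmixed.residual)
    reason = None
    if af_uq > max_af_counts:
        reason = (
            f"autofluorescence bound exceeded: upper-quartile mean {af_uq:.3f} "
            f"> {max_af_counts:.3f} counts"
        )
    elif res_uq > max_residual:
        reason = (
            f"residual bound exceeded: upper-quartile mean {res_uq:.3f} "
            f"> {max_residual:.3f} counts"
        )
    passed = reason is None
    unmixed.excluded = not passed
    unmixed.exclusion_reason = reason
    return QCResult(passed, reason, af_uq, res_uq)
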