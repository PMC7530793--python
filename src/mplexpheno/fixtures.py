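"""Deterministic, desk-scale study scenes used by the test-suite and demos.

Every fixture is generated programmatically from a fixed seed — nothing is
shipped as data — and stays small (<= 512 px square, <= 400 cells):

* ``sparse-mp1``    : 300 well-separated MP1 cells, no artefacts, no noise.
                      Clean-recovery reference for segmentation/phenotyping.
* ``hotspot-mp1``   : MP1 with two germinal-centre-like CD20-dominant hot
                      spots, nonspecific CD20->CD8 co-stain (nu = 0.3) and
                      neighbour spillover/masking (kappa = 0.3).
* ``mp2``           : the compartment-separated panel on sparse tissue
                      (no B-cell-follicle artefacts apply to MP2).
* ``overlap-spectra``: singleplex scenes for the CD20/CD8 crosstalk
                      comparison — the overlapping Opal650/690 pairing vs a
                      spectrally distant Opal570/690 pairing, both acquired
                      with the standard five filters.
* ``thick-section`` : tau = 5 twin of a tau = 1 scene, for the
                      autofluorescence exclusion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import panels, scene, spectral
from .errors import ConfigurationError
from .image import MultichannelImage

__all__ = ["make_fixture", "FIXTURE_NAMES", "SceneFixture", "OverlapSpectraFixture", "ThickSectionFixture"]

FIXTURE_NAMES = ["sparse-mp1", "hotspot-mp1", "mp2", "overlap-spectra", "thick-section"]


@dataclass
class SceneFixture:
    name: str
    config: scene.SceneConfig
    filters: spectral.FilterSet = field(default_factory=spectral.motif7)
    _truth: object = None
    _library: object = None

    @property
    def profiles(self):
        return scene.default_profiles(self.config.panel)

    @property
    def pairing(self) -> dict[str, str]:
        return panels.panel_fluorophores(self.config.panel)

    @property
    def library(self) -> spectral.SpectralLibrary:
        if self._library is None:
            fluors = sorted(
                set(self.pairing.values()), key=list(spectral.NOMINAL_PEAKS_NM).index
            )
            self._library = spectral.synthetic_library(fluors)
        return self._library

    def truth(self) -> scene.SceneTruth:
        if self._truth is None:
            self._truth = scene.simulate_scene(self.config, self.profiles)
        return self._truth

    def image(self, scale: float = 1.0) -> MultichannelImage:
        return scene.acquire(self.truth(), self.config, self.library, self.filters, scale=scale)

    def unmixed(self, scale: float = 1.0):
        return spectral.unmix(self.image(scale), self.library, self.filters)


def _sparse_mp1() -> SceneFixture:
    return SceneFixture(
        "sparse-mp1",
        scene.SceneConfig(
            panel=panels.MP1,
            shape=(512, 512),
            n_cells=300,
            hotspots=None,
            nu=0.0,
            kappa=0.0,
            tau=1.0,
            noise_sigma=0.0,
            seed=11,
        ),
    )


def _hotspot_mp1() -> SceneFixture:
    return SceneFixture(
        "hotspot-mp1",
        scene.SceneConfig(
            panel=panels.MP1,
            shape=(384, 384),
            n_cells=300,
            hotspots=scene.HotspotSpec(count=2, radius_px=55.0, density_multiplier=6.0),
            nu=0.3,
            kappa=0.3,
            tau=1.0,
            noise_sigma=0.05,
            min_separation_px=18.0,
            seed=12,
        ),
    )


def _mp2() -> SceneFixture:
    return SceneFixture(
        "mp2",
        scene.SceneConfig(
            panel=panels.MP2,
            shape=(448, 448),
            n_cells=300,
            hotspots=None,
            nu=0.0,
            kappa=0.3,
            tau=1.0,
            noise_sigma=0.05,
            seed=13,
        ),
    )


@dataclass
class ThickSectionFixture:
    """A tau = 5 section and its tau = 1 twin (identical otherwise)."""

    thick: SceneFixture
    thin: SceneFixture


def _thick_section() -> ThickSectionFixture:
    def cfg(tau: float) -> scene.SceneConfig:
        return scene.SceneConfig(
            panel=panels.MP1,
            shape=(256, 256),
            n_cells=100,
            hotspots=None,
            nu=0.0,
            kappa=0.0,
            tau=tau,
            noise_sigma=0.05,
            seed=15,
        )

    return ThickSectionFixture(
        thick=SceneFixture("thick-section", cfg(5.0)),
        thin=SceneFixture("thick-section-thin-twin", cfg(1.0)),
    )


@dataclass
class OverlapSpectraFixture:
    """Singleplex scenes and libraries for the crosstalk-ordering comparison.

    ``overlap_library`` pairs CD20 with Opal650 and CD8 with Opal690, whose
    emission peaks overlap inside the Cy5 band; ``spaced_library`` moves
    CD20 to Opal570.  Both are acquired with the standard five filters.
    """

    filters: spectral.FilterSet
    overlap_library: spectral.SpectralLibrary
    spaced_library: spectral.SpectralLibrary
    overlap_pairing: dict[str, str]
    spaced_pairing: dict[str, str]

    def singleplex_image(
        self,
        marker: str,
        pairing: dict[str, str],
        library: spectral.SpectralLibrary,
        seed: int,
        noise_sigma: float,
    ) -> MultichannelImage:
        """A small scene in which only `marker` is stained (plus AF)."""
        cfg = scene.SceneConfig(
            panel=panels.MP1,
            shape=(160, 160),
            n_cells=40,
            tau=1.0,
            noise_sigma=noise_sigma,
            seed=seed,
            min_separation_px=16.0,
        )
        profiles = [
            scene.PhenotypeProfile(
                f"{marker}+",
                {marker: scene.MarkerLevel(panels.MARKER_COMPARTMENT[marker], scene.POSITIVE_MEAN_COUNTS)},
                {scene.SPARSE: 1.0},
            )
        ]
        truth = scene.simulate_scene(cfg, profiles)
        planes, af = scene.render_truth_planes(truth, cfg)
        exposures = panels.default_exposures(self.filters.channels)
        return scene.mix_to_channels(
            {marker: planes[marker]},
            af,
            library,
            self.filters,
            exposures,
            noise_sigma=noise_sigma,
            seed=seed,
            marker_fluorophores=pairing,
        )

    def singleplex_scenes(
        self, pairing: dict[str, str], library: spectral.SpectralLibrary,
        seed: int, noise_sigma: float = 0.5,
    ) -> dict[str, MultichannelImage]:
        """One singleplex acquisition per fluorophore, keyed by fluorophore."""
        return {
            pairing[m]: self.singleplex_image(m, pairing, library, seed + i, noise_sigma)
            for i, m in enumerate(sorted(pairing))
        }


def _overlap_spectra() -> OverlapSpectraFixture:
    overlap_pairing = {"CD20": "Opal650", "CD8": "Opal690"}
    spaced_pairing = {"CD20": "Opal570", "CD8": "Opal690"}
    return OverlapSpectraFixture(
        filters=spectral.standard5(),
        overlap_library=spectral.synthetic_library(["Opal650", "Opal690"]),
        spaced_library=spectral.synthetic_library(["Opal570", "Opal690"]),
        overlap_pairing=overlap_pairing,
        spaced_pairing=spaced_pairing,
    )


_BUILDERS = {
    "sparse-mp1": _sparse_mp1,
    "hotspot-mp1": _hotspot_mp1,
    "mp2": _mp2,
    "overlap-spectra": _overlap_spectra,
    "thick-section": _thick_section,
}


def make_fixture(name: str):
    """Build a named fixture; unknown names list the valid ones."""
    if name not in _BUILDERS:
        raise ConfigurationError(
            f"unknown fixture {name!r}; valid fixtures: {FIXTURE_NAMES}"
        )
    return _BUILDERS[name]()
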