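"""File formats: multichannel TIFF images with channel metadata, CSV tables.

Images are written as multipage TIFF (OME flavour when the filename ends in
``.ome.tif``/``.ome.tiff``) with a JSON sidecar (`<path>.meta.json`)
carrying the channel map and per-channel exposure times; the sidecar
dialect is also accepted for plain TIFFs produced elsewhere.  Channel
naming is stable: acquisition channels keep their filter names, unmixed
planes are ``fluor:<name>`` plus ``AF`` and ``residual``.

Checksums used by the run manifest are computed over pixel values and
metadata (not raw file bytes), so they are reproducible across TIFF writer
versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError
from .image import MultichannelImage, UnmixedImage

__all__ = [
    "write_multichannel",
    "read_multichannel",
    "write_unmixed",
    "read_unmixed",
    "content_checksum",
]


def _is_ome(path: Path) -> bool:
    return path.name.endswith((".ome.tif", ".ome.tiff"))


def _write_stack(path: Path, stack: np.ndarray, names: list[str], meta: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(stack, dtype=np.float32)
    if _is_ome(path):
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={"axes": "CYX", "Channel": {"Name": names}},
        )
    else:
        tifffile.imwrite(path, data)
    sidecar = {"channels": names, **meta}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def _read_stack(path: Path) -> tuple[np.ndarray, dict]:
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = Path(str(path) + ".meta.json")
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing channel-map sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if len(meta["channels"]) != data.shape[0]:
        raise ConfigurationError("channel map does not match plane count")
    return data, meta


def write_multichannel(path, image: MultichannelImage) -> None:
    _write_stack(
        Path(path),
        image.planes,
        image.channel_names,
        {"exposures_ms": image.exposures_ms, "kind": "acquisition"},
    )


def read_multichannel(path) -> MultichannelImage:
    data, meta = _read_stack(Path(path))
    return MultichannelImage(data, meta["channels"], meta["exposures_ms"])


def write_unmixed(path, unmixed: UnmixedImage) -> None:
    names = [f"fluor:{n}" for n in unmixed.abundances] + ["AF", "residual"]
    stack = np.stack(
        [*unmixed.abundances.values(), unmixed.autofluorescence, unmixed.residual]
    )
    meta = {
        "kind": "unmixed",
        "excluded": unmixed.excluded,
        "exclusion_reason": unmixed.exclusion_reason,
        **{k: v for k, v in unmixed.meta.items() if isinstance(v, (str, int, float, bool))},
    }
    _write_stack(Path(path), stack, names, meta)


def read_unmixed(path) -> UnmixedImage:
    data, meta = _read_stack(Path(path))
    names = meta["channels"]
    abundances = {
        n.split(":", 1)[1]: data[i] for i, n in enumerate(names) if n.startswith("fluor:")
    }
    af = data[names.index("AF")]
    residual = data[names.index("residual")]
    return UnmixedImage(
        abundances,
        af,
        residual,
        excluded=bool(meta.get("excluded", False)),
        exclusion_reason=meta.get("exclusion_reason"),
    )


def content_checksum(*parts) -> str:
    """SHA-256 over array bytes / JSON-serialized metadata, order-sensitive."""
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, np.ndarray):
            h.update(np.ascontiguousarray(part).tobytes())
        elif hasattr(part, "to_csv"):  # DataFrame / Series
            h.update(part.to_csv(index=False).encode() if hasattr(part, "columns")
                     else part.to_csv().encode())
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()
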