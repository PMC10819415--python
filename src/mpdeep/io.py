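"""Reading and writing stacks (multi-page TIFF + JSON sidecar) and result CSVs.

Stacks travel as plain multi-page grayscale TIFF with the acquisition
metadata (z step, pixel size, channel, optional per-slice powers) in a JSON
sidecar next to the image file, keeping readers dependency-light.  Results
(SBR profiles, fits, maps) are written as CSV with a comment header that
records units and a short hash of the configuration that produced them, so
re-runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stacks import (
    AttenuationLengthFit,
    CHANNELS,
    ImageStack,
    PowerLawFit,
    PSFRadiiFit,
    SBRProfile,
)
from .sbr import SBRMap

__all__ = [
    "MetadataError",
    "read_stack",
    "write_stack",
    "write_results",
    "config_hash",
]

_SIDECAR_REQUIRED = ("z_step_um", "pixel_size_um", "channel")


class MetadataError(ValueError):
    """A stack sidecar is missing or inconsistent; the message names the field."""


def _sidecar_path(tiff_path: Path, sidecar: str | Path | None) -> Path:
    if sidecar is not None:
        return Path(sidecar)
    return tiff_path.with_suffix(".json")


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Load a multi-page grayscale TIFF plus its JSON sidecar into an ImageStack.

    Page order is slice order, shallow to deep.  The sidecar must provide
    ``z_step_um``, ``pixel_size_um`` and ``channel``; ``surface_powers`` is
    optional but must match the page count when present.  Missing or
    mismatched metadata raises :class:`MetadataError` naming the field.
    """
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None, ...]
    if voxels.ndim != 3:
        raise MetadataError(f"expected a stack of 2-D pages, got shape {voxels.shape}")
    if not np.issubdtype(voxels.dtype, np.integer):
        raise MetadataError("pixel data must be integer detector counts")

    spath = _sidecar_path(path, sidecar)
    if not spath.exists():
        raise MetadataError(f"sidecar file not found: {spath}")
    meta = json.loads(spath.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise MetadataError(f"sidecar is missing required field {key!r}")
    if meta["channel"] not in CHANNELS:
        raise MetadataError(f"channel must be one of {CHANNELS}, got {meta['channel']!r}")
    powers = meta.get("surface_powers")
    if powers is not None and len(powers) != voxels.shape[0]:
        raise MetadataError(
            f"surface_powers has {len(powers)} entries for {voxels.shape[0]} slices"
        )
    extra = {k: v for k, v in meta.items() if k not in (*_SIDECAR_REQUIRED, "surface_powers")}
    return ImageStack(
        voxels=voxels,
        z_step_um=float(meta["z_step_um"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        channel=meta["channel"],
        surface_powers=None if powers is None else np.asarray(powers, dtype=float),
        meta=extra,
    )


def write_stack(
    stack: ImageStack, path: str | Path, sidecar: str | Path | None = None
) -> tuple[Path, Path]:
    """Write an ImageStack as multi-page TIFF plus JSON sidecar; returns both paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(stack.voxels, dtype=np.uint16), photometric="minisblack"
    )
    spath = _sidecar_path(path, sidecar)
    meta = {
        "z_step_um": stack.z_step_um,
        "pixel_size_um": stack.pixel_size_um,
        "channel": stack.channel,
    }
    if stack.surface_powers is not None:
        meta["surface_powers"] = [float(p) for p in stack.surface_powers]
    meta.update({k: v for k, v in stack.meta.items() if _json_safe(v)})
    spath.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path, spath


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping (12 hex chars).

    Canonicalises with sorted keys so the hash changes iff a parameter does.
    """

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        return str(o)

    blob = json.dumps(params, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _result_frame(result) -> tuple[pd.DataFrame, dict]:
    """DataFrame + unit annotations for a supported result object."""
    if isinstance(result, SBRProfile):
        return result.to_frame(), {
            "type": "sbr_profile",
            "units": "depth_um in µm; background/signal in counts above zero-value",
            "channel": result.channel,
            "zero_value": result.zero_value,
        }
    if isinstance(result, SBRMap):
        frame = result.to_frame().reset_index().melt(
            id_vars="scattering_length_um", var_name="depth_um", value_name="sbr"
        )
        return frame, {"type": "sbr_map", "units": "µm", "order": result.order}
    if isinstance(result, (PowerLawFit, AttenuationLengthFit, PSFRadiiFit)):
        d = dataclasses.asdict(result)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return pd.DataFrame([d]), {"type": type(result).__name__, "units": "µm where applicable"}
    raise TypeError(f"unsupported result type: {type(result).__name__}")


def write_results(result, path: str | Path, config: dict | None = None) -> Path:
    """Write a result object as CSV with a unit/config-hash comment header.

    Field order is fixed per result type and floats are serialised at six
    significant digits, so identical inputs reproduce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame, notes = _result_frame(result)
    header_lines = [f"# {k} = {v}" for k, v in notes.items()]
    header_lines.append(f"# config_hash = {config_hash(config or {})}")
    csv_body = frame.to_csv(index=False, float_format="%.6g", lineterminator="\n")
    path.write_text("\n".join(header_lines) + "\n" + csv_body)
    return path
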