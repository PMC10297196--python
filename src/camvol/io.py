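"""Readers and writers for probability maps, tables and configuration.

Probability maps travel as 16-bit grayscale PNG (pixel value =
round(p * 65535)); pixel spacing rides in a sidecar CSV mapping image_id
to mm/pixel.  Tables are plain CSV with a header row; models are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError
from .extraction import ProbabilityMap

log = logging.getLogger("camvol")

PNG_MAX = 65535
SPACING_SIDECAR = "pixel_spacing.csv"

#: Documented table precision: volumes to 0.01 mm³, probabilities to 1e-6.
CSV_FLOAT_FORMAT = "%.6f"


def write_probability_map(pmap: ProbabilityMap, path) -> None:
    """Quantize to 16-bit grayscale PNG (p = value / 65535)."""
    q = np.round(pmap.values * PNG_MAX).astype(np.uint16)
    iio.imwrite(Path(path), q, extension=".png")


def read_probability_map(path, spacing_mm: float, image_id: str = "",
                         ) -> ProbabilityMap:
    """Load a grayscale PNG (8- or 16-bit) and rescale to [0, 1]."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read image {path.name}: {exc}") from exc
    if raw.ndim != 2:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale, got shape {raw.shape}")
    if raw.dtype == np.uint16:
        denom = PNG_MAX
    elif raw.dtype == np.uint8:
        denom = 255
    else:
        raise FormatError(f"{path.name}: unsupported dtype {raw.dtype}")
    return ProbabilityMap(values=raw.astype(float) / denom,
                          pixel_spacing_mm=spacing_mm,
                          image_id=image_id or path.stem)


def write_spacing_sidecar(spacing: Mapping[str, float], directory) -> Path:
    path = Path(directory) / SPACING_SIDECAR
    pd.DataFrame(
        {"image_id": list(spacing), "pixel_spacing_mm": list(spacing.values())}
    ).to_csv(path, index=False)
    return path


def read_spacing_sidecar(directory) -> dict[str, float]:
    path = Path(directory) / SPACING_SIDECAR
    if not path.exists():
        raise FormatError(f"missing spacing sidecar {path}")
    df = pd.read_csv(path)
    return dict(zip(df.image_id.astype(str), df.pixel_spacing_mm.astype(float)))


def write_table(df: pd.DataFrame, path) -> None:
    """CSV writer with the documented float precision."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing table {path}")
    return pd.read_csv(path)


def load_config_file(path) -> dict:
    """YAML (or JSON) config mirroring the cohort/pipeline config fields."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed config {path.name}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path.name} must be a mapping")
    # YAML turns integer-keyed mappings into int keys already; normalise
    if "n_images_by_nodule_count" in data:
        data["n_images_by_nodule_count"] = {
            int(k): int(v) for k, v in data["n_images_by_nodule_count"].items()}
    for tup in ("growth_factor_range", "shrink_factor_range", "grid_size"):
        if tup in data:
            data[tup] = tuple(data[tup])
    return data


def write_manifest(path, **entries) -> None:
    """Run manifest: config echo, seed, package versions."""
    import camvol

    payload = {"camvol_version": camvol.__version__,
               "numpy_version": np.__version__,
               "pandas_version": pd.__version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")


def setup_logging(level: str = "INFO", logfile: Optional[Path] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
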