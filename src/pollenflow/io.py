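"""Gallery and table I/O glue.

Galleries are directories of one grayscale image per object (16-bit TIFF or
8-bit PNG, named ``<object_id>.<ext>``) plus a ``truth.csv`` table when the
gallery is synthetic.  Feature tables are CSV or tab-delimited text with a
comment header documenting units (all lengths in micrometres), mirroring
the txt export convention of the acquisition software.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .masking import ObjectImage

_EXTS = (".tif", ".tiff", ".png")


def load_image(path, pixel_size_um: float) -> ObjectImage:
    """Load one gallery image, rescaling integer intensities to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return ObjectImage(pixels=data, pixel_size_um=pixel_size_um)


def read_gallery(
    gallery_dir,
    pixel_size_um: Optional[float] = None,
) -> Iterator[Tuple[str, ObjectImage]]:
    """Yield (object_id, image) pairs from a gallery directory.

    The pixel size comes from ``truth.csv`` when present, otherwise it must
    be given explicitly.
    """
    gallery_dir = Path(gallery_dir)
    truth_path = gallery_dir / "truth.csv"
    px_by_id = {}
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        if "pixel_size_um" in truth.columns:
            px_by_id = dict(zip(truth["object_id"], truth["pixel_size_um"]))
    paths = sorted(p for p in gallery_dir.iterdir() if p.suffix.lower() in _EXTS)
    if not paths:
        raise FileNotFoundError(f"no gallery images in {gallery_dir}")
    for path in paths:
        oid = path.stem
        px = px_by_id.get(oid, pixel_size_um)
        if px is None:
            raise ValueError(
                "pixel_size_um not given and no truth.csv in the gallery"
            )
        yield oid, load_image(path, float(px))


def load_truth(gallery_dir) -> Optional[pd.DataFrame]:
    path = Path(gallery_dir) / "truth.csv"
    if not path.exists():
        return None
    return pd.read_csv(path, keep_default_na=False)


def export_feature_table(records: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write a feature table with a unit-documenting comment header.

    ``dialect`` is ``csv`` or ``tab`` (tab-delimited txt).  Empty tables
    raise rather than producing an empty file.
    """
    if records.empty:
        raise ValueError("refusing to export an empty feature table")
    if dialect not in ("csv", "tab"):
        raise ValueError("dialect must be 'csv' or 'tab'")
    sep = "," if dialect == "csv" else "\t"
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# pollenflow feature table; lengths in micrometres (um), "
                 "areas in um^2; decimal point locale-independent\n")
        records.to_csv(fh, sep=sep, index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".txt", ".tsv") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "species_label" in df.columns:
        for col in ("species_label", "individual_label", "year_label"):
            if col in df.columns:
                df[col] = df[col].fillna("")
    return df
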