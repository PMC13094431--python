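"""Reading and writing the formats the pipeline touches.

imzML (continuous mode) carries the pixel grids; tissue masks travel as
label CSVs or indexed PNGs with a JSON legend sidecar; the curated
adipose-enriched lipid summary ships as a packaged TSV; result tables are
plain TSV.  Pixel coordinates are 0-based row-major (``x`` = column,
``y`` = row); imzML's 1-based convention is converted on read/write.
Intensities are stored as 32-bit floats and m/z values as 64-bit floats.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import normalize_adduct_name

__all__ = [
    "MSIDataset",
    "TissueMask",
    "Table1Record",
    "TISSUE_LABELS",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "read_mask",
    "write_mask",
    "load_table1",
    "write_tsv",
]

MZ_RANGE = (100.0, 1200.0)

TISSUE_LABELS = (
    "background", "muscle", "liver", "brain", "eye", "gill", "adipose", "other",
)


class FormatError(ValueError):
    """A file does not conform to the expected format or dialect."""


@dataclass
class MSIDataset:
    """A pixel grid of spectra sharing one m/z axis.

    ``intensities`` has shape ``(width * height, len(mz_axis))`` with pixels
    in row-major order.
    """

    replicate_id: str
    polarity: str
    width: int
    height: int
    mz_axis: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.validate()

    def validate(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.width < 1 or self.height < 1 or self.width * self.height < 1:
            raise ValueError("grid must contain at least one pixel")
        if self.mz_axis.ndim != 1 or len(self.mz_axis) == 0:
            raise ValueError("empty m/z axis")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.mz_axis[0] < MZ_RANGE[0] or self.mz_axis[-1] > MZ_RANGE[1]:
            raise ValueError(
                f"m/z axis outside acquisition range {MZ_RANGE}")
        if self.intensities.shape != (self.width * self.height, len(self.mz_axis)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} inconsistent "
                f"with {self.width}x{self.height} grid and "
                f"{len(self.mz_axis)}-point axis")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current."""
        return self.intensities.sum(axis=1, dtype=np.float64)

    def pixel(self, x: int, y: int) -> np.ndarray:
        return self.intensities[y * self.width + x]


@dataclass
class TissueMask:
    """Per-pixel tissue labels aligned to an MSIDataset grid."""

    width: int
    height: int
    labels: np.ndarray  # shape (height, width), dtype str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U16")
        if self.labels.shape != (self.height, self.width):
            raise ValueError("label array shape mismatch")
        bad = set(np.unique(self.labels)) - set(TISSUE_LABELS)
        if bad:
            raise FormatError(f"unknown label name(s): {sorted(bad)}")

    def flat(self) -> np.ndarray:
        """Labels in row-major pixel order, matching MSIDataset pixels."""
        return self.labels.reshape(-1)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def tissue_pixels(self) -> np.ndarray:
        """Flat indices of non-background pixels."""
        return np.nonzero(self.flat() != "background")[0]


# ---------------------------------------------------------------------------
# imzML

def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a continuous-mode imzML/ibd pair; returns the .imzML path."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    dataset.validate()
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        polarity=dataset.polarity,
        mode="continuous",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for y in range(dataset.height):
            for x in range(dataset.width):
                spec = dataset.intensities[y * dataset.width + x]
                writer.addSpectrum(dataset.mz_axis, spec, (x + 1, y + 1))
    return path


def _scan_imzml_header(path: Path) -> dict:
    """Pull mode, polarity and pixel size out of the imzML XML header."""
    text = path.read_text(errors="replace")
    info: dict = {}
    if "processed" in text and "IMS:1000031" in text:
        info["mode"] = "processed"
    elif "continuous" in text or "IMS:1000030" in text:
        info["mode"] = "continuous"
    else:
        info["mode"] = "unknown"
    if "negative scan" in text or 'name="negative scan"' in text:
        info["polarity"] = "negative"
    else:
        info["polarity"] = "positive"
    m = re.search(r'name="pixel size(?: \(x\))?" value="([\d.]+)"', text)
    if m:
        info["pixel_size_um"] = float(m.group(1))
    return info


def read_imzml(path: str | Path, replicate_id: str | None = None) -> MSIDataset:
    """Read a continuous-mode imzML/ibd pair into an :class:`MSIDataset`.

    Raises :class:`FormatError` for a missing .ibd companion and an
    unsupported-dialect error naming the mode for processed-mode files.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing .ibd companion for {path}")
    header = _scan_imzml_header(path)
    if header["mode"] == "processed":
        raise FormatError(
            "unsupported imzML dialect 'processed': only continuous-mode "
            "files sharing one m/z axis are supported")
    parser = ImzMLParser(str(path))
    coords = [(x, y) for (x, y, *_) in parser.coordinates]
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    width = max(xs)  # imzML coordinates are 1-based
    height = max(ys)
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=np.float64)
    if np.any(np.diff(mz0) <= 0):
        raise FormatError("m/z axis is not strictly increasing")
    inten = np.zeros((width * height, len(mz0)), dtype=np.float32)
    for i, (x, y) in enumerate(coords):
        mz, spec = parser.getspectrum(i)
        if len(mz) != len(mz0):
            raise FormatError(
                "spectra do not share one m/z axis (processed-mode content?)")
        inten[(y - 1) * width + (x - 1)] = spec
    return MSIDataset(
        replicate_id=replicate_id or path.stem,
        polarity=header["polarity"],
        width=width,
        height=height,
        mz_axis=mz0,
        intensities=inten,
        pixel_size_um=header.get("pixel_size_um", 50.0),
        metadata={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Tissue masks

def read_mask(
    path: str | Path,
    expected_shape: tuple[int, int] | None = None,
) -> TissueMask:
    """Read a tissue mask from a label CSV or an indexed PNG + legend.

    CSV cells hold label names (whitespace-normalized, case-folded).  A PNG
    requires a ``<name>.legend.json`` sidecar mapping palette index to label.
    ``expected_shape`` is ``(height, width)``; a mismatch raises.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        legend_path = path.with_suffix(".legend.json")
        if not legend_path.exists():
            raise FormatError(f"missing legend sidecar {legend_path}")
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
        arr = np.asarray(Image.open(path))
        labels = np.empty(arr.shape, dtype="<U16")
        for idx in np.unique(arr):
            if int(idx) not in legend:
                raise FormatError(f"palette index {idx} missing from legend")
            labels[arr == idx] = legend[int(idx)]
    else:
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            rows.append([c.strip().lower() for c in line.split(",")])
        if not rows:
            raise FormatError(f"empty mask file {path}")
        ncol = len(rows[0])
        if any(len(r) != ncol for r in rows):
            raise FormatError("ragged mask CSV")
        labels = np.array(rows, dtype="<U16")
    h, w = labels.shape
    if expected_shape is not None and (h, w) != tuple(expected_shape):
        raise FormatError(
            f"mask dimensions {(h, w)} do not match expected {expected_shape}")
    return TissueMask(width=w, height=h, labels=labels)


def write_mask(mask: TissueMask, path: str | Path) -> Path:
    """Write a mask as a label CSV, or as indexed PNG + legend for .png paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        from PIL import Image

        legend = {label: i for i, label in enumerate(TISSUE_LABELS)}
        arr = np.vectorize(legend.__getitem__)(mask.labels).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
        path.with_suffix(".legend.json").write_text(
            json.dumps({str(i): label for label, i in legend.items()}, indent=0))
    else:
        with open(path, "w") as fh:
            for row in mask.labels:
                fh.write(",".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Curated adipose-enriched lipid summary (packaged table1.tsv fixture)

@dataclass(frozen=True)
class Table1Record:
    """One curated adipose-enriched lipid with imaging and extraction stats."""

    polarity: str
    desi_avg_mz: float
    desi_between_rep_ppm: float
    annotation: str
    desi_adduct: str
    other_adducts_enriched: tuple[str, ...]
    avg_intensity_adipose: float
    avg_intensity_nonadipose: float
    avg_fold_change: float
    avg_roc: float
    lesa_observed_ms1: float
    dominant_fa_composition: str
    lesa_adduct: str
    other_adducts_detected: tuple[str, ...]
    lipid_class: str
    lesa_delta_ppm: float

    def __post_init__(self):
        if self.avg_fold_change <= 0:
            raise ValueError("fold change must be positive")
        if not 0.0 <= self.avg_roc <= 1.0:
            raise ValueError("AUC outside [0, 1]")
        for mz in (self.desi_avg_mz, self.lesa_observed_ms1):
            if not MZ_RANGE[0] <= mz <= MZ_RANGE[1]:
                raise ValueError(f"m/z {mz} outside acquisition range")


def _parse_adduct_list(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell == "-":
        return ()
    return tuple(normalize_adduct_name(tok) for tok in cell.split(","))


def load_table1(path: str | Path | None = None) -> list[Table1Record]:
    """Load the packaged adipose-enriched lipid summary (52 records)."""
    if path is None:
        source = resources.files("lipidmsi").joinpath("data/table1.tsv")
        df = pd.read_csv(source.open("r"), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        try:
            records.append(Table1Record(
                polarity="positive" if row["polarity"].strip() == "+" else "negative",
                desi_avg_mz=float(row["desi_avg_mz"]),
                desi_between_rep_ppm=float(row["desi_between_rep_ppm"]),
                annotation=row["annotation"].strip(),
                desi_adduct=normalize_adduct_name(row["desi_adduct"]),
                other_adducts_enriched=_parse_adduct_list(row["other_adducts_enriched"]),
                avg_intensity_adipose=float(row["avg_intensity_adipose"]),
                avg_intensity_nonadipose=float(row["avg_intensity_nonadipose"]),
                avg_fold_change=float(row["avg_fold_change"]),
                avg_roc=float(row["avg_roc"]),
                lesa_observed_ms1=float(row["lesa_observed_ms1"]),
                dominant_fa_composition=row["dominant_fa_composition"].strip(),
                lesa_adduct=normalize_adduct_name(row["lesa_adduct"]),
                other_adducts_detected=_parse_adduct_list(row["other_adducts_detected"]),
                lipid_class=row["lipid_class"].strip(),
                lesa_delta_ppm=float(row["lesa_delta_ppm"]),
            ))
        except ValueError as exc:
            raise FormatError(
                f"unparseable record {row['annotation']!r}: {exc}") from exc
    return records


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
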