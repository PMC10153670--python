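"""Dataset ingestion, preprocessing, and synthetic fixture generation.

Supports UCI-style delimited text (features plus an integer/categorical
label column), IDX-format image files (MNIST layout) flattened to vectors,
min-max normalization, per-feature mean imputation of missing values, and
the 36->4 spectral band averaging used for satellite-image data whose
attributes are 3x3 pixel neighbourhoods in four bands.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "load_tabular",
    "minmax_normalize",
    "impute_mean",
    "statlog_band_average",
    "read_idx_images",
    "write_idx",
    "make_synthetic",
]


@dataclass
class Dataset:
    """Feature matrix, integer labels, and per-feature extrema.

    ``provenance`` records where the data came from (file path or generator
    spec + seed) for run logging.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (samples, features) matching y")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.y.size else 0

    @property
    def xmin(self) -> np.ndarray:
        return np.nanmin(self.X, axis=0)

    @property
    def xmax(self) -> np.ndarray:
        return np.nanmax(self.X, axis=0)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X,
                          columns=[f"f{i}" for i in range(self.n_features)])
        df["label"] = self.y
        df.to_csv(path, index=False)


def load_tabular(path, delimiter: str = ",", label_col: int = -1,
                 missing: str = "?", header: str | bool = "auto") -> Dataset:
    """Read a delimited text dataset; one sample per row, one label column.

    Labels are factorized to 0-based integers in order of first appearance.
    The ``missing`` marker becomes NaN (impute before training).  With
    ``header="auto"`` a non-numeric first row is treated as column names.
    """
    head = 0 if header is True else None
    if header == "auto":
        probe = pd.read_csv(path, sep=delimiter, header=None, nrows=1,
                            na_values=missing)
        first = probe.iloc[0].tolist()
        ncol = len(first)
        label_pos = label_col % ncol
        # header iff any *feature* cell of the first row is non-numeric
        # (a string in the label column is just a categorical label)
        def _numeric(v):
            try:
                float(v)
                return True
            except (TypeError, ValueError):
                return pd.isna(v)
        head = 0 if any(not _numeric(v) for i, v in enumerate(first)
                        if i != label_pos) else None
    df = pd.read_csv(path, sep=delimiter, header=head, na_values=missing,
                     skipinitialspace=True)
    if df.isna().all(axis=1).any():
        raise ValueError(f"{path}: blank or unparseable row")
    labels = df.iloc[:, label_col]
    feats = df.drop(columns=[df.columns[label_col]])
    y, _ = pd.factorize(labels)
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = feats.apply(pd.to_numeric, errors="coerce")
        row = int(bad.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric feature in row {row}") from exc
    if np.any(y < 0):
        raise ValueError(f"{path}: missing label value")
    return Dataset(X=X, y=y, provenance=str(path))


def minmax_normalize(ds: Dataset) -> Dataset:
    """Affine per-feature rescale so min -> 0 and max -> 1.

    Constant features map to 0 with a warning.  Idempotent on
    already-normalized data.
    """
    lo, hi = ds.xmin, ds.xmax
    span = hi - lo
    const = span == 0
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant feature(s) mapped to 0",
                      stacklevel=2)
    span = np.where(const, 1.0, span)
    X = (ds.X - lo) / span
    X[:, const] = 0.0
    return replace(ds, X=X)


def impute_mean(ds: Dataset) -> Dataset:
    """Replace NaN entries by their feature's observed mean."""
    X = ds.X.copy()
    nan = np.isnan(X)
    if not nan.any():
        return replace(ds, X=X)
    if nan.all(axis=0).any():
        raise ValueError("a feature has no observed values to average")
    means = np.nanmean(X, axis=0)
    X[nan] = np.broadcast_to(means, X.shape)[nan]
    return replace(ds, X=X)


def statlog_band_average(ds: Dataset, layout: str = "band-major") -> Dataset:
    """Average the 9 neighbourhood pixels of each spectral band: 36 -> 4.

    ``layout`` names the attribute ordering: "band-major" (9 consecutive
    pixels per band) or "pixel-major" (4 consecutive band values per pixel).
    """
    if ds.n_features != 36:
        raise ValueError("band averaging expects exactly 36 features "
                         "(9 pixels x 4 bands)")
    if layout == "band-major":
        X = ds.X.reshape(ds.n_samples, 4, 9).mean(axis=2)
    elif layout == "pixel-major":
        X = ds.X.reshape(ds.n_samples, 9, 4).mean(axis=1)
    else:
        raise ValueError("layout must be 'band-major' or 'pixel-major'")
    return replace(ds, X=X)


# ---------------------------------------------------------------------------
# IDX image format (big-endian, magic 0x00000803 images / 0x00000801 labels)

_IDX_IMAGES = 0x00000803
_IDX_LABELS = 0x00000801


def read_idx_images(image_path, label_path) -> Dataset:
    """Read IDX image + label files into flattened rows scaled to [0, 1]."""
    with open(image_path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != _IDX_IMAGES:
            raise ValueError(f"{image_path}: bad IDX image magic {magic:#x}")
        pixels = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    with open(label_path, "rb") as fh:
        magic, nl = struct.unpack(">II", fh.read(8))
        if magic != _IDX_LABELS:
            raise ValueError(f"{label_path}: bad IDX label magic {magic:#x}")
        labels = np.frombuffer(fh.read(nl), dtype=np.uint8)
    if n != nl:
        raise ValueError("image and label counts differ")
    X = pixels.reshape(n, rows * cols).astype(float) / 255.0
    return Dataset(X=X, y=labels.astype(int), provenance=str(image_path))


def write_idx(image_path, label_path, images: np.ndarray,
              labels: np.ndarray) -> None:
    """Write uint8 images (n, rows, cols) and labels to IDX files."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(image_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES, n, rows, cols))
        fh.write(images.tobytes())
    with open(label_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS, n))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_synthetic(kind: str = "blobs", n_per_class: int = 50,
                   n_features: int = 2, n_classes: int = 2,
                   noise: float = 1.0, seed: int | None = 0,
                   separation: float = 5.0) -> Dataset:
    """Deterministic labelled toy datasets: Gaussian blobs, XOR, rings.

    blobs
        Isotropic Gaussian clusters (sd ``noise``) at random centers drawn
        with every pairwise center distance at least ``separation * noise``
        (redrawn until satisfied) — "moderately separated" classes.
    xor
        2-feature checkerboard: label is the quadrant parity around
        (0.5, 0.5) of uniform points, features jittered by ``noise``.
    rings
        Concentric annuli of radius 1, 2, ... with radial sd ``noise``.
    """
    rng = np.random.default_rng(seed)
    prov = (f"synthetic:{kind}(n_per_class={n_per_class}, N={n_features}, "
            f"J={n_classes}, noise={noise}, seed={seed})")
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)

    if kind == "blobs":
        for _ in range(1000):
            centers = rng.normal(0.0, 3.0, size=(n_classes, n_features))
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            if np.all(d[np.triu_indices(n_classes, 1)] >= separation * noise):
                break
        else:
            raise RuntimeError("could not place separated blob centers")
        X = centers[labels] + rng.normal(0.0, noise, size=(n, n_features))
    elif kind == "xor":
        if n_features != 2 or n_classes != 2:
            raise ValueError("xor is a 2-feature, 2-class task")
        X = rng.uniform(0.0, 1.0, size=(n, 2))
        labels = ((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5)).astype(int)
        X = X + rng.normal(0.0, noise, size=X.shape)
    elif kind == "rings":
        if n_features != 2:
            raise ValueError("rings is a 2-feature task")
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        r = (labels + 1.0) + rng.normal(0.0, noise, size=n)
        X = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    return Dataset(X=X, y=labels, provenance=prov)
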