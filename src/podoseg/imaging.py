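"""Data model and I/O for multi-channel fluorescence images and masks.

The pipeline works on single optical sections of kidney tissue, one
glomerulus per frame, with three fluorescence channels identifying
podocytes: a DNA counterstain (all nuclei), WT1 (podocyte cytoplasm) and
DACH1 (podocyte nuclei). Images are held as H x W x 3 float arrays in
[0, 1] with a physical pixel size in micrometres; masks are dense binary
grids co-registered with the image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

CHANNEL_ROLES = ("dna", "wt1", "dach1")


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class MultiChannelImage:
    """H x W x 3 float image in [0, 1] with named channel roles."""

    pixels: np.ndarray
    channel_roles: tuple = CHANNEL_ROLES
    pixel_size_um: float = 1.0
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an H x W x 3 pixel array")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("image smaller than 32 x 32 px")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values outside [0, 1]")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be finite and positive")

    @property
    def shape(self):
        return self.pixels.shape[:2]

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_roles.index(role)]


@dataclass
class MaskPair:
    """Co-registered binary glomerulus and podocyte-nuclei masks."""

    glom: np.ndarray
    podo: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.glom = np.asarray(self.glom, dtype=np.uint8)
        self.podo = np.asarray(self.podo, dtype=np.uint8)
        if self.glom.shape != self.podo.shape:
            raise ValueError("glom and podo masks differ in shape")
        for m in (self.glom, self.podo):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")


@dataclass
class LabeledObjects:
    """Connected components of a binary mask with physical areas."""

    labels: np.ndarray
    areas_um2: np.ndarray
    centroids_px: np.ndarray          # (K, 2) array of (row, col)
    pixel_size_um: float = 1.0

    @property
    def n_objects(self) -> int:
        return int(self.areas_um2.shape[0])

    def mask(self) -> np.ndarray:
        return (self.labels > 0).astype(np.uint8)


@dataclass
class SegSample:
    """One glomerulus image with its ground-truth masks and metadata."""

    image: MultiChannelImage
    masks: MaskPair
    subject_id: str
    glomerulus_id: str
    group: str = "control"            # {control, disease}
    lesion: str = "unknown"           # {normal, lesion, unknown}

    def __post_init__(self):
        if not self.subject_id or not self.glomerulus_id:
            raise ValueError("subject_id and glomerulus_id must be nonempty")
        if self.group not in ("control", "disease"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.lesion not in ("normal", "lesion", "unknown"):
            raise ValueError(f"unknown lesion flag {self.lesion!r}")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def _rescale_to_unit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def read_image(path, channel_map=None, pixel_size_um: float = 1.0,
               source_id: str | None = None) -> MultiChannelImage:
    """Read a TIFF or PNG into a role-ordered MultiChannelImage.

    channel_map maps role name -> channel index in the file; by default
    channels 0, 1, 2 are taken as (dna, wt1, dach1). Integer pixel types
    are rescaled to [0, 1] by the dtype maximum.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] <= 8 and arr.shape[0] < arr.shape[2]:
            arr = np.moveaxis(arr, 0, 2)  # channel-first TIFF
    else:
        arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: needs >=3 channels, found a single plane")
    if arr.shape[2] < 3:
        raise ValueError(f"{path}: needs >=3 channels, found {arr.shape[2]}")
    channel_map = channel_map or {r: i for i, r in enumerate(CHANNEL_ROLES)}
    unknown = set(channel_map) - set(CHANNEL_ROLES)
    if unknown:
        raise ValueError(f"unknown channel roles: {sorted(unknown)}")
    idx = [channel_map[r] for r in CHANNEL_ROLES]
    pixels = _rescale_to_unit(arr[:, :, idx])
    return MultiChannelImage(pixels, CHANNEL_ROLES, pixel_size_um,
                             source_id or os.path.basename(path))


def write_image(image: MultiChannelImage, path) -> None:
    arr = np.clip(image.pixels * 255.0 + 0.5, 0, 255).astype(np.uint8)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero value becomes 1."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got {arr.shape}")
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    iio.imwrite(os.fspath(path), (mask > 0).astype(np.uint8) * 255)


# ----------------------------------------------------------------------
# object labeling and size filtering
# ----------------------------------------------------------------------
def label_objects(mask: np.ndarray, pixel_size_um: float = 1.0,
                  connectivity: int = 8) -> LabeledObjects:
    """Connected-component labeling under 4- or 8-connectivity."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask) > 0
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    if labels.max() == 0:
        return LabeledObjects(labels, np.zeros(0), np.zeros((0, 2)),
                              pixel_size_um)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=float) * pixel_size_um**2
    cents = np.array([p.centroid for p in props], dtype=float)
    return LabeledObjects(labels, areas, cents, pixel_size_um)


def split_touching_objects(mask: np.ndarray, pixel_size_um: float = 1.0,
                           min_distance_um: float = 3.0) -> LabeledObjects:
    """Label nuclei while splitting touching profiles by watershed.

    Adjacent nuclear cross-sections merge under plain connected-component
    labeling; seeding a watershed on the Euclidean distance transform at
    local maxima at least `min_distance_um` apart separates them, the
    standard approach for convex nuclei.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        return LabeledObjects(mask.astype(np.int32), np.zeros(0),
                              np.zeros((0, 2)), pixel_size_um)
    dist = ndi.distance_transform_edt(mask)
    min_px = max(int(round(min_distance_um / pixel_size_um)), 1)
    coords = peak_local_max(dist, min_distance=min_px, labels=mask)
    if len(coords) == 0:
        return label_objects(mask, pixel_size_um, connectivity=8)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, markers, mask=mask)
    # relabel contiguously (watershed ids can skip when peaks coincide)
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    labels = remap[labels]
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=float) * pixel_size_um**2
    cents = np.array([p.centroid for p in props], dtype=float)
    return LabeledObjects(labels, areas, cents, pixel_size_um)


def equivalent_diameter_um(area_um2: np.ndarray) -> np.ndarray:
    """Diameter of the circle with the same area: 2 sqrt(A / pi)."""
    return 2.0 * np.sqrt(np.asarray(area_um2, dtype=float) / np.pi)


def filter_small_objects(objs: LabeledObjects, min_size: float,
                         units: str = "um_diameter") -> np.ndarray:
    """Remove objects below a physical size threshold; returns a binary mask.

    units='um_diameter' compares the equivalent circular diameter,
    units='um2_area' the object area. Survivors are unchanged.
    """
    if min_size < 0:
        raise ValueError("threshold must be nonnegative")
    if units == "um_diameter":
        sizes = equivalent_diameter_um(objs.areas_um2)
    elif units == "um2_area":
        sizes = objs.areas_um2
    else:
        raise ValueError(f"unknown units {units!r}")
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(objs.labels, keep).astype(np.uint8)


# ----------------------------------------------------------------------
# dataset manifest
# ----------------------------------------------------------------------
MANIFEST_COLUMNS = ["subject_id", "glomerulus_id", "group", "lesion",
                    "image_path", "glom_mask_path", "podo_mask_path",
                    "pixel_size_um"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "glomerulus_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_sample(row, root="") -> SegSample:
    """Load one manifest row into a SegSample."""
    j = lambda p: os.path.join(root, p) if root else p
    ps = float(row["pixel_size_um"])
    image = read_image(j(row["image_path"]), pixel_size_um=ps,
                       source_id=str(row["glomerulus_id"]))
    masks = MaskPair(read_mask(j(row["glom_mask_path"])),
                     read_mask(j(row["podo_mask_path"])), ps)
    return SegSample(image, masks, str(row["subject_id"]),
                     str(row["glomerulus_id"]), str(row["group"]),
                     str(row["lesion"]))
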