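"""Synthetic labeled root layouts and wall-stain segmentation.

A :class:`RootLayout` is the pixel-scale description of a root midplane
used by the 2D simulator: an integer label grid in which every cell is one
labeled region, all cell-wall pixels share a single wall label, and all
pixels outside the root share a single outside label, plus a map from cell
label to cell type (QC, VI, V, CEI, PER, CX, END, EPI, CSC, CC, LRC).

Because the original propidium-iodide confocal images are not distributed,
:func:`generate_layout` builds a synthetic root: vertical tissue files
(lateral root cap, epidermis, cortex, endodermis, pericycle, vasculature)
around a quiescent center near the tip, columella below it, with cell
walls of fixed 2-pixel width, and renders a matching synthetic wall-stain
image (bright walls, dim interiors, additive noise).  The segmentation
routine :func:`segment_image` then recovers the labeled layout from such a
stain image: global Otsu threshold, skeletonization of the wall mask back
to a fixed 2-pixel width, and 4-connected component labeling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, skeletonize

from .models import ConfigError

__all__ = [
    "CELL_TYPES",
    "RootLayout",
    "LayoutTemplate",
    "SegmentationError",
    "generate_layout",
    "segment_image",
    "assign_cell_types",
    "save_layout",
    "load_layout",
]

CELL_TYPES = ("QC", "VI", "V", "CEI", "PER", "CX", "END", "EPI", "CSC", "CC", "LRC")


class SegmentationError(RuntimeError):
    """Segmentation failed (e.g. no bimodal wall/interior intensity)."""


@dataclass
class RootLayout:
    """Pixel-label grid of a root midplane.

    ``labels`` has shape (height, width); ``outside_label`` marks pixels
    outside the root, ``wall_label`` all cell-wall pixels, and every other
    label one cell.  ``cell_types`` maps cell labels to type names (empty
    until :func:`assign_cell_types`).  ``pixel_size`` is in micrometers
    (1 pixel is about 0.5 um in the source images this emulates).
    """

    labels: np.ndarray
    wall_label: int = 1
    outside_label: int = 0
    cell_types: Dict[int, str] = field(default_factory=dict)
    basal_cells: Set[int] = field(default_factory=set)
    pixel_size: float = 0.5

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def cell_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[(lab != self.wall_label) & (lab != self.outside_label)]

    @property
    def cell_mask(self) -> np.ndarray:
        return (self.labels != self.wall_label) & (self.labels != self.outside_label)

    @property
    def wall_mask(self) -> np.ndarray:
        return self.labels == self.wall_label

    @property
    def root_mask(self) -> np.ndarray:
        return self.labels != self.outside_label

    def type_mask(self, *types: str) -> np.ndarray:
        """Boolean mask of all pixels belonging to cells of the given types."""
        wanted = {lab for lab, t in self.cell_types.items() if t in types}
        return np.isin(self.labels, list(wanted)) if wanted else np.zeros(self.shape, bool)


@dataclass
class LayoutTemplate:
    """Geometric recipe for a synthetic root.

    ``files`` lists the vertical tissue files left to right as
    ``(role, width_px, y_start)``: the file occupies columns of that width
    from ``y_start`` (rootward) to the top of the lattice.  Vascular files
    carry, from the bottom up: columella (CC) rows, one columella stem cell
    (CSC) row, one QC row, one vascular-initial (VI) row, then vascular (V)
    rows.  Cortex and endodermis files start with a cortex/endodermis
    initial (CEI).  ``noise_sd`` controls the synthetic stain image.
    """

    width: int = 228
    height: int = 448
    files: List[Tuple[str, int, int]] = field(default_factory=list)
    cc_rows: int = 3
    cc_height: int = 20
    csc_height: int = 16
    qc_height: int = 14
    vi_height: int = 16
    v_row_height: int = 30
    lateral_row_height: int = 26
    lrc_top: int = 260
    pixel_size: float = 0.5
    margin: int = 4
    wall_intensity: float = 200.0
    cell_intensity: float = 60.0
    outside_intensity: float = 15.0
    noise_sd: float = 6.0
    basal_types: Tuple[str, ...] = ("VI",)

    def __post_init__(self) -> None:
        if not self.files:
            self.files = self._default_files(self.width)
        total = sum(w for _, w, _ in self.files)
        if total != self.width:
            raise ConfigError(f"file widths sum to {total}, expected width {self.width}")
        if self.height < self.tip_stack_height + 2 * self.v_row_height:
            raise ConfigError("template height too small to place all tissue rows")

    @property
    def tip_stack_height(self) -> int:
        return (
            self.cc_rows * self.cc_height
            + self.csc_height
            + self.qc_height
            + self.vi_height
        )

    @staticmethod
    def _default_files(width: int) -> List[Tuple[str, int, int]]:
        # stylized WT midplane: symmetric files, vasculature deepest at the
        # tip (columella), laterals starting progressively higher, lateral
        # root cap at the flanks
        scale = width / 228.0
        base = [
            ("LRC", 16, 86),
            ("EPI", 18, 72),
            ("CX", 22, 58),
            ("END", 18, 44),
            ("PER", 16, 30),
            ("V", 16, 0),
            ("V", 16, 0),
            ("V", 16, 0),
            ("PER", 16, 30),
            ("END", 18, 44),
            ("CX", 22, 58),
            ("EPI", 18, 72),
            ("LRC", 16, 86),
        ]
        files = [(r, max(5, round(w * scale)), round(y * scale)) for r, w, y in base]
        # fix rounding drift on the central file
        drift = width - sum(w for _, w, _ in files)
        mid = len(files) // 2
        files[mid] = (files[mid][0], files[mid][1] + drift, files[mid][2])
        if files[mid][1] < 5:
            raise ConfigError("template width too small to place all tissue files")
        return files

    @classmethod
    def wildtype(cls) -> "LayoutTemplate":
        return cls(width=228, height=448)

    @classmethod
    def mutant(cls) -> "LayoutTemplate":
        return cls(width=231, height=448)

    @classmethod
    def small(cls, width: int = 100, height: int = 200) -> "LayoutTemplate":
        """Reduced lattice for fast simulations and tests.

        Uses fewer, proportionally larger cells than the full template so
        that the cell-interior to wall area ratio stays realistic at the
        coarse lattice (2-px walls around very small cells would otherwise
        turn the walls into a dominant reservoir).
        """
        u = width - 56
        if u < 20:
            raise ConfigError("small template needs width >= 76")
        files = [
            ("LRC", 8, 36),
            ("CX", 10, 20),
            ("PER", 10, 12),
            ("V", u // 2, 0),
            ("V", u - u // 2, 0),
            ("PER", 10, 12),
            ("CX", 10, 20),
            ("LRC", 8, 36),
        ]
        return cls(
            width=width,
            height=height,
            files=files,
            cc_rows=2,
            cc_height=14,
            csc_height=20,
            qc_height=22,
            vi_height=20,
            v_row_height=24,
            lateral_row_height=20,
            lrc_top=round(height * 0.58),
        )

    # -- geometry -----------------------------------------------------------

    def _row_edges(self, role: str, y_start: int, y_top: int) -> List[int]:
        """y boundaries of the cells in one file, bottom to top."""
        edges = [y_start]
        if role == "V":
            for _ in range(self.cc_rows):
                edges.append(edges[-1] + self.cc_height)
            edges.append(edges[-1] + self.csc_height)
            edges.append(edges[-1] + self.qc_height)
            edges.append(edges[-1] + self.vi_height)
            step = self.v_row_height
        else:
            step = self.lateral_row_height
        while edges[-1] + step <= y_top:
            edges.append(edges[-1] + step)
        if edges[-1] < y_top:
            edges[-1] = y_top  # absorb the remainder into the top cell
        return edges

    def _row_type(self, role: str, row: int) -> str:
        if role == "V":
            tip = ["CC"] * self.cc_rows + ["CSC", "QC", "VI"]
            return tip[row] if row < len(tip) else "V"
        if role in ("CX", "END") and row == 0:
            return "CEI"
        return role

    def build_maps(self) -> Tuple[np.ndarray, np.ndarray, Dict[int, str]]:
        """Ground-truth geometry: per-pixel cell index (-1 outside or wall is
        not yet carved), root mask, and cell-index -> type map."""
        ids = np.full((self.height, self.width), -1, dtype=np.int32)
        types: Dict[int, str] = {}
        x0 = 0
        next_id = 0
        for role, w, y_start in self.files:
            y_top = self.lrc_top if role == "LRC" else self.height - self.margin
            edges = self._row_edges(role, max(y_start, self.margin), y_top)
            xa = max(x0, self.margin)
            xb = min(x0 + w, self.width - self.margin)
            for row in range(len(edges) - 1):
                ids[edges[row] : edges[row + 1], xa:xb] = next_id
                types[next_id] = self._row_type(role, row)
                next_id += 1
            x0 += w
        return ids, ids >= 0, types


def _walls_from_ids(ids: np.ndarray) -> np.ndarray:
    """2-px walls wherever two different regions (or region and outside)
    touch; the root outline belongs to the wall label."""
    wall = np.zeros(ids.shape, bool)
    dx = ids[:, :-1] != ids[:, 1:]
    wall[:, :-1] |= dx
    wall[:, 1:] |= dx
    dy = ids[:-1, :] != ids[1:, :]
    wall[:-1, :] |= dy
    wall[1:, :] |= dy
    return wall


def generate_layout(
    template: Optional[LayoutTemplate] = None, seed: int = 0
) -> Tuple[RootLayout, np.ndarray]:
    """Build a typed synthetic layout and its wall-stain image.

    Deterministic for a given template and seed (the seed only drives the
    stain-image noise).  Returns ``(layout, stain)`` with ``stain`` a uint8
    image: bright on wall pixels, dim inside cells, dark outside.
    """
    template = template or LayoutTemplate.wildtype()
    ids, root, id_types = template.build_maps()
    wall = _walls_from_ids(ids) & _grow(root)
    cells = root & ~wall

    labels = np.zeros(ids.shape, dtype=np.int32)
    labels[wall] = 1
    cell_types: Dict[int, str] = {}
    basal: Set[int] = set()
    next_label = 2
    for cid in sorted(id_types):
        m = cells & (ids == cid)
        if not m.any():
            continue
        labels[m] = next_label
        cell_types[next_label] = id_types[cid]
        if id_types[cid] in template.basal_types:
            basal.add(next_label)
        next_label += 1

    layout = RootLayout(
        labels=labels,
        wall_label=1,
        outside_label=0,
        cell_types=cell_types,
        basal_cells=basal,
        pixel_size=template.pixel_size,
    )

    rng = np.random.default_rng(seed)
    stain = np.full(ids.shape, template.outside_intensity)
    stain[cells] = template.cell_intensity
    stain[labels == 1] = template.wall_intensity
    stain += rng.normal(0.0, template.noise_sd, ids.shape)
    stain = np.clip(stain, 0, 255).astype(np.uint8)
    return layout, stain


def _grow(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[:, :-1] |= mask[:, 1:]
    out[:, 1:] |= mask[:, :-1]
    out[:-1, :] |= mask[1:, :]
    out[1:, :] |= mask[:-1, :]
    return out


def segment_image(image: np.ndarray, min_cell_area: int = 4) -> RootLayout:
    """Recover a labeled layout (no cell types) from a wall-stain image.

    Pipeline: (1) global Otsu threshold isolates bright wall pixels;
    (2) the wall mask is skeletonized and re-thickened to the fixed 2-pixel
    width (guided by the thresholded mask, which suppresses isolated noise
    pixels); (3) 4-connected labeling of the non-wall pixels; components
    touching the image border are background and merge into the single
    outside label, the rest become cells.  Cells smaller than
    ``min_cell_area`` pixels are merged into the wall with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise SegmentationError("expected a 2D intensity image")
    if np.ptp(image) == 0:
        raise SegmentationError("constant image: no wall/interior intensity modes")
    thr = threshold_otsu(image)
    mask = image > thr
    frac = mask.mean()
    if frac < 0.01 or frac > 0.9:
        raise SegmentationError(
            f"threshold separates {frac:.0%} of pixels as walls; "
            "image does not look bimodal (walls vs interiors)"
        )
    skel = skeletonize(mask)
    # re-thicken the 1-px skeleton to the fixed 2-px wall width; keeping the
    # dilation inside the thresholded mask pins the wall onto the stained
    # pixels and drops noise specks away from walls
    wall = skel | (dilation(skel, footprint=np.ones((3, 3))) & mask)

    comp = cc_label(~wall, connectivity=1)
    border = np.zeros(image.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside_ids = np.unique(comp[border & ~wall])

    labels = np.ones(image.shape, dtype=np.int32)  # wall by default
    next_label = 2
    small = 0
    for cid in np.unique(comp):
        if cid == 0:
            continue
        m = comp == cid
        if cid in outside_ids:
            labels[m] = 0
            continue
        if m.sum() < min_cell_area:
            small += 1  # stays wall
            continue
        labels[m] = next_label
        next_label += 1
    if small:
        warnings.warn(
            f"merged {small} region(s) below {min_cell_area} px into the wall",
            RuntimeWarning,
            stacklevel=2,
        )
    return RootLayout(labels=labels, wall_label=1, outside_label=0)


def assign_cell_types(layout: RootLayout, template: LayoutTemplate) -> RootLayout:
    """Assign a cell type to every cell label using the template geometry.

    Each cell's pixels are looked up in the template's ground-truth type
    raster and the majority type wins; a cell whose pixels fall entirely
    outside the template's typed area is an error.
    """
    ids, _, id_types = template.build_maps()
    if ids.shape != layout.shape:
        raise ConfigError("template lattice does not match the layout")
    basal: Set[int] = set()
    for lab in layout.cell_labels:
        m = layout.labels == lab
        cell_ids = ids[m]
        cell_ids = cell_ids[cell_ids >= 0]
        if cell_ids.size == 0:
            ys, xs = np.nonzero(m)
            raise ConfigError(
                f"cell label {lab} (centroid {ys.mean():.0f},{xs.mean():.0f}) "
                "is not covered by the template"
            )
        winner = np.bincount(cell_ids).argmax()
        layout.cell_types[int(lab)] = id_types[int(winner)]
        if id_types[int(winner)] in template.basal_types:
            basal.add(int(lab))
    layout.basal_cells = basal
    return layout


def save_layout(layout: RootLayout, png_path, json_path=None) -> None:
    """Persist a layout as 16-bit grayscale PNG plus a JSON sidecar."""
    from PIL import Image

    png_path = Path(png_path)
    json_path = Path(json_path) if json_path else png_path.with_suffix(".json")
    if layout.labels.max() > 65535 or layout.labels.min() < 0:
        raise ConfigError("labels do not fit a 16-bit PNG")
    Image.fromarray(layout.labels.astype(np.uint16)).save(png_path)
    sidecar = {
        "wall_label": layout.wall_label,
        "outside_label": layout.outside_label,
        "pixel_size": layout.pixel_size,
        "cell_types": {str(k): v for k, v in layout.cell_types.items()},
        "basal_cells": sorted(int(b) for b in layout.basal_cells),
    }
    json_path.write_text(json.dumps(sidecar, indent=2))


def load_layout(png_path, json_path=None) -> RootLayout:
    from PIL import Image

    png_path = Path(png_path)
    json_path = Path(json_path) if json_path else png_path.with_suffix(".json")
    labels = np.asarray(Image.open(png_path), dtype=np.int32)
    meta = json.loads(json_path.read_text())
    return RootLayout(
        labels=labels,
        wall_label=int(meta["wall_label"]),
        outside_label=int(meta["outside_label"]),
        cell_types={int(k): v for k, v in meta["cell_types"].items()},
        basal_cells=set(meta.get("basal_cells", [])),
        pixel_size=float(meta["pixel_size"]),
    )
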