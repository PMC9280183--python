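"""Electrode geometry: labels, scalp coordinates, brain-region assignment,
and the azimuthal equidistant projection (AEP) onto the 2D imaging plane.

The five scalp regions used throughout the package are the frontal lobe,
parietal lobe, left and right temporal lobes, and occipital lobe. Electrodes
live on a head-centered unit sphere (x toward the right ear, y toward the
nasion, z toward the vertex). The AEP maps an electrode at polar angle
``phi`` from the vertex and azimuth ``psi`` to the plane point
``(phi*cos(psi), phi*sin(psi))``: azimuths are preserved exactly and the
planar radius equals the great-circle distance from the vertex, so scalp
topography is rendered without radial distortion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "ElectrodeMontage",
    "Projection2D",
    "MontageError",
    "load_montage",
    "default_montage",
    "assign_regions",
    "project_aep",
]

#: The five scalp regions, in canonical order.
REGIONS: tuple[str, ...] = (
    "frontal",
    "parietal",
    "left_temporal",
    "right_temporal",
    "occipital",
)

UNASSIGNED = "unassigned"


class MontageError(ValueError):
    """Raised for invalid montage geometry or region configuration."""


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels, unit-sphere coordinates, and region membership.

    Parameters
    ----------
    labels
        Unique, non-empty channel names, e.g. ``"F3"``.
    coords3d
        Array of shape ``(n, 3)``; every row must have unit Euclidean norm.
    region_of
        Mapping from label to one of :data:`REGIONS` or ``"unassigned"``.
    """

    labels: tuple[str, ...]
    coords3d: np.ndarray
    region_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords3d, dtype=float)
        object.__setattr__(self, "coords3d", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MontageError(f"coords3d must be (n, 3), got {coords.shape}")
        if len(self.labels) != coords.shape[0]:
            raise MontageError("labels and coords3d length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise MontageError("duplicate electrode labels")
        if any(not lab for lab in self.labels):
            raise MontageError("empty electrode label")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            bad = [self.labels[i] for i in np.where(np.abs(norms - 1) > 1e-9)[0]]
            raise MontageError(f"electrode coordinates not on the unit sphere: {bad}")
        for lab, reg in self.region_of.items():
            if reg not in REGIONS and reg != UNASSIGNED:
                raise MontageError(f"unknown region {reg!r} for electrode {lab!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"electrode {label!r} not in montage") from None

    def region_members(self, region: str) -> list[str]:
        """Labels assigned to ``region``, in montage order."""
        return [lab for lab in self.labels if self.region_of.get(lab, UNASSIGNED) == region]

    def coords_of(self, subset: Sequence[str]) -> np.ndarray:
        return self.coords3d[[self.index_of(lab) for lab in subset]]


@dataclass(frozen=True)
class Projection2D:
    """Planar (u, v) electrode coordinates with their source labels."""

    coords2d: np.ndarray
    source_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords2d, dtype=float)
        object.__setattr__(self, "coords2d", coords)
        object.__setattr__(self, "source_labels", tuple(self.source_labels))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise MontageError(f"coords2d must be (n, 2), got {coords.shape}")
        if coords.shape[0] != len(self.source_labels):
            raise MontageError("coords2d and source_labels length mismatch")


# --- region rule -----------------------------------------------------------

# Prefix rules, longest match first. Midline "z" electrodes follow their
# prefix (Fz -> frontal, Oz -> occipital ...); lateral temporal electrodes
# split by the 10-20 odd/even (left/right) numbering convention.
_PREFIX_REGION: tuple[tuple[str, str], ...] = (
    ("FP", "frontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("FC", "frontal"),
    ("F", "frontal"),
    ("TP", "temporal"),
    ("T", "temporal"),
    ("CP", "parietal"),
    ("C", "parietal"),
    ("PO", "occipital"),
    ("P", "parietal"),
    ("O", "occipital"),
)


def _prefix_rule(label: str) -> str:
    up = label.upper()
    for prefix, region in _PREFIX_REGION:
        if up.startswith(prefix):
            if region != "temporal":
                return region
            m = re.search(r"(\d+)$", up)
            if m is None:  # midline temporal does not occur in 10-20
                return UNASSIGNED
            return "left_temporal" if int(m.group(1)) % 2 else "right_temporal"
    return UNASSIGNED


def assign_regions(
    montage: ElectrodeMontage,
    rule: Mapping[str, str] | None = None,
    *,
    min_per_region: int = 3,
) -> ElectrodeMontage:
    """Assign every electrode to one of the five regions.

    ``rule`` may be an explicit label -> region table; labels it does not
    cover fall back to the default 10-20 prefix rule. Electrodes matching
    no rule map to ``"unassigned"``. Each of the five regions must end up
    with at least ``min_per_region`` electrodes (triangulated interpolation
    needs three non-collinear sites).
    """
    table = {k: v for k, v in (rule or {}).items()}
    for reg in table.values():
        if reg not in REGIONS and reg != UNASSIGNED:
            raise MontageError(f"region rule maps to unknown region {reg!r}")
    region_of = {
        lab: table.get(lab, _prefix_rule(lab)) for lab in montage.labels
    }
    out = ElectrodeMontage(montage.labels, montage.coords3d, region_of)
    for reg in REGIONS:
        n = len(out.region_members(reg))
        if n < min_per_region:
            raise MontageError(
                f"region {reg!r} has {n} electrodes; at least "
                f"{min_per_region} are required for interpolation"
            )
    return out


# --- projection ------------------------------------------------------------

def project_aep(montage: ElectrodeMontage, subset: Sequence[str] | None = None) -> Projection2D:
    """Azimuthal equidistant projection of ``subset`` (default: all electrodes).

    Each electrode at polar angle ``phi`` (great-circle distance from the
    vertex ``(0, 0, 1)``) and azimuth ``psi = atan2(y, x)`` maps to
    ``(u, v) = (phi*cos(psi), phi*sin(psi))``. The nose (+y) points toward
    +v, the right ear (+x) toward +u. An electrode antipodal to the vertex
    has no well-defined azimuth and is rejected.
    """
    labels = tuple(subset) if subset is not None else montage.labels
    xyz = montage.coords_of(labels)
    z = np.clip(xyz[:, 2], -1.0, 1.0)
    phi = np.arccos(z)
    if np.any(phi >= np.pi - 1e-12):
        bad = [labels[i] for i in np.where(phi >= np.pi - 1e-12)[0]]
        raise MontageError(f"electrodes antipodal to the vertex cannot be projected: {bad}")
    psi = np.arctan2(xyz[:, 1], xyz[:, 0])
    uv = np.column_stack([phi * np.cos(psi), phi * np.sin(psi)])
    return Projection2D(uv, labels)


# --- loading ---------------------------------------------------------------

def load_montage(
    path: str | Path,
    region_table: Mapping[str, str] | None = None,
    *,
    assign: bool = True,
) -> ElectrodeMontage:
    """Read a montage from a text file of ``label x y z`` rows.

    Fields may be separated by whitespace or commas; ``#`` starts a comment.
    Coordinates are normalized to unit norm on load. When ``assign`` is
    true, regions are assigned via :func:`assign_regions` (with
    ``region_table`` overriding the prefix rule).
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[\s,]+", line)
        if len(parts) != 4:
            raise MontageError(f"malformed montage line: {raw!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    coords = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MontageError("zero-length coordinate vector in montage file")
    montage = ElectrodeMontage(labels, coords / norms)
    if assign:
        montage = assign_regions(montage, region_table)
    return montage


def default_montage() -> ElectrodeMontage:
    """The packaged idealized 36-channel extended 10-20 montage, regions assigned."""
    ref = resources.files("eegfusion.data") / "montage_1020_36.txt"
    with resources.as_file(ref) as path:
        return load_montage(path)
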