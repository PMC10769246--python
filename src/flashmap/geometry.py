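"""Layered Golgi ribbon geometry and docking-site placement.

The Golgi stack is modelled in 2-D (the acquisition is near-TIRF, so axial
structure appears as in-plane offsets after projection): a ribbon backbone
polyline plus, per protein species, a parallel layer displaced along the
local stack normal (``axial_offset``, cis->trans) and optionally along the
ribbon tangent (``lateral_offset``).  Docking strands are laid on each
species' layer as a 1-D Poisson process, thinned by labeling efficiency and
smeared by membrane jitter and antibody/nanobody linkage error.

Coordinate convention (used package-wide): nanometres, origin at the field's
top-left corner, x to the right, y down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesSpec",
    "GolgiGeometry",
    "BindingSiteSet",
    "GeometryError",
    "build_geometry",
    "place_binding_sites",
    "offset_polyline",
    "polyline_length",
    "STACK_MARKERS",
    "GOLGI7_OFFSETS",
]

#: The five cis->trans Golgi stack markers of the seven-target panel,
#: in ground-truth axial order.
STACK_MARKERS = ("GM130", "GRASP65", "Giantin", "Golgin97", "TGN46")

#: Default axial offsets (nm along the stack normal) for the seven-target
#: preset.  These reproduce the qualitative cis->trans ordering of the
#: markers; they are configuration defaults, not measured ultrastructure.
GOLGI7_OFFSETS = {
    "GM130": 0.0,
    "GRASP65": 10.0,
    "VPS13B": 30.0,
    "Giantin": 80.0,
    "Golgin97": 190.0,
    "TGN46": 210.0,
    "bCOP": 0.0,  # COPI coat: same axial level as cis, laterally displaced
}

#: Lateral (tangential) offsets for the seven-target preset.
GOLGI7_LATERAL = {name: 0.0 for name in GOLGI7_OFFSETS}
GOLGI7_LATERAL["bCOP"] = 300.0


class GeometryError(ValueError):
    """A geometry section failed validation."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One labelled protein species and its ground-truth layer placement.

    Parameters
    ----------
    name:
        Species label, e.g. ``"GM130"``.
    axial_offset:
        Displacement (nm) of this species' layer from the backbone along the
        stack normal (cis->trans direction).
    lateral_offset:
        Displacement (nm) along the ribbon tangent.
    site_linear_density:
        Docking-site density along the layer, sites per micrometre.
    membrane_jitter_sigma:
        Per-coordinate Gaussian spread (nm) of epitopes around the ideal
        layer line.
    """

    name: str
    axial_offset: float = 0.0
    lateral_offset: float = 0.0
    site_linear_density: float = 50.0
    membrane_jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.site_linear_density <= 0:
            raise GeometryError(
                f"species {self.name!r}: site_linear_density must be > 0"
            )
        if self.membrane_jitter_sigma < 0:
            raise GeometryError(
                f"species {self.name!r}: membrane_jitter_sigma must be >= 0"
            )


def polyline_length(points: np.ndarray) -> float:
    """Total arc length of a polyline given as an (n, 2) array (nm)."""
    seg = np.diff(points, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def _vertex_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent per vertex (average of adjacent segment directions)."""
    seg = np.diff(points, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    tang = np.empty_like(points)
    tang[0] = seg[0]
    tang[-1] = seg[-1]
    if len(points) > 2:
        mid = seg[:-1] + seg[1:]
        norms = np.linalg.norm(mid, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        tang[1:-1] = mid / norms
    return tang


def offset_polyline(points: np.ndarray, axial: float, lateral: float) -> np.ndarray:
    """Shift a polyline by ``axial`` nm along its normal and ``lateral`` nm
    along its tangent.

    With x right / y down, the normal of tangent (tx, ty) is (-ty, tx); for a
    left-to-right horizontal backbone the axial direction therefore points
    down the field (increasing y), which is the cis->trans direction of the
    presets.
    """
    pts = np.asarray(points, dtype=float)
    tang = _vertex_tangents(pts)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    return pts + axial * normal + lateral * tang


@dataclass(frozen=True)
class GolgiGeometry:
    """A ribbon backbone, a species panel, and the field extent.

    ``backbone`` is an ordered (n, 2) array of control points (nm) defining
    the ribbon polyline; every species' offset layer must lie inside
    ``field_size``.
    """

    backbone: np.ndarray
    species_panel: tuple[SpeciesSpec, ...]
    field_size: tuple[float, float]

    def __post_init__(self) -> None:
        bb = np.asarray(self.backbone, dtype=float)
        object.__setattr__(self, "backbone", bb)
        object.__setattr__(self, "species_panel", tuple(self.species_panel))
        if bb.ndim != 2 or bb.shape[1] != 2 or bb.shape[0] < 2:
            raise GeometryError("backbone must be an (n>=2, 2) point array")
        w, h = self.field_size
        if not _inside(bb, w, h):
            raise GeometryError("backbone lies outside field_size")
        names = [s.name for s in self.species_panel]
        if len(set(names)) != len(names):
            raise GeometryError("species names must be unique within a panel")
        for spec in self.species_panel:
            layer = offset_polyline(bb, spec.axial_offset, spec.lateral_offset)
            if not _inside(layer, w, h):
                raise GeometryError(
                    f"layer of species {spec.name!r} lies outside field_size"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_panel)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species_panel]

    def layer(self, species_index: int) -> np.ndarray:
        """Offset polyline (nm) of one species' layer."""
        spec = self.species_panel[species_index]
        return offset_polyline(self.backbone, spec.axial_offset, spec.lateral_offset)


def _inside(points: np.ndarray, w: float, h: float) -> bool:
    return bool(
        np.all(points[:, 0] >= 0)
        and np.all(points[:, 0] <= w)
        and np.all(points[:, 1] >= 0)
        and np.all(points[:, 1] <= h)
    )


def build_geometry(config: dict) -> GolgiGeometry:
    """Build a validated :class:`GolgiGeometry` from a geometry config section.

    ``config["preset"]`` may be ``"two_layer"`` (two parallel straight
    ribbons separated by ``delta`` nm), ``"golgi7"`` (the seven-target panel
    with the default cis->trans offsets), or ``"explicit"`` with a
    ``backbone`` point list and a ``panel`` of species dicts.
    """
    cfg = dict(config)
    preset = cfg.get("preset", "explicit")
    if preset == "two_layer":
        return _two_layer(cfg)
    if preset == "golgi7":
        return _golgi7(cfg)
    if preset == "explicit":
        backbone = np.asarray(cfg["backbone"], dtype=float)
        panel = tuple(SpeciesSpec(**d) for d in cfg["panel"])
        field_size = tuple(cfg["field_size"])
        return GolgiGeometry(backbone, panel, field_size)
    raise GeometryError(f"unknown geometry preset {preset!r}")


def _two_layer(cfg: dict) -> GolgiGeometry:
    delta = float(cfg.get("delta", 60.0))
    length = float(cfg.get("ribbon_length", 4000.0))
    density = float(cfg.get("site_density_per_um", 200.0))
    jitter = float(cfg.get("membrane_jitter_sigma", 0.0))
    margin = float(cfg.get("margin", 500.0))
    field_size = tuple(
        cfg.get("field_size", (length + 2 * margin, abs(delta) + 2 * margin))
    )
    y0 = margin
    backbone = np.array([[margin, y0], [margin + length, y0]])
    panel = (
        SpeciesSpec("A", 0.0, 0.0, density, jitter),
        SpeciesSpec("B", delta, 0.0, density, jitter),
    )
    return GolgiGeometry(backbone, panel, field_size)


def _golgi7(cfg: dict) -> GolgiGeometry:
    """Seven-target panel on a curved ribbon.

    The backbone is a circular arc rather than a straight line: Golgi
    ribbons curve, so the stack normal varies along the ribbon and the
    inter-layer offsets are not expressible as a rigid translation (which
    also keeps translation-based round alignment from cancelling them).
    """
    length = float(cfg.get("ribbon_length", 8000.0))
    density = float(cfg.get("site_density_per_um", 50.0))
    jitter = float(cfg.get("membrane_jitter_sigma", 5.0))
    margin = float(cfg.get("margin", 600.0))
    arc_span = float(cfg.get("arc_span_deg", 240.0)) * np.pi / 180.0
    offsets = dict(GOLGI7_OFFSETS)
    offsets.update(cfg.get("axial_offsets", {}))
    laterals = dict(GOLGI7_LATERAL)
    laterals.update(cfg.get("lateral_offsets", {}))
    radius = length / arc_span
    # arc centred in the field; the normal (-ty, tx) points toward the arc
    # centre, so positive axial offsets give concentric arcs of smaller
    # radius (layer spacing = offset difference)
    theta = np.linspace(-arc_span / 2.0, arc_span / 2.0, 96)
    pad = margin + max(max(offsets.values()), 0.0) + max(laterals.values())
    cx = radius + pad
    cy = radius + pad
    xs = cx + radius * np.sin(theta)
    ys = cy - radius * np.cos(theta)
    backbone = np.column_stack([xs, ys])
    extent = 2 * (radius + pad)
    field_size = tuple(cfg.get("field_size", (extent, extent)))
    panel = tuple(
        SpeciesSpec(name, offsets[name], laterals[name], density, jitter)
        for name in offsets
    )
    return GolgiGeometry(backbone, panel, field_size)


@dataclass(frozen=True)
class BindingSiteSet:
    """Ground-truth docking-strand coordinates after labeling and linkage error.

    Arrays are aligned by site index; ``species_id`` indexes into
    ``species_names`` (and into the panel of the geometry that produced it).
    """

    species_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    species_names: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("species_id", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.species_id) == len(self.x) == len(self.y)):
            raise ValueError("site arrays must be aligned")
        if len(self.x) and not (
            np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))
        ):
            raise ValueError("site coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def subset(self, mask: np.ndarray) -> "BindingSiteSet":
        return BindingSiteSet(
            self.species_id[mask], self.x[mask], self.y[mask], self.species_names
        )


def _sample_on_polyline(polyline: np.ndarray, arc_pos: np.ndarray) -> np.ndarray:
    """Map arc-length positions to (x, y) points on a polyline."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, arc_pos, side="right") - 1, 0, len(seg_len) - 1)
    frac = (arc_pos - cum[idx]) / seg_len[idx]
    return polyline[idx] + frac[:, None] * seg[idx]


def place_binding_sites(
    geometry: GolgiGeometry,
    labeling_efficiency: float,
    linkage_sigma: float,
    seed: int | np.random.Generator,
) -> BindingSiteSet:
    """Lay docking sites on every species' layer.

    Candidate sites arrive as a 1-D Poisson process with the species' linear
    density along its offset polyline, are retained independently with
    probability ``labeling_efficiency``, and are then displaced by isotropic
    Gaussian noise of per-coordinate sd
    ``sqrt(membrane_jitter_sigma**2 + linkage_sigma**2)`` (epitope spread
    plus antibody/nanobody linkage error).  Deterministic given the seed.
    """
    if not 0 < labeling_efficiency <= 1:
        raise ValueError("labeling_efficiency must be in (0, 1]")
    if linkage_sigma < 0:
        raise ValueError("linkage_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ids, xs, ys = [], [], []
    for i, spec in enumerate(geometry.species_panel):
        layer = geometry.layer(i)
        length = polyline_length(layer)
        n_candidates = rng.poisson(spec.site_linear_density * length / 1000.0)
        n_kept = rng.binomial(n_candidates, labeling_efficiency)
        arc = rng.uniform(0.0, length, size=n_kept)
        pts = _sample_on_polyline(layer, arc)
        sigma = float(np.hypot(spec.membrane_jitter_sigma, linkage_sigma))
        if sigma > 0:
            pts = pts + rng.normal(0.0, sigma, size=pts.shape)
        ids.append(np.full(n_kept, i, dtype=np.int64))
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
    species_id = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if len(x) == 0:
        warnings.warn("binding-site placement produced no sites", stacklevel=2)
    return BindingSiteSet(species_id, x, y, tuple(geometry.species_names))
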