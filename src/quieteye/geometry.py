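"""Scene geometry: visual angles and area-of-interest (AOI) assignment.

The scene is described in a flat, target-centred angular frame (degrees of
visual angle, hoop centre at the origin, x rightward, y upward).  At the
eccentricities involved (a few degrees) the flat-plane approximation to the
view sphere is accurate to well under 0.1% and is used throughout.

Gaze is assigned to regions with the cursor-majority rule: the gaze cursor
is a disc of fixed angular radius, and a sample belongs to the region that
contains *more than half* of the disc's area.  A thin rim band surrounds the
hoop; when the majority of the cursor lies on the rim it is re-coded to the
backboard (above hoop mid-height) or the net (below), the only two fallback
regions available.  An exact 50/50 split has no majority and yields ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from shapely.geometry import Point, box

from .core import ConfigurationError, REGIONS

#: Disc polygons use this many segments per quarter circle; the resulting
#: area error is ~1e-5 of the disc, far below the 50% decision boundary.
_QUAD_SEGS = 64

#: Area fractions within this slop of 1/2 are treated as a tie (no majority).
_TIE_TOL = 1e-9

HOOP_THIRDS = ("hoop_left", "hoop_centre", "hoop_right")
DYNAMIC_REGIONS = ("ball", "passer")


def visual_angle(object_width_m: float, distance_m: float) -> float:
    """Visual angle (degrees) subtended by ``object_width_m`` at ``distance_m``.

    Uses the exact two-sided formula ``2*atan(w / 2d)``.  A 15.24 cm hoop
    third viewed from 7.01 m subtends 1.25 degrees (to 2 d.p.).
    """
    if distance_m <= 0:
        raise ValueError(f"distance must be positive, got {distance_m}")
    if object_width_m < 0:
        raise ValueError(f"object width must be non-negative, got {object_width_m}")
    return math.degrees(2.0 * math.atan(object_width_m / (2.0 * distance_m)))


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in angular coordinates (centre + extents)."""

    cx: float
    cy: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("rectangle extents must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.width / 2.0,
            self.cy - self.height / 2.0,
            self.cx + self.width / 2.0,
            self.cy + self.height / 2.0,
        )

    def shifted(self, dx: float, dy: float) -> "Rect":
        return Rect(self.cx + dx, self.cy + dy, self.width, self.height)


@dataclass(frozen=True)
class AOIRegion:
    name: str
    shape: Rect
    dynamic: bool = False

    def __post_init__(self) -> None:
        if self.name not in REGIONS:
            raise ConfigurationError(f"unknown region name {self.name!r}")


@dataclass
class SceneLayout:
    """The coded scene: three abutting hoop thirds, static aux regions, a rim
    band, and dynamic ball/passer regions whose positions arrive per sample."""

    viewing_distance_m: float
    hoop_width_m: float
    cursor_radius_deg: float
    regions: dict[str, AOIRegion]
    rim_band_deg: float

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.regions)
        if missing:
            raise ConfigurationError(f"layout missing regions: {sorted(missing)}")
        if self.cursor_radius_deg <= 0:
            raise ConfigurationError("cursor radius must be positive")
        widths = {self.regions[n].shape.width for n in HOOP_THIRDS}
        if max(widths) - min(widths) > 1e-9:
            raise ConfigurationError("hoop thirds must have equal angular width")
        # Thirds must abut left-to-right at a common height.
        left, centre, right = (self.regions[n].shape for n in HOOP_THIRDS)
        for a, b in ((left, centre), (centre, right)):
            if abs((a.cx + a.width / 2.0) - (b.cx - b.width / 2.0)) > 1e-6 or (
                abs(a.cy - b.cy) > 1e-6
            ):
                raise ConfigurationError("hoop thirds must abut at a common height")
        self._check_static_overlap()

    def _check_static_overlap(self) -> None:
        names = [n for n, r in self.regions.items() if not r.dynamic]
        polys = {n: box(*self.regions[n].shape.bounds) for n in names}
        hoop = set(HOOP_THIRDS)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if a in hoop and b in hoop:
                    continue  # thirds abut by construction
                inter = polys[a].intersection(polys[b]).area
                if inter > 1e-9:
                    raise ConfigurationError(
                        f"static regions {a!r} and {b!r} overlap (area {inter:.3g} deg^2)"
                    )

    @property
    def hoop_rect(self) -> Rect:
        """Bounding rectangle of the three abutting hoop thirds."""
        l = self.regions["hoop_left"].shape
        r = self.regions["hoop_right"].shape
        x0 = l.bounds[0]
        x1 = r.bounds[2]
        return Rect((x0 + x1) / 2.0, l.cy, x1 - x0, l.height)

    @property
    def hoop_mid_height_deg(self) -> float:
        return self.hoop_rect.cy


def _default_aux_regions(hoop: Rect, rim_band: float) -> dict[str, Rect]:
    """Regulation-sized net and backboard placed clear of the hoop+rim band.

    Physical extents of the net and backboard are not part of the coding
    scheme itself, so these defaults use regulation geometry (1.83 x 1.07 m
    backboard, 0.45 m net) at the configured viewing distance and are fully
    overridable.
    """
    bb_w, bb_h = 14.87, 8.68  # deg; 1.829 x 1.067 m at 7.01 m
    net_w, net_h = hoop.width, 3.68  # net drops straight below the hoop
    top = hoop.cy + hoop.height / 2.0 + rim_band
    bottom = hoop.cy - hoop.height / 2.0 - rim_band
    margin = 0.2
    return {
        "backboard": Rect(hoop.cx, top + margin + bb_h / 2.0, bb_w, bb_h),
        "net": Rect(hoop.cx, bottom - margin - net_h / 2.0, net_w, net_h),
    }


def build_scene_layout(
    hoop_width_m: float = 0.4572,
    distance_m: float = 7.01,
    cursor_diameter_deg: Optional[float] = None,
    aux_regions: Optional[Mapping[str, Rect]] = None,
    rim_band_deg: float = 0.16,
    hoop_height_deg: Optional[float] = None,
) -> SceneLayout:
    """Build the seven-region scene layout from physical hoop geometry.

    Each hoop third subtends ``visual_angle(hoop_width_m / 3, distance_m)``;
    with the defaults (45.72 cm hoop at 7.01 m) that is 1.25 degrees, and the
    gaze-cursor diameter defaults to the same 1.25 degrees.
    """
    if hoop_width_m <= 0:
        raise ConfigurationError("hoop width must be positive")
    third_deg = visual_angle(hoop_width_m / 3.0, distance_m)
    if cursor_diameter_deg is None:
        cursor_diameter_deg = third_deg
    if hoop_height_deg is None:
        hoop_height_deg = third_deg
    thirds = {
        "hoop_left": Rect(-third_deg, 0.0, third_deg, hoop_height_deg),
        "hoop_centre": Rect(0.0, 0.0, third_deg, hoop_height_deg),
        "hoop_right": Rect(third_deg, 0.0, third_deg, hoop_height_deg),
    }
    hoop = Rect(0.0, 0.0, 3.0 * third_deg, hoop_height_deg)
    aux = dict(_default_aux_regions(hoop, rim_band_deg))
    if aux_regions:
        aux.update(aux_regions)
    regions: dict[str, AOIRegion] = {
        name: AOIRegion(name, rect) for name, rect in thirds.items()
    }
    for name in ("net", "backboard"):
        regions[name] = AOIRegion(name, aux[name])
    # Dynamic regions: rectangle sizes from regulation ball (24 cm) and a
    # nominal passer silhouette; positions are supplied per sample.
    ball_deg = visual_angle(0.24, distance_m)
    regions["ball"] = AOIRegion("ball", Rect(0.0, 0.0, ball_deg, ball_deg), dynamic=True)
    regions["passer"] = AOIRegion(
        "passer", Rect(0.0, 0.0, visual_angle(0.5, distance_m), visual_angle(1.8, distance_m)),
        dynamic=True,
    )
    return SceneLayout(
        viewing_distance_m=distance_m,
        hoop_width_m=hoop_width_m,
        cursor_radius_deg=cursor_diameter_deg / 2.0,
        regions=regions,
        rim_band_deg=rim_band_deg,
    )


def _disc(cx: float, cy: float, r: float):
    return Point(cx, cy).buffer(r, quad_segs=_QUAD_SEGS)


def disc_rect_overlap(cx: float, cy: float, r: float, rect: Rect) -> float:
    """Area of intersection between the cursor disc and a rectangle."""
    return _disc(cx, cy, r).intersection(box(*rect.bounds)).area


def assign_aoi(
    cursor_centre: tuple[float, float],
    layout: SceneLayout,
    dynamic_positions: Optional[Mapping[str, tuple[float, float]]] = None,
) -> Optional[str]:
    """Cursor-majority AOI assignment.

    Returns the region holding a strict majority (>50%) of the cursor disc's
    area, or ``None`` when no region does (including exact ties).  Dynamic
    regions (ball, passer) are foreground objects and take precedence over
    static scenery when both contain a majority.  A rim-band majority is
    re-coded to backboard or net by the cursor's vertical position relative
    to hoop mid-height.
    """
    cx, cy = cursor_centre
    disc = _disc(cx, cy, layout.cursor_radius_deg)
    disc_area = disc.area
    half = 0.5 * disc_area

    def frac(rect: Rect) -> float:
        return disc.intersection(box(*rect.bounds)).area / disc_area

    # Foreground (dynamic) regions first.
    if dynamic_positions:
        for name in DYNAMIC_REGIONS:
            if name not in dynamic_positions:
                continue
            px, py = dynamic_positions[name]
            if not (math.isfinite(px) and math.isfinite(py)):
                continue
            shape = layout.regions[name].shape
            if frac(Rect(px, py, shape.width, shape.height)) > 0.5 + _TIE_TOL:
                return name

    for name, region in layout.regions.items():
        if region.dynamic:
            continue
        if frac(region.shape) > 0.5 + _TIE_TOL:
            return name

    # Rim band: the frame of width rim_band_deg around the hoop rectangle.
    hoop = layout.hoop_rect
    outer = Rect(hoop.cx, hoop.cy, hoop.width + 2 * layout.rim_band_deg,
                 hoop.height + 2 * layout.rim_band_deg)
    rim_area = (disc.intersection(box(*outer.bounds)).area
                - disc.intersection(box(*hoop.bounds)).area)
    if rim_area > half + _TIE_TOL * disc_area:
        return "backboard" if cy > layout.hoop_mid_height_deg else "net"
    return None
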