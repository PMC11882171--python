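"""Digital phantom simulator for VFA T1 relaxometry.

Renders multi-flip-angle FLASH acquisitions of (a) a cylindrical
quality-assurance phantom holding up to 12 gel tubes of certified T1 and
(b) a simple abdomen-like fixture (elliptical body, liver region,
surface reference tubes), so every pipeline stage is testable without
scanner data.

The forward model per pixel is the SPGR equation with the tissue (T1, M0)
of the region containing the pixel center, an effective flip angle
``nominal * b1(x, y)`` when a transmit-field (B1) error map is configured,
and Rician noise: each of ``averages`` excitations receives independent
complex Gaussian noise of standard deviation ``noise_sigma`` (in M0
units) per channel; the complex samples are averaged and the magnitude
taken, so zero-signal pixels follow a Rayleigh law with scale
``noise_sigma / sqrt(averages)``.

Geometry is expressed in mm in an image-centered frame: x along columns
(rightwards), y along rows (upwards), origin at the matrix center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mapping import FlipAngleImage
from .signal_model import AcquisitionParams, spgr_signal

__all__ = [
    "TubeSlot",
    "RadialB1Field",
    "PhantomSpec",
    "AbdomenFixtureSpec",
    "default_slot_center",
    "render_acquisition",
    "render_pair",
    "make_rr_validation_phantom",
    "DEFAULT_VALIDATION_PAIRS",
    "DEFAULT_SLOT_ASSIGNMENT",
]

#: Certified (pre, post) tube T1 pairs of the RR validation layout, ms.
DEFAULT_VALIDATION_PAIRS = ((657.0, 325.0), (1264.0, 487.0),
                            (657.0, 328.0), (813.0, 500.0))
#: Slot pair hosting each validation pair (each pair measured in two slots).
DEFAULT_SLOT_ASSIGNMENT = ((1, 12), (2, 11), (4, 9), (6, 7))


@dataclass(frozen=True)
class TubeSlot:
    """A tube in a numbered phantom slot: position (mm), diameter, certified T1."""

    slot_id: int
    center_mm: tuple[float, float]
    t1: float
    m0: float = 1000.0
    diameter_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError(f"slot {self.slot_id}: t1 must be > 0 ms")
        if self.m0 < 0 or self.diameter_mm <= 0:
            raise ValueError(f"slot {self.slot_id}: bad m0 or diameter")


@dataclass(frozen=True)
class RadialB1Field:
    """Smooth multiplicative flip-angle error: b(r) = 1 + amplitude * (r/R)^2.

    Mimics the space-related systematic error of a real transmit coil;
    ``radius_mm`` defaults to the phantom/body radius at render time.
    """

    amplitude: float = 0.08
    radius_mm: float | None = None

    def __call__(self, x: np.ndarray, y: np.ndarray, default_radius: float) -> np.ndarray:
        r2 = (x ** 2 + y ** 2)
        radius = self.radius_mm if self.radius_mm is not None else default_radius
        return 1.0 + self.amplitude * r2 / radius ** 2


def default_slot_center(slot_id: int, cylinder_radius_mm: float,
                        ring_fraction: float = 0.7) -> tuple[float, float]:
    """Center of a numbered slot: 12 equally spaced positions on a ring at
    ``ring_fraction`` of the cylinder radius, slot 1 at 12 o'clock,
    numbered clockwise."""
    if not 1 <= slot_id <= 12:
        raise ValueError("slot_id must be in 1..12")
    theta = math.radians(90.0 - (slot_id - 1) * 30.0)
    r = ring_fraction * cylinder_radius_mm
    return (r * math.cos(theta), r * math.sin(theta))


def _pixel_grid_mm(matrix, pixel_spacing):
    rows, cols = matrix
    sr, sc = pixel_spacing
    x = (np.arange(cols) - (cols - 1) / 2.0) * sc
    y = ((rows - 1) / 2.0 - np.arange(rows)) * sr
    return np.meshgrid(x, y)


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical tube phantom: geometry, tissue values, noise and B1 models."""

    matrix: tuple[int, int] = (208, 256)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    cylinder_radius_mm: float = 90.0
    slots: tuple[TubeSlot, ...] = ()
    background_t1: float = 500.0
    background_m0: float = 800.0
    noise_sigma: float = 0.0
    averages: int = 5
    b1_field: RadialB1Field | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.averages < 1:
            raise ValueError("averages must be >= 1")
        if self.background_t1 <= 0:
            raise ValueError("background_t1 must be > 0 ms")
        object.__setattr__(self, "slots", tuple(self.slots))
        seen = set()
        for s in self.slots:
            if s.slot_id in seen:
                raise ValueError(f"slot {s.slot_id} occupied twice")
            seen.add(s.slot_id)
            r = math.hypot(*s.center_mm) + s.diameter_mm / 2.0
            if r > self.cylinder_radius_mm:
                raise ValueError(
                    f"slot {s.slot_id} tube extends outside the cylinder")
        for i, a in enumerate(self.slots):
            for b in self.slots[i + 1:]:
                d = math.dist(a.center_mm, b.center_mm)
                if d < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise ValueError(
                        f"tubes in slots {a.slot_id} and {b.slot_id} overlap")

    def fields(self, phase: str | None = None):
        """Per-pixel (t1, m0) arrays.  Air outside the cylinder has m0 = 0."""
        x, y = _pixel_grid_mm(self.matrix, self.pixel_spacing)
        inside = x ** 2 + y ** 2 <= self.cylinder_radius_mm ** 2
        t1 = np.where(inside, self.background_t1, 1.0)
        m0 = np.where(inside, self.background_m0, 0.0)
        for s in self.slots:
            cx, cy = s.center_mm
            tube = (x - cx) ** 2 + (y - cy) ** 2 <= (s.diameter_mm / 2.0) ** 2
            t1 = np.where(tube, s.t1, t1)
            m0 = np.where(tube, s.m0, m0)
        return t1, m0

    def b1_map(self) -> np.ndarray | float:
        if self.b1_field is None:
            return 1.0
        x, y = _pixel_grid_mm(self.matrix, self.pixel_spacing)
        return self.b1_field(x, y, self.cylinder_radius_mm)

    # declarative (de)serialization used by the CLI spec files -----------
    def to_dict(self) -> dict:
        d = {
            "kind": "phantom",
            "matrix": list(self.matrix),
            "pixel_spacing": list(self.pixel_spacing),
            "cylinder_radius_mm": self.cylinder_radius_mm,
            "background_t1": self.background_t1,
            "background_m0": self.background_m0,
            "noise_sigma": self.noise_sigma,
            "averages": self.averages,
            "seed": self.seed,
            "slots": [
                {"slot_id": s.slot_id, "center_mm": list(s.center_mm),
                 "t1": s.t1, "m0": s.m0, "diameter_mm": s.diameter_mm}
                for s in self.slots],
        }
        if self.b1_field is not None:
            d["b1_field"] = {"type": "radial", "amplitude": self.b1_field.amplitude,
                             "radius_mm": self.b1_field.radius_mm}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        b1 = None
        if d.get("b1_field"):
            bd = d["b1_field"]
            if bd.get("type", "radial") != "radial":
                raise ValueError(f"unknown b1_field type {bd.get('type')!r}")
            b1 = RadialB1Field(amplitude=bd.get("amplitude", 0.08),
                               radius_mm=bd.get("radius_mm"))
        slots = tuple(
            TubeSlot(slot_id=s["slot_id"], center_mm=tuple(s["center_mm"]),
                     t1=s["t1"], m0=s.get("m0", 1000.0),
                     diameter_mm=s.get("diameter_mm", 20.0))
            for s in d.get("slots", ()))
        return cls(matrix=tuple(d.get("matrix", (208, 256))),
                   pixel_spacing=tuple(d.get("pixel_spacing", (1.5, 1.5))),
                   cylinder_radius_mm=d.get("cylinder_radius_mm", 90.0),
                   slots=slots,
                   background_t1=d.get("background_t1", 500.0),
                   background_m0=d.get("background_m0", 800.0),
                   noise_sigma=d.get("noise_sigma", 0.0),
                   averages=d.get("averages", 5),
                   b1_field=b1, seed=d.get("seed"))


@dataclass(frozen=True)
class AbdomenFixtureSpec:
    """Abdomen-like fixture: elliptical body, liver region, surface tubes.

    The liver carries distinct pre/post-contrast T1 (hepatobiliary
    enhancement); the three certified reference tubes on the abdominal
    surface keep the same T1 in both phases, so their true RR is zero.
    """

    matrix: tuple[int, int] = (208, 256)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    body_center_mm: tuple[float, float] = (0.0, -20.0)
    body_semiaxes_mm: tuple[float, float] = (140.0, 90.0)
    body_t1: tuple[float, float] = (800.0, 750.0)      # (pre, post)
    body_m0: float = 900.0
    liver_center_mm: tuple[float, float] = (-50.0, 0.0)
    liver_semiaxes_mm: tuple[float, float] = (55.0, 45.0)
    liver_t1: tuple[float, float] = (657.0, 325.0)     # (pre, post)
    liver_m0: float = 1000.0
    reference_tubes: tuple[TubeSlot, ...] = (
        TubeSlot(1, (-60.0, 85.0), 400.0),
        TubeSlot(2, (0.0, 85.0), 600.0),
        TubeSlot(3, (60.0, 85.0), 800.0),
    )
    noise_sigma: float = 0.0
    averages: int = 5
    b1_field: RadialB1Field | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for t1 in (*self.body_t1, *self.liver_t1):
            if t1 <= 0:
                raise ValueError("all t1 values must be > 0 ms")
        # liver inside body; tubes outside the body ellipse
        lx, ly = self.liver_center_mm
        if self._body_ellipse(np.array(lx), np.array(ly)) > 1:
            raise ValueError("liver region lies outside the body")
        for t in self.reference_tubes:
            if self._body_ellipse(np.array(t.center_mm[0]), np.array(t.center_mm[1])) <= 1:
                raise ValueError(f"reference tube {t.slot_id} overlaps the body")

    def _body_ellipse(self, x, y):
        cx, cy = self.body_center_mm
        ax, ay = self.body_semiaxes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2

    def fields(self, phase: str = "pre"):
        if phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        i = 0 if phase == "pre" else 1
        x, y = _pixel_grid_mm(self.matrix, self.pixel_spacing)
        body = self._body_ellipse(x, y) <= 1.0
        t1 = np.where(body, self.body_t1[i], 1.0)
        m0 = np.where(body, self.body_m0, 0.0)
        lx, ly = self.liver_center_mm
        ax, ay = self.liver_semiaxes_mm
        liver = ((x - lx) / ax) ** 2 + ((y - ly) / ay) ** 2 <= 1.0
        t1 = np.where(liver, self.liver_t1[i], t1)
        m0 = np.where(liver, self.liver_m0, m0)
        for t in self.reference_tubes:
            cx, cy = t.center_mm
            tube = (x - cx) ** 2 + (y - cy) ** 2 <= (t.diameter_mm / 2.0) ** 2
            t1 = np.where(tube, t.t1, t1)
            m0 = np.where(tube, t.m0, m0)
        return t1, m0

    def b1_map(self) -> np.ndarray | float:
        if self.b1_field is None:
            return 1.0
        x, y = _pixel_grid_mm(self.matrix, self.pixel_spacing)
        return self.b1_field(x, y, max(self.body_semiaxes_mm))


def render_acquisition(spec, flip_angle: float, tr: float,
                       phase: str | None = None,
                       flip_angles: tuple[float, ...] | None = None,
                       rng: np.random.Generator | None = None) -> FlipAngleImage:
    """Render one FLASH acquisition of a phantom/fixture spec.

    Deterministic for a fixed spec seed (or a supplied ``rng``).
    ``flip_angles`` optionally records the full protocol pair in the
    image's acquisition parameters.
    """
    t1, m0 = spec.fields(phase) if phase is not None else spec.fields()
    alpha_eff = flip_angle * np.asarray(spec.b1_map(), dtype=float)
    signal = spgr_signal(m0, t1, alpha_eff, tr)
    signal = np.asarray(signal, dtype=float)

    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        shape = (spec.averages,) + signal.shape
        noise = rng.normal(0.0, spec.noise_sigma, shape) \
            + 1j * rng.normal(0.0, spec.noise_sigma, shape)
        signal = np.abs(signal + noise.mean(axis=0))

    params = AcquisitionParams(
        tr=tr, flip_angles=flip_angles or (flip_angle,),
        pixel_spacing=spec.pixel_spacing, matrix=spec.matrix)
    label = phase or ("phantom" if isinstance(spec, PhantomSpec) else "pre")
    meta = {"phase": phase, "description": f"{label} FLASH FA{flip_angle:g}"}
    return FlipAngleImage(signal, flip_angle, params, meta)


def render_pair(spec, flip_angles: tuple[float, float], tr: float,
                phase: str | None = None,
                seed: int | None = None) -> tuple[FlipAngleImage, FlipAngleImage]:
    """Render the two flip-angle acquisitions of one protocol phase.

    A single random stream (seeded by ``seed``, falling back to the spec
    seed) drives both renders, so the two images carry independent noise
    while the pair as a whole is reproducible.
    """
    a_low, a_high = flip_angles
    if a_low == a_high:
        raise ValueError("the protocol needs two distinct flip angles")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    low = render_acquisition(spec, a_low, tr, phase=phase,
                             flip_angles=tuple(flip_angles), rng=rng)
    high = render_acquisition(spec, a_high, tr, phase=phase,
                              flip_angles=tuple(flip_angles), rng=rng)
    return low, high


def make_rr_validation_phantom(
        pairs=DEFAULT_VALIDATION_PAIRS,
        slot_assignment=DEFAULT_SLOT_ASSIGNMENT,
        tube_m0: float = 1000.0,
        **spec_kwargs) -> tuple[PhantomSpec, PhantomSpec]:
    """Paired pre/post phantom specs for the RR validation protocol.

    Each (t1_pre, t1_post) pair occupies the two slots listed for it in
    ``slot_assignment``; the pre spec holds the high (pre-contrast-like)
    tube of each pair, the post spec the low one, in the same slots.
    Extra keyword arguments (noise_sigma, b1_field, seed, ...) are passed
    through to both PhantomSpec objects.

    Raises ValueError on slot collisions or more than 12 requested slots.
    """
    pairs = tuple(pairs)
    slot_assignment = tuple(tuple(s) for s in slot_assignment)
    if len(slot_assignment) < len(pairs):
        raise ValueError("need a slot assignment for every tube pair")
    wanted = [s for group in slot_assignment[:len(pairs)] for s in group]
    if len(set(wanted)) != len(wanted):
        raise ValueError(f"slot collision in assignment {slot_assignment}")
    if len(wanted) > 12:
        raise ValueError("at most 12 slots are available")

    radius = spec_kwargs.get("cylinder_radius_mm", 90.0)
    pre_slots, post_slots = [], []
    for (t1_a, t1_b), slots in zip(pairs, slot_assignment):
        for sid in slots:
            center = default_slot_center(sid, radius)
            pre_slots.append(TubeSlot(sid, center, t1_a, m0=tube_m0))
            post_slots.append(TubeSlot(sid, center, t1_b, m0=tube_m0))
    pre = PhantomSpec(slots=tuple(pre_slots), **spec_kwargs)
    post = PhantomSpec(slots=tuple(post_slots), **spec_kwargs)
    return pre, post
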