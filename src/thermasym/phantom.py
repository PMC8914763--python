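"""Synthetic facial thermogram phantoms with known ground truth.

The phantoms emulate clinical acquisition conditions: a bilaterally
near-symmetric elliptical "face" of skin temperature ~31-35 °C over a uniform
~22 °C ambient background, additive Gaussian sensor noise at the camera's
±0.06 °C sensitivity scale, and — for the tumor class — a unilateral Gaussian
hot spot of configurable amplitude and extent.  The open-mouth view adds a
smaller, warmer elliptical cavity region on the symmetry axis.

Every phantom carries a :class:`PhantomTruth` with the exact symmetry axis,
lesion side and class label, so axis-estimation and classification accuracy
can be measured against ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .exceptions import PhantomSpecError
from .io import Thermogram

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortMember",
    "default_spec",
    "make_face_phantom",
    "make_mouth_phantom",
    "make_cohort",
]

# Open-mouth cavity geometry, relative to the face ellipse.  The cavity is
# centered on the symmetry axis in the lower half of the face and elongated
# along the axis so that its major axis coincides with the face's.
MOUTH_OFFSET_FRAC = 0.42   # cavity center, fraction of face semi-axis a below face center
MOUTH_A_FRAC = 0.30        # cavity semi-axis along the symmetry axis, fraction of a
MOUTH_B_FRAC = 0.18        # cavity semi-axis across the axis, fraction of b
MOUTH_GRADIENT_C = 0.4     # °C drop from cavity center to cavity rim


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic thermogram.

    The face is an ellipse with semi-axis ``a`` (pixels) along the symmetry
    axis and ``b`` across it.  ``axis_angle_deg`` tilts the symmetry axis away
    from vertical (image row axis), positive toward increasing column.  Inside
    the face, temperature falls off quadratically with normalized elliptical
    radius from ``skin_base_c`` at the center by ``radial_gradient_c`` at the
    rim; outside it is uniform ``ambient_c``.  A lesion is an isotropic
    Gaussian bump of peak ``lesion_amp_c`` with scale set by
    ``lesion_radius_px`` (the bump's sigma is half the radius), added to
    face-interior pixels only and required to sit strictly off-axis.
    """

    shape: tuple[int, int] = (240, 320)
    face_center: tuple[float, float] = (120.0, 160.0)
    face_semiaxes: tuple[float, float] = (90.0, 65.0)
    axis_angle_deg: float = 0.0
    skin_base_c: float = 33.0
    ambient_c: float = 22.0
    radial_gradient_c: float = 1.5
    noise_sd_c: float = 0.06
    lesion_amp_c: float = 0.0
    lesion_center: Optional[tuple[float, float]] = None
    lesion_radius_px: float = 8.0
    mouth_base_c: float = 35.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # --- axis geometry -----------------------------------------------------
    @property
    def axis_direction(self) -> np.ndarray:
        """Unit (row, col) vector along the symmetry axis."""
        alpha = math.radians(self.axis_angle_deg)
        return np.array([math.cos(alpha), math.sin(alpha)])

    def axis_coords(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates (u along axis, v across axis) relative to the face center."""
        dr = rows - self.face_center[0]
        dc = cols - self.face_center[1]
        alpha = math.radians(self.axis_angle_deg)
        u = dr * math.cos(alpha) + dc * math.sin(alpha)
        v = -dr * math.sin(alpha) + dc * math.cos(alpha)
        return u, v

    def validate(self) -> None:
        n_rows, n_cols = self.shape
        if n_rows < 8 or n_cols < 8:
            raise PhantomSpecError("phantom image must be at least 8 x 8")
        a, b = self.face_semiaxes
        if a <= 0 or b <= 0:
            raise PhantomSpecError("face semi-axes must be positive")
        if self.noise_sd_c < 0:
            raise PhantomSpecError("noise_sd_c must be >= 0")
        if self.lesion_amp_c < 0:
            raise PhantomSpecError("lesion_amp_c must be >= 0")
        if self.lesion_radius_px <= 0:
            raise PhantomSpecError("lesion_radius_px must be > 0")
        # face ellipse fully inside the image: check extreme points along both axes
        alpha = math.radians(self.axis_angle_deg)
        ar = np.array([math.cos(alpha), math.sin(alpha)])
        av = np.array([-math.sin(alpha), math.cos(alpha)])
        center = np.array(self.face_center)
        for extreme in (center + a * ar, center - a * ar, center + b * av, center - b * av):
            if not (0 <= extreme[0] <= n_rows - 1 and 0 <= extreme[1] <= n_cols - 1):
                raise PhantomSpecError("face ellipse extends outside the image")
        if self.lesion_amp_c > 0:
            if self.lesion_center is None:
                raise PhantomSpecError("lesion_amp_c > 0 requires lesion_center")
            u, v = self.axis_coords(
                np.array(self.lesion_center[0]), np.array(self.lesion_center[1])
            )
            if (u / a) ** 2 + (v / b) ** 2 >= 1.0:
                raise PhantomSpecError("lesion center must lie inside the face ellipse")
            if v == 0:
                raise PhantomSpecError("lesion center must lie strictly on one side of the axis")


@dataclasses.dataclass(frozen=True)
class PhantomTruth:
    """Ground truth attached to a generated phantom."""

    axis_point: tuple[float, float]
    axis_direction: tuple[float, float]
    has_lesion: bool
    lesion_side: str  # "left" | "right" | "none"
    class_label: int  # 0 = NT (no lesion), 1 = T (lesion)

    def __post_init__(self) -> None:
        if self.class_label != int(self.has_lesion):
            raise PhantomSpecError("class_label must equal int(has_lesion)")
        if self.lesion_side not in ("left", "right", "none"):
            raise PhantomSpecError(f"bad lesion_side {self.lesion_side!r}")


def _lesion_side(spec: PhantomSpec) -> str:
    if spec.lesion_amp_c == 0:
        return "none"
    _, v = spec.axis_coords(
        np.array(spec.lesion_center[0]), np.array(spec.lesion_center[1])
    )
    # v > 0 is toward increasing column for an upright axis, i.e. image right
    return "right" if v > 0 else "left"


def _truth(spec: PhantomSpec) -> PhantomTruth:
    return PhantomTruth(
        axis_point=tuple(float(x) for x in spec.face_center),
        axis_direction=tuple(float(x) for x in spec.axis_direction),
        has_lesion=spec.lesion_amp_c > 0,
        lesion_side=_lesion_side(spec),
        class_label=int(spec.lesion_amp_c > 0),
    )


def _base_field(spec: PhantomSpec, with_mouth: bool) -> np.ndarray:
    n_rows, n_cols = spec.shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    u, v = spec.axis_coords(rows, cols)
    a, b = spec.face_semiaxes
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0

    field = np.full(spec.shape, spec.ambient_c, dtype=float)
    field[inside] = spec.skin_base_c - spec.radial_gradient_c * rho2[inside]

    if with_mouth:
        am = MOUTH_A_FRAC * a
        bm = MOUTH_B_FRAC * b
        um = u - MOUTH_OFFSET_FRAC * a
        rho2_m = (um / am) ** 2 + (v / bm) ** 2
        mouth = rho2_m <= 1.0
        field[mouth] = spec.mouth_base_c - MOUTH_GRADIENT_C * rho2_m[mouth]

    if spec.lesion_amp_c > 0:
        sigma = spec.lesion_radius_px / 2.0
        r2 = (rows - spec.lesion_center[0]) ** 2 + (cols - spec.lesion_center[1]) ** 2
        bump = spec.lesion_amp_c * np.exp(-r2 / (2.0 * sigma**2))
        field[inside] += bump[inside]
    return field


def _finish(spec: PhantomSpec, field: np.ndarray, view: str, id_: str) -> tuple[Thermogram, PhantomTruth]:
    if spec.noise_sd_c > 0:
        rng = np.random.default_rng(spec.seed)
        field = field + rng.normal(0.0, spec.noise_sd_c, size=field.shape)
    return Thermogram(field, view=view, id=id_), _truth(spec)


def make_face_phantom(spec: PhantomSpec, id: str = "phantom") -> tuple[Thermogram, PhantomTruth]:
    """Generate a closed-mouth face-view phantom.

    Noiseless, lesion-free phantoms are exactly mirror-symmetric about the
    true axis by construction (temperature depends only on |v|).  Generation
    is deterministic given ``spec.seed``.
    """
    return _finish(spec, _base_field(spec, with_mouth=False), "face", id)


def make_mouth_phantom(spec: PhantomSpec, id: str = "phantom") -> tuple[Thermogram, PhantomTruth]:
    """Generate an open-mouth view phantom.

    Identical to the face phantom plus a warmer elliptical mouth-cavity
    region (base ``mouth_base_c``) centered on the symmetry axis, so the
    cavity is the warmest structure in the image.
    """
    return _finish(spec, _base_field(spec, with_mouth=True), "mouth", id)


# --- cohorts ---------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CohortMember:
    face: Thermogram
    mouth: Thermogram
    truth: PhantomTruth
    id: str
    #: nominal group assignment ("NT"/"T"); differs from the truth label only
    #: when a cohort is generated with lesion amplitude 0 (a null cohort, in
    #: which nominally "T" members carry no lesion by design)
    group: str = "NT"


def _member_seeds(cohort_seed: int, index: int) -> tuple[int, int, np.random.Generator]:
    """Counter-based per-member seed derivation: reproducible and independent."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    face_seed, mouth_seed = (int(s % 2**31) for s in ss.generate_state(2))
    placement_rng = np.random.default_rng(ss.spawn(1)[0])
    return face_seed, mouth_seed, placement_rng


def _lesioned_specs(
    base: PhantomSpec, amp: float, radius: float, rng: np.random.Generator
) -> tuple[PhantomSpec, PhantomSpec]:
    """Draw a random lesion side/position for the face and mouth views.

    The face lesion sits in the cheek region (off the mouth), the mouth lesion
    inside the cavity, both on the same randomly chosen side of the axis.
    """
    a, b = base.face_semiaxes
    side = 1.0 if rng.random() < 0.5 else -1.0
    alpha = math.radians(base.axis_angle_deg)
    rot = np.array([[math.cos(alpha), -math.sin(alpha)], [math.sin(alpha), math.cos(alpha)]])
    center = np.array(base.face_center)

    def to_rc(u: float, v: float) -> tuple[float, float]:
        rc = center + rot @ np.array([u, v])
        return float(rc[0]), float(rc[1])

    u_f = rng.uniform(-0.35 * a, 0.05 * a)
    v_f = side * rng.uniform(0.35 * b, 0.55 * b)
    face_spec = dataclasses.replace(
        base, lesion_amp_c=amp, lesion_center=to_rc(u_f, v_f), lesion_radius_px=radius
    )

    am, bm = MOUTH_A_FRAC * a, MOUTH_B_FRAC * b
    u_m = MOUTH_OFFSET_FRAC * a + rng.uniform(-0.3 * am, 0.3 * am)
    v_m = side * rng.uniform(0.35 * bm, 0.6 * bm)
    mouth_spec = dataclasses.replace(
        base,
        lesion_amp_c=amp,
        lesion_center=to_rc(u_m, v_m),
        lesion_radius_px=max(2.0, radius / 2.0),
    )
    return face_spec, mouth_spec


def make_cohort(
    n_nt: int,
    n_t: int,
    base_spec: PhantomSpec | None = None,
    lesion_amp_c: float = 1.0,
    lesion_radius_px: float = 8.0,
    seed: int = 0,
) -> list[CohortMember]:
    """Generate a labeled cohort of paired face/mouth phantoms.

    The first ``n_nt`` members are lesion-free (class NT = 0); the remaining
    ``n_t`` carry a unilateral hot spot of peak ``lesion_amp_c`` °C in both
    views (class T = 1), with side and position randomized per member.
    Per-member seeds derive deterministically from ``seed``, so two calls with
    the same arguments produce identical cohorts.
    """
    if n_nt < 0 or n_t < 0 or n_nt + n_t < 1:
        raise PhantomSpecError("cohort needs at least one member")
    base = base_spec if base_spec is not None else default_spec()
    members: list[CohortMember] = []
    for i in range(n_nt + n_t):
        face_seed, mouth_seed, placement = _member_seeds(seed, i)
        is_t = i >= n_nt
        lesioned = is_t and lesion_amp_c > 0
        label = "T" if is_t else "NT"
        member_id = f"{label}{(i - n_nt if is_t else i):03d}"
        if lesioned:
            face_spec, mouth_spec = _lesioned_specs(
                base, lesion_amp_c, lesion_radius_px, placement
            )
        else:
            face_spec = dataclasses.replace(base, lesion_amp_c=0.0, lesion_center=None)
            mouth_spec = face_spec
        face_spec = dataclasses.replace(face_spec, seed=face_seed)
        mouth_spec = dataclasses.replace(mouth_spec, seed=mouth_seed)
        face_tg, _ = make_face_phantom(face_spec, id=member_id)
        mouth_tg, _ = make_mouth_phantom(mouth_spec, id=member_id)
        # cohort truth: lesion side taken from the generating specs
        truth = PhantomTruth(
            axis_point=tuple(float(x) for x in base.face_center),
            axis_direction=tuple(float(x) for x in base.axis_direction),
            has_lesion=lesioned,
            lesion_side=_lesion_side(mouth_spec) if lesioned else "none",
            class_label=int(lesioned),
        )
        members.append(
            CohortMember(face=face_tg, mouth=mouth_tg, truth=truth, id=member_id, group=label)
        )
    return members


def default_spec(**overrides) -> PhantomSpec:
    """The standard acquisition-scale phantom: 240 x 320 px, upright face."""
    return PhantomSpec(**overrides)
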