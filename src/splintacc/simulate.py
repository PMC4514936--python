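"""Synthetic cadaver studies with known ground truth.

The generator emulates the design of the cadaver accuracy experiment the
pipeline analyses: 10 specimens, nine fiducial screws each (3 skull,
3 maxilla, 3 mandible), a planned Le Fort I maxillary repositioning (5 mm
advancement with asymmetric vertical repositioning of the buttresses), and
three error sources applied when producing the "post-operative" coordinates:

* a mandibular (condylar) repositioning error — a small rigid motion drawn
  per specimen from an axis-wise normal model;
* an intrinsic splint error — a second small rigid motion, drawn
  independently;
* anisotropic screw-deformation noise added per screw coordinate, largest on
  the mandible antero-posterior axis (screws bent by the maxillo-mandibular
  wiring).

Error transforms compose *additively in their parameters*: the maxilla
receives translation components and Euler angles equal to the sum of the
mandibular and splint parameters, applied as one rigid motion about the
region's planned barycenter.  This realises the error decomposition
MxRE = MdRE + SE exactly, component by component, which is what the
downstream splint-error subtraction assumes.  The skull receives no
transform — only deformation noise — mirroring its role as the registration
reference.

Default error-model means and SDs are calibrated so that a simulated study
lands in the ranges reported by the cadaver experiment (translations within
roughly +/-2 mm limits, rotations up to several degrees, splint error smaller
than mandibular error); the deformation-noise defaults make the simulated
deformation table largest on the mandible antero-posterior axis.  They are
plausible study-scale defaults, not fits to any particular dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import FiducialTriad, Region, Timepoint, barycenter
from .pose import euler_to_matrix
from .study import SpecimenSet

__all__ = [
    "ErrorModel",
    "SimulationConfig",
    "GroundTruth",
    "default_template",
    "planned_maxilla_transform",
    "simulate_study",
]

#: Fixed fiducial template (mm), planned timepoint, skull-fused frame.
#: x medio-lateral (+left), y antero-posterior (+anterior), z supero-inferior
#: (+superior).  Positions approximate the screw sites of the experiment:
#: skull — nasion and both infraorbital rims; maxilla — below the anterior
#: nasal spine and above both upper first molar roots; mandible — the mental
#: midline and below both lower first molar roots.
_TEMPLATE_COORDS: dict[Region, np.ndarray] = {
    Region.SKULL: np.array(
        [[0.0, 85.0, 30.0], [35.0, 72.0, 18.0], [-35.0, 72.0, 18.0]]
    ),
    Region.MAXILLA: np.array(
        [[0.0, 92.0, -6.0], [28.0, 58.0, -10.0], [-28.0, 58.0, -10.0]]
    ),
    Region.MANDIBLE: np.array(
        [[0.0, 95.0, -42.0], [30.0, 62.0, -36.0], [-30.0, 62.0, -36.0]]
    ),
}

#: Buttress points (mm) used to realise the planned maxillary movement, and
#: their planned displacements: 5 mm advancement everywhere, 4 mm superior
#: repositioning at the left pterygo-maxillary buttress, 3 mm superior at the
#: left naso-maxillary buttress, 3 mm inferior at the right pterygo-maxillary
#: buttress.
_BUTTRESS_POINTS = np.array(
    [[38.0, 38.0, 2.0],   # left pterygo-maxillary
     [14.0, 82.0, 6.0],   # left naso-maxillary
     [-38.0, 38.0, 2.0]]  # right pterygo-maxillary
)
_BUTTRESS_DISPLACEMENTS = np.array(
    [[0.0, 5.0, 4.0],
     [0.0, 5.0, 3.0],
     [0.0, 5.0, -3.0]]
)


def _as_vec3(value, name: str) -> np.ndarray:
    v = np.asarray(value, dtype=float).ravel()
    if v.size != 3:
        raise ValueError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass(frozen=True)
class ErrorModel:
    """Axis-wise normal model of one small rigid error motion.

    Translations in mm along (x, y, z); rotations in degrees about
    (x, y, z) = (pitch, roll, yaw).
    """

    translation_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("translation_mean", "translation_sd",
                     "rotation_mean", "rotation_sd"):
            v = _as_vec3(getattr(self, name), name)
            if name.endswith("_sd") and np.any(v < 0):
                raise ValueError(f"{name} must be non-negative, got {tuple(v)}")
            object.__setattr__(self, name, tuple(float(x) for x in v))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the 6 motion parameters (tx, ty, tz, pitch, roll, yaw)."""
        t = rng.normal(self.translation_mean, self.translation_sd)
        r = rng.normal(self.rotation_mean, self.rotation_sd)
        return np.concatenate([t, r])


#: Mandibular (condylar seating) error defaults: biased anteriorly and
#: superiorly with mm-scale spread, degree-scale rotations.
_DEFAULT_MANDIBLE_MODEL = ErrorModel(
    translation_mean=(0.7, 1.0, 0.7),
    translation_sd=(2.0, 1.4, 1.1),
    rotation_mean=(0.0, 0.1, 0.6),
    rotation_sd=(1.1, 0.65, 1.0),
)

#: Intrinsic splint error defaults: smaller translations, a pitch-dominant
#: rotational spread (the splint constrains the occlusal plane least in pitch).
_DEFAULT_SPLINT_MODEL = ErrorModel(
    translation_mean=(-0.45, 0.75, 0.35),
    translation_sd=(1.15, 1.5, 1.0),
    rotation_mean=(-1.5, -0.85, 0.55),
    rotation_sd=(4.0, 1.9, 1.05),
)

#: Screw-deformation noise SD (mm) per region and axis; mandible screws take
#: the maxillo-mandibular wiring load, most along the antero-posterior axis.
_DEFAULT_DEFORMATION_SD: dict[str, tuple[float, float, float]] = {
    "skull": (0.15, 0.25, 0.20),
    "maxilla": (0.25, 0.20, 0.20),
    "mandible": (0.55, 1.20, 0.45),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic study."""

    n_heads: int = 10
    advancement_mm: float = 5.0
    left_pterygo_impaction_mm: float = 4.0
    left_naso_impaction_mm: float = 3.0
    right_pterygo_descent_mm: float = 3.0
    mandible_model: ErrorModel = field(default_factory=lambda: _DEFAULT_MANDIBLE_MODEL)
    splint_model: ErrorModel = field(default_factory=lambda: _DEFAULT_SPLINT_MODEL)
    deformation_sd: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DEFORMATION_SD)
    )

    def __post_init__(self) -> None:
        if self.n_heads < 3:
            raise ValueError(f"n_heads must be >= 3, got {self.n_heads}")
        sds = {}
        for region in Region:
            v = _as_vec3(
                self.deformation_sd.get(region.value, (0.0, 0.0, 0.0)),
                f"deformation_sd[{region.value}]",
            )
            if np.any(v < 0):
                raise ValueError(
                    f"deformation SDs must be non-negative for {region.value}"
                )
            sds[region.value] = tuple(float(x) for x in v)
        object.__setattr__(self, "deformation_sd", sds)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("mandible_model", "splint_model"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = ErrorModel(**raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-specimen error parameters injected by the generator.

    For every head id: ``mandible`` and ``splint`` hold the 6 drawn motion
    parameters (tx, ty, tz in mm; pitch, roll, yaw in degrees); ``maxilla``
    is their component-wise sum (the additive composition realised by the
    generator); ``deformation`` maps region -> 3x3 per-screw noise vectors.
    """

    seed: int
    transforms: dict[str, dict[str, np.ndarray]]
    deformation: dict[str, dict[str, np.ndarray]]

    def params(self, head_id: str, which: str) -> np.ndarray:
        return self.transforms[head_id][which]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "transforms": {
                head: {k: list(v) for k, v in d.items()}
                for head, d in self.transforms.items()
            },
            "deformation": {
                head: {k: np.asarray(v).tolist() for k, v in d.items()}
                for head, d in self.deformation.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            seed=int(raw["seed"]),
            transforms={
                head: {k: np.asarray(v, float) for k, v in d.items()}
                for head, d in raw["transforms"].items()
            },
            deformation={
                head: {k: np.asarray(v, float) for k, v in d.items()}
                for head, d in raw["deformation"].items()
            },
        )


def default_template() -> dict[Region, FiducialTriad]:
    """Planned fiducial triads of the template specimen, one per region."""
    return {
        region: FiducialTriad.from_coords(region, Timepoint.PLANNED, coords)
        for region, coords in _TEMPLATE_COORDS.items()
    }


def planned_maxilla_transform(
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid transform (R, mu_src, mu_dst) realising the planned movement.

    The plan prescribes displacements at three maxillary buttress points
    (advancement plus asymmetric vertical repositioning), not a transform;
    the least-squares proper rigid motion fitted to those three displaced
    points (Kabsch) is taken as the planned transform.  Apply as
    ``p -> R @ (p - mu_src) + mu_dst``.
    """
    from scipy.spatial.transform import Rotation

    config = config or SimulationConfig()
    disp = np.array(
        [
            [0.0, config.advancement_mm, config.left_pterygo_impaction_mm],
            [0.0, config.advancement_mm, config.left_naso_impaction_mm],
            [0.0, config.advancement_mm, -config.right_pterygo_descent_mm],
        ]
    )
    src = _BUTTRESS_POINTS
    dst = _BUTTRESS_POINTS + disp
    mu_src = src.mean(axis=0)
    mu_dst = dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - mu_dst, src - mu_src)
    return rot.as_matrix(), mu_src, mu_dst


def _apply_params_about_barycenter(
    triad: FiducialTriad, params: np.ndarray
) -> np.ndarray:
    """Coordinates after the 6-parameter motion applied about the triad's
    own barycenter: rotation first (about the barycenter), then translation."""
    t = params[:3]
    R = euler_to_matrix(params[3], params[4], params[5])
    b = barycenter(triad).point.as_array()
    return (triad.coords - b) @ R.T + b + t


def simulate_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[SpecimenSet, GroundTruth]:
    """Generate one complete synthetic study.

    Per specimen: the planned skull and mandible triads are the template; the
    planned maxilla triad is the template maxilla after the planned
    repositioning.  Post-operative triads are produced by applying the drawn
    error motion (none for the skull, the mandibular draw for the mandible,
    the component-wise sum of mandibular and splint draws for the maxilla)
    about each region's planned barycenter, then adding per-screw
    deformation noise.  Bit-exactly reproducible for a given seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    template = default_template()

    R_plan, mu_src, mu_dst = planned_maxilla_transform(config)
    planned_maxilla = FiducialTriad.from_coords(
        Region.MAXILLA,
        Timepoint.PLANNED,
        (template[Region.MAXILLA].coords - mu_src) @ R_plan.T + mu_dst,
    )
    planned = {
        Region.SKULL: template[Region.SKULL],
        Region.MAXILLA: planned_maxilla,
        Region.MANDIBLE: template[Region.MANDIBLE],
    }

    width = max(2, len(str(config.n_heads)))
    specimen_set = SpecimenSet()
    transforms: dict[str, dict[str, np.ndarray]] = {}
    deformation: dict[str, dict[str, np.ndarray]] = {}

    for i in range(config.n_heads):
        head = f"H{i + 1:0{width}d}"
        md = config.mandible_model.draw(rng)
        se = config.splint_model.draw(rng)
        params = {
            "skull": np.zeros(6),
            "mandible": md,
            "splint": se,
            "maxilla": md + se,
        }
        noise = {
            region.value: rng.normal(
                0.0, config.deformation_sd[region.value], size=(3, 3)
            )
            for region in Region
        }
        transforms[head] = {
            k: params[k] for k in ("mandible", "splint", "maxilla")
        }
        deformation[head] = {k: noise[k] for k in noise}

        for region in Region:
            plan_triad = planned[region]
            specimen_set.add(head, plan_triad)
            post_coords = (
                _apply_params_about_barycenter(plan_triad, params[region.value])
                + noise[region.value]
            )
            specimen_set.add(
                head,
                FiducialTriad.from_coords(region, Timepoint.POSTOP, post_coords),
            )

    return specimen_set, GroundTruth(seed, transforms, deformation)
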