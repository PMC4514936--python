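"""Study-level containers: the full specimen set and analysis configuration."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .agreement import DEFAULT_CUTOFFS, DfMode
from .geometry import FiducialTriad, Region, Timepoint
from .pose import AngleConvention

__all__ = ["SpecimenSet", "StudyConfig", "RegistrationFrame", "IncompleteSpecimenError"]


class RegistrationFrame(str, enum.Enum):
    """Reference frame for pose differences.

    ``skull`` (default) mirrors the imaging protocol: planned and post-op
    scans are fused on the skull, so maxilla differences carry mandibular plus
    splint error.  ``mandible`` re-expresses every post-operative triad in the
    frame that maps the post-op mandible back onto its planned pose, so
    maxilla differences isolate the splint error.
    """

    SKULL = "skull"
    MANDIBLE = "mandible"


class IncompleteSpecimenError(ValueError):
    """Raised when a specimen is missing one of its six triads."""


@dataclass
class SpecimenSet:
    """N specimens x 3 regions x 2 timepoints of fiducial triads."""

    triads: dict[tuple[str, Region, Timepoint], FiducialTriad] = field(
        default_factory=dict
    )

    @property
    def head_ids(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.triads}))

    @property
    def n_heads(self) -> int:
        return len(self.head_ids)

    def add(self, head_id: str, triad: FiducialTriad) -> None:
        key = (head_id, triad.region, triad.timepoint)
        if key in self.triads:
            raise ValueError(
                f"duplicate triad for head={head_id} region={triad.region.value} "
                f"timepoint={triad.timepoint.value}"
            )
        self.triads[key] = triad

    def get(
        self, head_id: str, region: Region | str, timepoint: Timepoint | str
    ) -> FiducialTriad:
        key = (head_id, Region(region), Timepoint(timepoint))
        try:
            return self.triads[key]
        except KeyError:
            raise IncompleteSpecimenError(
                f"missing triad for head={head_id} region={Region(region).value} "
                f"timepoint={Timepoint(timepoint).value}"
            ) from None

    def validate_complete(self) -> None:
        """Every head must carry all 3 regions x 2 timepoints."""
        problems = []
        for head in self.head_ids:
            for region in Region:
                for timepoint in Timepoint:
                    if (head, region, timepoint) not in self.triads:
                        problems.append(
                            f"head={head} region={region.value} "
                            f"timepoint={timepoint.value}"
                        )
        if problems:
            raise IncompleteSpecimenError(
                "incomplete specimens, missing triads: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class StudyConfig:
    """Knobs of the accuracy analysis (not of the simulation)."""

    translational_cutoff_mm: float = DEFAULT_CUTOFFS["translational"]
    rotational_cutoff_deg: float = DEFAULT_CUTOFFS["rotational"]
    df_mode: DfMode = DfMode.N_MINUS_1
    convention: AngleConvention = AngleConvention.STANDARD
    frame: RegistrationFrame = RegistrationFrame.SKULL
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.translational_cutoff_mm <= 0 or self.rotational_cutoff_deg <= 0:
            raise ValueError("accuracy cutoffs must be positive")
        object.__setattr__(self, "df_mode", DfMode(self.df_mode))
        object.__setattr__(self, "convention", AngleConvention(self.convention))
        object.__setattr__(self, "frame", RegistrationFrame(self.frame))

    @property
    def cutoffs(self) -> dict[str, float]:
        return {
            "translational": self.translational_cutoff_mm,
            "rotational": self.rotational_cutoff_deg,
        }
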