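"""State space of the BMI / type 2 diabetes continuous-time Markov chain.

Ten living states: five BMI categories (normal weight, overweight, obesity
classes I-III, cut-points 25/30/35/40 kg/m2) crossed with type 2 diabetes
status.  Direct transitions move one BMI category up or down (diabetes
status unchanged) or switch diabetes from absent to present (BMI category
unchanged).  Diabetes is absorbing in the disease dimension: remission is
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

BMI_CLASSES = ("NW", "OW", "OB1", "OB2", "OB3")
N_BMI = len(BMI_CLASSES)
N_LIVING = 2 * N_BMI  # 10

#: Index of the obesity classes within :data:`BMI_CLASSES`.
OBESE_CLASSES = ("OB1", "OB2", "OB3")


@dataclass(frozen=True, order=True)
class HealthState:
    """One living state: a BMI category plus diabetes status."""

    bmi: int  # 0..4, index into BMI_CLASSES
    diabetic: bool

    def __post_init__(self) -> None:
        if not 0 <= self.bmi < N_BMI:
            raise ValueError(f"bmi index out of range: {self.bmi}")

    @property
    def index(self) -> int:
        """Position in the canonical ordering NW..OB3 non-diabetic, then diabetic."""
        return self.bmi + N_BMI * int(self.diabetic)

    @property
    def bmi_class(self) -> str:
        return BMI_CLASSES[self.bmi]

    @property
    def label(self) -> str:
        return self.bmi_class + ("-D" if self.diabetic else "")

    @classmethod
    def from_index(cls, index: int) -> "HealthState":
        if not 0 <= index < N_LIVING:
            raise ValueError(f"state index out of range: {index}")
        return cls(bmi=index % N_BMI, diabetic=index >= N_BMI)

    @classmethod
    def from_label(cls, bmi_class: str, diabetic: bool | int) -> "HealthState":
        try:
            bmi = BMI_CLASSES.index(bmi_class.upper())
        except ValueError:
            raise ValueError(f"unknown BMI class {bmi_class!r}") from None
        return cls(bmi=bmi, diabetic=bool(diabetic))


STATES = tuple(HealthState.from_index(i) for i in range(N_LIVING))
STATE_LABELS = tuple(s.label for s in STATES)

#: Canonical start state: normal weight, non-diabetic (everyone at age 3).
START_STATE = STATES[0]


def allowed_transitions() -> Iterator[tuple[HealthState, HealthState]]:
    """Yield every directly-allowed (from, to) pair of living states."""
    for s in STATES:
        if s.bmi + 1 < N_BMI:
            yield s, HealthState(s.bmi + 1, s.diabetic)
        if s.bmi - 1 >= 0:
            yield s, HealthState(s.bmi - 1, s.diabetic)
        if not s.diabetic:
            yield s, HealthState(s.bmi, True)


def is_allowed(a: HealthState, b: HealthState) -> bool:
    if a.diabetic == b.diabetic:
        return abs(a.bmi - b.bmi) == 1
    # onset only, never remission, BMI unchanged
    return (not a.diabetic) and b.diabetic and a.bmi == b.bmi
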