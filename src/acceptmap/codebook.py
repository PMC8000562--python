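"""Codebook of the standardized acceptability questionnaire.

Nine observational variables are recorded for every observed medicine
intake: the result of the intake, the patient's reaction on a 3-point
facial hedonic scale, the combined preparation/administration time class,
and six binary flags for methods used to ease or achieve administration
(dividing the dose, mixing with food or drink, altering the intended use,
using a device not provided with the medicine, using a reward, using
restraint).  Each variable takes one of a fixed, ordered set of
categories; there are 21 categories in total.

Every category carries a *connotation* flag: "fully taken", "positive
reaction", "short time" and each "no <method>" category are positively
connoted, all remaining categories negatively.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["Codebook", "CodebookError", "DEFAULT_CODEBOOK"]


class CodebookError(ValueError):
    """Raised when a codebook violates its structural invariants."""


_DEFAULT_VARIABLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("result_intake", ("fully", "partly", "not_taken")),
    ("reaction", ("positive", "neutral", "negative")),
    ("prep_admin_time", ("short", "medium", "long")),
    ("divided_dose", ("no", "yes")),
    ("food_drink", ("no", "yes")),
    ("alteration", ("no", "yes")),
    ("extra_device", ("no", "yes")),
    ("reward", ("no", "yes")),
    ("restraint", ("no", "yes")),
)

# positively connoted category per variable (always the first one here)
_POSITIVE = {
    "result_intake": "fully",
    "reaction": "positive",
    "prep_admin_time": "short",
    "divided_dose": "no",
    "food_drink": "no",
    "alteration": "no",
    "extra_device": "no",
    "reward": "no",
    "restraint": "no",
}

_EXPECTED_COUNTS = (3, 3, 3, 2, 2, 2, 2, 2, 2)


@dataclass(frozen=True)
class Codebook:
    """Ordered variables, their ordered categories, and connotation flags.

    Invariants (checked at construction): exactly 9 variables with
    category counts (3, 3, 3, 2, 2, 2, 2, 2, 2), 21 categories in total,
    and exactly one positively connoted category per variable.
    """

    variables: tuple[tuple[str, tuple[str, ...]], ...] = _DEFAULT_VARIABLES
    positive_connotation: dict[str, str] = field(
        default_factory=lambda: dict(_POSITIVE)
    )

    def __post_init__(self) -> None:
        if len(self.variables) != 9:
            raise CodebookError(
                f"expected 9 observational variables, got {len(self.variables)}"
            )
        counts = tuple(len(cats) for _, cats in self.variables)
        if counts != _EXPECTED_COUNTS:
            raise CodebookError(
                f"expected category counts {_EXPECTED_COUNTS}, got {counts}"
            )
        if self.n_categories != 21:
            raise CodebookError("total category count must be 21")
        for name, cats in self.variables:
            pos = self.positive_connotation.get(name)
            if pos not in cats:
                raise CodebookError(
                    f"variable {name!r} lacks a valid positively connoted category"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return [name for name, _ in self.variables]

    @property
    def n_categories(self) -> int:
        return sum(len(cats) for _, cats in self.variables)

    @property
    def columns(self) -> list[tuple[str, str]]:
        """All (variable, category) pairs in codebook order (length 21)."""
        return [(v, c) for v, cats in self.variables for c in cats]

    def categories(self, variable: str) -> tuple[str, ...]:
        for name, cats in self.variables:
            if name == variable:
                return cats
        raise KeyError(f"unknown variable {variable!r}")

    def is_positive(self, variable: str, category: str) -> bool:
        if category not in self.categories(variable):
            raise KeyError(f"unknown category {category!r} of {variable!r}")
        return self.positive_connotation[variable] == category

    def validate_value(self, variable: str, category: str) -> None:
        if category not in self.categories(variable):
            raise CodebookError(
                f"{category!r} is not a category of variable {variable!r}; "
                f"expected one of {self.categories(variable)}"
            )

    def hash(self) -> str:
        """Stable digest used to pair serialized models with their codebook."""
        payload = json.dumps(
            [self.variables, sorted(self.positive_connotation.items())],
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CODEBOOK = Codebook()
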