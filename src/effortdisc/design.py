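"""Experimental design of the Effort Discounting Questionnaire (EDQ) and file I/O.

The EDQ is a paper-and-pencil titration procedure: each page (condition)
opposes a fixed *effortful* payoff of amount ``A`` (obtainable after a fixed
30-minute delay during which the effort is exerted) to a descending list of
*effortless* alternatives running from 100% down to 0% of ``A``.  The full
design crosses effort domain (physical, cognitive) x reward amount
(PLN 80/400/3000) x effort intensity (30..150 task units), 30 conditions in
total.  Optional zero-effort pages (delay only) exist solely to measure the
"first indifference point" that is excluded from analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "PLN80_LADDER",
    "DesignSpec",
    "Condition",
    "TitrationLadder",
    "InvalidSpecError",
    "SchemaError",
    "enumerate_conditions",
    "build_ladder",
    "read_choices",
    "write_choices",
    "read_ip_table",
    "write_ip_table",
    "validate_choices",
    "load_config",
]

#: The 30 effortless alternatives printed on the PLN 80 page, top to bottom.
PLN80_LADDER: tuple[int, ...] = (
    80, 79, 77, 74, 71, 68, 65, 62, 59, 56, 53, 50, 47, 44, 41,
    38, 35, 32, 29, 26, 23, 20, 17, 14, 11, 8, 5, 2, 1, 0,
)

CHOICE_COLUMNS = [
    "participant_id", "domain", "amount", "effort_level",
    "row_index", "effortless_value", "choice",
]
IP_COLUMNS = ["participant_id", "domain", "amount", "effort_level", "ip"]
CHOICE_TOKENS = frozenset({"effortless", "effortful"})


class InvalidSpecError(ValueError):
    """Raised for design specifications violating the design invariants."""


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass(frozen=True)
class DesignSpec:
    """The 2 x 3 x 5 EDQ design (defaults reproduce the canonical study design).

    Parameters
    ----------
    effort_domains : labels of the effort types.
    amounts : reward amounts in PLN, strictly increasing.
    effort_levels : effort intensities in task units (squeezes / additions),
        strictly increasing.
    delay_minutes : fixed delay attached to every effortful alternative.
    include_zero_effort_pages : whether the delay-only pages (E = 0) used for
        the excluded first indifference point are generated.
    """

    effort_domains: tuple[str, ...] = ("physical", "cognitive")
    amounts: tuple[int, ...] = (80, 400, 3000)
    effort_levels: tuple[int, ...] = (30, 60, 90, 120, 150)
    delay_minutes: int = 30
    include_zero_effort_pages: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "effort_domains", tuple(self.effort_domains))
        object.__setattr__(self, "amounts", tuple(self.amounts))
        object.__setattr__(self, "effort_levels", tuple(self.effort_levels))
        if not self.effort_domains:
            raise InvalidSpecError("at least one effort domain is required")
        if len(set(self.effort_domains)) != len(self.effort_domains):
            raise InvalidSpecError("effort domains must be unique")
        for name, values in (("amounts", self.amounts),
                             ("effort_levels", self.effort_levels)):
            if not values:
                raise InvalidSpecError(f"{name} must be non-empty")
            if any(v <= 0 for v in values):
                raise InvalidSpecError(f"{name} must be strictly positive")
            if any(b <= a for a, b in zip(values, values[1:])):
                raise InvalidSpecError(f"{name} must be strictly increasing")

    @property
    def n_conditions(self) -> int:
        return (len(self.effort_domains) * len(self.amounts)
                * len(self.effort_levels))

    @classmethod
    def from_dict(cls, data: dict) -> "DesignSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidSpecError(f"unknown design keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class Condition:
    """One cell of the design: an EDQ page."""

    domain: str
    amount: int
    effort_level: int
    page_index: int

    @property
    def is_zero_effort(self) -> bool:
        return self.effort_level == 0


@dataclass(frozen=True)
class TitrationLadder:
    """The descending effortless amounts of one EDQ page."""

    amount: int
    rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.rows[0] != self.amount or self.rows[-1] != 0:
            raise InvalidSpecError("ladder must run from the amount down to 0")
        if any(b > a for a, b in zip(self.rows, self.rows[1:])):
            raise InvalidSpecError("ladder must be non-increasing")

    def __len__(self) -> int:
        return len(self.rows)

    def value_at(self, row_index: int) -> int:
        """Effortless value at ``row_index`` (1-based from the top)."""
        return self.rows[row_index - 1]


def enumerate_conditions(spec: DesignSpec,
                         include_zero_effort: bool = False) -> list[Condition]:
    """Enumerate the design cells in domain-major, amount-, effort-ordered form.

    Zero-effort pages (when requested and enabled in ``spec``) are appended
    after the regular conditions and never enter the canonical condition
    count.  Presentation-order counterbalancing is the caller's concern.
    """
    conditions = []
    page = 1
    for domain in spec.effort_domains:
        for amount in spec.amounts:
            for level in spec.effort_levels:
                conditions.append(Condition(domain, amount, level, page))
                page += 1
    if include_zero_effort and spec.include_zero_effort_pages:
        for domain in spec.effort_domains:
            for amount in spec.amounts:
                conditions.append(Condition(domain, amount, 0, page))
                page += 1
    return conditions


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal("1"),
                                                rounding=ROUND_HALF_UP))


def build_ladder(amount: int, spec: DesignSpec | None = None) -> TitrationLadder:
    """Build the 30-row titration ladder for ``amount``.

    The PLN 80 page is the printed canonical list; other amounts reuse its
    percentage profile (each row divided by 80), scaled and rounded half-up
    to integer PLN, preserving the 100% -> 0% span.
    """
    amount = int(amount)
    if amount <= 0:
        raise InvalidSpecError(f"amount must be positive, got {amount}")
    if amount == 80:
        return TitrationLadder(80, PLN80_LADDER)
    rows = tuple(_round_half_up(v / 80 * amount) for v in PLN80_LADDER)
    return TitrationLadder(amount, rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def validate_choices(choices: pd.DataFrame) -> list[tuple]:
    """Return (participant_id, domain, amount, effort_level) keys whose choice
    sequence violates the single-switch rule (effortless -> effortful, at most
    one switch, reading top to bottom)."""
    violations = []
    for key, grp in choices.groupby(
            ["participant_id", "domain", "amount", "effort_level"], sort=False):
        seq = grp.sort_values("row_index")["choice"].tolist()
        switched = False
        for token in seq:
            if token == "effortful":
                switched = True
            elif switched:  # effortless after the switch
                violations.append(key)
                break
    return violations


def write_choices(records: pd.DataFrame, path) -> None:
    _require_columns(records, CHOICE_COLUMNS, path)
    records[CHOICE_COLUMNS].to_csv(path, index=False)


def read_choices(path) -> pd.DataFrame:
    """Read a choices.csv file; raises on schema errors or unknown tokens.

    Single-switch violations do not abort the read; use
    :func:`validate_choices` to list them.
    """
    df = pd.read_csv(path)
    _require_columns(df, CHOICE_COLUMNS, path)
    bad = set(df["choice"].unique()) - CHOICE_TOKENS
    if bad:
        raise SchemaError(f"{path}: unknown choice tokens {sorted(bad)}")
    return df[CHOICE_COLUMNS].copy()


def write_ip_table(table: pd.DataFrame, path) -> None:
    _require_columns(table, IP_COLUMNS, path)
    table[IP_COLUMNS].to_csv(path, index=False)


def read_ip_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, IP_COLUMNS, path)
    out_of_range = df[(df["ip"] < 0) | (df["ip"] > df["amount"])]
    if not out_of_range.empty:
        rows = out_of_range.index[:5].tolist()
        raise SchemaError(
            f"{path}: indifference points outside [0, amount] at rows {rows}")
    return df[IP_COLUMNS].copy()


def load_config(path) -> dict:
    """Load a JSON or YAML pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
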