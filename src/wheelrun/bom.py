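"""Bill-of-materials and 3D-print-plan arithmetic.

Currency is handled in integer cents and print times in integer minutes, so
totals are exact.  A reference BOM for the published 50-wheel / 3-logger
build ships with the package; the validator is generic so users can cost
their own builds from the same CSV layout
(``name,category,unit_cost_usd,quantity,line_total_usd``).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError


class BomCategory(enum.Enum):
    MAJOR_EQUIPMENT = "MAJOR_EQUIPMENT"
    CONSUMABLE = "CONSUMABLE"


@dataclass(frozen=True)
class BomItem:
    """One purchasable line item; monetary fields in integer cents."""

    name: str
    category: BomCategory
    unit_cost_cents: int
    quantity: int
    line_total_cents: int

    def validate(self) -> None:
        """Line total must equal unit cost × quantity to within one cent."""
        expected = self.unit_cost_cents * self.quantity
        if abs(expected - self.line_total_cents) > 1:
            raise ValidationError(
                f"{self.name}: line total {_fmt(self.line_total_cents)} does not match "
                f"{_fmt(self.unit_cost_cents)} x {self.quantity} = {_fmt(expected)}"
            )


def _to_cents(usd: str | float) -> int:
    # parse via string to dodge float-of-cents drift on values like 8.49
    s = str(usd).strip().lstrip("$")
    if "." in s:
        whole, frac = s.split(".")
        frac = (frac + "00")[:2]
    else:
        whole, frac = s, "00"
    sign = -1 if whole.startswith("-") else 1
    return sign * (abs(int(whole)) * 100 + int(frac))


def _fmt(cents: int) -> str:
    return f"${cents / 100:,.2f}"


@dataclass(frozen=True)
class BomTotals:
    by_category_cents: dict
    grand_total_cents: int

    def usd(self, category: BomCategory | None = None) -> float:
        cents = (
            self.grand_total_cents
            if category is None
            else self.by_category_cents.get(category, 0)
        )
        return cents / 100.0


def bom_totals(items: Iterable[BomItem]) -> BomTotals:
    """Exact category totals and grand total; every item is validated first."""
    by_cat: dict[BomCategory, int] = {}
    for item in items:
        item.validate()
        by_cat[item.category] = by_cat.get(item.category, 0) + item.line_total_cents
    return BomTotals(by_cat, sum(by_cat.values()))


def load_bom(path: str | Path | None = None) -> list[BomItem]:
    """Read a BOM CSV; with no path, the packaged reference build."""
    if path is None:
        src = resources.files("wheelrun.data").joinpath("reference_bom.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(text.splitlines())
    expected = {"name", "category", "unit_cost_usd", "quantity", "line_total_usd"}
    if set(reader.fieldnames or []) != expected:
        raise ValidationError(
            f"BOM header must be {sorted(expected)}, got {reader.fieldnames}"
        )
    items = []
    for row in reader:
        items.append(
            BomItem(
                name=row["name"],
                category=BomCategory(row["category"]),
                unit_cost_cents=_to_cents(row["unit_cost_usd"]),
                quantity=int(row["quantity"]),
                line_total_cents=_to_cents(row["line_total_usd"]),
            )
        )
    return items


# --------------------------------------------------------------------------
# Print plan
# --------------------------------------------------------------------------


class PrintPartKind(enum.Enum):
    WHEEL = "WHEEL"
    BASE = "BASE"
    NUT_SET_OF_4 = "NUT_SET_OF_4"
    AXLE = "AXLE"


@dataclass(frozen=True)
class PrintPart:
    """One printed part of a wheel assembly: filament mass and print time."""

    part: PrintPartKind
    mass_g: float
    time_min: int

    def __post_init__(self):
        if self.mass_g < 0 or self.time_min < 0:
            raise ValidationError(f"{self.part.value}: mass and time must be >= 0")


#: The reference build's per-part filament masses and print times
#: (wheel 96 g / 4 h 20 m, base 38 g / 1 h 45 m, nut set 4 g / 28 m,
#: axle 6 g / 1 h 24 m).
REFERENCE_PRINT_PLAN: tuple[PrintPart, ...] = (
    PrintPart(PrintPartKind.WHEEL, 96.0, 4 * 60 + 20),
    PrintPart(PrintPartKind.BASE, 38.0, 1 * 60 + 45),
    PrintPart(PrintPartKind.NUT_SET_OF_4, 4.0, 28),
    PrintPart(PrintPartKind.AXLE, 6.0, 1 * 60 + 24),
)

NUTS_PER_WHEEL = 4


@dataclass(frozen=True)
class PrintPlanTotals:
    mass_per_wheel_g: float
    time_per_wheel_min: int
    build_mass_g: float
    build_time_min: int
    nut_count: int


def print_plan_totals(
    parts: Sequence[PrintPart] = REFERENCE_PRINT_PLAN, n_wheels: int = 1
) -> PrintPlanTotals:
    """Per-wheel and whole-build filament mass / print time / nut count.

    Requires exactly one entry per part kind.
    """
    kinds = [p.part for p in parts]
    missing = [k.value for k in PrintPartKind if k not in kinds]
    if missing:
        raise ValidationError(f"print plan missing part(s): {missing}")
    if len(kinds) != len(set(kinds)):
        raise ValidationError("print plan has duplicate part entries")
    mass = sum(p.mass_g for p in parts)
    t = sum(p.time_min for p in parts)
    return PrintPlanTotals(
        mass_per_wheel_g=mass,
        time_per_wheel_min=t,
        build_mass_g=mass * n_wheels,
        build_time_min=t * n_wheels,
        nut_count=NUTS_PER_WHEEL * n_wheels,
    )


def format_hm(minutes: int) -> str:
    return f"{minutes // 60} h {minutes % 60} min"
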