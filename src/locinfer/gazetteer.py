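"""Two-level Chinese administrative gazetteer.

The gazetteer holds province-level units (provinces, autonomous regions,
municipalities, Hong Kong and Macao) and city-level units (prefecture-level
cities, plus the municipalities and Hong Kong/Macao again, which belong to
both tiers).  Every unit carries a canonical name and a set of alias surface
forms (typically the suffixed official names such as 长沙市 or 四川省); a
surface index maps each form back to the unit(s) it denotes.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import (
    GazetteerConflictError,
    GazetteerFormatError,
    GazetteerLookupError,
    GazetteerReferentialError,
)

PROVINCE = "province"
CITY = "city"
LEVELS = (PROVINCE, CITY)

# One trailing administrative suffix is stripped before lookup, longest first.
ADMIN_SUFFIXES = ("特别行政区", "自治区", "省", "市")

_REQUIRED_COLUMNS = ("level", "canonical_name", "parent_province", "aliases")
_ALIAS_DELIMITER = "|"


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class AdminUnit:
    """One administrative unit at province or city level.

    ``parent_province`` is empty for province-level units; for city-level
    municipalities and Hong Kong/Macao it names the same-named
    province-level unit.
    """

    canonical_name: str
    level: str
    parent_province: str = ""
    aliases: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise GazetteerFormatError("AdminUnit canonical_name must be non-empty")
        if self.level not in LEVELS:
            raise GazetteerFormatError(f"invalid level {self.level!r}")

    @property
    def surfaces(self) -> frozenset:
        return self.aliases | {self.canonical_name}

    def __repr__(self) -> str:  # compact for test failure messages
        return f"AdminUnit({self.canonical_name}/{self.level})"


class Gazetteer:
    """Indexed collection of AdminUnits with surface-form lookup."""

    def __init__(self, units: Iterable[AdminUnit]):
        self.units: tuple[AdminUnit, ...] = tuple(units)
        self._by_level: dict[str, dict[str, AdminUnit]] = {PROVINCE: {}, CITY: {}}
        self.surface_index: dict[str, frozenset] = {}

        surface_owner: dict[tuple[str, str], AdminUnit] = {}
        for unit in self.units:
            level_map = self._by_level[unit.level]
            if unit.canonical_name in level_map:
                raise GazetteerConflictError(
                    f"duplicate canonical name {unit.canonical_name!r} at level {unit.level}"
                )
            level_map[unit.canonical_name] = unit
            for surf in unit.surfaces:
                key = (unit.level, surf)
                other = surface_owner.get(key)
                if other is not None and other is not unit:
                    raise GazetteerConflictError(
                        f"surface {surf!r} maps to both {other} and {unit}"
                    )
                surface_owner[key] = unit

        for unit in self.units:
            if unit.level == CITY:
                parent = unit.parent_province or unit.canonical_name
                if parent not in self._by_level[PROVINCE]:
                    raise GazetteerReferentialError(
                        f"city {unit.canonical_name!r} references unknown province {parent!r}"
                    )

        index: dict[str, set[AdminUnit]] = {}
        for unit in self.units:
            for surf in unit.surfaces:
                index.setdefault(surf, set()).add(unit)
        self.surface_index = {s: frozenset(us) for s, us in index.items()}

    def __len__(self) -> int:
        return len(self.units)

    @property
    def provinces(self) -> tuple[AdminUnit, ...]:
        return tuple(u for u in self.units if u.level == PROVINCE)

    @property
    def cities(self) -> tuple[AdminUnit, ...]:
        return tuple(u for u in self.units if u.level == CITY)

    def surfaces(self) -> set[str]:
        return set(self.surface_index)

    def unit(self, canonical_name: str, level: str) -> AdminUnit:
        try:
            return self._by_level[level][_nfc(canonical_name)]
        except KeyError:
            raise GazetteerLookupError(
                f"no unit {canonical_name!r} at level {level}"
            ) from None

    def canonicalize(self, surface: str) -> frozenset:
        """All units whose canonical name or alias equals ``surface``.

        The surface is NFC-normalized and, on a miss, one trailing
        administrative suffix (省/市/自治区/特别行政区) is stripped before a
        second exact lookup.  No match yields an empty set, never an error.
        """
        s = _nfc(surface)
        hit = self.surface_index.get(s)
        if hit:
            return hit
        for suffix in ADMIN_SUFFIXES:
            if s.endswith(suffix) and len(s) > len(suffix):
                return self.surface_index.get(s[: -len(suffix)], frozenset())
        return frozenset()

    def province_of(self, unit: AdminUnit) -> AdminUnit:
        """The province-level unit covering ``unit``.

        Provinces map to themselves; cities map to their parent province;
        municipalities and Hong Kong/Macao (present at both levels) map to
        the same-named province-level unit.
        """
        if unit not in self.surface_index.get(unit.canonical_name, frozenset()):
            raise GazetteerLookupError(f"{unit} does not belong to this gazetteer")
        if unit.level == PROVINCE:
            return unit
        parent = unit.parent_province or unit.canonical_name
        return self._by_level[PROVINCE][parent]


def load_gazetteer(source: Union[str, Path]) -> Gazetteer:
    """Load a gazetteer from a CSV file.

    Expected header: ``level,canonical_name,parent_province,aliases`` with
    aliases delimited by ``|``.  All surfaces are NFC-normalized on load.
    """
    path = Path(source)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise GazetteerFormatError(
                f"{path}: missing column(s) {', '.join(missing)}"
            )
        units = []
        for row in reader:
            level = _nfc((row["level"] or "").strip())
            name = _nfc((row["canonical_name"] or "").strip())
            parent = _nfc((row["parent_province"] or "").strip())
            raw_aliases = (row["aliases"] or "").strip()
            aliases = frozenset(
                _nfc(a.strip())
                for a in raw_aliases.split(_ALIAS_DELIMITER)
                if a.strip()
            )
            units.append(
                AdminUnit(
                    canonical_name=name,
                    level=level,
                    parent_province=parent,
                    aliases=aliases,
                )
            )
    return Gazetteer(units)


def bundled_gazetteer() -> Gazetteer:
    """The packaged China gazetteer (34 province-level units, 80+ cities)."""
    ref = resources.files("locinfer.data") / "gazetteer_cn.csv"
    with resources.as_file(ref) as path:
        return load_gazetteer(path)


# Functional aliases for the module-level API.
def canonicalize(surface: str, gaz: Gazetteer) -> frozenset:
    return gaz.canonicalize(surface)


def province_of(unit: AdminUnit, gaz: Gazetteer) -> AdminUnit:
    return gaz.province_of(unit)
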