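"""Class legends: the mapping from integer raster codes to land-cover classes.

A legend fixes the class vocabulary externally to the imagery: each entry
carries the integer code written in the raster, a human-readable name, an
optional succession rank (position on the successional gradient toward the
climax community, higher = closer to climax) and an ecological role used to
classify inter-epoch flows (``natural``, ``anthropogenic`` or ``water``).
Report rows always follow legend order, which makes every tabular output
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import yaml

__all__ = ["LegendEntry", "ClassLegend", "read_legend", "six_class_legend"]

#: Ecological roles recognised by the succession classifier.
VALID_ROLES = ("natural", "anthropogenic", "water")


@dataclass(frozen=True)
class LegendEntry:
    """One land-cover class: raster code, name, succession rank, role."""

    code: int
    name: str
    succession_rank: Optional[int] = None
    role: str = "natural"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"role for class {self.name!r} must be one of {VALID_ROLES}, "
                f"got {self.role!r}"
            )


@dataclass(frozen=True)
class ClassLegend:
    """Ordered collection of :class:`LegendEntry` plus the nodata code.

    Codes and names must be unique and the nodata code must not collide
    with any class code. Iteration order is entry order and is stable.
    """

    entries: tuple[LegendEntry, ...]
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        codes = [e.code for e in self.entries]
        names = [e.name for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate class codes in legend: {codes}")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names in legend: {names}")
        if self.nodata_code in codes:
            raise ValueError(
                f"nodata code {self.nodata_code} collides with a class code"
            )
        if not self.entries:
            raise ValueError("legend must define at least one class")

    def __iter__(self) -> Iterator[LegendEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(e.code for e in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def entry_for_code(self, code: int) -> LegendEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(f"class code {code} not in legend")

    def entry_for_name(self, name: str) -> LegendEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"class name {name!r} not in legend")

    def code_for_name(self, name: str) -> int:
        return self.entry_for_name(name).code


def _entries_from_records(records: Iterable[dict]) -> list[LegendEntry]:
    entries = []
    for rec in records:
        entries.append(
            LegendEntry(
                code=int(rec["code"]),
                name=str(rec["name"]),
                succession_rank=(
                    int(rec["succession_rank"])
                    if rec.get("succession_rank") is not None
                    else None
                ),
                role=str(rec.get("role", "natural")),
            )
        )
    return entries


def read_legend(path: Union[str, Path]) -> ClassLegend:
    """Load a legend from a YAML or JSON file.

    Expected structure::

        nodata_code: -9999
        classes:
          - {code: 1, name: croplands, succession_rank: 0, role: anthropogenic}
          - {code: 2, name: forests, succession_rank: 2, role: natural}
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "classes" not in doc:
        raise ValueError(f"legend file {path} must contain a 'classes' list")
    return ClassLegend(
        entries=tuple(_entries_from_records(doc["classes"])),
        nodata_code=int(doc.get("nodata_code", -9999)),
    )


def write_legend(legend: ClassLegend, path: Union[str, Path]) -> None:
    """Write a legend as YAML (or JSON if the suffix is ``.json``)."""
    doc = {
        "nodata_code": legend.nodata_code,
        "classes": [
            {
                "code": e.code,
                "name": e.name,
                "succession_rank": e.succession_rank,
                "role": e.role,
            }
            for e in legend.entries
        ],
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def six_class_legend(nodata_code: int = -9999) -> ClassLegend:
    """The six-class land-cover legend used throughout: croplands, forests,
    grasslands, water, settlements, others.

    Succession ranks encode the default gradient toward the climax:
    settlements = croplands (rank 0) < grasslands (1) < forests (2). Water
    is handled by its role rather than a rank; "others" (bare/transitional
    surfaces) sits below grasslands.
    """
    return ClassLegend(
        entries=(
            LegendEntry(1, "croplands", succession_rank=0, role="anthropogenic"),
            LegendEntry(2, "forests", succession_rank=2, role="natural"),
            LegendEntry(3, "grasslands", succession_rank=1, role="natural"),
            LegendEntry(4, "water", succession_rank=None, role="water"),
            LegendEntry(5, "settlements", succession_rank=0, role="anthropogenic"),
            LegendEntry(6, "others", succession_rank=0, role="natural"),
        ),
        nodata_code=nodata_code,
    )
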