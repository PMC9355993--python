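"""Region atlases: ordered region names and their measurement kind.

The atlas fixes the canonical ordering of every measurement vector,
random-effect vector and covariance matrix in the package. Regions are
either cortical thicknesses (mm) or subcortical volumes (mm^3); after
hemisphere averaging the default atlas has 41 regions (34 Desikan
cortical parcels plus 7 subcortical structures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import SchemaError

_DESIKAN_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens",
]


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of region names with a thickness/volume tag per region.

    Parameters
    ----------
    region_names
        Unique region identifiers; the order is canonical for every
        downstream vector and matrix.
    region_kind
        One tag per region, either ``"thickness"`` or ``"volume"``.
    """

    region_names: tuple[str, ...]
    region_kind: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        names = tuple(self.region_names)
        kinds = tuple(self.region_kind) if self.region_kind else tuple(
            "thickness" for _ in names
        )
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "region_kind", kinds)
        if len(names) == 0:
            raise SchemaError("atlas must contain at least one region")
        if len(set(names)) != len(names):
            raise SchemaError("atlas region names must be unique")
        if len(kinds) != len(names):
            raise SchemaError("region_kind must have one entry per region")
        bad = sorted({k for k in kinds} - {"thickness", "volume"})
        if bad:
            raise SchemaError(f"unknown region kinds: {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def index_of(self, names: Sequence[str]) -> list[int]:
        """Positions of ``names`` in canonical order (errors on misses)."""
        pos = {n: i for i, n in enumerate(self.region_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise SchemaError(f"regions not in atlas: {missing}")
        return [pos[n] for n in names]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_names": list(self.region_names),
            "region_kind": list(self.region_kind),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionAtlas":
        try:
            payload = json.loads(Path(path).read_text())
            return cls(
                region_names=tuple(payload["region_names"]),
                region_kind=tuple(payload["region_kind"]),
            )
        except (KeyError, json.JSONDecodeError) as exc:
            raise SchemaError(f"invalid atlas file {path}: {exc}") from exc


def desikan_atlas() -> RegionAtlas:
    """The default 41-region hemisphere-averaged atlas.

    34 Desikan cortical parcels (thickness) plus 7 subcortical
    structures (volume).
    """
    names = tuple(_DESIKAN_CORTICAL + _SUBCORTICAL)
    kinds = tuple(["thickness"] * len(_DESIKAN_CORTICAL)
                  + ["volume"] * len(_SUBCORTICAL))
    return RegionAtlas(names, kinds)


def toy_atlas(n_regions: int, kind: str = "thickness") -> RegionAtlas:
    """A small synthetic atlas (``region_1`` .. ``region_R``) for testing."""
    names = tuple(f"region_{i + 1}" for i in range(n_regions))
    return RegionAtlas(names, tuple(kind for _ in names))
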