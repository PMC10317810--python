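"""Regional morphometry feature schema.

The prediction pipeline represents each subject by a fixed-length vector of
regional morphometric measures: cortical thickness (mm) and surface area
(mm²) for the 68 cortical regions of the Desikan-Killiany parcellation
(34 per hemisphere), plus the volume (mm³) of 14 subcortical structures
(bilateral hippocampus, thalamus, amygdala, caudate, putamen, pallidum and
accumbens) — 150 features in total.

The within-vector ordering is a repository convention (the measures
themselves, not their order, carry the science): all thickness entries
first, then all area entries, then the 14 volumes; left hemisphere before
right within each block; regions in FreeSurfer's alphabetical aparc order;
subcortical structures in the order hippocampus, thalamus, amygdala,
caudate, putamen, pallidum, accumbens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "SchemaEntry",
    "RegionSchema",
    "build_default_schema",
    "DESIKAN_KILLIANY_REGIONS",
    "SUBCORTICAL_STRUCTURES",
    "MEASURE_UNITS",
    "write_schema_manifest",
    "read_schema_manifest",
]

#: The 34 cortical regions per hemisphere of the Desikan-Killiany atlas,
#: in FreeSurfer's canonical aparc order.
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Subcortical structures measured as volumes, both hemispheres each.
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "hippocampus",
    "thalamus",
    "amygdala",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
)

MEASURE_UNITS = {"thickness": "mm", "area": "mm^2", "volume": "mm^3"}

_HEMIS = ("left", "right")
_HEMI_PREFIX = {"left": "lh", "right": "rh"}


@dataclass(frozen=True)
class SchemaEntry:
    """One feature column: a (structure, hemisphere, measure) triple."""

    structure: str
    hemisphere: str  # 'left' or 'right'
    measure: str  # 'thickness' | 'area' | 'volume'

    @property
    def feature_name(self) -> str:
        return f"{_HEMI_PREFIX[self.hemisphere]}_{self.structure}_{self.measure}"

    @property
    def unit(self) -> str:
        return MEASURE_UNITS[self.measure]


@dataclass(frozen=True)
class RegionSchema:
    """Ordered catalogue of regional features defining feature-vector columns."""

    entries: tuple[SchemaEntry, ...]
    atlas_name: str = "desikan_killiany"

    def __post_init__(self):
        triples = [(e.structure, e.hemisphere, e.measure) for e in self.entries]
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (structure, hemisphere, measure) entries")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_names(self) -> list[str]:
        return [e.feature_name for e in self.entries]

    def count(self, measure: str) -> int:
        return sum(1 for e in self.entries if e.measure == measure)

    def index_of(self, feature_name: str) -> int:
        try:
            return self.feature_names.index(feature_name)
        except ValueError:
            raise KeyError(feature_name) from None


def build_default_schema() -> RegionSchema:
    """Build the canonical 150-entry schema (documented in the module docstring)."""
    entries: list[SchemaEntry] = []
    for measure in ("thickness", "area"):
        for hemi in _HEMIS:
            for region in DESIKAN_KILLIANY_REGIONS:
                entries.append(SchemaEntry(region, hemi, measure))
    for structure in SUBCORTICAL_STRUCTURES:
        for hemi in _HEMIS:
            entries.append(SchemaEntry(structure, hemi, "volume"))
    return RegionSchema(tuple(entries))


def write_schema_manifest(schema: RegionSchema, path) -> None:
    """Emit the schema as a two-column plain-text manifest (name, unit)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# atlas: {schema.atlas_name}\n")
        for entry in schema.entries:
            fh.write(f"{entry.feature_name}\t{entry.unit}\n")


def read_schema_manifest(path) -> RegionSchema:
    """Read a schema manifest written by :func:`write_schema_manifest`."""
    atlas = "desikan_killiany"
    entries: list[SchemaEntry] = []
    unit_to_measure = {u: m for m, u in MEASURE_UNITS.items()}
    prefix_to_hemi = {v: k for k, v in _HEMI_PREFIX.items()}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "atlas:" in line:
                    atlas = line.split("atlas:", 1)[1].strip()
                continue
            name, unit = line.split("\t")
            hemi_prefix, rest = name.split("_", 1)
            structure, measure = rest.rsplit("_", 1)
            if unit_to_measure[unit] != measure:
                raise ValueError(f"unit {unit!r} inconsistent with measure {measure!r}")
            entries.append(SchemaEntry(structure, prefix_to_hemi[hemi_prefix], measure))
    return RegionSchema(tuple(entries), atlas_name=atlas)


def make_custom_schema(names_measures: Iterable[tuple[str, str, str]]) -> RegionSchema:
    """Build a schema from (structure, hemisphere, measure) triples.

    Mainly for tests and property checks with small synthetic schemas.
    """
    return RegionSchema(tuple(SchemaEntry(s, h, m) for s, h, m in names_measures))
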