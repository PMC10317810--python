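"""Reader for FreeSurfer-style regional stats files (aparc.stats / aseg.stats).

Only the tabular regional outputs are consumed — surface reconstruction and
segmentation themselves are out of scope. The dialect: comment lines are
prefixed ``#``; a ``# ColHeaders ...`` comment names the whitespace-delimited
data columns. Cortical (aparc) rows carry per-region mean thickness and
surface area; subcortical (aseg) rows carry structure volumes.

Unknown structures in a file are ignored (tolerant reader); structures the
schema requires but the file lacks raise :class:`MissingRegionError`.
The mapping from FreeSurfer subcortical label spellings to canonical
structure names is a data file (``data/freesurfer_labels.csv``), not code.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .errors import MissingRegionError, StatsParseError
from .schema import RegionSchema

__all__ = ["read_regional_stats", "read_aparc_stats", "read_aseg_stats"]

# aparc.stats column names for the two measures we consume
_THICKNESS_COL = "ThickAvg"
_AREA_COL = "SurfArea"
_STRUCT_COL = "StructName"
_VOLUME_COL = "Volume_mm3"

# default ColHeaders of FreeSurfer outputs, used when the comment is absent
_APARC_DEFAULT_HEADERS = [
    "StructName", "NumVert", "SurfArea", "GrayVol", "ThickAvg",
    "ThickStd", "MeanCurv", "GausCurv", "FoldInd", "CurvInd",
]
_ASEG_DEFAULT_HEADERS = [
    "Index", "SegId", "NVoxels", "Volume_mm3", "StructName",
    "normMean", "normStdDev", "normMin", "normMax", "normRange",
]


def _load_subcortical_map() -> dict[str, tuple[str, str]]:
    mapping: dict[str, tuple[str, str]] = {}
    with resources.files("morphpred.data").joinpath("freesurfer_labels.csv").open() as fh:
        for row in csv.DictReader(fh):
            mapping[row["freesurfer_name"]] = (row["structure"], row["hemisphere"])
    return mapping


def _parse_stats(path, default_headers):
    """Parse one stats file into a list of {column: str} row dicts."""
    headers = list(default_headers)
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    headers = body.split()[1:]
                continue
            fields = line.split()
            if len(fields) != len(headers):
                raise StatsParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(headers)}",
                    line_number=lineno,
                )
            rows.append(dict(zip(headers, fields)))
    return rows


def _to_float(value: str, path, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise StatsParseError(f"{path}: non-numeric {column} value {value!r}") from None


def read_aparc_stats(path) -> dict[str, tuple[float, float]]:
    """Return {region: (thickness mm, area mm²)} for one hemisphere's aparc.stats."""
    out = {}
    for row in _parse_stats(path, _APARC_DEFAULT_HEADERS):
        name = row.get(_STRUCT_COL)
        if name is None:
            raise StatsParseError(f"{path}: no {_STRUCT_COL} column")
        out[name] = (
            _to_float(row[_THICKNESS_COL], path, _THICKNESS_COL),
            _to_float(row[_AREA_COL], path, _AREA_COL),
        )
    return out


def read_aseg_stats(path) -> dict[str, float]:
    """Return {FreeSurfer structure name: volume mm³} from an aseg.stats file."""
    out = {}
    for row in _parse_stats(path, _ASEG_DEFAULT_HEADERS):
        name = row.get(_STRUCT_COL)
        if name is None:
            raise StatsParseError(f"{path}: no {_STRUCT_COL} column")
        out[name] = _to_float(row[_VOLUME_COL], path, _VOLUME_COL)
    return out


def read_regional_stats(
    cortical_stats_paths: dict[str, object],
    subcortical_stats_path,
    schema: RegionSchema,
) -> np.ndarray:
    """Assemble one subject's feature row from FreeSurfer regional stats.

    Parameters
    ----------
    cortical_stats_paths
        ``{"left": lh.aparc.stats path, "right": rh.aparc.stats path}``.
    subcortical_stats_path
        Path to the subject's aseg.stats.
    schema
        Target schema; the returned row is aligned to its order. Units are
        preserved (mm, mm², mm³).
    """
    aparc = {hemi: read_aparc_stats(p) for hemi, p in cortical_stats_paths.items()}
    aseg = read_aseg_stats(subcortical_stats_path)
    subcort = _load_subcortical_map()
    by_canonical = {}
    for fs_name, volume in aseg.items():
        if fs_name in subcort:
            by_canonical[subcort[fs_name]] = volume

    row = np.empty(len(schema), dtype=np.float64)
    for j, entry in enumerate(schema.entries):
        if entry.measure == "volume":
            key = (entry.structure, entry.hemisphere)
            if key not in by_canonical:
                raise MissingRegionError(
                    f"structure {entry.structure!r} ({entry.hemisphere}) "
                    f"not found in {subcortical_stats_path}"
                )
            row[j] = by_canonical[key]
        else:
            hemi_table = aparc.get(entry.hemisphere)
            if hemi_table is None or entry.structure not in hemi_table:
                raise MissingRegionError(
                    f"cortical region {entry.structure!r} ({entry.hemisphere}) "
                    f"not found in the provided aparc stats"
                )
            thickness, area = hemi_table[entry.structure]
            row[j] = thickness if entry.measure == "thickness" else area
    return row
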