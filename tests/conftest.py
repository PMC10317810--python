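"""Shared fixtures: schemas, small tables, synthetic cohorts, stats files.

All fixture data is generated programmatically at test time; session-scoped
cohorts are reused across modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphpred import (
    FeatureTable,
    SyntheticCohortSpec,
    build_default_schema,
    simulate_cohort,
)
from morphpred.presets import fast_config, tiny_config
from morphpred.schema import make_custom_schema
from morphpred.simulate import default_effect_features


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_schema():
    """A 6-feature toy schema for cheap IO and property tests."""
    return make_custom_schema(
        [
            ("alpha", "left", "thickness"),
            ("alpha", "right", "thickness"),
            ("alpha", "left", "area"),
            ("alpha", "right", "area"),
            ("beta", "left", "volume"),
            ("beta", "right", "volume"),
        ]
    )


def make_table(schema, n_subjects, kind="baseline", seed=0, offset=10.0):
    """Random strictly-positive table on the given schema."""
    rng = np.random.default_rng(seed)
    values = offset + rng.random((n_subjects, len(schema))) * 5.0
    ids = [f"T{i:03d}" for i in range(n_subjects)]
    return FeatureTable(ids, values, schema.feature_names, kind)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def planted_indices():
    return default_effect_features()


@pytest.fixture(scope="session")
def signal_cohort(planted_indices):
    """n=120 single-arm cohort with d=1.5 on 10 baseline features."""
    spec = SyntheticCohortSpec(
        n_per_arm=(120, 2),
        baseline_effects={
            "quetiapine": [(i, 1.5) for i in planted_indices["quetiapine"]]
        },
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def signal_arm(signal_cohort):
    """(table, labels) of the large planted-signal arm."""
    idx = np.nonzero(signal_cohort.arm_of() == "quetiapine")[0]
    return signal_cohort.baseline.select(idx), signal_cohort.labels()[idx]


@pytest.fixture(scope="session")
def null_cohort():
    """n=120 single-arm cohort with no planted signal."""
    spec = SyntheticCohortSpec(n_per_arm=(120, 2), seed=43)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_arm(null_cohort):
    idx = np.nonzero(null_cohort.arm_of() == "quetiapine")[0]
    return null_cohort.baseline.select(idx), null_cohort.labels()[idx]


@pytest.fixture
def fast_cfg():
    return fast_config(0)


@pytest.fixture
def tiny_cfg():
    return tiny_config(0)


# ---------------------------------------------------------------------------
# FreeSurfer-style stats fixtures (synthetic, authored with known values)

APARC_THICKNESS_BASE = {"left": 2.0, "right": 3.0}
APARC_AREA_BASE = {"left": 1000.0, "right": 2000.0}
ASEG_VOLUME_BASE = 4000.0


def write_aparc(path, hemisphere, schema):
    """Synthetic aparc.stats: thickness = base + i*0.01, area = base + i."""
    regions = sorted(
        {e.structure for e in schema.entries if e.measure == "thickness"}
    )
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        f"# hemi {'lh' if hemisphere == 'left' else 'rh'}",
        "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd "
        "MeanCurv GausCurv FoldInd CurvInd",
    ]
    for i, region in enumerate(regions):
        thick = APARC_THICKNESS_BASE[hemisphere] + i * 0.01
        area = APARC_AREA_BASE[hemisphere] + i
        lines.append(
            f"{region} 1000 {area:.1f} 3000.0 {thick:.3f} 0.5 0.1 0.02 10 1.0"
        )
    path.write_text("\n".join(lines) + "\n")
    return {
        region: (
            APARC_THICKNESS_BASE[hemisphere] + i * 0.01,
            APARC_AREA_BASE[hemisphere] + i,
        )
        for i, region in enumerate(regions)
    }


ASEG_NAMES = [
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Thalamus-Proper",
    "Right-Thalamus-Proper",
    "Left-Amygdala",
    "Right-Amygdala",
    "Left-Caudate",
    "Right-Caudate",
    "Left-Putamen",
    "Right-Putamen",
    "Left-Pallidum",
    "Right-Pallidum",
    "Left-Accumbens-area",
    "Right-Accumbens-area",
]


def write_aseg(path, skip=(), extra_rows=()):
    """Synthetic aseg.stats: volume = 4000 + 10*i for the i-th structure."""
    lines = [
        "# Title Segmentation Statistics",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean "
        "normStdDev normMin normMax normRange",
    ]
    volumes = {}
    row = 1
    for i, name in enumerate(ASEG_NAMES):
        if name in skip:
            continue
        vol = ASEG_VOLUME_BASE + 10 * i
        volumes[name] = vol
        lines.append(f"{row} {10 + i} 3500 {vol:.1f} {name} 80.0 5.0 40.0 110.0 70.0")
        row += 1
    for extra in extra_rows:
        lines.append(extra)
    path.write_text("\n".join(lines) + "\n")
    return volumes


@pytest.fixture
def stats_files(tmp_path, schema):
    """Write a full synthetic aparc/aseg trio; return paths and expected values."""
    lh = tmp_path / "lh.aparc.stats"
    rh = tmp_path / "rh.aparc.stats"
    aseg = tmp_path / "aseg.stats"
    expected_lh = write_aparc(lh, "left", schema)
    expected_rh = write_aparc(rh, "right", schema)
    expected_vol = write_aseg(aseg)
    return {
        "lh": lh,
        "rh": rh,
        "aseg": aseg,
        "expected": {"left": expected_lh, "right": expected_rh, "volumes": expected_vol},
    }
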