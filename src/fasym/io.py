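"""Reading, validating and writing landmark configurations and metadata.

Two on-disk landmark formats are supported, matching the usual digitizing
workflow (3D Slicer for placement, TPS files for analysis):

* 3D Slicer Markups fiducial files (``.fcsv``) — one file per digitization,
  comment header lines starting with ``#`` followed by one CSV row per
  fiducial with x, y, z in columns 2-4 and the free-form label in column 12.
* TPS files with ``LM3=<k>`` blocks — many configurations per file, one
  coordinate triple per line, specimen identifier on an ``ID=`` line.
  Replicates are encoded in the ID as a ``_rep<k>`` suffix (TPS has no
  replicate field).

Specimen metadata travels as a CSV with columns ``specimen_id, sex,
age_at_death, decade_of_birth, matriline, n_hurricanes, age_at_hurricane``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scheme import LandmarkScheme

logger = logging.getLogger(__name__)

REPLICATE_SUFFIX = re.compile(r"^(?P<specimen>.+)_rep(?P<rep>\d+)$")

METADATA_COLUMNS = [
    "specimen_id",
    "sex",
    "age_at_death",
    "decade_of_birth",
    "matriline",
    "n_hurricanes",
    "age_at_hurricane",
]

VALID_SEX = {"F", "M"}
VALID_AGE_AT_HURRICANE = {"fetal", "juvenile", "adult", "none"}


class LandmarkSchemaError(ValueError):
    """Landmark file content disagrees with the landmark scheme."""


class LandmarkParseError(ValueError):
    """Landmark file is syntactically malformed."""


class MetadataError(ValueError):
    """Specimen metadata violates the expected schema or invariants."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitization of one specimen: an ``n_landmarks x 3`` coordinate block."""

    specimen_id: str
    replicate_id: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise LandmarkSchemaError(
                f"{self.specimen_id}: coordinates must be (k, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise LandmarkSchemaError(
                f"{self.specimen_id}: non-finite coordinate; incomplete "
                "configurations are rejected (no imputation)"
            )
        if self.replicate_id < 1:
            raise LandmarkSchemaError("replicate_id must be >= 1")
        object.__setattr__(self, "coords", coords)

    @property
    def label(self) -> str:
        return f"{self.specimen_id}_rep{self.replicate_id}"


@dataclass(frozen=True)
class Dataset:
    """Landmark configurations joined to specimen metadata.

    Invariants enforced at construction: every specimen has the same number
    of replicate digitizations, every configuration's specimen appears in the
    metadata table, and the metadata passes :func:`validate_metadata`.
    """

    scheme: LandmarkScheme
    configurations: tuple[LandmarkConfiguration, ...]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        configs = tuple(
            sorted(self.configurations, key=lambda c: (c.specimen_id, c.replicate_id))
        )
        object.__setattr__(self, "configurations", configs)
        metadata = validate_metadata(self.metadata)
        object.__setattr__(self, "metadata", metadata)
        counts: dict[str, int] = {}
        for c in configs:
            if c.coords.shape[0] != self.scheme.n_landmarks:
                raise LandmarkSchemaError(
                    f"{c.label}: expected {self.scheme.n_landmarks} landmarks, "
                    f"found {c.coords.shape[0]}"
                )
            counts[c.specimen_id] = counts.get(c.specimen_id, 0) + 1
        if not counts:
            raise MetadataError("dataset contains no landmark configurations")
        r_values = set(counts.values())
        if len(r_values) != 1:
            bad = sorted(s for s, k in counts.items() if k != max(r_values))
            raise MetadataError(
                f"unequal replicate counts across specimens; offending ids: {bad}"
            )
        known = set(metadata["specimen_id"])
        missing = sorted(set(counts) - known)
        if missing:
            raise MetadataError(f"configurations without metadata rows: {missing}")
        orphan = sorted(known - set(counts))
        if orphan:
            raise MetadataError(f"metadata rows without landmark data: {orphan}")

    @property
    def n(self) -> int:
        """Number of individuals."""
        return len(self.metadata)

    @property
    def r(self) -> int:
        """Replicate digitizations per individual."""
        return len(self.configurations) // self.n

    def replicates_of(self, specimen_id: str) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if c.specimen_id == specimen_id]

    def coordinate_array(self) -> np.ndarray:
        """All configurations stacked as ``(n*r, n_landmarks, 3)`` in sorted order."""
        return np.stack([c.coords for c in self.configurations])


# ---------------------------------------------------------------------------
# fcsv (3D Slicer Markups fiducial)
# ---------------------------------------------------------------------------

def read_fcsv(
    path: str | Path,
    scheme: LandmarkScheme,
    *,
    specimen_id: str | None = None,
    replicate_id: int = 1,
    label_map: Mapping[str, int] | None = None,
) -> LandmarkConfiguration:
    """Read one 3D Slicer Markups fiducial file into a configuration.

    Landmark order is taken from file row order unless ``label_map`` (fiducial
    label -> 0-based scheme index) is supplied, in which case rows may appear
    in any order.  The specimen and replicate identifiers default to the file
    stem parsed with the ``_rep<k>`` convention.
    """
    path = Path(path)
    rows: list[tuple[float, float, float, str]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if len(fields) < 4:
                raise LandmarkParseError(
                    f"{path}: row {lineno}: expected >= 4 comma-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                x, y, z = (float(fields[i]) for i in (1, 2, 3))
            except ValueError as exc:
                raise LandmarkParseError(
                    f"{path}: row {lineno}: non-numeric coordinate ({exc})"
                ) from None
            label = fields[11] if len(fields) > 11 else ""
            rows.append((x, y, z, label))
    if len(rows) != scheme.n_landmarks:
        raise LandmarkSchemaError(
            f"{path}: expected {scheme.n_landmarks} landmarks, found {len(rows)}"
        )
    coords = np.empty((scheme.n_landmarks, 3))
    if label_map is None:
        for i, (x, y, z, _) in enumerate(rows):
            coords[i] = (x, y, z)
    else:
        seen = np.zeros(scheme.n_landmarks, dtype=bool)
        for x, y, z, label in rows:
            if label not in label_map:
                raise LandmarkSchemaError(f"{path}: unmapped fiducial label {label!r}")
            idx = label_map[label]
            if seen[idx]:
                raise LandmarkSchemaError(f"{path}: duplicate label {label!r}")
            seen[idx] = True
            coords[idx] = (x, y, z)
    if specimen_id is None:
        specimen_id, replicate_id = split_replicate_label(path.stem)
    return LandmarkConfiguration(specimen_id, replicate_id, coords)


def write_fcsv(config: LandmarkConfiguration, path: str | Path) -> None:
    """Write a configuration as a Slicer Markups fiducial file."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = LPS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (x, y, z) in enumerate(config.coords, start=1):
            fh.write(
                f"vtkMRMLMarkupsFiducialNode_{i},{x:.6f},{y:.6f},{z:.6f},"
                f"0,0,0,1,1,1,0,LM-{i},,\n"
            )


def split_replicate_label(label: str) -> tuple[str, int]:
    """Split ``spec_rep2`` into ``("spec", 2)``; no suffix means replicate 1."""
    m = REPLICATE_SUFFIX.match(label)
    if m:
        return m.group("specimen"), int(m.group("rep"))
    return label, 1


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read all configurations from a TPS file (``LM3=`` 3-D dialect)."""
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected: int | None = None
    ident: str | None = None
    block_line = 0

    def flush(lineno: int) -> None:
        nonlocal coords, expected, ident
        if expected is None:
            return
        if len(coords) != expected:
            raise LandmarkParseError(
                f"{path}: block at line {block_line}: LM3={expected} but "
                f"{len(coords)} coordinate rows"
            )
        label = ident if ident is not None else f"specimen{len(configs) + 1}"
        specimen_id, replicate_id = split_replicate_label(label)
        configs.append(
            LandmarkConfiguration(specimen_id, replicate_id, np.array(coords))
        )
        coords, expected, ident = [], None, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush(lineno)
                block_line = lineno
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError:
                    raise LandmarkParseError(
                        f"{path}: line {lineno}: bad LM3 count {line!r}"
                    ) from None
            elif upper.startswith("ID="):
                ident = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                if expected is None:
                    raise LandmarkParseError(
                        f"{path}: line {lineno}: coordinates before any LM3= header"
                    )
                parts = line.split()
                if len(parts) != 3:
                    raise LandmarkParseError(
                        f"{path}: line {lineno}: expected 3 coordinates, got "
                        f"{len(parts)}"
                    )
                try:
                    coords.append([float(v) for v in parts])
                except ValueError:
                    raise LandmarkParseError(
                        f"{path}: line {lineno}: non-numeric coordinate {line!r}"
                    ) from None
        flush(-1)
    if not configs:
        logger.warning("%s: no landmark configurations found (empty TPS file)", path)
    return configs


def write_tps(
    configs: Iterable[LandmarkConfiguration], path: str | Path, *, decimals: int = 6
) -> None:
    """Write configurations as a TPS file; replicate encoded as ``_rep<k>`` ID suffix."""
    path = Path(path)
    with open(path, "w") as fh:
        for config in configs:
            fh.write(f"LM3={config.coords.shape[0]}\n")
            for x, y, z in config.coords:
                fh.write(f"{x:.{decimals}f} {y:.{decimals}f} {z:.{decimals}f}\n")
            fh.write(f"ID={config.label}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a specimen metadata table.

    Enforces the column schema, category levels, and the exposure-consistency
    invariant: ``n_hurricanes > 0`` exactly when ``age_at_hurricane != 'none'``.
    Adds the derived boolean ``hurricane_experienced`` column.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    md = metadata.copy()
    md["specimen_id"] = md["specimen_id"].astype(str)
    if md["specimen_id"].duplicated().any():
        dupes = sorted(md.loc[md["specimen_id"].duplicated(), "specimen_id"])
        raise MetadataError(f"duplicate specimen_id rows: {dupes}")
    md["sex"] = md["sex"].astype(str).str.strip().str.upper()
    bad_sex = sorted(set(md["sex"]) - VALID_SEX)
    if bad_sex:
        raise MetadataError(f"invalid sex codes {bad_sex}; expected F or M")
    md["age_at_death"] = pd.to_numeric(md["age_at_death"], errors="raise")
    if (md["age_at_death"] < 0).any():
        raise MetadataError("age_at_death must be non-negative")
    md["decade_of_birth"] = md["decade_of_birth"].astype(int)
    md["matriline"] = md["matriline"].astype(str)
    md["n_hurricanes"] = md["n_hurricanes"].astype(int)
    if not md["n_hurricanes"].isin([0, 1, 2]).all():
        raise MetadataError("n_hurricanes must be 0, 1 or 2")
    md["age_at_hurricane"] = md["age_at_hurricane"].astype(str).str.strip().str.lower()
    bad_age = sorted(set(md["age_at_hurricane"]) - VALID_AGE_AT_HURRICANE)
    if bad_age:
        raise MetadataError(
            f"invalid age_at_hurricane levels {bad_age}; expected "
            f"{sorted(VALID_AGE_AT_HURRICANE)}"
        )
    md["hurricane_experienced"] = md["n_hurricanes"] > 0
    inconsistent = md["hurricane_experienced"] != (md["age_at_hurricane"] != "none")
    if inconsistent.any():
        bad = sorted(md.loc[inconsistent, "specimen_id"])
        raise MetadataError(
            f"exposure inconsistency (n_hurricanes vs age_at_hurricane): {bad}"
        )
    return md.reset_index(drop=True)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata[METADATA_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------

def load_dataset(
    landmarks: str | Path,
    metadata_csv: str | Path,
    scheme: LandmarkScheme,
    *,
    expected_replicates: int | None = None,
    label_map: Mapping[str, int] | None = None,
) -> Dataset:
    """Load and join landmark data with metadata into a validated :class:`Dataset`.

    ``landmarks`` may be a TPS file, a directory of ``.fcsv`` files, or a
    directory of ``.tps`` files.  The result is independent of file order.
    """
    landmarks = Path(landmarks)
    configs: list[LandmarkConfiguration] = []
    if landmarks.is_file():
        configs.extend(read_tps(landmarks))
    elif landmarks.is_dir():
        fcsv_files = sorted(landmarks.glob("*.fcsv"))
        tps_files = sorted(landmarks.glob("*.tps"))
        for f in fcsv_files:
            configs.append(read_fcsv(f, scheme, label_map=label_map))
        for f in tps_files:
            configs.extend(read_tps(f))
        if not fcsv_files and not tps_files:
            raise FileNotFoundError(f"no .fcsv or .tps files under {landmarks}")
    else:
        raise FileNotFoundError(landmarks)

    metadata = read_metadata_csv(metadata_csv)
    dataset = Dataset(scheme=scheme, configurations=tuple(configs), metadata=metadata)
    if expected_replicates is not None and dataset.r != expected_replicates:
        raise MetadataError(
            f"expected {expected_replicates} replicates per specimen, found {dataset.r}"
        )
    logger.info(
        "loaded dataset: n=%d individuals, r=%d replicates, p=%d pairs, u=%d midline",
        dataset.n, dataset.r, scheme.n_pairs, scheme.n_midline,
    )
    return dataset
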