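"""Readers and writers for landmark datasets.

Supported formats: the TPS dialect written by common 2D digitizing tools
(``LM=``, coordinate lines, optional ``IMAGE=``, ``ID=``, ``SCALE=``),
classifier and covariate tables as headed CSV, and rooted Newick trees with
branch lengths.

Side and replicate labels are carried in the TPS ``ID=`` field with the
convention ``<specimen>_<L|R|N>_<image#>_<digit#>`` (``N`` = structure has no
side).  An ID without that suffix is taken as a bare specimen id (no side,
single replicate).  Explicit columns in a classifier table override the ID
convention downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .schemes import LandmarkScheme

__all__ = [
    "Configuration",
    "read_tps",
    "write_tps",
    "read_classifier_table",
    "read_covariate_table",
    "read_newick",
    "write_newick",
    "validate_dataset",
    "ValidationReport",
]

_SIDES = ("left", "right", "none")
_SIDE_TOKEN = {"L": "left", "R": "right", "N": "none"}
_TOKEN_SIDE = {v: k for k, v in _SIDE_TOKEN.items()}
_ID_RE = re.compile(r"^(?P<spec>.+)_(?P<side>[LRN])_(?P<img>\d+)_(?P<dig>\d+)$")


@dataclass
class Configuration:
    """One digitized landmark configuration (k x 2 coordinates plus labels)."""

    specimen_id: str
    structure: str
    side: str
    image_rep: int
    digit_rep: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in configuration {self.specimen_id!r}")
        if np.allclose(self.coords, self.coords[0]):
            raise ValueError(f"degenerate configuration {self.specimen_id!r}: "
                             "all landmarks identical")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def tps_id(self) -> str:
        return f"{self.specimen_id}_{_TOKEN_SIDE[self.side]}_{self.image_rep}_{self.digit_rep}"


class TpsParseError(ValueError):
    pass


def _finish_record(lines_expected, coords, rec_id, scale, structure, record_index):
    if lines_expected != len(coords):
        raise TpsParseError(
            f"record {record_index}: LM={lines_expected} declared but "
            f"{len(coords)} coordinate lines read")
    arr = np.asarray(coords, dtype=float)
    if scale is not None:
        arr = arr * scale
    m = _ID_RE.match(rec_id) if rec_id else None
    if m:
        specimen, side = m.group("spec"), _SIDE_TOKEN[m.group("side")]
        img, dig = int(m.group("img")), int(m.group("dig"))
    else:
        specimen, side, img, dig = (rec_id or f"record{record_index}"), "none", 1, 1
    return Configuration(specimen_id=specimen, structure=structure, side=side,
                         image_rep=img, digit_rep=dig, coords=arr)


def read_tps(path: str | Path, scheme: LandmarkScheme) -> list[Configuration]:
    """Parse a TPS file into configurations of ``scheme``.

    ``SCALE=`` factors are applied multiplicatively; side/replicate labels are
    parsed from the ``ID=`` naming convention documented in this module.
    """
    configs: list[Configuration] = []
    lines_expected: int | None = None
    coords: list[list[float]] = []
    rec_id: str | None = None
    scale: float | None = None
    record_index = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if lines_expected is not None:
                configs.append(_finish_record(lines_expected, coords, rec_id,
                                              scale, scheme.name, record_index))
                record_index += 1
            lines_expected = int(line[3:])
            coords, rec_id, scale = [], None, None
        elif upper.startswith("ID="):
            rec_id = line[3:]
        elif upper.startswith("IMAGE="):
            continue
        elif upper.startswith("SCALE="):
            scale = float(line[6:])
        else:
            if lines_expected is None:
                raise TpsParseError(f"coordinate line before any LM= header: {line!r}")
            parts = line.split()
            if len(parts) != 2:
                raise TpsParseError(f"record {record_index}: malformed coordinate line {line!r}")
            coords.append([float(parts[0]), float(parts[1])])
    if lines_expected is not None:
        configs.append(_finish_record(lines_expected, coords, rec_id, scale,
                                      scheme.name, record_index))
    for c in configs:
        if c.k != scheme.k:
            raise TpsParseError(f"configuration {c.specimen_id!r} has {c.k} landmarks, "
                                f"scheme {scheme.name!r} expects {scheme.k}")
    return configs


def write_tps(configs: Sequence[Configuration], path: str | Path) -> None:
    """Write configurations to TPS; an empty list yields an empty file."""
    structures = {c.structure for c in configs}
    if len(structures) > 1:
        raise ValueError(f"cannot mix schemes in one TPS file: {sorted(structures)}")
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{x:.10f} {y:.10f}")
        out.append(f"ID={c.tps_id()}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


_REQUIRED_CLASSIFIER_COLS = ("specimen_id", "species", "locality", "sex", "individual")


def read_classifier_table(path: str | Path) -> pd.DataFrame:
    """Read the specimen classifier CSV, indexed by specimen_id.

    Requires columns species, locality, sex, individual; species and sex must
    be complete.
    """
    df = pd.read_csv(path, dtype=str)
    for col in _REQUIRED_CLASSIFIER_COLS:
        if col not in df.columns:
            raise ValueError(f"classifier table missing required column {col!r}")
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id in classifier table: {dups}")
    if df["species"].isna().any() or df["sex"].isna().any():
        raise ValueError("classifier table has missing species or sex labels")
    return df.set_index("specimen_id")


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    """Read per-specimen integer counts (e.g. spinule rows), indexed by specimen_id."""
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise ValueError("covariate table missing required column 'specimen_id'")
    df = df.set_index("specimen_id")
    if (df.select_dtypes("number") < 0).any().any():
        raise ValueError("covariate counts must be non-negative")
    return df


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; missing branch lengths default to 1 (warned)."""
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"Newick parse error (duplicate tips or malformed tree): {exc}")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    defaulted = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            defaulted = True
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    if defaulted:
        warnings.warn("tree has missing branch lengths; defaulting them to 1.0")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick", suppress_rooting=True))


@dataclass
class ValidationReport:
    """Completeness audit of a landmark dataset against its replicate design."""

    retained_for_asymmetry: list[str]
    dropped_from_asymmetry: list[str]
    retained_for_means: list[str]
    missing_from_classifier: list[str]
    n_configurations: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_for_asymmetry)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_from_asymmetry)


def validate_dataset(configs: Sequence[Configuration], classifiers: pd.DataFrame,
                     scheme: LandmarkScheme) -> ValidationReport:
    """Audit side/replicate completeness.

    Specimens missing a side (matching symmetry) are dropped from asymmetry
    analyses but retained wherever per-individual means suffice (PCA, DFA,
    PLS).  The operation only reports; callers apply the policy.
    """
    by_spec: dict[str, set[str]] = {}
    for c in configs:
        by_spec.setdefault(c.specimen_id, set()).add(c.side)
    complete, incomplete = [], []
    for spec_id, sides in sorted(by_spec.items()):
        if scheme.symmetry == "matching" and sides != {"left", "right"}:
            incomplete.append(spec_id)
        else:
            complete.append(spec_id)
    missing = sorted(s for s in by_spec if s not in classifiers.index)
    return ValidationReport(
        retained_for_asymmetry=complete,
        dropped_from_asymmetry=incomplete,
        retained_for_means=sorted(by_spec),
        missing_from_classifier=missing,
        n_configurations=len(configs),
    )
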