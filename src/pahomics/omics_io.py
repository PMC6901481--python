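"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are tab-delimited UTF-8 text with Unix newlines.
Intensity matrices are features x samples with the first column holding the
feature identifier; missing values are written as empty fields and read from
any of {"", "NA", "NaN"}. Pathway collections use the standard GMT layout
(name, description, members). Readers validate and reject malformed input
rather than silently coercing it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six experimental-evidence categories retained when building the
#: interactome, plus the code marking computationally predicted interactions
#: (kept only so the filtering step can be exercised).
EVIDENCE_CODES = frozenset({"Y2H", "3D", "KS", "SIG", "APMS", "LIT"})
PREDICTED_CODE = "PRED"

GROUPS = ("case", "control")

_NA_TOKENS = ("", "NA", "NaN")

_FLOAT_FMT = "%.12g"


class OmicsIOError(ValueError):
    """Raised when an input file or in-memory container fails validation."""


@dataclass
class IntensityMatrix:
    """A features x samples abundance table with missingness and group labels.

    ``values`` holds floats with NaN for missing cells; the index carries the
    feature identifiers and the columns the sample identifiers. ``groups``
    maps every sample to ``case`` or ``control``. Raw-scale matrices
    (``transformed=False``) must be non-negative; after variance-stabilizing
    transformation the flag is set and negative values are legal.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise OmicsIOError(f"duplicate feature id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise OmicsIOError(f"duplicate sample id {dup!r}")
        missing_groups = [s for s in v.columns if s not in self.groups]
        if missing_groups:
            raise OmicsIOError(f"samples without a group: {missing_groups}")
        bad = {s: g for s, g in self.groups.items()
               if s in v.columns and g not in GROUPS}
        if bad:
            raise OmicsIOError(f"group labels must be in {GROUPS}, got {bad}")
        if not self.transformed:
            arr = v.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                rows = v.index[(v < 0).any(axis=1)]
                raise OmicsIOError(
                    f"negative raw intensity in feature {rows[0]!r}")
        all_missing = v.index[v.isna().all(axis=1)]
        if len(all_missing):
            raise OmicsIOError(
                f"feature {all_missing[0]!r} has no observed values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def copy_with(self, values: pd.DataFrame, *,
                  transformed: bool | None = None) -> "IntensityMatrix":
        return IntensityMatrix(
            values=values,
            groups=dict(self.groups),
            transformed=self.transformed if transformed is None else transformed,
        )


@dataclass
class GeneSetCollection:
    """Named sets of member identifiers (pathways, annotation lists)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise OmicsIOError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise OmicsIOError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_intensity_tsv(path, groups: Mapping[str, str], *,
                       transformed: bool = False) -> IntensityMatrix:
    """Read a features x samples TSV into an :class:`IntensityMatrix`.

    Rows with no observed value at all are dropped with a logged warning so
    the resulting matrix satisfies the one-observation-per-feature invariant.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_TOKENS,
                         keep_default_na=False, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise OmicsIOError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise OmicsIOError(f"{path}: duplicate feature id {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise OmicsIOError(f"{path}: non-numeric intensity ({exc})") from exc
    if not transformed:
        neg = values.index[(values < 0).any(axis=1)]
        if len(neg):
            raise OmicsIOError(
                f"{path}: negative intensity in feature {neg[0]!r}")
    empty = values.index[values.isna().all(axis=1)]
    if len(empty):
        logger.warning("%s: dropping %d feature(s) with no observed values "
                       "(first: %r)", path, len(empty), empty[0])
        values = values.drop(index=empty)
    values.index = values.index.astype(str)
    values.index.name = None
    return IntensityMatrix(values=values, groups=dict(groups),
                           transformed=transformed)


def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, sep="\t", na_rep="", float_format=_FLOAT_FMT,
                    index_label="feature_id", lineterminator="\n")


def read_sample_sheet(path) -> dict[str, str]:
    """Read a two-column sample -> group TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise OmicsIOError(
            f"{path}: expected columns sample_id, group; got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise OmicsIOError(f"{path}: duplicate sample id {dup!r}")
    bad = df.loc[~df["group"].isin(GROUPS), "group"]
    if len(bad):
        raise OmicsIOError(f"{path}: unknown group label {bad.iloc[0]!r}")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_sheet(groups: Mapping[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}
                 ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path) -> pd.DataFrame:
    """Read a (node_a, node_b, evidence_code) TSV.

    Evidence codes are restricted to the six experimental categories plus
    ``PRED``; unknown codes raise. Predicted edges load but are flagged in
    the boolean ``predicted`` column so the interactome builder can drop them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["node_a", "node_b", "evidence_code"]
    if list(df.columns[:3]) != required:
        raise OmicsIOError(
            f"{path}: expected columns {required}, got {list(df.columns)}")
    allowed = EVIDENCE_CODES | {PREDICTED_CODE}
    unknown = df.loc[~df["evidence_code"].isin(allowed), "evidence_code"]
    if len(unknown):
        raise OmicsIOError(
            f"{path}: unknown evidence code {unknown.iloc[0]!r}")
    df = df.copy()
    df["predicted"] = df["evidence_code"].eq(PREDICTED_CODE)
    n_pred = int(df["predicted"].sum())
    if n_pred:
        logger.warning("%s: %d computationally predicted edge(s) flagged",
                       path, n_pred)
    return df


def write_edge_list(records: pd.DataFrame | Iterable[tuple], path) -> None:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records),
                               columns=["node_a", "node_b", "evidence_code"])
    cols = ["node_a", "node_b", "evidence_code"]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OmicsIOError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if not members:
                raise OmicsIOError(f"{path}:{lineno}: set {name!r} is empty")
            if name in sets:
                raise OmicsIOError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_alias_map(path) -> dict[str, str]:
    """Optional two-column identifier alias file (old_id, new_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise OmicsIOError(f"{path}: alias file needs two columns")
    old, new = df.columns[:2]
    if df[old].duplicated().any():
        dup = df.loc[df[old].duplicated(), old].iloc[0]
        raise OmicsIOError(f"{path}: duplicate alias source {dup!r}")
    return dict(zip(df[old], df[new]))


def write_results_tsv(records: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
                   lineterminator="\n")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
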