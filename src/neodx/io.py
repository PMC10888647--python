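"""Sample tables, pathway sets and their file formats.

A :class:`SampleTable` is the pipeline's in-memory container: a samples ×
analytes concentration matrix (µmol/L) held in a :class:`pandas.DataFrame`
plus per-sample metadata (group label, hours post-insult, treatment arm).
Tables round-trip through plain CSV/TSV; pathway compound sets come in as
standard GMT files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MetabolitePanel, default_panel

__all__ = [
    "SampleTable",
    "PathwaySet",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "TREATMENTS",
    "META_COLUMNS",
]

TREATMENTS = ("none", "LPS", "LPS+HIE", "HIE", "HIE+TH")
META_COLUMNS = ("sample_id", "group", "time_h", "treatment")


@dataclass
class SampleTable:
    """Concentration matrix plus per-sample metadata.

    ``data`` is indexed by sample id with one column per panel code, in
    panel order; ``meta`` shares the index and carries ``group`` (str),
    ``time_h`` (float or NaN) and ``treatment``.
    """

    panel: MetabolitePanel
    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.loc[:, self.panel.codes].astype(float)
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the sample index")
        missing = [c for c in ("group", "time_h", "treatment")
                   if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata columns missing: {missing}")
        if self.meta["group"].isna().any() or (self.meta["group"] == "").any():
            bad = self.meta.index[
                self.meta["group"].isna() | (self.meta["group"] == "")
            ].tolist()
            raise ValueError(f"missing group label for samples {bad}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("non-finite concentration values")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative concentration at sample "
                f"{self.data.index[r]!r}, analyte {self.data.columns[c]!r}"
            )
        bad_t = set(self.meta["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(f"unknown treatment labels: {sorted(bad_t)}")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    def select_groups(self, *labels: str) -> "SampleTable":
        """Rows belonging to any of ``labels`` (order of appearance kept)."""
        for g in labels:
            if g not in set(self.groups):
                raise ValueError(f"group {g!r} not present in table")
        mask = self.groups.isin(labels)
        return SampleTable(self.panel, self.data[mask], self.meta[mask])

    def group_matrix(self, label: str) -> np.ndarray:
        return self.select_groups(label).X

    def binary_labels(self, negative: str, positive: str) -> np.ndarray:
        """0/1 vector over the rows of ``select_groups(negative, positive)``."""
        sub = self.select_groups(negative, positive)
        return (sub.groups == positive).to_numpy().astype(float)

    def concat(self, other: "SampleTable") -> "SampleTable":
        if self.panel.codes != other.panel.codes:
            raise ValueError("cannot concatenate tables with different panels")
        overlap = set(self.sample_ids) & set(other.sample_ids)
        if overlap:
            raise ValueError(f"duplicate sample ids: {sorted(overlap)[:5]}")
        return SampleTable(
            self.panel,
            pd.concat([self.data, other.data]),
            pd.concat([self.meta, other.meta]),
        )


def read_sample_table(
    path: str | Path | _io.IOBase,
    panel: MetabolitePanel | None = None,
    sep: str | None = None,
) -> SampleTable:
    """Read a CSV/TSV concentration table.

    The header must name every panel code plus the metadata columns
    ``sample_id, group, time_h, treatment``; analyte columns are reordered
    to panel order.  Unknown analyte columns, negative concentrations and
    missing group labels are rejected with informative errors.
    """
    panel = panel or default_panel()
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("missing required column 'sample_id'")
    for col in ("group", "treatment"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if "time_h" not in df.columns:
        df["time_h"] = np.nan
    unknown = [
        c for c in df.columns
        if c not in META_COLUMNS and c not in panel
    ]
    if unknown:
        raise ValueError(f"unknown analyte column(s): {unknown}")
    absent = [c for c in panel.codes if c not in df.columns]
    if absent:
        raise ValueError(f"panel analyte column(s) missing from file: {absent}")
    df = df.set_index("sample_id")
    meta = df[["group", "time_h", "treatment"]].copy()
    meta["time_h"] = pd.to_numeric(meta["time_h"], errors="coerce")
    data = df[panel.codes]
    return SampleTable(panel, data, meta)


def write_sample_table(
    table: SampleTable, path: str | Path, sep: str = ","
) -> None:
    """Write a table as CSV/TSV; lossless round-trip with the reader."""
    out = table.meta[["group", "time_h", "treatment"]].join(table.data)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


@dataclass
class PathwaySet:
    """A named library of pathway → compound-name sets over a universe."""

    name: str
    library: str
    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("no pathways")
        for pname, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pname!r} is empty")
        if not self.universe:
            self.universe = set().union(*self.pathways.values())
        for pname, members in self.pathways.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"pathway {pname!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def restrict_universe(self, universe: set[str]) -> "PathwaySet":
        """Intersect every pathway and the universe with ``universe``.

        Used to score enrichment against the panel's own compound space
        rather than the full library; pathways left empty are dropped.
        """
        pw = {
            name: members & universe
            for name, members in self.pathways.items()
        }
        pw = {name: m for name, m in pw.items() if m}
        if not pw:
            raise ValueError("no pathways overlap the requested universe")
        return PathwaySet(self.name, self.library,
                          pw, self.universe & universe)


def read_gmt(
    path: str | Path,
    name: str | None = None,
    library: str = "custom",
    universe: set[str] | None = None,
) -> PathwaySet:
    """Parse a GMT file (``name <tab> description <tab> members...``).

    The universe defaults to the union of all members; pass ``universe``
    to score against an explicit compound space instead.
    """
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pname = fields[0].strip()
            members = {m.strip() for m in fields[2:] if m.strip()}
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway "
                                 f"{pname!r} has no members")
            pathways[pname] = members
    if not pathways:
        raise ValueError(f"{path}: no pathways")
    return PathwaySet(
        name or Path(path).stem, library, pathways, universe or set()
    )
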