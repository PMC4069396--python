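"""Readers, writers and validated domain types for every external artifact.

All tabular artifacts are plain TSV. Hit tables follow the 12-column BLAST
``outfmt 6`` dialect. The reaction database is a small stanza-based text
format (one reaction per stanza: ``ID``, ``EC`` and ``EQ`` lines) documented
in ``docs/methods.md``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "FeatureTable",
    "SampleMetadata",
    "HitRecord",
    "Reaction",
    "HierarchyMap",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_hit_table",
    "write_hit_table",
    "read_reaction_db",
    "write_reaction_db",
    "read_hierarchy_map",
    "write_hierarchy_map",
]


class FormatError(ValueError):
    """A file or in-memory value violates the format contract."""


_PROPORTION_TOL = 1e-9


@dataclass(frozen=True)
class FeatureTable:
    """Features x samples abundance matrix (OTU counts or EC/gene-family counts).

    ``units_tag`` is one of ``counts`` (non-negative integers),
    ``proportions`` (percent scale: every sample column sums to 100) or
    ``normalized`` (arbitrary non-negative values, e.g. quantile normalized).
    """

    data: pd.DataFrame
    units_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.units_tag not in ("counts", "proportions", "normalized"):
            raise FormatError(f"unknown units_tag {self.units_tag!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise FormatError("non-finite value in feature table")
        if values.size and values.min() < 0:
            raise FormatError("negative value in feature table")
        if self.units_tag == "counts" and values.size:
            if not np.allclose(values, np.round(values), rtol=0, atol=0):
                raise FormatError("non-integer value in a counts table")
        if self.units_tag == "proportions" and values.size:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 100.0, rtol=0, atol=1e-6):
                bad = np.asarray(self.data.columns)[~np.isclose(sums, 100.0, rtol=0, atol=1e-6)]
                raise FormatError(f"proportion columns not summing to 100: {list(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.units_tag == other.units_tag
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.counts, other.counts, rtol=0, atol=1e-12)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample environmental measurements and the EPA-BM group label.

    Concentrations use the study's units: TPH in ug/kg sediment; DIN, NH3-N and
    NO3-N in mg/l porewater; total N as a mass fraction. Missing measurements
    are ``nan``; the group label is never missing.
    """

    sample_id: str
    exceeds_epa_bm: bool
    tph: float = math.nan
    din: float = math.nan
    nh3_n: float = math.nan
    no3_n: float = math.nan
    total_n: float = math.nan
    distance_km: float = math.nan
    depth_m: float = math.nan

    def __post_init__(self) -> None:
        for name in ("tph", "din", "nh3_n", "no3_n", "total_n", "distance_km", "depth_m"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise FormatError(f"{self.sample_id}: negative {name} = {v}")


@dataclass(frozen=True)
class HitRecord:
    """One pairwise-alignment hit of a read against a functional gene database."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score):
            raise FormatError(f"{self.query_id}: non-finite bit score")
        if self.evalue < 0:
            raise FormatError(f"{self.query_id}: negative e-value")
        if self.aln_length < 1:
            raise FormatError(f"{self.query_id}: alignment length < 1")
        if not 0 <= self.pct_identity <= 100:
            raise FormatError(f"{self.query_id}: identity outside [0, 100]")


_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")


@dataclass(frozen=True)
class Reaction:
    """A metabolic reaction with its EC links and signed stoichiometry.

    Substrates are the left side of the equation as written, products the
    right side; coefficients are positive.
    """

    reaction_id: str
    ec_numbers: tuple[str, ...]
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.ec_numbers:
            raise FormatError(f"{self.reaction_id}: reaction has no EC number")
        for ec in self.ec_numbers:
            if not _EC_RE.match(ec):
                raise FormatError(f"{self.reaction_id}: malformed EC number {ec!r}")
        if not self.substrates or not self.products:
            raise FormatError(f"{self.reaction_id}: empty substrate or product list")
        for side_name, side in (("substrate", self.substrates), ("product", self.products)):
            ids = [m for m, _ in side]
            if len(ids) != len(set(ids)):
                raise FormatError(f"{self.reaction_id}: duplicate {side_name} metabolite")
            for m, coeff in side:
                if coeff <= 0:
                    raise FormatError(f"{self.reaction_id}: non-positive coefficient for {m}")


class HierarchyMap:
    """Total map function_id -> (level1, level2, level3) category strings."""

    def __init__(self, mapping: dict[str, tuple[str, str, str]]):
        self._mapping = dict(mapping)

    def __contains__(self, function_id: str) -> bool:
        return function_id in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HierarchyMap) and self._mapping == other._mapping

    def lookup(self, function_id: str) -> tuple[str, str, str]:
        try:
            return self._mapping[function_id]
        except KeyError:
            raise KeyError(f"function {function_id!r} not in hierarchy map") from None

    def level(self, function_id: str, level: int) -> str:
        if level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        return self.lookup(function_id)[level - 1]

    def items(self):
        return self._mapping.items()


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, units_tag: str = "counts") -> FeatureTable:
    """Read a TSV feature table (first column feature id, header = sample ids)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        raise FormatError(f"{path}: empty feature table")
    header = first.split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicated sample ids in header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty feature table") from None
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in table ({exc})") from None
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        return FeatureTable(values, units_tag=units_tag)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    data = table.data
    if table.units_tag == "counts":
        data = data.astype(np.int64)
    data.to_csv(Path(path), sep="\t", index_label="feature_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = {
    "sample_id",
    "exceeds_epa_bm",
    "tph",
    "din",
    "nh3_n",
    "no3_n",
    "total_n",
    "distance_km",
    "depth_m",
}

_BOOL_VALUES = {"0": False, "1": True, "false": False, "true": True}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata from TSV; missing values are encoded ``NA``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata file") from None
    if df.empty:
        raise FormatError(f"{path}: metadata file has no rows")
    cols = set(df.columns)
    if "sample_id" not in cols:
        raise FormatError(f"{path}: missing sample_id column")
    if "exceeds_epa_bm" not in cols:
        raise FormatError(f"{path}: missing exceeds_epa_bm column")
    unknown = cols - _META_COLUMNS
    if unknown:
        logger.warning("%s: ignoring unknown metadata columns %s", path, sorted(unknown))

    def _num(raw: str, where: str) -> float:
        if raw in ("NA", ""):
            return math.nan
        try:
            return float(raw)
        except ValueError:
            raise FormatError(f"{path}: non-numeric value {raw!r} in {where}") from None

    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        flag_raw = row["exceeds_epa_bm"].strip().lower()
        if flag_raw not in _BOOL_VALUES:
            raise FormatError(
                f"{path}: exceeds_epa_bm for {sid!r} must be 0/1/true/false, got {row['exceeds_epa_bm']!r}"
            )
        kwargs = {
            name: _num(row[name], f"{name} of {sid}")
            for name in ("tph", "din", "nh3_n", "no3_n", "total_n", "distance_km", "depth_m")
            if name in cols
        }
        records.append(SampleMetadata(sample_id=sid, exceeds_epa_bm=_BOOL_VALUES[flag_raw], **kwargs))
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    names = ["sample_id", "exceeds_epa_bm", "tph", "din", "nh3_n", "no3_n", "total_n", "distance_km", "depth_m"]
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "exceeds_epa_bm": int(r.exceeds_epa_bm)}
        for name in names[2:]:
            v = getattr(r, name)
            row[name] = "NA" if math.isnan(v) else f"{v:.10g}"
        rows.append(row)
    pd.DataFrame(rows, columns=names).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hit tables (BLAST outfmt 6)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> Iterator[HitRecord]:
    """Lazily yield validated hits from a 12-column tabular (outfmt 6) file.

    Columns 5-10 (mismatches .. send) are parsed for arity but unused.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                record = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            yield record


def write_hit_table(hits, path: str | Path) -> None:
    """Write hits in outfmt-6; the unused columns 5-10 are zero-filled."""
    with open(Path(path), "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Reaction database
# ---------------------------------------------------------------------------

_COEFF_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S.*)$")


def _parse_side(side: str, reaction_id: str, path: Path) -> tuple[tuple[str, float], ...]:
    terms = []
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            raise FormatError(f"{path}: {reaction_id}: empty term in equation")
        m = _COEFF_TERM_RE.match(term)
        coeff = float(m.group(1)) if m.group(1) else 1.0
        terms.append((m.group(2).strip(), coeff))
    return tuple(terms)


def read_reaction_db(path: str | Path) -> list[Reaction]:
    """Parse the stanza-based reaction database.

    Each stanza has an ``ID`` line, an ``EC`` line (semicolon-separated EC
    numbers) and an ``EQ`` line with an equation ``2 A + B <=> C`` ( ``<=>``
    marks a reversible reaction, ``=>`` an irreversible one; an omitted
    coefficient is 1). Stanzas are separated by ``//`` or blank lines.
    """
    path = Path(path)
    reactions: list[Reaction] = []
    stanza: dict[str, str] = {}

    def _flush() -> None:
        if not stanza:
            return
        rid = stanza.get("ID")
        if rid is None:
            raise FormatError(f"{path}: stanza without ID line")
        if "EC" not in stanza:
            raise FormatError(f"{path}: {rid}: stanza without EC line")
        if "EQ" not in stanza:
            raise FormatError(f"{path}: {rid}: stanza without EQ line")
        ecs = tuple(e.strip() for e in stanza["EC"].split(";") if e.strip())
        eq = stanza["EQ"]
        if "<=>" in eq:
            left, right = eq.split("<=>", 1)
            reversible = True
        elif "=>" in eq:
            left, right = eq.split("=>", 1)
            reversible = False
        else:
            raise FormatError(f"{path}: {rid}: equation lacks '=>' or '<=>' separator")
        try:
            reactions.append(
                Reaction(
                    reaction_id=rid,
                    ec_numbers=ecs,
                    substrates=_parse_side(left, rid, path),
                    products=_parse_side(right, rid, path),
                    reversible=reversible,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
        stanza.clear()

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line == "//":
                _flush()
                continue
            if line.startswith("#"):
                continue
            key, _, value = line.partition(" ")
            if key in ("ID", "EC", "EQ"):
                stanza[key] = value.strip()
            else:
                raise FormatError(f"{path}: unknown line type {key!r}")
    _flush()
    return reactions


def write_reaction_db(reactions: list[Reaction], path: str | Path) -> None:
    def _side(side) -> str:
        return " + ".join(m if c == 1 else f"{c:g} {m}" for m, c in side)

    with open(Path(path), "w") as fh:
        for r in reactions:
            arrow = "<=>" if r.reversible else "=>"
            fh.write(f"ID {r.reaction_id}\n")
            fh.write(f"EC {'; '.join(r.ec_numbers)}\n")
            fh.write(f"EQ {_side(r.substrates)} {arrow} {_side(r.products)}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Hierarchy map
# ---------------------------------------------------------------------------

def read_hierarchy_map(path: str | Path) -> HierarchyMap:
    """Read a 4-column TSV (function, level1, level2, level3) with a header."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty hierarchy map") from None
    if df.shape[1] != 4:
        raise FormatError(f"{path}: expected 4 columns, got {df.shape[1]}")
    mapping: dict[str, tuple[str, str, str]] = {}
    for _, row in df.iterrows():
        fid = row.iloc[0]
        if fid in mapping:
            raise FormatError(f"{path}: duplicate function id {fid!r}")
        mapping[fid] = (row.iloc[1], row.iloc[2], row.iloc[3])
    return HierarchyMap(mapping)


def write_hierarchy_map(hmap: HierarchyMap, path: str | Path) -> None:
    rows = [
        {"function_id": fid, "level1": lv[0], "level2": lv[1], "level3": lv[2]}
        for fid, lv in sorted(hmap.items())
    ]
    pd.DataFrame(rows, columns=["function_id", "level1", "level2", "level3"]).to_csv(
        Path(path), sep="\t", index=False
    )
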