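"""Core domain objects for community count data.

The central object is :class:`CommunityMatrix`, an integer taxa-by-samples
count table with per-sample metadata (river section, technical replicate).
Taxon-level traits — taxonomy, three ecological-guild codes (habitat water
velocity, water layer, egg type) and conservation/origin status flags — live
in :class:`TaxonRecord`. A historical species checklist, which may be known
only through its summary totals, is a :class:`Checklist`.

A bundled reference dataset (:func:`load_table1_fixture`) holds the
sequence counts of 97 fish species detected by 12S eDNA metabarcoding in 12
dam-separated sections of a river mainstem, with full trait and flag
annotation; it drives most worked examples and tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VELOCITY_GUILDS",
    "LAYER_GUILDS",
    "EGG_GUILDS",
    "STATUS_FLAGS",
    "TABLE1_SECTIONS",
    "SampleInfo",
    "CommunityMatrix",
    "TaxonRecord",
    "Checklist",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "read_community_table",
    "write_community_table",
    "read_taxon_table",
    "write_taxon_table",
    "load_table1_fixture",
    "load_historical_checklist",
    "validate",
]

#: Habitat water-velocity guilds: F flowing water (rheophilic),
#: E eurytopic, S slow / semi-lentic water.
VELOCITY_GUILDS = frozenset({"F", "E", "S"})
#: Water-layer guilds: P1 pelagic, D1 demersal, B benthopelagic.
LAYER_GUILDS = frozenset({"P1", "D1", "B"})
#: Egg / spawning-type guilds: A adhesive, D2 drifting, D3 demersal,
#: P2 pelagic eggs, O other.
EGG_GUILDS = frozenset({"A", "D2", "D3", "P2", "O"})
#: Per-species status flags.
STATUS_FLAGS = frozenset(
    {
        "shared_historical",  # also present in the historical checklist
        "protected",  # nationally protected species
        "alien",  # non-native species
        "extreme_abundance",  # dominance index above the screening threshold
        "endemic_upper_yangtze",  # endemic to the upper Yangtze drainage
    }
)

#: Section codes of the bundled survey, in source-table column order.
TABLE1_SECTIONS = (
    "HJD", "PD", "YZD", "DF", "WJD", "SFY", "GPT", "SL", "ST", "PS", "YP", "FL",
)


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ParseError(ValueError):
    """A cell failed to parse; the message carries the row number."""


class IntegrityError(RuntimeError):
    """A bundled data file does not match its recorded checksum."""


@dataclass(frozen=True)
class SampleInfo:
    """Identity and grouping of one sample (column)."""

    sample_id: str
    section: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomy, ecological guilds and status flags of one taxon."""

    taxon_id: str
    order: str
    family: str
    genus: str
    species: str
    velocity_guild: str
    layer_guild: str
    egg_guild: str
    flags: frozenset = frozenset()
    accessions: tuple = ()

    def violations(self) -> list[str]:
        out = []
        if not self.species:
            out.append(f"{self.taxon_id}: empty species name")
        if self.velocity_guild not in VELOCITY_GUILDS:
            out.append(
                f"{self.taxon_id}: velocity guild {self.velocity_guild!r} "
                f"not in {sorted(VELOCITY_GUILDS)}"
            )
        if self.layer_guild not in LAYER_GUILDS:
            out.append(
                f"{self.taxon_id}: layer guild {self.layer_guild!r} "
                f"not in {sorted(LAYER_GUILDS)}"
            )
        if self.egg_guild not in EGG_GUILDS:
            out.append(
                f"{self.taxon_id}: egg guild {self.egg_guild!r} "
                f"not in {sorted(EGG_GUILDS)}"
            )
        bad = set(self.flags) - STATUS_FLAGS
        if bad:
            out.append(f"{self.taxon_id}: unknown flags {sorted(bad)}")
        return out


class CommunityMatrix:
    """Taxa-by-samples integer count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = taxon ids,
        columns = sample ids.
    samples
        One :class:`SampleInfo` per column, in column order.
    keep_empty
        Allow taxa whose count is zero in every sample.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleInfo] | None = None,
        *,
        keep_empty: bool = False,
    ) -> None:
        counts = counts.copy()
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("need at least 1 taxon and 1 sample")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated taxon ids: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dup}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        empty = counts.sum(axis=1) == 0
        if empty.any() and not keep_empty:
            raise ValueError(
                "all-zero taxa present (pass keep_empty=True to allow): "
                f"{counts.index[empty].tolist()[:5]}"
            )
        if samples is None:
            samples = [SampleInfo(str(c), str(c)) for c in counts.columns]
        samples = list(samples)
        if [s.sample_id for s in samples] != [str(c) for c in counts.columns]:
            raise ValueError("sample metadata does not match count columns")
        self.counts = counts.astype(np.int64)
        self.samples = samples
        self.keep_empty = keep_empty

    # -- basic views -------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def sections(self) -> list[str]:
        """Distinct section codes in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.section, None)
        return list(seen)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CommunityMatrix({self.counts.shape[0]} taxa x "
            f"{self.counts.shape[1]} samples, total={self.grand_total()})"
        )


@dataclass
class Checklist:
    """A species checklist; entries may be absent with only summary totals."""

    entries: list[tuple[str, str, str, str]] = field(default_factory=list)
    summary_counts: dict[str, int] = field(default_factory=dict)

    RANKS = ("species", "genus", "family", "order")

    def __post_init__(self) -> None:
        if self.entries and not self.summary_counts:
            self.summary_counts = {
                rank: len({e[i] for e in self.entries})
                for i, rank in enumerate(self.RANKS)
            }
        if self.entries and self.summary_counts:
            for i, rank in enumerate(self.RANKS):
                n = len({e[i] for e in self.entries})
                if rank in self.summary_counts and self.summary_counts[rank] != n:
                    raise ValueError(
                        f"summary count for {rank} ({self.summary_counts[rank]}) "
                        f"does not match entries ({n})"
                    )
        if not self.entries and not self.summary_counts:
            raise ValueError("checklist needs entries or summary_counts")

    @property
    def n_species(self) -> int:
        return self.summary_counts["species"]

    def species_names(self) -> set[str]:
        return {e[0] for e in self.entries}


# ---------------------------------------------------------------------------
# Tab-separated readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "taxon_id": "taxon_id",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "velocity_guild": "velocity_guild",
    "layer_guild": "layer_guild",
    "egg_guild": "egg_guild",
    "flags": "flags",
    "accessions": "accessions",
}

_META_COLUMNS = tuple(_DEFAULT_SCHEMA)


def _parse_count(cell, row_no: int, col) -> int:
    """Parse one count cell, accepting thousands separators like '87,709'."""
    s = str(cell).strip().replace(",", "").replace(" ", "")
    try:
        v = int(s)
    except ValueError:
        raise ParseError(
            f"row {row_no}: count {cell!r} in column {col!r} is not an integer"
        ) from None
    if v < 0:
        raise ParseError(f"row {row_no}: negative count {v} in column {col!r}")
    return v


def read_community_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    samples: Sequence[SampleInfo] | None = None,
    *,
    sep: str | None = None,
    keep_empty: bool = False,
) -> tuple[CommunityMatrix, list[TaxonRecord]]:
    """Read a taxa-by-samples count table with a taxon-metadata block.

    Every column not named in ``schema`` is treated as a sample count
    column; counts may contain thousands separators. Row order is
    preserved. Raises :class:`SchemaError` for missing metadata columns
    and :class:`ParseError` (with the offending row number) for bad
    counts.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("")
    sch = dict(_DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    for key in ("taxon_id", "species"):
        if sch[key] not in df.columns:
            raise SchemaError(f"missing required column {sch[key]!r}")
    meta_cols = [sch[k] for k in _META_COLUMNS if sch[k] in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise SchemaError("no sample count columns found")

    counts = pd.DataFrame(
        [
            [_parse_count(df.iloc[i][c], i + 2, c) for c in sample_cols]
            for i in range(len(df))
        ],
        index=pd.Index(df[sch["taxon_id"]], name="taxon_id"),
        columns=sample_cols,
        dtype=np.int64,
    )
    records = []
    for _, row in df.iterrows():
        flags = frozenset(
            t for t in str(row.get(sch["flags"], "")).split(";") if t
        )
        acc = tuple(t for t in str(row.get(sch["accessions"], "")).split(";") if t)
        records.append(
            TaxonRecord(
                taxon_id=row[sch["taxon_id"]],
                order=row.get(sch["order"], ""),
                family=row.get(sch["family"], ""),
                genus=row.get(sch["genus"], ""),
                species=row[sch["species"]],
                velocity_guild=row.get(sch["velocity_guild"], ""),
                layer_guild=row.get(sch["layer_guild"], ""),
                egg_guild=row.get(sch["egg_guild"], ""),
                flags=flags,
                accessions=acc,
            )
        )
    matrix = CommunityMatrix(counts, samples, keep_empty=keep_empty)
    return matrix, records


def write_community_table(
    matrix: CommunityMatrix,
    records: Sequence[TaxonRecord] | None,
    path: str | Path,
    *,
    header_lines: Iterable[str] = (),
) -> None:
    """Write the TSV dialect :func:`read_community_table` consumes."""
    path = Path(path)
    by_id = {r.taxon_id: r for r in records or []}
    cols = list(_META_COLUMNS) + matrix.sample_ids
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for tid in matrix.taxon_ids:
            r = by_id.get(tid)
            meta = [
                tid,
                r.order if r else "",
                r.family if r else "",
                r.genus if r else "",
                r.species if r else tid,
                r.velocity_guild if r else "",
                r.layer_guild if r else "",
                r.egg_guild if r else "",
                ";".join(sorted(r.flags)) if r else "",
                ";".join(r.accessions) if r else "",
            ]
            row = meta + [str(int(v)) for v in matrix.counts.loc[tid]]
            fh.write("\t".join(row) + "\n")


def read_taxon_table(path: str | Path) -> list[TaxonRecord]:
    """Read a trait/flag table: one row per taxon, flags semicolon-separated."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in ("taxon_id", "species"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TaxonRecord(
                taxon_id=row["taxon_id"],
                order=row.get("order", ""),
                family=row.get("family", ""),
                genus=row.get("genus", ""),
                species=row["species"],
                velocity_guild=row.get("velocity_guild", ""),
                layer_guild=row.get("layer_guild", ""),
                egg_guild=row.get("egg_guild", ""),
                flags=frozenset(t for t in row.get("flags", "").split(";") if t),
                accessions=tuple(
                    t for t in row.get("accessions", "").split(";") if t
                ),
            )
        )
    return out


def write_taxon_table(records: Sequence[TaxonRecord], path: str | Path) -> None:
    cols = list(_META_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.taxon_id, r.order, r.family, r.genus, r.species,
                        r.velocity_guild, r.layer_guild, r.egg_guild,
                        ";".join(sorted(r.flags)), ";".join(r.accessions),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Bundled reference data
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("ednadiv") / "data" / name)


def load_table1_fixture() -> tuple[CommunityMatrix, list[TaxonRecord]]:
    """Load the bundled 97-species x 12-section eDNA survey count table.

    Columns are pooled per river section (one column per section, in the
    source table's order); guild codes, status flags and reference
    accessions are fully populated. The file is checksum-verified against
    its metadata sidecar; a mismatch raises :class:`IntegrityError`.
    """
    tsv = _data_path("table1.tsv")
    meta = json.loads(_data_path("table1_meta.json").read_text())
    digest = hashlib.sha256(tsv.read_bytes()).hexdigest()
    if digest != meta["sha256"]:
        raise IntegrityError(
            f"fixture checksum mismatch: {digest} != {meta['sha256']}"
        )
    samples = [SampleInfo(sec, sec, 1) for sec in meta["section_order"]]
    matrix, records = read_community_table(tsv, samples=samples)
    if matrix.grand_total() != meta["grand_total"]:
        raise IntegrityError("fixture grand total changed")
    return matrix, records


def load_historical_checklist() -> Checklist:
    """Historical checklist of the surveyed mainstem (summary totals only)."""
    data = json.loads(_data_path("historical_checklist.json").read_text())
    return Checklist(summary_counts=data["summary_counts"])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(
    matrix: CommunityMatrix,
    records: Sequence[TaxonRecord] | None = None,
    *,
    section_codes: Iterable[str] | None = None,
) -> list[str]:
    """Report invariant violations; empty list means everything holds.

    Checks the count matrix (non-negativity, uniqueness, empty taxa),
    sample metadata (declared section codes, replicate numbers), record
    alignment and per-record guild/flag domains. Never raises.
    """
    out: list[str] = []
    counts = matrix.counts
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)].tolist()
        out.append(f"negative counts for taxa {bad}")
    empty = counts.index[counts.sum(axis=1) == 0].tolist()
    if empty and not matrix.keep_empty:
        out.append(f"all-zero taxa not allowed: {empty}")
    ids = [s.sample_id for s in matrix.samples]
    if len(set(ids)) != len(ids):
        out.append("duplicated sample ids")
    if section_codes is not None:
        allowed = set(section_codes)
        for s in matrix.samples:
            if s.section not in allowed:
                out.append(
                    f"sample {s.sample_id}: section {s.section!r} not declared"
                )
    if records is not None:
        rec_ids = [r.taxon_id for r in records]
        dup = {t for t in rec_ids if rec_ids.count(t) > 1}
        if dup:
            out.append(f"duplicated taxon ids in records: {sorted(dup)}")
        if set(rec_ids) != set(matrix.taxon_ids):
            missing = set(matrix.taxon_ids) - set(rec_ids)
            extra = set(rec_ids) - set(matrix.taxon_ids)
            if missing:
                out.append(f"taxa without records: {sorted(missing)[:5]}")
            if extra:
                out.append(f"records without taxa: {sorted(extra)[:5]}")
        for r in records:
            out.extend(r.violations())
    return out
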