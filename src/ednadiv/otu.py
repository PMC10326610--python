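"""From annotated OTU tables to depth-normalized community matrices.

Metabarcoding reads arrive clustered into OTUs, each annotated with its
best-hit taxon, percent identity, E-value and a target-class (fish) flag.
This module applies the standard retention thresholds (identity >= 97%,
E-value <= 1e-5, cluster size over 10 reads, target class only), merges
OTUs assigned to the same taxon, pools technical replicates per river
section, and normalizes sequencing depth by rarefaction — subsampling
without replacement to a common depth so diversity indices are comparable
across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix, ParseError, SampleInfo, SchemaError

__all__ = [
    "OtuRow",
    "AnnotatedOtuTable",
    "read_otu_table",
    "write_otu_table",
    "filter_otus",
    "collapse_to_taxa",
    "pool_replicates",
    "rarefy",
    "relative_abundance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OtuRow:
    """One OTU with its per-sample counts and annotation."""

    otu_id: str
    counts: tuple[int, ...]
    best_hit_taxon: str | None
    identity: float
    evalue: float
    is_target_class: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.otu_id}: identity {self.identity} not in [0,1]")
        if self.evalue < 0:
            raise ValueError(f"{self.otu_id}: negative E-value")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.otu_id}: negative count")

    @property
    def total(self) -> int:
        return sum(self.counts)


class AnnotatedOtuTable:
    """OTU-by-sample counts plus per-OTU annotation."""

    def __init__(self, rows: Sequence[OtuRow], samples: Sequence[SampleInfo]):
        rows = list(rows)
        ids = [r.otu_id for r in rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated otu ids: {dup}")
        n = len(samples)
        for r in rows:
            if len(r.counts) != n:
                raise ValueError(
                    f"{r.otu_id}: {len(r.counts)} counts for {n} samples"
                )
        self.rows = rows
        self.samples = list(samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.counts for r in self.rows],
            index=pd.Index([r.otu_id for r in self.rows], name="otu_id"),
            columns=self.sample_ids,
            dtype=np.int64,
        )

    def __len__(self) -> int:
        return len(self.rows)


def read_otu_table(
    path: str | Path, samples: Sequence[SampleInfo] | None = None
) -> AnnotatedOtuTable:
    """Read the annotated OTU TSV dialect.

    Expected columns: ``otu_id``, one integer column per sample, then
    ``taxon``, ``identity``, ``evalue``, ``target_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"otu_id", "taxon", "identity", "evalue", "target_class"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s) {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    rows = []
    for i, row in df.iterrows():
        try:
            counts = tuple(int(str(row[c]).replace(",", "")) for c in sample_cols)
        except ValueError:
            raise ParseError(f"row {i + 2}: non-integer count") from None
        rows.append(
            OtuRow(
                otu_id=row["otu_id"],
                counts=counts,
                best_hit_taxon=row["taxon"] or None,
                identity=float(row["identity"]),
                evalue=float(row["evalue"]),
                is_target_class=str(row["target_class"]).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    if samples is None:
        samples = [SampleInfo(c, c) for c in sample_cols]
    return AnnotatedOtuTable(rows, samples)


def write_otu_table(
    table: AnnotatedOtuTable, path: str | Path, *, header_lines=()
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "\t".join(
                ["otu_id", *table.sample_ids, "taxon", "identity", "evalue",
                 "target_class"]
            )
            + "\n"
        )
        for r in table.rows:
            fh.write(
                "\t".join(
                    [
                        r.otu_id,
                        *(str(c) for c in r.counts),
                        r.best_hit_taxon or "",
                        repr(r.identity),
                        repr(r.evalue),
                        "1" if r.is_target_class else "0",
                    ]
                )
                + "\n"
            )


def filter_otus(
    table: AnnotatedOtuTable,
    *,
    min_identity: float = 0.97,
    max_evalue: float = 1e-5,
    min_cluster_size: int = 11,
    target_only: bool = True,
) -> AnnotatedOtuTable:
    """Retain OTUs passing the annotation-quality and size thresholds.

    Defaults implement: identity >= 97%, E-value <= 1e-5, clusters of
    over 10 reads (i.e. total >= 11), assigned to the target class. Row
    order is preserved and the input is left untouched; an empty result
    is returned with a warning, not an error.
    """
    kept = [
        r
        for r in table.rows
        if r.identity >= min_identity
        and r.evalue <= max_evalue
        and r.total >= min_cluster_size
        and (r.is_target_class or not target_only)
    ]
    if not kept:
        log.warning("filter_otus: no OTUs passed the thresholds")
    return AnnotatedOtuTable(kept, table.samples)


def collapse_to_taxa(table: AnnotatedOtuTable) -> CommunityMatrix:
    """Merge OTUs assigned to the same taxon by summing their counts.

    Unassigned OTUs are dropped with a logged count. Taxon order follows
    first appearance.
    """
    unassigned = sum(1 for r in table.rows if r.best_hit_taxon is None)
    if unassigned:
        log.info("collapse_to_taxa: dropping %d unassigned OTUs", unassigned)
    order: dict[str, np.ndarray] = {}
    for r in table.rows:
        if r.best_hit_taxon is None:
            continue
        acc = order.setdefault(
            r.best_hit_taxon, np.zeros(len(table.samples), dtype=np.int64)
        )
        acc += np.asarray(r.counts, dtype=np.int64)
    if not order:
        raise ValueError("no assigned OTUs to collapse")
    counts = pd.DataFrame.from_dict(order, orient="index", dtype=np.int64)
    counts.index.name = "taxon_id"
    counts.columns = table.sample_ids
    return CommunityMatrix(counts, table.samples, keep_empty=True)


def pool_replicates(matrix: CommunityMatrix) -> CommunityMatrix:
    """Sum technical replicates into one column per river section."""
    sections = matrix.sections
    cols = {}
    for sec in sections:
        ids = [s.sample_id for s in matrix.samples if s.section == sec]
        cols[sec] = matrix.counts[ids].sum(axis=1)
    pooled = pd.DataFrame(cols, dtype=np.int64)
    pooled.index.name = "taxon_id"
    samples = [SampleInfo(sec, sec, 1) for sec in sections]
    return CommunityMatrix(pooled, samples, keep_empty=matrix.keep_empty)


def rarefy(
    matrix: CommunityMatrix,
    depth: int | Literal["min"] = "min",
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> CommunityMatrix:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` uses the smallest sample total, so no sample is
    excluded. Draws are multivariate hypergeometric (each read equally
    likely, no replacement), hence every rarefied count is bounded by the
    original count and column totals equal ``depth`` exactly. A ``seed``
    (or an explicit generator) makes the draw reproducible.
    """
    totals = matrix.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    low = totals[totals < depth]
    if len(low):
        raise ValueError(
            f"depth {depth} exceeds total of sample(s) {low.index.tolist()}"
        )
    if rng is None:
        if seed is None:
            raise ValueError("rarefy needs a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)
    out = {}
    for sid in matrix.sample_ids:
        col = matrix.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    rare = pd.DataFrame(out, index=matrix.counts.index, dtype=np.int64)
    return CommunityMatrix(rare, matrix.samples, keep_empty=True)


def relative_abundance(matrix: CommunityMatrix) -> pd.DataFrame:
    """Read ratios: each column divided by its total (columns sum to 1)."""
    totals = matrix.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {zero.index.tolist()}")
    return matrix.counts / totals
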