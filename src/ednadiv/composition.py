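"""Guild composition, family composition and checklist comparison.

Summaries of what kind of community the survey detected: per-section
composition of the three ecological-guild axes (habitat water velocity,
water layer, egg type), either by number of species present or by
sequence abundance; species counts per family; dominance summaries with
the rheophilic (flowing-water guild) share; the fraction of OTUs shared
by every section; and detection metrics of the eDNA species list against
a historical checklist (detection rate, alien / indigenous / endemic
proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .alpha import DominanceRecord, mcnaughton
from .community import Checklist, CommunityMatrix, SampleInfo, TaxonRecord
from .otu import AnnotatedOtuTable

__all__ = [
    "GUILD_AXES",
    "guild_composition",
    "family_composition",
    "DetectionReport",
    "checklist_metrics",
    "shared_otu_fraction",
    "DominanceSummary",
    "dominance_summary",
]

GUILD_AXES = {
    "velocity": "velocity_guild",
    "layer": "layer_guild",
    "egg": "egg_guild",
}


def guild_composition(
    matrix: CommunityMatrix,
    records: Sequence[TaxonRecord],
    axis: Literal["velocity", "layer", "egg"],
    basis: Literal["species_count", "sequence_abundance"],
) -> pd.DataFrame:
    """Per-section guild proportions on one ecological axis.

    ``species_count`` counts each taxon present (nonzero) in a section
    once; ``sequence_abundance`` weights by reads. Returns a long-format
    frame (section, axis, basis, guild, proportion); proportions sum to
    1 within each section.
    """
    if axis not in GUILD_AXES:
        raise ValueError(f"axis must be one of {sorted(GUILD_AXES)}")
    if basis not in ("species_count", "sequence_abundance"):
        raise ValueError(f"unknown basis {basis!r}")
    attr = GUILD_AXES[axis]
    code_of: dict[str, str] = {}
    for r in records:
        code = getattr(r, attr)
        if not code:
            raise ValueError(f"taxon {r.taxon_id} has no {axis} guild code")
        code_of[r.taxon_id] = code
    missing = [t for t in matrix.taxon_ids if t not in code_of]
    if missing:
        raise ValueError(f"taxa without records: {missing[:5]}")

    rows = []
    codes = pd.Series({t: code_of[t] for t in matrix.taxon_ids})
    for sid in matrix.sample_ids:
        col = matrix.counts[sid]
        if basis == "species_count":
            weights = (col > 0).astype(float)
        else:
            weights = col.astype(float)
        total = weights.sum()
        if total == 0:
            raise ValueError(f"section {sid!r} has no detections")
        by_guild = weights.groupby(codes).sum() / total
        for guild, prop in by_guild.items():
            rows.append(
                {
                    "section": sid,
                    "axis": axis,
                    "basis": basis,
                    "guild": guild,
                    "proportion": float(prop),
                }
            )
    return pd.DataFrame(rows)


def family_composition(
    records: Sequence[TaxonRecord],
) -> dict[str, tuple[int, float]]:
    """Species count and proportion per family, largest first."""
    if not records:
        raise ValueError("no records")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.family] = counts.get(r.family, 0) + 1
    total = len(records)
    return {
        fam: (n, n / total)
        for fam, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


@dataclass(frozen=True)
class DetectionReport:
    """eDNA-vs-checklist detection metrics and status-flag proportions."""

    n_edna_species: int
    n_checklist_species: int
    n_shared: int
    detection_rate: float
    n_alien: int
    pct_alien: float
    n_indigenous: int
    pct_indigenous: float
    n_endemic: int
    pct_endemic: float
    family_composition: dict[str, tuple[int, float]] = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "family_composition"}
        d["family_composition"] = {
            f: {"count": c, "proportion": p}
            for f, (c, p) in self.family_composition.items()
        }
        return d


def checklist_metrics(
    records: Sequence[TaxonRecord], checklist: Checklist
) -> DetectionReport:
    """Compare the detected species list against a historical checklist.

    Shared species are matched by exact species name when the checklist
    carries entries, otherwise by the ``shared_historical`` flag. The
    detection rate is the detected richness over the checklist richness.
    Alien / indigenous / endemic tallies come from the status flags
    (indigenous = not alien).
    """
    n_edna = len(records)
    if n_edna == 0:
        raise ValueError("no detected species")
    if checklist.entries:
        names = checklist.species_names()
        n_shared = sum(1 for r in records if r.species in names)
    else:
        n_shared = sum(1 for r in records if "shared_historical" in r.flags)
    n_checklist = checklist.n_species
    n_alien = sum(1 for r in records if "alien" in r.flags)
    n_endemic = sum(1 for r in records if "endemic_upper_yangtze" in r.flags)
    n_indig = n_edna - n_alien
    return DetectionReport(
        n_edna_species=n_edna,
        n_checklist_species=n_checklist,
        n_shared=n_shared,
        detection_rate=n_edna / n_checklist,
        n_alien=n_alien,
        pct_alien=n_alien / n_edna,
        n_indigenous=n_indig,
        pct_indigenous=n_indig / n_edna,
        n_endemic=n_endemic,
        pct_endemic=n_endemic / n_edna,
        family_composition=family_composition(records),
    )


def shared_otu_fraction(
    otu_table: AnnotatedOtuTable,
    sections: Mapping[str, str] | None = None,
) -> tuple[int, float]:
    """OTUs detected in every section, as a count and fraction of all OTUs.

    ``sections`` optionally remaps sample id -> section; by default the
    section recorded in the table's sample metadata is used.
    """
    if len(otu_table) == 0:
        raise ValueError("empty OTU table")
    if sections is None:
        section_of = {s.sample_id: s.section for s in otu_table.samples}
    else:
        section_of = dict(sections)
    frame = otu_table.counts_frame()
    by_section = frame.T.groupby(
        [section_of[c] for c in frame.columns]
    ).sum().T
    everywhere = (by_section > 0).all(axis=1)
    n_shared = int(everywhere.sum())
    return n_shared, n_shared / len(otu_table)


@dataclass(frozen=True)
class DominanceSummary:
    """Dominant taxa of one scope with their rheophilic share."""

    scope: str
    dominant: list[str]  # taxon ids, most dominant first
    dominant_species: list[str]
    n_rheophilic: int
    rheophilic_share: float  # fraction of dominant taxa with velocity guild F


def _summarize(
    scope: str,
    records: Sequence[DominanceRecord],
    taxa_by_id: Mapping[str, TaxonRecord],
) -> DominanceSummary:
    doms = sorted(
        (r for r in records if r.dominant), key=lambda r: r.y, reverse=True
    )
    ids = [r.taxon_id for r in doms]
    n_f = sum(1 for t in ids if taxa_by_id[t].velocity_guild == "F")
    return DominanceSummary(
        scope=scope,
        dominant=ids,
        dominant_species=[taxa_by_id[t].species for t in ids],
        n_rheophilic=n_f,
        rheophilic_share=n_f / len(ids) if ids else 0.0,
    )


def dominance_summary(
    records: Sequence[DominanceRecord],
    taxa: Sequence[TaxonRecord],
    per: Literal["whole", "section"] = "whole",
    *,
    matrix: CommunityMatrix | None = None,
    threshold: float = 0.02,
) -> list[DominanceSummary]:
    """Dominant taxa with rheophilic share, whole-survey or per section.

    ``per="whole"`` summarizes the given records (computed over the full
    matrix). ``per="section"`` recomputes dominance within each section
    column of ``matrix`` (each section is its own scope, so f_i is the
    presence indicator there) and summarizes each.
    """
    taxa_by_id = {t.taxon_id: t for t in taxa}
    missing = {r.taxon_id for r in records} - set(taxa_by_id)
    if missing:
        raise ValueError(f"dominance records without taxa: {sorted(missing)[:5]}")
    if per == "whole":
        return [_summarize("whole", records, taxa_by_id)]
    if per != "section":
        raise ValueError("per must be 'whole' or 'section'")
    if matrix is None:
        raise ValueError("per='section' needs the community matrix")
    out = []
    for sid in matrix.sample_ids:
        sub = CommunityMatrix(
            matrix.counts[[sid]], [SampleInfo(sid, sid, 1)], keep_empty=True
        )
        out.append(_summarize(sid, mcnaughton(sub, threshold), taxa_by_id))
    return out
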