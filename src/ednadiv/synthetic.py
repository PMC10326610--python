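"""Synthetic eDNA survey data with known ground truth.

Generates the whole input stack the analysis consumes — an annotated OTU
table, taxon trait records, a historical checklist and the true
underlying community — so every pipeline stage can be tested without any
sequencing data. The default configuration mirrors the survey design the
package targets: 12 river sections with 3 technical replicates each,
per-replicate sequencing depth in the half-million-read range, a
log-normal species-abundance distribution modulated per section, species
split over 1..k OTUs, and a tunable fraction of OTU annotations built to
fail the retention thresholds.

Randomness is split into one child stream per logical component
(abundance, section effects, depth, OTU annotation, traits, checklist),
so changing one component's draws does not perturb the others and a
fixed config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .community import Checklist, SampleInfo, TaxonRecord
from .groups import GroupedValues
from .otu import AnnotatedOtuTable, OtuRow

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_null_groups",
    "planted_counts",
]

_DEF_VEL = {"F": 37 / 97, "E": 33 / 97, "S": 27 / 97}
_DEF_LAYER = {"B": 54 / 97, "D1": 24 / 97, "P1": 19 / 97}
_DEF_EGG = {"A": 47 / 97, "D2": 26 / 97, "D3": 10 / 97, "O": 9 / 97, "P2": 5 / 97}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the target survey design."""

    n_species: int = 97
    n_sections: int = 12
    n_replicates: int = 3
    depth_mean: int = 625_000  # reads per replicate sample
    depth_spread: int = 120_000  # depth ~ uniform(mean-spread, mean+spread)
    abundance_mu: float = 0.0  # log-normal species-abundance distribution
    abundance_sigma: float = 2.0
    section_sigma: float = 0.75  # per-(section, species) log-normal modulation
    max_otus_per_species: int = 3
    fail_fraction: float = 0.1  # extra OTUs built to fail retention thresholds
    alien_fraction: float = 12 / 97
    endemic_fraction: float = 13 / 97
    protected_fraction: float = 4 / 97
    detection_rate_target: float = 97 / 193  # detected / checklist species
    velocity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_VEL)
    )
    layer_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_LAYER)
    )
    egg_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_EGG))
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.n_sections < 1 or self.n_replicates < 1:
            raise ValueError("n_species, n_sections, n_replicates must be >= 1")
        if self.depth_mean - self.depth_spread < self.n_species:
            raise ValueError(
                "minimum depth smaller than species count: "
                "abundant species could not all be observed"
            )
        for name, probs in (
            ("velocity_probs", self.velocity_probs),
            ("layer_probs", self.layer_probs),
            ("egg_probs", self.egg_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name, frac in (
            ("alien_fraction", self.alien_fraction),
            ("fail_fraction", self.fail_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.detection_rate_target <= 1.0:
            raise ValueError("detection_rate_target must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    true_abundance: np.ndarray  # per-species relative abundance (base)
    section_effects: np.ndarray  # (species, sections) multipliers
    presence: dict[str, set[str]]  # section -> taxon ids with nonzero reads
    depths: dict[str, int]  # sample id -> drawn depth
    flags: dict[str, frozenset]  # taxon id -> status flags
    n_species_otus: int  # leading OTU rows drawn from true species
    seed: int

    def richness(self, section: str) -> int:
        return len(self.presence[section])


def _round_count(fraction: float, n: int) -> int:
    """Deterministic rounding rule: floor(fraction * n + 0.5)."""
    return int(np.floor(fraction * n + 0.5))


def generate_community(
    config: SyntheticConfig,
) -> tuple[AnnotatedOtuTable, list[TaxonRecord], Checklist, SyntheticTruth]:
    """Draw one synthetic survey dataset with its ground truth.

    Species abundances are log-normal, modulated per section by
    independent log-normal multipliers; each replicate draws a uniform
    depth and a multinomial read vector; each species' reads are split
    across 1..k OTUs with annotations passing the retention thresholds,
    plus a ``fail_fraction`` share of extra OTUs whose annotation
    (identity, E-value, target class or cluster size) is built to fail.
    The checklist holds all detected species plus enough absent ones to
    hit ``detection_rate_target``, with flags assigned so the two shared-
    species conventions (name match vs flag) agree.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (
        ss_abund, ss_sect, ss_depth, ss_otu, ss_trait, ss_check,
    ) = root.spawn(6)
    rng_abund = np.random.default_rng(ss_abund)
    rng_sect = np.random.default_rng(ss_sect)
    rng_depth = np.random.default_rng(ss_depth)
    rng_otu = np.random.default_rng(ss_otu)
    rng_trait = np.random.default_rng(ss_trait)
    rng_check = np.random.default_rng(ss_check)

    s, k = config.n_species, config.n_sections
    taxon_ids = [f"SP{i + 1:03d}" for i in range(s)]
    sections = [f"SEC{j + 1:02d}" for j in range(k)]
    samples = [
        SampleInfo(f"{sec}_r{r + 1}", sec, r + 1)
        for sec in sections
        for r in range(config.n_replicates)
    ]

    base = rng_abund.lognormal(config.abundance_mu, config.abundance_sigma, s)
    effects = rng_sect.lognormal(0.0, config.section_sigma, (s, k))
    probs = base[:, None] * effects
    probs = probs / probs.sum(axis=0)

    depths = {
        smp.sample_id: int(
            rng_depth.integers(
                config.depth_mean - config.depth_spread,
                config.depth_mean + config.depth_spread + 1,
            )
        )
        for smp in samples
    }
    counts = np.zeros((s, len(samples)), dtype=np.int64)
    for idx, smp in enumerate(samples):
        j = sections.index(smp.section)
        counts[:, idx] = rng_depth.multinomial(depths[smp.sample_id], probs[:, j])

    # ---- species -> OTUs with annotations -------------------------------
    rows: list[OtuRow] = []
    otu_no = 0
    for i, tid in enumerate(taxon_ids):
        m = int(rng_otu.integers(1, config.max_otus_per_species + 1))
        weights = rng_otu.dirichlet(np.ones(m))
        split = np.zeros((m, len(samples)), dtype=np.int64)
        for idx in range(len(samples)):
            split[:, idx] = rng_otu.multinomial(counts[i, idx], weights)
        for row in split:
            otu_no += 1
            rows.append(
                OtuRow(
                    otu_id=f"OTU{otu_no:05d}",
                    counts=tuple(int(c) for c in row),
                    best_hit_taxon=tid,
                    identity=float(rng_otu.uniform(0.97, 1.0)),
                    evalue=float(10.0 ** rng_otu.uniform(-30, -6)),
                    is_target_class=True,
                )
            )
    n_species_otus = len(rows)
    n_fail = _round_count(config.fail_fraction, len(rows))
    for _ in range(n_fail):
        otu_no += 1
        mode = rng_otu.integers(4)
        identity = float(rng_otu.uniform(0.97, 1.0))
        evalue = float(10.0 ** rng_otu.uniform(-30, -6))
        target = True
        total = int(rng_otu.integers(20, 2000))
        if mode == 0:
            identity = float(rng_otu.uniform(0.80, 0.969))
        elif mode == 1:
            evalue = float(10.0 ** rng_otu.uniform(-4.9, -1))
        elif mode == 2:
            target = False
        else:
            total = int(rng_otu.integers(1, 11))  # cluster of 10 or fewer
        spread = rng_otu.multinomial(total, np.ones(len(samples)) / len(samples))
        rows.append(
            OtuRow(
                otu_id=f"OTU{otu_no:05d}",
                counts=tuple(int(c) for c in spread),
                best_hit_taxon=taxon_ids[int(rng_otu.integers(s))],
                identity=identity,
                evalue=evalue,
                is_target_class=target,
            )
        )
    table = AnnotatedOtuTable(rows, samples)

    # ---- trait records and flags ----------------------------------------
    def _codes(probs_map: Mapping[str, float], n: int) -> list[str]:
        labels = list(probs_map)
        return list(
            rng_trait.choice(labels, size=n, p=[probs_map[l] for l in labels])
        )

    vel = _codes(config.velocity_probs, s)
    lay = _codes(config.layer_probs, s)
    egg = _codes(config.egg_probs, s)
    n_alien = _round_count(config.alien_fraction, s)
    alien_idx = set(rng_trait.choice(s, size=n_alien, replace=False).tolist())
    indigenous = [i for i in range(s) if i not in alien_idx]
    n_endemic = min(_round_count(config.endemic_fraction, s), len(indigenous))
    endemic_idx = set(
        rng_trait.choice(indigenous, size=n_endemic, replace=False).tolist()
    )
    n_prot = min(_round_count(config.protected_fraction, s), len(indigenous))
    prot_idx = set(
        rng_trait.choice(indigenous, size=n_prot, replace=False).tolist()
    )

    n_checklist = max(s, int(round(s / config.detection_rate_target)))
    # shared-with-history = indigenous detected species (aliens absent
    # from the historical list), so flag and name-match conventions agree
    flags: dict[str, frozenset] = {}
    records = []
    for i, tid in enumerate(taxon_ids):
        fl = set()
        if i in alien_idx:
            fl.add("alien")
        else:
            fl.add("shared_historical")
        if i in endemic_idx:
            fl.add("endemic_upper_yangtze")
        if i in prot_idx:
            fl.add("protected")
        flags[tid] = frozenset(fl)
        records.append(
            TaxonRecord(
                taxon_id=tid,
                order=f"Order{i % 5 + 1}",
                family=f"Family{i % 12 + 1}",
                genus=f"Genus{i + 1}",
                species=f"Species {i + 1}",
                velocity_guild=vel[i],
                layer_guild=lay[i],
                egg_guild=egg[i],
                flags=flags[tid],
            )
        )

    entries = [
        (r.species, r.genus, r.family, r.order)
        for r in records
        if "shared_historical" in r.flags
    ]
    n_extra = n_checklist - len(records) + sum(
        1 for r in records if "alien" in r.flags
    )
    for j in range(n_extra):
        entries.append(
            (
                f"Historical species {j + 1}",
                f"Genus{s + j + 1}",
                f"Family{int(rng_check.integers(1, 13))}",
                f"Order{int(rng_check.integers(1, 6))}",
            )
        )
    checklist = Checklist(entries=entries)

    by_section = {
        sec: {
            taxon_ids[i]
            for i in range(s)
            if counts[
                :, [idx for idx, smp in enumerate(samples) if smp.section == sec]
            ][i].sum()
            > 0
        }
        for sec in sections
    }
    truth = SyntheticTruth(
        true_abundance=base / base.sum(),
        section_effects=effects,
        presence=by_section,
        depths=depths,
        flags=flags,
        n_species_otus=n_species_otus,
        seed=config.seed,
    )
    return table, records, checklist, truth


def generate_null_groups(
    n_groups: int,
    n_per_group: int,
    distribution: str = "normal",
    seed: int = 0,
    *,
    shift: Mapping[str, float] | None = None,
) -> GroupedValues:
    """I.i.d. grouped draws for calibration studies.

    ``distribution`` is ``normal`` (mean 0, sd 1), ``lognormal`` or
    ``uniform``; ``shift`` adds a constant to named groups to create a
    planted effect.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    obs = []
    for g in range(n_groups):
        label = f"G{g + 1:02d}"
        if distribution == "normal":
            vals = rng.normal(0.0, 1.0, n_per_group)
        elif distribution == "lognormal":
            vals = rng.lognormal(0.0, 1.0, n_per_group)
        elif distribution == "uniform":
            vals = rng.uniform(0.0, 1.0, n_per_group)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        if shift and label in shift:
            vals = vals + shift[label]
        obs.extend((label, float(v)) for v in vals)
    return GroupedValues(obs)


def planted_counts(
    s_core: int,
    n1: int,
    n2: int,
    depth: int,
    seed: int = 0,
) -> np.ndarray:
    """A count vector with exactly ``n1`` singletons and ``n2`` doubletons.

    The remaining ``depth - n1 - 2*n2`` reads are spread over ``s_core``
    abundant species, each guaranteed at least 3 reads, so the singleton
    and doubleton tallies are exactly as planted.
    """
    rest = depth - n1 - 2 * n2
    if s_core < 1 or rest < 3 * s_core:
        raise ValueError("depth too small for the requested composition")
    rng = np.random.default_rng(seed)
    core = rng.multinomial(rest - 3 * s_core, np.ones(s_core) / s_core) + 3
    return np.concatenate(
        [core, np.ones(n1, dtype=np.int64), np.full(n2, 2, dtype=np.int64)]
    )
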