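"""Alpha-diversity estimators and McNaughton dominance screening.

All estimators operate on a vector of integer sequence counts, one entry
per taxon, for a single sample:

* Chao1 richness (bias-corrected): ``S_obs + n1*(n1-1) / (2*(n2+1))``,
  where ``n1``/``n2`` are the singleton/doubleton taxon counts. Finite
  even with no doubletons; the classic ``n1**2/(2*n2)`` form is available
  behind a flag.
* Shannon entropy ``H = -sum p_i ln p_i`` (natural log by default; the
  base is an option and cancels out of Pielou evenness).
* Finite-sample Simpson concentration
  ``D = sum n_i (n_i - 1) / (N (N - 1))`` — the probability that two
  reads drawn without replacement belong to the same taxon; higher values
  mean lower diversity. A probability form ``sum p_i**2`` is provided for
  proportion inputs; the two are not identical at finite N.
* Pielou evenness ``J = H / ln S_obs``, defined only for S_obs >= 2.
* Good's coverage ``C = 1 - n1/N``, the estimated fraction of reads from
  already-observed taxa.

Community-level dominance uses the McNaughton index
``Y_i = (n_i / N) * f_i`` with ``n_i`` the taxon's total count over all
samples, ``N`` the grand total and ``f_i`` the fraction of samples where
the taxon occurs; taxa with ``Y_i`` strictly above 0.02 are flagged
dominant (extremely high relative sequence abundance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix

__all__ = [
    "AlphaIndices",
    "DominanceRecord",
    "chao1",
    "shannon",
    "simpson",
    "simpson_probability",
    "pielou",
    "goods_coverage",
    "alpha_table",
    "alpha_frame",
    "mcnaughton",
    "dominant_taxa",
]


def _counts_array(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if arr.sum() == 0:
        raise ValueError("all-zero count vector")
    return arr


def chao1(counts: Sequence[int], *, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts."""
    arr = _counts_array(counts)
    s_obs = int((arr > 0).sum())
    n1 = int((arr == 1).sum())
    n2 = int((arr == 2).sum())
    if bias_corrected:
        return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with no doubletons")
    return s_obs + n1 * n1 / (2.0 * n2)


def shannon(counts: Sequence[int], *, base: float | None = None) -> float:
    """Shannon diversity H; natural log unless ``base`` is given."""
    arr = _counts_array(counts)
    p = arr[arr > 0] / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(counts: Sequence[int]) -> float:
    """Finite-sample Simpson concentration on integer counts."""
    arr = _counts_array(counts)
    n = int(arr.sum())
    if n < 2:
        raise ValueError("Simpson needs at least 2 sequences")
    return float((arr * (arr - 1)).sum() / (n * (n - 1)))


def simpson_probability(proportions: Sequence[float]) -> float:
    """Probability form sum(p_i^2) for proportion inputs."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    tot = p.sum()
    if tot <= 0:
        raise ValueError("proportions sum to zero")
    p = p / tot
    return float((p**2).sum())


def pielou(counts: Sequence[int], *, base: float | None = None) -> float:
    """Evenness J = H / H_max; 1 iff all positive counts are equal."""
    arr = _counts_array(counts)
    s_obs = int((arr > 0).sum())
    if s_obs < 2:
        raise ValueError("Pielou undefined for fewer than 2 observed taxa")
    # the log base cancels in the ratio
    return shannon(arr, base=base) / (
        math.log(s_obs) / (math.log(base) if base is not None else 1.0)
    )


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage C = 1 - n1/N."""
    arr = _counts_array(counts)
    n1 = int((arr == 1).sum())
    return 1.0 - n1 / int(arr.sum())


@dataclass(frozen=True)
class AlphaIndices:
    """All per-sample alpha indices plus the raw summaries they use."""

    sample_id: str
    s_obs: int
    n1: int
    n2: int
    n_total: int
    chao1: float
    shannon: float
    h_max: float
    simpson: float
    pielou: float  # nan when S_obs < 2 (H_max = 0)
    coverage: float


def alpha_table(
    matrix: CommunityMatrix, *, base: float | None = None
) -> list[AlphaIndices]:
    """Per-sample alpha indices for every column of the matrix.

    Pielou evenness is reported as ``nan`` for samples with a single
    observed taxon (its denominator is zero there); errors from genuinely
    invalid samples are re-raised annotated with the sample id.
    """
    out = []
    for sid in matrix.sample_ids:
        arr = matrix.sample(sid)
        try:
            s_obs = int((arr > 0).sum())
            h = shannon(arr, base=base)
            h_max = math.log(s_obs) / (math.log(base) if base else 1.0)
            rec = AlphaIndices(
                sample_id=sid,
                s_obs=s_obs,
                n1=int((arr == 1).sum()),
                n2=int((arr == 2).sum()),
                n_total=int(arr.sum()),
                chao1=chao1(arr),
                shannon=h,
                h_max=h_max,
                simpson=simpson(arr),
                pielou=h / h_max if s_obs >= 2 else float("nan"),
                coverage=goods_coverage(arr),
            )
        except ValueError as err:
            raise ValueError(f"sample {sid!r}: {err}") from err
        out.append(rec)
    return out


def alpha_frame(matrix: CommunityMatrix, *, base: float | None = None) -> pd.DataFrame:
    """:func:`alpha_table` as a DataFrame indexed by sample id."""
    recs = alpha_table(matrix, base=base)
    return pd.DataFrame([r.__dict__ for r in recs]).set_index("sample_id")


@dataclass(frozen=True)
class DominanceRecord:
    """McNaughton dominance terms for one taxon over a set of samples."""

    taxon_id: str
    n_i: int
    n_total: int
    f_i: float
    y: float
    dominant: bool


def mcnaughton(
    matrix: CommunityMatrix, threshold: float = 0.02
) -> list[DominanceRecord]:
    """McNaughton dominance Y_i = (n_i/N) * f_i for every taxon.

    ``f_i`` is the occurrence frequency over the matrix columns (for the
    bundled survey: the fraction of the 12 pooled sections where the
    taxon was detected). The dominance call is strict: Y > threshold.
    """
    grand = matrix.grand_total()
    if grand <= 0:
        raise ValueError("grand total must be positive")
    n_samples = len(matrix.samples)
    out = []
    for tid in matrix.taxon_ids:
        row = matrix.counts.loc[tid].to_numpy()
        n_i = int(row.sum())
        f_i = float((row > 0).sum() / n_samples)
        y = (n_i / grand) * f_i
        out.append(
            DominanceRecord(
                taxon_id=tid,
                n_i=n_i,
                n_total=grand,
                f_i=f_i,
                y=y,
                dominant=y > threshold,
            )
        )
    return out


def dominant_taxa(records: Sequence[DominanceRecord]) -> list[str]:
    """Ids of dominant taxa, most dominant first."""
    return [
        r.taxon_id
        for r in sorted(records, key=lambda r: r.y, reverse=True)
        if r.dominant
    ]
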