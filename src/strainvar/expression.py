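"""Expression (FPKM) and exon-usage (PSI) computation with rank-based
comparison of high-impact gene/exon sets against a random background.

FPKM normalizes unique read counts by feature length and library size:
``fpkm = count * 1e9 / (length_nt * library_size)``.

PSI (percent spliced in) estimates the fraction of transcripts that include
an exon from reads mapping into the exon (inclusion) versus junction reads
jumping over it (exclusion).  Inclusion counts are normalized by the number
of read start positions overlapping the exon (``exon_length + read_length -
1``) so they are comparable to single-position junction counts:
``psi = inc_norm / (inc_norm + exclusion)``.  An exon with no reads at all
is assigned PSI 0 (unused exon); exclusion 0 with any inclusion gives PSI 1
(constitutive exon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountTable:
    """Uniquely-assigned read counts for genes or exons across tissues.

    ``counts`` is a features x tissues DataFrame; ``lengths`` a per-feature
    Series in nt.  Library sizes default to column sums.
    """

    unit: str  # "gene" or "exon"
    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("gene", "exon"):
            raise ValueError("unit must be 'gene' or 'exon'")
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every feature needs a positive length")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str = "gene") -> "CountTable":
        """Read a TSV with columns: feature, length, then one per tissue."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "length" not in df.columns:
            raise ValueError(f"{path}: expected a 'length' column")
        lengths = df.pop("length")
        return cls(unit=unit, counts=df, lengths=lengths)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature")


def compute_fpkm(t: CountTable) -> pd.DataFrame:
    """Gene x tissue FPKM matrix: count * 1e9 / (length * library_size)."""
    if t.unit != "gene":
        raise ValueError("FPKM is defined on gene-level counts")
    lib = t.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    lengths = t.lengths.to_numpy(dtype=float)[:, None]
    return pd.DataFrame(
        t.counts.to_numpy(dtype=float) * 1e9 / (lengths * lib[None, :]),
        index=t.counts.index,
        columns=t.counts.columns,
    )


def compute_psi(
    inclusion: float, exclusion: float, exon_length: int, read_length: int
) -> float:
    """PSI for one exon in one tissue; see module docstring for the model."""
    if exon_length <= 0 or read_length <= 0:
        raise ValueError("exon_length and read_length must be positive")
    if inclusion < 0 or exclusion < 0:
        raise ValueError("read counts must be non-negative")
    if inclusion == 0 and exclusion == 0:
        return 0.0
    inc_norm = inclusion * read_length / (exon_length + read_length - 1)
    return inc_norm / (inc_norm + exclusion)


@dataclass(frozen=True)
class ExonUsage:
    exon_id: str
    tissue: str
    inclusion_reads: int
    exclusion_reads: int
    psi: float


def psi_table(
    exon_counts: pd.DataFrame, read_length: int
) -> pd.DataFrame:
    """PSI per (exon, tissue) from a long table with columns
    exon, tissue, length, inclusion, exclusion."""
    required = {"exon", "tissue", "length", "inclusion", "exclusion"}
    if not required <= set(exon_counts.columns):
        raise ValueError(f"exon table needs columns {sorted(required)}")
    out = exon_counts.copy()
    out["psi"] = [
        compute_psi(r.inclusion, r.exclusion, r.length, read_length)
        for r in out.itertuples()
    ]
    return out


@dataclass(frozen=True)
class RankCompareResult:
    statistic: float
    pvalue: float
    group_mean: float
    group_sem: float
    background_mean: float
    background_sem: float


def rank_compare(
    group_values: Sequence[float],
    background_values: Sequence[float],
    *,
    alternative: str = "two-sided",
) -> RankCompareResult:
    """Nonparametric comparison of a feature set against background.

    Two groups are compared with the Wilcoxon rank-sum (Mann-Whitney U)
    test: exact p for small tie-free samples, normal approximation with tie
    correction otherwise.  Means +/- SEM are reported alongside, matching
    the usual bar-plot presentation.
    """
    g = np.asarray(group_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if g.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([g, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; comparison is degenerate", stacklevel=2)
        stat, p = float(g.size * b.size / 2), 1.0
    else:
        method = "exact" if (g.size <= 20 and b.size <= 20) else "asymptotic"
        res = stats.mannwhitneyu(g, b, alternative=alternative, method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return RankCompareResult(
        statistic=stat,
        pvalue=p,
        group_mean=float(g.mean()),
        group_sem=float(stats.sem(g)) if g.size > 1 else 0.0,
        background_mean=float(b.mean()),
        background_sem=float(stats.sem(b)) if b.size > 1 else 0.0,
    )


def rank_compare_k(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis comparison for more than two groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    stat, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(stat), float(p)


def expressed_genes(
    fpkm: pd.DataFrame, threshold: float = 1.0
) -> pd.Index:
    """Genes whose mean FPKM across tissues reaches the threshold."""
    return fpkm.index[fpkm.mean(axis=1) >= threshold]


def sample_background_exons(
    all_exons: Sequence[str], n: int, seed: int
) -> list[str]:
    """Uniform background sample of exon ids, without replacement.

    The caller restricts ``all_exons`` to exons of expressed genes first.
    If fewer than ``n`` exons are available the whole population is
    returned with a warning.
    """
    exons = list(all_exons)
    if n >= len(exons):
        if n > len(exons):
            warnings.warn(
                f"requested {n} background exons but only {len(exons)} "
                f"available; using all",
                stacklevel=2,
            )
        return exons
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(exons), size=n, replace=False)
    return [exons[i] for i in sorted(idx)]
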