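"""Cross-species SNV-density windows and per-window ancestry assignment.

Two window concepts live here.  *Syntenic windows* compare nucleotide
diversity between species on a common coordinate frame: each window starts
every ``window_step_bp`` and extends until it contains
``syntenic_window_bp`` of that species' syntenic sequence; per-species SNV
counts are z-scored across windows so species with very different overall
diversity become comparable.  *Count windows* chop the genome into segments
of a fixed number of SNVs (20,000 by default) for the cluster-mosaic
analysis: within each segment a strain's 0/1 genotype vector is compared by
Spearman correlation against the average genotype profile of each ancestral
cluster, and the best-correlated cluster is assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Genotype, GenotypeMatrix, PipelineConfig, VariantSite


# ---------------------------------------------------------------------------
# Syntenic sliding-window SNV density
# ---------------------------------------------------------------------------

def _species_chrom_windows(
    blocks: np.ndarray,  # (n, 2) sorted [start, end], 1-based inclusive
    positions: np.ndarray,  # sorted SNV positions of this species on the frame
    starts: np.ndarray,
    window_bp: int,
) -> list[tuple[int, int, int, int] | None]:
    """For each window start: (start, end, syntenic_nt, snv_count) or None
    when the chromosome runs out of syntenic sequence."""
    s, e = blocks[:, 0], blocks[:, 1]
    lens = e - s + 1
    cum = np.concatenate([[0], np.cumsum(lens)])  # syntenic nt before block i

    def syntenic_upto(pos: int) -> int:
        """Syntenic nt in [1, pos]."""
        i = np.searchsorted(s, pos, side="right")  # blocks starting <= pos
        total = cum[i]
        if i > 0 and e[i - 1] > pos:
            total -= e[i - 1] - pos
        return int(total)

    total_syntenic = int(cum[-1])
    out: list[tuple[int, int, int, int] | None] = []
    for w_start in starts:
        before = syntenic_upto(int(w_start) - 1)
        if total_syntenic - before < window_bp:
            out.append(None)
            continue
        target = before + window_bp
        # smallest genomic pos with syntenic_upto(pos) == target
        i = int(np.searchsorted(cum, target, side="left"))  # first block idx+1
        w_end = int(s[i - 1] + (target - cum[i - 1]) - 1)
        in_window = positions[
            (positions >= w_start) & (positions <= w_end)
        ]
        # count only SNVs inside syntenic blocks
        idx = np.searchsorted(s, in_window, side="right") - 1
        inside = (idx >= 0) & (in_window <= e[np.clip(idx, 0, len(e) - 1)])
        out.append((int(w_start), w_end, window_bp, int(inside.sum())))
    return out


def window_snv_density(
    sites_by_species: Mapping[str, Sequence[VariantSite]],
    synteny_map: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Sliding-window SNV density per species with per-species z-scores.

    ``synteny_map`` columns: species, chrom, start, end (1-based inclusive
    blocks on the common frame).  Returns a tidy frame with one row per
    (species, chrom, window start): end, syntenic_nt, snv_count and z.
    Windows where a species runs out of syntenic sequence are omitted for
    that species.
    """
    cfg = cfg or PipelineConfig()
    required = {"species", "chrom", "start", "end"}
    if not required <= set(synteny_map.columns):
        raise ValueError(f"synteny map needs columns {sorted(required)}")

    rows = []
    for (species, chrom), grp in synteny_map.groupby(["species", "chrom"]):
        blocks = np.asarray(sorted(zip(grp["start"], grp["end"])), dtype=np.int64)
        positions = np.asarray(
            sorted(
                site.pos
                for site in sites_by_species.get(species, [])
                if site.chrom == chrom
            ),
            dtype=np.int64,
        )
        chrom_end = int(blocks[:, 1].max())
        starts = np.arange(1, chrom_end + 1, cfg.window_step_bp, dtype=np.int64)
        for win in _species_chrom_windows(
            blocks, positions, starts, cfg.syntenic_window_bp
        ):
            if win is None:
                continue
            w_start, w_end, nt, count = win
            rows.append((species, chrom, w_start, w_end, nt, count))
    df = pd.DataFrame(
        rows, columns=["species", "chrom", "start", "end", "syntenic_nt", "snv_count"]
    )
    if df.empty:
        df["z"] = []
        return df

    def zscore(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        if sd == 0:
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / sd

    df["z"] = df.groupby("species")["snv_count"].transform(zscore)
    return df


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: value at rank ceil(pct/100 * n)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    rank = max(1, int(np.ceil(pct / 100.0 * v.size)))
    return float(v[rank - 1])


def shared_extreme_loci(
    windows: pd.DataFrame,
    tail: str = "low",
    cfg: PipelineConfig | None = None,
) -> list[tuple[str, int, int]]:
    """Loci where *every* species sits in its own extreme density tail.

    A window is kept when each species' z is within that species' lower
    (``tail='low'``) or upper (``tail='high'``) ``extreme_percentile`` tail;
    windows missing any species are excluded.  Kept windows overlapping or
    sharing a boundary are merged into loci ``(chrom, start, end)``.
    """
    cfg = cfg or PipelineConfig()
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    species = sorted(windows["species"].unique())
    if len(species) < 2:
        raise ValueError("need windows from at least two species")

    thresholds = {}
    for sp in species:
        z = windows.loc[windows["species"] == sp, "z"].to_numpy()
        pct = (
            cfg.extreme_percentile if tail == "low" else 100 - cfg.extreme_percentile
        )
        thresholds[sp] = nearest_rank_percentile(z, pct)

    wide = windows.pivot_table(
        index=["chrom", "start"], columns="species", values="z", aggfunc="first"
    ).dropna()  # windows present in all species only
    ends = windows.groupby(["chrom", "start"])["end"].max()

    kept = []
    for (chrom, start), row in wide.iterrows():
        ok = all(
            (row[sp] <= thresholds[sp]) if tail == "low" else (row[sp] >= thresholds[sp])
            for sp in species
        )
        if ok:
            kept.append((chrom, int(start), int(ends.loc[(chrom, start)])))

    kept.sort()
    loci: list[tuple[str, int, int]] = []
    for chrom, s, e in kept:
        if loci and loci[-1][0] == chrom and s <= loci[-1][2] + 1:
            loci[-1] = (chrom, loci[-1][1], max(loci[-1][2], e))
        else:
            loci.append((chrom, s, e))
    return loci


def genes_in_loci(
    loci: Sequence[tuple[str, int, int]], models: Iterable
) -> list[str]:
    """Gene ids whose transcript span intersects any locus."""
    out = []
    for m in models:
        if any(c == m.chrom and m.start <= e and s <= m.end for c, s, e in loci):
            out.append(m.gene_id)
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Fixed-SNV-count windows and cluster-mosaic assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountWindow:
    """Consecutive block of site indices on one chromosome."""

    index: int
    chrom: str
    first: int  # global index of first site (inclusive)
    last: int  # global index of last site (inclusive)
    start_pos: int
    end_pos: int

    @property
    def site_indices(self) -> range:
        return range(self.first, self.last + 1)

    @property
    def n_sites(self) -> int:
        return self.last - self.first + 1


def windowize_by_count(
    sites: Sequence[VariantSite], n: int
) -> list[CountWindow]:
    """Split sorted sites into consecutive windows of ``n`` sites.

    Windows never span chromosomes; the last window of each chromosome may
    hold fewer than ``n`` sites.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if list(sites) != sorted(sites):
        raise ValueError("sites must be sorted")
    out: list[CountWindow] = []
    i = 0
    while i < len(sites):
        chrom = sites[i].chrom
        j = i
        while j < len(sites) and sites[j].chrom == chrom and j - i < n:
            j += 1
        out.append(
            CountWindow(
                index=len(out),
                chrom=chrom,
                first=i,
                last=j - 1,
                start_pos=sites[i].pos,
                end_pos=sites[j - 1].pos,
            )
        )
        i = j
    return out


@dataclass(frozen=True)
class StrainAssignment:
    cluster: str | None
    coefficient: float
    tie: bool = False
    withheld_reason: str | None = None

    @property
    def withheld(self) -> bool:
        return self.cluster is None


@dataclass(frozen=True)
class WindowAssignment:
    window: CountWindow
    assignments: Mapping[str, StrainAssignment]


MIN_INFORMATIVE_SITES = 10


def cluster_profiles(
    m: GenotypeMatrix,
    site_index: Sequence[int],
    memberships: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Per-cluster mean genotype (fraction ALT-homozygous members) per site.

    Missing calls are excluded from the mean; an all-missing site yields NaN
    for that cluster.
    """
    clusters: dict[str, list[int]] = {}
    for strain, cl in memberships.items():
        clusters.setdefault(cl, []).append(m.sample_index(strain))
    calls = m.calls[:, list(site_index)].astype(float)
    calls[m.calls[:, list(site_index)] == Genotype.MISSING] = np.nan
    calls[calls == Genotype.HET] = np.nan  # hom-only analysis
    calls = calls / 2.0  # REF_HOM -> 0, ALT_HOM -> 1
    profiles = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        for cl, idx in clusters.items():
            profiles[cl] = np.nanmean(calls[idx, :], axis=0)
    return profiles


def assign_window_clusters(
    m: GenotypeMatrix,
    window: CountWindow,
    memberships: Mapping[str, str],
    target_strains: Sequence[str],
) -> WindowAssignment:
    """Assign each target strain's window genotypes to the best cluster.

    Spearman rank correlation (midrank ties) between the strain's 0/1 vector
    and each cluster's mean profile; missing calls excluded pairwise.  Best
    cluster maximizes the coefficient; exact ties go to the lexicographically
    first cluster with a tie flag.  Assignment is withheld when fewer than
    ``MIN_INFORMATIVE_SITES`` informative sites remain or every correlation
    is undefined (constant vectors).
    """
    if len(set(memberships.values())) < 2:
        raise ValueError("memberships must cover at least two clusters")
    idx = list(window.site_indices)
    profiles = cluster_profiles(m, idx, memberships)

    out: dict[str, StrainAssignment] = {}
    for strain in target_strains:
        row = m.calls[m.sample_index(strain), idx].astype(float)
        row[row == Genotype.MISSING] = np.nan
        row[row == Genotype.HET] = np.nan
        row = row / 2.0
        called = ~np.isnan(row)
        if called.sum() < MIN_INFORMATIVE_SITES:
            out[strain] = StrainAssignment(None, np.nan, False, "too_few_sites")
            continue
        best: tuple[float, str] | None = None
        tie = False
        for cl in sorted(profiles):
            mask = called & ~np.isnan(profiles[cl])
            if mask.sum() < MIN_INFORMATIVE_SITES:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                rho = stats.spearmanr(row[mask], profiles[cl][mask]).statistic
            if np.isnan(rho):
                continue
            if best is None or rho > best[0]:
                best = (float(rho), cl)
                tie = False
            elif rho == best[0]:
                tie = True
        if best is None:
            out[strain] = StrainAssignment(None, np.nan, False, "undefined_correlation")
        else:
            out[strain] = StrainAssignment(best[1], best[0], tie)
    return WindowAssignment(window=window, assignments=out)


def mosaic_table(
    m: GenotypeMatrix,
    memberships: Mapping[str, str],
    target_strains: Sequence[str],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-window best-cluster calls for all target strains, as a tidy frame."""
    cfg = cfg or PipelineConfig()
    windows = windowize_by_count(m.sites, cfg.snvs_per_window)
    rows = []
    for w in windows:
        wa = assign_window_clusters(m, w, memberships, target_strains)
        for strain, a in wa.assignments.items():
            rows.append(
                (
                    w.index,
                    w.chrom,
                    w.start_pos,
                    w.end_pos,
                    strain,
                    a.cluster,
                    a.coefficient,
                    a.tie,
                    a.withheld_reason,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "window",
            "chrom",
            "start",
            "end",
            "strain",
            "cluster",
            "rho",
            "tie",
            "withheld",
        ],
    )
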