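"""Substrain-variant discovery and characterization.

Substrains are colonies split from a common parent inbred strain; variants
that differ between them arose after separation, by genetic drift (de novo
mutations fixing in a small closed colony) or by introgression of a segment
from another strain.  This module finds sites that are variable among the
substrains of each strain group, tracks their genome-wide spacing (dense
runs betray introgressed segments), compares their mutational spectrum
(pyrimidine-collapsed, with the C>T class split by CpG context) against a
control SNV set, and contrasts conservation and nonsyn/syn pressure between
substrain and control variants.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import consequence
from .consequence import GeneModel, fetch
from .variant_io import Genotype, GenotypeMatrix, StrainGroupTable, VariantSite


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

@dataclass
class SubstrainVariantSet:
    """Sites variable between the substrains of one strain group."""

    group: str
    sites: list[VariantSite]
    genotypes: np.ndarray  # members x sites, Genotype codes
    members: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def find_substrain_variants(
    m: GenotypeMatrix, groups: StrainGroupTable | Mapping[str, Sequence[str]]
) -> dict[str, SubstrainVariantSet]:
    """Per group, sites where the substrains disagree.

    Requires a homozygous-only matrix.  A site enters a group's set iff all
    members are called (no MISSING) and at least two distinct genotypes
    occur among them; groups are handled independently.
    """
    if (m.calls == Genotype.HET).any():
        raise ValueError("matrix contains heterozygous calls; partition first")
    out: dict[str, SubstrainVariantSet] = {}
    for group, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {group!r} has fewer than two members")
        idx = [m.sample_index(s) for s in members]
        sub = m.calls[idx, :]
        complete = ~(sub == Genotype.MISSING).any(axis=0)
        variable = (sub != sub[0, :]).any(axis=0)
        keep = np.flatnonzero(complete & variable)
        out[group] = SubstrainVariantSet(
            group=group,
            sites=[m.sites[j] for j in keep],
            genotypes=sub[:, keep],
            members=list(members),
        )
    return out


def group_report(sets: Mapping[str, SubstrainVariantSet | int]) -> pd.DataFrame:
    """Per-group substrain SNV counts with a Total row.

    Accepts either discovered variant sets or plain per-group counts.
    """
    counts = {
        g: (v if isinstance(v, int) else v.n_sites) for g, v in sets.items()
    }
    df = pd.DataFrame(
        {"group": list(counts) + ["Total"],
         "substrain_snvs": list(counts.values()) + [sum(counts.values())]}
    )
    return df


def control_variant_set(
    m: GenotypeMatrix, substrain_sets: Mapping[str, SubstrainVariantSet]
) -> list[VariantSite]:
    """Control comparison set: all sites minus those shared by every sample
    minus all substrain-variable sites."""
    shared = (m.calls == Genotype.ALT_HOM).all(axis=0)
    substrain_sites = {s for v in substrain_sets.values() for s in v.sites}
    return [
        site
        for j, site in enumerate(m.sites)
        if not shared[j] and site not in substrain_sites
    ]


# ---------------------------------------------------------------------------
# Genomic spacing
# ---------------------------------------------------------------------------

def consecutive_distances(
    sites: Sequence[VariantSite],
) -> dict[str, np.ndarray]:
    """Distances between consecutive sites, per chromosome.

    A chromosome with a single site yields an empty array; across all
    chromosomes the number of distances is n_sites - n_chromosomes.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    out = {}
    for chrom, pos in by_chrom.items():
        if sorted(pos) != pos:
            raise ValueError(f"positions on {chrom} not sorted")
        out[chrom] = np.diff(np.asarray(pos, dtype=np.int64))
    return out


def distance_table(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Tidy (chrom, pos, distance_to_previous) table for spacing plots."""
    rows = []
    for chrom, d in consecutive_distances(sites).items():
        pos = [s.pos for s in sites if s.chrom == chrom]
        for p, dist in zip(pos[1:], d):
            rows.append((chrom, p, int(dist)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance"])


# ---------------------------------------------------------------------------
# Mutational spectrum
# ---------------------------------------------------------------------------

class SpectrumClass(str, enum.Enum):
    C_A = "C>A"
    C_G = "C>G"
    C_T_CpG = "C>T_CpG"
    C_T_nonCpG = "C>T_nonCpG"
    T_A = "T>A"
    T_C = "T>C"
    T_G = "T>G"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SpectrumCounts:
    """Pyrimidine-collapsed substitution-class counts with the C>T class
    split by CpG context."""

    counts: Mapping[SpectrumClass, int]

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in SpectrumClass}
        if any(v < 0 for v in full.values()):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, c: SpectrumClass) -> int:
        return self.counts[c]


def classify_substitution(
    site: VariantSite, ref
) -> SpectrumClass:
    """Spectrum class of one SNV, collapsed to the pyrimidine strand.

    CpG context is read from the reference: a C followed by G on the strand
    where the reference base is a pyrimidine.  At a contig edge the site is
    classed non-CpG with a warning.
    """
    if not site.is_snv:
        raise ValueError(f"{site.chrom}:{site.pos} is not an SNV")
    r, a = site.ref, site.alt
    if r in "CT":
        pyr_r, pyr_a = r, a
        cpg_neighbor_pos = site.pos + 1  # base after the C on +
    else:
        pyr_r, pyr_a = _COMP[r], _COMP[a]
        cpg_neighbor_pos = site.pos - 1  # C on - strand: G before it on +
    key = f"{pyr_r}>{pyr_a}"
    if key != "C>T":
        return SpectrumClass(key)
    try:
        neighbor = fetch(ref, site.chrom, cpg_neighbor_pos, cpg_neighbor_pos)
    except (IndexError, KeyError, ValueError):
        neighbor = ""
    if cpg_neighbor_pos < 1 or not neighbor:
        warnings.warn(
            f"no CpG context at contig edge for {site.chrom}:{site.pos}; "
            f"counted as non-CpG",
            stacklevel=2,
        )
        return SpectrumClass.C_T_nonCpG
    is_cpg = neighbor == ("G" if r == "C" else "C")
    return SpectrumClass.C_T_CpG if is_cpg else SpectrumClass.C_T_nonCpG


def mutation_spectrum(sites: Iterable[VariantSite], ref) -> SpectrumCounts:
    """Tally the 7-class substitution spectrum of a set of SNVs."""
    counts = {c: 0 for c in SpectrumClass}
    for site in sites:
        counts[classify_substitution(site, ref)] += 1
    return SpectrumCounts(counts)


@dataclass(frozen=True)
class ClassComparison:
    observed: int
    expected: float
    ci_low: float
    ci_high: float
    pvalue: float  # multiplicity-adjusted
    direction: str  # enriched / depleted / ns


@dataclass(frozen=True)
class SpectrumComparison:
    classes: Mapping[SpectrumClass, ClassComparison]
    observed_total: int
    control_total: int


def compare_spectra(
    observed: SpectrumCounts,
    control: SpectrumCounts,
    *,
    alpha: float = 0.05,
    ci: str = "normal",
    bonferroni: bool = True,
) -> SpectrumComparison:
    """Observed-vs-expected comparison of substitution spectra.

    The control set fixes the expected class proportions; each class is
    tested with a two-sided exact binomial test of the observed count
    against p0 = control proportion at n = observed total.  P-values are
    Bonferroni-adjusted across the 7 classes by default.  The 95% CI is on
    the expected count at n = observed total (normal approximation, or
    Clopper-Pearson with ``ci='exact'``).  Direction is called at the
    adjusted p < alpha.
    """
    if observed.total == 0 or control.total == 0:
        raise ValueError("observed and control totals must be positive")
    n = observed.total
    k = len(SpectrumClass)
    out = {}
    for cls in SpectrumClass:
        ctrl = control[cls]
        if ctrl == 0 and observed[cls] > 0:
            warnings.warn(
                f"control has no {cls.value} variants; using a floor "
                f"proportion of 0.5/control_total",
                stacklevel=2,
            )
            p0 = 0.5 / control.total
        else:
            p0 = ctrl / control.total
        expected = n * p0
        if p0 == 0:
            p = 1.0 if observed[cls] == 0 else 0.0
            lo = hi = 0.0
        else:
            p = stats.binomtest(observed[cls], n, p0, alternative="two-sided").pvalue
            if ci == "exact":
                lo_p, hi_p = _clopper_pearson(expected, n)
                lo, hi = n * lo_p, n * hi_p
            else:
                half = 1.96 * np.sqrt(n * p0 * (1 - p0))
                lo, hi = max(0.0, expected - half), expected + half
        p_adj = min(1.0, p * k) if bonferroni else p
        if p_adj < alpha:
            direction = "enriched" if observed[cls] > expected else "depleted"
        else:
            direction = "ns"
        out[cls] = ClassComparison(
            observed=observed[cls],
            expected=float(expected),
            ci_low=float(lo),
            ci_high=float(hi),
            pvalue=float(p_adj),
            direction=direction,
        )
    return SpectrumComparison(
        classes=out, observed_total=n, control_total=control.total
    )


def _clopper_pearson(expected: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    x = int(round(expected))
    a = (1 - conf) / 2
    lo = stats.beta.ppf(a, x, n - x + 1) if x > 0 else 0.0
    hi = stats.beta.ppf(1 - a, x + 1, n - x) if x < n else 1.0
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Conservation and selection contrasts
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Per-base conservation scores (e.g. phastCons) from bedGraph/wiggle.

    bedGraph intervals are 0-based half-open on disk and converted to the
    internal 1-based convention on load.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            self._starts[chrom] = np.asarray([s for s, _, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.asarray([e for _, e, _ in ivs], dtype=np.int64)
            sc = np.asarray([x for _, _, x in ivs], dtype=float)
            if ((sc < 0) | (sc > 1)).any():
                raise ValueError("conservation scores must lie in [0, 1]")
            self._scores[chrom] = sc

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end, score = line.split()[:4]
                intervals.setdefault(chrom, []).append(
                    (int(start) + 1, int(end), float(score))
                )
        return cls(intervals)

    def score_at(self, chrom: str, pos: int) -> float | None:
        if chrom not in self._starts:
            return None
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        if i < 0 or pos > self._ends[chrom][i]:
            return None
        return float(self._scores[chrom][i])

    def scores_for(
        self, sites: Iterable[VariantSite]
    ) -> tuple[np.ndarray, int]:
        """(scores at covered sites, number of sites without a score)."""
        vals, skipped = [], 0
        for s in sites:
            v = self.score_at(s.chrom, s.pos)
            if v is None:
                skipped += 1
            else:
                vals.append(v)
        return np.asarray(vals, dtype=float), skipped


@dataclass(frozen=True)
class ConservationContrast:
    substrain_mean: float
    substrain_sem: float
    control_mean: float
    control_sem: float
    t_statistic: float
    pvalue: float
    n_substrain: int
    n_control: int
    skipped_substrain: int
    skipped_control: int


def conservation_compare(
    substrain_sites: Sequence[VariantSite],
    control_sites: Sequence[VariantSite],
    track: ConservationTrack,
) -> ConservationContrast:
    """Welch two-sample t-test of conservation scores at variant positions."""
    a, skip_a = track.scores_for(substrain_sites)
    b, skip_b = track.scores_for(control_sites)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"insufficient scored sites (substrain={a.size}, control={b.size})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ConservationContrast(
        substrain_mean=float(a.mean()),
        substrain_sem=float(stats.sem(a)),
        control_mean=float(b.mean()),
        control_sem=float(stats.sem(b)),
        t_statistic=float(t),
        pvalue=float(p),
        n_substrain=int(a.size),
        n_control=int(b.size),
        skipped_substrain=skip_a,
        skipped_control=skip_b,
    )


def substrain_kaks_contrast(
    substrain_sites: Sequence[VariantSite],
    control_sites: Sequence[VariantSite],
    models: Sequence[GeneModel],
    ref,
) -> dict[str, float]:
    """Aggregate nonsyn/syn count ratio for each variant set.

    Counts are pooled over all genes; a set with zero synonymous changes
    gets an infinite ratio with a warning.  Returns a dict with the two
    ratios and a ``substrain_exceeds_control`` flag (strict comparison).
    """
    if not substrain_sites:
        raise ValueError("substrain site set is empty")

    def pooled_ratio(sites: Sequence[VariantSite]) -> tuple[float, int, int]:
        n = s = 0
        for gene in models:
            st = consequence.count_syn_nonsyn(gene, sites, ref)
            n += st.n_nonsyn
            s += st.n_syn
        if s == 0:
            warnings.warn("zero synonymous changes; ratio is infinite", stacklevel=3)
            return float("inf"), n, s
        return n / s, n, s

    r_sub, n_sub, s_sub = pooled_ratio(substrain_sites)
    r_ctl, n_ctl, s_ctl = pooled_ratio(control_sites)
    return {
        "substrain_ratio": r_sub,
        "control_ratio": r_ctl,
        "substrain_nonsyn": n_sub,
        "substrain_syn": s_sub,
        "control_nonsyn": n_ctl,
        "control_syn": s_ctl,
        "substrain_exceeds_control": r_sub > r_ctl,
    }
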