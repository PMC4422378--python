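"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be fabricated here: a random
reference, a multi-substrain homozygous genotype matrix with ancestral
cluster structure and per-substrain drift of a configurable mutational
spectrum, gene models with plantable HIGH-impact variants (optionally
rescued by a partner variant on the same haplotype), overdispersed
expression counts with a configurable repression effect, degraded call sets
with known FN/FP rates, and conservation tracks with a planted shift at
constrained intervals.

The default :class:`PopulationScenario` emulates the structure of the rat
inbred-strain panel this pipeline was built around: 9 ancestral clusters,
two strains per cluster of which seven strains have 2-4 sequenced
substrains, ~50k ancestral SNVs on a 2 Mb genome, drift SNVs with a
CpG-enriched C>T spectrum, and a small heterozygous/missing noise floor
(the published call set was 97.5% homozygous).

A single integer seed fans out into independent per-generator streams, so
adding a generator never perturbs the output of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consequence import GeneModel, revcomp
from .population import windowize_by_count
from .substrain import SpectrumClass
from .variant_io import (
    Genotype,
    GenotypeMatrix,
    StrainGroupTable,
    VariantSite,
)

_NUC = np.array(list("ACGT"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, generator name)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------

def generate_reference(
    length: int, gc_fraction: float = 0.42, seed: int = 0, chrom: str = "chr1"
) -> dict[str, str]:
    """Random reference with the requested GC content, as {chrom: sequence}."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = _rng(seed, f"reference:{chrom}")
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    seq = rng.choice(_NUC, size=length, p=[at, gc, gc, at])
    return {chrom: "".join(seq)}


def write_fasta(ref: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Population scenario
# ---------------------------------------------------------------------------

# drift spectrum: CpG-deamination-dominated, qualitatively matching the
# observed substrain spectrum (C>T enriched, strongest at CpG; T>C below
# its share among older strain-level variants)
DEFAULT_DRIFT_SPECTRUM: dict[SpectrumClass, float] = {
    SpectrumClass.C_A: 0.09,
    SpectrumClass.C_G: 0.07,
    SpectrumClass.C_T_CpG: 0.28,
    SpectrumClass.C_T_nonCpG: 0.21,
    SpectrumClass.T_A: 0.06,
    SpectrumClass.T_C: 0.21,
    SpectrumClass.T_G: 0.08,
}

# substrain counts per strain, cycled over clusters x strains: seven strains
# carry 2-4 substrains (these form the substrain-variability groups), the
# rest are single substrains
DEFAULT_SUBSTRAIN_COUNTS = (2, 1, 3, 1, 4, 1, 2, 1, 3, 1, 2, 1, 4, 1, 1, 1, 1, 1)


@dataclass
class PopulationScenario:
    n_clusters: int = 9
    strains_per_cluster: int = 2
    substrains_per_strain: tuple[int, ...] = DEFAULT_SUBSTRAIN_COUNTS
    genome_length: int = 2_000_000
    n_ancestral_snvs: int = 50_000
    n_drift_snvs: int = 500
    drift_spectrum: Mapping[SpectrumClass, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIFT_SPECTRUM)
    )
    snvs_per_window: int = 2_000
    mosaic_switches: tuple[tuple[int, int, int], ...] = ()
    # each switch: (target cluster index, window index, source cluster index)
    het_rate: float = 0.025
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.drift_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"drift_spectrum must sum to 1, got {total}")
        for name in ("n_clusters", "strains_per_cluster", "genome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ancestral_snvs < 0 or self.n_drift_snvs < 0:
            raise ValueError("SNV counts must be non-negative")
        if not (0 <= self.het_rate < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("noise rates must be in [0, 1)")


@dataclass
class TruthBundle:
    """Planted ground truth referring only to emitted records."""

    drift_sites: dict[str, list[VariantSite]] = field(default_factory=dict)
    group_variable_sites: dict[str, list[VariantSite]] = field(default_factory=dict)
    window_clusters: dict[str, dict[int, str]] = field(default_factory=dict)
    noise_sites: list[VariantSite] = field(default_factory=list)
    fn_sites: list[VariantSite] = field(default_factory=list)
    fp_sites: list[VariantSite] = field(default_factory=list)
    repression_factor: float | None = None
    repressed_genes: list[str] = field(default_factory=list)
    conservation_shift: float | None = None
    rescued: dict[str, bool] = field(default_factory=dict)


@dataclass
class PopulationData:
    matrix: GenotypeMatrix
    groups: StrainGroupTable
    memberships: dict[str, str]  # sample -> cluster id
    truth: TruthBundle
    scenario: PopulationScenario


def _sample_names(
    scenario: PopulationScenario,
) -> tuple[list[str], dict[str, str], dict[str, list[str]], dict[str, int]]:
    """Sample names, sample->cluster, strain->substrains, sample->cluster idx."""
    samples: list[str] = []
    memberships: dict[str, str] = {}
    strains: dict[str, list[str]] = {}
    cluster_idx: dict[str, int] = {}
    k = 0
    counts = scenario.substrains_per_strain
    for c in range(scenario.n_clusters):
        for s in range(scenario.strains_per_cluster):
            strain = f"C{c + 1}S{s + 1}"
            n_sub = counts[k % len(counts)]
            k += 1
            members = [f"{strain}/{chr(ord('a') + i)}" for i in range(n_sub)]
            strains[strain] = members
            for m in members:
                samples.append(m)
                memberships[m] = f"cluster{c + 1}"
                cluster_idx[m] = c
    return samples, memberships, strains, cluster_idx


def _context_indices(seq: str) -> dict[SpectrumClass, np.ndarray]:
    """Genome positions (0-based) eligible for each drift spectrum class."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    is_t = arr == b"T"
    next_g = np.zeros(len(arr), dtype=bool)
    next_g[:-1] = arr[1:] == b"G"
    return {
        SpectrumClass.C_A: np.flatnonzero(is_c),
        SpectrumClass.C_G: np.flatnonzero(is_c),
        SpectrumClass.C_T_CpG: np.flatnonzero(is_c & next_g),
        SpectrumClass.C_T_nonCpG: np.flatnonzero(is_c & ~next_g),
        SpectrumClass.T_A: np.flatnonzero(is_t),
        SpectrumClass.T_C: np.flatnonzero(is_t),
        SpectrumClass.T_G: np.flatnonzero(is_t),
    }


_CLASS_ALT = {
    SpectrumClass.C_A: "A",
    SpectrumClass.C_G: "G",
    SpectrumClass.C_T_CpG: "T",
    SpectrumClass.C_T_nonCpG: "T",
    SpectrumClass.T_A: "A",
    SpectrumClass.T_C: "C",
    SpectrumClass.T_G: "G",
}


def generate_population(
    ref: Mapping[str, str], scenario: PopulationScenario
) -> PopulationData:
    """Homozygous genotype matrix with cluster structure and substrain drift.

    Ancestral SNVs are private to one cluster and shared by all its
    samples; drift SNVs are private to a single substrain, placed at
    positions whose reference context matches the class drawn from
    ``drift_spectrum`` (so CpG classes sit at CpG sites).  Planted mosaic
    switches copy a source cluster's ancestral genotypes into all samples
    of a target cluster within one fixed-SNV-count window.  Heterozygous
    and missing noise is injected last, at the scenario's rates, never on
    drift sites (their truth must survive into the emitted records).
    """
    (chrom, seq), = ref.items()
    if len(seq) != scenario.genome_length:
        seq = seq[: scenario.genome_length]
        if len(seq) < scenario.genome_length:
            raise ValueError("reference shorter than scenario.genome_length")
    samples, memberships, strains, cluster_of = _sample_names(scenario)
    n_samples = len(samples)
    rng_anc = _rng(scenario.seed, "population:ancestral")
    rng_drift = _rng(scenario.seed, "population:drift")
    rng_noise = _rng(scenario.seed, "population:noise")

    used = np.zeros(len(seq), dtype=bool)

    # ancestral cluster-private SNVs
    anc_pos = rng_anc.choice(len(seq), size=scenario.n_ancestral_snvs, replace=False)
    used[anc_pos] = True
    anc_owner = rng_anc.integers(0, scenario.n_clusters, size=anc_pos.size)
    records: list[tuple[int, str, str, int | None, str | None]] = []
    # (0-based pos, ref, alt, owner cluster or None, drift sample or None)
    for p, owner in zip(anc_pos, anc_owner):
        r = seq[p]
        alt = str(rng_anc.choice([b for b in "ACGT" if b != r]))
        records.append((int(p), r, alt, int(owner), None))

    # substrain drift SNVs with context-respecting spectrum
    classes = list(scenario.drift_spectrum)
    probs = np.array([scenario.drift_spectrum[c] for c in classes])
    ctx = _context_indices(seq)
    truth = TruthBundle()
    for sample in samples:
        drawn = rng_drift.choice(len(classes), size=scenario.n_drift_snvs, p=probs)
        sample_sites: list[VariantSite] = []
        for ci in drawn:
            cls = classes[ci]
            pool = ctx[cls]
            for _ in range(50):
                p = int(pool[rng_drift.integers(0, pool.size)])
                if not used[p]:
                    break
            else:
                raise RuntimeError(
                    f"could not place a {cls.value} drift SNV: "
                    f"context pool exhausted"
                )
            used[p] = True
            alt = _CLASS_ALT[cls]
            records.append((p, seq[p], alt, None, sample))
            sample_sites.append(VariantSite(chrom, p + 1, seq[p], alt))
        truth.drift_sites[sample] = sample_sites

    records.sort(key=lambda r: r[0])
    sites = [VariantSite(chrom, p + 1, r, a) for p, r, a, _, _ in records]
    calls = np.full((n_samples, len(sites)), Genotype.REF_HOM, dtype=np.int8)
    sample_index = {s: i for i, s in enumerate(samples)}
    sample_cluster = np.array([cluster_of[s] for s in samples])
    owner_of_site = np.full(len(sites), -1, dtype=np.int64)
    cols_by_owner: dict[int, list[int]] = {}
    for j, (_, _, _, owner, drift_sample) in enumerate(records):
        if owner is not None:
            owner_of_site[j] = owner
            cols_by_owner.setdefault(owner, []).append(j)
        else:
            calls[sample_index[drift_sample], j] = Genotype.ALT_HOM
    for owner, cols in cols_by_owner.items():
        rows = np.flatnonzero(sample_cluster == owner)
        calls[np.ix_(rows, cols)] = Genotype.ALT_HOM

    # planted mosaic switches on ancestral sites
    windows = windowize_by_count(sites, scenario.snvs_per_window)
    for s in samples:
        truth.window_clusters[s] = {
            w.index: f"cluster{cluster_of[s] + 1}" for w in windows
        }
    for target_c, w_idx, source_c in scenario.mosaic_switches:
        if w_idx >= len(windows):
            raise ValueError(f"switch window {w_idx} out of range ({len(windows)})")
        w = windows[w_idx]
        target_samples = [s for s in samples if cluster_of[s] == target_c]
        for j in w.site_indices:
            if owner_of_site[j] < 0:
                continue  # drift sites keep their substrain truth
            gt = (
                Genotype.ALT_HOM
                if owner_of_site[j] == source_c
                else Genotype.REF_HOM
            )
            for s in target_samples:
                calls[sample_index[s], j] = gt
        for s in target_samples:
            truth.window_clusters[s][w_idx] = f"cluster{source_c + 1}"

    # het / missing noise, sparing drift sites
    drift_cols = {
        j for j, (_, _, _, owner, _) in enumerate(records) if owner is None
    }
    eligible = np.array([j for j in range(len(sites)) if j not in drift_cols])
    if eligible.size and (scenario.het_rate or scenario.missing_rate):
        n_het = rng_noise.binomial(eligible.size, scenario.het_rate)
        n_mis = rng_noise.binomial(eligible.size, scenario.missing_rate)
        noisy = rng_noise.choice(eligible, size=min(n_het + n_mis, eligible.size),
                                 replace=False)
        for k, j in enumerate(noisy):
            i = rng_noise.integers(0, n_samples)
            calls[i, j] = Genotype.HET if k < n_het else Genotype.MISSING
            truth.noise_sites.append(sites[j])

    groups = StrainGroupTable(
        {strain: members for strain, members in strains.items() if len(members) > 1}
    )
    m = GenotypeMatrix(samples, sites, calls)

    # group-variable truth: drift sites of group members are variable between
    # substrains by construction (private to one member)
    for gname, members in groups.items():
        sites_g: set[VariantSite] = set()
        for mem in members:
            sites_g.update(truth.drift_sites[mem])
        truth.group_variable_sites[gname] = sorted(sites_g)

    return PopulationData(
        matrix=m,
        groups=groups,
        memberships=memberships,
        truth=truth,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# Gene models with plantable HIGH-impact variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHighImpact:
    focal: VariantSite
    partner: VariantSite | None
    gene_id: str
    transcript_id: str
    rescued: bool


_SENSE_CODONS = [
    c
    for c in (
        a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"
    )
    if c not in ("TAA", "TAG", "TGA", "ATG")
]


def generate_gene_models(
    ref: Mapping[str, str],
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    rescue_fraction: float = 0.1,
    high_variants_per_gene: int = 1,
) -> tuple[list[GeneModel], list[PlantedHighImpact], dict[str, str]]:
    """Non-overlapping complete gene models spliced into a copy of ``ref``.

    Each gene is a translatable CDS (ATG ... stop) split over
    ``exons_per_gene`` exons with canonical GT..AG introns, on a random
    strand.  One codon per planted variant is forced to CAA (Gln) and the
    focal SNV C>T turns it into a TAA stop; for a ``rescue_fraction`` of
    planted variants a partner SNV in the same codon (A>C at position 2)
    turns the joint codon into TCA (Ser), restoring the reading frame.

    Returns (models, planted variants, modified reference).
    """
    (chrom, seq), = ref.items()
    rng = _rng(seed, "genes")
    seq_list = list(seq)
    models: list[GeneModel] = []
    planted: list[PlantedHighImpact] = []
    cursor = 100
    n_rescued_target = int(round(rescue_fraction * n_genes * high_variants_per_gene))
    rescue_flags = [True] * n_rescued_target + [False] * (
        n_genes * high_variants_per_gene - n_rescued_target
    )
    rng.shuffle(rescue_flags)
    flag_iter = iter(rescue_flags)

    for g in range(n_genes):
        n_codons = int(rng.integers(40, 100))
        codons = ["ATG"] + [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        ]
        target_codon_idx = sorted(
            rng.choice(range(2, n_codons - 2), size=high_variants_per_gene,
                       replace=False)
        )
        for ci in target_codon_idx:
            codons[ci] = "CAA"
        codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
        cds = "".join(codons)

        # split CDS into exons with canonical introns
        n_ex = min(exons_per_gene, max(1, len(cds) // 30))
        cuts = sorted(rng.choice(range(10, len(cds) - 10), size=n_ex - 1,
                                 replace=False)) if n_ex > 1 else []
        pieces = []
        prev = 0
        for c in list(cuts) + [len(cds)]:
            pieces.append(cds[prev:c])
            prev = c
        introns = [
            "GT"
            + "".join(rng.choice(_NUC, size=int(rng.integers(46, 196))))
            + "AG"
            for _ in range(len(pieces) - 1)
        ]

        strand = str(rng.choice(["+", "-"]))
        coding_region = pieces[0]
        exon_bounds_local = [(0, len(pieces[0]) - 1)]
        for piece, intron in zip(pieces[1:], introns):
            start = len(coding_region) + len(intron)
            coding_region += intron + piece
            exon_bounds_local.append((start, start + len(piece) - 1))
        genomic = coding_region if strand == "+" else revcomp(coding_region)

        start0 = cursor + int(rng.integers(50, 500))
        end0 = start0 + len(genomic)
        if end0 + 100 > len(seq_list):
            raise ValueError(
                f"reference too short to place {n_genes} genes "
                f"(ran out at gene {g})"
            )
        seq_list[start0:end0] = list(genomic)
        cursor = end0

        L = len(genomic)
        exons = []
        for s_loc, e_loc in exon_bounds_local:
            if strand == "+":
                exons.append((start0 + s_loc + 1, start0 + e_loc + 1))
            else:
                exons.append((start0 + (L - 1 - e_loc) + 1, start0 + (L - 1 - s_loc) + 1))
        exons.sort()
        gene_id = f"gene{g + 1}"
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds=tuple(exons),
        )
        models.append(model)

        # planted focal/partner variants in the forced CAA codons
        for ci in target_codon_idx:
            cpos = ci * 3  # coding index of the C
            focal = _coding_snv(model, seq_list, cpos, "T")
            rescued = next(flag_iter)
            partner = (
                _coding_snv(model, seq_list, cpos + 1, "C") if rescued else None
            )
            planted.append(
                PlantedHighImpact(
                    focal=focal,
                    partner=partner,
                    gene_id=gene_id,
                    transcript_id=model.transcript_id,
                    rescued=rescued,
                )
            )

    return models, planted, {chrom: "".join(seq_list)}


def _coding_to_genomic(model: GeneModel, cpos: int) -> int:
    """1-based genomic position of 0-based coding position."""
    total = model.coding_length
    if model.strand == "-":
        cpos = total - 1 - cpos
    offset = 0
    for s, e in model.cds:
        length = e - s + 1
        if cpos < offset + length:
            return s + (cpos - offset)
        offset += length
    raise IndexError(f"coding position {cpos} outside CDS")


def _coding_snv(
    model: GeneModel, seq_list: list[str], cpos: int, alt_coding: str
) -> VariantSite:
    gpos = _coding_to_genomic(model, cpos)
    ref_base = seq_list[gpos - 1]
    alt = alt_coding if model.strand == "+" else revcomp(alt_coding)
    return VariantSite(model.chrom, gpos, ref_base, alt)


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def generate_expression(
    models: Sequence[GeneModel],
    repression_factor: float = 1.0,
    n_tissues: int = 12,
    seed: int = 0,
    repressed_genes: Sequence[str] = (),
    library_scale: float = 1.0,
):
    """Overdispersed (gamma-Poisson) gene counts and exon in/exclusion reads.

    Genes in ``repressed_genes`` have their mean expression scaled by
    ``repression_factor``; their exons also receive elevated exclusion
    (junction-skipping) reads.  Returns (CountTable, exon DataFrame,
    TruthBundle).
    """
    import pandas as pd

    from .expression import CountTable

    if not 0 < repression_factor <= 1:
        raise ValueError("repression_factor must be in (0, 1]")
    rng = _rng(seed, "expression")
    tissues = [f"tissue{t + 1}" for t in range(n_tissues)]
    repressed = set(repressed_genes)

    gene_ids = [m.gene_id for m in models]
    lengths = pd.Series(
        {m.gene_id: float(m.coding_length or (m.end - m.start + 1)) for m in models}
    )
    base_mean = rng.lognormal(mean=np.log(300.0), sigma=0.8, size=len(models))
    dispersion = 5.0  # gamma shape; smaller = noisier
    counts = np.empty((len(models), n_tissues), dtype=np.int64)
    for i, m in enumerate(models):
        mu = base_mean[i] * library_scale
        if m.gene_id in repressed:
            mu *= repression_factor
        lam = rng.gamma(dispersion, mu / dispersion, size=n_tissues)
        counts[i] = rng.poisson(lam)
    table = CountTable(
        unit="gene",
        counts=pd.DataFrame(counts, index=gene_ids, columns=tissues),
        lengths=lengths,
    )

    exon_rows = []
    for m in models:
        for k, (s, e) in enumerate(m.exons, 1):
            exon_id = f"{m.transcript_id}.exon{k}"
            length = e - s + 1
            flagged = m.gene_id in repressed
            for t in tissues:
                incl_mu = 40.0 * (repression_factor if flagged else 1.0)
                excl_mu = 8.0 if flagged else 0.6
                exon_rows.append(
                    (
                        exon_id,
                        m.gene_id,
                        t,
                        length,
                        int(rng.poisson(incl_mu)),
                        int(rng.poisson(excl_mu)),
                    )
                )
    exons = pd.DataFrame(
        exon_rows,
        columns=["exon", "gene", "tissue", "length", "inclusion", "exclusion"],
    )
    truth = TruthBundle(
        repression_factor=repression_factor, repressed_genes=sorted(repressed)
    )
    return table, exons, truth


# ---------------------------------------------------------------------------
# Validation truth sets
# ---------------------------------------------------------------------------

def generate_validation_truth(
    truth_sites: Sequence[VariantSite],
    regions: Sequence[tuple[str, int, int]],
    fn_rate: float,
    fp_rate: float,
    seed: int,
    ref: Mapping[str, str],
) -> tuple[list[VariantSite], list[VariantSite], TruthBundle]:
    """Degrade a truth call set with known FN and FP rates.

    The test set drops each truth site independently with probability
    ``fn_rate`` and adds Poisson(fp_rate * evaluated_nt) spurious SNVs at
    random unused positions within the regions.  Returns
    (truth within regions, degraded test set, truth bundle).
    """
    if not (0 <= fn_rate < 1 and 0 <= fp_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = _rng(seed, "validation")
    in_regions = [
        s
        for s in truth_sites
        if any(c == s.chrom and a <= s.pos <= b for c, a, b in regions)
    ]
    keep = rng.random(len(in_regions)) >= fn_rate
    test = [s for s, k in zip(in_regions, keep) if k]
    fn = [s for s, k in zip(in_regions, keep) if not k]

    taken = {(s.chrom, s.pos) for s in in_regions}
    evaluated_nt = sum(b - a + 1 for _, a, b in regions)
    n_fp = int(rng.poisson(fp_rate * evaluated_nt))
    fp: list[VariantSite] = []
    for _ in range(n_fp):
        for _ in range(100):
            chrom, a, b = regions[int(rng.integers(0, len(regions)))]
            pos = int(rng.integers(a, b + 1))
            if (chrom, pos) not in taken:
                break
        else:
            continue
        taken.add((chrom, pos))
        r = ref[chrom][pos - 1].upper()
        alt = str(rng.choice([x for x in "ACGT" if x != r]))
        site = VariantSite(chrom, pos, r, alt)
        fp.append(site)
        test.append(site)
    truth_bundle = TruthBundle(fn_sites=fn, fp_sites=fp)
    return sorted(in_regions), sorted(test), truth_bundle


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------

def generate_conservation(
    ref: Mapping[str, str],
    constrained_intervals: Sequence[tuple[str, int, int]] = (),
    shift: float = 0.0,
    seed: int = 0,
    base_mean: float = 0.2,
    concentration: float = 10.0,
):
    """Per-base conservation scores in [0, 1] as a ConservationTrack.

    Background scores are Beta-distributed with mean ``base_mean``;
    positions inside ``constrained_intervals`` (1-based inclusive) are drawn
    with the mean elevated by ``shift`` at the same concentration.
    """
    from .substrain import ConservationTrack

    if not 0 <= shift < 1 - base_mean:
        raise ValueError("shift must be in [0, 1 - base_mean)")
    rng = _rng(seed, "conservation")
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, seq in ref.items():
        n = len(seq)
        scores = rng.beta(
            concentration * base_mean, concentration * (1 - base_mean), size=n
        )
        if shift > 0:
            m = base_mean + shift
            for c, a, b in constrained_intervals:
                if c != chrom:
                    continue
                a0, b0 = max(1, a) - 1, min(n, b)
                scores[a0:b0] = rng.beta(
                    concentration * m, concentration * (1 - m), size=b0 - a0
                )
        np.clip(scores, 0.0, 1.0, out=scores)
        intervals[chrom] = [(i + 1, i + 1, float(scores[i])) for i in range(n)]
    return ConservationTrack(intervals)


def write_bedgraph(track, path: str | Path) -> None:
    """Emit a ConservationTrack as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track._starts):
            starts = track._starts[chrom]
            ends = track._ends[chrom]
            scores = track._scores[chrom]
            for s, e, x in zip(starts, ends, scores):
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{x:.4f}\n")


def write_truth_json(truth: TruthBundle, path: str | Path) -> None:
    def enc(x):
        if isinstance(x, VariantSite):
            return f"{x.chrom}:{x.pos}:{x.ref}:{x.alt}"
        raise TypeError(type(x))

    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, default=enc, indent=1)
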