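"""Variant data model, VCF readers/writers and pipeline configuration.

The central in-memory container is :class:`GenotypeMatrix`: an ordered list of
bi-allelic :class:`VariantSite` records together with a samples x sites array
of genotype codes.  Inbred strains are (nearly) fully homozygous, so the code
set is deliberately small: ``REF_HOM``, ``ALT_HOM``, ``HET`` and ``MISSING``.
Heterozygous residue is treated as noise (incomplete fixation, collapsed
duplications, technical error) and is split off as whole sites by
:func:`partition_zygosity` before any downstream analysis.

Coordinates are 1-based inclusive throughout (VCF convention); BED-like
0-based half-open intervals are converted at the file boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

_NUCS = frozenset("ACGT")


class Genotype(enum.IntEnum):
    """Per-sample genotype code for one bi-allelic site."""

    MISSING = -1
    REF_HOM = 0
    HET = 1
    ALT_HOM = 2


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Classify a normalized ref/alt allele pair."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INS
    if len(alt) < len(ref):
        return VariantClass.DEL
    return VariantClass.MNV


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single bi-allelic variant: 1-based position, one ALT allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _NUCS:
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.vclass is VariantClass.SNV


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of :class:`Genotype` codes.

    ``calls[i, j]`` is the genotype of ``samples[i]`` at ``sites[j]``.
    Sites are kept sorted by (chrom, pos, ref, alt).
    """

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(list(names), list(self.sites), self.calls[idx, :])

    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            list(self.samples),
            [self.sites[i] for i in index],
            self.calls[:, index],
        )

    def sort_sites(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_sites), key=lambda i: self.sites[i])
        return self.subset_sites(order)


class StrainGroupTable(dict):
    """Mapping group name -> ordered member sample names.

    Each group has >= 2 members and a sample belongs to at most one group.
    """

    def __init__(self, groups: Mapping[str, Sequence[str]]):
        seen: dict[str, str] = {}
        clean: dict[str, list[str]] = {}
        for name, members in groups.items():
            members = list(members)
            if len(members) < 2:
                raise ValueError(f"group {name!r} has < 2 members")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"sample {m!r} in both groups {seen[m]!r} and {name!r}"
                    )
                seen[m] = name
            clean[name] = members
        super().__init__(clean)


def read_group_table(path: str | Path) -> StrainGroupTable:
    """Read a TSV with header columns ``group`` and ``sample``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"group", "sample"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'group' and 'sample'")
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["group"], []).append(row["sample"])
    return StrainGroupTable(groups)


def write_group_table(groups: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tsample\n")
        for name, members in groups.items():
            for m in members:
                fh.write(f"{name}\t{m}\n")


@dataclass
class PipelineConfig:
    """Tunable analysis parameters shared across the pipeline.

    Defaults mirror the published analysis: 100 kb syntenic windows advanced
    in 25 kb steps, lower/upper 10th-percentile tails for shared-extreme loci,
    20,000-SNV ancestry windows, >= 6 coding SNVs for per-gene Ka/Ks,
    FPKM >= 1 to call a gene expressed and 16,000 background exons.
    """

    syntenic_window_bp: int = 100_000
    window_step_bp: int = 25_000
    extreme_percentile: float = 10.0
    snvs_per_window: int = 20_000
    min_coding_snvs: int = 6
    expressed_fpkm_threshold: float = 1.0
    background_exon_sample_n: int = 16_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("syntenic_window_bp", "window_step_bp", "snvs_per_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.extreme_percentile < 50:
            raise ValueError("extreme_percentile must be in (0, 50)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat ``key=value`` file; unknown keys are an error."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, float | int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            num = float(value)
            if key in ("extreme_percentile", "expressed_fpkm_threshold"):
                kwargs[key] = num
            else:
                kwargs[key] = int(num)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")


# ---------------------------------------------------------------------------
# VCF reading/writing
# ---------------------------------------------------------------------------

def _split_record_calls(
    genotypes: list[list[int]], alt_index: int
) -> np.ndarray:
    """Map cyvcf2 genotype triplets to codes for one ALT of a record."""
    out = np.empty(len(genotypes), dtype=np.int8)
    for i, gt in enumerate(genotypes):
        a, b = gt[0], gt[1]
        if a < 0 or b < 0:
            out[i] = Genotype.MISSING
        elif a == b == alt_index:
            out[i] = Genotype.ALT_HOM
        elif a == b:
            # hom-ref, or hom for a different ALT of a multi-allelic record:
            # w.r.t. this split site the sample does not carry the allele
            out[i] = Genotype.REF_HOM
        else:
            out[i] = Genotype.HET
    return out


def read_variant_table(
    path: str | Path, sample_subset: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one site per ALT allele; sites come
    back sorted by (chrom, pos).  Phasing is ignored.  Records whose alleles
    are not plain A/C/G/T strings (symbolic ALTs, breakends) are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = set(sample_subset) - set(all_samples)
        if unknown:
            raise KeyError(f"samples not in {path}: {sorted(unknown)}")

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes
        if gts is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} has no GT field")
        for k, alt in enumerate(rec.ALT, start=1):
            try:
                site = VariantSite(rec.CHROM, rec.POS, rec.REF, alt)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed record at {rec.CHROM}:{rec.POS}: {exc}"
                ) from exc
            sites.append(site)
            columns.append(_split_record_calls(gts, k))
    vcf.close()

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(all_samples), 0), dtype=np.int8)
    )
    m = GenotypeMatrix(all_samples, sites, calls).sort_sites()
    if sample_subset is not None:
        m = m.subset_samples(sample_subset)
    return m


_GT_STRING = {
    Genotype.REF_HOM: "0/0",
    Genotype.HET: "0/1",
    Genotype.ALT_HOM: "1/1",
    Genotype.MISSING: "./.",
}

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_variant_table(
    m: GenotypeMatrix, path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file (GT field only)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for j, site in enumerate(m.sites):
            gts = "\t".join(_GT_STRING[Genotype(c)] for c in m.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def partition_zygosity(m: GenotypeMatrix) -> tuple[GenotypeMatrix, list[VariantSite]]:
    """Split off sites with any heterozygous call.

    Returns ``(hom_matrix, het_sites)``.  A site heterozygous in any sample is
    removed globally, matching the separate-file treatment of the published
    call set; counts are conserved:
    ``m.n_sites == hom.n_sites + len(het_sites)``.
    """
    if m.n_sites == 0:
        return m, []
    het_mask = (m.calls == Genotype.HET).any(axis=0)
    hom = m.subset_sites(np.flatnonzero(~het_mask))
    het_sites = [m.sites[j] for j in np.flatnonzero(het_mask)]
    return hom, het_sites
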