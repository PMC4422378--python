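"""Truth-set concordance and genome-wide error extrapolation.

A finished-sequence truth set (e.g. capillary-sequenced BAC clones from one
strain) is compared against the pipeline's calls restricted to the same
regions.  The resulting TP/FN/FP tallies are scaled to the whole genome under
the assumption that the truth regions are representative: for every missed
variant per true positive in the truth regions, the same ratio of calls is
assumed missed among all genome-wide calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .variant_io import VariantSite


@dataclass(frozen=True)
class ConcordanceCounts:
    """TP/FN/FP tallies over a set of evaluated truth regions."""

    evaluated_nt: int
    tp: int
    fn: int
    fp: int
    vclass: str = "SNV"

    def __post_init__(self) -> None:
        if min(self.evaluated_nt, self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def truth_total(self) -> int:
        return self.tp + self.fn

    @property
    def test_total(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class GenomewideEstimate:
    est_missed: int
    pct_missed: float
    est_fp: int
    pct_fp: float


def merge_intervals(
    regions: Iterable[tuple[str, int, int]], warn: bool = True
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent 1-based inclusive (chrom, start, end) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        if end < start:
            raise ValueError(f"interval end < start on {chrom}: {start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    overlapped = False
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                if s <= cur_e:
                    overlapped = True
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    if overlapped and warn:
        warnings.warn("overlapping truth regions were merged", stacklevel=2)
    return merged


def _in_regions(site: VariantSite, merged: list[tuple[str, int, int]]) -> bool:
    return any(c == site.chrom and s <= site.pos <= e for c, s, e in merged)


def tally_concordance(
    truth: Sequence[VariantSite],
    test: Sequence[VariantSite],
    regions: Iterable[tuple[str, int, int]],
    vclass: str = "SNV",
) -> ConcordanceCounts:
    """Tally exact-match concordance of ``test`` against ``truth``.

    A pair matches iff (chrom, pos, ref, alt) are identical after
    normalization (left-aligned, split to bi-allelic); both call sets are
    first restricted to the merged evaluated regions.  ``evaluated_nt`` is
    the total merged region length.
    """
    merged = merge_intervals(regions)
    evaluated_nt = sum(e - s + 1 for _, s, e in merged)
    truth_in = {s for s in truth if _in_regions(s, merged)}
    test_in = {s for s in test if _in_regions(s, merged)}
    tp = len(truth_in & test_in)
    return ConcordanceCounts(
        evaluated_nt=evaluated_nt,
        tp=tp,
        fn=len(truth_in) - tp,
        fp=len(test_in) - tp,
        vclass=vclass,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extrapolate_genomewide(
    c: ConcordanceCounts, total_called: int
) -> GenomewideEstimate:
    """Scale truth-region error tallies to the genome-wide call set.

    est_missed = round(total_called * fn / tp)   (missed per observed TP)
    pct_missed = 100 * fn / (tp + fn)            (miss rate among true sites)
    est_fp     = round(total_called * fp / tp)
    pct_fp     = 100 * fp / (tp + fp)            (FP rate among calls)

    Counts are rounded half-up; percentages to one decimal.
    """
    if c.tp == 0:
        raise ZeroDivisionError(
            "no true positives in the truth regions: error rates undefined"
        )
    est_missed = _round_half_up(total_called * c.fn / c.tp)
    pct_missed = round(100.0 * c.fn / (c.tp + c.fn), 1)
    est_fp = _round_half_up(total_called * c.fp / c.tp)
    pct_fp = round(100.0 * c.fp / (c.tp + c.fp), 1)
    return GenomewideEstimate(est_missed, pct_missed, est_fp, pct_fp)


def concordance_report(c: ConcordanceCounts, est: GenomewideEstimate) -> str:
    """Human-readable validation summary."""
    return (
        f"Evaluated {c.evaluated_nt:,} nt ({c.vclass})\n"
        f"  concordant (TP): {c.tp:,}\n"
        f"  missed (FN):     {c.fn:,}\n"
        f"  spurious (FP):   {c.fp:,}\n"
        f"Genome-wide extrapolation:\n"
        f"  estimated missed calls: {est.est_missed:,} ({est.pct_missed}%)\n"
        f"  estimated false calls:  {est.est_fp:,} ({est.pct_fp}%)\n"
    )
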