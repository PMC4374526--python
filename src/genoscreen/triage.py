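"""Cross-strain variant triage.

Per-strain call sets are pre-filtered on quality (strict inequalities:
depth > 3, mapping quality > 20, call quality > 20, heterozygous-class calls
dropped), then variants present in *every* strain — real differences between
the common parent and the reference assembly — are subtracted, leaving each
strain's private candidate mutations.  Records are never modified, only kept
or dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "StrainCallSet",
    "TriageThresholds",
    "CdsInterval",
    "filter_calls",
    "subtract_shared",
    "flag_coding",
    "triage_report",
    "run_triage",
]

logger = logging.getLogger(__name__)

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    map_quality: float
    call_quality: float
    genotype_class: str = HOMOZYGOUS
    coding: Optional[bool] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.genotype_class not in (HOMOZYGOUS, HETEROZYGOUS):
            raise ValueError(f"unknown genotype class {self.genotype_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-strain subtraction: exact allele match."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def affected_interval(self) -> tuple[int, int]:
        """Genomic interval altered by the record (anchor-inclusive)."""
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass(frozen=True)
class StrainCallSet:
    strain_id: str
    records: tuple[VariantRecord, ...]

    def __post_init__(self):
        recs = tuple(sorted(self.records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)))
        keys = [r.key for r in recs]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant records in strain {self.strain_id}")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records}


@dataclass(frozen=True)
class TriageThresholds:
    """Strict lower bounds: a record passes only if it exceeds every one."""

    min_depth_exclusive: int = 3
    min_mq_exclusive: float = 20.0
    min_qual_exclusive: float = 20.0
    drop_heterozygous: bool = True

    def __post_init__(self):
        if min(self.min_depth_exclusive, self.min_mq_exclusive, self.min_qual_exclusive) < 0:
            raise ValueError("thresholds must be >= 0")

    def passes(self, r: VariantRecord) -> bool:
        if r.depth <= self.min_depth_exclusive:
            return False
        if r.map_quality <= self.min_mq_exclusive:
            return False
        if r.call_quality <= self.min_qual_exclusive:
            return False
        if self.drop_heterozygous and r.genotype_class != HOMOZYGOUS:
            return False
        return True


def filter_calls(
    calls: StrainCallSet, thresholds: TriageThresholds | None = None
) -> StrainCallSet:
    """Quality pre-filter.  Order-preserving, idempotent, output ⊆ input."""
    thresholds = thresholds or TriageThresholds()
    kept = tuple(r for r in calls.records if thresholds.passes(r))
    return StrainCallSet(calls.strain_id, kept)


def subtract_shared(
    callsets: Sequence[StrainCallSet], min_strains: Optional[int] = None
) -> list[StrainCallSet]:
    """Remove variants present in every input call set (keyed by
    chrom, pos, ref, alt).

    ``min_strains`` lowers the "present in all" requirement: a variant seen
    in at least that many strains is treated as parental and subtracted.
    Defaults to all strains.
    """
    if len(callsets) < 2:
        raise ValueError("subtraction needs at least two call sets")
    n_required = len(callsets) if min_strains is None else min_strains
    if not 2 <= n_required <= len(callsets):
        raise ValueError(f"min_strains must be in [2, {len(callsets)}]")

    counts: dict[tuple, int] = {}
    for cs in callsets:
        for k in cs.keys():
            counts[k] = counts.get(k, 0) + 1
    shared = {k for k, c in counts.items() if c >= n_required}

    _warn_unmatched_indels(callsets, shared)

    return [
        StrainCallSet(cs.strain_id, tuple(r for r in cs.records if r.key not in shared))
        for cs in callsets
    ]


def _warn_unmatched_indels(callsets: Sequence[StrainCallSet], shared: set) -> None:
    """Indel representations are not normalised across strains; flag distinct
    indel alleles sitting at the same position in different strains, which may
    be one parental event that escaped subtraction."""
    by_pos: dict[tuple[str, int], set] = {}
    for cs in callsets:
        for r in cs.records:
            if len(r.ref) != len(r.alt) and r.key not in shared:
                by_pos.setdefault((r.chrom, r.pos), set()).add(r.key)
    suspicious = [p for p, ks in by_pos.items() if len(ks) > 1]
    if suspicious:
        warnings.warn(
            f"unmatched indel representations at {len(suspicious)} position(s): "
            f"{suspicious[:5]} — no indel normalisation is applied",
            stacklevel=3,
        )


@dataclass(frozen=True)
class CdsInterval:
    """Genomic footprint of a coding sequence (1-based, inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid CDS interval")


def flag_coding(calls: StrainCallSet, cds: CdsInterval) -> StrainCallSet:
    """Flag each record as coding iff its altered interval overlaps the CDS."""
    flagged = []
    for r in calls.records:
        if r.chrom != cds.chrom:
            logger.warning(
                "record %s:%d on a chromosome absent from the CDS model", r.chrom, r.pos
            )
            flagged.append(replace(r, coding=False))
            continue
        a, b = r.affected_interval
        flagged.append(replace(r, coding=(a <= cds.end and b >= cds.start)))
    return StrainCallSet(calls.strain_id, tuple(flagged))


def run_triage(
    callsets: Sequence[StrainCallSet],
    thresholds: TriageThresholds | None = None,
    cds: CdsInterval | None = None,
    min_strains: Optional[int] = None,
) -> tuple[list[StrainCallSet], pd.DataFrame]:
    """Filter, subtract, optionally flag coding hits; return the surviving
    call sets plus a per-strain report table."""
    thresholds = thresholds or TriageThresholds()
    filtered = [filter_calls(cs, thresholds) for cs in callsets]
    surviving = subtract_shared(filtered, min_strains=min_strains)
    if cds is not None:
        surviving = [flag_coding(cs, cds) for cs in surviving]
    report = triage_report(callsets, filtered, surviving)
    return surviving, report


def triage_report(
    inputs: Sequence[StrainCallSet],
    filtered: Sequence[StrainCallSet],
    surviving: Sequence[StrainCallSet],
) -> pd.DataFrame:
    rows = []
    for raw, f, s in zip(inputs, filtered, surviving):
        rows.append(
            {
                "strain": raw.strain_id,
                "n_input": len(raw),
                "n_post_filter": len(f),
                "n_post_subtraction": len(s),
                "n_coding": sum(1 for r in s.records if r.coding),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "n_input", "n_post_filter", "n_post_subtraction", "n_coding"])
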