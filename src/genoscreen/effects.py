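"""Coding-consequence classification for c.-notation variants.

A variant is applied to a coding-sequence model and the mutant sequence is
translated in frame from the start codon.  The effect class is one of:

``frameshift``           net inserted-minus-deleted length inside the CDS is
                         not a multiple of three
``nonsense``             an in-frame premature stop appears without a frame
                         change
``missense`` / ``silent``  single-codon substitutions
``inframe_deletion``     whole-codon-count deletion
``inframe_substitution`` in-frame inversion / delins / insertion, reported as
                         substituted peptide ref -> alt
``start_lost``           the ATG is destroyed
``upstream_noncoding``   the variant lies entirely 5' of the CDS
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .hgvs import (
    DELETION,
    DELINS,
    DUPLICATION,
    INSERTION,
    INVERSION,
    SUBSTITUTION,
    HgvsVariant,
    apply_variant,
    c_span_length,
)

__all__ = ["CdsModel", "EffectCall", "classify_effect", "translate_cds",
           "FRAMESHIFT", "NONSENSE", "MISSENSE", "SILENT", "INFRAME_DELETION",
           "INFRAME_SUBSTITUTION", "START_LOST", "UPSTREAM_NONCODING"]

FRAMESHIFT = "frameshift"
NONSENSE = "nonsense"
MISSENSE = "missense"
SILENT = "silent"
INFRAME_DELETION = "inframe_deletion"
INFRAME_SUBSTITUTION = "inframe_substitution"
START_LOST = "start_lost"
UPSTREAM_NONCODING = "upstream_noncoding"

_STOPS = {"TAA", "TAG", "TGA"}


def translate_cds(seq: str) -> str:
    """Translate from the first base using the standard code, stopping at the
    first stop codon (which is not included).  A trailing partial codon is
    ignored."""
    usable = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:usable]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


@dataclass(frozen=True)
class CdsModel:
    """A bare coding sequence plus optional upstream context.

    ``cds_seq`` must start with ATG, be a codon multiple, end in a stop
    codon, and contain no internal stop codon.
    """

    cds_seq: str
    upstream_seq: str = ""
    id: str = "cds"

    def __post_init__(self):
        object.__setattr__(self, "cds_seq", self.cds_seq.upper())
        object.__setattr__(self, "upstream_seq", self.upstream_seq.upper())
        n = len(self.cds_seq)
        if n % 3 != 0:
            raise ValueError(f"CDS length {n} is not a multiple of 3")
        if n < 6:
            raise ValueError("CDS must hold at least a start and a stop codon")
        if not self.cds_seq.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if self.cds_seq[-3:] not in _STOPS:
            raise ValueError("CDS does not end with a stop codon")
        internal = {self.cds_seq[k : k + 3] for k in range(0, n - 3, 3)}
        if internal & _STOPS:
            raise ValueError("CDS contains an internal stop codon")

    @property
    def upstream_len(self) -> int:
        return len(self.upstream_seq)

    @property
    def n_codons(self) -> int:
        return len(self.cds_seq) // 3

    @property
    def protein(self) -> str:
        return translate_cds(self.cds_seq)


@dataclass(frozen=True)
class EffectCall:
    effect_class: str
    first_affected_codon: Optional[int] = None
    ref_residues: Optional[str] = None
    alt_residues: Optional[str] = None
    # supplementary, not part of the class: where translation now terminates
    new_stop_codon: Optional[int] = None
    net_length_change: Optional[int] = None


def _span(v: HgvsVariant) -> tuple[int, int]:
    return v.start, v.span_end


def _deleted_in_cds(v: HgvsVariant, cds_len: int) -> int:
    """Reference bases removed by v that lie inside the CDS (positive coords)."""
    if v.kind in (INSERTION, DUPLICATION):
        return 0
    start, end = _span(v)
    if end < 1:
        return 0
    start = max(start, 1)
    end = min(end, cds_len)
    if start > end:
        return 0
    return c_span_length(start, end)


def _protein_diff(ref_prot: str, mut_prot: str) -> tuple[int, str, str]:
    """(first_affected_codon, ref_residues, alt_residues) by trimming the
    common prefix and suffix of the two translations."""
    n = min(len(ref_prot), len(mut_prot))
    p = 0
    while p < n and ref_prot[p] == mut_prot[p]:
        p += 1
    s = 0
    while s < n - p and ref_prot[-1 - s] == mut_prot[-1 - s]:
        s += 1
    return p + 1, ref_prot[p : len(ref_prot) - s], mut_prot[p : len(mut_prot) - s]


def classify_effect(cds: CdsModel, v: HgvsVariant) -> EffectCall:
    """Predict the coding consequence of ``v`` on ``cds``."""
    start, end = _span(v)
    cds_len = len(cds.cds_seq)

    if end < 1:
        return EffectCall(UPSTREAM_NONCODING)

    inserted = v.inserted_length if v.kind not in (SUBSTITUTION, INVERSION) else _deleted_in_cds(v, cds_len)
    deleted = _deleted_in_cds(v, cds_len)
    net = (inserted - deleted) if v.kind not in (SUBSTITUTION, INVERSION) else 0

    # start codon destroyed?
    covers_start = start <= 3 and end >= 1
    if v.kind in (DELETION, DELINS, INVERSION) and covers_start:
        # an inversion or delins could in principle recreate ATG; check when
        # the mutant sequence is constructible
        if v.insert is None and v.kind == DELINS:
            return EffectCall(START_LOST, 1, net_length_change=net)
        mutant = apply_variant(cds, v)[cds.upstream_len :]
        if not mutant.startswith("ATG"):
            return EffectCall(START_LOST, 1, net_length_change=net)
    if v.kind in (INSERTION, DUPLICATION) and 1 <= start <= 2:
        mutant = apply_variant(cds, v)[cds.upstream_len :]
        if not mutant.startswith("ATG"):
            return EffectCall(START_LOST, 1, net_length_change=net)
    if v.kind == SUBSTITUTION and 1 <= start <= 3:
        return EffectCall(START_LOST, 1, net_length_change=0)

    first_cds_pos = max(start, 1)
    first_codon = (first_cds_pos + 2) // 3

    if net % 3 != 0:
        new_stop = None
        if v.insert is not None or v.kind in (DELETION, DUPLICATION):
            mutant = apply_variant(cds, v)[cds.upstream_len :]
            usable = mutant[: len(mutant) - len(mutant) % 3]
            if "*" in str(Seq(usable).translate()):
                new_stop = len(translate_cds(mutant)) + 1
        return EffectCall(FRAMESHIFT, first_codon, net_length_change=net,
                          new_stop_codon=new_stop)

    if v.kind == DELINS and v.insert is None:
        # in-frame external-token delins: peptides unknown without the insert
        return EffectCall(INFRAME_SUBSTITUTION, first_codon, net_length_change=net)

    mutant = apply_variant(cds, v)[cds.upstream_len :]
    ref_prot = cds.protein
    mut_prot = translate_cds(mutant)

    expected_len = len(ref_prot) + net // 3
    if len(mut_prot) < expected_len:
        # premature in-frame stop before the original terminator
        if mut_prot == ref_prot[: len(mut_prot)]:
            pos = len(mut_prot) + 1
        else:
            pos = _protein_diff(ref_prot, mut_prot)[0]
        ref_res = ref_prot[pos - 1] if pos <= len(ref_prot) else None
        return EffectCall(
            NONSENSE, pos, ref_res, "*",
            net_length_change=net, new_stop_codon=len(mut_prot) + 1,
        )

    pos, ref_res, alt_res = _protein_diff(ref_prot, mut_prot)

    if v.kind == SUBSTITUTION:
        if not ref_res:
            return EffectCall(SILENT, first_codon, net_length_change=0)
        return EffectCall(MISSENSE, pos, ref_res, alt_res, net_length_change=0)

    if not ref_res and not alt_res:
        return EffectCall(SILENT, first_codon, net_length_change=net)

    if v.kind == DELETION:
        return EffectCall(INFRAME_DELETION, pos, ref_res, alt_res, net_length_change=net)

    return EffectCall(INFRAME_SUBSTITUTION, pos, ref_res, alt_res, net_length_change=net)
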