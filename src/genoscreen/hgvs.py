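"""Parsing, formatting and application of HGVS c.-notation variants.

Coordinates follow the HGVS convention for coding sequences: position 1 is
the A of the start codon, there is no position 0, and negative positions
count backwards into the sequence 5' of the start codon (c.-1 is the base
immediately upstream of the ATG).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "HgvsVariant",
    "HgvsParseError",
    "ReferenceMismatchError",
    "MultipleEditsError",
    "ExternalInsertError",
    "parse_hgvs_c",
    "format_hgvs",
    "c_span_length",
    "apply_variant",
    "name_variant",
    "codons_spanned",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SUBSTITUTION = "substitution"
DELETION = "deletion"
INSERTION = "insertion"
DELINS = "delins"
INVERSION = "inversion"
DUPLICATION = "duplication"

KINDS = (SUBSTITUTION, DELETION, INSERTION, DELINS, INVERSION, DUPLICATION)


class HgvsParseError(ValueError):
    """Raised when an HGVS string cannot be parsed."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's stated reference base disagrees with the CDS."""


class MultipleEditsError(ValueError):
    """Raised when two sequences differ by more than one contiguous edit."""


class ExternalInsertError(ValueError):
    """Raised when applying a delins whose insert is an unfetched external token."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HgvsVariant:
    """One coding-sequence variant in HGVS c. coordinates.

    ``insert`` holds the alternate base for substitutions and the inserted
    sequence for insertions/delins/duplications.  A delins whose insert is an
    external accession span (e.g. ``CM000150.2:1390060_1390808``) stores the
    token in ``external_insert`` and its declared length in ``insert_len``;
    the sequence itself is never fetched.
    """

    kind: str
    start: int
    end: Optional[int] = None
    ref_base: Optional[str] = None
    insert: Optional[str] = None
    external_insert: Optional[str] = None
    insert_len: Optional[int] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise HgvsParseError(f"unknown variant kind: {self.kind!r}")
        if self.start == 0 or self.end == 0:
            raise HgvsParseError("HGVS c. position 0 does not exist")
        if self.end is not None and self.start > self.end:
            raise HgvsParseError(
                f"start {self.start} greater than end {self.end}"
            )
        if self.kind == SUBSTITUTION:
            if not (self.ref_base and self.insert) or len(self.ref_base) != 1 or len(self.insert) != 1:
                raise HgvsParseError("substitution requires single ref and alt base")
        if self.kind in (INVERSION, DELETION, DELINS, DUPLICATION) and self.end is None:
            # single-position del/dup like c.3508del is allowed
            if self.kind in (INVERSION,):
                raise HgvsParseError(f"{self.kind} requires a start_end span")

    @property
    def span_end(self) -> int:
        return self.end if self.end is not None else self.start

    @property
    def span_length(self) -> int:
        """Number of reference bases covered by the variant span."""
        if self.kind == INSERTION:
            return 0
        return c_span_length(self.start, self.span_end)

    @property
    def inserted_length(self) -> int:
        if self.insert is not None:
            return len(self.insert)
        if self.insert_len is not None:
            return self.insert_len
        if self.kind == DUPLICATION:
            return self.span_length
        if self.kind in (INVERSION, SUBSTITUTION):
            return self.span_length
        return 0


def c_span_length(start: int, end: int) -> int:
    """Length in bases of the inclusive c. span start..end.

    Accounts for the missing position 0 when the span crosses the
    upstream/CDS boundary: c.-2_2 covers bases -2, -1, 1, 2 = 4 bases.
    """
    if start == 0 or end == 0:
        raise HgvsParseError("HGVS c. position 0 does not exist")
    if start > end:
        raise HgvsParseError(f"span start {start} > end {end}")
    if start < 0 < end:
        return end - start  # no zero between -1 and 1
    return end - start + 1


_POS = r"(-?\d+)"
_RE_SUB = re.compile(rf"^{_POS}([ACGTacgt])>([ACGTacgt])$")
_RE_DEL = re.compile(rf"^{_POS}(?:_{_POS})?del([ACGTacgt]+)?$")
_RE_INS = re.compile(rf"^{_POS}_{_POS}ins([ACGTacgt]+)$")
_RE_DUP = re.compile(rf"^{_POS}(?:_{_POS})?dup$")
_RE_INV = re.compile(rf"^{_POS}_{_POS}inv$")
_RE_DELINS = re.compile(rf"^{_POS}(?:_{_POS})?delins(\S+)$")
_RE_EXTERNAL = re.compile(r"^([A-Za-z0-9_.]+):(\d+)_(\d+)$")


def _int_pos(tok: str) -> int:
    p = int(tok)
    if p == 0:
        raise HgvsParseError("position 0 is not a valid c. coordinate")
    return p


def parse_hgvs_c(text: str) -> HgvsVariant:
    """Parse an HGVS coding-DNA variant description.

    Whitespace inside the string (as printed in some tables, e.g.
    ``c.1015A > T``) is stripped before parsing.
    """
    body = re.sub(r"\s+", "", text)
    if not body.startswith("c."):
        raise HgvsParseError(f"not a c. description: {text!r}")
    body = body[2:]

    m = _RE_SUB.match(body)
    if m:
        pos = _int_pos(m.group(1))
        return HgvsVariant(SUBSTITUTION, pos, None, m.group(2).upper(), m.group(3).upper())

    m = _RE_INV.match(body)
    if m:
        return HgvsVariant(INVERSION, _int_pos(m.group(1)), _int_pos(m.group(2)))

    m = _RE_INS.match(body)
    if m:
        start, end = _int_pos(m.group(1)), _int_pos(m.group(2))
        if c_span_length(start, end) != 2:
            raise HgvsParseError(
                f"insertion flanking positions must be adjacent: {text!r}"
            )
        return HgvsVariant(INSERTION, start, end, insert=m.group(3).upper())

    m = _RE_DELINS.match(body)
    if m:
        start = _int_pos(m.group(1))
        end = _int_pos(m.group(2)) if m.group(2) else None
        ins = m.group(3)
        if re.fullmatch(r"[ACGTacgt]+", ins):
            return HgvsVariant(DELINS, start, end, insert=ins.upper())
        ext = _RE_EXTERNAL.match(ins)
        if ext:
            a, b = int(ext.group(2)), int(ext.group(3))
            if a > b:
                raise HgvsParseError(f"external span reversed in {text!r}")
            return HgvsVariant(
                DELINS, start, end, external_insert=ins, insert_len=b - a + 1
            )
        raise HgvsParseError(f"unrecognised delins insert token: {ins!r}")

    m = _RE_DEL.match(body)
    if m:
        start = _int_pos(m.group(1))
        end = _int_pos(m.group(2)) if m.group(2) else None
        listed = m.group(3).upper() if m.group(3) else None
        v = HgvsVariant(DELETION, start, end, ref_base=listed)
        if listed is not None and len(listed) != v.span_length:
            raise HgvsParseError(
                f"listed deleted bases do not match span length in {text!r}"
            )
        return v

    m = _RE_DUP.match(body)
    if m:
        start = _int_pos(m.group(1))
        end = _int_pos(m.group(2)) if m.group(2) else None
        return HgvsVariant(DUPLICATION, start, end)

    raise HgvsParseError(f"cannot parse HGVS description: {text!r}")


def format_hgvs(v: HgvsVariant) -> str:
    """Render a variant back to its canonical HGVS c. string."""
    span = f"{v.start}" if v.end is None or v.end == v.start else f"{v.start}_{v.end}"
    if v.kind == SUBSTITUTION:
        return f"c.{v.start}{v.ref_base}>{v.insert}"
    if v.kind == DELETION:
        return f"c.{span}del"
    if v.kind == INSERTION:
        return f"c.{v.start}_{v.end}ins{v.insert}"
    if v.kind == DUPLICATION:
        return f"c.{span}dup"
    if v.kind == INVERSION:
        return f"c.{span}inv"
    if v.kind == DELINS:
        ins = v.insert if v.insert is not None else v.external_insert
        return f"c.{span}delins{ins}"
    raise AssertionError(v.kind)


def _c_to_index(pos: int, upstream_len: int) -> int:
    """Map a c. coordinate to a 0-based index in upstream_seq + cds_seq."""
    if pos == 0:
        raise HgvsParseError("position 0 does not exist")
    if pos > 0:
        return upstream_len + pos - 1
    return upstream_len + pos  # pos = -1 -> last upstream base


def apply_variant(cds, v: HgvsVariant) -> str:
    """Apply ``v`` to a :class:`~genoscreen.effects.CdsModel`.

    Returns the mutated ``upstream + CDS`` sequence with the upstream part
    still attached (slice with ``cds.upstream_len`` offsets if only the CDS
    is wanted).  Raises :class:`ReferenceMismatchError` when the variant's
    stated reference base disagrees with the sequence — this guards against
    off-by-one coordinate bugs.
    """
    full = cds.upstream_seq + cds.cds_seq
    up = len(cds.upstream_seq)
    i = _c_to_index(v.start, up)
    j = _c_to_index(v.span_end, up)
    if i < 0 or j >= len(full):
        raise ValueError(
            f"variant span c.{v.start}_{v.span_end} outside the modelled sequence"
        )

    if v.kind == SUBSTITUTION:
        if full[i] != v.ref_base:
            raise ReferenceMismatchError(
                f"reference base at c.{v.start} is {full[i]}, variant says {v.ref_base}"
            )
        return full[:i] + v.insert + full[i + 1 :]

    if v.kind == DELETION:
        if v.ref_base is not None and full[i : j + 1] != v.ref_base:
            raise ReferenceMismatchError(
                f"deleted bases at c.{v.start} are {full[i:j+1]}, variant says {v.ref_base}"
            )
        return full[:i] + full[j + 1 :]

    if v.kind == INSERTION:
        # insert between flanking positions start and end
        return full[: i + 1] + v.insert + full[i + 1 :]

    if v.kind == DUPLICATION:
        return full[: j + 1] + full[i : j + 1] + full[j + 1 :]

    if v.kind == INVERSION:
        return full[:i] + revcomp(full[i : j + 1]) + full[j + 1 :]

    if v.kind == DELINS:
        if v.insert is None:
            raise ExternalInsertError(
                f"cannot apply delins with unfetched external insert {v.external_insert!r}"
            )
        return full[:i] + v.insert + full[j + 1 :]

    raise AssertionError(v.kind)


def codons_spanned(v: HgvsVariant) -> tuple[int, int, int, bool]:
    """Codon range covered by the variant's CDS span.

    Returns ``(first_codon, last_codon, count, clipped)`` where codon of
    position p is ceil(p / 3) and ``clipped`` flags a span that extended into
    negative (upstream) coordinates and was restricted to its CDS part.
    """
    start, end = v.start, v.span_end
    clipped = False
    if end < 1:
        raise ValueError("variant span lies entirely upstream of the CDS")
    if start < 1:
        start = 1
        clipped = True
    first = (start + 2) // 3
    last = (end + 2) // 3
    return first, last, last - first + 1, clipped


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for k in range(n):
        if a[k] != b[k]:
            return k
    return n


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for k in range(1, n + 1):
        if a[-k] != b[-k]:
            return k - 1
    return n


def name_variant(ref_cds, mut_seq: str) -> Optional[HgvsVariant]:
    """Describe the single contiguous edit turning the reference CDS into
    ``mut_seq`` as an HGVS variant, 3'-shifted per the HGVS rule.

    Returns ``None`` when the sequences are identical.  Comparison is over
    CDS (positive) coordinates only.  Two clearly disjoint substitution loci
    raise :class:`MultipleEditsError`.
    """
    ref = ref_cds.cds_seq
    mut = mut_seq
    if ref == mut:
        return None

    # maximising the common prefix first yields the 3'-most representation
    p = _common_prefix_len(ref, mut)
    s = _common_suffix_len(ref[p:], mut[p:])
    ref_edit = ref[p : len(ref) - s]
    alt_edit = mut[p : len(mut) - s]

    if len(ref_edit) == len(alt_edit) == 1:
        return HgvsVariant(SUBSTITUTION, p + 1, None, ref_edit, alt_edit)

    if len(ref_edit) == len(alt_edit) and len(ref_edit) > 1:
        # same-length block: substitution run, inversion, or two disjoint edits
        mismatches = [k for k in range(len(ref_edit)) if ref_edit[k] != alt_edit[k]]
        gaps = [b - a for a, b in zip(mismatches, mismatches[1:])]
        if gaps and max(gaps) > 8:
            a = mismatches[0]
            b = mismatches[max(range(len(gaps)), key=gaps.__getitem__) + 1]
            raise MultipleEditsError(
                f"two disjoint edits detected at c.{p + 1 + a} and c.{p + 1 + b}"
            )
        if revcomp(ref_edit) == alt_edit:
            return HgvsVariant(INVERSION, p + 1, p + len(ref_edit))
        return HgvsVariant(DELINS, p + 1, p + len(ref_edit), insert=alt_edit)

    if not alt_edit:  # pure deletion
        start, end = p + 1, p + len(ref_edit)
        return HgvsVariant(DELETION, start, end if end > start else None)

    if not ref_edit:  # pure insertion; report duplications as dup
        ins = alt_edit
        if p >= len(ins) and ref[p - len(ins) : p] == ins:
            start, end = p - len(ins) + 1, p
            return HgvsVariant(DUPLICATION, start, end if end > start else None)
        if p == 0:
            raise ValueError("insertion before CDS base 1 cannot be named in c. CDS coordinates")
        return HgvsVariant(INSERTION, p, p + 1, insert=ins)

    return HgvsVariant(DELINS, p + 1, p + len(ref_edit), insert=alt_edit)
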