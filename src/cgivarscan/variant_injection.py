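"""Mapping variants into promoter windows and applying alleles.

Alleles in variant tables are taken to be reported on the + genomic
strand (the dbSNP convention).  When a promoter sequence is stored on
the − strand, ``inject_coordinates`` reverse-complements ref/alt and
mirrors the coordinate so the substitution lands on the stored string.

Deletion alleles use the explicit notation ``ref="TCCC..."``, ``alt="-"``
rather than VCF anchored-base style; the VCF reader in
:mod:`cgivarscan.io_formats` converts anchored records to this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cgi_detection import reverse_complement

_VALID = set("ACGTN")


class RefMismatchError(ValueError):
    """The promoter sequence does not carry the expected reference allele."""


@dataclass(frozen=True)
class Variant:
    """One allelic change anchored at a 1-based genomic position.

    ``pos_genomic`` is the position of the first reference base.  ``alt``
    may be ``"-"`` for a deletion.  ``kind`` is derived from the allele
    lengths: substitution, insertion, deletion or mnv.
    """

    rsid: str
    chrom: str
    pos_genomic: int
    ref: str
    alt: str
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos_genomic <= 0:
            raise ValueError(f"{self.rsid}: position must be positive")
        if not self.ref or set(self.ref.upper()) - _VALID:
            raise ValueError(f"{self.rsid}: bad ref allele {self.ref!r}")
        if self.alt != "-" and (not self.alt or set(self.alt.upper()) - _VALID):
            raise ValueError(f"{self.rsid}: bad alt allele {self.alt!r}")
        object.__setattr__(self, "ref", self.ref.upper())
        if self.alt != "-":
            object.__setattr__(self, "alt", self.alt.upper())
        object.__setattr__(self, "kind", self._derive_kind())

    def _derive_kind(self) -> str:
        alt = self.alt_effective
        if len(self.ref) == len(alt) == 1:
            return "substitution"
        if len(alt) > len(self.ref):
            return "insertion"
        if len(alt) < len(self.ref):
            return "deletion"
        return "mnv"

    @property
    def alt_effective(self) -> str:
        return "" if self.alt == "-" else self.alt

    @property
    def net_length_change(self) -> int:
        return len(self.alt_effective) - len(self.ref)


def genomic_to_local(promoter, pos_genomic: int) -> int:
    """Promoter-local 0-based offset of a 1-based genomic position.

    On the + strand offset 0 is ``tss - upstream_bp``; on the − strand
    the window is mirrored so offset 0 is ``tss + upstream_bp``.
    """
    if promoter.strand == "+":
        offset = pos_genomic - (promoter.tss_genomic - promoter.upstream_bp)
    else:
        offset = (promoter.tss_genomic + promoter.upstream_bp) - pos_genomic
    if not 0 <= offset < len(promoter.bases):
        raise ValueError(
            f"position {promoter.chrom}:{pos_genomic} outside promoter window "
            f"of {promoter.gene_symbol}"
        )
    return offset


def local_to_genomic(promoter, offset: int) -> int:
    """Inverse of :func:`genomic_to_local`."""
    if not 0 <= offset < len(promoter.bases):
        raise ValueError(f"offset {offset} outside promoter of {promoter.gene_symbol}")
    if promoter.strand == "+":
        return (promoter.tss_genomic - promoter.upstream_bp) + offset
    return (promoter.tss_genomic + promoter.upstream_bp) - offset


def is_cpg_site(seq: str, offset: int) -> bool:
    """True iff the base at ``offset`` is the C or the G of a CpG dinucleotide."""
    if not 0 <= offset < len(seq):
        raise IndexError(f"offset {offset} out of range for length {len(seq)}")
    seq = seq.upper()
    if seq[offset] == "C" and offset + 1 < len(seq) and seq[offset + 1] == "G":
        return True
    if seq[offset] == "G" and offset > 0 and seq[offset - 1] == "C":
        return True
    return False


def apply_variant(seq: str, offset: int, ref: str, alt: str) -> str:
    """Replace ``seq[offset:offset+len(ref)]`` (which must equal ``ref``) by ``alt``.

    ``alt == "-"`` deletes the reference bases.  Raises
    :class:`RefMismatchError` reporting expected vs observed bases.
    """
    ref = ref.upper()
    alt_eff = "" if alt == "-" else alt.upper()
    observed = seq[offset : offset + len(ref)].upper()
    if observed != ref:
        raise RefMismatchError(
            f"reference mismatch at offset {offset}: expected {ref!r}, found {observed!r}"
        )
    return seq[:offset] + alt_eff + seq[offset + len(ref) :]


def invert_variant(seq_variant: str, offset: int, ref: str, alt: str) -> str:
    """Undo an :func:`apply_variant` call (swap the roles of ref and alt)."""
    alt_eff = "" if alt == "-" else alt
    return apply_variant(seq_variant, offset, alt_eff, ref if ref else "-")


def inject_coordinates(promoter, variant: Variant) -> tuple[int, str, str]:
    """(local offset, ref, alt) for applying ``variant`` to ``promoter.bases``.

    A multi-base allele spans genomic positions ``pos..pos+len(ref)-1``;
    on a − strand promoter that genomic interval maps to local
    coordinates ending at the mirrored first base, and ref/alt are
    reverse-complemented.
    """
    if promoter.strand == "+":
        return genomic_to_local(promoter, variant.pos_genomic), variant.ref, variant.alt
    last = variant.pos_genomic + len(variant.ref) - 1
    offset = genomic_to_local(promoter, last)
    ref_rc = reverse_complement(variant.ref)
    alt_rc = "-" if variant.alt == "-" else reverse_complement(variant.alt)
    return offset, ref_rc, alt_rc


def apply_to_promoter(promoter, variant: Variant) -> tuple[str, int, str, str]:
    """Strand-aware injection: (variant sequence, local offset, ref, alt used)."""
    offset, ref, alt = inject_coordinates(promoter, variant)
    return apply_variant(promoter.bases, offset, ref, alt), offset, ref, alt
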