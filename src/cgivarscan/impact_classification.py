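"""Wild-type vs variant-allele island comparison.

For one (promoter, variant, allele) triple the classifier calls islands
on the wild sequence and on the sequence with the allele applied, keeps
the islands overlapping the variant locus (padded by one caller window
on each side — a single change cannot move an island boundary farther
than one window under the sliding-window caller), and labels the change:

======== ==============================================================
status   meaning
======== ==============================================================
unchanged  same island content on both sides (or no island on either)
abolished  an overlapping wild island, nothing on the variant side
gained     no wild island, a variant-side island appears
split      one wild island replaced by two or more variant islands
reduced    overlapping islands persist with smaller total size
enlarged   overlapping islands persist with larger total size (a merge
           of several wild islands is also reported here, with a note)
======== ==============================================================

For indels, variant-side island coordinates right of the locus are
shifted back by the net length change before the overlap comparison, so
wild and variant islands are compared in a common (wild) frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cgi_detection import CGIParams, CpGIsland, find_islands
from .io_formats import PromoterSequence, VariantTable
from .variant_injection import Variant, apply_to_promoter, is_cpg_site

logger = logging.getLogger(__name__)

STATUSES = ("unchanged", "reduced", "enlarged", "abolished", "split", "gained")


@dataclass(frozen=True)
class ImpactRecord:
    gene_symbol: str
    rsid: str
    allele: str
    locus_local: tuple[int, int]
    wild_islands: tuple[CpGIsland, ...]
    variant_islands: tuple[CpGIsland, ...]
    status: str
    wild_size_bp: int
    variant_sizes_bp: tuple[int, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "abolished":
            assert not self.variant_sizes_bp and self.wild_size_bp > 0
        if self.status == "split":
            assert len(self.variant_sizes_bp) >= 2
        if self.status == "gained":
            assert self.wild_size_bp == 0 and self.variant_sizes_bp

    @property
    def delta_bp(self) -> int:
        return sum(self.variant_sizes_bp) - self.wild_size_bp


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _shift_back(island: CpGIsland, locus_end_wild: int, net: int) -> tuple[int, int]:
    """Map a variant-frame island interval into the wild coordinate frame."""

    def back(v: int) -> int:
        if v <= locus_end_wild + min(net, 0):
            return v
        return v - net

    s, e = back(island.start), back(island.end)
    return min(s, e), max(s, max(e, s + 1))


def classify_variant(
    promoter: PromoterSequence,
    variant: Variant,
    params: CGIParams | None = None,
    allow_non_cpg: bool = False,
) -> ImpactRecord:
    """Compare island calls with and without one alternate allele."""
    params = params or CGIParams()
    variant_seq, offset, ref, alt = apply_to_promoter(promoter, variant)
    if variant.kind == "substitution" and not is_cpg_site(promoter.bases, offset):
        if not allow_non_cpg:
            raise ValueError(
                f"{variant.rsid}: position is not part of a CpG dinucleotide "
                "(pass allow_non_cpg=True to process anyway)"
            )
        logger.warning("%s: substitution outside a CpG site", variant.rsid)

    locus = (offset, offset + len(ref))
    pad = params.window_bp
    window = (locus[0] - pad, locus[1] + pad)
    net = variant.net_length_change

    wild = [i for i in find_islands(promoter.bases, params) if _overlaps((i.start, i.end), window)]
    variant_islands = []
    for isl in find_islands(variant_seq, params):
        back = _shift_back(isl, locus[1], net)
        if _overlaps(back, window):
            variant_islands.append(isl)

    wild_size = sum(i.size for i in wild)
    var_sizes = tuple(i.size for i in variant_islands)
    note = ""
    if not wild and not variant_islands:
        status = "unchanged"
    elif wild and not variant_islands:
        status = "abolished"
    elif not wild and variant_islands:
        status = "gained"
    elif len(wild) == 1 and len(variant_islands) >= 2:
        status = "split"
    else:
        if len(wild) >= 2 and len(variant_islands) == 1:
            note = "merge of wild islands"
        delta = sum(var_sizes) - wild_size
        status = "reduced" if delta < 0 else "enlarged" if delta > 0 else "unchanged"

    return ImpactRecord(
        gene_symbol=promoter.gene_symbol,
        rsid=variant.rsid,
        allele=f"{ref}>{alt}",
        locus_local=locus,
        wild_islands=tuple(wild),
        variant_islands=tuple(variant_islands),
        status=status,
        wild_size_bp=wild_size,
        variant_sizes_bp=var_sizes,
        note=note,
    )


@dataclass
class CohortResult:
    records: list[ImpactRecord] = field(default_factory=list)
    rejects: list[tuple[Variant, str]] = field(default_factory=list)


def classify_cohort(
    promoters: list[PromoterSequence],
    variant_table: VariantTable,
    params: CGIParams | None = None,
    allow_non_cpg: bool = False,
) -> CohortResult:
    """Classify every (variant, allele) against its containing promoter.

    A variant is assigned to the unique promoter whose genomic window on
    the same chromosome contains it; unmapped or ambiguous variants go to
    the rejects list rather than aborting the run.  Records are ordered
    by gene then genomic position.
    """
    params = params or CGIParams()
    result = CohortResult()
    for variant in variant_table:
        hosts = [
            p
            for p in promoters
            if p.chrom == variant.chrom and p.contains_genomic(variant.pos_genomic)
        ]
        if len(hosts) != 1:
            why = "no containing promoter" if not hosts else "ambiguous promoter"
            result.rejects.append((variant, why))
            continue
        try:
            result.records.append(
                classify_variant(hosts[0], variant, params, allow_non_cpg=allow_non_cpg)
            )
        except ValueError as exc:
            result.rejects.append((variant, str(exc)))
    order = {p.gene_symbol: i for i, p in enumerate(promoters)}
    result.records.sort(key=lambda r: (order.get(r.gene_symbol, 1 << 30), r.locus_local))
    return result


def records_to_frame(records: list[ImpactRecord]) -> pd.DataFrame:
    """Table-1-style report: one row per (variant, allele)."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene_symbol,
                "rsid": r.rsid,
                "allele": r.allele,
                "locus_start": r.locus_local[0],
                "locus_end": r.locus_local[1],
                "wild_status": "Present" if r.wild_size_bp else "Absent",
                "variant_status": r.status,
                "wild_size": r.wild_size_bp,
                "variant_sizes": ";".join(str(s) for s in r.variant_sizes_bp) or "0",
                "delta": r.delta_bp,
                "note": r.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "rsid",
            "allele",
            "locus_start",
            "locus_end",
            "wild_status",
            "variant_status",
            "wild_size",
            "variant_sizes",
            "delta",
            "note",
        ],
    )
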