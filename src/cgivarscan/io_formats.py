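"""File formats: promoter FASTA + metadata, variant tables, BED output, fixtures.

Internal coordinates are promoter-local, 0-based, half-open; the
external interfaces use 1-based inclusive genomic coordinates (variant
tables, metadata) and 0-based half-open coordinates (BED), the usual
VCF/BED split.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_injection import Variant, local_to_genomic

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class PromoterSequence:
    """A gene's promoter window around the TSS.

    The window is the closed genomic interval
    ``[tss - upstream_bp, tss + downstream_bp]`` including the TSS base,
    so the default −2000/+2000 window is 4001 bp long.  ``bases`` is the
    promoter-local string (0-based), on the strand declared in the
    metadata.
    """

    gene_symbol: str
    chrom: str
    strand: str
    tss_genomic: int
    bases: str
    upstream_bp: int = 2000
    downstream_bp: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_symbol}: strand must be '+' or '-'")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError(f"{self.gene_symbol}: window extents must be non-negative")
        expected = self.upstream_bp + self.downstream_bp + 1
        if len(self.bases) != expected:
            raise ValueError(
                f"{self.gene_symbol}: sequence length {len(self.bases)} does not match "
                f"window {self.upstream_bp}+{self.downstream_bp}+1 = {expected}"
            )
        bad = set(self.bases.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.gene_symbol}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())

    def contains_genomic(self, pos: int) -> bool:
        lo = self.tss_genomic - self.upstream_bp
        hi = self.tss_genomic + self.downstream_bp
        if self.strand == "-":
            lo = self.tss_genomic - self.downstream_bp
            hi = self.tss_genomic + self.upstream_bp
        return lo <= pos <= hi


@dataclass(frozen=True)
class VariantTable:
    records: tuple[Variant, ...]

    def __post_init__(self) -> None:
        # keep chromosome blocks in first-seen order, positions sorted within each
        chrom_rank = {}
        for v in self.records:
            chrom_rank.setdefault(v.chrom, len(chrom_rank))
        ordered = tuple(
            sorted(self.records, key=lambda v: (chrom_rank[v.chrom], v.pos_genomic))
        )
        object.__setattr__(self, "records", ordered)
        seen: set[tuple[str, int, str, str]] = set()
        for v in self.records:
            key = (v.rsid, v.pos_genomic, v.ref, v.alt)
            if key in seen:
                raise ValueError(f"duplicate variant record {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# promoter FASTA + sidecar metadata
# ---------------------------------------------------------------------------

_META_COLS = ["gene", "chrom", "strand", "tss", "upstream", "downstream"]


def read_promoter_fasta(path, metadata_path) -> list[PromoterSequence]:
    """Load promoters from a FASTA whose record IDs match the metadata ``gene`` column."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns {sorted(missing)}")
    meta = meta.set_index("gene", verify_integrity=True)
    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"no metadata row for FASTA record {rec.id!r}")
        row = meta.loc[rec.id]
        promoters.append(
            PromoterSequence(
                gene_symbol=rec.id,
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tss_genomic=int(row["tss"]),
                upstream_bp=int(row["upstream"]),
                downstream_bp=int(row["downstream"]),
                bases=str(rec.seq).upper(),
            )
        )
    return promoters


def write_promoter_fasta(promoters, path, metadata_path) -> None:
    records = [
        SeqRecord(Seq(p.bases), id=p.gene_symbol, description="") for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")
    meta = pd.DataFrame(
        [
            (p.gene_symbol, p.chrom, p.strand, p.tss_genomic, p.upstream_bp, p.downstream_bp)
            for p in promoters
        ],
        columns=_META_COLS,
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables (TSV and minimal VCF)
# ---------------------------------------------------------------------------


def read_variant_table(path) -> VariantTable:
    """TSV with columns rsid, chrom, pos, ref, alts (comma-separated; '-' = deletion).

    Multi-allelic rows expand into one :class:`Variant` per alternate
    allele, all sharing the rsid.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    required = {"rsid", "chrom", "pos", "ref", "alts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        for alt in str(row.alts).split(","):
            records.append(
                Variant(
                    rsid=row.rsid,
                    chrom=row.chrom,
                    pos_genomic=int(row.pos),
                    ref=str(row.ref),
                    alt=alt.strip(),
                )
            )
    return VariantTable(tuple(records))


def read_variant_vcf(path) -> VariantTable:
    """Minimal VCF reader: CHROM, POS, ID, REF, ALT only; INFO/FORMAT ignored.

    Anchored-base indels are converted to the explicit table notation:
    ``REF=GA ALT=G`` becomes a deletion of ``A`` at POS+1 with alt ``-``.
    Insertions sharing the anchor base (``REF=G ALT=GGCGGT``) are kept as
    printed in variant tables.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed VCF line: {line!r}")
            chrom, pos, vid, ref, alts = fields[:5]
            for alt in alts.split(","):
                records.append(_vcf_to_table_notation(vid, chrom, int(pos), ref, alt))
    return VariantTable(tuple(records))


def _vcf_to_table_notation(rsid, chrom, pos, ref, alt) -> Variant:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) > 1 and len(alt) >= 1 and ref.startswith(alt) and len(alt) < len(ref):
        # anchored deletion: drop the shared prefix
        return Variant(rsid, chrom, pos + len(alt), ref[len(alt) :], "-")
    return Variant(rsid, chrom, pos, ref, alt)


def write_variant_table(table: VariantTable, path) -> None:
    rows = []
    for v in table:
        rows.append((v.rsid, v.chrom, v.pos_genomic, v.ref, v.alt))
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alts"])
    # re-collapse shared (rsid, pos, ref) rows into comma-separated alts
    df = (
        df.groupby(["rsid", "chrom", "pos", "ref"], sort=False)["alts"]
        .agg(",".join)
        .reset_index()[["rsid", "chrom", "pos", "ref", "alts"]]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED output for islands
# ---------------------------------------------------------------------------


def island_genomic_interval(island, promoter: PromoterSequence) -> tuple[int, int]:
    """Half-open genomic interval covered by a promoter-local island.

    The interval is the per-base genomic mapping of the island written
    half-open: (smallest mapped position, largest mapped position + 1).
    On the + strand this is simply the local interval shifted by
    ``tss - upstream_bp``; on the − strand it is mirrored about the
    window.
    """
    if island.start < 0 or island.end > len(promoter.bases):
        raise ValueError("island outside promoter bounds")
    a = local_to_genomic(promoter, island.start)
    b = local_to_genomic(promoter, island.end - 1)
    lo, hi = min(a, b), max(a, b)
    return lo, hi + 1


def write_islands_bed(islands, promoter: PromoterSequence, path) -> None:
    """BED6 lines (chrom, start, end, gene, round(100*ObsExp), strand)."""
    with open(path, "w") as fh:
        for island in islands:
            start, end = island_genomic_interval(island, promoter)
            fh.write(
                f"{promoter.chrom}\t{start}\t{end}\t{promoter.gene_symbol}\t"
                f"{round(100 * island.obs_exp)}\t{promoter.strand}\n"
            )


def read_bed_intervals(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


# ---------------------------------------------------------------------------
# bundled study tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    sno: int
    gene_symbol: str
    island_label: str
    wild_island_size_bp: int
    rsid: str
    allele_change: str
    flag: str
    cpg_coordinate: str
    wild_status: str
    variant_status: str
    variant_sizes_bp: tuple[int, ...]


@dataclass(frozen=True)
class Table2Row:
    gene_symbol: str
    rsid: str
    allele_change: str
    flag: str
    wild_tfs: frozenset[str]
    variant_tfs: frozenset[str]

    @property
    def flagged_changed(self) -> bool:
        return self.wild_tfs != self.variant_tfs


def _data_path(name: str):
    return resources.files("cgivarscan.data").joinpath(name)


def load_table1_fixture(path=None) -> list[Table1Row]:
    """The 200-row study table: per-allele island status and sizes."""
    src = Path(path) if path is not None else _data_path("table1_snvs.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str).fillna("")
    rows = []
    for r in df.itertuples(index=False):
        sizes = tuple(int(x) for x in str(r.variant_sizes_bp).split(";"))
        rows.append(
            Table1Row(
                sno=int(r.sno),
                gene_symbol=r.gene,
                island_label=r.island,
                wild_island_size_bp=int(r.wild_size_bp),
                rsid=r.rsid,
                allele_change=r.allele,
                flag=r.flag,
                cpg_coordinate=r.coordinate,
                wild_status=r.wild_status,
                variant_status=r.variant_status,
                variant_sizes_bp=sizes,
            )
        )
    _check_table1(rows)
    return rows


def _check_table1(rows) -> None:
    if len(rows) != 200:
        raise ValueError(f"table 1 fixture must have 200 rows, found {len(rows)}")
    for row in rows:
        if row.wild_status != "Present":
            raise ValueError(f"row {row.sno}: wild status must be Present")
        if row.variant_status == "Abolished" and row.variant_sizes_bp != (0,):
            raise ValueError(f"row {row.sno}: abolished rows carry size 0")
        if row.variant_status == "Split" and len(row.variant_sizes_bp) < 2:
            raise ValueError(f"row {row.sno}: split rows need >= 2 sizes")
        if row.variant_status not in ("Present", "Abolished", "Split"):
            raise ValueError(f"row {row.sno}: unknown status {row.variant_status!r}")


def load_table2_fixture(path=None) -> list[Table2Row]:
    """The 17 island-abolishing variants with wild/variant TF predictions."""
    src = Path(path) if path is not None else _data_path("table2_tfs.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str).fillna("")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            Table2Row(
                gene_symbol=r.gene,
                rsid=r.rsid,
                allele_change=r.allele,
                flag=r.flag,
                wild_tfs=_tf_set(r.wild_tfs),
                variant_tfs=_tf_set(r.variant_tfs),
            )
        )
    if len(rows) != 17:
        raise ValueError(f"table 2 fixture must have 17 rows, found {len(rows)}")
    return rows


def _tf_set(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(x.strip() for x in cell.split(",") if x.strip())
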