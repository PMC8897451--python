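"""Synthetic promoters with planted, truth-labelled CpG-island variants.

The generator emulates the two compositional regimes the study design
rests on: CpG-depleted bulk promoter background, and embedded intervals
that satisfy the island-calling criteria with a controllable margin.
Planted variants come with an intended impact label (abolish / reduce /
split / enlarge / none) that is *guaranteed* by running the classifier
itself at generation time — closed-form guarantees are brittle at the
caller's merge/trim boundaries, so every emitted truth record has been
verified against :func:`cgivarscan.impact_classification.classify_variant`.

Constructions
-------------
* background — first-order Markov chain whose stationary GC equals the
  requested value exactly; the C→G transition probability is scaled by
  ``1 - cpg_depletion`` (the removed mass moves to C→C), which depletes
  CpG dinucleotides without touching GC content.
* generic island — an even interleave of ``CG`` and ``GC`` tokens in A/T
  filler, giving exact C, G and CpG counts (tokens never touch, so no
  accidental CpGs form at junctions).
* knife-edge island — a 101 bp block whose two possible 100 bp windows
  each hold exactly ``window/2 + 1`` G+C bases: one C→T substitution
  drops every window to 50 % GC, below the strict threshold, so the
  island is abolished.
* periodic island — a tile of exactly window length repeated n times;
  every window then has identical, marginal GC (51 of 100), so a single
  C→T kills precisely the windows covering it, truncating the island
  (edge hit → reduce) or cutting it in two (central hit → split).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cgi_detection import CGIParams, cpg_obs_exp, find_islands, gc_percent
from .impact_classification import classify_variant
from .io_formats import (
    PromoterSequence,
    VariantTable,
    write_promoter_fasta,
    write_variant_table,
)
from .variant_injection import Variant, is_cpg_site

LABELS = ("abolish", "reduce", "enlarge", "split", "none")

# expected classifier status per intended label
_LABEL_STATUS = {
    "abolish": "abolished",
    "reduce": "reduced",
    "enlarge": "enlarged",
    "split": "split",
    "none": "unchanged",
}


class ConstructionError(RuntimeError):
    """A planted construct could not be realised within the retry budget."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    planted_variants: tuple[tuple[str, int], ...]
    promoter_length: int = 4001
    background_gc: float = 0.40
    background_cpg_depletion: float = 0.75
    island_length_bp: int = 300
    island_gc: float = 0.65
    island_oe_margin: float = 0.15
    seed: int = 0
    params: CGIParams = field(default_factory=CGIParams)

    def __post_init__(self) -> None:
        for label, count in self.planted_variants:
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r}")
            if count < 0:
                raise ValueError("counts must be non-negative")
        if self.island_length_bp <= self.params.min_island_bp:
            raise ValueError("island_length_bp must exceed min_island_bp")
        if not 0 <= self.background_cpg_depletion <= 1:
            raise ValueError("cpg_depletion must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    rsid: str
    promoter_id: str
    offset: int
    ref: str
    alt: str
    intended_label: str
    construction_note: str


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def generate_background(length: int, gc: float, cpg_depletion: float, seed) -> str:
    """CpG-depleted random sequence with stationary GC exactly ``gc``.

    ``seed`` may be an int or a numpy Generator.  Every row of the chain
    sends the same total probability mass into {C, G}, so the stationary
    GC fraction equals ``gc`` regardless of the depletion level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    at, s = (1.0 - gc) / 2.0, gc / 2.0
    base_row = np.array([at, s, s, at])  # A C G T
    c_row = np.array([at, s + s * cpg_depletion, s * (1.0 - cpg_depletion), at])
    if length <= 0:
        return ""
    # draw all randomness up front for determinism independent of content
    u = rng.random(length)
    cum_base = np.cumsum(base_row)
    cum_c = np.cumsum(c_row)
    out = np.empty(length, dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    prev_is_c = False
    for i in range(length):
        cum = cum_c if prev_is_c else cum_base
        j = int(np.searchsorted(cum, u[i], side="right"))
        j = min(j, 3)
        out[i] = bases[j]
        prev_is_c = j == 1
    return out.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# island blocks
# ---------------------------------------------------------------------------


def _interleave_tokens(tokens: list[str], length: int, edge_gaps: bool = True) -> str:
    """Spread tokens evenly through A/T filler; >=1 filler base between
    tokens (and, with ``edge_gaps``, around them), so no CpG forms across
    token junctions.  With ``edge_gaps=False`` the first token starts at
    position 0 and the last token ends at the final position."""
    token_len = sum(len(t) for t in tokens)
    k = len(tokens)
    filler = length - token_len
    min_filler = k + 1 if edge_gaps else k - 1
    if filler < min_filler:
        raise ConstructionError(
            f"cannot interleave {k} tokens ({token_len} bases) into {length} bases"
        )
    if edge_gaps:
        gaps = [1] * (k + 1)
        extra = filler - (k + 1)
        for i in range(extra):
            gaps[i % (k + 1)] += 1
    else:
        gaps = [0] + [1] * (k - 1) + [0]
        extra = filler - (k - 1)
        for i in range(extra):
            gaps[1 + i % max(k - 1, 1)] += 1
    parts = []
    pos = 0

    def fill(n: int) -> str:
        nonlocal pos
        s = "".join("AT"[(pos + j) % 2] for j in range(n))
        pos += n
        return s

    for gap, token in zip(gaps, tokens + [""]):
        parts.append(fill(gap))
        parts.append(token)
        pos += len(token)
    return "".join(parts)[:length]


def _mix_tokens(primary: list[str], secondary: list[str]) -> list[str]:
    """Evenly merge two token streams (keeps CpG tokens spread out)."""
    out: list[str] = []
    n, m = len(primary), len(secondary)
    total = n + m
    pi = si = 0
    for i in range(total):
        # Bresenham-style: emit primary when its quota is due
        if pi * total <= i * n and pi < n:
            out.append(primary[pi])
            pi += 1
        elif si < m:
            out.append(secondary[si])
            si += 1
        else:
            out.append(primary[pi])
            pi += 1
    return out


def make_island_block(
    length: int,
    gc: float,
    oe_margin: float,
    params: CGIParams | None = None,
) -> str:
    """A block whose aggregate GC is within 0.02 of ``gc`` and whose
    Obs/Exp ratio is at least ``oe_min + oe_margin``; every base count is
    exact by construction and re-verified with the public statistics."""
    params = params or CGIParams()
    half_gc = int(round(gc * length / 2))
    target_oe = params.oe_min + oe_margin
    for bump in range(4):  # deterministic adjustment if verification fails
        n_cpg = int(np.floor(target_oe * half_gc**2 / length)) + 1 + bump
        if n_cpg > half_gc:
            break
        tokens = _mix_tokens(["CG"] * n_cpg, ["GC"] * (half_gc - n_cpg))
        block = _interleave_tokens(tokens, length)
        ok_gc = abs(gc_percent(block) / 100.0 - gc) <= 0.02
        ok_oe = cpg_obs_exp(block) > target_oe
        if ok_gc and ok_oe:
            return block
    raise ConstructionError(f"infeasible island parameters gc={gc}, oe_margin={oe_margin}")


def plant_island(
    seq: str,
    start: int,
    length: int,
    gc: float = 0.65,
    oe_margin: float = 0.15,
    params: CGIParams | None = None,
) -> str:
    """Replace ``seq[start:start+length]`` with a criterion-passing block."""
    if start < 0 or start + length > len(seq):
        raise ValueError("island placement outside sequence")
    block = make_island_block(length, gc, oe_margin, params)
    return seq[:start] + block + seq[start + length :]


def make_knife_edge_block(params: CGIParams | None = None) -> str:
    """Length window+1 block: both windows hold exactly window/2 + 1 GC
    bases, so removing a single G or C abolishes every qualifying window."""
    params = params or CGIParams()
    w = params.window_bp
    length = w + 1
    need_gc = w // 2 + 1  # strictly above 50 % in a w-bp window
    # tokens: a few CpGs for the Obs/Exp criterion, the rest as inert GC pairs
    n_cpg = 4
    n_pairs = (need_gc - 2 * n_cpg) // 2
    tokens = _mix_tokens(["CG"] * n_cpg, ["GC"] * n_pairs)
    singles = need_gc - 2 * n_cpg - 2 * n_pairs
    if singles:
        tokens.append("G" * singles)
    # G+C bases occupy exactly positions 1..length-2: the union of
    # qualifying windows is then the block itself and no trimming occurs
    interior = _interleave_tokens(tokens, length - 2, edge_gaps=False)
    block = "A" + interior + "T"
    assert len(block) == length
    return block


def make_periodic_block(n_tiles: int, params: CGIParams | None = None) -> str:
    """``n_tiles`` copies of a window-length tile with marginal GC.

    Each tile holds exactly window/2 + 1 G+C bases, so *every* window of
    the repeat has GC one base above threshold and a single C→T kills
    exactly the windows covering it.
    """
    params = params or CGIParams()
    w = params.window_bp
    need_gc = w // 2 + 1
    n_cpg = max(4, int(np.ceil(params.oe_min * (need_gc // 2) ** 2 / w)) + 2)
    n_pairs = (need_gc - 2 * n_cpg) // 2
    tokens = _mix_tokens(["CG"] * n_cpg, ["GC"] * n_pairs)
    singles = need_gc - 2 * n_cpg - 2 * n_pairs
    if singles:
        tokens.append("G" * singles)
    tile = _interleave_tokens(tokens, w)
    return tile * n_tiles


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


def _cpg_c_positions(seq: str, lo: int, hi: int) -> list[int]:
    return [i for i in range(lo, min(hi, len(seq) - 1)) if seq[i : i + 2] == "CG"]


def plant_variant(
    seq: str,
    label: str,
    params: CGIParams | None = None,
    seed: int = 0,
    promoter_id: str = "synthP",
    max_tries: int = 40,
) -> tuple[str, TruthRecord]:
    """Choose a variant in ``seq`` that the classifier provably assigns ``label``.

    The sequence is returned unchanged; the variant is described by the
    truth record.  Candidate sites are enumerated deterministically
    (seeded order) and each candidate is verified by running
    :func:`classify_variant`; a :class:`ConstructionError` names the
    label if no candidate within the try budget verifies.
    """
    params = params or CGIParams()
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    islands = find_islands(seq, params)

    candidates: list[tuple[int, str, str, str]] = []  # (offset, ref, alt, note)
    if label == "none":
        lo_band = [
            i
            for i in range(params.window_bp, len(seq) - params.window_bp)
            if seq[i] in "AT"
            and not any(
                isl.start - params.window_bp < i < isl.end + params.window_bp
                for isl in islands
            )
        ]
        rng.shuffle(lo_band)
        for i in lo_band[:max_tries]:
            candidates.append((i, seq[i], "T" if seq[i] == "A" else "A", "background A/T swap"))
    elif label == "enlarge":
        for isl in islands:
            mid = (isl.start + isl.end) // 2
            for off in range(0, 30):
                for i in (mid + off, mid - off):
                    if isl.start < i < isl.end - 1 and seq[i] in "AT":
                        candidates.append(
                            (i, seq[i], seq[i] + "GCGGC", "mid-island GC-rich insertion")
                        )
    else:
        for isl in sorted(islands, key=lambda x: x.size):
            cs = _cpg_c_positions(seq, isl.start, isl.end)
            if not cs:
                continue
            if label == "abolish":
                order = cs
            elif label == "reduce":
                # edge-proximal CpGs first
                order = sorted(cs, key=lambda i: min(i - isl.start, isl.end - i))
            else:  # split: central CpGs first
                order = sorted(cs, key=lambda i: abs(i - (isl.start + isl.end) // 2))
            for i in order:
                candidates.append((i, "C", "T", f"CpG C>T in island [{isl.start},{isl.end})"))

    want = _LABEL_STATUS[label]
    tried = 0
    for offset, ref, alt, note in candidates:
        if tried >= max_tries:
            break
        tried += 1
        promoter = _as_promoter(seq, promoter_id)
        variant = Variant(
            rsid=f"synth:{label}:{promoter_id}",
            chrom=promoter.chrom,
            pos_genomic=promoter.tss_genomic - promoter.upstream_bp + offset,
            ref=ref,
            alt=alt,
        )
        record = classify_variant(promoter, variant, params, allow_non_cpg=True)
        if record.status == want:
            if label in ("abolish", "reduce", "split") and not is_cpg_site(seq, offset):
                continue
            return seq, TruthRecord(
                rsid=variant.rsid,
                promoter_id=promoter_id,
                offset=offset,
                ref=ref,
                alt=alt,
                intended_label=label,
                construction_note=note,
            )
    raise ConstructionError(f"could not realise label {label!r} within {max_tries} tries")


def _as_promoter(seq: str, promoter_id: str, chrom: str | None = None) -> PromoterSequence:
    half = (len(seq) - 1) // 2
    return PromoterSequence(
        gene_symbol=promoter_id,
        chrom=chrom or f"chr_{promoter_id}",
        strand="+",
        tss_genomic=1_000_000,
        upstream_bp=half,
        downstream_bp=len(seq) - 1 - half,
        bases=seq,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

_PAD = 150  # A/T quiet zone around planted constructs
_ISLAND_START = 1200


def _build_promoter_sequence(label: str, spec: SyntheticSpec, seed: int) -> str:
    params = spec.params
    seq = generate_background(
        spec.promoter_length, spec.background_gc, spec.background_cpg_depletion, seed
    )

    def at_fill(n: int, phase: int = 0) -> str:
        return "".join("AT"[(phase + j) % 2] for j in range(n))

    if label == "abolish":
        block = make_knife_edge_block(params)
    elif label == "reduce":
        block = make_periodic_block(max(3, spec.island_length_bp // params.window_bp), params)
    elif label == "split":
        block = make_periodic_block(
            max(4, -(-2 * (params.min_island_bp + 10) // params.window_bp)), params
        )
    else:  # enlarge / none both get a generic island (distal for 'none')
        block = make_island_block(spec.island_length_bp, spec.island_gc, spec.island_oe_margin, params)

    s = _ISLAND_START
    seq = (
        seq[: s - _PAD]
        + at_fill(_PAD)
        + block
        + at_fill(_PAD, phase=1)
        + seq[s + len(block) + _PAD :]
    )
    if label == "none":
        # quiet A/T stretch well away from the island for the background variant
        q = 3000
        seq = seq[: q - _PAD] + at_fill(2 * _PAD + 1) + seq[q + _PAD + 1 :]
    assert len(seq) == spec.promoter_length
    return seq


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[PromoterSequence], VariantTable, list[TruthRecord]]:
    """One promoter per planted variant; every truth label verified.

    Fully deterministic for a given spec (including its seed): promoter
    backgrounds, construct placement and candidate ordering all derive
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    promoters: list[PromoterSequence] = []
    variants: list[Variant] = []
    truths: list[TruthRecord] = []
    idx = 0
    for label, count in spec.planted_variants:
        for _ in range(count):
            pid = f"synthP{idx:04d}"
            base_seed = int(rng.integers(0, 2**31 - 1))
            last_err: Exception | None = None
            for attempt in range(6):
                try:
                    seq = _build_promoter_sequence(label, spec, base_seed + 10007 * attempt)
                    _, truth = plant_variant(
                        seq, label, spec.params, seed=base_seed + attempt, promoter_id=pid
                    )
                    break
                except ConstructionError as exc:  # pragma: no cover - retry path
                    last_err = exc
            else:  # pragma: no cover
                raise ConstructionError(f"label {label!r}: {last_err}")
            promoter = _as_promoter(seq, pid, chrom=f"chrS{idx:04d}")
            promoters.append(promoter)
            variants.append(
                Variant(
                    rsid=truth.rsid,
                    chrom=promoter.chrom,
                    pos_genomic=promoter.tss_genomic - promoter.upstream_bp + truth.offset,
                    ref=truth.ref,
                    alt=truth.alt,
                )
            )
            truths.append(truth)
            idx += 1
    return promoters, VariantTable(tuple(variants)), truths


def write_dataset(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Generate and write FASTA + metadata + variant + truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    promoters, table, truths = generate_dataset(spec)
    paths = {
        "fasta": out / "promoters.fa",
        "metadata": out / "promoters_meta.tsv",
        "variants": out / "variants.tsv",
        "truth": out / "truth.tsv",
    }
    write_promoter_fasta(promoters, paths["fasta"], paths["metadata"])
    write_variant_table(table, paths["variants"])
    pd.DataFrame(
        [
            (t.rsid, t.promoter_id, t.offset, t.ref, t.alt, t.intended_label, t.construction_note)
            for t in truths
        ],
        columns=["rsid", "promoter_id", "offset", "ref", "alt", "intended_label", "note"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
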