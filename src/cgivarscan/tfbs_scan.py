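"""PWM scanning of wild and variant alleles for transcription-factor differences.

A motif is a 4 x w count matrix (rows A, C, G, T).  Scoring uses the
standard log-odds transform

    lo[b, j] = log2( (counts[b, j] + pseudocount) / column_total / background[b] )

and a hit is reported where the summed log-odds over a window reaches a
fraction ``threshold_frac`` of the motif's maximum achievable score.
Differential scanning compares the TF-name sets hitting the variant
locus in the wild and variant sequences and reports gains and losses.

Motif libraries load from JASPAR count format or MEME minimal format via
Bio.motifs; a small bundled library (including an Sp1-like GC-box) backs
the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio import motifs as bio_motifs

from .cgi_detection import reverse_complement

ALPHABET = "ACGT"


@dataclass(frozen=True)
class PWM:
    name: str
    counts: np.ndarray  # shape (4, w), rows in A,C,G,T order
    pseudocount: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"{self.name}: counts must be 4 x w")
        if counts.shape[1] < 4:
            raise ValueError(f"{self.name}: motif width must be >= 4")
        if (counts < 0).any():
            raise ValueError(f"{self.name}: negative counts")
        if not np.isclose(sum(self.background), 1.0):
            raise ValueError(f"{self.name}: background must sum to 1")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        adjusted = self.counts + self.pseudocount
        freqs = adjusted / adjusted.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float)[:, None]
        return np.log2(freqs / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=0))

    def score(self, kmer: str) -> float:
        """Log-odds of one sequence of exactly the motif width."""
        if len(kmer) != self.width:
            raise ValueError(f"{self.name}: expected {self.width}-mer")
        lo = self.log_odds
        idx = [ALPHABET.index(b) for b in kmer.upper()]
        return float(sum(lo[b, j] for j, b in enumerate(idx)))


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    start: int
    strand: str
    score: float
    rel_score: float


def read_pwms(path) -> list[PWM]:
    """Load motifs from a JASPAR count file or a MEME minimal file."""
    with open(path) as fh:
        head = fh.read(2048)
    fmt = "minimal" if "MEME version" in head else "jaspar"
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, fmt):
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            name = m.name or getattr(m, "matrix_id", None) or "motif"
            out.append(PWM(name=str(name), counts=counts))
    return out


def bundled_motifs() -> list[PWM]:
    """The small motif library shipped with the package."""
    path = resources.files("cgivarscan.data").joinpath("toy_motifs.jaspar")
    with resources.as_file(path) as p:
        return read_pwms(p)


def _scan_one_strand(seq: str, pwm: PWM) -> np.ndarray:
    """Log-odds score at every start position (vectorised over positions)."""
    w = pwm.width
    n = len(seq) - w + 1
    if n <= 0:
        return np.empty(0)
    codes = np.full(len(seq), -1, dtype=np.int64)
    for i, b in enumerate(ALPHABET):
        codes[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    lo = pwm.log_odds
    # N or other bases contribute the background-neutral score 0
    lo_ext = np.vstack([lo, np.zeros((1, w))])
    codes = np.where(codes < 0, 4, codes)
    idx = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo_ext[idx, np.arange(w)].sum(axis=1)


def scan_window(
    seq: str,
    pwms: list[PWM],
    threshold_frac: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All motif hits in ``seq`` with relative score >= ``threshold_frac``.

    Reverse-strand hits are reported at the forward-strand start of the
    matched interval.  Hits come back sorted by position.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    hits: list[MotifHit] = []
    for pwm in pwms:
        w = pwm.width
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        for strand, s in strands:
            scores = _scan_one_strand(s, pwm)
            for pos in np.nonzero(scores >= threshold_frac * pwm.max_score)[0]:
                start = int(pos) if strand == "+" else len(seq) - w - int(pos)
                hits.append(
                    MotifHit(
                        tf_name=pwm.name,
                        start=start,
                        strand=strand,
                        score=float(scores[pos]),
                        rel_score=float(scores[pos]) / pwm.max_score,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.tf_name, h.strand))
    return hits


@dataclass(frozen=True)
class TFDiffRecord:
    rsid: str
    wild_tfs: frozenset[str]
    variant_tfs: frozenset[str]

    @property
    def gained(self) -> frozenset[str]:
        return self.variant_tfs - self.wild_tfs

    @property
    def lost(self) -> frozenset[str]:
        return self.wild_tfs - self.variant_tfs

    @property
    def changed(self) -> bool:
        return self.wild_tfs != self.variant_tfs


def _tfs_overlapping_locus(
    seq: str, locus: tuple[int, int], flank: int, pwms, threshold_frac
) -> frozenset[str]:
    lo = max(0, locus[0] - flank)
    hi = min(len(seq), locus[1] + flank)
    window = seq[lo:hi]
    names = set()
    for pwm in pwms:
        for hit in scan_window(window, [pwm], threshold_frac):
            s = lo + hit.start
            if s < locus[1] and locus[0] < s + pwm.width:
                names.add(pwm.name)
    return frozenset(names)


def differential_hits(
    wild_seq: str,
    variant_seq: str,
    locus: tuple[int, int],
    pwms: list[PWM],
    threshold_frac: float = 0.8,
    flank: int = 20,
    net_length_change: int = 0,
    rsid: str = "",
) -> TFDiffRecord:
    """TF sets hitting the variant locus in the wild and variant sequences.

    ``locus`` is in wild coordinates, ``[offset, offset + len(ref))``;
    on the variant side the locus end moves by ``net_length_change``.
    """
    wild_tfs = _tfs_overlapping_locus(wild_seq, locus, flank, pwms, threshold_frac)
    var_locus = (locus[0], max(locus[0] + 1, locus[1] + net_length_change))
    variant_tfs = _tfs_overlapping_locus(variant_seq, var_locus, flank, pwms, threshold_frac)
    return TFDiffRecord(rsid=rsid, wild_tfs=wild_tfs, variant_tfs=variant_tfs)
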