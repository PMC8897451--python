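"""Sliding-window CpG-island calling.

A CpG island (CGI) is called operationally: an interval longer than
``min_island_bp`` whose GC percentage strictly exceeds ``gc_min_percent``
and whose observed/expected CpG-dinucleotide ratio strictly exceeds
``oe_min``.  The Obs/Exp ratio is the classical composition-normalised
statistic

    ObsExp = (#CpG * L) / (#C * #G)

with the convention that the ratio is 0 when the sequence contains no C
or no G (such a window holds no CpG and cannot qualify).

The caller is deterministic: qualifying fixed-width windows are merged
into candidate intervals, each candidate is verified in aggregate, and a
candidate that fails in aggregate is trimmed one base at a time from the
end whose removal improves the failing statistic most (an exact tie
trims one base from each end, which keeps the caller invariant under
reverse complementation) until it passes or becomes too short.  ``N``
bases count toward interval length but never toward G+C or CpG content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class CGIParams:
    """Thresholds and window mechanics for island calling.

    All three criteria are strict inequalities: a 100 bp candidate at
    ``min_island_bp=100`` is rejected, as is a window at exactly 50.0 %
    GC or Obs/Exp exactly 0.60.
    """

    min_island_bp: int = 100
    gc_min_percent: float = 50.0
    oe_min: float = 0.60
    window_bp: int = 100
    step_bp: int = 1

    def __post_init__(self) -> None:
        if self.window_bp < 10:
            raise ValueError("window_bp must be >= 10")
        if self.step_bp < 1:
            raise ValueError("step_bp must be >= 1")
        for name in ("min_island_bp", "gc_min_percent", "oe_min"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")


@dataclass(frozen=True)
class CpGIsland:
    """A called island in promoter-local 0-based half-open coordinates."""

    start: int
    end: int
    gc_percent: float
    obs_exp: float
    n_cpg: int

    @property
    def size(self) -> int:
        return self.end - self.start


def gc_percent(seq: str) -> float:
    """GC percentage of ``seq`` in [0, 100]; N counts toward length only."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * (seq.count("C") + seq.count("G")) / len(seq)


def cpg_obs_exp(seq: str) -> float:
    """Observed/expected CpG ratio; 0 when the sequence has no C or no G."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (n_c * n_g)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        bad = chr(arr[int(np.argmax(out < 0))])
        raise ValueError(f"illegal character {bad!r} in sequence")
    return out


def _prefix_counts(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prefix sums of C, G and CpG-start indicators (CpG at i means seq[i:i+2]=='CG')."""
    code = _encode(seq)
    is_c = (code == 1).astype(np.int64)
    is_g = (code == 2).astype(np.int64)
    cpg = np.zeros(len(code), dtype=np.int64)
    if len(code) >= 2:
        cpg[:-1] = (code[:-1] == 1) & (code[1:] == 2)
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(cpg)]),
    )


def _interval_stats(
    s: int, e: int, pc: np.ndarray, pg: np.ndarray, pcpg: np.ndarray
) -> tuple[float, float, int]:
    """(gc_percent, obs_exp, n_cpg) of [s, e) from prefix sums."""
    length = e - s
    n_c = int(pc[e] - pc[s])
    n_g = int(pg[e] - pg[s])
    # CpG dinucleotides fully inside the interval start in [s, e-1)
    n_cpg = int(pcpg[e - 1] - pcpg[s]) if length >= 2 else 0
    gc = 100.0 * (n_c + n_g) / length
    oe = 0.0 if n_c == 0 or n_g == 0 else n_cpg * length / (n_c * n_g)
    return gc, oe, n_cpg


def qualifying_windows(seq: str, params: CGIParams | None = None) -> list[tuple[int, int]]:
    """Start/end pairs of fixed-width windows passing both composition criteria."""
    params = params or CGIParams()
    w, step = params.window_bp, params.step_bp
    if len(seq) < w:
        return []
    pc, pg, pcpg = _prefix_counts(seq)
    starts = np.arange(0, len(seq) - w + 1, step)
    n_c = pc[starts + w] - pc[starts]
    n_g = pg[starts + w] - pg[starts]
    n_cpg = pcpg[starts + w - 1] - pcpg[starts]
    gc = 100.0 * (n_c + n_g) / w
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * w / np.maximum(denom, 1), 0.0)
    ok = (gc > params.gc_min_percent) & (oe > params.oe_min)
    return [(int(s), int(s) + w) for s in starts[ok]]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals (input need not be sorted)."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def candidate_intervals(seq: str, params: CGIParams | None = None) -> list[tuple[int, int]]:
    """Pre-trim candidates: the merged union of qualifying windows."""
    return merge_intervals(qualifying_windows(seq, params))


def _trim(
    s: int, e: int, params: CGIParams, pc: np.ndarray, pg: np.ndarray, pcpg: np.ndarray
) -> tuple[int, int] | None:
    """Shrink [s, e) until both aggregate criteria pass; None if it cannot."""

    def failing(gc: float, oe: float) -> str | None:
        if gc <= params.gc_min_percent:
            return "gc"
        if oe <= params.oe_min:
            return "oe"
        return None

    gc, oe, _ = _interval_stats(s, e, pc, pg, pcpg)
    while failing(gc, oe) is not None and (e - s) > params.min_island_bp + 1:
        stat = failing(gc, oe)
        gc_l, oe_l, _ = _interval_stats(s + 1, e, pc, pg, pcpg)
        gc_r, oe_r, _ = _interval_stats(s, e - 1, pc, pg, pcpg)
        left_val, right_val = (gc_l, gc_r) if stat == "gc" else (oe_l, oe_r)
        if left_val > right_val:
            s += 1
            gc, oe = gc_l, oe_l
        elif right_val > left_val:
            e -= 1
            gc, oe = gc_r, oe_r
        else:
            # exact tie (common when both ends are A/T): trim both ends —
            # the only deterministic choice that keeps island calls
            # invariant under reverse complementation
            s += 1
            e -= 1
            gc, oe, _ = _interval_stats(s, e, pc, pg, pcpg)
    if failing(gc, oe) is None and (e - s) > params.min_island_bp:
        return s, e
    return None


def find_islands(seq: str, params: CGIParams | None = None) -> list[CpGIsland]:
    """Call CpG islands in ``seq``.

    Returns sorted, disjoint, non-adjacent islands; every island strictly
    passes all three criteria recomputed on its own substring.
    """
    params = params or CGIParams()
    if len(seq) < params.window_bp:
        return []
    candidates = candidate_intervals(seq, params)
    if not candidates:
        return []
    pc, pg, pcpg = _prefix_counts(seq)
    islands: list[CpGIsland] = []
    for s, e in candidates:
        trimmed = _trim(s, e, params, pc, pg, pcpg)
        if trimmed is None:
            continue
        ts, te = trimmed
        gc, oe, n_cpg = _interval_stats(ts, te, pc, pg, pcpg)
        islands.append(CpGIsland(ts, te, gc, oe, n_cpg))
    return islands


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_RC)[::-1]


def islands_strand_symmetric(seq: str, params: CGIParams | None = None) -> bool:
    """True iff island calls on the reverse complement mirror the forward calls.

    Holds for ``step_bp == 1`` because GC content, CpG count and the
    window lattice are all invariant under reverse complementation.
    """
    fwd = find_islands(seq, params)
    rev = find_islands(reverse_complement(seq), params)
    n = len(seq)
    mirrored = sorted((n - i.end, n - i.start) for i in rev)
    return [(i.start, i.end) for i in fwd] == mirrored
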