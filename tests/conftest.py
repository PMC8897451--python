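import numpy as np
import pytest

from cgivarscan import CGIParams, PromoterSequence
from cgivarscan.cgi_detection import merge_intervals


@pytest.fixture
def params():
    return CGIParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_sequence(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_promoter(bases, gene="GENE", chrom="chr1", strand="+", tss=1_000_000):
    half = (len(bases) - 1) // 2
    return PromoterSequence(
        gene_symbol=gene,
        chrom=chrom,
        strand=strand,
        tss_genomic=tss,
        upstream_bp=half,
        downstream_bp=len(bases) - 1 - half,
        bases=bases,
    )


def brute_force_candidates(seq, params):
    """Independent window-enumeration oracle: qualify every window by direct
    substring statistics, then merge overlapping/adjacent windows."""
    w = params.window_bp
    wins = []
    for s in range(0, len(seq) - w + 1, params.step_bp):
        sub = seq[s : s + w]
        n_c, n_g = sub.count("C"), sub.count("G")
        gc = 100.0 * (n_c + n_g) / w
        oe = 0.0 if n_c == 0 or n_g == 0 else sub.count("CG") * w / (n_c * n_g)
        if gc > params.gc_min_percent and oe > params.oe_min:
            wins.append((s, s + w))
    return merge_intervals(wins)
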