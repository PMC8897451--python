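"""Synthetic promoter generator: background statistics, constructs, determinism."""

import numpy as np
import pytest

from cgivarscan import (
    CGIParams,
    SyntheticSpec,
    cpg_obs_exp,
    find_islands,
    gc_percent,
    generate_background,
    generate_dataset,
    plant_island,
    plant_variant,
    write_dataset,
)
from cgivarscan.synthetic_data import (
    ConstructionError,
    make_island_block,
    make_knife_edge_block,
    make_periodic_block,
)


def test_background_zero_gc_is_at_only():
    seq = generate_background(2000, 0.0, 0.75, seed=1)
    assert set(seq) <= {"A", "T"}


def test_background_deterministic():
    assert generate_background(5000, 0.4, 0.75, seed=7) == generate_background(
        5000, 0.4, 0.75, seed=7
    )
    assert generate_background(5000, 0.4, 0.75, seed=7) != generate_background(
        5000, 0.4, 0.75, seed=8
    )


def test_background_composition_statistics():
    """10 kb at the default study conditions: GC within 0.40 +/- 0.03 and
    a clearly CpG-depleted Obs/Exp ratio (< 0.5)."""
    seq = generate_background(10_000, 0.40, 0.75, seed=123)
    assert abs(gc_percent(seq) / 100 - 0.40) <= 0.03
    assert cpg_obs_exp(seq) < 0.5


def test_background_without_depletion_is_near_independent():
    seq = generate_background(20_000, 0.5, 0.0, seed=5)
    assert 0.85 < cpg_obs_exp(seq) < 1.15


def test_island_block_satisfies_criteria(params):
    block = make_island_block(300, 0.65, 0.15, params)
    assert abs(gc_percent(block) / 100 - 0.65) <= 0.02
    assert cpg_obs_exp(block) > params.oe_min + 0.15
    islands = find_islands(block, params)
    assert len(islands) == 1 and islands[0].size > params.min_island_bp


def test_plant_island_in_background(params):
    seq = generate_background(2000, 0.4, 0.75, seed=9)
    seq = plant_island(seq, 800, 300, 0.65, 0.15, params)
    islands = find_islands(seq, params)
    assert any(i.start < 1100 and i.end > 800 for i in islands)


def test_plant_island_bounds_checked():
    with pytest.raises(ValueError):
        plant_island("A" * 100, 50, 100)


def test_infeasible_island_parameters_raise():
    with pytest.raises(ConstructionError):
        make_island_block(120, 0.95, 0.15)  # too GC-dense to interleave


def test_knife_edge_block_is_knife_edged(params):
    """The construct passes every criterion, but removing one C drops every
    window to exactly 50 % GC, below the strict threshold."""
    block = make_knife_edge_block(params)
    assert len(block) == params.window_bp + 1
    assert find_islands(block, params)
    i = block.index("CG")
    broken = block[:i] + "T" + block[i + 1 :]
    assert find_islands(broken, params) == []


def test_periodic_block_windows_are_marginal(params):
    block = make_periodic_block(3, params)
    w = params.window_bp
    counts = {
        block[s : s + w].count("C") + block[s : s + w].count("G")
        for s in range(len(block) - w + 1)
    }
    assert counts == {w // 2 + 1}


def test_two_planted_islands_found_separately(params):
    seq = "A" * 250 + make_island_block(300, 0.65, 0.15) + "T" * 250 + make_island_block(
        300, 0.65, 0.15
    ) + "A" * 250
    assert len(find_islands(seq, params)) == 2


@pytest.mark.parametrize("label", ["abolish", "reduce", "split", "enlarge", "none"])
def test_plant_variant_unknown_on_hostile_sequence(label):
    # no island, no CpG: every label except 'none' must fail loudly
    seq = "AT" * 1000 + "A"
    if label == "none":
        _, truth = plant_variant(seq, label, seed=0)
        assert truth.intended_label == "none"
    else:
        with pytest.raises(ConstructionError, match=label):
            plant_variant(seq, label, seed=0, max_tries=3)


def test_generate_dataset_counts_and_verified_labels():
    spec = SyntheticSpec(
        planted_variants=(("abolish", 5), ("reduce", 5), ("split", 3), ("none", 5)),
        seed=3,
    )
    promoters, table, truths = generate_dataset(spec)
    assert len(promoters) == len(truths) == 18
    assert len(table) == 18
    assert all(t.rsid.startswith("synth:") for t in truths)
    labels = sorted(t.intended_label for t in truths)
    assert labels == sorted(["abolish"] * 5 + ["reduce"] * 5 + ["split"] * 3 + ["none"] * 5)


def test_dataset_bytes_deterministic(tmp_path):
    spec = SyntheticSpec(planted_variants=(("abolish", 2), ("none", 2)), seed=17)
    a = write_dataset(spec, tmp_path / "a")
    b = write_dataset(spec, tmp_path / "b")
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes(), key


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(planted_variants=(("bogus", 1),))
    with pytest.raises(ValueError):
        SyntheticSpec(planted_variants=(("none", -1),))
    with pytest.raises(ValueError):
        SyntheticSpec(planted_variants=(("none", 1),), island_length_bp=90)
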