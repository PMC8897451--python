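"""Aggregation of impact rows and the end-to-end run."""

import numpy as np
import pytest

from cgivarscan import (
    SyntheticSpec,
    fixture_summary,
    load_table1_fixture,
    load_table2_fixture,
    per_gene_summary,
    run_pipeline,
    summarize,
    write_dataset,
)
from cgivarscan.summary_pipeline import load_config, round_half_up, summary_frame


def test_round_half_up():
    assert round_half_up(8.45) == 8.5
    assert round_half_up(58.823529) == 58.8
    assert round_half_up(34.95) == 35.0


def test_fixture_totals():
    stats = fixture_summary()
    assert stats.n_total == 200
    assert stats.n_abolished == 17 and stats.pct_abolished == 8.5
    assert stats.n_size_changed == 70 and stats.pct_size_changed == 35.0


def test_fixture_tf_change_counts():
    stats = fixture_summary()
    assert stats.n_tf_changed == 10
    assert stats.pct_tf_changed_of_abolished == 58.8  # displayed as 59 %


def test_fixture_per_gene_counts():
    stats = fixture_summary()
    pg = stats.per_gene
    assert pg["LDLR"].n_abolished == 5 and pg["LDLR"].pct_abolished == 31
    assert pg["LDLR"].n_size_changed == 7 and pg["LDLR"].pct_size_changed == 44
    assert pg["MMP9"].n_abolished == 5
    assert pg["TIMP1"].n_abolished == 4 and pg["TIMP1"].pct_abolished == 67
    assert pg["SH2B3"].n_abolished == 2
    assert pg["APOE"].n == 1 and pg["APOE"].n_abolished == 1


def test_per_gene_zero_changes():
    rows = [r for r in load_table1_fixture() if r.gene_symbol == "KSR2"]
    frame = per_gene_summary(rows)
    ksr2 = frame.set_index("gene").loc["KSR2"]
    assert ksr2["n_abolished"] == 0 and ksr2["pct_abolished"] == 0


def test_summarize_permutation_invariant(rng):
    rows = load_table1_fixture()
    shuffled = list(rows)
    rng.shuffle(shuffled)
    a, b = summarize(rows), summarize(shuffled)
    assert a.n_abolished == b.n_abolished
    assert a.pct_size_changed == b.pct_size_changed
    assert a.per_gene == b.per_gene


def test_summarize_empty_rejected():
    with pytest.raises(ValueError):
        summarize([])


def test_status_counts_sum_to_total():
    s = fixture_summary()
    assert (
        s.n_abolished + s.n_reduced + s.n_enlarged + s.n_split + s.n_gained + s.n_unchanged
        == s.n_total
    )


def test_config_defaults_and_override(tmp_path):
    cfg = load_config()
    assert cfg["cgi"]["window_bp"] == 100
    custom = tmp_path / "c.yaml"
    custom.write_text("cgi:\n  oe_min: 0.65\ntfbs:\n  flank: 30\n")
    cfg = load_config(custom)
    assert cfg["cgi"]["oe_min"] == 0.65 and cfg["cgi"]["min_island_bp"] == 100
    assert cfg["tfbs"]["flank"] == 30 and cfg["tfbs"]["threshold_frac"] == 0.8


@pytest.fixture(scope="module")
def synthetic_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("pipeline")
    spec = SyntheticSpec(
        planted_variants=(("abolish", 3), ("reduce", 3), ("none", 2)), seed=17
    )
    paths = write_dataset(spec, root / "data")
    return root, paths


def test_run_pipeline_end_to_end(synthetic_run):
    root, paths = synthetic_run
    cohort, tf_records, stats = run_pipeline(
        paths["fasta"],
        paths["metadata"],
        paths["variants"],
        root / "out",
        config={"allow_non_cpg": True},
    )
    assert len(cohort.records) == 8 and not cohort.rejects
    assert stats.n_abolished == 3 and stats.n_reduced == 3 and stats.n_unchanged == 2
    assert tf_records == []  # no motif file: TF step skipped
    assert stats.n_tf_changed == 0
    for name in ("impact_records.tsv", "summary.tsv", "per_gene.tsv", "rejects.tsv"):
        assert (root / "out" / name).exists()


def test_run_pipeline_reproducible_reports(synthetic_run):
    root, paths = synthetic_run
    outs = []
    for sub in ("r1", "r2"):
        run_pipeline(
            paths["fasta"], paths["metadata"], paths["variants"], root / sub,
            config={"allow_non_cpg": True},
        )
        outs.append((root / sub / "impact_records.tsv").read_bytes())
    assert outs[0] == outs[1]


def test_run_pipeline_with_motifs(synthetic_run):
    from importlib import resources

    root, paths = synthetic_run
    with resources.as_file(
        resources.files("cgivarscan.data").joinpath("toy_motifs.jaspar")
    ) as pwms:
        _, tf_records, stats = run_pipeline(
            paths["fasta"], paths["metadata"], paths["variants"], root / "tf",
            config={"allow_non_cpg": True},
            pwms_path=pwms,
        )
    # TF scan is restricted to abolishing rows by default
    assert len(tf_records) == 3
    assert stats.n_tf_changed == sum(1 for t in tf_records if t.changed)


def test_summary_frame_lists_all_metrics():
    frame = summary_frame(fixture_summary())
    metrics = set(frame["metric"])
    assert {"n_total", "n_abolished", "pct_abolished", "n_size_changed", "n_tf_changed"} <= metrics
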