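"""Pipeline orchestration, summary construction, and the CLI surface."""

from __future__ import annotations

import numpy as np
import pandas as pd
from click.testing import CliRunner

from splicetriage.cli import main
from splicetriage.reporting import render_summary, run_pipeline, summarize
from splicetriage.synthetic_data import SimulationConfig, write_fixture_set


def _write(tmp_path, rows):
    p = tmp_path / "muts.tsv"
    p.write_text("gene\thgvs_c\n" + "".join(f"TOY\t{r}\n" for r in rows))
    return p


def test_rule_forced_summary_counts(toy_model, tmp_path):
    """2 nonsense + 3 frameshift + 5 synonymous-neutral: the rules force 5
    severe and 5 neutral in the summary column."""
    rows = ["c.58G>T", "c.18C>A",                       # nonsense (Glu20*, Cys6*)
            "c.4delG", "c.7delC", "c.16delT",           # frameshift
            "c.30C>T", "c.9G>A", "c.27T>C", "c.63C>T", "c.24T>C"]  # synonymous
    res = run_pipeline(toy_model, _write(tmp_path, rows))
    assert len(res.per_variant) == 10 and not res.rejects
    summary = res.summary
    assert summary["summary_n"][summary["severity"] == "severe"].sum() == 5
    assert summary["summary_n"][summary["severity"] == "neutral"].sum() == 5
    assert summary["summary_n"][summary["severity"] == "mild"].sum() == 0


def test_no_protein_column_for_synonymous_and_splice_rows(toy_model, tmp_path):
    res = run_pipeline(toy_model, _write(tmp_path, ["c.30C>T", "c.45+1G>A"]))
    sub = res.summary[res.summary["mutation_class"].isin(["Synonymous", "Splicing site"])]
    assert (sub["protein_n"] == "-").all()


def test_empty_mutation_table(toy_model, tmp_path):
    res = run_pipeline(toy_model, _write(tmp_path, []))
    assert res.per_variant.empty and res.summary.empty
    assert render_summary(res.summary).startswith("(no variants)")


def test_unparseable_rows_go_to_rejects_and_pipeline_continues(toy_model, tmp_path):
    res = run_pipeline(toy_model, _write(tmp_path, ["c.30C>T", "c.nonsense", "c.44A>T"]))
    assert len(res.per_variant) == 2 and len(res.rejects) == 1


def test_count_conservation_per_class(toy_model, tmp_path):
    rows = ["c.30C>T", "c.44A>T", "c.58G>T", "c.4delG", "c.45+1G>A", "c.4_15del12"]
    res = run_pipeline(toy_model, _write(tmp_path, rows))
    for (_, cls), cdf in res.summary.groupby(["gene", "mutation_class"]):
        assert cdf["summary_n"].sum() == cdf["class_total"].iloc[0]
        assert cdf["splicing_n"].sum() == cdf["class_total"].iloc[0]
    assert res.summary.groupby("mutation_class")["class_total"].first().sum() \
        == len(rows)


def test_percentages_recomputed_and_rounded(toy_model, tmp_path):
    rows = ["c.30C>T"] * 1  # one synonymous in a 3-variant table -> 33%
    rows += ["c.44A>T", "c.58G>T"]
    res = run_pipeline(toy_model, _write(tmp_path, rows))
    syn = res.summary[res.summary["mutation_class"] == "Synonymous"]
    assert (syn["class_pct"] == 33).all()


def test_summarize_is_derived_solely_from_per_variant_rows(toy_model, tmp_path):
    res = run_pipeline(toy_model, _write(tmp_path, ["c.30C>T", "c.58G>T"]))
    again = summarize(res.per_variant)
    pd.testing.assert_frame_equal(res.summary, again)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_classify_missing_fasta_exits_2(tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, ["classify", "--fasta", str(tmp_path / "nope.fa"),
                                  "--gene-model", str(tmp_path / "nope.yaml"),
                                  "--mutations", str(tmp_path / "nope.tsv"),
                                  "--out", str(tmp_path / "out")])
    assert result.exit_code == 2
    assert "nope.fa" in result.output


def test_cli_simulate_deterministic_and_classify_summarize_roundtrip(tmp_path):
    runner = CliRunner()
    for sub in ("a", "b"):
        r = runner.invoke(main, ["simulate", "--seed", "4", "--n-variants", "30",
                                 "--out", str(tmp_path / sub)])
        assert r.exit_code == 0, r.output
    for name in ["mutations.tsv", "ground_truth.tsv", "SYNGENE1.fa"]:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    out = tmp_path / "cls"
    r = runner.invoke(main, ["classify",
                             "--fasta", str(tmp_path / "a" / "SYNGENE1.fa"),
                             "--gene-model", str(tmp_path / "a" / "SYNGENE1.model.yaml"),
                             "--mutations", str(tmp_path / "a" / "mutations.tsv"),
                             "--external", str(tmp_path / "a" / "external_verdicts.tsv"),
                             "--out", str(out)])
    assert r.exit_code == 0, r.output
    per_variant = pd.read_csv(out / "per_variant.tsv", sep="\t")
    assert len(per_variant) == 30

    r = runner.invoke(main, ["summarize", "--results", str(out / "per_variant.tsv")])
    assert r.exit_code == 0
    assert "Severity" in r.output


def test_cli_row_counts_conserved_through_files(tmp_path):
    runner = CliRunner()
    runner.invoke(main, ["simulate", "--seed", "4", "--n-variants", "30",
                         "--out", str(tmp_path / "sim")])
    out = tmp_path / "cls"
    runner.invoke(main, ["classify",
                         "--fasta", str(tmp_path / "sim" / "SYNGENE1.fa"),
                         "--gene-model", str(tmp_path / "sim" / "SYNGENE1.model.yaml"),
                         "--mutations", str(tmp_path / "sim" / "mutations.tsv"),
                         "--out", str(out)])
    per_variant = pd.read_csv(out / "per_variant.tsv", sep="\t")
    rejects = pd.read_csv(out / "rejects.tsv", sep="\t")
    muts = pd.read_csv(tmp_path / "sim" / "mutations.tsv", sep="\t")
    assert len(per_variant) + len(rejects) == len(muts)
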