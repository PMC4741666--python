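"""Pipeline orchestration and Table-style severity summaries.

``run_pipeline`` pushes every mutation-table row through parsing, variant
application, classification, both grading channels and the consensus, and
returns one per-variant row plus a count summary shaped like the published
synthesis table: per (gene, mutation class) a severe/mild/neutral breakdown
for the splicing channel, the protein channel and the overall summary, with
"-" in the protein column for classes that have no protein channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .consensus import Channel, ChannelVerdict, combine_channel, combine_overall
from .export_scan import diff_export_elements, load_export_table
from .genome_variant import (
    GeneModel,
    SpliceTriageError,
    VariantClass,
    VariantDescriptor,
    apply_variant,
    classify_variant,
    is_start_loss,
    protein_hgvs,
    read_mutation_table,
    serialize_hgvs,
)
from .protein_effect import (
    ExternalVerdictRow,
    ProteinLabel,
    assess_protein,
    protein_label_to_severity,
    read_external_verdicts,
)
from .splice_scoring import Severity, diff_splice_sites
from .sre_scan import diff_motifs, load_motif_table

log = logging.getLogger("splicetriage")

# classes whose protein column prints "-"
_NO_PROTEIN_CHANNEL = {VariantClass.synonymous, VariantClass.splice_site}
_SEVERITIES = [Severity.severe, Severity.mild, Severity.neutral]

# summary row order and labels, matching the published table
_CLASS_ROWS = [
    (VariantClass.missense, "Missense"),
    (VariantClass.nonsense, "Nonsense"),
    (VariantClass.synonymous, "Synonymous"),
    (VariantClass.frameshift, "Frameshift"),
    (VariantClass.inframe_indel, "In frame indels"),
    (VariantClass.splice_site, "Splicing site"),
]


@dataclass
class PipelineResult:
    per_variant: pd.DataFrame
    summary: pd.DataFrame
    rejects: list[dict] = field(default_factory=list)


def _round_half_up_pct(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def classify_one(model: GeneModel, desc: VariantDescriptor, config: PipelineConfig,
                 external: list[ExternalVerdictRow] | None = None,
                 motif_table=None, export_table=None) -> dict:
    """Full grading of a single parsed variant; one output row."""
    pair = apply_variant(model, desc)
    vclass = classify_variant(model, desc, pair)

    splice_events = diff_splice_sites(model, pair, config.thresholds,
                                      config.splice_window)
    sre_events = diff_motifs(motif_table if motif_table is not None
                             else load_motif_table(config.motif_table),
                             pair, model, config.sre_window)
    splicing = combine_channel(Channel.splicing, splice_events + sre_events)

    pv = assess_protein(vclass, pair, model, external, config.surrogate_threshold)
    protein = ChannelVerdict(Channel.protein, protein_label_to_severity(pv.label),
                             contributing_events=[pv])
    overall = combine_overall(splicing, protein)

    export_changes = diff_export_elements(
        export_table if export_table is not None else load_export_table(config.export_table),
        pair)

    report_class = vclass
    if vclass is VariantClass.stop_loss:
        report_class = VariantClass(config.stop_loss_class_row)
    warning = "start_loss" if is_start_loss(desc) else ""
    return {
        "gene": model.gene_id,
        "hgvs_c": serialize_hgvs(desc),
        "hgvs_p": protein_hgvs(pair),
        "variant_class": report_class.value,
        "raw_class": vclass.value,
        "splicing_severity": splicing.severity.value,
        "protein_severity": pv.label.value,
        "protein_source": pv.source.value,
        "consensus": overall.severity.value,
        "n_splice_events": len(splice_events),
        "n_sre_events": len(sre_events),
        "n_export_changes": len(export_changes),
        "basis": ";".join(f"{c.value}={s.value}" for c, s in overall.basis),
        "warning": warning,
    }


def run_pipeline(model: GeneModel, mutations: str | Path | list,
                 config: PipelineConfig | None = None,
                 external_verdicts: str | Path | list[ExternalVerdictRow] | None = None,
                 ) -> PipelineResult:
    """Run the full triage over a mutation table.

    ``mutations`` is a TSV path or a pre-parsed list of (gene, descriptor)
    pairs; unparseable rows go to the rejects report and processing
    continues.  Every surviving input variant appears exactly once in the
    per-variant output, and the summary is derived solely from those rows.
    """
    config = config or PipelineConfig()
    rejects: list[dict] = []
    if isinstance(mutations, (str, Path)):
        records, rejects = read_mutation_table(mutations)
    else:
        records = list(mutations)

    ext_by_hgvs: dict[str, list[ExternalVerdictRow]] = {}
    if external_verdicts is not None:
        if isinstance(external_verdicts, (str, Path)):
            ext_rows, ext_rejects = read_external_verdicts(external_verdicts)
            for r in ext_rejects:
                log.warning("rejected external verdict row: %s", r)
        else:
            ext_rows = list(external_verdicts)
        for r in ext_rows:
            ext_by_hgvs.setdefault(r.hgvs_c, []).append(r)

    motif_table = load_motif_table(config.motif_table)
    export_table = load_export_table(config.export_table)

    rows = []
    for gene, desc in records:
        hgvs = serialize_hgvs(desc)
        try:
            row = classify_one(model, desc, config,
                               external=ext_by_hgvs.get(hgvs),
                               motif_table=motif_table, export_table=export_table)
            row["gene"] = gene or model.gene_id
            rows.append(row)
        except SpliceTriageError as exc:
            rejects.append({"line": -1, "gene": gene, "hgvs_c": hgvs,
                            "error": str(exc)})
    per_variant = pd.DataFrame(rows)
    return PipelineResult(per_variant=per_variant,
                          summary=summarize(per_variant),
                          rejects=rejects)


def summarize(per_variant: pd.DataFrame) -> pd.DataFrame:
    """Severity count matrix per (gene, class): splicing / protein / summary
    columns, with per-class totals and integer percentages."""
    cols = ["gene", "mutation_class", "class_total", "class_pct", "severity",
            "splicing_n", "protein_n", "summary_n"]
    if per_variant.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for gene, gdf in per_variant.groupby("gene", sort=True):
        gene_total = len(gdf)
        for vclass, label in _CLASS_ROWS:
            cdf = gdf[gdf["variant_class"] == vclass.value]
            if cdf.empty:
                continue
            total = len(cdf)
            pct = _round_half_up_pct(100.0 * total / gene_total)
            no_protein = vclass in _NO_PROTEIN_CHANNEL
            for sev in _SEVERITIES:
                out.append({
                    "gene": gene,
                    "mutation_class": label,
                    "class_total": total,
                    "class_pct": pct,
                    "severity": sev.value,
                    "splicing_n": int((cdf["splicing_severity"] == sev.value).sum()),
                    "protein_n": "-" if no_protein
                    else int((cdf["protein_severity"] == sev.value).sum()),
                    "summary_n": int((cdf["consensus"] == sev.value).sum()),
                })
    return pd.DataFrame(out, columns=cols)


def render_summary(summary: pd.DataFrame) -> str:
    """Human-readable rendering of the summary matrix."""
    if summary.empty:
        return "(no variants)\n"
    lines = []
    for gene, gdf in summary.groupby("gene", sort=True):
        lines.append(f"{gene} ({int(gdf.groupby('mutation_class')['class_total'].first().sum())})")
        lines.append(f"  {'Mutation type':<16}{'':<12}{'Severity':<10}"
                     f"{'Splicing':>9}{'Protein':>9}{'Summary':>9}")
        for cls, cdf in gdf.groupby("mutation_class", sort=False):
            first = cdf.iloc[0]
            header = f"{cls} {first['class_total']} ({first['class_pct']}%)"
            for i, (_, row) in enumerate(cdf.iterrows()):
                left = header if i == 0 else ""
                lines.append(f"  {left:<28}{row['severity'].capitalize():<10}"
                             f"{row['splicing_n']:>9}{str(row['protein_n']):>9}"
                             f"{row['summary_n']:>9}")
    return "\n".join(lines) + "\n"
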