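"""End-to-end analysis: grouping -> consensus -> calls -> hotspots -> tables."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import calling, grouping, hotspots, stats
from .io import AnnotatedSequence, write_report_tables

logger = logging.getLogger(__name__)


@dataclass
class GroupAnalysis:
    """All per-group derived objects for one clonal family."""

    group: grouping.ClonalGroup
    consensus: calling.Consensus
    annotation: hotspots.HotspotAnnotation
    calls: list[calling.MutationCall]
    tandem_runs: list[calling.TandemRun]
    target_counts: dict


@dataclass
class ReportBundle:
    groups: list[grouping.ClonalGroup]
    singletons: list[AnnotatedSequence]
    analyses: list[GroupAnalysis]
    tables: dict[str, pd.DataFrame]
    summary: dict


def analyze_group(group: grouping.ClonalGroup) -> GroupAnalysis:
    consensus = calling.build_consensus(group)
    annotation = hotspots.scan_motifs(consensus)
    calls = calling.call_mutations(group, consensus, annotation)
    runs: list[calling.TandemRun] = []
    for seq_id in sorted({c.seq_id for c in calls}):
        member_calls = [c for c in calls if c.seq_id == seq_id]
        runs.extend(calling.detect_tandem_runs(member_calls))
    counts = hotspots.count_targets_by_region(annotation, consensus, group.members)
    return GroupAnalysis(group, consensus, annotation, calls, runs, counts)


def _per_group_hotspot_freqs(analyses: Sequence[GroupAnalysis]):
    """Per-group in-motif vs outside mutation frequencies, per base class."""
    out = {}
    for bc in ("GC", "AT"):
        fin, fout = [], []
        for a in analyses:
            n_in = a.target_counts[bc]["FR"]["in"] + a.target_counts[bc]["CDR"]["in"]
            n_out = a.target_counts[bc]["FR"]["out"] + a.target_counts[bc]["CDR"]["out"]
            o_in = sum(
                1 for c in a.calls
                if c.base_class == bc and c.in_hotspot
                and c.region in stats.FR_LABELS | stats.CDR_LABELS
            )
            o_out = sum(
                1 for c in a.calls
                if c.base_class == bc and not c.in_hotspot
                and c.region in stats.FR_LABELS | stats.CDR_LABELS
            )
            if n_in and n_out:
                fin.append(o_in / n_in)
                fout.append(o_out / n_out)
        out[bc] = (fin, fout)
    return out


def analyze_sequences(
    seqs: Sequence[AnnotatedSequence], min_group_size: int = 2
) -> ReportBundle:
    """Run the full mutation analysis over an annotated repertoire."""
    groups, singletons = grouping.group_by_cdr3j(seqs, min_size=min_group_size)
    analyses = [analyze_group(g) for g in groups]
    all_calls = [c for a in analyses for c in a.calls]

    region_table = stats.region_frequency_table(analyses)
    pooled = stats.pooled_region_summary(region_table)
    tandem = stats.tandem_table(analyses)
    mut_frames = []
    mut_tests = {}
    for stratum in ("ALL", "FR", "CDR"):
        frame, tests = stats.mutability_table(analyses, stratum)
        frame.insert(0, "stratum", stratum)
        mut_frames.append(frame)
        mut_tests[stratum] = tests
    mutability = pd.concat(mut_frames, ignore_index=True)
    merged_counts = hotspots.merge_target_counts(a.target_counts for a in analyses)
    hotspot_table, hotspot_tests = hotspots.hotspot_enrichment_table(
        all_calls, merged_counts, _per_group_hotspot_freqs(analyses)
    )
    tissue_table, tissue_tests = stats.tissue_stratified_table(analyses)
    spectrum = stats.substitution_spectrum(all_calls)
    cdr_fr = stats.compare_cdr_fr(analyses) if len(analyses) >= 2 else {}

    def pooled_value(region: str, column: str) -> float:
        sel = pooled.loc[pooled.region == region, column]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def tandem_pct(rc: str) -> float:
        sel = tandem.loc[
            (tandem.group_id == "Total") & (tandem.region_class == rc),
            "tandem_freq_pct",
        ]
        return float(sel.iloc[0]) if len(sel) else 0.0

    summary = {
        "n_sequences": len(seqs),
        "n_groups": len(groups),
        "n_singletons": len(singletons),
        "n_mutations": len(all_calls),
        "overall_freq": pooled_value("ALL", "freq"),
        "fr_freq": pooled_value("FR", "freq"),
        "cdr_freq": pooled_value("CDR", "freq"),
        "fr_freq_nsyn": pooled_value("FR", "freq_nsyn"),
        "fr_freq_syn": pooled_value("FR", "freq_syn"),
        "cdr_freq_nsyn": pooled_value("CDR", "freq_nsyn"),
        "cdr_freq_syn": pooled_value("CDR", "freq_syn"),
        "p_cdr_vs_fr": cdr_fr,
        "gc_enrichment_ratio": hotspot_tests["GC"]["enrichment_ratio"],
        "at_enrichment_ratio": hotspot_tests["AT"]["enrichment_ratio"],
        "hotspot_tests": hotspot_tests,
        "mutability_index": {
            row.base: row.mutability_index
            for row in mutability.loc[mutability.stratum == "ALL"].itertuples()
            if row.base != "Total"
        },
        "mutability_tests": mut_tests,
        "substitution_spectrum": spectrum,
        "tandem_fr_pct": tandem_pct("FR"),
        "tandem_cdr_pct": tandem_pct("CDR"),
        "tissue_tests": tissue_tests,
    }
    tables = {
        "groups": grouping.groups_table(groups),
        "region_freq": region_table,
        "region_pooled": pooled,
        "tandem": tandem,
        "mutability": mutability,
        "hotspots": hotspot_table,
        "tissue": tissue_table,
        "mutations": mutations_table(analyses),
    }
    return ReportBundle(groups, singletons, analyses, tables, summary)


def mutations_table(analyses: Sequence[GroupAnalysis]) -> pd.DataFrame:
    """Per-call table; columns are 1-based in this report output."""
    rows = [
        {
            "seq_id": c.seq_id,
            "column": c.column + 1,
            "region": c.region,
            "consensus_base": c.consensus_base,
            "observed_base": c.observed_base,
            "effect": c.effect,
            "motif": c.motif if c.in_hotspot else "NONE",
            "tandem_run_id": c.tandem_run_id,
        }
        for a in analyses
        for c in a.calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "column", "region", "consensus_base",
            "observed_base", "effect", "motif", "tandem_run_id",
        ],
    )


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    paths = write_report_tables(bundle.tables, out_dir)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(bundle.summary), indent=2) + "\n")
    return paths + [summary_path]
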