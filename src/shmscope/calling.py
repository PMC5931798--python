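"""Consensus building, per-position mutation calling and tandem detection.

Without an assembled germline locus, mutations are counted relative to the
clonal group's own consensus (plurality base per column). This undercounts
any mutation shared by the founder with a majority of descendants — a
documented limitation of consensus-referenced mutation counting.

Each substitution is classified as synonymous or nonsynonymous by applying
it ALONE to the consensus codon that contains it (neighbouring mutations,
including tandem partners, are ignored for the classification), using the
standard nuclear genetic code. A change producing a stop codon counts as
nonsynonymous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .grouping import ClonalGroup
from .io import RegionMap

logger = logging.getLogger(__name__)

SYN = "SYN"
NSYN = "NSYN"
UNDETERMINED = "UNDETERMINED"

MOTIF_GC = "DGYW_WRCH"
MOTIF_AT = "WA_TW"
MOTIF_NONE = "NONE"


@dataclass
class Consensus:
    """Plurality consensus of a clonal group, in group alignment frame."""

    group_id: str
    residues: str
    region_map: RegionMap

    @property
    def coding_columns(self) -> list[int]:
        """Non-gap columns from frame_offset on; triplets form codons."""
        return [
            col
            for col in range(self.region_map.frame_offset, len(self.residues))
            if self.residues[col] != "-"
        ]


@dataclass
class MutationCall:
    """One nucleotide difference between a member and its group consensus."""

    seq_id: str
    column: int
    consensus_base: str
    observed_base: str
    region: Optional[str]
    effect: str
    base_class: str  # "GC" | "AT", by consensus base
    in_hotspot: bool = False
    motif: str = MOTIF_NONE
    tandem_run_id: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.consensus_base != self.observed_base
        assert "-" not in (self.consensus_base, self.observed_base)
        assert self.base_class == ("GC" if self.consensus_base in "GC" else "AT")


@dataclass(frozen=True)
class TandemRun:
    """>=2 consecutively mutated alignment columns in one member."""

    seq_id: str
    columns: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.columns)


def build_consensus(group: ClonalGroup) -> Consensus:
    """Per-column plurality consensus of a clonal group.

    A column is gap in the consensus only when gaps are the strict
    majority state. Among tied top bases, the base of the earliest member
    (input order) carrying one of them wins; the tie is logged.
    """
    if group.size < 2:
        raise ValueError(f"group {group.group_id}: consensus needs >=2 members")
    length = len(group.members[0].residues)
    out = []
    for col in range(length):
        column = [m.residues[col] for m in group.members]
        n_gap = column.count("-")
        if n_gap * 2 > len(column):
            out.append("-")
            continue
        counts: dict[str, int] = {}
        for b in column:
            if b != "-":
                counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        tied = [b for b, n in counts.items() if n == top]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            winner = next(b for b in column if b in tied)
            logger.debug(
                "group %s column %d: consensus tie among %s; first-member base %s",
                group.group_id, col, sorted(tied), winner,
            )
            out.append(winner)
    return Consensus(group.group_id, "".join(out), group.members[0].region_map)


def classify_effect(consensus: Consensus, column: int, observed_base: str) -> str:
    """SYN/NSYN by independent single-base substitution into the consensus codon.

    The reading frame runs over the consensus' non-gap columns starting at
    ``frame_offset``. Columns before the frame start, or in an incomplete
    terminal codon, are UNDETERMINED (counted in totals, excluded from
    SYN/NSYN tallies).
    """
    coding = consensus.coding_columns
    try:
        idx = coding.index(column)
    except ValueError:
        return UNDETERMINED
    codon_cols = coding[(idx // 3) * 3 : (idx // 3) * 3 + 3]
    if len(codon_cols) < 3:
        return UNDETERMINED
    codon = [consensus.residues[c] for c in codon_cols]
    mutant = list(codon)
    mutant[idx % 3] = observed_base
    aa_ref = str(Seq("".join(codon)).translate())
    aa_mut = str(Seq("".join(mutant)).translate())
    return SYN if aa_ref == aa_mut else NSYN


def call_mutations(
    group: ClonalGroup,
    consensus: Consensus,
    hotspot_annotation=None,
) -> list[MutationCall]:
    """One call per (member, column) where member and consensus bases differ.

    Insertion columns (consensus gap under a member base) produce no
    calls; member-gap columns produce no calls and are excluded from that
    member's denominators downstream. When a hotspot annotation (from
    ``hotspot_analysis.scan_motifs`` on this consensus) is supplied, each
    call is flagged in/out of the motif set matching its base class.
    Tandem run membership is assigned per member.
    """
    calls: list[MutationCall] = []
    for member in group.members:
        member_calls: list[MutationCall] = []
        for col, (c, m) in enumerate(zip(consensus.residues, member.residues)):
            if c == "-" or m == "-" or c == m:
                continue
            base_class = "GC" if c in "GC" else "AT"
            in_hotspot = False
            motif = MOTIF_NONE
            if hotspot_annotation is not None:
                if base_class == "GC" and col in hotspot_annotation.gc_targets:
                    in_hotspot, motif = True, MOTIF_GC
                elif base_class == "AT" and col in hotspot_annotation.at_targets:
                    in_hotspot, motif = True, MOTIF_AT
            member_calls.append(
                MutationCall(
                    seq_id=member.seq_id,
                    column=col,
                    consensus_base=c,
                    observed_base=m,
                    region=consensus.region_map.label_of(col),
                    effect=classify_effect(consensus, col, m),
                    base_class=base_class,
                    in_hotspot=in_hotspot,
                    motif=motif,
                )
            )
        detect_tandem_runs(member_calls)
        calls.extend(member_calls)
    return calls


def detect_tandem_runs(calls_for_one_member: Sequence[MutationCall]) -> list[TandemRun]:
    """Maximal runs of >=2 consecutive mutated alignment columns.

    Adjacency is on alignment columns within one member; an intervening
    unmutated or gap column breaks the run (gap columns never carry calls,
    so strict column adjacency implements both rules). Each call's
    ``tandem_run_id`` is set (1-based per member) or cleared.
    """
    ids = {c.seq_id for c in calls_for_one_member}
    if len(ids) > 1:
        raise ValueError(f"calls span multiple members: {sorted(ids)}")
    ordered = sorted(calls_for_one_member, key=lambda c: c.column)
    runs: list[TandemRun] = []
    block: list[MutationCall] = []

    def flush() -> None:
        if len(block) >= 2:
            run_id = len(runs) + 1
            for c in block:
                c.tandem_run_id = run_id
            runs.append(
                TandemRun(block[0].seq_id, tuple(c.column for c in block))
            )
        else:
            for c in block:
                c.tandem_run_id = None

    for call in ordered:
        if block and call.column == block[-1].column + 1:
            block.append(call)
        else:
            flush()
            block = [call]
    flush()
    return runs
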