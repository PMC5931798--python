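"""Clonal family reconstruction and junction diversity.

Clones sharing a byte-identical CDR3-J nucleotide string (every base after
the predicted end of the germline V segment through the end of the J
segment) within one individual are treated as descendants of a single
founder thymocyte: independent rearrangements essentially never produce
the same junction, because exonuclease trimming and non-templated (N) and
palindromic (P) additions diversify the V-J join. Identity is required at
the nucleotide level over the whole CDR3-J interval — amino-acid identity
is not sufficient.

Germline V/J boundaries are inferred by cross-individual agreement: a
nucleotide present at the same column in clones of more than one
individual must be germline, so the V segment is extended 5'->3' until a
run of columns with no cross-individual agreement, and the J segment
symmetrically from the 3' end.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .io import AnnotatedSequence

logger = logging.getLogger(__name__)


@dataclass
class ClonalGroup:
    """Sequences sharing one (family, individual, CDR3-J key)."""

    group_id: str
    family_id: str
    individual_id: str
    cdr3j_key: str
    members: list[AnnotatedSequence]

    @property
    def size(self) -> int:
        return len(self.members)


class JunctionBoundary(NamedTuple):
    family_id: str
    v_end: int  # exclusive column of the last inferred germline V base
    j_start: int  # inclusive column of the first inferred germline J base


class JoinStats(NamedTuple):
    n_total: int
    n_unique: int
    fraction_unique: float
    length_range: tuple[int, int]


def extract_cdr3j_key(seq: AnnotatedSequence) -> str:
    """Ungapped CDR3+J nucleotide string (empty if the interval is all gaps)."""
    key = seq.region_residues("CDR3") + seq.region_residues("J")
    return key.replace("-", "")


def group_by_cdr3j(
    seqs: Sequence[AnnotatedSequence], min_size: int = 2
) -> tuple[list[ClonalGroup], list[AnnotatedSequence]]:
    """Partition sequences into clonal groups by exact CDR3-J identity.

    The grouping key is ``(family_id, cdr3j_key, individual_id)`` — the
    same junction seen in two individuals is treated as two independent
    events, never one clone. Keys with fewer than ``min_size`` sequences
    are returned as singletons. Groups are ordered by family, then
    descending size, then key, and labelled ``<family>.g<k>`` within each
    family; member order follows input order (it is the consensus
    tie-break order downstream).
    """
    buckets: dict[tuple[str, str, str], list[AnnotatedSequence]] = defaultdict(list)
    for seq in seqs:
        buckets[(seq.family_id, extract_cdr3j_key(seq), seq.individual_id)].append(seq)

    groups: list[ClonalGroup] = []
    singletons: list[AnnotatedSequence] = []
    ordered = sorted(
        buckets.items(), key=lambda kv: (kv[0][0], -len(kv[1]), kv[0][1], kv[0][2])
    )
    counters: dict[str, int] = defaultdict(int)
    for (family, key, individual), members in ordered:
        if len(members) < min_size:
            singletons.extend(members)
            continue
        counters[family] += 1
        groups.append(
            ClonalGroup(
                group_id=f"{family}.g{counters[family]}",
                family_id=family,
                individual_id=individual,
                cdr3j_key=key,
                members=members,
            )
        )
    # order singletons deterministically by id
    singletons.sort(key=lambda s: s.seq_id)
    for g in groups:
        assert all(extract_cdr3j_key(m) == g.cdr3j_key for m in g.members)
    return groups, singletons


# ---------------------------------------------------------------------------
# junction boundary inference
# ---------------------------------------------------------------------------

def _agreeing(column_bases: dict[str, set[str]]) -> bool:
    """True if some non-gap base is carried by >=2 individuals at a column."""
    counts: dict[str, int] = defaultdict(int)
    for bases in column_bases.values():
        for b in bases:
            counts[b] += 1
    return any(n >= 2 for n in counts.values())


def infer_junction_boundaries(
    seqs: Sequence[AnnotatedSequence], break_threshold: int = 2
) -> JunctionBoundary:
    """Infer germline V end / J start columns for one family.

    Scans 5'->3' from FR1: the last column at which >=2 individuals share
    an identical non-gap base, before a run of >= ``break_threshold``
    consecutive columns without such agreement, fixes ``v_end``;
    ``j_start`` is found symmetrically scanning 3'->5' from the J end.
    If no break is found (sequences germline-identical throughout), both
    boundaries fall back to the region map's CDR3 start.
    """
    if not seqs:
        raise ValueError("no sequences given")
    families = {s.family_id for s in seqs}
    if len(families) != 1:
        raise ValueError(f"sequences span multiple families: {sorted(families)}")
    family = seqs[0].family_id
    individuals = {s.individual_id for s in seqs}
    if len(individuals) < 2:
        raise ValueError(
            f"cannot infer germline boundary for family {family!r}: "
            "fewer than two individuals represented"
        )
    rm = seqs[0].region_map
    start = rm.interval("FR1")[0]
    end = rm.interval("J")[1]

    def bases_at(col: int) -> tuple[dict[str, set[str]], int]:
        per_ind: dict[str, set[str]] = defaultdict(set)
        n_cov = 0
        for s in seqs:
            b = s.residues[col]
            if b != "-":
                per_ind[s.individual_id].add(b)
                n_cov += 1
        return per_ind, n_cov

    # Per column: True = cross-individual agreement, False = disagreement
    # (break fuel; includes columns only one individual covers, which is
    # how the scan stops at trimmed junction tails), None = alignment
    # artifact (a column carried by a single clone, e.g. an insertion):
    # skipped, it is evidence of nothing.
    agree: list[bool | None] = []
    for col in range(start, end):
        per_ind, n_cov = bases_at(col)
        if _agreeing(per_ind):
            agree.append(True)
        elif n_cov <= 1:
            agree.append(None)
        else:
            agree.append(False)

    def scan(indices) -> int | None:
        last_agree = None
        run = 0
        for i in indices:
            if agree[i] is None:
                continue
            if agree[i]:
                last_agree = i
                run = 0
            else:
                run += 1
                if run >= break_threshold:
                    return last_agree
        return None  # no break: germline agreement throughout

    fwd = scan(range(len(agree)))
    v_end = start + fwd + 1 if fwd is not None else None
    bwd = scan(range(len(agree) - 1, -1, -1))
    j_start = start + bwd if bwd is not None else None

    if v_end is None or j_start is None or v_end > j_start:
        cdr3_start = rm.interval("CDR3")[0]
        logger.info(
            "family %s: no junction break found; falling back to CDR3 start %d",
            family, cdr3_start,
        )
        return JunctionBoundary(family, cdr3_start, cdr3_start)
    return JunctionBoundary(family, v_end, j_start)


def count_unique_joins(
    seqs: Sequence[AnnotatedSequence], boundary: JunctionBoundary
) -> JoinStats:
    """Uniqueness statistics of the V-J join strings (exact string equality)."""
    joins = [
        s.residues[boundary.v_end : boundary.j_start].replace("-", "") for s in seqs
    ]
    if not joins:
        return JoinStats(0, 0, 0.0, (0, 0))
    lengths = [len(j) for j in joins]
    n_unique = len(set(joins))
    return JoinStats(
        n_total=len(joins),
        n_unique=n_unique,
        fraction_unique=n_unique / len(joins),
        length_range=(min(lengths), max(lengths)),
    )


# ---------------------------------------------------------------------------
# identity-threshold family assignment
# ---------------------------------------------------------------------------

def _pairwise_identity(a: AnnotatedSequence, b: AnnotatedSequence,
                       start: int, end: int) -> float:
    matches = compared = 0
    for col in range(start, end):
        x, y = a.residues[col], b.residues[col]
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            matches += 1
    return matches / compared if compared else 0.0


def _single_linkage(n: int, linked: set[tuple[int, int]]) -> list[int]:
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in linked:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


def assign_families_by_identity(
    seqs: Sequence[AnnotatedSequence],
    family_threshold: float = 0.85,
    subfamily_threshold: float = 0.90,
) -> dict[str, tuple[str, str]]:
    """Single-linkage clustering of V segments by ungapped pairwise identity.

    Identity is matches over columns where both sequences are non-gap,
    computed over the germline V interval (FR1 start through FR3 end).
    Returns ``{seq_id: (family_label, subfamily_label)}`` with labels
    assigned deterministically in first-seen input order. Single linkage
    approximates the tree-cutting used in practice: it is transitive, so
    a chain of >=threshold pairs merges even if ends fall below it.
    """
    n = len(seqs)
    if n == 0:
        return {}
    rm = seqs[0].region_map
    start = rm.interval("FR1")[0]
    end = rm.interval("FR3")[1]

    idents = {}
    for i, j in itertools.combinations(range(n), 2):
        idents[(i, j)] = _pairwise_identity(seqs[i], seqs[j], start, end)

    fam_roots = _single_linkage(
        n, {ij for ij, v in idents.items() if v >= family_threshold}
    )
    sub_roots = _single_linkage(
        n, {ij for ij, v in idents.items() if v >= subfamily_threshold}
    )

    fam_label: dict[int, str] = {}
    sub_label: dict[tuple[str, int], str] = {}
    sub_counters: dict[str, int] = defaultdict(int)
    out: dict[str, tuple[str, str]] = {}
    for i, seq in enumerate(seqs):
        fr = fam_roots[i]
        if fr not in fam_label:
            fam_label[fr] = f"F{len(fam_label) + 1}"
        fam = fam_label[fr]
        sr = (fam, sub_roots[i])
        if sr not in sub_label:
            sub_counters[fam] += 1
            sub_label[sr] = f"{fam}.{sub_counters[fam]}"
        out[seq.seq_id] = (fam, sub_label[sr])
    return out


def groups_table(groups: Iterable[ClonalGroup]):
    """Summary DataFrame mirroring the groups.tsv report."""
    import pandas as pd

    rows = [
        {
            "group_id": g.group_id,
            "family_id": g.family_id,
            "individual_id": g.individual_id,
            "n_members": g.size,
            "cdr3j_key": g.cdr3j_key,
            "member_seq_ids": ";".join(m.seq_id for m in g.members),
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "family_id", "individual_id",
            "n_members", "cdr3j_key", "member_seq_ids",
        ],
    )
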