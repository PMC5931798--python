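"""Synthetic TcR-like repertoires with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* a germline locus of mutually similar V genes and a set of J genes,
  derived from common ancestors at a target nucleotide identity;
* V-J rearrangement per founder thymocyte: exonuclease trimming of both
  cut ends, palindromic (P) additions at untrimmed ends and non-templated
  (N) nucleotides, with out-of-frame or internal-stop junctions rejected
  and resampled (cloned repertoires contain only productive sequences);
* clonal expansion into families of 2-9 members;
* a two-phase hypermutation process over each descendant: deaminase-type
  events at G:C (boosted inside DGYW/WRCH targets), polymerase-eta-type
  events at A:T (boosted inside WA/TW), an extra multiplier inside CDRs,
  a transition bias, and tandem runs in which one event extends across
  adjacent positions; plus rare in-frame insertions.

Position weights are computed against the FOUNDER sequence (motifs are not
rescanned after each mutation), mirroring the analysis convention of
counting only consensus motifs. Weights are renormalized so the realized
mean per-base mutation rate equals ``per_base_rate`` — including the
expected extra bases contributed by tandem extensions; without that
correction the multipliers and tandem process would inflate the marginal
rate and parameter-recovery checks would be systematically biased.

Tandem run lengths are drawn from the empirical run-length histogram of
shark TcR-alpha tandem mutations (runs of 2:3:4 bases at odds 40:10:1),
truncated at ``tandem_max``. With the default ``tandem_prob`` of 0.25 this
puts roughly 43% of mutated bases inside tandem runs, matching the
published shark repertoire.

CDR3 and J columns are protected from mutation by default so the clonal
grouping truth is exactly recoverable; a config flag lifts the protection.

Every emitted dataset carries a truth log (lineage provenance per sequence
and one row per mutation/insertion event) whose replay against the naive
founder reproduces each emitted sequence byte-exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .hotspots import scan_target_positions
from .io import (
    AnnotatedSequence,
    RegionMap,
    write_annotated_fasta,
    write_region_config,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NON_STOP_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)
BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: run-length odds for tandem extensions (empirical 40:10:1 for 2:3:4)
TANDEM_LENGTH_WEIGHTS = {2: 40.0, 3: 10.0, 4: 1.0}

# fixed IMGT-like V-region template (nucleotides): FR1, CDR1, FR2, CDR2 are
# constant; FR3 absorbs the rest of the V gene up to a 9-nt CDR3 tail.
_FR1, _CDR1, _FR2, _CDR2, _TAIL = 75, 21, 51, 21, 9


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the emulated study conditions."""

    seed: int = 0
    n_v_genes: int = 9
    n_j_genes: int = 6
    v_length_nt: int = 300
    j_length_nt: int = 48
    c_length_nt: int = 30
    family_identity: float = 0.90
    n_founders: int = 48
    members_min: int = 2
    members_max: int = 9
    trim_max: int = 6
    np_min: int = 0
    np_max: int = 12
    per_base_rate: float = 0.02
    gc_hotspot_multiplier: float = 4.0
    at_hotspot_multiplier: float = 2.0
    cdr_multiplier: float = 2.0
    transition_bias: float = 2.0
    tandem_prob: float = 0.25
    tandem_max: int = 4
    insertion_prob: float = 0.01
    n_individuals: int = 2
    protect_cdr3j: bool = True

    def validate(self) -> None:
        probs = {
            "family_identity": self.family_identity,
            "per_base_rate": self.per_base_rate,
            "tandem_prob": self.tandem_prob,
            "insertion_prob": self.insertion_prob,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gc_hotspot_multiplier", "at_hotspot_multiplier",
                     "cdr_multiplier", "transition_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.v_length_nt % 3:
            raise ValueError("v_length_nt must be a multiple of 3")
        if self.j_length_nt % 3 or self.c_length_nt % 3:
            raise ValueError("j/c segment lengths must be codon multiples")
        if self.v_length_nt < _FR1 + _CDR1 + _FR2 + _CDR2 + _TAIL + 3:
            raise ValueError("v_length_nt too short for the region template")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not 1 <= self.members_min <= self.members_max:
            raise ValueError("invalid members_per_group range")
        if self.trim_max < 0 or self.trim_max > _TAIL:
            raise ValueError(f"trim_max must be in [0, {_TAIL}]")
        if not 0 <= self.np_min <= self.np_max:
            raise ValueError("invalid np_length range")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.tandem_max < 2:
            raise ValueError("tandem_max must be >= 2")


@dataclass
class GermlineLocus:
    v_genes: list[str]
    j_genes: list[str]
    c_segment: str


@dataclass
class Founder:
    founder_id: str
    family_id: str
    v_idx: int
    j_idx: int
    v_trim: int
    j_trim: int
    np_insert: str
    naive: str  # ungapped productive sequence
    individual_id: str = "I1"

    # local coordinate segment lengths (set at rearrangement)
    n_v: int = 0
    np_len: int = 0
    n_j: int = 0


@dataclass
class MutationEvent:
    seq_id: str
    column: int  # founder-local position until dataset assembly maps it
    from_base: str
    to_base: str
    phase: str  # deaminase | polymerase_eta | tandem_extension | insertion
    in_hotspot: bool


@dataclass
class SimulatedMember:
    seq_id: str
    tissue: str
    sequence: str  # ungapped mutated sequence (insertions excluded)
    events: list[MutationEvent]
    insertion: tuple[int, str] | None  # (local codon-boundary position, bases)


@dataclass
class TruthLog:
    lineages: pd.DataFrame
    mutations: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: list[AnnotatedSequence]
    region_maps: dict[str, RegionMap]
    truth: TruthLog


# ---------------------------------------------------------------------------
# germline locus
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, n_nt: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n_nt // 3)
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _mutate_orf(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-mutate an ORF at the given per-base rate, never creating stops."""
    out = list(seq)
    for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
        original = out[pos]
        alternatives = [b for b in BASES if b != original]
        rng.shuffle(alternatives)
        start = (pos // 3) * 3
        for b in alternatives:
            out[pos] = b
            if "".join(out[start : start + 3]) not in STOP_CODONS:
                break
        else:
            out[pos] = original
    return "".join(out)


def make_germline_locus(cfg: SimulationConfig, rng: np.random.Generator) -> GermlineLocus:
    """Generate V and J germline sets around random ancestors.

    Each gene diverges independently from its ancestor at rate
    ``(1 - family_identity)/2`` so expected pairwise identity matches the
    target. All segments translate without internal stops by construction.
    """
    cfg.validate()
    d = (1.0 - cfg.family_identity) / 2.0
    v_ancestor = _random_orf(rng, cfg.v_length_nt)
    j_ancestor = _random_orf(rng, cfg.j_length_nt)
    v_genes = [_mutate_orf(rng, v_ancestor, d) for _ in range(cfg.n_v_genes)]
    j_genes = [_mutate_orf(rng, j_ancestor, d) for _ in range(cfg.n_j_genes)]
    c_segment = _random_orf(rng, cfg.c_length_nt)
    return GermlineLocus(v_genes, j_genes, c_segment)


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def simulate_rearrangement(
    locus: GermlineLocus, cfg: SimulationConfig, rng: np.random.Generator,
    founder_idx: int,
) -> Founder:
    """One productive V-J rearrangement with trimming and N/P addition.

    The N/P length is adjusted by at most 2 nt so the downstream J segment
    stays in its design frame (total length is then automatically a codon
    multiple); junctions whose spanning codons contain a stop are resampled.
    """
    v_len = cfg.v_length_nt
    for _attempt in range(200):
        v_idx = int(rng.integers(0, cfg.n_v_genes))
        j_idx = int(rng.integers(0, cfg.n_j_genes))
        v_trim = int(rng.integers(0, cfg.trim_max + 1))
        j_trim = int(rng.integers(0, min(cfg.trim_max, cfg.j_length_nt - 3) + 1))
        target = int(rng.integers(cfg.np_min, cfg.np_max + 1))
        n_v = v_len - v_trim
        np_len = target + ((j_trim - (n_v + target)) % 3)

        p_v = p_j = ""
        if v_trim == 0 and np_len:
            k = min(int(rng.integers(0, 3)), np_len)
            p_v = _revcomp(locus.v_genes[v_idx][-k:]) if k else ""
        if j_trim == 0 and np_len - len(p_v) > 0:
            k = min(int(rng.integers(0, 3)), np_len - len(p_v))
            p_j = _revcomp(locus.j_genes[j_idx][:k]) if k else ""
        for _inner in range(50):
            n_part = _random_bases(rng, np_len - len(p_v) - len(p_j))
            np_insert = p_v + n_part + p_j
            naive = (
                locus.v_genes[v_idx][:n_v]
                + np_insert
                + locus.j_genes[j_idx][j_trim:]
                + locus.c_segment
            )
            assert len(naive) % 3 == 0
            if "*" not in str(Seq(naive).translate()):
                return Founder(
                    founder_id=f"f{founder_idx:03d}",
                    family_id=f"simV{v_idx + 1}",
                    v_idx=v_idx,
                    j_idx=j_idx,
                    v_trim=v_trim,
                    j_trim=j_trim,
                    np_insert=np_insert,
                    naive=naive,
                    n_v=n_v,
                    np_len=np_len,
                    n_j=cfg.j_length_nt - j_trim,
                )
    raise RuntimeError("could not sample a productive rearrangement")


def _local_region_labels(founder: Founder, cfg: SimulationConfig) -> np.ndarray:
    """Region label per founder-local (ungapped) position."""
    fr3_end = cfg.v_length_nt - _TAIL
    labels = np.empty(len(founder.naive), dtype=object)
    bounds = [
        ("FR1", 0, _FR1),
        ("CDR1", _FR1, _FR1 + _CDR1),
        ("FR2", _FR1 + _CDR1, _FR1 + _CDR1 + _FR2),
        ("CDR2", _FR1 + _CDR1 + _FR2, _FR1 + _CDR1 + _FR2 + _CDR2),
        ("FR3", _FR1 + _CDR1 + _FR2 + _CDR2, fr3_end),
        ("CDR3", fr3_end, founder.n_v + founder.np_len),
        ("J", founder.n_v + founder.np_len, founder.n_v + founder.np_len + founder.n_j),
        ("C", founder.n_v + founder.np_len + founder.n_j, len(founder.naive)),
    ]
    for lab, start, end in bounds:
        labels[start:end] = lab
    return labels


# ---------------------------------------------------------------------------
# hypermutation
# ---------------------------------------------------------------------------

def _tandem_length_dist(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array(
        [l for l in sorted(TANDEM_LENGTH_WEIGHTS) if l <= cfg.tandem_max]
    )
    weights = np.array([TANDEM_LENGTH_WEIGHTS[l] for l in lengths])
    return lengths, weights / weights.sum()


def _substitute(rng: np.random.Generator, base: str, kappa: float) -> str:
    ts = _TRANSITION[base]
    tv = [b for b in BASES if b not in (base, ts)]
    weights = np.array([kappa, 1.0, 1.0])
    choice = rng.choice(3, p=weights / weights.sum())
    return (ts, tv[0], tv[1])[choice]


def simulate_shm_lineage(
    founder: Founder, cfg: SimulationConfig, rng: np.random.Generator,
    n_members: int | None = None,
    tissue_probs: Sequence[float] = (0.6, 0.2, 0.2),
) -> list[SimulatedMember]:
    """Expand one founder into a mutated clonal family.

    Per-position seed probability = per_base_rate x relative weight
    (hotspot and CDR multipliers), normalized over eligible positions and
    deflated by the expected tandem contribution. Each seed event extends
    into a tandem run with probability ``tandem_prob``; the run is placed
    to contain the seed, clipped at ineligible positions.
    """
    if n_members is None:
        n_members = int(rng.integers(cfg.members_min, cfg.members_max + 1))

    naive = founder.naive
    L = len(naive)
    labels = _local_region_labels(founder, cfg)
    gc_t, at_t, _ = scan_target_positions(naive)

    w = np.ones(L)
    if gc_t:
        w[sorted(gc_t)] *= cfg.gc_hotspot_multiplier
    if at_t:
        w[sorted(at_t)] *= cfg.at_hotspot_multiplier
    cdr_labels = {"CDR1", "CDR2"} | (set() if cfg.protect_cdr3j else {"CDR3"})
    w[np.isin(labels, sorted(cdr_labels))] *= cfg.cdr_multiplier

    eligible = np.ones(L, dtype=bool)
    if cfg.protect_cdr3j:
        eligible &= ~np.isin(labels, ["CDR3", "J"])

    lengths, length_p = _tandem_length_dist(cfg)
    expected_extra = float(np.dot(length_p, lengths - 1))
    inflation = 1.0 + cfg.tandem_prob * expected_extra
    mean_w = w[eligible].mean() if eligible.any() else 1.0
    p = np.where(eligible, cfg.per_base_rate * w / mean_w / inflation, 0.0)
    p = np.clip(p, 0.0, 0.95)

    members: list[SimulatedMember] = []
    tissues = ("THY", "PBL", "SPV")
    for k in range(n_members):
        tissue = tissues[int(rng.choice(3, p=np.asarray(tissue_probs)))]
        seq_id = f"{founder.family_id}_{tissue}{k}_{founder.founder_id}"
        hits = np.nonzero(rng.random(L) < p)[0]
        mutated: dict[int, MutationEvent] = {}
        for pos in hits:
            pos = int(pos)
            if pos in mutated:
                continue
            base = naive[pos]
            phase = "deaminase" if base in "GC" else "polymerase_eta"
            mutated[pos] = MutationEvent(
                seq_id, pos, base, _substitute(rng, base, cfg.transition_bias),
                phase, pos in (gc_t if base in "GC" else at_t),
            )
            if rng.random() < cfg.tandem_prob:
                run_len = int(rng.choice(lengths, p=length_p))
                start = pos - int(rng.integers(0, run_len))
                for q in range(start, start + run_len):
                    if q == pos or q < 0 or q >= L or not eligible[q] or q in mutated:
                        continue
                    b = naive[q]
                    mutated[q] = MutationEvent(
                        seq_id, q, b, _substitute(rng, b, cfg.transition_bias),
                        "tandem_extension", q in (gc_t if b in "GC" else at_t),
                    )
        seq = list(naive)
        for pos, ev in mutated.items():
            seq[pos] = ev.to_base
        insertion = None
        if rng.random() < cfg.insertion_prob:
            ins_len = int(rng.choice(np.array([3, 18])))
            fr3_start = _FR1 + _CDR1 + _FR2 + _CDR2
            fr3_end = cfg.v_length_nt - _TAIL
            q = int(rng.choice(np.arange(fr3_start, fr3_end + 1, 3)))
            idx = rng.integers(0, len(NON_STOP_CODONS), size=ins_len // 3)
            insertion = (q, "".join(NON_STOP_CODONS[i] for i in idx))
        members.append(
            SimulatedMember(
                seq_id=seq_id,
                tissue=tissue,
                sequence="".join(seq),
                events=sorted(mutated.values(), key=lambda e: e.column),
                insertion=insertion,
            )
        )
    return members


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _base_column_of_local(founder: Founder, cfg: SimulationConfig, pad: int):
    """Map founder-local positions to base-layout alignment columns."""
    v_len, j_len = cfg.v_length_nt, cfg.j_length_nt

    def col(pos: int) -> int:
        if pos < founder.n_v:
            return pos
        pos -= founder.n_v
        if pos < founder.np_len:
            return v_len + pos
        pos -= founder.np_len
        if pos < founder.n_j:
            return v_len + pad + founder.j_trim + pos
        pos -= founder.n_j
        return v_len + pad + j_len + pos

    return col


def _skeleton_row(founder: Founder, sequence: str, cfg: SimulationConfig, pad: int) -> str:
    """Lay an ungapped member sequence onto the family base layout."""
    n_v, np_len, n_j = founder.n_v, founder.np_len, founder.n_j
    v_part = sequence[:n_v]
    np_part = sequence[n_v : n_v + np_len]
    j_part = sequence[n_v + np_len : n_v + np_len + n_j]
    c_part = sequence[n_v + np_len + n_j :]
    return (
        v_part
        + "-" * founder.v_trim
        + np_part
        + "-" * (pad - np_len)
        + "-" * founder.j_trim
        + j_part
        + c_part
    )


def generate_dataset(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate a full synthetic repertoire (optionally writing it to disk).

    Deterministic under a fixed seed (byte-identical outputs): one seeded
    stream drives the locus; each founder draws from its own counter-keyed
    substream so changing one founder's member count cannot shift another
    founder's draws. Founders whose CDR3-J key collides with an existing
    founder of the same family and individual are resampled, matching the
    working assumption that two thymocytes never create the same junction.

    Writes ``simulated.fasta``, ``regions.tsv``, ``truth_lineages.tsv``
    and ``truth_mutations.tsv`` when ``out_dir`` is given.
    """
    cfg.validate()
    locus = make_germline_locus(cfg, np.random.default_rng([cfg.seed, 0]))

    founders: list[Founder] = []
    family_members: dict[str, list[tuple[Founder, list[SimulatedMember]]]] = {}
    seen_keys: set[tuple[str, str, str]] = set()
    for fidx in range(cfg.n_founders):
        rng_f = np.random.default_rng([cfg.seed, 1 + fidx])
        individual = f"I{1 + int(rng_f.integers(0, cfg.n_individuals))}"
        for _try in range(50):
            founder = simulate_rearrangement(locus, cfg, rng_f, fidx)
            # junction key: everything from the CDR3 start (local) onward
            key = (
                founder.family_id,
                individual,
                founder.naive[cfg.v_length_nt - _TAIL :],
            )
            if key not in seen_keys:
                seen_keys.add(key)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a unique junction")
        founder.individual_id = individual
        members = simulate_shm_lineage(founder, cfg, rng_f)
        founders.append(founder)
        family_members.setdefault(founder.family_id, []).append((founder, members))

    sequences: list[AnnotatedSequence] = []
    region_maps: dict[str, RegionMap] = {}
    lineage_rows = []
    mutation_rows = []

    for family_id in sorted(family_members):
        entries = family_members[family_id]
        pad = max(f.np_len for f, _ in entries)
        v_len, j_len, c_len = cfg.v_length_nt, cfg.j_length_nt, cfg.c_length_nt

        # collect insertion blocks: (base_column, owner seq_id, bases)
        blocks = sorted(
            (m.insertion[0], m.seq_id, m.insertion[1])
            for _, ms in entries
            for m in ms
            if m.insertion is not None
        )

        block_starts: dict[tuple[int, str], int] = {}
        _off = 0
        for _bc, _sid, _bases in blocks:
            block_starts[(_bc, _sid)] = _bc + _off
            _off += len(_bases)

        def final_col(base_col: int) -> int:
            return base_col + sum(len(b[2]) for b in blocks if b[0] <= base_col)

        def expand(row: str, owner: str | None = None) -> str:
            pieces = []
            prev = 0
            for base_col, seq_id, bases in blocks:
                pieces.append(row[prev:base_col])
                pieces.append(bases if (owner == seq_id) else "-" * len(bases))
                prev = base_col
            pieces.append(row[prev:])
            return "".join(pieces)

        fr3_start = _FR1 + _CDR1 + _FR2 + _CDR2
        fr3_end = v_len - _TAIL
        total_ins = sum(len(b[2]) for b in blocks)
        intervals = (
            ("FR1", 0, _FR1),
            ("CDR1", _FR1, _FR1 + _CDR1),
            ("FR2", _FR1 + _CDR1, fr3_start - _CDR2),
            ("CDR2", fr3_start - _CDR2, fr3_start),
            ("FR3", fr3_start, fr3_end + total_ins),
            ("CDR3", fr3_end + total_ins, v_len + pad + total_ins),
            ("J", v_len + pad + total_ins, v_len + pad + j_len + total_ins),
            ("C", v_len + pad + j_len + total_ins,
             v_len + pad + j_len + c_len + total_ins),
        )
        region_maps[family_id] = RegionMap(
            family_id=family_id, intervals=intervals, frame_offset=0
        )

        for founder, members in entries:
            col_of = _base_column_of_local(founder, cfg, pad)
            lineage_base = {
                "founder_id": founder.founder_id,
                "family_id": family_id,
                "individual_id": founder.individual_id,
                "v_gene": f"V{founder.v_idx + 1}",
                "j_gene": f"J{founder.j_idx + 1}",
                "v_trim": founder.v_trim,
                "j_trim": founder.j_trim,
                "np_insert": founder.np_insert,
            }
            for m in members:
                row = expand(_skeleton_row(founder, m.sequence, cfg, pad), owner=m.seq_id)
                sequences.append(
                    AnnotatedSequence(
                        seq_id=m.seq_id,
                        individual_id=founder.individual_id,
                        tissue=m.tissue,
                        family_id=family_id,
                        residues=row,
                        region_map=region_maps[family_id],
                    )
                )
                lineage_rows.append(
                    {"seq_id": m.seq_id, "tissue": m.tissue, **lineage_base}
                )
                for ev in m.events:
                    mutation_rows.append(
                        {
                            "seq_id": m.seq_id,
                            "column": final_col(col_of(ev.column)),
                            "from_base": ev.from_base,
                            "to_base": ev.to_base,
                            "phase": ev.phase,
                            "in_hotspot": ev.in_hotspot,
                        }
                    )
                if m.insertion is not None:
                    start = block_starts[(m.insertion[0], m.seq_id)]
                    for i, b in enumerate(m.insertion[1]):
                        mutation_rows.append(
                            {
                                "seq_id": m.seq_id,
                                "column": start + i,
                                "from_base": "-",
                                "to_base": b,
                                "phase": "insertion",
                                "in_hotspot": False,
                            }
                        )

    truth = TruthLog(
        lineages=pd.DataFrame(lineage_rows),
        mutations=pd.DataFrame(
            mutation_rows,
            columns=["seq_id", "column", "from_base", "to_base", "phase", "in_hotspot"],
        ),
    )
    dataset = SimulatedDataset(cfg, sequences, region_maps, truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_annotated_fasta(sequences, out_dir / "simulated.fasta")
        write_region_config(region_maps, out_dir / "regions.tsv")
        truth.lineages.to_csv(out_dir / "truth_lineages.tsv", sep="\t", index=False)
        truth.mutations.to_csv(out_dir / "truth_mutations.tsv", sep="\t", index=False)
    return dataset


def naive_aligned_row(dataset: SimulatedDataset, seq_id: str) -> str:
    """The unmutated founder sequence laid out in ``seq_id``'s alignment row.

    Replaying the truth-log events for ``seq_id`` on top of this row
    reproduces the emitted aligned sequence byte-exactly (the truth-replay
    invariant exercised by the test suite).
    """
    lin = dataset.truth.lineages
    row = lin.loc[lin.seq_id == seq_id]
    if row.empty:
        raise KeyError(seq_id)
    founder_id = row.iloc[0].founder_id
    emitted = next(s for s in dataset.sequences if s.seq_id == seq_id)
    naive = list(emitted.residues)
    muts = dataset.truth.mutations
    for ev in muts.loc[muts.seq_id == seq_id].itertuples():
        naive[ev.column] = ev.from_base
    return "".join(naive)
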