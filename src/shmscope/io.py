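"""Reading and writing of aligned repertoire data and region annotations.

Coordinate convention: all positions are 0-based, half-open alignment
columns. Input sequences are assumed pre-aligned within a V family;
alignment itself is an input contract, never recomputed here.

Sequence IDs follow the clone-naming convention
``<family>_<TISSUE><clone>_<suffix>`` (e.g. ``aV7.2_THY09_051410``), from
which the V family and source tissue are parsed. The donor individual is
not encoded in clone names; it is read from an ``individual=<id>`` token
on the FASTA description line when present.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Region labels in 5'->3' order over a V-region alignment.
REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "J", "C")
#: Labels belonging to the (translated) V region proper.
V_REGION_LABELS = REGION_LABELS[:6]
FR_LABELS = frozenset({"FR1", "FR2", "FR3"})
CDR_LABELS = frozenset({"CDR1", "CDR2", "CDR3"})

TISSUES = ("THY", "PBL", "SPV", "SPLEEN", "OTHER")
#: Peripheral (non-thymic) lymphoid tissues.
PERIPHERY_TISSUES = frozenset({"PBL", "SPV", "SPLEEN"})

ALPHABET = frozenset("ACGT-")

_TISSUE_RE = re.compile(r"^(THY|PBL|SPV|SPLEEN|SPL)", re.IGNORECASE)
_INDIVIDUAL_RE = re.compile(r"individual=(\S+)")


@dataclass(frozen=True)
class RegionMap:
    """Per-family annotation of alignment columns into sequence regions.

    ``intervals`` is an ordered tuple of ``(label, start, end)`` with
    0-based half-open column coordinates. ``frame_offset`` is the column
    (0, 1 or 2) where codon position 1 of FR1 begins.
    """

    family_id: str
    intervals: tuple[tuple[str, int, int], ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        labels = [lab for lab, _, _ in self.intervals]
        unknown = set(labels) - set(REGION_LABELS)
        if unknown:
            raise ValueError(
                f"family {self.family_id!r}: unknown region labels {sorted(unknown)}"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"family {self.family_id!r}: duplicate region labels")
        order = [REGION_LABELS.index(lab) for lab in labels]
        if order != sorted(order):
            raise ValueError(
                f"family {self.family_id!r}: region labels out of 5'->3' order"
            )
        prev_end = None
        for lab, start, end in self.intervals:
            if not (0 <= start <= end):
                raise ValueError(
                    f"family {self.family_id!r}: bad interval for {lab}: ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"family {self.family_id!r}: overlapping intervals at {lab}"
                )
            prev_end = end
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(
                f"family {self.family_id!r}: frame_offset must be 0, 1 or 2"
            )
        # FR1 through CDR3 must tile contiguously (CDR3 may be ragged in
        # length, but the intervals themselves cannot leave holes).
        v_intervals = [iv for iv in self.intervals if iv[0] in V_REGION_LABELS]
        for (la, _, ea), (lb, sb, _) in zip(v_intervals, v_intervals[1:]):
            if sb != ea:
                raise ValueError(
                    f"family {self.family_id!r}: gap between {la} and {lb} "
                    f"({ea} != {sb}); FR1..CDR3 must be contiguous"
                )
        # Codon-count consistency is advisory only: insertion columns
        # (e.g. from rare in-frame insertions) legitimately widen a region.
        for lab, start, end in self.intervals:
            if lab in ("FR1", "CDR1", "FR2", "CDR2", "FR3") and (end - start) % 3:
                logger.warning(
                    "family %s: region %s length %d is not a codon multiple",
                    self.family_id, lab, end - start,
                )

    # -- queries --------------------------------------------------------
    @property
    def alignment_length(self) -> int:
        return max(end for _, _, end in self.intervals)

    def interval(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.intervals:
            if lab == label:
                return start, end
        raise KeyError(f"family {self.family_id!r} has no region {label!r}")

    def has_region(self, label: str) -> bool:
        return any(lab == label for lab, _, _ in self.intervals)

    def label_of(self, column: int) -> str | None:
        """Region label containing an alignment column, or None."""
        for lab, start, end in self.intervals:
            if start <= column < end:
                return lab
        return None

    def columns(self, label: str) -> range:
        start, end = self.interval(label)
        return range(start, end)


@dataclass
class AnnotatedSequence:
    """One aligned clone with region map and source metadata."""

    seq_id: str
    individual_id: str
    tissue: str
    family_id: str
    residues: str
    region_map: RegionMap

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"{self.seq_id}: unknown tissue {self.tissue!r}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def region_residues(self, label: str) -> str:
        start, end = self.region_map.interval(label)
        return self.residues[start:end]


def parse_seq_id(seq_id: str) -> tuple[str, str]:
    """Parse ``(family_id, tissue)`` from a clone name.

    The family is the header prefix before the first underscore; the
    tissue is the leading THY/PBL/SPV/SPLEEN token of any later field.
    An unparseable tissue yields OTHER with a warning, never an error.
    """
    tokens = seq_id.split("_")
    family = tokens[0]
    for tok in tokens[1:]:
        m = _TISSUE_RE.match(tok)
        if m:
            code = m.group(1).upper()
            return family, ("SPLEEN" if code == "SPL" else code)
    logger.warning("no tissue token in sequence id %r; using OTHER", seq_id)
    return family, "OTHER"


# ---------------------------------------------------------------------------
# region configuration
# ---------------------------------------------------------------------------

def read_region_config(path: str | Path) -> dict[str, RegionMap]:
    """Load per-family region maps from a TSV or YAML file.

    TSV columns: family_id, region_label, start, end, frame_offset.
    YAML layout: ``{family: {frame_offset: int, regions: [{label, start, end}]}}``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        maps = {}
        for family, spec in data.items():
            intervals = tuple(
                (r["label"], int(r["start"]), int(r["end"])) for r in spec["regions"]
            )
            maps[family] = RegionMap(
                family_id=str(family),
                intervals=intervals,
                frame_offset=int(spec.get("frame_offset", 0)),
            )
        return maps
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "region_label": str})
    required = {"family_id", "region_label", "start", "end", "frame_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region config {path}: missing columns {sorted(missing)}")
    maps = {}
    for family, sub in df.groupby("family_id", sort=False):
        sub = sub.sort_values("start")
        intervals = tuple(
            (row.region_label, int(row.start), int(row.end))
            for row in sub.itertuples()
        )
        offsets = sub["frame_offset"].unique()
        if len(offsets) != 1:
            raise ValueError(f"family {family!r}: inconsistent frame_offset values")
        maps[str(family)] = RegionMap(
            family_id=str(family), intervals=intervals, frame_offset=int(offsets[0])
        )
    return maps


def write_region_config(maps: Mapping[str, RegionMap], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "family_id": rm.family_id,
            "region_label": lab,
            "start": start,
            "end": end,
            "frame_offset": rm.frame_offset,
        }
        for rm in maps.values()
        for lab, start, end in rm.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_annotated_fasta(
    fasta_path: str | Path, regions_path: str | Path
) -> list[AnnotatedSequence]:
    """Read a gapped multi-FASTA into annotated, validated sequences.

    Residues are uppercased; gap characters are preserved. Every record's
    family (header prefix before the first underscore) must have a region
    map; records of one family must share one alignment length covering
    the map. Characters outside ``{A,C,G,T,-}`` are a hard error naming
    the offending column.
    """
    maps = read_region_config(regions_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        logger.warning("empty FASTA: %s", fasta_path)
        return []
    seqs: list[AnnotatedSequence] = []
    family_lengths: dict[str, int] = {}
    for rec in records:
        family, tissue = parse_seq_id(rec.id)
        if family not in maps:
            raise ValueError(
                f"sequence {rec.id!r}: no region map for family {family!r}"
            )
        residues = str(rec.seq).upper()
        for col, ch in enumerate(residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"sequence {rec.id!r}: unsupported residue {ch!r} at column {col}"
                )
        rm = maps[family]
        if len(residues) < rm.alignment_length:
            raise ValueError(
                f"sequence {rec.id!r}: length {len(residues)} shorter than "
                f"region map extent {rm.alignment_length}"
            )
        prev = family_lengths.setdefault(family, len(residues))
        if prev != len(residues):
            raise ValueError(
                f"family {family!r}: inconsistent alignment lengths "
                f"({prev} vs {len(residues)} at {rec.id!r})"
            )
        m = _INDIVIDUAL_RE.search(rec.description)
        individual = m.group(1) if m else "NA"
        seqs.append(
            AnnotatedSequence(
                seq_id=rec.id,
                individual_id=individual,
                tissue=tissue,
                family_id=family,
                residues=residues,
                region_map=rm,
            )
        )
    return seqs


def write_annotated_fasta(seqs: Iterable[AnnotatedSequence], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(
            Seq(s.residues),
            id=s.seq_id,
            description=f"individual={s.individual_id}",
        )
        for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
    return path


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

#: column -> decimals applied when writing report TSVs. Percentages go to
#: 2 decimals, mutability indices to 2, raw per-nucleotide frequencies to 4.
_ROUNDING = {
    "freq_pct": 2,
    "freq_in_pct": 2,
    "freq_out_pct": 2,
    "mutation_freq_pct": 2,
    "tandem_freq_pct": 2,
    "mutability_index": 2,
    "expected": 2,
    "expected_mutations": 2,
    "probability": 3,
    "freq": 4,
}


def write_report_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write each table of a report bundle as ``<name>.tsv`` under out_dir.

    Reruns overwrite deterministically. An unwritable directory raises.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        out = df.copy()
        for col, nd in _ROUNDING.items():
            if col in out.columns:
                out[col] = pd.to_numeric(out[col], errors="coerce").round(nd)
        path = out_dir / f"{name}.tsv"
        out.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
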