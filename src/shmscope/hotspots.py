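"""AID / polymerase-eta hotspot motif scanning and enrichment statistics.

The deaminase motif pair DGYW/WRCH marks mutable G:C targets (the G of
DGYW, the C of WRCH) and the error-prone-repair pair WA/TW marks mutable
A:T targets (the A of WA, the T of TW). DGYW/WRCH and WA/TW are mutually
reverse-complementary, so scanning both patterns on the coding strand
covers AID targets on either strand; no reverse-complement scan is needed.

Motifs are counted only on the group consensus — a motif created (or
destroyed) by a member's mutation is never counted, so target sets are a
fixed property of the consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy import stats as sps

from .calling import Consensus, MutationCall
from .io import CDR_LABELS, FR_LABELS

# IUPAC classes: D=A/G/T, Y=C/T, W=A/T, R=A/G, H=A/C/T.
# Each entry: name, lookahead regex, offset of the mutable base, base class.
MOTIFS = (
    ("DGYW", re.compile(r"(?=([AGT]G[CT][AT]))"), 1, "GC"),
    ("WRCH", re.compile(r"(?=([AT][AG]C[ACT]))"), 2, "GC"),
    ("WA", re.compile(r"(?=([AT]A))"), 1, "AT"),
    ("TW", re.compile(r"(?=(T[AT]))"), 0, "AT"),
)


class MotifWindow(NamedTuple):
    motif: str
    start: int  # position of the window start (ungapped or column space)
    target: int  # position of the mutable base


@dataclass
class HotspotAnnotation:
    """Mutable-target columns of a consensus, deduplicated across windows."""

    group_id: str
    gc_targets: frozenset[int]
    at_targets: frozenset[int]
    windows: tuple[MotifWindow, ...] = ()


def scan_target_positions(sequence: str) -> tuple[set[int], set[int], list[MotifWindow]]:
    """Scan an ungapped sequence for hotspot motifs.

    Returns (gc_target_positions, at_target_positions, windows), with
    overlapping windows allowed and target positions deduplicated.
    """
    gc: set[int] = set()
    at: set[int] = set()
    windows: list[MotifWindow] = []
    for name, pattern, offset, klass in MOTIFS:
        for m in pattern.finditer(sequence):
            pos = m.start() + offset
            windows.append(MotifWindow(name, m.start(), pos))
            (gc if klass == "GC" else at).add(pos)
    return gc, at, windows


def scan_motifs(consensus: Consensus) -> HotspotAnnotation:
    """Hotspot targets of a consensus, as alignment columns.

    Scanning runs on the ungapped consensus (motifs straddle insertion gap
    columns) and positions are mapped back to alignment columns.
    """
    cols = [i for i, b in enumerate(consensus.residues) if b != "-"]
    ungapped = "".join(consensus.residues[i] for i in cols)
    gc, at, windows = scan_target_positions(ungapped)
    gc_cols = frozenset(cols[p] for p in gc)
    at_cols = frozenset(cols[p] for p in at)
    for col in gc_cols:
        assert consensus.residues[col] in "GC"
    for col in at_cols:
        assert consensus.residues[col] in "AT"
    mapped = tuple(
        MotifWindow(w.motif, cols[w.start], cols[w.target]) for w in windows
    )
    return HotspotAnnotation(consensus.group_id, gc_cols, at_cols, mapped)


# ---------------------------------------------------------------------------
# per-region target totals
# ---------------------------------------------------------------------------

def count_targets_by_region(
    ann: HotspotAnnotation, consensus: Consensus, members: Sequence
) -> dict[str, dict[str, dict[str, int]]]:
    """Nucleotide totals in/out of motif per base class and region class.

    Returns ``counts[base_class][region_class]["in"|"out"]`` where
    region_class is "FR" (FR1+FR2+FR3) or "CDR" (CDR1+CDR2+CDR3), with
    totals summed over members: a member contributes a column only where
    both it and the consensus are non-gap (member gaps reduce that
    member's denominator; insertion columns are not germline positions).
    """
    counts = {
        bc: {rc: {"in": 0, "out": 0} for rc in ("FR", "CDR")} for bc in ("GC", "AT")
    }
    rm = consensus.region_map
    for col, base in enumerate(consensus.residues):
        if base == "-":
            continue
        label = rm.label_of(col)
        if label in FR_LABELS:
            rc = "FR"
        elif label in CDR_LABELS:
            rc = "CDR"
        else:
            continue
        bc = "GC" if base in "GC" else "AT"
        targets = ann.gc_targets if bc == "GC" else ann.at_targets
        stratum = "in" if col in targets else "out"
        n = sum(1 for m in members if m.residues[col] != "-")
        counts[bc][rc][stratum] += n
    return counts


def merge_target_counts(
    per_group: Iterable[Mapping[str, Mapping[str, Mapping[str, int]]]]
) -> dict[str, dict[str, dict[str, int]]]:
    total = {
        bc: {rc: {"in": 0, "out": 0} for rc in ("FR", "CDR")} for bc in ("GC", "AT")
    }
    for counts in per_group:
        for bc in total:
            for rc in total[bc]:
                for st in ("in", "out"):
                    total[bc][rc][st] += counts[bc][rc][st]
    return total


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hotspot_enrichment(
    n_in: int, obs_in: int, n_out: int, obs_out: int
) -> dict[str, float]:
    """Observed/expected hotspot targeting for one base class.

    Expected counts split the class's observed total in proportion to
    nucleotide totals (expected_in = total x n_in/(n_in+n_out)); the
    enrichment ratio is the in-motif mutation frequency over the outside
    frequency; the chi-square statistic (df=1) compares observed with
    expected over the {in, out} split.
    """
    total_nuc = n_in + n_out
    total_obs = obs_in + obs_out
    freq_in = 100.0 * obs_in / n_in if n_in else float("nan")
    freq_out = 100.0 * obs_out / n_out if n_out else float("nan")
    expected_in = total_obs * n_in / total_nuc if total_nuc else float("nan")
    expected_out = total_obs * n_out / total_nuc if total_nuc else float("nan")
    if freq_out == 0:
        ratio = float("inf")
    else:
        ratio = freq_in / freq_out
    if expected_in > 0 and expected_out > 0:
        chisq = (obs_in - expected_in) ** 2 / expected_in
        chisq += (obs_out - expected_out) ** 2 / expected_out
        chisq_p = float(sps.chi2.sf(chisq, df=1))
    else:
        chisq, chisq_p = float("nan"), float("nan")
    return {
        "total_in": n_in,
        "observed_in": obs_in,
        "total_out": n_out,
        "observed_out": obs_out,
        "freq_in_pct": freq_in,
        "freq_out_pct": freq_out,
        "expected_in": expected_in,
        "expected_out": expected_out,
        "enrichment_ratio": ratio,
        "chisq_stat": chisq,
        "chisq_p": chisq_p,
    }


def _one_tailed_t(greater: Sequence[float], lesser: Sequence[float]) -> float:
    """Pooled-variance one-tailed Student t (H1: mean(greater) > mean(lesser))."""
    import numpy as np

    a, b = np.asarray(greater, float), np.asarray(lesser, float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    res = sps.ttest_ind(a, b, equal_var=True, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p) and np.isclose(a.mean(), b.mean()):
        return 0.5  # zero pooled variance, equal means: no evidence either way
    return p


def hotspot_enrichment_table(
    calls: Sequence[MutationCall],
    counts: Mapping[str, Mapping[str, Mapping[str, int]]],
    per_group_freqs: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
):
    """Hotspot targeting table over FR/CDR/ALL/Outside strata.

    ``counts`` comes from :func:`count_targets_by_region` (merged over
    groups); observed mutations are tallied from the calls' in_hotspot
    flags, restricted to FR/CDR columns. ``per_group_freqs`` optionally
    maps base class to (in-motif, outside) per-group frequency vectors for
    the one-tailed t-test. Returns (DataFrame, tests dict).
    """
    import pandas as pd

    def region_class(label):
        if label in FR_LABELS:
            return "FR"
        if label in CDR_LABELS:
            return "CDR"
        return None

    obs = {
        bc: {rc: {"in": 0, "out": 0} for rc in ("FR", "CDR")} for bc in ("GC", "AT")
    }
    for c in calls:
        rc = region_class(c.region)
        if rc is None:
            continue
        obs[c.base_class][rc]["in" if c.in_hotspot else "out"] += 1

    rows = []
    tests = {}
    for bc, motif in (("GC", "DGYW/WRCH"), ("AT", "WA/TW")):
        n_in = counts[bc]["FR"]["in"] + counts[bc]["CDR"]["in"]
        n_out = counts[bc]["FR"]["out"] + counts[bc]["CDR"]["out"]
        o_in = obs[bc]["FR"]["in"] + obs[bc]["CDR"]["in"]
        o_out = obs[bc]["FR"]["out"] + obs[bc]["CDR"]["out"]
        enr = hotspot_enrichment(n_in, o_in, n_out, o_out)
        total_obs = o_in + o_out
        ttest_p = float("nan")
        if per_group_freqs and bc in per_group_freqs:
            fin, fout = per_group_freqs[bc]
            ttest_p = _one_tailed_t(fin, fout)
        tests[bc] = {
            "chisq_stat": enr["chisq_stat"],
            "chisq_p": enr["chisq_p"],
            "enrichment_ratio": enr["enrichment_ratio"],
            "ttest_p": ttest_p,
        }
        for stratum, n, o in (
            ("FR", counts[bc]["FR"]["in"], obs[bc]["FR"]["in"]),
            ("CDR", counts[bc]["CDR"]["in"], obs[bc]["CDR"]["in"]),
            ("ALL", n_in, o_in),
            ("Outside", n_out, o_out),
        ):
            expected = total_obs * n / (n_in + n_out) if (n_in + n_out) else float("nan")
            rows.append(
                {
                    "base_class": bc,
                    "motif": motif,
                    "stratum": stratum,
                    "total_nucleotides": n,
                    "observed_mutations": o,
                    "expected_mutations": expected,
                    "mutation_freq_pct": 100.0 * o / n if n else 0.0,
                    "chisq_p": tests[bc]["chisq_p"],
                    "ttest_p": ttest_p,
                }
            )
    # expectation conservation: in + out expecteds sum to the class total
    for bc in ("GC", "AT"):
        sub = [r for r in rows if r["base_class"] == bc and r["stratum"] in ("ALL", "Outside")]
        tot = sum(r["observed_mutations"] for r in sub)
        exp = sum(r["expected_mutations"] for r in sub)
        assert tot == 0 or abs(exp - tot) < 1e-9
    return pd.DataFrame(rows), tests


def count_motifs_per_region(consensus: Consensus) -> dict[str, int]:
    """Number of DGYW/WRCH motif windows whose mutable base lies in each region.

    Windows (not deduplicated targets) are counted; a window straddling a
    region boundary is assigned by the region of its mutable position.
    """
    ann = scan_motifs(consensus)
    rm = consensus.region_map
    out: dict[str, int] = {}
    for w in ann.windows:
        if w.motif not in ("DGYW", "WRCH"):
            continue
        label = rm.label_of(w.target)
        if label is None:
            continue
        out[label] = out.get(label, 0) + 1
    return out
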