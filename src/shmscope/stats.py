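"""Summary statistics: region-stratified frequencies, tandem tables,
base mutability indices, substitution spectra and tissue comparisons.

Conventions used throughout:

* Pooled frequencies are total-count ratios (sum of mutations over sum of
  nucleotides across groups), never the mean of per-group ratios.
* The mutability index (MI) of a base is observed mutations over
  composition-expected mutations (expected = base frequency x total
  observed); MI = 1 means mutation blind to base identity.
* Base-substitution bias is tested with a paired chi-square construction,
  (G,C) together against their expecteds and (A,T) together, each on one
  degree of freedom. This is the only construction that reproduces the
  published p-values from the published occurrence/observed counts, so it
  is adopted as the convention here.
* All t-tests are unpaired pooled-variance Student tests, one-tailed, with
  the clonal group as the observation unit. No multiple-testing correction
  is applied by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import MutationCall, NSYN, SYN, UNDETERMINED
from .io import CDR_LABELS, FR_LABELS, PERIPHERY_TISSUES

logger = logging.getLogger(__name__)

BASES = ("G", "C", "A", "T")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
#: the transversion category the source tables single out
CA_GT_TRANSVERSIONS = {("C", "A"), ("A", "C"), ("G", "T"), ("T", "G")}

FINE_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "J", "C")


def pooled_frequency(mutations: Sequence[float], nucleotides: Sequence[float]) -> float:
    """Total mutations over total nucleotides (a ratio of sums)."""
    n = float(np.sum(nucleotides))
    return float(np.sum(mutations)) / n if n else 0.0


def tandem_fraction(tandem_bases: float, all_mutations: float) -> float:
    """Percent of mutations that sit inside tandem runs."""
    return 100.0 * tandem_bases / all_mutations if all_mutations else 0.0


# ---------------------------------------------------------------------------
# per-group denominators
# ---------------------------------------------------------------------------

def region_nucleotide_totals(group, consensus) -> dict[str, int]:
    """Nucleotides per region, summed over members.

    A member contributes a column only where both it and the consensus are
    non-gap: member gaps reduce that member's denominator, and insertion
    columns (consensus gaps) are excluded entirely.
    """
    totals = {r: 0 for r in FINE_REGIONS}
    rm = consensus.region_map
    for col, base in enumerate(consensus.residues):
        if base == "-":
            continue
        label = rm.label_of(col)
        if label not in totals:
            continue
        totals[label] += sum(1 for m in group.members if m.residues[col] != "-")
    return totals


# ---------------------------------------------------------------------------
# region frequency table
# ---------------------------------------------------------------------------

def region_frequency_table(analyses: Sequence) -> pd.DataFrame:
    """Per-group x region mutation counts and frequencies.

    One row per (group, region) over FR1..CDR3, J, C with synonymous,
    nonsynonymous and undetermined counts, plus total nucleotides and the
    frequency in percent. Rows are emitted even for mutation-free regions.
    """
    rows = []
    for a in analyses:
        totals = region_nucleotide_totals(a.group, a.consensus)
        counts = {r: {"syn": 0, "nsyn": 0, "undetermined": 0} for r in FINE_REGIONS}
        for c in a.calls:
            if c.region in counts:
                key = {SYN: "syn", NSYN: "nsyn"}.get(c.effect, "undetermined")
                counts[c.region][key] += 1
        for region in FINE_REGIONS:
            if not a.consensus.region_map.has_region(region):
                continue
            k = counts[region]
            total_mut = k["syn"] + k["nsyn"] + k["undetermined"]
            nt = totals[region]
            rows.append(
                {
                    "group_id": a.group.group_id,
                    "region": region,
                    "n_sequences": a.group.size,
                    "total_nucleotides": nt,
                    "syn": k["syn"],
                    "nsyn": k["nsyn"],
                    "undetermined": k["undetermined"],
                    "total_mutations": total_mut,
                    "freq_pct": 100.0 * total_mut / nt if nt else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "region", "n_sequences", "total_nucleotides",
            "syn", "nsyn", "undetermined", "total_mutations", "freq_pct",
        ],
    )


def pooled_region_summary(region_table: pd.DataFrame) -> pd.DataFrame:
    """Pooled frequencies per region and per region class (FR, CDR, V)."""
    if region_table.empty:
        return pd.DataFrame(
            [{"region": "ALL", "total_nucleotides": 0, "syn": 0, "nsyn": 0,
              "undetermined": 0, "total_mutations": 0, "freq": 0.0,
              "freq_syn": 0.0, "freq_nsyn": 0.0}]
        )

    def classify(region: str) -> list[str]:
        out = [region]
        if region in FR_LABELS:
            out.append("FR")
        if region in CDR_LABELS:
            out.append("CDR")
        if region in FR_LABELS or region in CDR_LABELS:
            out.append("ALL")
        return out

    acc: dict[str, dict[str, float]] = {}
    for row in region_table.itertuples():
        for key in classify(row.region):
            slot = acc.setdefault(
                key,
                {"total_nucleotides": 0, "syn": 0, "nsyn": 0,
                 "undetermined": 0, "total_mutations": 0},
            )
            slot["total_nucleotides"] += row.total_nucleotides
            slot["syn"] += row.syn
            slot["nsyn"] += row.nsyn
            slot["undetermined"] += row.undetermined
            slot["total_mutations"] += row.total_mutations
    order = list(FINE_REGIONS) + ["FR", "CDR", "ALL"]
    rows = []
    for key in order:
        if key not in acc:
            continue
        slot = acc[key]
        nt = slot["total_nucleotides"]
        rows.append(
            {
                "region": key,
                **{k: int(v) for k, v in slot.items()},
                "freq": slot["total_mutations"] / nt if nt else 0.0,
                "freq_syn": slot["syn"] / nt if nt else 0.0,
                "freq_nsyn": slot["nsyn"] / nt if nt else 0.0,
            }
        )
    return pd.DataFrame(rows)


def per_group_class_frequency(
    analyses: Sequence,
    region_class: str,
    effect: str | None = None,
    labels: Iterable[str] | None = None,
) -> np.ndarray:
    """Per-group mutation frequency over FR or CDR columns (optionally SYN/NSYN only)."""
    if labels is None:
        labels = FR_LABELS if region_class == "FR" else CDR_LABELS
    labels = frozenset(labels)
    freqs = []
    for a in analyses:
        totals = region_nucleotide_totals(a.group, a.consensus)
        nt = sum(totals[r] for r in labels if r in totals)
        muts = sum(
            1
            for c in a.calls
            if c.region in labels and (effect is None or c.effect == effect)
        )
        freqs.append(muts / nt if nt else 0.0)
    return np.asarray(freqs, float)


# ---------------------------------------------------------------------------
# tandem table
# ---------------------------------------------------------------------------

def tandem_table(analyses: Sequence) -> pd.DataFrame:
    """Tandem-run statistics per group and region class, plus a Total row.

    Run-length histogram columns count runs of 2, 3 and >=4 mutated bases
    (a run is assigned to FR or CDR by its first column); tandem bases
    count every mutated base belonging to a run, by its own region, so
    tandem bases + point mutations = all mutations within a class.
    """
    rows = []
    tot = {rc: {"runs2": 0, "runs3": 0, "runs4": 0, "tandem_bases": 0, "all_mutations": 0}
           for rc in ("FR", "CDR")}

    def region_class(label):
        if label in FR_LABELS:
            return "FR"
        if label in CDR_LABELS:
            return "CDR"
        return None

    for a in analyses:
        per = {rc: {"runs2": 0, "runs3": 0, "runs4": 0, "tandem_bases": 0, "all_mutations": 0}
               for rc in ("FR", "CDR")}
        for c in a.calls:
            rc = region_class(c.region)
            if rc is None:
                continue
            per[rc]["all_mutations"] += 1
            if c.tandem_run_id is not None:
                per[rc]["tandem_bases"] += 1
        for run in a.tandem_runs:
            rc = region_class(a.consensus.region_map.label_of(run.columns[0]))
            if rc is None:
                continue
            key = "runs2" if run.length == 2 else "runs3" if run.length == 3 else "runs4"
            per[rc][key] += 1
        for rc in ("FR", "CDR"):
            rows.append(
                {
                    "group_id": a.group.group_id,
                    "region_class": rc,
                    "n_sequences": a.group.size,
                    **per[rc],
                    "tandem_freq_pct": tandem_fraction(
                        per[rc]["tandem_bases"], per[rc]["all_mutations"]
                    ),
                }
            )
            for k in tot[rc]:
                tot[rc][k] += per[rc][k]
    for rc in ("FR", "CDR"):
        rows.append(
            {
                "group_id": "Total",
                "region_class": rc,
                "n_sequences": sum(a.group.size for a in analyses),
                **tot[rc],
                "tandem_freq_pct": tandem_fraction(
                    tot[rc]["tandem_bases"], tot[rc]["all_mutations"]
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutability indices
# ---------------------------------------------------------------------------

def mutability_from_counts(
    occurrence: Mapping[str, float], observed: Mapping[str, float]
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Mutability-index table from base occurrence and observed-mutation counts.

    expected_b = (occurrence_b / total occurrence) x total observed;
    MI_b = observed_b / expected_b (NA when expected is 0). The paired
    chi-square tests are computed over (G,C) and over (A,T): the statistic
    sums (O-E)^2/E for the two bases of the pair and is referred to a
    chi-square distribution on one degree of freedom.
    """
    total_occ = float(sum(occurrence.get(b, 0) for b in BASES))
    total_obs = float(sum(observed.get(b, 0) for b in BASES))
    rows = []
    expected = {}
    for b in BASES:
        occ = float(occurrence.get(b, 0))
        obs = float(observed.get(b, 0))
        prob = occ / total_occ if total_occ else 0.0
        exp = prob * total_obs
        expected[b] = exp
        mi = obs / exp if exp > 0 else float("nan")
        rows.append(
            {
                "base": b,
                "occurrence": int(occ),
                "probability": prob,
                "observed": int(obs),
                "expected": exp,
                "mutability_index": mi,
            }
        )
    rows.append(
        {
            "base": "Total",
            "occurrence": int(total_occ),
            "probability": 1.0 if total_occ else 0.0,
            "observed": int(total_obs),
            "expected": total_obs,
            "mutability_index": float("nan"),
        }
    )
    tests = {}
    for name, pair in (("GC", ("G", "C")), ("AT", ("A", "T"))):
        stat = 0.0
        ok = all(expected[b] > 0 for b in pair)
        if ok:
            for b in pair:
                stat += (float(observed.get(b, 0)) - expected[b]) ** 2 / expected[b]
            p = float(sps.chi2.sf(stat, df=1))
        else:
            stat, p = float("nan"), float("nan")
        tests[name] = {"chisq_stat": stat, "chisq_p": p}
    return pd.DataFrame(rows), tests


def base_composition(analyses: Sequence, region_labels: Iterable[str]) -> dict[str, int]:
    """Occurrence of each consensus base over members' non-gap columns."""
    labels = set(region_labels)
    occ = {b: 0 for b in BASES}
    for a in analyses:
        rm = a.consensus.region_map
        for col, base in enumerate(a.consensus.residues):
            if base == "-" or rm.label_of(col) not in labels:
                continue
            occ[base] += sum(1 for m in a.group.members if m.residues[col] != "-")
    return occ


def mutability_table(
    analyses: Sequence, stratum: str = "ALL"
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Mutability indices computed from analyzed groups.

    ``stratum`` selects the columns considered: "ALL" (FR+CDR), "FR" or
    "CDR". Occurrence is consensus base composition weighted by member
    coverage; observed counts are mutation calls in those regions.
    """
    if stratum == "ALL":
        labels = FR_LABELS | CDR_LABELS
    elif stratum == "FR":
        labels = FR_LABELS
    elif stratum == "CDR":
        labels = CDR_LABELS
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    occ = base_composition(analyses, labels)
    obs = {b: 0 for b in BASES}
    for a in analyses:
        for c in a.calls:
            if c.region in labels:
                obs[c.consensus_base] += 1
    return mutability_from_counts(occ, obs)


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------

def substitution_spectrum(calls: Sequence[MutationCall]) -> dict[str, float]:
    """Transition / C:A-or-G:T transversion / G:C-target shares of all calls."""
    n = len(calls)
    if n == 0:
        return {
            "n": 0, "transition_pct": 0.0,
            "ca_gt_transversion_pct": 0.0, "gc_mutation_pct": 0.0,
        }
    transitions = sum(
        1 for c in calls if (c.consensus_base, c.observed_base) in TRANSITIONS
    )
    ca_gt = sum(
        1 for c in calls if (c.consensus_base, c.observed_base) in CA_GT_TRANSVERSIONS
    )
    gc = sum(1 for c in calls if c.base_class == "GC")
    return {
        "n": n,
        "transition_pct": 100.0 * transitions / n,
        "ca_gt_transversion_pct": 100.0 * ca_gt / n,
        "gc_mutation_pct": 100.0 * gc / n,
    }


# ---------------------------------------------------------------------------
# tissue stratification
# ---------------------------------------------------------------------------

def _tissue_class(tissue: str) -> str | None:
    if tissue == "THY":
        return "thymus"
    if tissue in PERIPHERY_TISSUES:
        return "periphery"
    return None


def tissue_stratified_table(
    analyses: Sequence,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mutation counts and frequencies per tissue class (thymus vs periphery).

    Denominators and calls are restricted to each group's members from the
    tissue class in question. The accompanying one-tailed t-tests compare
    per-group FR (and CDR) frequencies, periphery > thymus; a class with
    fewer than two contributing groups skips the test with a warning.
    """
    from .hotspots import _one_tailed_t

    per_class_rows = []
    group_freqs: dict[str, dict[str, list[float]]] = {
        "thymus": {"FR": [], "CDR": []},
        "periphery": {"FR": [], "CDR": []},
    }
    agg: dict[str, dict[str, dict[str, float]]] = {
        tc: {r: {"syn": 0, "nsyn": 0, "undetermined": 0, "total": 0, "nt": 0}
             for r in FINE_REGIONS}
        for tc in ("thymus", "periphery")
    }
    n_seqs = {"thymus": 0, "periphery": 0}
    for a in analyses:
        rm = a.consensus.region_map
        for tc in ("thymus", "periphery"):
            members = [m for m in a.group.members if _tissue_class(m.tissue) == tc]
            if not members:
                continue
            n_seqs[tc] += len(members)
            member_ids = {m.seq_id for m in members}
            nt = {r: 0 for r in FINE_REGIONS}
            for col, base in enumerate(a.consensus.residues):
                if base == "-":
                    continue
                label = rm.label_of(col)
                if label in nt:
                    nt[label] += sum(1 for m in members if m.residues[col] != "-")
            muts = {r: {"syn": 0, "nsyn": 0, "undetermined": 0, "total": 0}
                    for r in FINE_REGIONS}
            for c in a.calls:
                if c.seq_id in member_ids and c.region in muts:
                    key = {SYN: "syn", NSYN: "nsyn"}.get(c.effect, "undetermined")
                    muts[c.region][key] += 1
                    muts[c.region]["total"] += 1
            for r in FINE_REGIONS:
                agg[tc][r]["nt"] += nt[r]
                for k in ("syn", "nsyn", "undetermined", "total"):
                    agg[tc][r][k] += muts[r][k]
            for rc, labels in (("FR", FR_LABELS), ("CDR", CDR_LABELS)):
                denom = sum(nt[r] for r in labels)
                num = sum(muts[r]["total"] for r in labels)
                if denom:
                    group_freqs[tc][rc].append(num / denom)

    for tc in ("thymus", "periphery"):
        for rc, labels in (("FR", FR_LABELS), ("CDR", CDR_LABELS)):
            nt = sum(agg[tc][r]["nt"] for r in labels)
            for kind in ("nsyn", "syn", "total"):
                count = sum(agg[tc][r][kind] for r in labels)
                per_class_rows.append(
                    {
                        "tissue_class": tc,
                        "n_sequences": n_seqs[tc],
                        "region_class": rc,
                        "mutation_type": {"nsyn": "N", "syn": "S", "total": "ALL"}[kind],
                        "mutations": count,
                        "total_nucleotides": nt,
                        "freq_pct": 100.0 * count / nt if nt else 0.0,
                    }
                )

    tests = {}
    for rc in ("FR", "CDR"):
        thy, per = group_freqs["thymus"][rc], group_freqs["periphery"][rc]
        if len(thy) < 2 or len(per) < 2:
            logger.warning(
                "tissue comparison (%s): <2 groups in a tissue class; test skipped", rc
            )
            tests[rc] = float("nan")
        else:
            tests[rc] = _one_tailed_t(per, thy)
    return pd.DataFrame(per_class_rows), tests


# ---------------------------------------------------------------------------
# CDR vs FR comparison
# ---------------------------------------------------------------------------

def compare_cdr_fr(analyses: Sequence, include_cdr3: bool = False) -> dict[str, float]:
    """One-tailed p-values (CDR > FR) for ALL / NSYN / SYN per-group frequencies.

    The observation unit is the clonal group; the test is an unpaired
    pooled-variance Student t, one-tailed in the CDR > FR direction.

    By default CDR3 is excluded from the tested CDR frequency: clonal
    groups are defined by an identical CDR3-J junction, so within a group
    the CDR3 columns are identical by construction and can never exhibit a
    mutation. Including those structurally mutation-free columns in the
    denominator would bias the comparison toward FR regardless of the true
    targeting; the descriptive region tables still report CDR3 as counted.
    """
    from .hotspots import _one_tailed_t

    if len(analyses) < 2:
        raise ValueError("need >=2 analyzed groups to compare CDR vs FR")
    cdr_labels = CDR_LABELS if include_cdr3 else frozenset({"CDR1", "CDR2"})
    out = {}
    for name, effect in (("ALL", None), ("NSYN", NSYN), ("SYN", SYN)):
        cdr = per_group_class_frequency(analyses, "CDR", effect, labels=cdr_labels)
        fr = per_group_class_frequency(analyses, "FR", effect)
        out[name] = _one_tailed_t(cdr, fr)
    return out
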