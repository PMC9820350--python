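"""Expression quantification: RPKM with multiread and partial-alignment
handling, active-peptidase percentage normalization, and midgut
fractionation arithmetic.

The quantification rules:

* each read contributes exactly one unit in total; a multiread (a read
  aligning to more than one contig) is counted once, not once per
  target — by default the unit goes to the best-scoring target (ties
  broken lexicographically by contig id), optionally split 1/k over the
  k targets (``policy="fractional"``);
* a unit on a contig that aligns only partially is scaled by the
  aligned fraction when that fraction exceeds 50% of the contig length,
  and contributes nothing below that cutoff;
* RPKM = units / (gene length in kb) / (total mapped reads in millions).

For cross-species comparison each active proline-specific peptidase's
RPKM is expressed as a percentage of the summed RPKM of all active
PSPs. Catalytically dead homologs (DPP 10) and the broad-specificity
peptidases for which post-proline cleavage is incidental (LAP, CND) are
excluded from the denominator and carry no percentage.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Peptidase types whose expression enters the active-PSP denominator.
ACTIVE_PSP_TYPES = frozenset(
    {"POP", "DPP4", "DPP8", "PRCP", "APP1", "APP2", "APP3", "XPD"})
#: Types always excluded: inactive homolog and broad-specificity enzymes.
EXCLUDED_PSP_TYPES = frozenset({"DPP10", "LAP", "CND"})


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment line."""

    read_id: str
    contig_id: str
    score: float
    aligned_len: int
    contig_len: int

    def __post_init__(self) -> None:
        if self.contig_len <= 0:
            raise ValueError(f"{self.read_id}: contig_len must be positive")
        if not 0 <= self.aligned_len <= self.contig_len:
            raise ValueError(
                f"{self.read_id}: aligned_len must be in [0, contig_len]")


@dataclass
class ExpressionRecord:
    gene_id: str
    psp_type: str
    rpkm: float
    active: bool
    percent_active: Optional[float] = None


@dataclass(frozen=True)
class FractionActivity:
    """Raw activities of one peptidase across midgut fractions.

    ``activities`` maps (section, fraction) -> activity in arbitrary
    units, with section in {"AM", "PM"} (anterior/posterior mesenteron)
    and fraction in {"soluble_contents", "insoluble_contents",
    "soluble_tissue", "insoluble_tissue"}.
    """

    peptidase_id: str
    activities: dict

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.activities.values()):
            raise ValueError("activities must be non-negative")


def contig_weight(contig_len: int, aligned_len: int) -> float:
    """Contribution weight of a partial alignment.

    Proportional to the aligned part when it exceeds half the contig's
    length, zero otherwise.
    """
    if contig_len <= 0:
        raise ValueError("contig_len must be positive")
    if not 0 <= aligned_len <= contig_len:
        raise ValueError("aligned_len must be in [0, contig_len]")
    frac = aligned_len / contig_len
    return frac if frac > 0.5 else 0.0


def count_units(records: Sequence[AlignmentRecord],
                policy: str = "best") -> dict[str, float]:
    """Read units per contig; every read contributes exactly one unit.

    ``policy="best"``: a multiread's unit goes to its best-scoring
    contig (ties -> lexicographically first). ``policy="fractional"``:
    the unit is split equally over the read's k targets. Contigs that
    appear in the input but receive no unit are reported with 0.
    """
    if policy not in ("best", "fractional"):
        raise ValueError(f"unknown multiread policy {policy!r}")
    units: dict[str, float] = {r.contig_id: 0.0 for r in records}
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        by_read[r.read_id].append(r)
    for hits in by_read.values():
        if policy == "fractional":
            for h in hits:
                units[h.contig_id] += 1.0 / len(hits)
        else:
            best = min(hits, key=lambda h: (-h.score, h.contig_id))
            units[best.contig_id] += 1.0
    return units


def rpkm(units: float, gene_len: int, total_mapped: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_len <= 0 or total_mapped <= 0:
        raise ValueError("gene_len and total_mapped must be positive")
    return units / (gene_len / 1000.0) / (total_mapped / 1e6)


def quantify(records: Sequence[AlignmentRecord],
             policy: str = "best",
             weight_partials: bool = True) -> pd.DataFrame:
    """Per-contig units and RPKM from an alignment table.

    Unit assignment follows the multiread policy; each assigned unit is
    then scaled by :func:`contig_weight` of its alignment (full
    alignments weigh 1). ``total_mapped`` is the number of distinct
    reads in the table.
    """
    if not records:
        raise ValueError("no alignment records")
    total_reads = len({r.read_id for r in records})
    units: dict[str, float] = {r.contig_id: 0.0 for r in records}
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        by_read[r.read_id].append(r)
    for hits in by_read.values():
        if policy == "fractional":
            chosen = [(h, 1.0 / len(hits)) for h in hits]
        elif policy == "best":
            chosen = [(min(hits, key=lambda h: (-h.score, h.contig_id)), 1.0)]
        else:
            raise ValueError(f"unknown multiread policy {policy!r}")
        for h, u in chosen:
            w = contig_weight(h.contig_len, h.aligned_len) if weight_partials else 1.0
            units[h.contig_id] += u * w
    contig_lens = {r.contig_id: r.contig_len for r in records}
    rows = [
        {
            "contig_id": cid,
            "length": contig_lens[cid],
            "units": u,
            "rpkm": rpkm(u, contig_lens[cid], total_reads),
        }
        for cid, u in sorted(units.items())
    ]
    return pd.DataFrame(rows, columns=["contig_id", "length", "units", "rpkm"])


def active_psp_percentages(records: Iterable[ExpressionRecord],
                           ndigits: int = 1) -> list[ExpressionRecord]:
    """Fill percent_active = 100 * RPKM / sum(RPKM of active PSPs).

    Records whose type is in the excluded set (DPP10, LAP, CND) never
    enter the denominator and keep ``percent_active=None``. Percentages
    are rounded to ``ndigits`` decimals for reporting.
    """
    records = list(records)
    active = [r for r in records
              if r.active and r.psp_type not in EXCLUDED_PSP_TYPES]
    if not active:
        raise ValueError("no active records")
    total = sum(r.rpkm for r in active)
    if total <= 0:
        raise ValueError("active RPKM sum is zero")
    for r in records:
        if r.active and r.psp_type not in EXCLUDED_PSP_TYPES:
            r.percent_active = round(100.0 * r.rpkm / total, ndigits)
        else:
            r.percent_active = None
    return records


def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "psp_type": r.psp_type,
            "rpkm": r.rpkm,
            "active": r.active,
            "percent_active": r.percent_active,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "gene_id", "psp_type", "rpkm", "active", "percent_active"])


def fraction_percentages(fa: FractionActivity) -> tuple[tuple[float, float], dict]:
    """((AM%, PM%), per-section fraction distribution).

    AM% and PM% are percentages of the summed activity across both
    midgut sections; within each section the four fractions are
    expressed as percentages of that section's total. Each percentage
    set sums to 100.
    """
    am = sum(v for (sec, _), v in fa.activities.items() if sec == "AM")
    pm = sum(v for (sec, _), v in fa.activities.items() if sec == "PM")
    total = am + pm
    if total <= 0:
        raise ValueError("total activity must be positive")
    dist: dict = {}
    for sec, sec_total in (("AM", am), ("PM", pm)):
        fracs = {f: v for (s, f), v in fa.activities.items() if s == sec}
        if sec_total > 0:
            dist[sec] = {f: 100.0 * v / sec_total for f, v in fracs.items()}
        else:
            dist[sec] = {f: math.nan for f in fracs}
    return (100.0 * am / total, 100.0 * pm / total), dist


# -- packaged expression fixtures ------------------------------------------

def load_expression_table(species: str) -> list[ExpressionRecord]:
    """Published midgut RPKM values for ``"tcastaneum"`` or ``"tmolitor"``.

    The active flag is derived from the peptidase type: DPP10, LAP and
    CND are inactive or excluded, everything else active.
    """
    name = f"expression_{species}.tsv"
    with resources.files("pspkit.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        ExpressionRecord(
            gene_id=row["gene_id"],
            psp_type=row["psp_type"],
            rpkm=float(row["rpkm"]),
            active=row["psp_type"] in ACTIVE_PSP_TYPES,
        )
        for _, row in df.iterrows()
    ]


def load_published_percentages(species: str) -> dict[str, float]:
    """Published percentage shares, keyed by gene id (active PSPs only)."""
    name = f"expression_{species}.tsv"
    with resources.files("pspkit.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for _, row in df.iterrows():
        if row["published_percent"] != "-":
            out[row["gene_id"]] = float(row["published_percent"])
    return out


def read_alignment_tsv(path) -> list[AlignmentRecord]:
    """Read an alignment table (read_id, contig_id, score, aligned_len,
    contig_len) from TSV."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentRecord(str(r.read_id), str(r.contig_id), float(r.score),
                        int(r.aligned_len), int(r.contig_len))
        for r in df.itertuples(index=False)
    ]


def write_alignment_tsv(records: Sequence[AlignmentRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
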