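"""Staged digestion engine for Gln/Pro-rich peptides.

Models the cooperative hydrolysis of immunogenic gliadin fragments by an
insect digestive peptidase complex as a sequence of stages: luminal
post-glutamine endoproteolysis (cysteine cathepsins), brush-border /
epithelial proline-specific exopeptidolysis (DPP 4, PRCP, ...), and
cytoplasmic dipeptide clearance (prolidase XPD). Within each stage the
engine repeatedly fires the first applicable (enzyme, fragment, bond)
event — lowest enzyme priority (panel listing order) first, then first
fragment in left-to-right order, then lowest bond index — until nothing
in the stage applies, then advances to the next stage. The fixed
priority order makes every digest fully deterministic.

Fragments reduced to a single residue become free amino acids and are no
longer substrates. Residue conservation (input multiset == residuals +
free residues) holds for every digest and is the engine's core
invariant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .peptide import Peptide, expand_repeats
from .rules import CleavageRule, applicable_sites, cleave_at, default_rules

#: The 26-mer gamma-gliadin immunogenic fragment used as the worked example.
GLIADIN_26MER = "FLQPQQPFPQQPQQPYPQQPQQPFPQ"

#: Gln/Pro-rich gliadin peptides resistant to human digestive peptidases,
#: in compact repeat notation where applicable.
GLIADIN_PEPTIDES: dict[str, str] = {
    "alpha_12mer": "QLQPFPQPQLPY",
    "alpha_13mer": "PQPQLPYPQPQLP",
    "alpha_19mer": "LGQQQPFPPQQPYPQPQPF",
    "alpha_27mer": "LQLQPF(PQPQLPY)_3_PQPQPF",
    "gamma_26mer": "FLQPQQPF(PQQ)_2_PY(PQQ)_2_PFPQ",
}

#: Residual fragments regarded as non-immunogenic.
DEFAULT_ALLOWLIST = frozenset({"FLQP"})


@dataclass(frozen=True)
class Stage:
    label: str
    enzymes: tuple[str, ...]
    compartment: str = "lumen"  # annotation only; does not gate chemistry


@dataclass(frozen=True)
class EnzymePanel:
    """Ordered stages of enzyme ids; order within a stage is priority."""

    name: str
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages or any(not s.enzymes for s in self.stages):
            raise ValueError("panel must have non-empty stages")

    def enzyme_ids(self) -> list[str]:
        return [e for s in self.stages for e in s.enzymes]


#: The core hydrolysis scheme: cathepsins, then DPP 4 + PRCP, then XPD.
DEFAULT_PANEL = EnzymePanel(
    "core",
    (
        Stage("luminal", ("CC",), "lumen"),
        Stage("brush_border", ("DPP4", "PRCP"), "epithelium"),
        Stage("cytoplasmic", ("XPD",), "epithelium"),
    ),
)

#: Full complement: adds POP to the luminal stage, DPP 8 / APP / LAP to
#: the exopeptidase stage and CND to dipeptide clearance.
EXTENDED_PANEL = EnzymePanel(
    "extended",
    (
        Stage("luminal", ("CC", "POP"), "lumen"),
        Stage("brush_border", ("DPP4", "DPP8", "PRCP", "APP", "LAP"), "epithelium"),
        Stage("cytoplasmic", ("XPD", "CND"), "epithelium"),
    ),
)

PANELS: dict[str, EnzymePanel] = {p.name: p for p in (DEFAULT_PANEL, EXTENDED_PANEL)}


@dataclass(frozen=True)
class DigestEvent:
    stage: str
    enzyme: str
    parent_id: str
    parent_seq: str
    bond: int
    products: tuple[str, str]


@dataclass
class DigestResult:
    input_id: str
    input_seq: str
    residuals: list[Peptide]          # fragments of length >= 2 remaining
    free_residues: Counter            # single residues released
    events: list[DigestEvent]

    @property
    def n_free(self) -> int:
        return sum(self.free_residues.values())

    def residue_balance(self) -> tuple[Counter, Counter]:
        """(input multiset, output multiset) — equal for every digest."""
        out = Counter(self.free_residues)
        for frag in self.residuals:
            out.update(frag.seq)
        return Counter(self.input_seq), out


@dataclass(frozen=True)
class ResidualReport:
    input_id: str
    complete: bool
    residual_fragments: tuple[str, ...]  # residuals not on the allowlist
    allowlisted: tuple[str, ...]


def digest(p: Peptide,
           panel: EnzymePanel = DEFAULT_PANEL,
           rules: Optional[dict[str, CleavageRule]] = None,
           cc_mode: str = "post_q") -> DigestResult:
    """Digest ``p`` through the panel's stages to a fixed point.

    Deterministic given the panel: within a stage the firing order is
    enzyme priority (listing order), then fragment order (left to
    right), then lowest bond. Raises ``KeyError``-derived config errors
    for enzyme ids missing from the rule map.
    """
    if len(p) == 0:
        raise ValueError("cannot digest an empty peptide")
    if rules is None:
        rules = default_rules(cc_mode=cc_mode)
    for enzyme in panel.enzyme_ids():
        if enzyme not in rules:
            raise KeyError(f"panel enzyme {enzyme!r} not found in rule map")

    free: Counter = Counter()
    events: list[DigestEvent] = []

    def absorb(frag: Peptide, pool: list[Peptide], at: int) -> None:
        """Insert fragment into the pool at index, or free a single residue."""
        if len(frag) == 1:
            free[frag.seq] += 1
        else:
            pool.insert(at, frag)

    fragments: list[Peptide] = []
    absorb(p, fragments, 0)

    for stage in panel.stages:
        while True:
            fired = False
            for enzyme in stage.enzymes:
                rule = rules[enzyme]
                for idx, frag in enumerate(fragments):
                    sites = applicable_sites(rule, frag)
                    if not sites:
                        continue
                    bond = sites[0]
                    left, right = cleave_at(frag, bond)
                    events.append(DigestEvent(
                        stage.label, enzyme, frag.id, frag.seq, bond,
                        (left.seq, right.seq)))
                    fragments.pop(idx)
                    absorb(right, fragments, idx)
                    absorb(left, fragments, idx)
                    fired = True
                    break
                if fired:
                    break
            if not fired:
                break

    return DigestResult(p.id, p.seq, fragments, free, events)


def assess_residuals(result: DigestResult,
                     allowlist: Iterable[str] = DEFAULT_ALLOWLIST) -> ResidualReport:
    """Judge whether a digest is complete up to non-immunogenic residuals."""
    allowed = {expand_repeats(s) for s in allowlist}
    allowlisted = tuple(f.seq for f in result.residuals if f.seq in allowed)
    leftovers = tuple(f.seq for f in result.residuals if f.seq not in allowed)
    return ResidualReport(result.input_id, not leftovers, leftovers, allowlisted)


def digest_report(peptides: Sequence,
                  panel: EnzymePanel = DEFAULT_PANEL,
                  rules: Optional[dict[str, CleavageRule]] = None,
                  allowlist: Iterable[str] = DEFAULT_ALLOWLIST,
                  cc_mode: str = "post_q") -> pd.DataFrame:
    """Batch digestion summary, one row per input peptide.

    Inputs may be :class:`Peptide` objects or ``(id, sequence)`` pairs;
    sequences may use the compact ``(MOTIF)_n_`` repeat notation, which
    is expanded before digestion.
    """
    rows = []
    for item in peptides:
        pid, seq = (item.id, item.seq) if isinstance(item, Peptide) else item
        expanded = Peptide(pid, expand_repeats(seq))
        res = digest(expanded, panel, rules, cc_mode=cc_mode)
        rep = assess_residuals(res, allowlist)
        inp, out = res.residue_balance()
        rows.append({
            "id": pid,
            "length": len(expanded),
            "n_events": len(res.events),
            "n_free_residues": res.n_free,
            "residuals": ",".join(sorted(f.seq for f in res.residuals)),
            "complete": rep.complete,
            "conserved": inp == out,
        })
    return pd.DataFrame(rows, columns=[
        "id", "length", "n_events", "n_free_residues",
        "residuals", "complete", "conserved",
    ])
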