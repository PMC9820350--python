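"""Substrate-specificity rules of the digestive peptidase complex.

Each peptidase is encoded as a :class:`CleavageRule`: an action mode
(endo / N-terminal dipeptidyl / N- or C-terminal monopeptidase /
dipeptidase), residue-class constraints on the P2, P1 and P1' positions
of the scissile bond, and substrate length bounds. The classes mirror
the Xaa / Xbb placeholders of substrate general formulas: Xaa is any
amino acid, Xbb any amino acid except proline.

Bond indexing is 1-based: bond ``k`` lies between residues ``k`` and
``k+1``, so valid bonds on an n-mer are ``1 .. n-1``.

The nine frozen default rules:

=======  ================================================================
enzyme   specificity
=======  ================================================================
CC       cysteine cathepsins; endo, cleave after Gln unless Pro follows
POP      prolyl oligopeptidase; endo, Xbb-Pro|Xbb with 1-15 residue
         flanks on each side of the three-residue core (5-33mers only)
DPP4     dipeptidyl peptidase 4; releases Xbb-Pro dipeptide from the
         N-terminus when a non-Pro residue follows
DPP8     same S9B formula as DPP4, distinct enzyme id
PRCP     prolyl carboxypeptidase; releases the C-terminal non-Pro
         residue that follows a Pro
APP      aminopeptidase P; releases the N-terminal non-Pro residue
         preceding a Pro, on 3-11mers
XPD      prolidase; cleaves Xbb-Pro dipeptides
LAP      leucyl aminopeptidase; releases any N-terminal residue when a
         non-Pro residue follows (chains of length >= 2)
CND      cytosolic non-specific dipeptidase; any dipeptide except
         Pro-Pro
=======  ================================================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import yaml

from .peptide import Peptide

ENZYME_IDS = ("CC", "POP", "DPP4", "DPP8", "PRCP", "APP", "XPD", "LAP", "CND")


class Action(str, enum.Enum):
    ENDO = "endo"
    N_DIPEPTIDYL = "n_dipeptidyl"
    N_MONO = "n_mono"
    C_MONO = "c_mono"
    DIPEPTIDASE = "dipeptidase"


#: Residue-class predicates over single residues.
RESIDUE_CLASSES: dict[str, Callable[[str], bool]] = {
    "any": lambda r: True,          # Xaa
    "non_pro": lambda r: r != "P",  # Xbb
    "pro": lambda r: r == "P",
    "gln": lambda r: r == "Q",
}


@dataclass(frozen=True)
class CleavageRule:
    """One peptidase's action mode plus positional and length constraints.

    ``p2_class`` / ``p1_class`` / ``p1prime_class`` constrain the residues
    around the scissile bond; which sequence positions those map onto
    depends on the action (e.g. for an N-dipeptidyl enzyme they are
    substrate positions 1, 2 and 3). ``flank_bounds`` (POP only) bounds
    the residue counts strictly outside the P2-P1-P1' core on each side.
    ``exclude_pairs`` lists dipeptides a dipeptidase refuses outright.
    """

    enzyme: str
    action: Action
    p2_class: str = "any"
    p1_class: str = "any"
    p1prime_class: str = "any"
    min_len: int = 2
    max_len: Optional[int] = None
    flank_bounds: Optional[tuple[int, int]] = None
    exclude_pairs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.action is Action.DIPEPTIDASE and not (
            self.min_len == 2 and self.max_len == 2
        ):
            raise ValueError("dipeptidase rules must have min_len = max_len = 2")
        for cls in (self.p2_class, self.p1_class, self.p1prime_class):
            if cls not in RESIDUE_CLASSES:
                raise ValueError(f"unknown residue class {cls!r}")


def default_rules(cc_mode: str = "post_q") -> dict[str, CleavageRule]:
    """The nine frozen rules of the digestive complex.

    ``cc_mode`` selects the cysteine-cathepsin specificity: ``"post_q"``
    (cleave after any Gln not followed by Pro) or ``"qq_only"``
    (Gln|Gln bonds only). On Gln/Pro-rich gliadin repeats the two modes
    typically coincide, because nearly every Gln is followed by Gln or
    Pro.
    """
    if cc_mode not in ("post_q", "qq_only"):
        raise ValueError(f"unknown cc_mode {cc_mode!r}")
    cc_p1prime = "non_pro" if cc_mode == "post_q" else "gln"
    return {
        "CC": CleavageRule("CC", Action.ENDO, p1_class="gln",
                           p1prime_class=cc_p1prime, min_len=3),
        "POP": CleavageRule("POP", Action.ENDO, p2_class="non_pro",
                            p1_class="pro", p1prime_class="non_pro",
                            min_len=5, max_len=33, flank_bounds=(1, 15)),
        "DPP4": CleavageRule("DPP4", Action.N_DIPEPTIDYL, p2_class="non_pro",
                             p1_class="pro", p1prime_class="non_pro", min_len=3),
        "DPP8": CleavageRule("DPP8", Action.N_DIPEPTIDYL, p2_class="non_pro",
                             p1_class="pro", p1prime_class="non_pro", min_len=3),
        "PRCP": CleavageRule("PRCP", Action.C_MONO, p2_class="non_pro",
                             p1_class="pro", p1prime_class="non_pro", min_len=3),
        "APP": CleavageRule("APP", Action.N_MONO, p1_class="non_pro",
                            p1prime_class="pro", min_len=3, max_len=11),
        "XPD": CleavageRule("XPD", Action.DIPEPTIDASE, p1_class="non_pro",
                            p1prime_class="pro", min_len=2, max_len=2),
        "LAP": CleavageRule("LAP", Action.N_MONO, p1_class="any",
                            p1prime_class="non_pro", min_len=2),
        "CND": CleavageRule("CND", Action.DIPEPTIDASE, min_len=2, max_len=2,
                            exclude_pairs=("PP",)),
    }


def applicable_sites(rule: CleavageRule, p: Peptide) -> list[int]:
    """Bond indices (1-based, sorted) at which ``rule`` may cleave ``p``.

    Pure in (rule, sequence); an empty list means the substrate violates
    the length bounds or no position matches the positional classes.
    """
    seq = p.seq
    n = len(seq)
    if n < rule.min_len or (rule.max_len is not None and n > rule.max_len):
        return []
    p2 = RESIDUE_CLASSES[rule.p2_class]
    p1 = RESIDUE_CLASSES[rule.p1_class]
    p1p = RESIDUE_CLASSES[rule.p1prime_class]

    if rule.action is Action.ENDO:
        sites = []
        for k in range(1, n):  # bond between residues k and k+1
            if not (p1(seq[k - 1]) and p1p(seq[k])):
                continue
            if rule.p2_class != "any":
                if k < 2 or not p2(seq[k - 2]):
                    continue
            if rule.flank_bounds is not None:
                lo, hi = rule.flank_bounds
                n_flank = k - 2      # residues N-terminal of the P2 position
                c_flank = n - k - 1  # residues C-terminal of the P1' position
                if not (lo <= n_flank <= hi and lo <= c_flank <= hi):
                    continue
            sites.append(k)
        return sites

    if rule.action is Action.N_DIPEPTIDYL:
        # scissile bond fixed between positions 2 and 3
        if n >= 3 and p2(seq[0]) and p1(seq[1]) and p1p(seq[2]):
            return [2]
        return []

    if rule.action is Action.N_MONO:
        if p1(seq[0]) and p1p(seq[1]):
            return [1]
        return []

    if rule.action is Action.C_MONO:
        if n >= 3 and p2(seq[n - 3]) and p1(seq[n - 2]) and p1p(seq[n - 1]):
            return [n - 1]
        return []

    if rule.action is Action.DIPEPTIDASE:
        if seq in rule.exclude_pairs:
            return []
        if p1(seq[0]) and p1p(seq[1]):
            return [1]
        return []

    raise AssertionError(f"unhandled action {rule.action}")


def cleave_at(p: Peptide, bond: int) -> tuple[Peptide, Peptide]:
    """Split ``p`` at bond ``bond`` into (left, right) fragments.

    Fragment ids carry 1-based inclusive coordinates relative to the
    parent, e.g. ``pep[1-2]`` / ``pep[3-5]``.
    """
    n = len(p)
    if not 1 <= bond < n:
        raise ValueError(f"bond {bond} out of range for length-{n} peptide {p.id!r}")
    left = Peptide(f"{p.id}[1-{bond}]", p.seq[:bond])
    right = Peptide(f"{p.id}[{bond + 1}-{n}]", p.seq[bond:])
    return left, right


# -- rule (de)serialization ------------------------------------------------

def rules_to_config(rules: dict[str, CleavageRule]) -> dict:
    out = {}
    for name, r in rules.items():
        d = {
            "action": r.action.value,
            "p2_class": r.p2_class,
            "p1_class": r.p1_class,
            "p1prime_class": r.p1prime_class,
            "min_len": r.min_len,
        }
        if r.max_len is not None:
            d["max_len"] = r.max_len
        if r.flank_bounds is not None:
            d["flank_bounds"] = list(r.flank_bounds)
        if r.exclude_pairs:
            d["exclude_pairs"] = list(r.exclude_pairs)
        out[name] = d
    return out


def rules_from_config(config: dict) -> dict[str, CleavageRule]:
    rules = {}
    for name, d in config.items():
        rules[name] = CleavageRule(
            enzyme=name,
            action=Action(d["action"]),
            p2_class=d.get("p2_class", "any"),
            p1_class=d.get("p1_class", "any"),
            p1prime_class=d.get("p1prime_class", "any"),
            min_len=d.get("min_len", 2),
            max_len=d.get("max_len"),
            flank_bounds=tuple(d["flank_bounds"]) if "flank_bounds" in d else None,
            exclude_pairs=tuple(d.get("exclude_pairs", ())),
        )
    return rules


def save_rules(rules: dict[str, CleavageRule], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rules_to_config(rules), fh, sort_keys=True)


def load_rules(path: str) -> dict[str, CleavageRule]:
    with open(path) as fh:
        return rules_from_config(yaml.safe_load(fh))
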