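"""Family and activity classification of candidate peptidase sequences.

A candidate is aligned pairwise against each reference profile and its
residues are read off at the profile's anchor positions: catalytic-triad
residues for the serine families (S9A prolyl oligopeptidase, S9B
dipeptidyl peptidases, S28 prolyl carboxypeptidase), metal-binding and
essential residues for the metallopeptidases (M24B aminopeptidase P /
prolidase, M17 leucyl aminopeptidase, M20 non-specific dipeptidase).

Activity calls:

* ``active`` — every catalytic / metal / essential anchor carries an
  admissible residue;
* ``inactive_homolog`` — the catalytic-serine anchor carries a
  non-catalytic residue (classically Ser -> Gly, the DPP 10 situation)
  while the remaining key anchors are intact;
* ``incomplete`` — an anchor falls in a gap or deviates in any other
  pattern.

S9B candidates additionally get an exopeptidase-only vs
endopeptidase-capable annotation from the substrate-tunnel determinant
position (Asp/Asn -> exo-only, the DPP 4 situation; a small Ala there
marks FAP-like endopeptidase capability). S9A candidates are annotated
with the presence of the subfamily's conserved sequence motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .peptide import Peptide

KEY_ROLES = frozenset({"catalytic", "metal", "essential"})


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment scoring for anchor transfer."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    free_end_gaps: bool = True  # tolerate terminal extensions/truncations

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


DEFAULT_ALIGN_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class Anchor:
    role: str       # catalytic | S1 | S2 | S3 | metal | essential | determinant
    position: int   # 1-based residue index in the reference sequence
    expected: frozenset


@dataclass(frozen=True)
class AnchorProfile:
    """Reference anchor residues for one peptidase family."""

    family: str                 # S9A, S9B, S9X, S28, M24B, M17, M20
    reference_id: str
    reference_seq: Peptide
    anchors: tuple[Anchor, ...]
    motifs: tuple[str, ...] = ()
    #: S9B exo/endo determinant: reference position and the residue sets
    #: marking exopeptidase-only vs endopeptidase-capable enzymes.
    determinant_position: Optional[int] = None
    determinant_exo: frozenset = frozenset({"D", "N"})

    def __post_init__(self) -> None:
        n = len(self.reference_seq)
        for a in self.anchors:
            if not 1 <= a.position <= n:
                raise ValueError(
                    f"anchor {a.role}@{a.position} outside reference "
                    f"{self.reference_id!r} (length {n})")

    def catalytic_serine_anchor(self) -> Optional[Anchor]:
        for a in self.anchors:
            if a.role == "catalytic" and "S" in a.expected:
                return a
        return None


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float


@dataclass(frozen=True)
class ClassificationReport:
    candidate_id: str
    best_family: str
    best_reference: str
    anchor_observations: tuple  # ((role, position, observed, ok), ...)
    activity_call: str          # active | inactive_homolog | incomplete
    notes: tuple[str, ...] = ()
    scores: tuple = ()          # ((family, score), ...)


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.free_end_gaps:
        aligner.end_gap_score = 0.0
    return aligner


def global_align(a: Peptide, b: Peptide,
                 params: AlignmentParams = DEFAULT_ALIGN_PARAMS) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two peptides.

    Returns the gapped sequence pair and the score. Among co-optimal
    alignments the aligner's first enumeration is taken, which is
    deterministic for fixed inputs and parameters.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(params).align(a.seq, b.seq)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), aln.score)


def _reference_to_candidate_map(reference: Peptide, candidate: Peptide,
                                params: AlignmentParams) -> dict[int, str]:
    """Map each 1-based reference position to the aligned candidate
    residue, omitting positions that fall in gaps."""
    aln = _aligner(params).align(reference.seq, candidate.seq)[0]
    mapping: dict[int, str] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            mapping[t0 + off + 1] = candidate.seq[q0 + off]
    return mapping


def extract_anchor_residues(candidate: Peptide, profile: AnchorProfile,
                            params: AlignmentParams = DEFAULT_ALIGN_PARAMS,
                            ) -> dict[int, str]:
    """Observed candidate residue (or ``"-"``) at each anchor position."""
    mapping = _reference_to_candidate_map(profile.reference_seq, candidate, params)
    positions = {a.position for a in profile.anchors}
    if profile.determinant_position is not None:
        positions.add(profile.determinant_position)
    return {pos: mapping.get(pos, "-") for pos in sorted(positions)}


def classify(candidate: Peptide, profiles: Sequence[AnchorProfile],
             params: AlignmentParams = DEFAULT_ALIGN_PARAMS) -> ClassificationReport:
    """Assign family by best alignment score and call activity from anchors."""
    if not profiles:
        raise ValueError("at least one profile is required")
    scored = [
        (global_align(candidate, prof.reference_seq, params).score, i, prof)
        for i, prof in enumerate(profiles)
    ]
    best_score, _, best = max(scored, key=lambda t: (t[0], -t[1]))
    observed = extract_anchor_residues(candidate, best, params)

    anchor_rows = []
    key_mismatches: list[Anchor] = []
    gap_in_key = False
    for a in best.anchors:
        obs = observed[a.position]
        ok = obs in a.expected
        anchor_rows.append((a.role, a.position, obs, ok))
        if a.role in KEY_ROLES and not ok:
            key_mismatches.append(a)
            if obs == "-":
                gap_in_key = True

    ser_anchor = best.catalytic_serine_anchor()
    if not key_mismatches:
        call = "active"
    elif (
        not gap_in_key
        and ser_anchor is not None
        and len(key_mismatches) == 1
        and key_mismatches[0] is ser_anchor
    ):
        call = "inactive_homolog"
    else:
        call = "incomplete"

    notes: list[str] = []
    if call == "inactive_homolog" and best.family == "S9B":
        notes.append("DPP10-like: catalytic Ser replaced, triad otherwise intact")
    if best.family == "S9B" and best.determinant_position is not None:
        det = observed.get(best.determinant_position, "-")
        if det in best.determinant_exo:
            notes.append(f"exo-only (determinant {det})")
        elif det == "A":
            notes.append(f"endo-capable (determinant {det})")
        else:
            notes.append(f"determinant {det} unassigned")
    if best.motifs:
        hits = [m for m in best.motifs if m in candidate.seq]
        notes.append(f"motifs {len(hits)}/{len(best.motifs)}")

    return ClassificationReport(
        candidate_id=candidate.id,
        best_family=best.family,
        best_reference=best.reference_id,
        anchor_observations=tuple(anchor_rows),
        activity_call=call,
        notes=tuple(notes),
        scores=tuple((p.family, s) for s, _, p in sorted(scored, key=lambda t: -t[0])),
    )


def classification_table(reports: Iterable[ClassificationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "candidate_id": r.candidate_id,
            "family": r.best_family,
            "reference": r.best_reference,
            "activity_call": r.activity_call,
            "anchors": ";".join(
                f"{role}{pos}={obs}" for role, pos, obs, _ in r.anchor_observations),
            "notes": "; ".join(r.notes),
        })
    return pd.DataFrame(rows, columns=[
        "candidate_id", "family", "reference", "activity_call", "anchors", "notes"])


# -- packaged anchor tables (human reference numbering) --------------------

def load_anchor_table() -> pd.DataFrame:
    """Diagnostic-residue positions in human reference numbering.

    Columns: family, reference_id, role, position, expected (residues
    admissible at that position, including synonymous substitutions seen
    in active insect homologs). Reference sequences themselves are not
    packaged; pair this table with user-supplied reference FASTA to
    build :class:`AnchorProfile` objects via :func:`profiles_from_table`.
    """
    with resources.files("pspkit.data").joinpath("anchor_profiles.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def profiles_from_table(table: pd.DataFrame,
                        references: dict[str, Peptide]) -> list[AnchorProfile]:
    """Combine an anchor table with reference sequences into profiles.

    ``references`` maps reference_id -> sequence. Rows whose
    reference_id has no sequence are skipped. Rows with role
    ``determinant`` set the S9B exo/endo determinant position.
    """
    profiles = []
    for (family, ref_id), grp in table.groupby(["family", "reference_id"], sort=True):
        if ref_id not in references:
            continue
        anchors = []
        det_pos = None
        motifs: list[str] = []
        for _, row in grp.iterrows():
            if row["role"] == "motif":
                motifs.append(row["expected"])
            elif row["role"] == "determinant":
                det_pos = int(row["position"])
            else:
                anchors.append(Anchor(row["role"], int(row["position"]),
                                      frozenset(row["expected"])))
        profiles.append(AnchorProfile(
            family=family, reference_id=ref_id,
            reference_seq=references[ref_id],
            anchors=tuple(anchors), motifs=tuple(motifs),
            determinant_position=det_pos,
        ))
    return profiles
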