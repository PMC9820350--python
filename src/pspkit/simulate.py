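"""Seeded generators for gliadin-like peptides, ORF tilings and
read-alignment tables.

The generators emulate the statistical structure each analysis stage
assumes, so the whole pipeline is testable without any external
downloads:

* :func:`gen_gliadin_peptides` — Gln/Pro-rich peptides assembled from
  the canonical gliadin repeat motifs (PQQPFPQ, PQQPFPQQ, PQPQPFP,
  PQQPY) with random non-Q/P flanks, under composition caps mirroring
  real gliadins (Gln <= 50%, Pro <= 35% of residues);
* :func:`gen_orf_set` — overlapping translation windows over a random
  "true" protein with controlled per-residue substitution noise, plus
  the ground truth for reconstruction tests;
* :func:`gen_alignment_table` — read-to-contig alignment records whose
  counts are drawn multinomially from known expression levels, with
  controlled fractions of multireads and partial alignments, plus the
  realized true RPKM.

Every generator is a pure function of its spec (seed included): the
same spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .peptide import Peptide, STANDARD_RESIDUES
from .orf_cluster import OrfRecord
from .quant import AlignmentRecord, rpkm

#: Gliadin repeat motifs (gamma-, omega- and alpha-gliadin repeats).
DEFAULT_MOTIFS = ("PQQPFPQ", "PQQPFPQQ", "PQPQPFP", "PQQPY")

#: Residues used for flanks: everything except Gln and Pro, so flank
#: length directly controls the Q/P composition.
_FLANK_RESIDUES = sorted(STANDARD_RESIDUES - {"Q", "P"})
_ALL_RESIDUES = sorted(STANDARD_RESIDUES)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GliadinSpec:
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    repeats: int = 2
    flank_len: tuple[int, int] = (3, 10)   # inclusive uniform range per side
    q_cap: Optional[float] = 0.5
    p_cap: Optional[float] = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise GeneratorError("repeats must be >= 1")
        for m in self.motifs:
            if not set(m) <= STANDARD_RESIDUES:
                raise GeneratorError(f"motif {m!r} has non-standard residues")
        for cap, res in ((self.q_cap, "Q"), (self.p_cap, "P")):
            if cap is not None and cap <= 0 and any(res in m for m in self.motifs):
                raise GeneratorError(
                    f"cap {cap} for {res} impossible with the given motifs")


@dataclass(frozen=True)
class OrfSimSpec:
    protein_length: int = 90
    window: int = 30
    step: int = 15
    sub_rate: float = 0.0
    n_proteins: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sub_rate <= 1:
            raise GeneratorError("sub_rate must be in [0, 1]")
        if self.step < 1 or self.window <= self.step:
            raise GeneratorError("window must exceed step (to guarantee overlap)")
        if self.protein_length < self.window:
            raise GeneratorError("protein must be at least one window long")


@dataclass(frozen=True)
class OrfTruth:
    proteins: dict            # protein_id -> sequence
    source: dict              # orf_id -> (protein_id, 0-based start)


@dataclass(frozen=True)
class ReadSimSpec:
    #: (gene_id, length_in_bases, relative expression weight)
    genes: tuple[tuple[str, int, float], ...] = (
        ("g1", 1000, 10.0), ("g2", 2000, 5.0), ("g3", 500, 1.0))
    total_reads: int = 10000
    multiread_frac: float = 0.0
    partial_frac: float = 0.0
    partial_range: tuple[float, float] = (0.55, 0.95)  # aligned fraction
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.multiread_frac, self.partial_frac):
            if not 0 <= f <= 1:
                raise GeneratorError("fractions must be in [0, 1]")
        if self.multiread_frac > 0 and len(self.genes) < 2:
            raise GeneratorError("multireads need at least two genes")


def gen_gliadin_peptides(spec: GliadinSpec, n: int) -> list[Peptide]:
    """Generate ``n`` gliadin-like peptides: motif repeats plus flanks.

    Flank lengths are drawn per side from ``spec.flank_len``; when
    composition caps are set and the drawn flanks leave the peptide too
    Q- or P-rich, the flanks are extended symmetrically until the caps
    hold (impossible caps raise at spec construction).
    """
    if n < 1:
        raise GeneratorError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    peptides = []
    for i in range(n):
        core = "".join(
            spec.motifs[rng.integers(len(spec.motifs))]
            for _ in range(spec.repeats))
        lo, hi = spec.flank_len
        n_flank = int(rng.integers(lo, hi + 1))
        c_flank = int(rng.integers(lo, hi + 1))

        need = 0
        for cap, res in ((spec.q_cap, "Q"), (spec.p_cap, "P")):
            if cap is not None:
                count = core.count(res)
                need = max(need, math.ceil(count / cap))
        extra = max(0, need - (len(core) + n_flank + c_flank))
        n_flank += (extra + 1) // 2
        c_flank += extra // 2

        left = "".join(rng.choice(_FLANK_RESIDUES, size=n_flank)) if n_flank else ""
        right = "".join(rng.choice(_FLANK_RESIDUES, size=c_flank)) if c_flank else ""
        peptides.append(Peptide(f"gliadin{i + 1}", left + core + right))
    return peptides


def gen_orf_set(spec: OrfSimSpec) -> tuple[list[OrfRecord], OrfTruth]:
    """Tiling translation windows over random true proteins, with noise.

    Windows start every ``step`` residues while a full window fits, and
    a final window is anchored at the protein's C-terminus so coverage
    is complete. Substitutions replace a residue with a different
    uniformly drawn residue, independently at ``sub_rate`` per residue.
    """
    rng = np.random.default_rng(spec.seed)
    proteins: dict[str, str] = {}
    source: dict[str, tuple[str, int]] = {}
    orfs: list[OrfRecord] = []
    for p in range(spec.n_proteins):
        pid = f"protein{p + 1}"
        seq = "".join(rng.choice(_ALL_RESIDUES, size=spec.protein_length))
        proteins[pid] = seq
        starts = list(range(0, spec.protein_length - spec.window + 1, spec.step))
        if starts[-1] + spec.window < spec.protein_length:
            starts.append(spec.protein_length - spec.window)
        for k, start in enumerate(starts, start=1):
            window = list(seq[start:start + spec.window])
            for idx in range(len(window)):
                if spec.sub_rate > 0 and rng.random() < spec.sub_rate:
                    choices = [r for r in _ALL_RESIDUES if r != window[idx]]
                    window[idx] = choices[rng.integers(len(choices))]
            oid = f"{pid}_orf{k}"
            orfs.append(OrfRecord(oid, Peptide(oid, "".join(window)), pid))
            source[oid] = (pid, start)
    return orfs, OrfTruth(proteins, source)


def gen_alignment_table(spec: ReadSimSpec,
                        ) -> tuple[list[AlignmentRecord], dict[str, float]]:
    """Read-alignment records with known realized RPKM.

    Read counts per gene are multinomial with probability proportional
    to expression weight x length (so the weight plays the role of a
    target RPKM up to normalization). A ``multiread_frac`` of reads
    gains a strictly lower-scoring secondary target, which the default
    best-score policy ignores — truth is then still recovered exactly.
    A ``partial_frac`` of reads aligns over only part of the contig.
    Returns the records and the realized RPKM per gene computed from
    the drawn counts.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [g for g, _, _ in spec.genes]
    lengths = {g: l for g, l, _ in spec.genes}
    probs = np.array([l * w for _, l, w in spec.genes], dtype=float)
    if probs.sum() <= 0:
        raise GeneratorError("expression weights must not all be zero")
    probs /= probs.sum()
    counts = rng.multinomial(spec.total_reads, probs)

    records: list[AlignmentRecord] = []
    read_no = 0
    for gid, count in zip(gene_ids, counts):
        for _ in range(count):
            read_no += 1
            rid = f"r{read_no:06d}"
            clen = lengths[gid]
            if spec.partial_frac > 0 and rng.random() < spec.partial_frac:
                lo, hi = spec.partial_range
                alen = int(round(clen * rng.uniform(lo, hi)))
            else:
                alen = clen
            records.append(AlignmentRecord(rid, gid, 100.0, alen, clen))
            if spec.multiread_frac > 0 and rng.random() < spec.multiread_frac:
                others = [g for g in gene_ids if g != gid]
                alt = others[rng.integers(len(others))]
                alt_score = float(rng.integers(50, 100))  # strictly < 100
                records.append(
                    AlignmentRecord(rid, alt, alt_score,
                                    lengths[alt], lengths[alt]))

    truth = {
        gid: rpkm(int(c), lengths[gid], spec.total_reads)
        for gid, c in zip(gene_ids, counts)
    }
    return records, truth


# -- synthetic reference profiles for annotation tests ---------------------

def gen_reference_profile(family: str = "S9B", length: int = 80,
                          seed: int = 0):
    """A short synthetic reference with the anchor structure of a family.

    Returns ``(profile, catalytic_positions)``. Serine families get a
    Ser/Asp/His triad planted in order; metal families get their
    metal-site residues. Positions are spread over the sequence. The
    reference sequence is random otherwise, so candidates derived from
    it align unambiguously.
    """
    from .annotate import Anchor, AnchorProfile

    # fold the family label into the stream so profiles for different
    # families differ even under one seed
    rng = np.random.default_rng([seed, *(ord(c) for c in family)])
    seq = list(rng.choice(_ALL_RESIDUES, size=length))
    serine_triads = {"S9A": "SDH", "S9B": "SDH", "S28": "SDH"}
    metal_sites = {"M24B": "DDHEE", "M17": "KDKDDER", "M20": "HDDEEDHH"}
    if family in serine_triads:
        residues = serine_triads[family]
        role = "catalytic"
    elif family in metal_sites:
        residues = metal_sites[family]
        role = "metal"
    else:
        raise GeneratorError(f"unknown family {family!r}")
    k = len(residues)
    positions = [int(round((i + 1) * length / (k + 1))) for i in range(k)]
    for pos, res in zip(positions, residues):
        seq[pos - 1] = res
    ref = Peptide(f"{family}_synthetic_ref", "".join(seq))
    anchors = tuple(Anchor(role, pos, frozenset(res))
                    for pos, res in zip(positions, residues))
    det_pos = None
    if family == "S9B":
        det_pos = positions[0] + 3  # determinant a few residues past Ser
        seq[det_pos - 1] = "D"
        ref = Peptide(ref.id, "".join(seq))
    profile = AnchorProfile(
        family=family, reference_id=ref.id, reference_seq=ref,
        anchors=anchors, determinant_position=det_pos)
    return profile, positions
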