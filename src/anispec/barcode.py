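"""ITS/LSU barcode extraction from assemblies and pairwise difference counts.

Fungal species descriptions habitually report barcode distances in the idiom
"N differences out of M aligned nucleotides".  Here M counts alignment
columns where *both* sequences have a base (indel columns are excluded from
both M and N and reported separately) and N counts the mismatching such
columns.  IUPAC ambiguity codes with a compatible overlap (e.g. ``A`` vs
``R``) are not counted as differences, since Sanger-derived GenBank barcodes
routinely carry them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .align import AlignScores, blast_best_local_hits, exact_global_alignment
from .genome import GenomeSequence, reverse_complement

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class BarcodeInputError(ValueError):
    """Invalid barcode input (too short, bad alphabet, duplicates)."""


class BarcodeNotFoundError(RuntimeError):
    """No region of the assembly matched the reference above the threshold."""


@dataclass(frozen=True)
class BarcodeReference:
    """A reference barcode (ITS, LSU or combined ITS+LSU) sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 100:
            raise BarcodeInputError(
                f"reference {self.name!r} shorter than 100 bp")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise BarcodeInputError(
                f"reference {self.name!r} has non-IUPAC characters: "
                f"{sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass
class ExtractedBarcode:
    """A barcode located in an assembly; coordinates 0-based half-open."""

    source_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str          # in reference orientation
    identity_to_reference: float


@dataclass
class PairwiseDiff:
    """Difference counts between two barcodes over their global alignment."""

    id_a: str
    id_b: str
    n_aligned: int
    n_substitutions: int
    n_indel_columns: int

    @property
    def summary_text(self) -> str:
        return (f"{self.n_substitutions} differences out of "
                f"{self.n_aligned} aligned nucleotides")


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_barcode(genome: GenomeSequence, reference: BarcodeReference,
                    min_identity: float = 75.0) -> ExtractedBarcode:
    """Locate the barcode region by best local alignment of the reference
    against all contigs, both strands, and return the aligned subject span.

    Raises :class:`BarcodeNotFoundError` when the best alignment falls below
    ``min_identity`` or covers an implausible span (outside 0.5x-2x the
    reference length) — the situation in which real pipelines fall back to
    re-assembling rRNA reads.
    """
    hits = blast_best_local_hits([(reference.name, reference.sequence)],
                                 genome)
    hit = hits.get(reference.name)
    if hit is None:
        raise BarcodeNotFoundError(
            f"no similarity to {reference.name!r} found in {genome.id!r}")
    if hit.identity_percent < min_identity:
        raise BarcodeNotFoundError(
            f"best match of {reference.name!r} in {genome.id!r} is only "
            f"{hit.identity_percent:.1f}% identical "
            f"(threshold {min_identity}%)")
    span = hit.s_end - hit.s_start
    if not 0.5 * len(reference.sequence) <= span <= 2.0 * len(reference.sequence):
        raise BarcodeNotFoundError(
            f"matched span {span} bp implausible for reference of "
            f"{len(reference.sequence)} bp in {genome.id!r}")
    region = genome.sequence(hit.contig)[hit.s_start:hit.s_end]
    if hit.strand == "-":
        region = reverse_complement(region)
    return ExtractedBarcode(
        source_id=genome.id, contig=hit.contig,
        start=hit.s_start, end=hit.s_end, strand=hit.strand,
        sequence=region, identity_to_reference=hit.identity_percent)


# ---------------------------------------------------------------------------
# difference counting
# ---------------------------------------------------------------------------


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def count_alignment_columns(row_a: str, row_b: str) -> tuple[int, int, int]:
    """Column scan of an aligned pair: (n_aligned, n_substitutions, n_indel).

    ``n_aligned`` counts columns where both rows have a base;
    ``n_substitutions`` the incompatible such columns; ``n_indel_columns``
    the columns with a gap in exactly one row.
    """
    n_aligned = n_sub = n_indel = 0
    for a, b in zip(row_a, row_b):
        if a == "-" and b == "-":
            continue
        if a == "-" or b == "-":
            n_indel += 1
            continue
        n_aligned += 1
        if not _compatible(a, b):
            n_sub += 1
    return n_aligned, n_sub, n_indel


def align_and_count(seq_a: str, seq_b: str, id_a: str = "A", id_b: str = "B",
                    scores: AlignScores = AlignScores()) -> PairwiseDiff:
    """Globally align two barcodes (affine gaps) and count differences."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    for label, s in ((id_a, seq_a), (id_b, seq_b)):
        if len(s) < 50:
            raise BarcodeInputError(
                f"sequence {label!r} shorter than 50 bp ({len(s)})")
        bad = set(s) - set(IUPAC_SETS)
        if bad:
            raise BarcodeInputError(
                f"sequence {label!r} has non-IUPAC characters: {sorted(bad)}")
    row_a, row_b, _ = exact_global_alignment(seq_a, seq_b, scores)
    n_aligned, n_sub, n_indel = count_alignment_columns(row_a, row_b)
    return PairwiseDiff(id_a=id_a, id_b=id_b, n_aligned=n_aligned,
                        n_substitutions=n_sub, n_indel_columns=n_indel)


def batch_diff(sequences: Iterable[tuple[str, str]],
               scores: AlignScores = AlignScores()
               ) -> dict[str, dict[str, PairwiseDiff]]:
    """All-vs-all difference matrix; symmetric with an all-zero diagonal."""
    seqs = list(sequences)
    if len(seqs) < 2:
        raise BarcodeInputError("need at least 2 sequences")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise BarcodeInputError(f"duplicate sequence ids in {ids}")
    matrix: dict[str, dict[str, PairwiseDiff]] = {i: {} for i in ids}
    for i, (id_a, a) in enumerate(seqs):
        matrix[id_a][id_a] = PairwiseDiff(id_a, id_a, n_aligned=len(a),
                                          n_substitutions=0, n_indel_columns=0)
        for id_b, b in seqs[i + 1:]:
            d = align_and_count(a, b, id_a, id_b, scores)
            matrix[id_a][id_b] = d
            matrix[id_b][id_a] = PairwiseDiff(
                id_b, id_a, d.n_aligned, d.n_substitutions, d.n_indel_columns)
    return matrix


def write_diff_tsv(matrix: dict[str, dict[str, PairwiseDiff]],
                   path: str | Path) -> None:
    """Per-pair TSV of the upper triangle."""
    ids = list(matrix)
    with open(path, "w") as fh:
        fh.write("idA\tidB\tn_substitutions\tn_aligned\tn_indel_columns\t"
                 "summary_text\n")
        for i, id_a in enumerate(ids):
            for id_b in ids[i + 1:]:
                d = matrix[id_a][id_b]
                fh.write(f"{id_a}\t{id_b}\t{d.n_substitutions}\t"
                         f"{d.n_aligned}\t{d.n_indel_columns}\t"
                         f"{d.summary_text}\n")
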