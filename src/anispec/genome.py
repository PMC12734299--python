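"""Multi-contig genome assemblies and FASTA round-tripping.

The central in-memory container is :class:`GenomeSequence`, a named, ordered
collection of contigs.  Sequences are uppercased on ingest and restricted to
the nucleotide alphabet ``A/C/G/T/N`` plus IUPAC ambiguity codes; contig names
must be unique within an assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement handling IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Invalid assembly (empty, duplicate contig names, bad alphabet)."""


@dataclass
class GenomeSequence:
    """A named multi-contig nucleotide assembly.

    Parameters
    ----------
    id:
        Strain label, e.g. ``"PSN1167"``.
    contigs:
        Ordered list of ``(name, sequence)`` pairs.  Sequences are uppercased
        and validated on construction.
    """

    id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise GenomeError(f"genome {self.id!r} has no contigs")
        seen: set[str] = set()
        cleaned: list[tuple[str, str]] = []
        for name, seq in self.contigs:
            if name in seen:
                raise GenomeError(f"duplicate contig name {name!r} in {self.id!r}")
            seen.add(name)
            seq = seq.upper()
            bad = set(seq) - IUPAC_CODES
            if bad:
                raise GenomeError(
                    f"contig {name!r} of {self.id!r} contains non-nucleotide "
                    f"characters: {sorted(bad)}"
                )
            cleaned.append((name, seq))
        self.contigs = cleaned

    # -- mapping-style access ------------------------------------------------

    def __len__(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs)

    @property
    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs}

    def sequence(self, contig: str) -> str:
        for name, seq in self.contigs:
            if name == contig:
                return seq
        raise KeyError(f"no contig {contig!r} in genome {self.id!r}")

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path, id: str | None = None) -> "GenomeSequence":
        path = Path(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise GenomeError(f"no sequences in {path}")
        label = id if id is not None else path.stem
        return cls(id=label, contigs=[(r.id, str(r.seq)) for r in records])

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


def write_multi_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs to one FASTA file."""
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
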