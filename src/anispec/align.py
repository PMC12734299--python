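"""Pairwise alignment engines behind the ANI and barcode operations.

Two interchangeable local-alignment backends are provided:

* ``blast`` — the NCBI ``blastn`` command-line tool (``-task blastn``), used
  for full-size assemblies.  One invocation aligns a whole batch of query
  fragments against a multi-contig subject.
* ``exact`` — Biopython's :class:`Bio.Align.PairwiseAligner`, an exact affine
  Smith–Waterman.  Quadratic, so reserved for small genomes and for
  oracle-grade comparisons.

Both report identity with the same convention: ``matches / alignment
columns``, where gap columns count toward the denominator.  Global alignment
(for barcode difference counting) always uses the exact aligner.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import Align

from .genome import GenomeSequence, reverse_complement


class AlignmentBackendError(RuntimeError):
    """The external alignment tool failed or is unavailable."""


@dataclass(frozen=True)
class AlignScores:
    """Nucleotide scoring used by the exact aligner.

    Standard defaults; exposed because substitution/indel counts of
    near-tied alignments can shift by one under different scores.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class LocalHit:
    """Best local alignment of one query fragment against a subject genome."""

    contig: str
    identity_percent: float       # matches / columns * 100, gaps in columns
    aligned_query_fraction: float  # aligned query bases / query length
    matches: int
    columns: int
    score: float
    q_start: int                  # 0-based half-open on the query
    q_end: int
    s_start: int                  # 0-based half-open on the subject contig
    s_end: int
    strand: str                   # '+' or '-'


def _aligner(scores: AlignScores, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scores.match
    al.mismatch_score = scores.mismatch
    al.open_gap_score = scores.gap_open
    al.extend_gap_score = scores.gap_extend
    return al


# ---------------------------------------------------------------------------
# exact engine
# ---------------------------------------------------------------------------


def exact_best_local_hit(fragment: str, subject: GenomeSequence,
                         scores: AlignScores = AlignScores()
                         ) -> Optional[LocalHit]:
    """Exact best local alignment of ``fragment`` against all subject contigs,
    both strands.  Returns ``None`` only for empty inputs."""
    if not fragment:
        return None
    al = _aligner(scores, "local")
    best: Optional[LocalHit] = None
    for name, seq in subject:
        if not seq:
            continue
        for strand in "+-":
            query = fragment if strand == "+" else reverse_complement(fragment)
            alns = al.align(seq, query)
            if len(alns) == 0:
                continue
            a = alns[0]
            if best is not None and a.score < best.score:
                continue
            counts = a.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            t_rng = a.aligned[0]
            q_rng = a.aligned[1]
            q_start, q_end = int(q_rng[0][0]), int(q_rng[-1][1])
            s_start, s_end = int(t_rng[0][0]), int(t_rng[-1][1])
            if strand == "-":  # map back to forward-query coordinates
                q_start, q_end = len(fragment) - q_end, len(fragment) - q_start
            hit = LocalHit(
                contig=name,
                identity_percent=100.0 * counts.identities / columns,
                aligned_query_fraction=(q_end - q_start) / len(fragment),
                matches=counts.identities, columns=columns,
                score=float(a.score),
                q_start=q_start, q_end=q_end,
                s_start=s_start, s_end=s_end, strand=strand)
            if best is None or hit.score > best.score:
                best = hit
    return best


def exact_global_alignment(seq_a: str, seq_b: str,
                           scores: AlignScores = AlignScores()
                           ) -> tuple[str, str, float]:
    """Optimal global (Needleman–Wunsch, affine) alignment.

    Returns the two gapped row strings and the score.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot globally align an empty sequence")
    al = _aligner(scores, "global")
    a = al.align(seq_a, seq_b)[0]
    return str(a[0]), str(a[1]), float(a.score)


# ---------------------------------------------------------------------------
# blast engine
# ---------------------------------------------------------------------------


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise AlignmentBackendError(
            "blastn not found on PATH; use the 'exact' engine or install "
            "NCBI BLAST+")
    return exe


def blast_best_local_hits(fragments: list[tuple[str, str]],
                          subject: GenomeSequence,
                          evalue: float = 1e-3,
                          task: str = "blastn") -> dict[str, LocalHit]:
    """Best blastn hit per query fragment (highest bitscore HSP).

    ``fragments`` is a list of ``(name, sequence)``.  Fragments with no HSP
    are simply absent from the returned mapping.  Low-complexity filtering is
    off: the statistics downstream need divergent-versus-absent to be a clean
    dichotomy, not a masking artefact.
    """
    exe = _require_blastn()
    if not fragments:
        return {}
    with tempfile.TemporaryDirectory(prefix="anispec_blast_") as td:
        qpath = Path(td) / "query.fa"
        spath = Path(td) / "subject.fa"
        with open(qpath, "w") as fh:
            for name, seq in fragments:
                fh.write(f">{name}\n{seq}\n")
        with open(spath, "w") as fh:
            for name, seq in subject:
                fh.write(f">{name}\n{seq}\n")
        cmd = [exe, "-task", task, "-query", str(qpath),
               "-subject", str(spath), "-evalue", str(evalue),
               "-dust", "no", "-soft_masking", "false",
               "-outfmt",
               "6 qseqid sseqid nident length qstart qend sstart send bitscore"]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignmentBackendError(
                f"blastn failed (exit {proc.returncode}): {proc.stderr[:500]}")
        out = proc.stdout

    frag_len = {name: len(seq) for name, seq in fragments}
    best: dict[str, LocalHit] = {}
    for line in out.splitlines():
        q, s, nident, length, qs, qe, ss, se, bits = line.split("\t")
        score = float(bits)
        if q in best and score <= best[q].score:
            continue
        nident, length = int(nident), int(length)
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        strand = "+" if ss <= se else "-"
        s_start, s_end = (ss - 1, se) if strand == "+" else (se - 1, ss)
        best[q] = LocalHit(
            contig=s,
            identity_percent=100.0 * nident / length,
            aligned_query_fraction=(qe - qs + 1) / frag_len[q],
            matches=nident, columns=length, score=score,
            q_start=qs - 1, q_end=qe,
            s_start=s_start, s_end=s_end, strand=strand)
    return best
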