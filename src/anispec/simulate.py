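"""Synthetic genome pairs, rDNA cassettes, mating-type fixtures and coverage tables.

This module manufactures the ground-truth worlds against which the rest of the
package is validated without downloading real assemblies:

* pairs of genomes derived from a common random ancestor, with a uniform
  background substitution divergence, an optional minority fraction of strongly
  divergent blocks (the bimodal identity-spectrum structure seen between
  conspecific strains that hybridised or accumulated localized divergence),
  and strain-specific segments that have no counterpart in the partner genome;
* a planted rDNA cassette (ITS+LSU) for barcode-extraction round trips;
* mating-type (MAT) locus fixtures in the architectures observed in
  Sordariales assemblies, with gene annotations;
* per-gene read-coverage tables under a Poisson noise model, for homokaryotic
  versus heterokaryotic (mixed mat1-1 / mat1-2 nuclei) mycelia.

Substitutions follow a Jukes–Cantor-like scheme: each substituted site is
replaced by one of the three alternative bases with equal probability.  The
divergence parameters are expected *pairwise* per-site substitution
probabilities; each lineage mutates independently at half that rate, and the
exact expected pairwise identity (accounting for double hits) is recorded in
the :class:`TruthRecord` so recovery tests can be sharp.

Strain-specific segments are implemented as paired replacement: at each
sampled interval *both* genomes receive distinct fresh random sequence.  A
one-sided replacement would double the realized zero-hit fraction, because the
partner-direction query over that locus would also find nothing (the partner
lost the ancestral copy).  With paired replacement the realized specific
fraction per direction equals ``specific_fraction``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .genome import GenomeSequence, reverse_complement
from .matlocus import (
    GENE_LENGTHS_BP,
    MAT11_GENES,
    MAT12_GENES,
    FLANK_GENES,
    GeneAnnotation,
    GeneCoverage,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

Interval = tuple[str, int, int]

ARCHITECTURE_LABELS = (
    "fused",
    "split_unlinked",
    "split_edge_reassemblable",
    "single_mat1-1",
    "single_mat1-2",
)


class ParameterError(ValueError):
    """Invalid simulation parameter."""


class SimulationError(RuntimeError):
    """Simulation could not satisfy its constraints (e.g. interval placement)."""


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------


def expected_pairwise_identity(d: float) -> float:
    """Exact expected pairwise identity (percent) for pairwise divergence ``d``.

    Each lineage substitutes independently with probability ``d/2`` per site;
    two substituted sites coincide with probability 1/3 (uniform choice among
    the three alternative bases), so

    ``P(match) = (1 - d/2)^2 + (d/2)^2 / 3``.
    """
    p = d / 2.0
    return 100.0 * ((1.0 - p) ** 2 + p * p / 3.0)


def divergence_for_identity(identity_percent: float) -> float:
    """Invert :func:`expected_pairwise_identity`.

    Returns the pairwise divergence parameter whose expected identity equals
    ``identity_percent``.
    """
    if not 0.0 < identity_percent <= 100.0:
        raise ParameterError("identity must be in (0, 100]")
    q = 1.0 - identity_percent / 100.0
    # (4/3) p^2 - 2 p + q = 0, smaller root
    disc = 4.0 - (16.0 / 3.0) * q
    p = (2.0 - np.sqrt(disc)) / (8.0 / 3.0)
    return float(2.0 * p)


@dataclass
class SimulationParams:
    """Parameters for :func:`evolve_pair`.

    ``background_divergence`` and ``divergent_block_divergence`` are expected
    pairwise per-site substitution probabilities (see module docstring);
    ``divergent_block_fraction`` / ``specific_fraction`` are genome
    proportions; blocks and specific segments are placed uniformly without
    overlap.
    """

    length_bp: int = 1_000_000
    gc_fraction: float = 0.5
    background_divergence: float = 0.002
    divergent_block_fraction: float = 0.0
    divergent_block_divergence: float = 0.0
    specific_fraction: float = 0.0
    indel_rate: float = 0.0
    mean_indel_len: float = 3.0
    n_contigs: int = 1
    seed: int = 0
    divergent_block_len: int = 5_000
    specific_segment_len: int = 5_000

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "background_divergence",
                     "divergent_block_fraction", "divergent_block_divergence",
                     "specific_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.divergent_block_fraction + self.specific_fraction > 0.5:
            raise ParameterError(
                "divergent_block_fraction + specific_fraction must be <= 0.5")
        if self.divergent_block_fraction > 0 and \
                self.divergent_block_divergence <= self.background_divergence:
            raise ParameterError(
                "divergent_block_divergence must exceed background_divergence")
        if self.length_bp < 10_000:
            raise ParameterError("length_bp must be at least 10 kb "
                                 "(10 fragment windows)")
        if self.n_contigs < 1:
            raise ParameterError("n_contigs must be >= 1")
        if self.mean_indel_len <= 0:
            raise ParameterError("mean_indel_len must be positive")


@dataclass
class TruthRecord:
    """Planted simulation parameters and realized divergence.

    Identities are percentages on [0, 100]; intervals are 0-based half-open
    ``(contig, start, end)`` in pre-indel coordinates.  ``expected_*`` values
    are the analytic double-hit-corrected expectations; ``realized_*`` are the
    direct column counts over the known positional alignment.
    """

    seed_used: int
    expected_background_identity: float
    realized_background_identity: float
    expected_block_identity: float | None = None
    realized_block_identity: float | None = None
    block_intervals: list[Interval] = field(default_factory=list)
    specific_intervals_A: list[Interval] = field(default_factory=list)
    specific_intervals_B: list[Interval] = field(default_factory=list)
    cassette_interval: tuple[str, int, int, str] | None = None
    indel_net_A: int = 0
    indel_net_B: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["block_intervals"] = [tuple(x) for x in d["block_intervals"]]
        d["specific_intervals_A"] = [tuple(x) for x in d["specific_intervals_A"]]
        d["specific_intervals_B"] = [tuple(x) for x in d["specific_intervals_B"]]
        if d.get("cassette_interval") is not None:
            d["cassette_interval"] = tuple(d["cassette_interval"])
        return cls(**d)


# ---------------------------------------------------------------------------
# ancestor generation and pair evolution
# ---------------------------------------------------------------------------


def _contig_split(length_bp: int, n_contigs: int) -> list[int]:
    base = length_bp // n_contigs
    lens = [base] * n_contigs
    lens[-1] += length_bp - base * n_contigs
    return lens


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.empty(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[raw == b] = i
    return codes


def generate_ancestor(length_bp: int, gc_fraction: float, n_contigs: int,
                      seed: int, id: str = "ancestor") -> GenomeSequence:
    """Generate an i.i.d. random ancestor assembly.

    Bases are independent with ``P(G) = P(C) = gc_fraction / 2``.  The genome
    is split into ``n_contigs`` contigs of (near-)equal length.  Deterministic
    for a fixed seed.
    """
    if length_bp <= 0 or n_contigs <= 0:
        raise ParameterError("length_bp and n_contigs must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ParameterError("gc_fraction must be in [0, 1]")
    if length_bp < n_contigs * 1000:
        raise ParameterError("need at least 1 kb per contig")
    rng = np.random.default_rng(seed)
    contigs = []
    for i, clen in enumerate(_contig_split(length_bp, n_contigs)):
        contigs.append((f"contig_{i + 1}", _decode(_random_codes(rng, clen, gc_fraction))))
    return GenomeSequence(id=id, contigs=contigs)


def _sample_intervals(rng: np.random.Generator,
                      contig_lens: dict[str, int],
                      n_intervals: int, interval_len: int,
                      occupied: dict[str, list[tuple[int, int]]],
                      max_retries: int = 1000) -> list[Interval]:
    """Uniformly place non-overlapping intervals by bounded rejection sampling."""
    names = list(contig_lens)
    weights = np.array([max(contig_lens[c] - interval_len + 1, 0) for c in names],
                       dtype=float)
    if weights.sum() <= 0:
        raise SimulationError("contigs too short for requested interval length")
    weights /= weights.sum()
    out: list[Interval] = []
    for _ in range(n_intervals):
        for attempt in range(max_retries):
            c = names[rng.choice(len(names), p=weights)]
            start = int(rng.integers(0, contig_lens[c] - interval_len + 1))
            end = start + interval_len
            if all(end <= s or start >= e for s, e in occupied.setdefault(c, [])):
                occupied[c].append((start, end))
                out.append((c, start, end))
                break
        else:
            raise SimulationError(
                f"could not place interval of {interval_len} bp after "
                f"{max_retries} retries")
    return out


def _mask_from_intervals(n: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def _substitute(rng: np.random.Generator, codes: np.ndarray,
                rate: np.ndarray) -> np.ndarray:
    out = codes.copy()
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def _apply_indels(rng: np.random.Generator, codes: np.ndarray,
                  rate: float, mean_len: float, gc: float) -> tuple[np.ndarray, int]:
    """Apply geometric-length indels; returns (sequence, net length change)."""
    if rate <= 0:
        return codes, 0
    sites = np.nonzero(rng.random(codes.size) < rate)[0]
    if sites.size == 0:
        return codes, 0
    lengths = rng.geometric(1.0 / mean_len, size=sites.size)
    is_ins = rng.random(sites.size) < 0.5
    pieces: list[np.ndarray] = []
    prev = 0
    net = 0
    for pos, ln, ins in zip(sites, lengths, is_ins):
        pieces.append(codes[prev:pos])
        if ins:
            pieces.append(_random_codes(rng, int(ln), gc))
            prev = pos
            net += int(ln)
        else:
            prev = min(pos + int(ln), codes.size)
            net -= prev - pos
    pieces.append(codes[prev:])
    return np.concatenate(pieces), net


def evolve_pair(ancestor: GenomeSequence, params: SimulationParams
                ) -> tuple[GenomeSequence, GenomeSequence, TruthRecord]:
    """Derive two genomes independently from a common ancestor.

    Substitutions are applied per lineage at half the pairwise rate —
    ``background_divergence / 2`` outside divergent blocks and
    ``divergent_block_divergence / 2`` inside them.  A fraction
    ``specific_fraction`` of the genome is replaced, in both genomes, by
    distinct fresh random sequence (lineage-unique segments; see module
    docstring).  The returned :class:`TruthRecord` stores both the analytic
    expected identities and the realized column-count identities.
    """
    rng = np.random.default_rng(params.seed)
    contig_lens = ancestor.contig_lengths

    n_blocks = int(round(params.divergent_block_fraction * len(ancestor)
                         / params.divergent_block_len))
    n_spec = int(round(params.specific_fraction * len(ancestor)
                       / params.specific_segment_len))
    occupied: dict[str, list[tuple[int, int]]] = {}
    block_iv = _sample_intervals(rng, contig_lens, n_blocks,
                                 params.divergent_block_len, occupied)
    spec_iv = _sample_intervals(rng, contig_lens, n_spec,
                                params.specific_segment_len, occupied)

    p_bg = params.background_divergence / 2.0
    p_blk = params.divergent_block_divergence / 2.0

    contigs_a: list[tuple[str, str]] = []
    contigs_b: list[tuple[str, str]] = []
    bg_match = bg_total = blk_match = blk_total = 0
    net_a = net_b = 0
    for name, seq in ancestor:
        codes = _encode(seq)
        n = codes.size
        blocks_here = [(s, e) for c, s, e in block_iv if c == name]
        specs_here = [(s, e) for c, s, e in spec_iv if c == name]
        block_mask = _mask_from_intervals(n, blocks_here)
        spec_mask = _mask_from_intervals(n, specs_here)
        rate = np.full(n, p_bg)
        rate[block_mask] = p_blk
        rate[spec_mask] = 0.0
        a = _substitute(rng, codes, rate)
        b = _substitute(rng, codes, rate)
        eq = a == b
        bg_sel = ~(block_mask | spec_mask)
        bg_match += int(eq[bg_sel].sum())
        bg_total += int(bg_sel.sum())
        blk_match += int(eq[block_mask].sum())
        blk_total += int(block_mask.sum())
        for s, e in specs_here:
            a[s:e] = _random_codes(rng, e - s, params.gc_fraction)
            b[s:e] = _random_codes(rng, e - s, params.gc_fraction)
        a, da = _apply_indels(rng, a, params.indel_rate, params.mean_indel_len,
                              params.gc_fraction)
        b, db = _apply_indels(rng, b, params.indel_rate, params.mean_indel_len,
                              params.gc_fraction)
        net_a += da
        net_b += db
        contigs_a.append((name, _decode(a)))
        contigs_b.append((name, _decode(b)))

    truth = TruthRecord(
        seed_used=params.seed,
        expected_background_identity=expected_pairwise_identity(
            params.background_divergence),
        realized_background_identity=100.0 * bg_match / bg_total,
        expected_block_identity=(expected_pairwise_identity(
            params.divergent_block_divergence) if n_blocks else None),
        realized_block_identity=(100.0 * blk_match / blk_total
                                 if blk_total else None),
        block_intervals=block_iv,
        specific_intervals_A=list(spec_iv),
        specific_intervals_B=list(spec_iv),
        indel_net_A=net_a,
        indel_net_B=net_b,
    )
    a_gen = GenomeSequence(id=f"{ancestor.id}_A", contigs=contigs_a)
    b_gen = GenomeSequence(id=f"{ancestor.id}_B", contigs=contigs_b)
    return a_gen, b_gen, truth


def simulate_pair(params: SimulationParams
                  ) -> tuple[GenomeSequence, GenomeSequence, TruthRecord]:
    """Generate an ancestor and evolve a genome pair from it in one call."""
    anc = generate_ancestor(params.length_bp, params.gc_fraction,
                            params.n_contigs, params.seed,
                            id=f"sim{params.seed}")
    return evolve_pair(anc, params)


# ---------------------------------------------------------------------------
# rDNA cassette
# ---------------------------------------------------------------------------


def random_cassette(length: int = 1200, gc: float = 0.5, seed: int = 0) -> str:
    """A random stand-in for an ITS+LSU rDNA cassette sequence."""
    if length < 500:
        raise ParameterError("cassette length must be >= 500")
    rng = np.random.default_rng(seed)
    return _decode(_random_codes(rng, length, gc))


def insert_rdna_cassette(genome: GenomeSequence, cassette_sequence: str,
                         contig: str, position: int, strand: str = "+"
                         ) -> tuple[GenomeSequence, tuple[str, int, int, str]]:
    """Insert a barcode cassette verbatim into one contig.

    The cassette is reverse-complemented first when ``strand`` is ``"-"``.
    Returns the new genome and the recorded ``(contig, start, end, strand)``
    interval (coordinates on the post-insertion contig).
    """
    if len(cassette_sequence) < 500:
        raise ParameterError("cassette length must be >= 500")
    if strand not in "+-":
        raise ParameterError("strand must be '+' or '-'")
    target = genome.sequence(contig)
    if not 0 <= position <= len(target):
        raise ParameterError(
            f"position {position} outside contig {contig!r} "
            f"(length {len(target)})")
    inserted = cassette_sequence if strand == "+" else \
        reverse_complement(cassette_sequence)
    new_contigs = []
    for name, seq in genome:
        if name == contig:
            seq = seq[:position] + inserted + seq[position:]
        new_contigs.append((name, seq))
    out = GenomeSequence(id=genome.id, contigs=new_contigs)
    return out, (contig, position, position + len(cassette_sequence), strand)


# ---------------------------------------------------------------------------
# mating-type locus fixtures
# ---------------------------------------------------------------------------


def _lay_genes(rng: np.random.Generator, genes: list[str], start: int,
               contig: str, pseudogenize_mat113: bool,
               gap_range: tuple[int, int] = (500, 3000)
               ) -> tuple[list[GeneAnnotation], int]:
    """Place genes left-to-right from ``start``; returns annotations and end."""
    anns = []
    pos = start
    for g in genes:
        pos += int(rng.integers(*gap_range))
        glen = GENE_LENGTHS_BP[g]
        anns.append(GeneAnnotation(
            gene=g, contig=contig, start=pos, end=pos + glen,
            strand="+" if rng.random() < 0.5 else "-",
            pseudogene=(pseudogenize_mat113 and g == "mat1-1-3"),
        ))
        pos += glen
    return anns, pos


def _mirror(anns: list[GeneAnnotation], clen: int) -> list[GeneAnnotation]:
    out = []
    for a in anns:
        out.append(GeneAnnotation(
            gene=a.gene, contig=a.contig, start=clen - a.end, end=clen - a.start,
            strand="-" if a.strand == "+" else "+", pseudogene=a.pseudogene))
    return sorted(out, key=lambda x: x.start)


def build_mat_fixture(architecture: str, edge_distance: int = 2000,
                      pseudogenize_mat113: bool = False, seed: int = 0,
                      ) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """Build contigs + annotations realizing a mating-type locus architecture.

    ``architecture`` is one of :data:`ARCHITECTURE_LABELS`:

    * ``fused`` — both idiomorphs clustered between APN2 and SLA2 on one
      contig (the common homothallic Sordariales arrangement);
    * ``split_unlinked`` — one idiomorph flanked by APN2/SLA2, the other on a
      separate contig far from its edges;
    * ``split_edge_reassemblable`` — the locus broken over two contigs with
      the mat genes within ``edge_distance`` of the contig ends, so that the
      fused locus can be recovered by joining the edges;
    * ``single_mat1-1`` / ``single_mat1-2`` — only one idiomorph present,
      flanked by APN2 and SLA2.

    Gene order within the locus and strands are randomized; layout geometry
    (gaps, margins) is drawn from the seed.
    """
    if architecture not in ARCHITECTURE_LABELS:
        raise ParameterError(
            f"unknown architecture {architecture!r}; "
            f"expected one of {ARCHITECTURE_LABELS}")
    rng = np.random.default_rng(seed)
    anns: list[GeneAnnotation] = []
    contigs: list[tuple[str, str]] = []

    def margin() -> int:
        return int(rng.integers(5_000, 30_000))

    def filler(n: int) -> str:
        return _decode(_random_codes(rng, n, 0.5))

    mats = ["mat1-1-1", "mat1-1-2", "mat1-1-3", "mat1-2-1"]
    rng.shuffle(mats)

    if architecture in ("fused", "single_mat1-1", "single_mat1-2"):
        if architecture == "single_mat1-1":
            inner = [g for g in mats if g in MAT11_GENES]
        elif architecture == "single_mat1-2":
            inner = [g for g in mats if g in MAT12_GENES]
        else:
            inner = mats
        layout = ["APN2"] + inner + ["SLA2"]
        if rng.random() < 0.5:
            layout.reverse()
        a, end = _lay_genes(rng, layout, margin(), "mat_contig",
                            pseudogenize_mat113)
        clen = end + margin()
        anns += a
        contigs.append(("mat_contig", filler(clen)))
    elif architecture == "split_unlinked":
        flanked_11 = rng.random() < 0.5
        inner = [g for g in mats if (g in MAT11_GENES) == flanked_11]
        orphan = [g for g in mats if (g in MAT11_GENES) != flanked_11]
        layout = ["APN2"] + inner + ["SLA2"]
        if rng.random() < 0.5:
            layout.reverse()
        a, end = _lay_genes(rng, layout, margin(), "mat_contig",
                            pseudogenize_mat113)
        clen = end + margin()
        anns += a
        contigs.append(("mat_contig", filler(clen)))
        # orphan idiomorph mid-contig, well clear of the edges
        safe = max(3 * edge_distance, 6_000)
        a2, end2 = _lay_genes(rng, orphan, safe, "orphan_contig",
                              pseudogenize_mat113)
        clen2 = end2 + safe
        anns += a2
        contigs.append(("orphan_contig", filler(clen2)))
    else:  # split_edge_reassemblable
        k = int(rng.integers(1, len(mats)))  # 1..3 mat genes with APN2
        left_mats, right_mats = mats[:k], mats[k:]
        # contig L: ... APN2, left_mats -> contig end (tail < edge_distance)
        aL, endL = _lay_genes(rng, ["APN2"] + left_mats, margin(), "matL_contig",
                              pseudogenize_mat113)
        tail = int(rng.integers(0, max(edge_distance, 1)))
        clenL = endL + tail
        # contig R laid as: SLA2 ... right_mats toward the end, then mirrored so
        # the mat genes sit near the start of the contig
        aR, endR = _lay_genes(rng, ["SLA2"] + list(reversed(right_mats)),
                              margin(), "matR_contig", pseudogenize_mat113)
        tailR = int(rng.integers(0, max(edge_distance, 1)))
        clenR = endR + tailR
        aR = _mirror(aR, clenR)
        if rng.random() < 0.5:
            aL = _mirror(aL, clenL)
        if rng.random() < 0.5:
            aR = _mirror(aR, clenR)
        anns += aL + aR
        contigs.append(("matL_contig", filler(clenL)))
        contigs.append(("matR_contig", filler(clenR)))

    # a decoy contig with no annotated genes, as real assemblies have
    contigs.append(("other_contig", filler(int(rng.integers(15_000, 40_000)))))
    genome = GenomeSequence(id=f"matfix_{architecture}_{seed}", contigs=contigs)
    return genome, sorted(anns, key=lambda x: (x.contig, x.start))


# ---------------------------------------------------------------------------
# per-gene coverage simulation
# ---------------------------------------------------------------------------


@dataclass
class CoverageSimParams:
    """Parameters for :func:`simulate_gene_coverage`.

    ``mean_depth`` is the expected reads/kbp of a single-copy gene present in
    every nucleus.  ``nuclear_ratio`` is the proportion of mat1-1 nuclei in a
    heterokaryon.  ``gene_list`` maps gene symbols to lengths in bp.
    """

    mean_depth: float = 200.0
    nuclear_ratio: float = 0.5
    gene_list: dict[str, int] = field(
        default_factory=lambda: dict(GENE_LENGTHS_BP))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be positive")
        if not 0.0 <= self.nuclear_ratio <= 1.0:
            raise ParameterError("nuclear_ratio must be in [0, 1]")
        if any(l <= 0 for l in self.gene_list.values()):
            raise ParameterError("all gene lengths must be positive")


def expected_gene_depth(gene: str, params: CoverageSimParams,
                        karyotype: Literal["homokaryon", "heterokaryon"]
                        ) -> float:
    """Expected reads/kbp for one gene under the chosen karyotype model."""
    if karyotype == "homokaryon":
        return params.mean_depth
    if karyotype != "heterokaryon":
        raise ParameterError(f"unknown karyotype {karyotype!r}")
    r = params.nuclear_ratio
    if gene in MAT11_GENES:
        return r * params.mean_depth
    if gene in MAT12_GENES:
        return (1.0 - r) * params.mean_depth
    return params.mean_depth


def simulate_gene_coverage(params: CoverageSimParams,
                           karyotype: Literal["homokaryon", "heterokaryon"]
                           ) -> GeneCoverage:
    """Draw Poisson per-gene read counts and report them as reads/kbp.

    In a homokaryon every gene is present in every nucleus and has expectation
    ``mean_depth``.  In a heterokaryon the mat1-1 genes come only from the
    mat1-1 nuclei (fraction ``nuclear_ratio``) and the mat1-2-1 gene only from
    the rest, while the flanking single-copy genes (APN2, SLA2) are present in
    all nuclei.
    """
    rng = np.random.default_rng(params.seed)
    cov: dict[str, float] = {}
    for gene, length in params.gene_list.items():
        kbp = length / 1000.0
        lam = expected_gene_depth(gene, params, karyotype) * kbp
        cov[gene] = float(rng.poisson(lam)) / kbp
    return GeneCoverage(cov)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_annotations_tsv(annotations: list[GeneAnnotation],
                          path: str | Path) -> None:
    """5-column TSV: gene, contig, start, end, strand (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("gene\tcontig\tstart\tend\tstrand\n")
        for a in annotations:
            fh.write(f"{a.gene}\t{a.contig}\t{a.start}\t{a.end}\t{a.strand}\n")


def write_annotations_gff3(annotations: list[GeneAnnotation],
                           path: str | Path, source: str = "anispec") -> None:
    """GFF3 (1-based inclusive coordinates on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene};Name={a.gene}"
            if a.pseudogene:
                attrs += ";pseudo=true"
            fh.write("\t".join([
                a.contig, source, "gene", str(a.start + 1), str(a.end),
                ".", a.strand, ".", attrs]) + "\n")


def write_coverage_tsv(coverage: GeneCoverage, path: str | Path) -> None:
    """2-column TSV: gene, reads_per_kbp."""
    with open(path, "w") as fh:
        fh.write("gene\treads_per_kbp\n")
        for gene, depth in coverage.items():
            fh.write(f"{gene}\t{depth:.3f}\n")
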