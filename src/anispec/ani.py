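"""Reciprocal fragment-based average nucleotide identity (ANI).

The genome-pair comparison proceeds BLAST-fragment style: the query assembly
is tiled into non-overlapping windows (1 kb by default), each fragment is
locally aligned against the whole subject assembly (both strands), and the
best alignment per fragment yields one identity observation.  Fragments whose
best alignment covers less than half the fragment or falls below 70% identity
are *zero hits* — the query's "specific sequences" with no detectable
counterpart in the subject.  A directional ANI is the unweighted mean
identity over hit fragments; the reciprocal ANI averages the two directions.

Beyond the single ANI number the per-fragment identity spectrum is kept: its
shape separates a uniformly divergent pair (distinct species) from a
conspecific pair carrying a minority of highly divergent blocks, which drags
the mean down while most fragments stay above the species-level identity cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .align import (AlignScores, LocalHit, blast_best_local_hits,
                    exact_best_local_hit)
from .genome import GenomeSequence

DEFAULT_BIN_EDGES = (70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 97.0, 99.0, 99.5, 100.0)


class AniInputError(ValueError):
    """Invalid input to an ANI operation."""


class AniUndefinedError(RuntimeError):
    """A direction produced no hit fragments, so its ANI is undefined."""


@dataclass(frozen=True)
class AniConfig:
    """Fragmentation, hit-filter and engine settings.

    The 1 kb non-overlapping window is the common fragment-ANI convention;
    hit criteria (query coverage >= 0.5, identity >= 70%) separate "divergent
    but alignable" from "no similarity found".  ``engine='auto'`` uses the
    exact Smith–Waterman for small genomes (both below
    ``exact_size_limit_bp``) and blastn otherwise.
    """

    window_bp: int = 1000
    step_bp: int = 1000
    min_fragment_length: int = 500
    min_identity: float = 70.0
    min_aligned_fraction: float = 0.5
    max_n_fraction: float = 0.5
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    high_id_cut: float = 99.5
    divergent_band: tuple[float, float] = (85.0, 90.0)
    engine: Literal["auto", "blast", "exact"] = "auto"
    exact_size_limit_bp: int = 50_000
    scores: AlignScores = AlignScores()

    def __post_init__(self) -> None:
        if not self.window_bp >= self.min_fragment_length >= 100:
            raise AniInputError(
                "require window_bp >= min_fragment_length >= 100")
        if self.step_bp < 1:
            raise AniInputError("step_bp must be >= 1")
        edges = self.bin_edges
        if any(a >= b for a, b in zip(edges, edges[1:])) or edges[-1] != 100.0:
            raise AniInputError(
                "bin edges must be strictly increasing and end at 100")

    def resolve_engine(self, query: GenomeSequence,
                       subject: GenomeSequence) -> str:
        if self.engine != "auto":
            return self.engine
        small = max(len(query), len(subject)) <= self.exact_size_limit_bp
        return "exact" if small else "blast"


@dataclass(frozen=True)
class Fragment:
    """A query tile: 0-based half-open window on one contig."""

    contig: str
    start: int
    length: int

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.start + self.length}"


@dataclass
class FragmentHit:
    """Outcome for one fragment; ``identity_percent`` is None for zero hits."""

    fragment: Fragment
    identity_percent: Optional[float]
    aligned_fraction: float


@dataclass
class IdentityHistogram:
    """Counts of hit fragments per identity bin, plus the zero-hit count.

    Bins are half-open ``[lo, hi)``; the top bin is closed at 100.
    """

    bin_edges: tuple[float, ...]
    counts: list[int]
    zero_hits: int

    @classmethod
    def from_hits(cls, identities: Sequence[float],
                  bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                  zero_hits: int = 0) -> "IdentityHistogram":
        edges = tuple(float(e) for e in bin_edges)
        if any(a >= b for a, b in zip(edges, edges[1:])) or edges[-1] != 100.0:
            raise AniInputError(
                "bin edges must be strictly increasing and end at 100")
        ids = np.asarray(identities, dtype=float)
        if ids.size and (ids.min() < 0 or ids.max() > 100):
            raise AniInputError("identity values outside [0, 100]")
        # np.histogram closes the last bin, matching the [lo,100] convention;
        # values below the first edge are counted into the first bin
        clipped = np.clip(ids, edges[0], 100.0) if ids.size else ids
        counts, _ = np.histogram(clipped, bins=np.asarray(edges))
        return cls(bin_edges=edges, counts=[int(c) for c in counts],
                   zero_hits=int(zero_hits))

    @property
    def n_fragments(self) -> int:
        return sum(self.counts) + self.zero_hits


@dataclass
class DirectionalANI:
    """One direction of a genome-pair comparison (query tiled, subject whole)."""

    query_id: str
    subject_id: str
    ani_percent: float
    n_fragments: int        # tiled fragments that passed the N-mask filter
    n_hits: int
    n_masked: int
    specific_fraction: float  # zero-hit fraction of n_fragments
    histogram: IdentityHistogram
    hits: list[FragmentHit] = field(default_factory=list, repr=False)

    def identities(self) -> np.ndarray:
        return np.array([h.identity_percent for h in self.hits
                         if h.identity_percent is not None])


@dataclass
class ReciprocalANI:
    """Both directions plus their average and pooled spectrum summaries."""

    forward: DirectionalANI
    reverse: DirectionalANI
    ani_mean: float
    high_identity_fraction: float   # of pooled hit fragments, id >= high_id_cut
    divergent_band_fraction: float  # of pooled fragments, id in divergent band

    @property
    def pair(self) -> tuple[str, str]:
        return (self.forward.query_id, self.forward.subject_id)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fragment_genome(genome: GenomeSequence, window_bp: int = 1000,
                    step_bp: int = 1000, min_fragment_length: int = 500,
                    max_n_fraction: float = 0.5
                    ) -> tuple[list[Fragment], int]:
    """Tile a genome into query fragments.

    Returns ``(fragments, n_masked)``: trailing windows shorter than
    ``min_fragment_length`` are discarded; windows with more than
    ``max_n_fraction`` of N are masked out and counted separately.
    """
    if len(genome) == 0:
        raise AniInputError(f"genome {genome.id!r} is empty")
    fragments: list[Fragment] = []
    n_masked = 0
    for name, seq in genome:
        for start in range(0, len(seq), step_bp):
            piece = seq[start:start + window_bp]
            if len(piece) < min_fragment_length:
                continue
            if piece.count("N") > max_n_fraction * len(piece):
                n_masked += 1
                continue
            fragments.append(Fragment(contig=name, start=start,
                                      length=len(piece)))
    return fragments, n_masked


def _fragment_seq(genome: GenomeSequence, frag: Fragment) -> str:
    return genome.sequence(frag.contig)[frag.start:frag.start + frag.length]


def _hit_passes(hit: LocalHit, config: AniConfig) -> bool:
    return (hit.aligned_query_fraction >= config.min_aligned_fraction
            and hit.identity_percent >= config.min_identity)


def best_fragment_identity(fragment_sequence: str, subject: GenomeSequence,
                           config: AniConfig = AniConfig(),
                           engine: Optional[str] = None
                           ) -> tuple[Optional[float], float]:
    """Best local alignment of one fragment against a subject genome.

    Returns ``(identity_percent, aligned_fraction)``; identity is ``None``
    for a zero hit (best alignment absent or failing the hit criteria).
    """
    eng = engine or ("exact" if len(subject) <= config.exact_size_limit_bp
                     else "blast")
    if eng == "exact":
        hit = exact_best_local_hit(fragment_sequence, subject, config.scores)
    else:
        hit = blast_best_local_hits([("frag", fragment_sequence)],
                                    subject).get("frag")
    if hit is None:
        return None, 0.0
    if not _hit_passes(hit, config):
        return None, hit.aligned_query_fraction
    return hit.identity_percent, hit.aligned_query_fraction


def directional_ani(query: GenomeSequence, subject: GenomeSequence,
                    config: AniConfig = AniConfig()) -> DirectionalANI:
    """Fragment the query, align every fragment to the subject, summarize.

    Raises :class:`AniUndefinedError` when no fragment produces a hit.
    """
    if len(query) == 0 or len(subject) == 0:
        raise AniInputError("both genomes must be non-empty")
    fragments, n_masked = fragment_genome(
        query, config.window_bp, config.step_bp, config.min_fragment_length,
        config.max_n_fraction)
    if not fragments:
        raise AniInputError(
            f"genome {query.id!r} yielded no usable fragments")

    engine = config.resolve_engine(query, subject)
    named = [(f.name, _fragment_seq(query, f)) for f in fragments]
    if engine == "blast":
        raw = blast_best_local_hits(named, subject)
    else:
        raw = {}
        for name, seq in named:
            h = exact_best_local_hit(seq, subject, config.scores)
            if h is not None:
                raw[name] = h

    hits: list[FragmentHit] = []
    identities: list[float] = []
    for frag in fragments:
        h = raw.get(frag.name)
        if h is not None and _hit_passes(h, config):
            hits.append(FragmentHit(frag, h.identity_percent,
                                    h.aligned_query_fraction))
            identities.append(h.identity_percent)
        else:
            hits.append(FragmentHit(
                frag, None, h.aligned_query_fraction if h else 0.0))

    n_fragments = len(fragments)
    n_hits = len(identities)
    zero_hits = n_fragments - n_hits
    if n_hits == 0:
        raise AniUndefinedError(
            f"ANI undefined for direction {query.id} -> {subject.id}: "
            f"no fragment passed the hit criteria "
            f"({zero_hits} zero hits of {n_fragments} fragments)")
    return DirectionalANI(
        query_id=query.id, subject_id=subject.id,
        ani_percent=float(np.mean(identities)),
        n_fragments=n_fragments, n_hits=n_hits, n_masked=n_masked,
        specific_fraction=zero_hits / n_fragments,
        histogram=IdentityHistogram.from_hits(identities, config.bin_edges,
                                              zero_hits),
        hits=hits)


def reciprocal_ani(genome_a: GenomeSequence, genome_b: GenomeSequence,
                   config: AniConfig = AniConfig()) -> ReciprocalANI:
    """Both directional ANIs with identical parameters, averaged.

    The pooled spectrum summaries quantify the two diagnostic features of
    the identity spectrum: the mass at species-level identity
    (``high_identity_fraction``, over hit fragments) and the mass in the
    divergent band (``divergent_band_fraction``, over all fragments).
    """
    try:
        fwd = directional_ani(genome_a, genome_b, config)
    except AniUndefinedError as e:
        raise AniUndefinedError(
            f"forward direction ({genome_a.id} -> {genome_b.id}) "
            f"undefined: {e}") from e
    try:
        rev = directional_ani(genome_b, genome_a, config)
    except AniUndefinedError as e:
        raise AniUndefinedError(
            f"reverse direction ({genome_b.id} -> {genome_a.id}) "
            f"undefined: {e}") from e

    pooled = np.concatenate([fwd.identities(), rev.identities()])
    n_frag = fwd.n_fragments + rev.n_fragments
    lo, hi = config.divergent_band
    return ReciprocalANI(
        forward=fwd, reverse=rev,
        ani_mean=(fwd.ani_percent + rev.ani_percent) / 2.0,
        high_identity_fraction=float(np.mean(pooled >= config.high_id_cut))
        if pooled.size else 0.0,
        divergent_band_fraction=float(
            np.sum((pooled >= lo) & (pooled < hi))) / n_frag,
    )


# alias matching the field idiom "identity histogram of a hit list"
def identity_histogram(identities: Sequence[float],
                       bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                       zero_hits: int = 0) -> IdentityHistogram:
    """Bin hit identities into the spectrum histogram (see the class)."""
    return IdentityHistogram.from_hits(identities, bin_edges, zero_hits)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _directional_summary(d: DirectionalANI) -> dict:
    return {
        "query_id": d.query_id,
        "subject_id": d.subject_id,
        "ani_percent": d.ani_percent,
        "n_fragments": d.n_fragments,
        "n_hits": d.n_hits,
        "n_masked": d.n_masked,
        "specific_fraction": d.specific_fraction,
        "histogram": {
            "bin_edges": list(d.histogram.bin_edges),
            "counts": d.histogram.counts,
            "zero_hits": d.histogram.zero_hits,
        },
    }


def write_ani_report(result: ReciprocalANI, path: str | Path,
                     config: AniConfig = AniConfig()) -> None:
    """JSON report: both directions, the average, and a config echo."""
    report = {
        "pair": list(result.pair),
        "ani_mean": result.ani_mean,
        "high_identity_fraction": result.high_identity_fraction,
        "divergent_band_fraction": result.divergent_band_fraction,
        "forward": _directional_summary(result.forward),
        "reverse": _directional_summary(result.reverse),
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "scores"},
            "scores": asdict(config.scores),
            "ani_definition": "unweighted mean identity over hit fragments; "
                              "identity = matches / alignment columns "
                              "(gap columns included)",
        },
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def write_fragment_table(d: DirectionalANI, path: str | Path) -> None:
    """Per-fragment TSV: contig, start, identity (NA for zero hits)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tidentity\n")
        for h in d.hits:
            ident = "NA" if h.identity_percent is None \
                else f"{h.identity_percent:.3f}"
            fh.write(f"{h.fragment.contig}\t{h.fragment.start}\t{ident}\n")


def plot_identity_spectrum(result: ReciprocalANI, path: str | Path) -> None:
    """Bar plot of the pooled per-fragment identity spectrum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, d in zip(axes, (result.forward, result.reverse)):
        edges = d.histogram.bin_edges
        labels = [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
        labels.append("zero hit")
        values = d.histogram.counts + [d.histogram.zero_hits]
        ax.bar(range(len(values)), values, color="#6b8ec9")
        ax.set_xticks(range(len(values)))
        ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
        ax.set_title(f"{d.query_id} vs {d.subject_id} "
                     f"(ANI {d.ani_percent:.2f}%)", fontsize=9)
        ax.set_ylabel("fragments")
    fig.suptitle(f"reciprocal ANI {result.ani_mean:.2f}%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
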