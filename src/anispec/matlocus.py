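"""Mating-type locus architecture, coverage-ratio test and breeding-system call.

In Sordariales fungi the mating-type (MAT) locus sits between two conserved
single-copy genes, *APN2* and *SLA2*.  A homothallic (self-fertile) strain
typically carries the genes of both idiomorphs — *mat1-1* (``mat1-1-1``,
``mat1-1-2``, ``mat1-1-3``) and *mat1-2* (``mat1-2-1``) — fused in one
cluster between the flanks.  A heterothallic strain carries only one
idiomorph per nucleus; assemblies of mixed (heterokaryotic) mycelia then show
the two idiomorphs on different contigs and roughly half the read coverage on
each idiomorph relative to the flanking genes.

This module classifies locus architecture from gene annotations, attempts to
rescue a fused locus split across contig edges by the assembler, tests
flank-versus-mat coverage under a Poisson model, and combines the evidence
into a breeding-system call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

import pandas as pd
from scipy import stats

FLANK_GENES = frozenset({"APN2", "SLA2"})
MAT11_GENES = frozenset({"mat1-1-1", "mat1-1-2", "mat1-1-3"})
MAT12_GENES = frozenset({"mat1-2-1"})
MAT_GENES = MAT11_GENES | MAT12_GENES
GENE_VOCABULARY = FLANK_GENES | MAT_GENES

# typical Sordariales gene spans, used by the fixture generator and as the
# default coverage-simulation gene list
GENE_LENGTHS_BP: dict[str, int] = {
    "APN2": 3600,
    "SLA2": 3300,
    "mat1-1-1": 1100,
    "mat1-1-2": 1200,
    "mat1-1-3": 700,
    "mat1-2-1": 800,
}


class AnnotationError(ValueError):
    """Invalid gene annotation input."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene placement: 0-based half-open coordinates on a contig."""

    gene: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.gene not in GENE_VOCABULARY:
            raise AnnotationError(
                f"gene {self.gene!r} not in vocabulary {sorted(GENE_VOCABULARY)}")
        if not self.start < self.end:
            raise AnnotationError(
                f"{self.gene}: start must be < end ({self.start}, {self.end})")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene}: strand must be '+' or '-'")


ArchitectureClass = Literal["fused", "split_unlinked", "single_idiomorph",
                            "incomplete"]


@dataclass
class MatArchitecture:
    """Architecture verdict with supporting evidence strings."""

    architecture: ArchitectureClass
    idiomorph_present: frozenset[str]  # subset of {"mat1-1", "mat1-2"}
    edge_reassembled: bool = False
    evidence: list[str] = field(default_factory=list)

    @property
    def single_idiomorph_label(self) -> Optional[str]:
        if self.architecture == "single_idiomorph":
            return next(iter(self.idiomorph_present))
        return None


@dataclass
class GeneCoverage(Mapping[str, float]):
    """Per-gene read coverage in reads/kbp."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if v < 0:
                raise AnnotationError(f"negative coverage for {g}: {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


CoverageVerdict = Literal["equal_coverage", "elevated_flank", "undetermined"]

BreedingSystem = Literal["homothallic", "heterothallic_likely",
                         "single_mating_type_unresolved", "undetermined"]


@dataclass
class BreedingCall:
    """Breeding-system inference with the evidence trail."""

    call: BreedingSystem
    flank_mat_ratio: Optional[float] = None
    test_pvalue: Optional[float] = None
    evidence: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------


def _idiomorphs_present(genes: set[str]) -> frozenset[str]:
    present = set()
    if genes & MAT11_GENES:
        present.add("mat1-1")
    if genes & MAT12_GENES:
        present.add("mat1-2")
    return frozenset(present)


def _between_flanks(anns: list[GeneAnnotation]) -> bool:
    """True if all mat genes on this contig lie between APN2 and SLA2."""
    by_gene = {a.gene: a for a in anns}
    if "APN2" not in by_gene or "SLA2" not in by_gene:
        return False
    lo = min(by_gene["APN2"].start, by_gene["SLA2"].start)
    hi = max(by_gene["APN2"].end, by_gene["SLA2"].end)
    return all(lo <= a.start and a.end <= hi
               for a in anns if a.gene in MAT_GENES)


def classify_architecture(annotations: Iterable[GeneAnnotation],
                          contig_lengths: Mapping[str, int],
                          edge_distance: int = 2000,
                          try_edge_reassembly: bool = True) -> MatArchitecture:
    """Classify the mating-type locus architecture from gene annotations.

    Classes:

    * ``fused`` — both idiomorphs present, all mat genes between APN2 and
      SLA2 on one contig (possibly after edge reassembly, flagged in
      ``edge_reassembled``);
    * ``split_unlinked`` — both idiomorphs present, exactly one of them
      flanked by APN2/SLA2, the other on a contig carrying neither flank;
    * ``single_idiomorph`` — only one idiomorph's genes present (with both
      flanks found);
    * ``incomplete`` — flanks missing, vocabulary empty, or contradictory
      placements (the same gene annotated on two contigs).
    """
    anns = list(annotations)
    if not anns:
        raise AnnotationError("no annotations provided")
    for a in anns:
        if a.contig not in contig_lengths:
            raise AnnotationError(
                f"no contig length provided for {a.contig!r}")

    evidence: list[str] = []
    seen: dict[str, str] = {}
    for a in anns:
        if a.gene in seen and seen[a.gene] != a.contig:
            evidence.append(
                f"duplicated gene {a.gene} on contigs {seen[a.gene]} and "
                f"{a.contig}; classification abandoned")
            return MatArchitecture("incomplete",
                                   _idiomorphs_present({x.gene for x in anns}),
                                   evidence=evidence)
        seen[a.gene] = a.contig

    genes = {a.gene for a in anns}
    idio = _idiomorphs_present(genes)
    flanks = genes & FLANK_GENES
    if len(flanks) < 2 or not idio:
        evidence.append(f"flanks found: {sorted(flanks)}; "
                        f"idiomorphs found: {sorted(idio)}")
        return MatArchitecture("incomplete", idio, evidence=evidence)

    by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in anns:
        by_contig.setdefault(a.contig, []).append(a)

    if len(idio) == 1:
        evidence.append(f"single idiomorph {next(iter(idio))} present")
        return MatArchitecture("single_idiomorph", idio, evidence=evidence)

    # both idiomorphs present
    if len(by_contig) == 1:
        contig = next(iter(by_contig))
        if _between_flanks(by_contig[contig]):
            evidence.append(
                f"all mat genes between APN2 and SLA2 on {contig}")
            return MatArchitecture("fused", idio, evidence=evidence)
        evidence.append(f"mat genes on {contig} not bracketed by APN2/SLA2")
        return MatArchitecture("incomplete", idio, evidence=evidence)

    if try_edge_reassembly:
        joined = attempt_edge_reassembly(anns, contig_lengths, edge_distance)
        if joined is not None:
            return joined

    # split over contigs: look for one flanked cluster and one orphan
    flanked = [c for c, ca in by_contig.items()
               if {"APN2", "SLA2"} <= {a.gene for a in ca}
               and _between_flanks(ca)]
    orphans = [c for c, ca in by_contig.items()
               if not ({a.gene for a in ca} & FLANK_GENES)]
    if len(flanked) == 1 and orphans and len(flanked) + len(orphans) == len(by_contig):
        orphan_genes = {a.gene for c in orphans for a in by_contig[c]}
        flanked_genes = {a.gene for a in by_contig[flanked[0]]} & MAT_GENES
        if _idiomorphs_present(orphan_genes) and \
                _idiomorphs_present(flanked_genes) and \
                not (_idiomorphs_present(orphan_genes) &
                     _idiomorphs_present(flanked_genes)):
            evidence.append(
                f"idiomorph {sorted(_idiomorphs_present(flanked_genes))} "
                f"flanked on {flanked[0]}; "
                f"{sorted(_idiomorphs_present(orphan_genes))} unlinked on "
                f"{'/'.join(orphans)}")
            return MatArchitecture("split_unlinked", idio, evidence=evidence)

    evidence.append("mat genes split over contigs in a layout that is "
                    "neither edge-reassemblable nor a flanked+orphan split")
    return MatArchitecture("incomplete", idio, evidence=evidence)


def _edge_gap(anns: list[GeneAnnotation], contig_len: int) -> tuple[int, int]:
    """(gap to contig start, gap to contig end) of the annotation cluster."""
    lo = min(a.start for a in anns)
    hi = max(a.end for a in anns)
    return lo, contig_len - hi


def attempt_edge_reassembly(annotations: Iterable[GeneAnnotation],
                            contig_lengths: Mapping[str, int],
                            edge_distance: int = 2000
                            ) -> Optional[MatArchitecture]:
    """Try to rescue a fused locus split across two contig edges.

    Succeeds when one contig carries APN2 plus part of the mat cluster with
    the mat genes within ``edge_distance`` of a contig end (strictly less
    than; ``edge_distance=0`` never reassembles), another carries SLA2 plus
    the remaining mat genes likewise at an edge, and the union of mat genes
    covers both idiomorphs.  Returns a ``fused`` :class:`MatArchitecture`
    with ``edge_reassembled=True``, or ``None`` when no join is possible.
    """
    anns = list(annotations)
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for a in anns:
        by_contig.setdefault(a.contig, []).append(a)

    apn2 = [c for c, ca in by_contig.items()
            if "APN2" in {a.gene for a in ca}]
    sla2 = [c for c, ca in by_contig.items()
            if "SLA2" in {a.gene for a in ca}]
    if len(apn2) != 1 or len(sla2) != 1 or apn2[0] == sla2[0]:
        return None
    c1, c2 = apn2[0], sla2[0]
    genes1 = {a.gene for a in by_contig[c1]}
    genes2 = {a.gene for a in by_contig[c2]}
    # each of the two contigs may carry only its flank plus mat genes
    if genes1 & FLANK_GENES != {"APN2"} or genes2 & FLANK_GENES != {"SLA2"}:
        return None
    mats = (genes1 | genes2) & MAT_GENES
    idio = _idiomorphs_present(mats)
    if idio != frozenset({"mat1-1", "mat1-2"}):
        return None

    def reaches_edge(contig: str) -> bool:
        cluster = [a for a in by_contig[contig] if a.gene in MAT_GENES]
        if not cluster:
            # a lone flank: the flank itself must abut the edge
            cluster = by_contig[contig]
        lo, hi = _edge_gap(cluster, contig_lengths[contig])
        return min(lo, hi) < edge_distance

    if reaches_edge(c1) and reaches_edge(c2):
        return MatArchitecture(
            "fused", idio, edge_reassembled=True,
            evidence=[f"locus reassembled by joining {c1} and {c2} edges "
                      f"(edge_distance={edge_distance})"])
    return None


# ---------------------------------------------------------------------------
# coverage-ratio test
# ---------------------------------------------------------------------------


def coverage_ratio_test(coverage: GeneCoverage, fold_threshold: float = 1.5,
                        alpha: float = 0.05,
                        exclude_pseudogenes: Iterable[str] = ()
                        ) -> tuple[Optional[float], Optional[float],
                                   CoverageVerdict]:
    """Compare flanking-gene to mat-gene read coverage.

    Heterokaryotic mycelia carry each idiomorph in only part of their nuclei,
    so the flanking single-copy genes (APN2, SLA2) are expected to show the
    summed coverage of the two idiomorphs — i.e. roughly twice the per-mat
    coverage at a balanced nuclear ratio.

    The verdict is ``elevated_flank`` when BOTH the fold ratio
    ``mean(flanks)/mean(mat genes)`` reaches ``fold_threshold`` AND a
    one-sided conditional Poisson rate test (flank rate > mat rate; reads/kbp
    treated as Poisson counts at 1 kbp exposure per gene) is significant at
    ``alpha``; otherwise ``equal_coverage``.  Genes listed in
    ``exclude_pseudogenes`` are dropped from the mat mean (pseudogenes may
    diverge in read mappability).

    Returns ``(flank_mat_ratio, pvalue, verdict)``.
    """
    excl = set(exclude_pseudogenes)
    flank = [coverage[g] for g in sorted(FLANK_GENES) if g in coverage]
    mat = [coverage[g] for g in sorted(MAT_GENES)
           if g in coverage and g not in excl]
    if not flank or not mat:
        return None, None, "undetermined"
    mean_mat = sum(mat) / len(mat)
    if mean_mat == 0:
        return None, None, "undetermined"
    ratio = (sum(flank) / len(flank)) / mean_mat

    # conditional binomial (C-)test for two Poisson rates, one-sided
    x = round(sum(flank))
    n = round(sum(flank) + sum(mat))
    p0 = len(flank) / (len(flank) + len(mat))
    pvalue = float(stats.binom.sf(x - 1, n, p0))

    verdict: CoverageVerdict = (
        "elevated_flank" if ratio >= fold_threshold and pvalue < alpha
        else "equal_coverage")
    return ratio, pvalue, verdict


# ---------------------------------------------------------------------------
# breeding-system inference
# ---------------------------------------------------------------------------


def infer_breeding_system(architecture: MatArchitecture,
                          coverage_verdict: Optional[CoverageVerdict] = None,
                          fertility_observed: Optional[bool] = None,
                          flank_mat_ratio: Optional[float] = None,
                          test_pvalue: Optional[float] = None) -> BreedingCall:
    """Combine locus architecture, coverage and fertility into one call.

    * ``fused`` → homothallic (a single genome carries the whole locus);
    * ``split_unlinked`` + ``equal_coverage`` → homothallic (all six genes at
      single-copy depth, so the arrangement is genomic, not a heterokaryon
      assembly artefact);
    * ``split_unlinked`` + ``elevated_flank`` → heterothallic_likely (the
      idiomorph coverages sum to the flank coverage, as expected for a
      heterokaryon);
    * ``split_unlinked`` without a coverage verdict → undetermined;
    * ``single_idiomorph`` → heterothallic_likely, downgraded to
      ``single_mating_type_unresolved`` when the strain nonetheless produced
      fruiting bodies (partial sexual development with a single mating type
      leaves homothallism open);
    * ``incomplete`` → undetermined.
    """
    ev = list(architecture.evidence)
    arch = architecture.architecture
    call: BreedingSystem
    if arch == "fused":
        call = "homothallic"
        ev.append("complete fused mating-type locus present"
                  + (" (after contig-edge reassembly)"
                     if architecture.edge_reassembled else ""))
    elif arch == "split_unlinked":
        if coverage_verdict == "equal_coverage":
            call = "homothallic"
            ev.append("unlinked idiomorphs but flank and mat genes at equal "
                      "coverage: single genome carries both idiomorphs")
        elif coverage_verdict == "elevated_flank":
            call = "heterothallic_likely"
            ev.append("flanking genes at elevated coverage relative to mat "
                      "genes: consistent with a mat1-1/mat1-2 heterokaryon")
        else:
            call = "undetermined"
            ev.append("unlinked idiomorphs and no usable coverage evidence")
    elif arch == "single_idiomorph":
        if fertility_observed:
            call = "single_mating_type_unresolved"
            ev.append("single idiomorph yet fruiting observed: homothallism "
                      "versus heterothallism unresolved")
        else:
            call = "heterothallic_likely"
            ev.append("single idiomorph present: probable heterothallic "
                      "isolate having lost one mating type")
    else:
        call = "undetermined"
        ev.append("incomplete locus annotation")
    return BreedingCall(call=call, flank_mat_ratio=flank_mat_ratio,
                        test_pvalue=test_pvalue, evidence=ev)


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------


def read_annotations_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read the 5-column TSV (gene, contig, start, end, strand; 0-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "contig", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise AnnotationError(
            f"annotation TSV must have columns {sorted(required)}")
    pseudo = df["pseudogene"] if "pseudogene" in df.columns else \
        pd.Series(False, index=df.index)
    return [GeneAnnotation(gene=str(r.gene), contig=str(r.contig),
                           start=int(r.start), end=int(r.end),
                           strand=str(r.strand), pseudogene=bool(p))
            for r, p in zip(df.itertuples(), pseudo)]


def read_annotations_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based inclusive → 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            id_spec=["ID", "Name"], merge_strategy="error")
    out = []
    for feat in db.all_features():
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        if name not in GENE_VOCABULARY:
            continue
        pseudo = feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
        out.append(GeneAnnotation(gene=name, contig=feat.seqid,
                                  start=feat.start - 1, end=feat.end,
                                  strand=feat.strand if feat.strand in "+-" else "+",
                                  pseudogene=pseudo))
    if not out:
        raise AnnotationError(f"no vocabulary genes found in {path}")
    return sorted(out, key=lambda a: (a.contig, a.start))


def read_coverage_tsv(path: str | Path) -> GeneCoverage:
    """Read the 2-column coverage TSV (gene, reads_per_kbp)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "reads_per_kbp"} <= set(df.columns):
        raise AnnotationError(
            "coverage TSV must have columns gene, reads_per_kbp")
    return GeneCoverage({str(r.gene): float(r.reads_per_kbp)
                         for r in df.itertuples()})
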