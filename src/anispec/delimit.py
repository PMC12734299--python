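"""Species-delimitation decision rules over reciprocal ANI results.

The core rule set encodes the genome-wide identity thresholds used for
fungal species delimitation — strains above 99.5% ANI consistently
conspecific, strains below 99% usually distinct — plus an identity-spectrum
exception: a pair whose ANI is dragged below the species line by a minority
of highly divergent blocks (a bimodal spectrum with most fragments at
species-level identity, a clear 85-90% band, and few specific sequences) is
still called conspecific.  Pairs landing between the two thresholds are
reported as ambiguous rather than adjudicated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .ani import AniConfig, ReciprocalANI, reciprocal_ani, write_ani_report
from .genome import GenomeSequence

Verdict = Literal["same_species", "different_species", "ambiguous",
                  "same_species_divergent_blocks"]


class DelimitInputError(ValueError):
    """Invalid input to the delimitation pipeline."""


@dataclass(frozen=True)
class DelimitThresholds:
    """Decision thresholds (all percentages/proportions configurable).

    ``t_same``/``t_diff`` are the conspecific / distinct-species ANI lines.
    The remaining fields quantify the spectrum exception: at least
    ``high_id_min_fraction`` of hit fragments above ``high_id_cut``, at least
    ``divergent_band_min_fraction`` of fragments inside ``divergent_band``,
    and mean specific fraction at most ``max_specific_for_conspecific``.
    """

    t_same: float = 99.5
    t_diff: float = 99.0
    high_id_cut: float = 99.5
    high_id_min_fraction: float = 0.80
    divergent_band: tuple[float, float] = (85.0, 90.0)
    divergent_band_min_fraction: float = 0.02
    max_specific_for_conspecific: float = 0.03

    def __post_init__(self) -> None:
        if not self.t_diff < self.t_same:
            raise DelimitInputError("require t_diff < t_same")
        for name in ("high_id_min_fraction", "divergent_band_min_fraction",
                     "max_specific_for_conspecific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DelimitInputError(f"{name}={v} outside [0, 1]")


@dataclass
class SpeciesCall:
    """Verdict for one strain pair, with the rule that fired."""

    id_a: str
    id_b: str
    verdict: Verdict
    ani_mean: float
    evidence: list[str] = field(default_factory=list)


def classify_pair(r: ReciprocalANI,
                  t: DelimitThresholds = DelimitThresholds()) -> SpeciesCall:
    """Apply the threshold + spectrum rules to one reciprocal ANI result.

    Rule order:

    1. ``ani_mean >= t_same`` → same_species;
    2. ``ani_mean < t_diff`` with a bimodal spectrum (high-identity majority,
       divergent band present, few specific sequences) →
       same_species_divergent_blocks;
    3. ``ani_mean < t_diff`` otherwise → different_species;
    4. ``t_diff <= ani_mean < t_same`` → ambiguous.
    """
    if r.forward is None or r.reverse is None:  # defensive; types forbid it
        raise DelimitInputError("incomplete ReciprocalANI")
    id_a, id_b = r.pair
    ani = r.ani_mean
    mean_specific = (r.forward.specific_fraction
                     + r.reverse.specific_fraction) / 2.0
    if ani >= t.t_same:
        return SpeciesCall(id_a, id_b, "same_species", ani, [
            f"ANI {ani:.2f}% >= {t.t_same}%: conspecific"])
    if ani < t.t_diff:
        bimodal = (r.high_identity_fraction >= t.high_id_min_fraction
                   and r.divergent_band_fraction >= t.divergent_band_min_fraction
                   and mean_specific <= t.max_specific_for_conspecific)
        if bimodal:
            return SpeciesCall(id_a, id_b, "same_species_divergent_blocks", ani, [
                f"ANI {ani:.2f}% < {t.t_diff}% but spectrum is bimodal: "
                f"{100 * r.high_identity_fraction:.1f}% of hit fragments >= "
                f"{t.high_id_cut}%, "
                f"{100 * r.divergent_band_fraction:.1f}% of fragments in "
                f"[{t.divergent_band[0]:g},{t.divergent_band[1]:g})%, "
                f"mean specific fraction {100 * mean_specific:.1f}%"])
        return SpeciesCall(id_a, id_b, "different_species", ani, [
            f"ANI {ani:.2f}% < {t.t_diff}%: distinct species "
            f"(high-identity fraction {100 * r.high_identity_fraction:.1f}%, "
            f"divergent band {100 * r.divergent_band_fraction:.1f}%, "
            f"mean specific fraction {100 * mean_specific:.1f}%)"])
    return SpeciesCall(id_a, id_b, "ambiguous", ani, [
        f"ANI {ani:.2f}% between {t.t_diff}% and {t.t_same}%: "
        f"undecided zone"])


# ---------------------------------------------------------------------------
# all-pairs orchestration
# ---------------------------------------------------------------------------


def run_all_pairs(genomes: Iterable[GenomeSequence],
                  config: AniConfig = AniConfig(),
                  thresholds: DelimitThresholds = DelimitThresholds()
                  ) -> tuple[dict[tuple[str, str], SpeciesCall],
                             dict[tuple[str, str], ReciprocalANI]]:
    """Compute the upper-triangular pairwise ANI matrix and verdicts.

    Returns ``(calls, ani_results)``, each keyed by the unordered pair
    ``(id_a, id_b)`` in input order.
    """
    glist = list(genomes)
    if len(glist) < 2:
        raise DelimitInputError("need at least 2 genomes")
    ids = [g.id for g in glist]
    if len(set(ids)) != len(ids):
        raise DelimitInputError(f"duplicate genome ids in {ids}")
    calls: dict[tuple[str, str], SpeciesCall] = {}
    results: dict[tuple[str, str], ReciprocalANI] = {}
    for i, ga in enumerate(glist):
        for gb in glist[i + 1:]:
            r = reciprocal_ani(ga, gb, config)
            results[(ga.id, gb.id)] = r
            calls[(ga.id, gb.id)] = classify_pair(r, thresholds)
    return calls, results


def ani_matrix(calls: dict[tuple[str, str], SpeciesCall]) -> pd.DataFrame:
    """Symmetric ANI matrix as a DataFrame (diagonal = 100)."""
    ids: list[str] = []
    for a, b in calls:
        for x in (a, b):
            if x not in ids:
                ids.append(x)
    m = pd.DataFrame(np.full((len(ids), len(ids)), np.nan),
                     index=ids, columns=ids)
    for (a, b), call in calls.items():
        m.loc[a, b] = m.loc[b, a] = call.ani_mean
    np.fill_diagonal(m.values, 100.0)
    return m


def write_report(calls: dict[tuple[str, str], SpeciesCall],
                 ani_results: dict[tuple[str, str], ReciprocalANI],
                 out_dir: str | Path,
                 config: AniConfig = AniConfig(),
                 thresholds: DelimitThresholds = DelimitThresholds()) -> None:
    """Write the delimitation report set to ``out_dir``.

    Produces ``ani_matrix.tsv`` (symmetric percent matrix), ``verdicts.tsv``
    (one row per pair with the rule evidence), and one JSON per pair with the
    full histograms plus a config/threshold echo.
    """
    if not calls:
        raise DelimitInputError("no calls to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ani_matrix(calls).to_csv(out / "ani_matrix.tsv", sep="\t",
                             float_format="%.4f")
    with open(out / "verdicts.tsv", "w") as fh:
        fh.write("idA\tidB\tani_mean\tverdict\tevidence\n")
        for (a, b), call in calls.items():
            fh.write(f"{a}\t{b}\t{call.ani_mean:.4f}\t{call.verdict}\t"
                     f"{'; '.join(call.evidence)}\n")
    for (a, b), r in ani_results.items():
        write_ani_report(r, out / f"pair_{a}__{b}.json", config)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(asdict(thresholds), fh, indent=2)


def read_verdicts(path: str | Path) -> dict[tuple[str, str], SpeciesCall]:
    """Round-trip reader for ``verdicts.tsv``."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[(r.idA, r.idB)] = SpeciesCall(
            id_a=r.idA, id_b=r.idB, verdict=r.verdict,
            ani_mean=float(r.ani_mean), evidence=str(r.evidence).split("; "))
    return out
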