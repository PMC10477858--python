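"""Rule-based genome classifiers.

Viral contigs assembled from virome-enriched metagenomes are recognised by
an ensemble vote over independent lines of evidence (prediction scores,
reference hits, phage-orthologous-group content), with circularity and
high CheckV completeness as alternative routes.  The module also implements
the contamination/length pre-filters, lifestyle binning of a continuous
virulence score, and rule-based identification of the two most prevalent
gut-phage clades (crAssphages and Gubaphages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

__all__ = [
    "RecognitionEvidence",
    "ViralCall",
    "LifestyleBin",
    "LIFESTYLE_LABELS",
    "classify_viral",
    "filter_contig",
    "bin_lifestyle",
    "classify_crassphage",
    "classify_gubaphage",
]


@dataclass
class RecognitionEvidence:
    """Per-contig evidence feeding the viral recognition vote.

    Scores are in [0, 1]; identity/coverage/completeness percentages in
    [0, 100].  Absent evidence is ``None`` and simply fails the
    corresponding criterion.
    """

    contig_id: str
    length: int
    circular: bool = False
    virsorter_score: Optional[float] = None
    virfinder_score: Optional[float] = None
    pprmeta_phage_score: Optional[float] = None
    refseq_hit: Optional[Tuple[float, float]] = None  # (identity %, coverage %)
    pog_orf_hits: int = 0
    checkv_completeness: Optional[float] = None
    bacterial_hit: Optional[Tuple[float, float]] = None  # (identity %, frac of length)

    def __post_init__(self):
        if self.length is None or self.length <= 0:
            raise ValueError(f"{self.contig_id}: contig length must be positive")
        for name in ("virsorter_score", "virfinder_score", "pprmeta_phage_score"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.contig_id}: {name}={v} outside [0,1]")


@dataclass
class ViralCall:
    contig_id: str
    is_virus: bool
    criteria_met: frozenset = field(default_factory=frozenset)
    route: str = "rejected"  # circular | voting | checkv_plus_one | rejected


def _criteria_met(ev: RecognitionEvidence) -> frozenset:
    met = set()
    if ev.virsorter_score is not None and ev.virsorter_score >= 0.7:
        met.add(1)
    if ev.virfinder_score is not None and ev.virfinder_score > 0.6:
        met.add(2)
    if ev.pprmeta_phage_score is not None and ev.pprmeta_phage_score > 0.7:
        met.add(3)
    if ev.refseq_hit is not None:
        ident, cov = ev.refseq_hit
        if ident > 50.0 and cov > 90.0:
            met.add(4)
    # >=3 ORFs with phage-orthologous-group hits AND >=2 per 10 kb of length
    if ev.pog_orf_hits >= 3 and ev.pog_orf_hits / (ev.length / 10_000.0) >= 2.0:
        met.add(5)
    return frozenset(met)


def classify_viral(ev: RecognitionEvidence) -> ViralCall:
    """Ensemble vote: circular, OR >=2 of 5 criteria, OR 1 criterion + high
    CheckV completeness (>=90%).

    The five criteria (strict comparators as published): VirSorter >= 0.7,
    VirFinder > 0.6, PPR-Meta phage score > 0.7, Viral RefSeq hit with
    > 50% identity and > 90% coverage, and >= 3 ORFs with phage-orthologous-
    group hits at a rate of >= 2 per 10 kb.
    """
    met = _criteria_met(ev)
    if ev.circular:
        return ViralCall(ev.contig_id, True, met, "circular")
    if len(met) >= 2:
        return ViralCall(ev.contig_id, True, met, "voting")
    if (
        len(met) >= 1
        and ev.checkv_completeness is not None
        and ev.checkv_completeness >= 90.0
    ):
        return ViralCall(ev.contig_id, True, met, "checkv_plus_one")
    return ViralCall(ev.contig_id, False, met, "rejected")


def filter_contig(ev: RecognitionEvidence) -> Tuple[bool, Optional[str]]:
    """Contamination and length pre-filter.

    Drops contigs with a bacterial nucleotide hit of >=90% identity covering
    >=50% of their length, and fragments (linear <=5 kb; circular <=1.5 kb).
    Returns ``(keep, reason)`` with ``reason`` None when kept.
    """
    if ev.bacterial_hit is not None:
        ident, frac = ev.bacterial_hit
        if ident >= 90.0 and frac >= 0.5:
            return False, "contamination"
    if ev.circular:
        if ev.length <= 1500:
            return False, "length"
    elif ev.length <= 5000:
        return False, "length"
    return True, None


LIFESTYLE_LABELS = (
    "temperate",
    "uncertain_temperate",
    "uncertain_virulent",
    "virulent",
)

# bins over the virulence score: [0, 0.3] / (0.3, 0.5] / (0.5, 0.7] / (0.7, 1]
_LIFESTYLE_EDGES = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class LifestyleBin:
    score: float
    label: str


def bin_lifestyle(score: float) -> LifestyleBin:
    """Bin a continuous virulence score into the four lifestyle labels.

    Scores <= 0.3 are temperate and > 0.7 virulent; the two uncertain bins
    are half-open on the left, so a score of exactly 0.5 is
    uncertain-temperate.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"lifestyle score {score} outside [0,1]")
    for edge, label in zip(_LIFESTYLE_EDGES, LIFESTYLE_LABELS):
        if score <= edge:
            return LifestyleBin(score, label)
    return LifestyleBin(score, "virulent")


def classify_crassphage(
    length: int,
    blastx_best_evalue: Optional[float] = None,
    nt_identity: Optional[float] = None,
    nt_coverage_fraction: Optional[float] = None,
) -> bool:
    """crAssphage rule: > 70 kb AND (marker-protein BLASTx e-value < 1e-10,
    OR >= 95% nucleotide identity over >= 80% of the contig length against
    the prototypical crAssphage genome)."""
    if length <= 70_000:
        return False
    if blastx_best_evalue is not None and blastx_best_evalue < 1e-10:
        return True
    if (
        nt_identity is not None
        and nt_coverage_fraction is not None
        and nt_identity >= 95.0
        and nt_coverage_fraction >= 0.80
    ):
        return True
    return False


GUBAPHAGE_GENERA = ("G1.1", "G1.2", "G1.3", "G2")


def classify_gubaphage(
    terminase_hits: Sequence[Tuple[str, float]], evalue_max: float = 1e-5
) -> Optional[str]:
    """Assign a Gubaphage genus from large-terminase protein hits.

    The best (lowest e-value) qualifying hit wins; e-value ties break
    lexicographically by genus.  Returns None with no qualifying hit.
    """
    qualifying = []
    for genus, ev in terminase_hits:
        if ev <= 0:
            raise ValueError("e-values must be positive")
        if genus not in GUBAPHAGE_GENERA:
            raise ValueError(f"unknown Gubaphage genus {genus!r}")
        if ev < evalue_max:
            qualifying.append((ev, genus))
    if not qualifying:
        return None
    return min(qualifying)[1]
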