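"""Synthetic phage-bacterium community generator with planted ground truth.

Every downstream stage of the analysis (viral recognition voting,
methylation-density statistics, motif algebra, MTase clustering and
host prediction) is exercised against communities generated here, with the
truth of every planted signal recorded:

* genomes are i.i.d. nucleotide sequences at a target GC content;
* methylation sites are planted only inside occurrences of the configured
  IUPAC motifs, at the motif's methylated base, to a per-lifestyle,
  per-type target density;
* each linked phage carries two MTase proteins evolved from its true
  host's MTases at a controlled identity, while decoy bacteria carry
  copies at a lower identity — creating the high-identity gene-sharing
  regime that makes MTase-homology host prediction work;
* per-sample read counts couple presence probability to methylation
  density through a monotone logit link, so the prevalence-density partial
  correlation (controlling for sequencing depth) is recoverable;
* a rank-complete taxonomy supports LCA host-range evaluation.

Identical config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import methylome
from .classify import LIFESTYLE_LABELS, RecognitionEvidence
from .hostpred import Taxonomy
from .methylome import CDS, MethylationSite, compute_rpkm
from .motif import IupacMotif, methylated_positions

__all__ = [
    "AMINO_ACIDS",
    "CDS_CATEGORIES",
    "CommunityConfig",
    "PlantedTruth",
    "Community",
    "generate_genome",
    "plant_cds",
    "plant_methylation",
    "evolve_protein",
    "generate_host_links",
    "generate_abundance",
    "generate_taxonomy",
    "generate_recognition_evidence",
    "generate_community",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# functional CDS categories: the known-viral-function labels plus tRNA and
# the two poorly characterised classes
CDS_CATEGORIES = (
    "Assembly",
    "Immune evasion",
    "Lysis",
    "Integration",
    "Replication",
    "Regulation",
    "Packaging",
    "Infection",
    "tRNA",
    "hypothetical",
    "unsorted",
)


def _default_motifs() -> Tuple[IupacMotif, ...]:
    return (
        IupacMotif("GATC", 1, "m6A"),
        IupacMotif("GANTC", 1, "m6A"),
        IupacMotif("CCWGG", 1, "m4C"),
        IupacMotif("GCGC", 1, "m4C"),
    )


def _default_densities() -> Dict[str, Dict[str, float]]:
    # m4C density rises with virulence while m6A falls — the trend the
    # community statistics are expected to recover; absolute values sit
    # well below what the default motif set can support on a random genome.
    return {
        "temperate": {"m6A": 0.012, "m4C": 0.004},
        "uncertain_temperate": {"m6A": 0.010, "m4C": 0.006},
        "uncertain_virulent": {"m6A": 0.008, "m4C": 0.008},
        "virulent": {"m6A": 0.006, "m4C": 0.010},
    }


def _default_lifestyle_proportions() -> Dict[str, float]:
    # observed composition of a high-quality gut-phage collection
    return {
        "temperate": 0.1368,
        "uncertain_temperate": 0.5958,
        "uncertain_virulent": 0.1861,
        "virulent": 0.0811,
    }


_LIFESTYLE_SCORE_BINS = {
    "temperate": (0.0, 0.3),
    "uncertain_temperate": (0.3, 0.5),
    "uncertain_virulent": (0.5, 0.7),
    "virulent": (0.7, 1.0),
}


@dataclass
class CommunityConfig:
    """Parameters of a synthetic phage-bacterium community."""

    n_phages: int = 50
    n_bacteria: int = 50
    phage_length_range: Tuple[int, int] = (8_000, 20_000)
    gc_content: float = 0.45
    motif_set: Tuple[IupacMotif, ...] = field(default_factory=_default_motifs)
    density_by_lifestyle: Dict[str, Dict[str, float]] = field(
        default_factory=_default_densities
    )
    lifestyle_proportions: Dict[str, float] = field(
        default_factory=_default_lifestyle_proportions
    )
    mtase_share_identity: float = 0.95
    n_decoy_identity: float = 0.70
    linked_fraction: float = 0.8
    n_mtases_per_bacterium: int = 3
    mtase_length: int = 300
    n_samples: int = 50
    depth_range: Tuple[int, int] = (1_000_000, 5_000_000)
    prevalence_density_coupling: float = 0.8
    base_presence_prob: float = 0.3
    cds_per_10kb: int = 10
    n_species: int = 30
    n_genera: int = 15
    n_families: int = 8
    viral_fraction: float = 0.8
    recognition_sensitivity: float = 0.9
    seed: int = 0

    def __post_init__(self):
        for ls, dens in self.density_by_lifestyle.items():
            for t, d in dens.items():
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"density {d} for {ls}/{t} outside [0,1]")
        if not self.mtase_share_identity > self.n_decoy_identity:
            raise ValueError("mtase_share_identity must exceed n_decoy_identity")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content outside [0,1]")
        if not self.n_species >= self.n_genera >= self.n_families >= 1:
            raise ValueError("need n_species >= n_genera >= n_families >= 1")


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating a community."""

    true_host_pairs: List[Tuple[str, str]] = field(default_factory=list)
    true_lifestyles: Dict[str, str] = field(default_factory=dict)
    planted_site_positions: Dict[str, List[Tuple[int, str, str]]] = field(
        default_factory=dict
    )
    planted_motif_memberships: Dict[str, Dict[Tuple[int, str], str]] = field(
        default_factory=dict
    )
    planted_cluster_ids: Dict[str, str] = field(default_factory=dict)
    planted_densities: Dict[str, Dict[str, float]] = field(default_factory=dict)
    viral_labels: Dict[str, bool] = field(default_factory=dict)


@dataclass
class Community:
    """An in-memory synthetic community plus its planted truth."""

    config: CommunityConfig
    genomes: Dict[str, str]
    cds: Dict[str, List[CDS]]
    sites: Dict[str, List[MethylationSite]]
    lifestyle_scores: Dict[str, float]
    phage_proteins: Dict[str, Dict[str, str]]
    bacterial_proteins: Dict[str, Dict[str, str]]
    counts: np.ndarray  # genomes x samples read counts
    library_sizes: np.ndarray  # per-sample mapped reads
    rpkm: np.ndarray
    taxonomy: Taxonomy
    species_of: Dict[str, Tuple[str, str]]
    evidence: List[RecognitionEvidence]
    truth: PlantedTruth

    @property
    def phage_ids(self) -> List[str]:
        return sorted(self.genomes)


def generate_genome(length: int, gc: float, rng) -> str:
    """I.i.d. nucleotide sequence with expected G+C fraction ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0,1]")
    rng = _as_rng(rng)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def plant_cds(
    genome_length: int,
    n_cds: int,
    rng,
    categories: Sequence[str] = CDS_CATEGORIES,
    cds_length_range: Tuple[int, int] = (150, 450),
) -> List[CDS]:
    """Place non-overlapping CDS intervals with random strands/categories."""
    rng = _as_rng(rng)
    if n_cds == 0:
        return []
    lo, hi = cds_length_range
    if n_cds * lo > genome_length:
        raise ValueError(
            f"cannot pack {n_cds} CDSs of >= {lo} bp into {genome_length} bp"
        )
    for _ in range(20):
        lengths = rng.integers(lo, hi + 1, size=n_cds)
        if lengths.sum() <= genome_length:
            break
        lengths = np.full(n_cds, lo)
    free = genome_length - int(lengths.sum())
    gaps = rng.multinomial(free, [1.0 / (n_cds + 1)] * (n_cds + 1))
    out = []
    pos = 0
    cats = list(categories)
    for i in range(n_cds):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        cat = cats[i % len(cats)] if i < len(cats) else cats[int(rng.integers(len(cats)))]
        out.append(CDS(start, end, strand, cat, cds_id=f"cds{i:04d}"))
        pos = end
    return out


def plant_methylation(
    genome: str,
    motifs: Sequence[IupacMotif],
    density_targets: Mapping[str, float],
    rng,
    mean_coverage: float = 20.0,
) -> Tuple[List[MethylationSite], Dict[Tuple[int, str], str]]:
    """Plant methylation sites inside motif occurrences to target densities.

    For each modification type the candidate positions are the methylated
    bases of all occurrences (both strands) of that type's motifs; a random
    subset matching ``round(target x target-base count)`` is emitted.  When
    the motifs cannot support the requested density a warning is raised and
    all candidates are emitted.  Returns the sites and a map from
    (position, strand) to the pattern of the motif that produced it.
    """
    rng = _as_rng(rng)
    seq = genome.upper()
    sites: List[MethylationSite] = []
    memberships: Dict[Tuple[int, str], str] = {}
    for mod_type in ("m6A", "m4C"):
        target = float(density_targets.get(mod_type, 0.0))
        if target == 0.0:
            continue
        type_motifs = [m for m in motifs if m.mod_type == mod_type]
        if not type_motifs:
            raise ValueError(f"no motifs provided for requested type {mod_type}")
        candidates: Dict[Tuple[int, str], str] = {}
        for m in type_motifs:
            for key in methylated_positions(seq, m, both_strands=True):
                candidates.setdefault(key, m.pattern)
        b1, b2 = methylome._TARGET_BASES[mod_type]
        denom = seq.count(b1) + seq.count(b2)
        k = int(round(target * denom))
        keys = sorted(candidates)
        if k > len(keys):
            warnings.warn(
                f"{mod_type} density {target} unreachable "
                f"({len(keys)} motif positions, {k} requested); emitting all"
            )
            chosen = keys
        else:
            idx = rng.choice(len(keys), size=k, replace=False)
            chosen = [keys[i] for i in sorted(idx)]
        for pos, strand in chosen:
            cov = int(rng.poisson(mean_coverage)) + 1
            ipd = float(np.clip(rng.normal(4.0, 0.8), 1.5, None))
            sites.append(
                MethylationSite("", pos, strand, mod_type, cov, round(ipd, 3))
            )
            memberships[(pos, strand)] = candidates[(pos, strand)]
    return sites, memberships


def evolve_protein(parent: str, target_identity: float, rng) -> str:
    """Point-substituted copy of a protein at a controlled identity.

    Exactly ``round((1 - target) x L)`` positions are substituted with a
    different residue; no indels, so the realised identity is exact up to
    rounding.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    rng = _as_rng(rng)
    L = len(parent)
    n_sub = int(round((1.0 - target_identity) * L))
    if n_sub == 0:
        return parent
    positions = rng.choice(L, size=n_sub, replace=False)
    chars = list(parent)
    for p in positions:
        alternatives = AMINO_ACIDS.replace(chars[p], "")
        chars[p] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _random_protein(length: int, rng) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_host_links(
    config: CommunityConfig, rng, phage_ids: Sequence[str], bact_ids: Sequence[str]
) -> Tuple[Dict[str, Dict[str, str]], Dict[str, Dict[str, str]], PlantedTruth]:
    """MTase repertoires for phages and bacteria with planted host links.

    Each bacterium gets ``n_mtases_per_bacterium`` random MTase proteins.
    Linked phages carry two proteins evolved from their true host's MTases
    at ``mtase_share_identity``; for every link a different (decoy)
    bacterium additionally receives copies of the same parents evolved at
    ``n_decoy_identity``.  Parent protein ids double as planted cluster ids.
    """
    rng = _as_rng(rng)
    truth = PlantedTruth()
    bact_proteins: Dict[str, Dict[str, str]] = {}
    for b in bact_ids:
        bact_proteins[b] = {}
        for j in range(config.n_mtases_per_bacterium):
            pid = f"{b}_mtase{j}"
            bact_proteins[b][pid] = _random_protein(config.mtase_length, rng)
            truth.planted_cluster_ids[pid] = pid
    phage_proteins: Dict[str, Dict[str, str]] = {p: {} for p in phage_ids}
    n_linked = int(round(config.linked_fraction * len(phage_ids)))
    for i, p in enumerate(phage_ids[:n_linked]):
        host = bact_ids[int(rng.integers(len(bact_ids)))]
        truth.true_host_pairs.append((p, host))
        parents = sorted(bact_proteins[host])[:2]
        for j, parent_id in enumerate(parents):
            pid = f"{p}_mtase{j}"
            phage_proteins[p][pid] = evolve_protein(
                bact_proteins[host][parent_id], config.mtase_share_identity, rng
            )
            truth.planted_cluster_ids[pid] = parent_id
        if len(bact_ids) > 1:
            decoy = host
            while decoy == host:
                decoy = bact_ids[int(rng.integers(len(bact_ids)))]
            for j, parent_id in enumerate(parents):
                pid = f"{decoy}_decoy_{p}_{j}"
                bact_proteins[decoy][pid] = evolve_protein(
                    bact_proteins[host][parent_id], config.n_decoy_identity, rng
                )
                truth.planted_cluster_ids[pid] = parent_id
    return phage_proteins, bact_proteins, truth


def generate_taxonomy(
    n_species: int, n_genera: int, n_families: int, rng
) -> Tuple[Taxonomy, List[Tuple[str, str]]]:
    """Rank-complete taxonomy: every species under one genus, one family."""
    if not n_species >= n_genera >= n_families >= 1:
        raise ValueError("need n_species >= n_genera >= n_families >= 1")
    rng = _as_rng(rng)
    tax = Taxonomy()
    species_nodes = []
    # guarantee every genus/family is used, then fill the rest at random
    genus_of_species = list(range(n_genera)) + [
        int(rng.integers(n_genera)) for _ in range(n_species - n_genera)
    ]
    family_of_genus = list(range(n_families)) + [
        int(rng.integers(n_families)) for _ in range(n_genera - n_families)
    ]
    for i in range(n_species):
        g = genus_of_species[i]
        f = family_of_genus[g]
        lineage = [
            ("species", f"s{i:03d}"),
            ("genus", f"g{g:03d}"),
            ("family", f"f{f:03d}"),
        ]
        tax.add_lineage(lineage)
        species_nodes.append(lineage[0])
    return tax, species_nodes


def generate_abundance(
    config: CommunityConfig,
    rng,
    genome_lengths: Mapping[str, int],
    overall_density: Mapping[str, float],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read counts, library sizes and the derived RPKM matrix.

    Presence probability per genome follows a logit link on the
    standardised planted methylation density with slope
    ``3 x prevalence_density_coupling``; present genomes receive a count
    whose RPKM sits above the presence threshold, absent ones below it.
    The RPKM matrix is recomputed exactly from the counts.
    """
    rng = _as_rng(rng)
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    gids = sorted(genome_lengths)
    dens = np.array([overall_density[g] for g in gids], dtype=float)
    z = (dens - dens.mean()) / dens.std() if dens.std() > 0 else np.zeros_like(dens)
    p0 = config.base_presence_prob
    logit0 = np.log(p0 / (1 - p0))
    p_present = 1.0 / (1.0 + np.exp(-(logit0 + 3.0 * config.prevalence_density_coupling * z)))
    libs = rng.integers(
        config.depth_range[0], config.depth_range[1] + 1, size=config.n_samples
    )
    counts = np.zeros((len(gids), config.n_samples), dtype=np.int64)
    for i, g in enumerate(gids):
        len_kb = genome_lengths[g] / 1_000.0
        for s in range(config.n_samples):
            lib_m = libs[s] / 1_000_000.0
            if rng.random() < p_present[i]:
                rpkm = 0.6 + rng.lognormal(mean=0.5, sigma=0.8)
            else:
                rpkm = rng.uniform(0.0, 0.3)
            counts[i, s] = int(round(rpkm * len_kb * lib_m))
    rpkm_mat = np.array(
        [
            [
                compute_rpkm(counts[i, s], genome_lengths[g], int(libs[s]))
                for s in range(config.n_samples)
            ]
            for i, g in enumerate(gids)
        ]
    )
    return counts, libs, rpkm_mat


def generate_recognition_evidence(
    genome_lengths: Mapping[str, int],
    viral_fraction: float,
    rng,
    sensitivity: float = 0.9,
) -> Tuple[List[RecognitionEvidence], Dict[str, bool]]:
    """Tool-evidence rows with planted viral labels.

    Planted-viral contigs receive at least two passing criteria with
    probability ``sensitivity`` (otherwise one criterion, sometimes rescued
    by high CheckV completeness); non-viral contigs receive weak scores and
    occasionally a bacterial contamination hit.
    """
    if not 0.0 <= viral_fraction <= 1.0:
        raise ValueError("viral_fraction must be in [0,1]")
    rng = _as_rng(rng)
    evidence = []
    labels: Dict[str, bool] = {}
    for gid in sorted(genome_lengths):
        length = genome_lengths[gid]
        viral = bool(rng.random() < viral_fraction)
        labels[gid] = viral
        if viral:
            strong = rng.random() < sensitivity
            n_pass = int(rng.integers(2, 5)) if strong else 1
            passing = rng.permutation(["virsorter", "virfinder", "pprmeta", "pog"])
            chosen = list(passing[:n_pass])
            ev = RecognitionEvidence(
                gid,
                length,
                circular=bool(rng.random() < 0.1),
                virsorter_score=round(rng.uniform(0.75, 1.0), 3)
                if "virsorter" in chosen
                else round(rng.uniform(0.0, 0.6), 3),
                virfinder_score=round(rng.uniform(0.65, 1.0), 3)
                if "virfinder" in chosen
                else round(rng.uniform(0.0, 0.55), 3),
                pprmeta_phage_score=round(rng.uniform(0.75, 1.0), 3)
                if "pprmeta" in chosen
                else round(rng.uniform(0.0, 0.65), 3),
                pog_orf_hits=max(3, int(np.ceil(2 * length / 10_000))) if "pog" in chosen else 0,
                checkv_completeness=round(rng.uniform(90.0, 100.0), 1)
                if not strong
                else round(rng.uniform(50.0, 100.0), 1),
            )
        else:
            ev = RecognitionEvidence(
                gid,
                length,
                circular=False,
                virsorter_score=round(rng.uniform(0.0, 0.5), 3),
                virfinder_score=round(rng.uniform(0.0, 0.5), 3),
                pprmeta_phage_score=round(rng.uniform(0.0, 0.5), 3),
                pog_orf_hits=0,
                checkv_completeness=round(rng.uniform(0.0, 60.0), 1),
                bacterial_hit=(round(rng.uniform(90.0, 99.0), 1), 0.8)
                if rng.random() < 0.3
                else None,
            )
        evidence.append(ev)
    return evidence, labels


def generate_community(config: CommunityConfig) -> Community:
    """Generate a full synthetic community from a config (deterministic)."""
    rng = np.random.default_rng(config.seed)
    phage_ids = [f"phage{i:03d}" for i in range(config.n_phages)]
    bact_ids = [f"bact{i:03d}" for i in range(config.n_bacteria)]

    # lifestyles and virulence scores
    labels = list(config.lifestyle_proportions)
    probs = np.array([config.lifestyle_proportions[l] for l in labels], dtype=float)
    probs /= probs.sum()
    lifestyles = {p: labels[int(i)] for p, i in zip(phage_ids, rng.choice(len(labels), size=config.n_phages, p=probs))}
    scores = {}
    for p in phage_ids:
        lo, hi = _LIFESTYLE_SCORE_BINS[lifestyles[p]]
        scores[p] = round(float(rng.uniform(lo + 1e-6, hi)), 4)

    genomes: Dict[str, str] = {}
    cds: Dict[str, List[CDS]] = {}
    sites: Dict[str, List[MethylationSite]] = {}
    truth = PlantedTruth(true_lifestyles=dict(lifestyles))
    for p in phage_ids:
        length = int(rng.integers(*config.phage_length_range))
        genomes[p] = generate_genome(length, config.gc_content, rng)
        n_cds = max(1, int(round(config.cds_per_10kb * length / 10_000)))
        cds[p] = plant_cds(length, n_cds, rng)
        targets = config.density_by_lifestyle[lifestyles[p]]
        raw_sites, members = plant_methylation(
            genomes[p], config.motif_set, targets, rng
        )
        sites[p] = [dataclasses.replace(s, genome_id=p) for s in raw_sites]
        truth.planted_site_positions[p] = [
            (s.position, s.strand, s.mod_type) for s in sites[p]
        ]
        truth.planted_motif_memberships[p] = members
        realized = {
            t: methylome.methylation_density(sites[p], genomes[p], t, validate=False)
            for t in ("m6A", "m4C")
        }
        truth.planted_densities[p] = realized

    phage_prots, bact_prots, link_truth = generate_host_links(
        config, rng, phage_ids, bact_ids
    )
    truth.true_host_pairs = link_truth.true_host_pairs
    truth.planted_cluster_ids = link_truth.planted_cluster_ids

    taxonomy, species_nodes = generate_taxonomy(
        config.n_species, config.n_genera, config.n_families, rng
    )
    species_of = {
        b: species_nodes[int(rng.integers(len(species_nodes)))] for b in bact_ids
    }

    overall = {
        p: 0.5 * (truth.planted_densities[p]["m6A"] + truth.planted_densities[p]["m4C"])
        for p in phage_ids
    }
    counts, libs, rpkm = generate_abundance(
        config, rng, {p: len(genomes[p]) for p in phage_ids}, overall
    )

    evidence, viral_labels = generate_recognition_evidence(
        {p: len(genomes[p]) for p in phage_ids},
        config.viral_fraction,
        rng,
        config.recognition_sensitivity,
    )
    truth.viral_labels = viral_labels

    return Community(
        config=config,
        genomes=genomes,
        cds=cds,
        sites=sites,
        lifestyle_scores=scores,
        phage_proteins=phage_prots,
        bacterial_proteins=bact_prots,
        counts=counts,
        library_sizes=libs,
        rpkm=rpkm,
        taxonomy=taxonomy,
        species_of=species_of,
        evidence=evidence,
        truth=truth,
    )


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length sequences (no alignment)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        raise ValueError("empty sequences")
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / len(a)


def all_protein_edges(community: Community, min_identity: float = 30.0) -> List:
    """All-vs-all protein similarity edges (both directions) for clustering.

    Proteins share a common length by construction, so identity is
    positional and coverage is 100%.  Pairs below ``min_identity`` are
    omitted; self-pairs are skipped.
    """
    from .mtase import SimilarityEdge

    ids: List[str] = []
    seqs: List[str] = []
    for prots in list(community.phage_proteins.values()) + list(
        community.bacterial_proteins.values()
    ):
        for pid in sorted(prots):
            ids.append(pid)
            seqs.append(prots[pid])
    if not ids:
        return []
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(ids), -1
    )
    ident = 100.0 * (arr[:, None, :] == arr[None, :, :]).mean(axis=-1)
    edges = []
    order = np.argsort(ids)
    for a in order:
        for b in order:
            if a == b or ident[a, b] < min_identity:
                continue
            edges.append(SimilarityEdge(ids[a], ids[b], float(ident[a, b]), 100.0))
    return edges


def community_mtase_matches(
    community: Community, min_identity: float = 30.0
) -> List:
    """Exhaustive phage-MTase x bacterial-MTase similarity matches.

    All proteins in a community have equal length by construction, so
    identity is computed positionally (substitution-only evolution);
    coverage is 100%.  Pairs below ``min_identity`` are omitted, mirroring
    a similarity-search hit cutoff.
    """
    from .hostpred import MtaseMatch, simscore as _ss

    matches = []
    for p, prots in sorted(community.phage_proteins.items()):
        for pp, pseq in sorted(prots.items()):
            for b, bprots in sorted(community.bacterial_proteins.items()):
                for bp, bseq in sorted(bprots.items()):
                    ident = hamming_identity(pseq, bseq)
                    if ident >= min_identity:
                        matches.append(
                            MtaseMatch(p, pp, b, bp, _ss(ident, 100.0))
                        )
    return matches
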