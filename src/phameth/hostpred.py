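"""MTase-homology phage-host prediction.

Because phages and their bacterial hosts exchange DNA methyltransferase
genes, high protein similarity between a phage-encoded MTase and a
bacterium-encoded one is evidence of a host relationship.  The feature is
the SimScore (percent identity x query coverage / 100).  Calibration
against a gold standard uses the ROC AUC of the per-pair maximum SimScore
over random non-interacting pairs; assignment requires at least two phage
MTase proteins whose best hits agree on the same host with SimScore above a
stringent threshold.  Multi-host predictions are summarised by the
taxonomic rank of the last common ancestor of the predicted hosts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .mtase import SimilarityEdge

__all__ = [
    "RANKS",
    "Taxonomy",
    "HostAssignment",
    "simscore",
    "pair_feature",
    "negative_pairs",
    "roc_auc",
    "assign_hosts",
    "lca_host_range",
    "evaluate_precision",
]

# ranks ordered leaf -> root
RANKS = ("species", "genus", "family", "order", "class", "phylum", "domain", "root")
_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}


class Taxonomy:
    """A rank-labelled rooted tree supporting LCA queries.

    Nodes are (rank, name) handles; every node except the root has exactly
    one parent whose rank is strictly closer to the root.
    """

    def __init__(self):
        self._parent: Dict[Tuple[str, str], Tuple[str, str]] = {}
        self.root = ("root", "root")

    def add_lineage(self, lineage: Sequence[Tuple[str, str]]) -> None:
        """Register a leaf-to-root lineage, e.g.
        ``[("species", "s1"), ("genus", "g1"), ("family", "f1")]``.
        The root is appended implicitly."""
        chain = list(lineage) + [self.root]
        for child, parent in zip(chain, chain[1:]):
            if _RANK_LEVEL[child[0]] >= _RANK_LEVEL[parent[0]]:
                raise ValueError(
                    f"rank must increase toward root: {child} -> {parent}"
                )
            existing = self._parent.get(child)
            if existing is not None and existing != parent:
                raise ValueError(f"conflicting parent for {child}")
            self._parent[child] = parent

    def lineage(self, node: Tuple[str, str]) -> List[Tuple[str, str]]:
        if node != self.root and node not in self._parent:
            raise KeyError(f"node {node} not in taxonomy")
        out = [node]
        while out[-1] != self.root:
            out.append(self._parent[out[-1]])
        return out

    def ancestor_at(self, node, rank: str) -> Optional[Tuple[str, str]]:
        for anc in self.lineage(node):
            if anc[0] == rank:
                return anc
        return None

    def lca(self, nodes: Sequence[Tuple[str, str]]) -> Tuple[str, str]:
        """Last common ancestor (deepest shared node) of a set of nodes."""
        if not nodes:
            raise ValueError("need at least one node")
        common = None
        for node in nodes:
            lin = self.lineage(node)
            common = set(lin) if common is None else common & set(lin)
        # the deepest (lowest rank level) node among the shared ancestors
        return min(common, key=lambda n: _RANK_LEVEL[n[0]])


@dataclass
class HostAssignment:
    phage_id: str
    host_genome_id: str
    supporting_matches: Tuple[Tuple[str, str, float], ...]  # (phage prot, host prot, simscore)
    host_species: Optional[Tuple[str, str]] = None


def simscore(identity: float, query_coverage: float) -> float:
    """SimScore = identity x query coverage / 100 (all percent scales)."""
    if not (0.0 <= identity <= 100.0 and 0.0 <= query_coverage <= 100.0):
        raise ValueError("identity and coverage must be in [0, 100]")
    return identity * query_coverage / 100.0


@dataclass(frozen=True)
class MtaseMatch:
    """One phage-MTase -> host-MTase similarity, genome-resolved."""

    phage_id: str
    phage_protein: str
    host_id: str
    host_protein: str
    simscore: float


def pair_feature(
    phage_id: str, host_id: str, matches: Iterable[MtaseMatch]
) -> float:
    """Max SimScore over all MTase matches of a (phage, host) pair; 0 if none."""
    best = 0.0
    for m in matches:
        if m.phage_id == phage_id and m.host_id == host_id:
            best = max(best, m.simscore)
    return best


def negative_pairs(
    gold_pairs: Set[Tuple[str, str]],
    phages: Sequence[str],
    hosts: Sequence[str],
    n_per_positive: int = 1,
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """Sample random non-interacting (phage, host) pairs.

    Sampled uniformly without replacement from the complement of the gold
    pairs; reproducible per seed.
    """
    n_request = n_per_positive * len(gold_pairs)
    if n_request == 0:
        return []
    candidates = [
        (p, h)
        for p in sorted(set(phages))
        for h in sorted(set(hosts))
        if (p, h) not in gold_pairs
    ]
    if n_request > len(candidates):
        raise ValueError(
            f"requested {n_request} negatives, only {len(candidates)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_request, replace=False)
    return [candidates[i] for i in idx]


def roc_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> float:
    """ROC AUC via the Mann-Whitney statistic; ties contribute 1/2."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def assign_hosts(
    matches: Iterable[MtaseMatch],
    min_simscore: float = 90.0,
    min_agreeing_matches: int = 2,
) -> List[HostAssignment]:
    """Rule-based host assignment from MTase similarity matches.

    For every phage protein only its single best (highest-SimScore) match
    is kept (ties break on host id then host protein).  A host qualifies
    for a phage when at least ``min_agreeing_matches`` distinct phage
    proteins point to it with SimScore strictly above ``min_simscore``.
    All qualifying hosts are returned.
    """
    best: Dict[Tuple[str, str], MtaseMatch] = {}
    for m in matches:
        key = (m.phage_id, m.phage_protein)
        cur = best.get(key)
        if cur is None or (-m.simscore, m.host_id, m.host_protein) < (
            -cur.simscore,
            cur.host_id,
            cur.host_protein,
        ):
            best[key] = m
    by_pair: Dict[Tuple[str, str], List[MtaseMatch]] = {}
    for m in best.values():
        if m.simscore > min_simscore:
            by_pair.setdefault((m.phage_id, m.host_id), []).append(m)
    assignments = []
    for (phage, host), ms in sorted(by_pair.items()):
        if len({m.phage_protein for m in ms}) >= min_agreeing_matches:
            support = tuple(
                sorted((m.phage_protein, m.host_protein, m.simscore) for m in ms)
            )
            assignments.append(HostAssignment(phage, host, support))
    return assignments


def lca_host_range(
    host_species: Sequence[Tuple[str, str]], taxonomy: Taxonomy
) -> str:
    """Taxonomic rank of the host range of one phage.

    A single predicted host has species-level range; multiple hosts have
    the rank of the last common ancestor of all of them.
    """
    if not host_species:
        raise ValueError("no hosts given")
    uniq = sorted(set(host_species))
    for node in uniq:
        taxonomy.lineage(node)  # raises KeyError for unknown hosts
    if len(uniq) == 1:
        return "species"
    return taxonomy.lca(uniq)[0]


def evaluate_precision(
    assignments: Sequence[HostAssignment],
    gold_pairs: Set[Tuple[str, str]],
    species_of: Mapping[str, Tuple[str, str]],
    taxonomy: Taxonomy,
    rank: str = "species",
) -> Optional[float]:
    """Precision of host assignments against a gold standard at a rank.

    An assignment is correct when its host matches any gold host of the
    same phage at the requested rank (species: same species; genus: same
    genus ancestor).  Returns None when there are no assignments.
    """
    if rank not in ("species", "genus"):
        raise ValueError("rank must be species or genus")
    if not assignments:
        return None
    gold_by_phage: Dict[str, Set[str]] = {}
    for p, h in gold_pairs:
        gold_by_phage.setdefault(p, set()).add(h)
    n_correct = 0
    for a in assignments:
        golds = gold_by_phage.get(a.phage_id, set())
        pred_taxon = _taxon_at(a.host_genome_id, species_of, taxonomy, rank)
        gold_taxa = {_taxon_at(h, species_of, taxonomy, rank) for h in golds}
        if pred_taxon in gold_taxa:
            n_correct += 1
    return n_correct / len(assignments)


def _taxon_at(host_id, species_of, taxonomy, rank):
    sp = species_of[host_id]
    if rank == "species":
        return sp
    return taxonomy.ancestor_at(sp, rank)
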