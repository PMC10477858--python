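"""DNA-methyltransferase annotation, enrichment and protein clustering.

MTases are recognised from conserved-domain hits against a fixed whitelist
of MTase domain accessions, classified as orphan (no cognate restriction
endonuclease) or non-orphan by best hit to an annotated reference, with
enrichment of the non-orphan class tested by hypergeometric and chi-square
statistics.  Pairwise protein similarities (identity x query coverage,
"SimScore") are assembled into an undirected graph and clustered with the
Markov Cluster algorithm (alternating expansion and inflation on a
column-stochastic matrix); clusters are categorised by the origin of their
members, the gene-sharing clusters (phage + bacterial members) being the
signal of phage-bacterium MTase exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

__all__ = [
    "MTASE_DOMAIN_ACCESSIONS",
    "DomainHit",
    "SimilarityEdge",
    "ProteinCluster",
    "annotate_mtases",
    "best_reference_hits",
    "classify_orphan",
    "orphan_enrichment",
    "align_proteins",
    "build_similarity_graph",
    "mcl_cluster",
    "categorize_clusters",
]

# conserved-domain accessions whose hits define an MTase protein
MTASE_DOMAIN_ACCESSIONS = frozenset(
    {
        "cd21179",
        "COG0350",
        "KOG3191",
        "pfam05869",
        "pfam12047",
        "PRK10904",
        "PRK11524",
        "TIGR00589",
        "TIGR00675",
        "TIGR01712",
        "TIGR02987",
    }
)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_accession: str
    evalue: float

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError("e-value must be positive")


@dataclass(frozen=True)
class SimilarityEdge:
    """A directed pairwise protein similarity (query -> subject)."""

    query_id: str
    subject_id: str
    identity: float  # percent
    query_coverage: float  # percent
    evalue: float = 1e-30

    @property
    def simscore(self) -> float:
        return self.identity * self.query_coverage / 100.0

    def __post_init__(self):
        for name in ("identity", "query_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0,100]")


@dataclass
class ProteinCluster:
    cluster_id: int
    member_ids: Tuple[str, ...]
    origin_category: Optional[str] = None  # phage_only | bacteria_only | gene_sharing


def _normalize_accession(acc: str) -> str:
    acc = acc.strip()
    return acc[:-4] if acc.lower().endswith(".smp") else acc


def annotate_mtases(
    hits: Iterable[DomainHit], evalue_max: float = 1e-5
) -> Set[str]:
    """Protein ids with >=1 whitelisted MTase-domain hit at e <= evalue_max."""
    out: Set[str] = set()
    for h in hits:
        try:
            acc = _normalize_accession(h.domain_accession)
        except AttributeError:
            warnings.warn(f"skipping malformed domain hit row: {h!r}")
            continue
        if acc in MTASE_DOMAIN_ACCESSIONS and h.evalue <= evalue_max:
            out.add(h.protein_id)
    return out


def best_reference_hits(
    edges: Iterable[SimilarityEdge],
) -> Dict[str, SimilarityEdge]:
    """Best reference hit per query: lowest e-value, then highest SimScore,
    then lexicographically smallest subject id."""
    best: Dict[str, SimilarityEdge] = {}
    for e in edges:
        cur = best.get(e.query_id)
        if cur is None:
            best[e.query_id] = e
            continue
        key_new = (e.evalue, -e.simscore, e.subject_id)
        key_cur = (cur.evalue, -cur.simscore, cur.subject_id)
        if key_new < key_cur:
            best[e.query_id] = e
    return best


def classify_orphan(
    mtases: Iterable[str],
    reference_edges: Iterable[SimilarityEdge],
    orphan_flags: Mapping[str, bool],
    identity_bins: Sequence[float] = (0.0, 50.0, 90.0),
) -> Dict[float, Dict[str, float]]:
    """Proportion of MTases whose best reference homolog is non-orphan,
    stratified by identity bins (hit identity >= bin threshold).

    Returns per bin: n_with_hit, n_nonorphan, proportion.  Bins with no
    qualifying hits are omitted (no division by zero).
    """
    mtases = set(mtases)
    best = best_reference_hits(e for e in reference_edges if e.query_id in mtases)
    out: Dict[float, Dict[str, float]] = {}
    for b in identity_bins:
        hits = [e for e in best.values() if e.identity >= b]
        if not hits:
            continue
        n_nonorphan = sum(1 for e in hits if not orphan_flags[e.subject_id])
        out[b] = {
            "n_with_hit": len(hits),
            "n_nonorphan": n_nonorphan,
            "proportion": n_nonorphan / len(hits),
        }
    return out


def orphan_enrichment(k: int, n: int, K: int, N: int) -> Dict[str, float]:
    """Enrichment of a class (e.g. non-orphan) in a sample vs a population.

    ``k`` of ``n`` sampled items belong to the class; ``K`` of ``N``
    population items do.  Returns the two proportions, the one-sided
    hypergeometric upper-tail p-value P(X >= k) for drawing n items from the
    (N, K) population, and the chi-square p-value (no continuity
    correction) on the 2x2 table [[k, n-k], [K, N-K]].
    """
    if not (0 <= k <= n and 0 <= K <= N and n <= N and k <= K):
        raise ValueError("invalid counts")
    p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
    table = np.array([[k, n - k], [K, N - K]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        chi2, p_chi = 0.0, 1.0
    else:
        chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "sample_proportion": k / n if n else float("nan"),
        "population_proportion": K / N if N else float("nan"),
        "p_hypergeometric": p_hyper,
        "chi2_statistic": float(chi2),
        "p_chi2": float(p_chi),
    }


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_proteins(
    a: str, b: str, query_id: str = "query", subject_id: str = "subject"
) -> SimilarityEdge:
    """Local protein alignment (BLOSUM62, affine gaps open 11 / extend 1).

    Identity is matches over alignment columns (percent); query coverage is
    the aligned span of the query over its length (percent).  No alignment
    above score 0 yields a zero edge.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    aligner = _make_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        return SimilarityEdge(query_id, subject_id, 0.0, 0.0, evalue=1.0)
    # aligned coordinate blocks on query (target) and subject
    q_blocks, s_blocks = aln.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        seg_q, seg_s = a[qs:qe], b[ss:se]
        matches += sum(1 for x, y in zip(seg_q, seg_s) if x == y)
        columns += qe - qs
    # count gap columns between blocks as alignment columns
    for i in range(1, len(q_blocks)):
        columns += q_blocks[i][0] - q_blocks[i - 1][1]
        columns += s_blocks[i][0] - s_blocks[i - 1][1]
    if columns == 0:
        return SimilarityEdge(query_id, subject_id, 0.0, 0.0, evalue=1.0)
    identity = 100.0 * matches / columns
    span = q_blocks[-1][1] - q_blocks[0][0]
    coverage = 100.0 * span / len(a)
    return SimilarityEdge(query_id, subject_id, identity, min(coverage, 100.0))


def alignment_significant(
    a: str, b: str, n_shuffle: int = 20, z_min: float = 4.0, seed: int = 0
) -> bool:
    """Empirical significance of a local alignment vs a shuffled null.

    The alignment score of (a, b) is compared with scores of a against
    ``n_shuffle`` residue-shuffled copies of b; significant when the z-score
    exceeds ``z_min``.
    """
    rng = np.random.default_rng(seed)
    aligner = _make_aligner()
    score = aligner.score(a.upper(), b.upper())
    chars = np.array(list(b.upper()))
    null = []
    for _ in range(n_shuffle):
        rng.shuffle(chars)
        null.append(aligner.score(a.upper(), "".join(chars)))
    mu, sd = float(np.mean(null)), float(np.std(null))
    if sd == 0:
        return score > mu
    return (score - mu) / sd >= z_min


def build_similarity_graph(
    edges: Iterable[SimilarityEdge],
    min_query_coverage: float = 75.0,
    evalue_max: float = 1e-5,
) -> nx.Graph:
    """Undirected SimScore-weighted graph from directed similarity edges.

    Edges require query coverage strictly > ``min_query_coverage`` and
    e-value <= ``evalue_max``; the two directions of a pair are symmetrised
    keeping the larger SimScore, and self-edges are dropped.
    """
    g = nx.Graph()
    for e in edges:
        if e.query_id == e.subject_id:
            continue
        if e.query_coverage <= min_query_coverage or e.evalue > evalue_max:
            continue
        u, v = e.query_id, e.subject_id
        w = e.simscore
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    on_iteration=None,
) -> List[ProteinCluster]:
    """Markov clustering of a weighted undirected graph.

    Adds self-loops weighted by each node's maximum incident edge weight,
    column-normalises, then alternates expansion (matrix squaring) and
    inflation (entrywise power, column renormalisation) with pruning of
    entries below ``prune``, until the largest column change drops below
    ``tol``.  Clusters are read off the attractor rows of the limit matrix;
    nodes not reached by any attractor become singletons, so the output
    always partitions the node set.  ``on_iteration``, if given, is called
    with the column-stochastic matrix after every iteration (for inspection).
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[u], idx[v]] = w
        M[idx[v], idx[u]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        M = np.power(M, inflation)     # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if on_iteration is not None:
            on_iteration(M.copy())
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; interpreting "
                      "the current matrix")

    # attractors: rows with non-negligible diagonal mass
    eps = max(prune, 1e-9)
    attractors = np.where(np.diag(M) > eps)[0]
    # union attractor supports that overlap -> clusters
    g2 = nx.Graph()
    g2.add_nodes_from(range(n))
    for a in attractors:
        members = np.where(M[a] > eps)[0]
        for m in members:
            g2.add_edge(a, m)
    clusters = []
    for cid, comp in enumerate(
        sorted(nx.connected_components(g2), key=lambda c: sorted(c)[0])
    ):
        clusters.append(
            ProteinCluster(cid, tuple(sorted(nodes[i] for i in comp)))
        )
    return clusters


def categorize_clusters(
    clusters: Sequence[ProteinCluster],
    origin: Mapping[str, str],
    identity_edges: Optional[Iterable[SimilarityEdge]] = None,
) -> Dict[str, object]:
    """Categorise clusters by member origin and summarise gene sharing.

    ``origin`` maps protein id to "phage" or "bacteria".  Returns category
    counts (phage_only / bacteria_only / gene_sharing), the fraction of
    phage proteins inside gene-sharing clusters, and — when
    ``identity_edges`` are provided — the best-bacterial-homolog identity of
    each phage protein plus the fraction sharing > 90% identity.
    """
    counts = {"phage_only": 0, "bacteria_only": 0, "gene_sharing": 0}
    n_phage_total = 0
    n_phage_sharing = 0
    for c in clusters:
        origins = set()
        for m in c.member_ids:
            try:
                origins.add(origin[m])
            except KeyError:
                raise ValueError(f"no origin label for protein {m!r}") from None
        if origins == {"phage"}:
            cat = "phage_only"
        elif origins == {"bacteria"}:
            cat = "bacteria_only"
        else:
            cat = "gene_sharing"
        c.origin_category = cat
        counts[cat] += 1
        n_phage = sum(1 for m in c.member_ids if origin[m] == "phage")
        n_phage_total += n_phage
        if cat == "gene_sharing":
            n_phage_sharing += n_phage
    result: Dict[str, object] = {
        "counts": counts,
        "n_clusters": len(clusters),
        "frac_phage_in_gene_sharing": (
            n_phage_sharing / n_phage_total if n_phage_total else float("nan")
        ),
    }
    if identity_edges is not None:
        best: Dict[str, float] = {}
        for e in identity_edges:
            if origin.get(e.query_id) == "phage" and origin.get(e.subject_id) == "bacteria":
                best[e.query_id] = max(best.get(e.query_id, 0.0), e.identity)
        result["phage_best_bacterial_identity"] = best
        result["frac_phage_over_90_identity"] = (
            sum(1 for v in best.values() if v > 90.0) / len(best)
            if best
            else float("nan")
        )
    return result
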