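"""Format readers/writers and the end-to-end pipeline.

On-disk conventions: FASTA wrapped at 60 columns; methylation calls in a
GFF3 dialect emulating single-molecule base-modification output (source
``kinModCall``, type column ``m6A``/``m4C``, start = end, 1-based,
attributes ``coverage=`` and ``IPDRatio=``); CDS annotations in GFF3 with a
``category=`` attribute; everything else as headered TSV.  Coordinates are
1-based inclusive on disk and 0-based internally; the converters here are
the only place that translation happens.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import classify, hostpred, methylome, motif, mtase, simulate

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_methylation_gff",
    "write_methylation_gff",
    "read_cds_gff",
    "write_cds_gff",
    "write_community",
    "run_pipeline",
]

_LEGAL = set("ACGTN")


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping (upper-cased)."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _LEGAL - set(simulate.AMINO_ACIDS)
        if bad:
            raise ValueError(f"illegal characters {bad} in record {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path) -> None:
    """Write sequences as FASTA, 60 columns per line."""
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_methylation_gff(
    sites: Mapping[str, Sequence[methylome.MethylationSite]], path
) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(sites):
        for s in sorted(sites[gid], key=lambda s: (s.position, s.strand, s.mod_type)):
            pos1 = s.position + 1
            attrs = f"coverage={s.coverage};IPDRatio={s.ipd_ratio}"
            lines.append(
                f"{gid}\tkinModCall\t{s.mod_type}\t{pos1}\t{pos1}\t.\t{s.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_methylation_gff(path) -> List[methylome.MethylationSite]:
    """Parse the base-modification GFF dialect into sites (0-based)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"line {ln}: expected 9 GFF columns")
        gid, _src, mod_type, start, end, _score, strand, _frame, attrs = fields
        if mod_type not in methylome.MOD_TYPES:
            raise ValueError(f"line {ln}: unknown modification type {mod_type!r}")
        if start != end:
            raise ValueError(f"line {ln}: base modifications must have start == end")
        kv = {}
        for item in attrs.strip().split(";"):
            if not item:
                continue
            if "=" not in item:
                raise ValueError(f"line {ln}: malformed attribute {item!r}")
            k, v = item.split("=", 1)
            kv[k] = v
        try:
            coverage = int(kv["coverage"])
            ipd = float(kv["IPDRatio"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"line {ln}: bad coverage/IPDRatio attributes") from exc
        out.append(
            methylome.MethylationSite(
                gid, int(start) - 1, strand, mod_type, coverage, ipd
            )
        )
    return out


def write_cds_gff(cds: Mapping[str, Sequence[methylome.CDS]], path) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(cds):
        for c in cds[gid]:
            attrs = f"ID={c.cds_id};category={c.category}"
            lines.append(
                f"{gid}\tphameth\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cds_gff(path) -> Dict[str, List[methylome.CDS]]:
    out: Dict[str, List[methylome.CDS]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"line {ln}: expected 9 GFF columns")
        gid, _src, ftype, start, end, _score, strand, _frame, attrs = fields
        if ftype != "CDS":
            continue
        kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
        out.setdefault(gid, []).append(
            methylome.CDS(
                int(start) - 1,
                int(end),
                strand,
                kv.get("category", "hypothetical"),
                kv.get("ID", ""),
            )
        )
    return out


def _evidence_frame(evidence: Sequence[classify.RecognitionEvidence]) -> pd.DataFrame:
    rows = []
    for e in evidence:
        rows.append(
            {
                "contig_id": e.contig_id,
                "length": e.length,
                "circular": int(e.circular),
                "virsorter_score": e.virsorter_score,
                "virfinder_score": e.virfinder_score,
                "pprmeta_phage_score": e.pprmeta_phage_score,
                "refseq_identity": e.refseq_hit[0] if e.refseq_hit else None,
                "refseq_coverage": e.refseq_hit[1] if e.refseq_hit else None,
                "pog_orf_hits": e.pog_orf_hits,
                "checkv_completeness": e.checkv_completeness,
                "bacterial_identity": e.bacterial_hit[0] if e.bacterial_hit else None,
                "bacterial_fraction": e.bacterial_hit[1] if e.bacterial_hit else None,
            }
        )
    return pd.DataFrame(rows)


def read_evidence_tsv(path) -> List[classify.RecognitionEvidence]:
    df = pd.read_csv(path, sep="\t")
    out = []

    def _val(row, col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    for _, row in df.iterrows():
        refseq = None
        if not pd.isna(row["refseq_identity"]):
            refseq = (float(row["refseq_identity"]), float(row["refseq_coverage"]))
        bact = None
        if not pd.isna(row["bacterial_identity"]):
            bact = (float(row["bacterial_identity"]), float(row["bacterial_fraction"]))
        out.append(
            classify.RecognitionEvidence(
                str(row["contig_id"]),
                int(row["length"]),
                bool(row["circular"]),
                _val(row, "virsorter_score"),
                _val(row, "virfinder_score"),
                _val(row, "pprmeta_phage_score"),
                refseq,
                int(row["pog_orf_hits"]),
                _val(row, "checkv_completeness"),
                bact,
            )
        )
    return out


def write_community(community: simulate.Community, out_dir) -> None:
    """Write every artifact of a synthetic community (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(community.genomes, out / "genomes.fasta")
    write_methylation_gff(community.sites, out / "methylation.gff3")
    write_cds_gff(community.cds, out / "cds.gff3")
    phage_faa = {
        pid: seq
        for g, prots in sorted(community.phage_proteins.items())
        for pid, seq in sorted(prots.items())
    }
    bact_faa = {
        pid: seq
        for g, prots in sorted(community.bacterial_proteins.items())
        for pid, seq in sorted(prots.items())
    }
    write_fasta(phage_faa, out / "proteins_phage.faa")
    write_fasta(bact_faa, out / "proteins_bact.faa")
    gids = sorted(community.genomes)
    counts = pd.DataFrame(
        community.counts,
        index=pd.Index(gids, name="genome_id"),
        columns=[f"sample{s:03d}" for s in range(community.config.n_samples)],
    )
    counts.to_csv(out / "abundance_counts.tsv", sep="\t")
    libs = pd.DataFrame(
        {
            "sample": [f"sample{s:03d}" for s in range(community.config.n_samples)],
            "mapped_reads": community.library_sizes,
        }
    )
    libs.to_csv(out / "library_sizes.tsv", sep="\t", index=False)
    tax_rows = []
    for b in sorted(community.species_of):
        sp = community.species_of[b]
        lineage = community.taxonomy.lineage(sp)
        row = {"genome_id": b}
        row.update({rank: name for rank, name in lineage if rank != "root"})
        tax_rows.append(row)
    pd.DataFrame(tax_rows).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    pd.DataFrame(
        community.truth.true_host_pairs, columns=["phage_id", "host_id"]
    ).to_csv(out / "gold_pairs.tsv", sep="\t", index=False)
    _evidence_frame(community.evidence).to_csv(out / "evidence.tsv", sep="\t", index=False)
    scores = pd.DataFrame(
        {
            "genome_id": gids,
            "lifestyle_score": [community.lifestyle_scores[g] for g in gids],
        }
    )
    scores.to_csv(out / "lifestyle_scores.tsv", sep="\t", index=False)
    truth = community.truth
    truth_json = {
        "true_host_pairs": truth.true_host_pairs,
        "true_lifestyles": truth.true_lifestyles,
        "planted_densities": truth.planted_densities,
        "viral_labels": truth.viral_labels,
        "planted_site_counts": {
            g: len(v) for g, v in truth.planted_site_positions.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))


def _config_hash(config: simulate.CommunityConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: simulate.CommunityConfig,
    out_dir=None,
    stages: Sequence[str] = (
        "recognition",
        "methylome",
        "motifs",
        "mtase",
        "host_prediction",
    ),
) -> Dict:
    """Run the full analysis on a freshly generated synthetic community.

    Stages run in dependency order on the community defined by ``config``;
    the returned report (also written as ``report.json`` under ``out_dir``)
    contains per-stage summary tables and provenance.  Deterministic:
    identical config + seed reproduce a byte-identical report.
    """
    community = simulate.generate_community(config)
    report: Dict = {
        "provenance": {"seed": config.seed, "config_hash": _config_hash(config)}
    }

    if "recognition" in stages:
        calls = [classify.classify_viral(e) for e in community.evidence]
        by_route: Dict[str, int] = {}
        for c in calls:
            by_route[c.route] = by_route.get(c.route, 0) + 1
        labels = community.truth.viral_labels
        tp = sum(1 for c in calls if c.is_virus and labels[c.contig_id])
        fn = sum(1 for c in calls if not c.is_virus and labels[c.contig_id])
        tn = sum(1 for c in calls if not c.is_virus and not labels[c.contig_id])
        fp = sum(1 for c in calls if c.is_virus and not labels[c.contig_id])
        lifestyle_counts: Dict[str, int] = {}
        for g, s in community.lifestyle_scores.items():
            lab = classify.bin_lifestyle(s).label
            lifestyle_counts[lab] = lifestyle_counts.get(lab, 0) + 1
        report["recognition"] = {
            "n_contigs": len(calls),
            "calls_by_route": by_route,
            "recall": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "lifestyle_counts": lifestyle_counts,
        }

    if "methylome" in stages:
        densities = {}
        for g in sorted(community.genomes):
            seq = community.genomes[g]
            split = methylome.region_split(community.sites[g], community.cds[g], seq)
            densities[g] = {
                "m6A": methylome.methylation_density(community.sites[g], seq, "m6A"),
                "m4C": methylome.methylation_density(community.sites[g], seq, "m4C"),
                "coding": split["coding"],
                "noncoding": split["noncoding"],
            }
        prev = methylome.prevalence(community.rpkm, threshold=0.5)
        depth = np.array(
            [
                sum(s.coverage for s in community.sites[g])
                for g in sorted(community.genomes)
            ],
            dtype=float,
        )
        overall = np.array(
            [
                0.5 * (densities[g]["m6A"] + densities[g]["m4C"])
                for g in sorted(community.genomes)
            ]
        )
        r, t, p = methylome.partial_pearson(prev.astype(float), overall, depth)
        frac_methylated = np.mean(
            [
                1.0 if (densities[g]["m6A"] > 0 or densities[g]["m4C"] > 0) else 0.0
                for g in densities
            ]
        )
        report["methylome"] = {
            "mean_density_m6A": float(np.mean([d["m6A"] for d in densities.values()])),
            "mean_density_m4C": float(np.mean([d["m4C"] for d in densities.values()])),
            "frac_genomes_methylated": float(frac_methylated),
            "partial_correlation": {"r": r, "statistic": t, "p": p},
        }

    if "motifs" in stages:
        motifs = list(config.motif_set)
        hits = {
            m: [
                g
                for g in sorted(community.genomes)
                if motif.scan(community.genomes[g], m.pattern, both_strands=True)
            ]
            for m in motifs
        }
        supported = motif.support_filter(hits, min_genomes=min(len(community.genomes), 100))
        derep = motif.dereplicate(supported)
        n4, n6, shared, total = motif.type_union_accounting(
            [m for m in derep if m.mod_type == "m4C"],
            [m for m in derep if m.mod_type == "m6A"],
        )
        report["motifs"] = {
            "n_supported": len(supported),
            "n_after_dereplication": len(derep),
            "n_m4C": n4,
            "n_m6A": n6,
            "n_shared": shared,
            "n_total": total,
        }

    matches = None
    if "mtase" in stages or "host_prediction" in stages:
        matches = simulate.community_mtase_matches(community)

    if "mtase" in stages:
        origin = {}
        for g, prots in community.phage_proteins.items():
            for pid in prots:
                origin[pid] = "phage"
        for g, prots in community.bacterial_proteins.items():
            for pid in prots:
                origin[pid] = "bacteria"
        edges = simulate.all_protein_edges(community)
        graph = mtase.build_similarity_graph(edges)
        # isolated proteins become singleton clusters
        graph.add_nodes_from(origin)
        clusters = mtase.mcl_cluster(graph)
        summary = mtase.categorize_clusters(clusters, origin, identity_edges=edges)
        report["mtase"] = {
            "n_proteins": len(origin),
            "n_clusters": summary["n_clusters"],
            "cluster_categories": summary["counts"],
            "frac_phage_in_gene_sharing": summary["frac_phage_in_gene_sharing"],
            "frac_phage_over_90_identity": summary["frac_phage_over_90_identity"],
        }

    if "host_prediction" in stages:
        gold = set(community.truth.true_host_pairs)
        assignments = hostpred.assign_hosts(matches)
        species_of = community.species_of
        precision_sp = hostpred.evaluate_precision(
            assignments, gold, species_of, community.taxonomy, rank="species"
        )
        precision_gen = hostpred.evaluate_precision(
            assignments, gold, species_of, community.taxonomy, rank="genus"
        )
        assigned_pairs = {(a.phage_id, a.host_genome_id) for a in assignments}
        recall = (
            sum(1 for pair in gold if pair in assigned_pairs) / len(gold)
            if gold
            else None
        )
        auc = None
        if gold:
            negatives = hostpred.negative_pairs(
                gold,
                sorted(community.phage_proteins),
                sorted(community.bacterial_proteins),
                n_per_positive=1,
                seed=config.seed,
            )
            pos_scores = [hostpred.pair_feature(p, h, matches) for p, h in sorted(gold)]
            neg_scores = [hostpred.pair_feature(p, h, matches) for p, h in negatives]
            auc = hostpred.roc_auc(pos_scores, neg_scores)
        by_phage: Dict[str, List] = {}
        for a in assignments:
            by_phage.setdefault(a.phage_id, []).append(species_of[a.host_genome_id])
        ranges = {
            p: hostpred.lca_host_range(hosts, community.taxonomy)
            for p, hosts in by_phage.items()
        }
        rank_counts: Dict[str, int] = {}
        for r_ in ranges.values():
            rank_counts[r_] = rank_counts.get(r_, 0) + 1
        report["host_prediction"] = {
            "n_assignments": len(assignments),
            "n_phages_assigned": len(by_phage),
            "precision_species": precision_sp,
            "precision_genus": precision_gen,
            "recall_of_planted_pairs": recall,
            "auc": auc,
            "host_range_rank_counts": rank_counts,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_community(community, out / "community")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
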