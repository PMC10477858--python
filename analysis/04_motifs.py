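"""Motif dereplication, genome-support filtering and reference overlap.

Scans every community genome for the configured motif set plus two
deliberately redundant specific variants, applies the genome-support
filter, dereplicates to a non-redundant set (the redundant variants must
collapse into their covering motifs), compares against a small
REBASE-style reference list with the relaxed subsumption criterion, and
reports the m4C/m6A union accounting.
"""

import json
from pathlib import Path

import pandas as pd

from phameth import io, motif
from phameth.motif import IupacMotif

RESULTS = Path(__file__).resolve().parent.parent / "results"

# redundant, more specific variants of the default community motifs:
# each is a possibility of one of the planted motifs and must be removed
REDUNDANT = (
    IupacMotif("AGATCT", 2, "m6A"),   # contains GATC
    IupacMotif("CCAGG", 1, "m4C"),    # a possibility of CCWGG
)

REFERENCE = ("GATC", "GANTC", "CCWGG", "RGCGCY")


def main() -> None:
    genomes = io.read_fasta(RESULTS / "community" / "genomes.fasta")
    candidates = [
        IupacMotif("GATC", 1, "m6A"),
        IupacMotif("GANTC", 1, "m6A"),
        IupacMotif("CCWGG", 1, "m4C"),
        IupacMotif("GCGC", 1, "m4C"),
        *REDUNDANT,
    ]
    hits = {
        m: [g for g in genomes if motif.scan(genomes[g], m.pattern, both_strands=True)]
        for m in candidates
    }
    supported = motif.support_filter(hits, min_genomes=min(len(genomes), 100))
    derep = motif.dereplicate(supported)
    n_overlap, matches = motif.reference_overlap(
        [m.pattern for m in derep], REFERENCE
    )
    n4, n6, shared, total = motif.type_union_accounting(
        [m for m in derep if m.mod_type == "m4C"],
        [m for m in derep if m.mod_type == "m6A"],
    )
    rows = [
        {
            "pattern": m.pattern,
            "methylated_index": m.methylated_index,
            "mod_type": m.mod_type,
            "support": len(set(hits[m])),
            "reference_overlaps": ";".join(matches[m.pattern]),
        }
        for m in derep
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "motifs.tsv", sep="\t", index=False)
    report = {
        "n_candidates": len(candidates),
        "n_supported": len(supported),
        "n_after_dereplication": len(derep),
        "n_overlapping_reference": n_overlap,
        "n_m4C": n4,
        "n_m6A": n6,
        "n_shared": shared,
        "n_total": total,
    }
    (RESULTS / "motif_report.json").write_text(json.dumps(report, indent=2))
    print(
        f"{len(candidates)} candidate motifs -> {len(supported)} supported -> "
        f"{len(derep)} after dereplication; {n_overlap} overlap the reference"
    )
    print(f"union accounting: {n4} m4C + {n6} m6A - {shared} shared = {total}")


if __name__ == "__main__":
    main()
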