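"""Viral recognition voting and lifestyle binning on the community.

Reads the evidence table written by 01_simulate.py, applies the
contamination/length filter and the ensemble vote, compares calls against
the planted viral labels, and bins the virulence scores into lifestyles.
"""

import json
from pathlib import Path

import pandas as pd

from phameth import classify, io

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    evidence = io.read_evidence_tsv(RESULTS / "community" / "evidence.tsv")
    truth = json.loads((RESULTS / "community" / "truth.json").read_text())
    labels = truth["viral_labels"]

    rows = []
    for ev in evidence:
        keep, reason = classify.filter_contig(ev)
        call = classify.classify_viral(ev)
        rows.append(
            {
                "contig_id": ev.contig_id,
                "kept": int(keep),
                "drop_reason": reason or "",
                "is_virus": int(call.is_virus),
                "route": call.route,
                "criteria_met": ",".join(map(str, sorted(call.criteria_met))),
                "planted_viral": int(labels[ev.contig_id]),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "viral_calls.tsv", sep="\t", index=False)

    tp = ((df.is_virus == 1) & (df.planted_viral == 1)).sum()
    fn = ((df.is_virus == 0) & (df.planted_viral == 1)).sum()
    tn = ((df.is_virus == 0) & (df.planted_viral == 0)).sum()
    fp = ((df.is_virus == 1) & (df.planted_viral == 0)).sum()
    print(f"voting recall {tp / (tp + fn):.3f}, specificity {tn / (tn + fp):.3f}")
    print(df.route.value_counts().to_string())

    scores = pd.read_csv(RESULTS / "community" / "lifestyle_scores.tsv", sep="\t")
    scores["lifestyle"] = [
        classify.bin_lifestyle(s).label for s in scores.lifestyle_score
    ]
    scores.to_csv(RESULTS / "lifestyles.tsv", sep="\t", index=False)
    print(scores.lifestyle.value_counts().to_string())


if __name__ == "__main__":
    main()
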