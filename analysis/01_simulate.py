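"""Generate the default synthetic phage-bacterium community.

Writes every community artifact (genomes, methylation calls, CDS
annotations, proteins, abundances, taxonomy, gold host pairs, recognition
evidence, planted truth) under results/community/ for the downstream
drivers to consume.
"""

import sys
from pathlib import Path

from phameth import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    cfg = simulate.CommunityConfig(seed=seed)
    community = simulate.generate_community(cfg)
    io.write_community(community, OUT / "community")
    n_sites = sum(len(v) for v in community.sites.values())
    print(
        f"community: {cfg.n_phages} phages, {cfg.n_bacteria} bacteria, "
        f"{cfg.n_samples} samples, seed {seed}"
    )
    print(f"planted methylation sites: {n_sites}")
    print(f"planted host links: {len(community.truth.true_host_pairs)}")
    print(f"artifacts written to {OUT / 'community'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
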