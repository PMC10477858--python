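# phameth

Community-scale analysis of DNA methylation in phage genomes.

Gut bacteria defend themselves against phages with restriction–modification
systems: a restriction endonuclease cleaves unmethylated foreign DNA at a
specific sequence motif, while a cognate DNA methyltransferase (MTase)
protects the bacterium's own genome. Phages counter by methylating their
genomes — often with MTase genes acquired from their hosts. `phameth`
implements the computational machinery needed to study this at the
community scale from single-molecule base-modification calls:

* **Viral contig recognition** — an ensemble vote over prediction scores,
  reference hits and phage-orthologous-group content, with circularity and
  high CheckV completeness as alternative routes, plus contamination and
  length filters, lifestyle binning, and rule-based crAssphage/Gubaphage
  identification (`phameth.classify`).
* **Methylation-density statistics** — for each modification type
  (m6A, m4C) the density is the number of distinct methylated target bases
  over the number of target bases on both strands (m6A: #A + #T on the
  forward strand). Densities are computed genome-wide, split by
  coding/non-coding regions, per CDS and per functional gene category;
  prevalence is derived from RPKM abundance at a presence threshold
  (RPKM ≥ 0.5), and its association with methylation density is tested by
  partial Pearson correlation controlling for sequencing depth,
  r = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) (`phameth.methylome`).
* **Degenerate-motif algebra** — IUPAC motifs overlap when some window of
  the more specific pattern is position-wise contained in the more
  degenerate one (AKCTCG is one of the possibilities of BCNC); the module
  implements this subsumption test, fixed-point dereplication, genome
  scanning, genome-support filtering and m4C/m6A union accounting
  (`phameth.motif`).
* **MTase annotation and clustering** — MTases from conserved-domain hits
  against an 11-accession whitelist (e ≤ 1e-5), orphan/non-orphan
  classification with hypergeometric and chi-square enrichment, pairwise
  protein similarity (SimScore = identity × query coverage / 100), and
  Markov clustering (MCL: alternating expansion and inflation on a
  column-stochastic matrix) into protein clusters categorised as
  phage-only, bacteria-only or gene-sharing (`phameth.mtase`).
* **Phage–host prediction** — hosts are assigned when at least two phage
  MTase proteins have their best hit on the same bacterium with
  SimScore > 90; calibrated by ROC AUC against random non-interacting
  pairs and evaluated at species/genus rank with LCA host ranges
  (`phameth.hostpred`).
* **Synthetic community generator** — genomes with planted motif-consistent
  methylation at per-lifestyle target densities, MTase repertoires with
  planted host links at controlled protein identity, abundance tables
  whose presence probability couples to methylation density, and a
  rank-complete taxonomy — all with recorded ground truth
  (`phameth.simulate`).

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
community of 50 phages, 50 bacteria and 50 samples (seed 1) and write
their tables under `results/`:

```bash
python analysis/01_simulate.py 1
python analysis/02_recognition.py
python analysis/03_methylome.py
python analysis/06_host_prediction.py
```

prints, among other things:

```
voting recall 1.000, specificity 1.000
mean density by lifestyle:
                     density_m6A  density_m4C
temperate               0.012009     0.004031
uncertain_temperate     0.010000     0.006002
uncertain_virulent      0.007992     0.007999
virulent                0.005990     0.009975
partial correlation (prevalence ~ density | depth): r=0.939, p=2.11e-23
SimScore AUC (gold vs random pairs): 1.000
40 assignments; precision species=1.000, genus=1.000; recall of planted pairs=1.000
```

Reading the output: the recognition vote recovers every planted viral
label; the realised methylation densities reproduce the configured
per-lifestyle targets (m4C rising and m6A falling with virulence); the
prevalence–density partial correlation is strongly positive once
sequencing depth is controlled for; and with MTases planted at 95%
identity to the true host against 70% decoys, the two-agreeing-matches
rule recovers all 40 planted host links without false positives.

The same analysis is available as a library call
(`phameth.io.run_pipeline(CommunityConfig(seed=1))`) or through the CLI
(`phameth run-all --seed 1 --out-dir out/`).

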