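"""Methylation-density statistics and prevalence/partial-correlation analysis.

A methylation *site* is one called modified base (m6A or m4C) on one strand
of one genome.  Density of a modification type is the number of distinct
methylated target bases divided by the number of target bases available on
both strands — for m6A the forward-strand A count plus the forward-strand T
count (each forward T is a reverse-strand A).  Densities are computed
genome-wide, split by coding/non-coding regions, per CDS, and per
functional gene category.  Prevalence across samples is derived from RPKM
abundance with a presence threshold, and its association with methylation
density is assessed by partial Pearson correlation controlling for
sequencing depth (the residual-regression formulation).

Internal coordinates are 0-based; GFF conversion lives in :mod:`phameth.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "MethylationSite",
    "CDS",
    "MOD_TYPES",
    "methylation_density",
    "region_split",
    "cds_summary",
    "functional_rates",
    "compute_rpkm",
    "prevalence",
    "partial_pearson",
    "residualize",
    "rarefaction",
]

MOD_TYPES = ("m6A", "m4C")

# forward-strand bases that count as targets on either strand
_TARGET_BASES = {"m6A": ("A", "T"), "m4C": ("C", "G")}
# base required at the called position: forward strand / reverse strand
_SITE_BASE = {("m6A", "+"): "A", ("m6A", "-"): "T",
              ("m4C", "+"): "C", ("m4C", "-"): "G"}


@dataclass(frozen=True)
class MethylationSite:
    """One called modified base.

    ``position`` is the 0-based index on forward coordinates; a site on the
    ``-`` strand at position *p* modifies the base pairing with the forward
    base at *p* (so an m6A site on ``-`` sits on a forward T).
    """

    genome_id: str
    position: int
    strand: str
    mod_type: str
    coverage: int = 0
    ipd_ratio: float = 0.0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"mod_type must be one of {MOD_TYPES}")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class CDS:
    """A coding interval, 0-based half-open, with strand and category."""

    start: int
    end: int
    strand: str = "+"
    category: str = "hypothetical"
    cds_id: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad CDS interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _check_site(site: MethylationSite, sequence: str) -> None:
    if site.position >= len(sequence):
        raise ValueError(f"site position {site.position} beyond genome end")
    expected = _SITE_BASE[(site.mod_type, site.strand)]
    if sequence[site.position].upper() != expected:
        raise ValueError(
            f"site at {site.position}{site.strand} ({site.mod_type}) expects "
            f"forward base {expected}, found {sequence[site.position]!r}"
        )


def _dedupe(sites: Iterable[MethylationSite], mod_type: str):
    """Distinct (position, strand) keys of one type (merging samples)."""
    return {(s.position, s.strand) for s in sites if s.mod_type == mod_type}


def methylation_density(
    sites: Iterable[MethylationSite],
    sequence: str,
    mod_type: str,
    region_mask: Optional[np.ndarray] = None,
    validate: bool = True,
) -> float:
    """Fraction of target bases of a modification type that are methylated.

    Numerator: distinct methylated (position, strand) pairs of the type,
    restricted to positions where ``region_mask`` is True.  Denominator:
    target bases on both strands in the same region (m6A: forward A + T;
    m4C: forward C + G).  Returns 0 with a warning for an empty denominator.
    """
    if mod_type not in MOD_TYPES:
        raise ValueError(f"mod_type must be one of {MOD_TYPES}")
    seq = sequence.upper()
    sites = list(sites)
    if validate:
        for s in sites:
            if s.mod_type == mod_type:
                _check_site(s, seq)
    if region_mask is None:
        region_mask = np.ones(len(seq), dtype=bool)
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != (len(seq),):
            raise ValueError("region_mask length must equal genome length")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    b1, b2 = _TARGET_BASES[mod_type]
    denom = int(np.sum(region_mask & ((arr == b1.encode()) | (arr == b2.encode()))))
    if denom == 0:
        warnings.warn(f"no {mod_type} target bases in region; density set to 0")
        return 0.0
    numer = sum(1 for pos, _ in _dedupe(sites, mod_type) if region_mask[pos])
    return numer / denom


def coding_mask(cds_list: Sequence[CDS], genome_length: int) -> np.ndarray:
    """Boolean mask marking positions inside the union of CDS intervals."""
    mask = np.zeros(genome_length, dtype=bool)
    for c in cds_list:
        if c.end > genome_length:
            raise ValueError(f"CDS [{c.start},{c.end}) outside genome")
        mask[c.start : c.end] = True
    return mask


def region_split(
    sites: Iterable[MethylationSite],
    cds_list: Sequence[CDS],
    sequence: str,
) -> Dict[str, Dict[str, float]]:
    """Coding vs non-coding densities per modification type.

    A position is coding when inside any CDS interval (union).  The
    genome-wide density equals the target-base-weighted mean of the two
    regional densities by construction.
    """
    sites = list(sites)
    mask = coding_mask(cds_list, len(sequence))
    out = {"coding": {}, "noncoding": {}}
    for t in MOD_TYPES:
        out["coding"][t] = methylation_density(sites, sequence, t, mask)
        out["noncoding"][t] = methylation_density(sites, sequence, t, ~mask)
    return out


def cds_summary(
    sites: Iterable[MethylationSite],
    cds_list: Sequence[CDS],
    per_genome_length: Optional[int] = None,
) -> Dict[str, Dict]:
    """Per-CDS methylation summaries per modification type.

    Returns, for each type, the fraction of CDSs carrying at least one site
    and the per-CDS ratio of modified bases to CDS length.  With
    ``per_genome_length`` the ratio denominator is the whole genome length
    instead (the literal reading of a modified-bases-per-genome-length
    figure); the default is per-CDS length.
    """
    if not cds_list:
        raise ValueError("at least one CDS required")
    sites = list(sites)
    out = {}
    for t in MOD_TYPES:
        keys = _dedupe(sites, t)
        ratios = []
        n_methylated = 0
        for c in cds_list:
            n_in = sum(1 for (pos, strand) in keys if c.start <= pos < c.end)
            if n_in:
                n_methylated += 1
            denom = per_genome_length if per_genome_length else len(c)
            ratios.append(n_in / denom)
        out[t] = {
            "frac_methylated_cds": n_methylated / len(cds_list),
            "per_cds_ratio": ratios,
        }
    return out


def functional_rates(
    genomes: Mapping[str, Tuple[Sequence[CDS], Iterable[MethylationSite]]],
) -> Dict[str, Dict[str, float]]:
    """Per category x type: fraction of genomes with >=1 methylated gene.

    ``genomes`` maps genome id to its (CDS list, site list).  For each
    functional category the fraction is computed only over genomes that
    possess at least one gene of that category; categories absent from all
    genomes do not appear in the output.
    """
    possessing: Dict[str, int] = {}
    methylated: Dict[Tuple[str, str], int] = {}
    for gid, (cds_list, sites) in genomes.items():
        sites = list(sites)
        cats = {c.category for c in cds_list}
        for cat in cats:
            possessing[cat] = possessing.get(cat, 0) + 1
        for t in MOD_TYPES:
            keys = _dedupe(sites, t)
            hit_cats = {
                c.category
                for c in cds_list
                if any(c.start <= pos < c.end for pos, _ in keys)
            }
            for cat in hit_cats:
                methylated[(cat, t)] = methylated.get((cat, t), 0) + 1
    return {
        cat: {t: methylated.get((cat, t), 0) / n for t in MOD_TYPES}
        for cat, n in possessing.items()
    }


def compute_rpkm(count: float, genome_length: int, library_mapped_reads: int) -> float:
    """Reads per kilobase of genome per million mapped reads."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if library_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return count / ((genome_length / 1_000.0) * (library_mapped_reads / 1_000_000.0))


def prevalence(rpkm: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-genome number of samples with RPKM >= threshold.

    ``rpkm`` is a genomes x samples matrix; a value exactly at the threshold
    counts as present.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rpkm = np.asarray(rpkm, dtype=float)
    return (rpkm >= threshold).sum(axis=-1)


def residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of ordinary least squares of ``v`` on ``z`` with intercept.

    With a constant ``z`` this reduces to mean-centering.  Residuals are
    mean-zero and orthogonal to ``z``.
    """
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    if v.shape != z.shape or v.ndim != 1:
        raise ValueError("v and z must be equal-length 1-d arrays")
    if len(v) < 3:
        raise ValueError("need n >= 3")
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_pearson(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> Tuple[float, float, float]:
    """First-order partial Pearson correlation of x and y given z.

    r = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the two-sided
    p-value uses t = r sqrt((n-3)/(1-r^2)) on n-3 degrees of freedom.
    Equals the Pearson correlation of the OLS residuals of x and y on z.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("x and y must be non-constant")

    def _r(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        return float(np.sum(a * b) / denom) if denom > 0 else 0.0

    if np.std(z) == 0:
        r_xz = r_yz = 0.0
    else:
        r_xz, r_yz = _r(x, z), _r(y, z)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("a variable is collinear with the control; r undefined")
    r_xy = _r(x, y)
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(t), float(p)


def rarefaction(
    site_records: Sequence[Tuple[str, Tuple]],
    depth_fractions: Sequence[float],
    reps: int = 50,
    seed: int = 0,
) -> Dict[float, float]:
    """Mean number of unique sites recovered at subsampled observation depth.

    ``site_records`` are (sample, site-key) observations, one per called
    site per sample; site keys repeat across samples.  For each fraction f
    the records are subsampled without replacement to round(f * N) and the
    unique site keys counted, averaged over ``reps`` draws.  Fraction 1.0
    returns the exact total unique count.
    """
    records = list(site_records)
    n = len(records)
    rng = np.random.default_rng(seed)
    out: Dict[float, float] = {}
    total_unique = len({key for _, key in records})
    for f in depth_fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must be in (0, 1]")
        if f == 1.0 or n == 0:
            out[f] = float(total_unique)
            continue
        k = int(round(f * n))
        counts = []
        for _ in range(reps):
            idx = rng.choice(n, size=k, replace=False)
            counts.append(len({records[i][1] for i in idx}))
        out[f] = float(np.mean(counts))
    return out
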