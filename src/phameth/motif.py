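"""IUPAC degenerate-motif algebra.

Methylation motifs called from single-molecule sequencing data are reported
as IUPAC degenerate nucleotide strings (e.g. ``GATC``, ``BCNC``) together
with the index of the methylated base.  Motif lists produced per genome are
highly redundant: a specific motif such as ``AKCTCG`` is *one of the
possibilities* of a more degenerate motif such as ``BCNC`` (the window
``KCTC`` is position-wise contained in ``BCNC``).  This module implements
the subsumption test behind that notion of overlap, fixed-point
dereplication, genome scanning, genome-support filtering, comparison against
a reference motif collection, and the m4C/m6A union accounting used to count
non-redundant motifs across modification types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

__all__ = [
    "IUPAC_SETS",
    "IupacMotif",
    "iupac_set",
    "revcomp_pattern",
    "expand_motif",
    "motif_overlapped",
    "dereplicate",
    "scan",
    "methylated_positions",
    "support_filter",
    "reference_overlap",
    "type_union_accounting",
]

IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# complement of each degenerate symbol (complement of the underlying set)
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_set(symbol: str) -> frozenset:
    """Return the set of literal bases a degenerate symbol stands for."""
    try:
        return IUPAC_SETS[symbol.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol: {symbol!r}") from None


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of a degenerate pattern."""
    return "".join(_COMPLEMENT[s] for s in reversed(pattern.upper()))


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate methylation motif.

    Parameters
    ----------
    pattern :
        IUPAC string, e.g. ``"GATC"`` or ``"BCNC"``.
    methylated_index :
        0-based index of the methylated base within the pattern.
    mod_type :
        ``"m6A"`` (the methylated base is an A) or ``"m4C"`` (a C).
    """

    pattern: str
    methylated_index: int
    mod_type: str

    def __post_init__(self):
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise ValueError("empty motif pattern")
        for s in pat:
            if s not in IUPAC_SETS:
                raise ValueError(f"unknown IUPAC symbol {s!r} in {pat!r}")
        if not 0 <= self.methylated_index < len(pat):
            raise ValueError("methylated_index outside pattern")
        if self.mod_type not in ("m6A", "m4C"):
            raise ValueError(f"mod_type must be m6A or m4C, got {self.mod_type!r}")
        base = "A" if self.mod_type == "m6A" else "C"
        if base not in IUPAC_SETS[pat[self.methylated_index]]:
            raise ValueError(
                f"symbol at methylated_index must allow {base} for {self.mod_type}"
            )

    def __len__(self) -> int:
        return len(self.pattern)


def _pattern(m) -> str:
    return m.pattern if isinstance(m, IupacMotif) else str(m).upper()


def _window_subsumed(window: str, short: str) -> bool:
    # every position of the window is one of the possibilities of `short`
    return all(iupac_set(a) <= iupac_set(b) for a, b in zip(window, short))


def motif_overlapped(candidate, reference, check_revcomp: bool = False) -> bool:
    """Test whether two motifs overlap in the relaxed, subsumption sense.

    Let ``L`` be the longer and ``S`` the shorter of the two patterns.  The
    motifs overlap iff some length-``|S|`` window of ``L`` is position-wise
    subsumed by ``S`` (each IUPAC set of the window is a subset of the
    corresponding set of ``S``).  ``AKCTCG`` overlaps ``BCNC`` via the
    window ``KCTC``.  With ``check_revcomp`` the reverse complement of the
    candidate is tried as well.
    """
    cand, ref = _pattern(candidate), _pattern(reference)
    if not cand or not ref:
        raise ValueError("patterns must be non-empty")

    def _windows(short: str, long_: str) -> bool:
        k = len(short)
        return any(
            _window_subsumed(long_[o : o + k], short)
            for o in range(len(long_) - k + 1)
        )

    def _one_way(a: str, b: str) -> bool:
        # equal lengths: "one is a possibility of the other" holds in
        # either containment direction
        if len(a) == len(b):
            return _windows(a, b) or _windows(b, a)
        short, long_ = (a, b) if len(a) < len(b) else (b, a)
        return _windows(short, long_)

    if _one_way(cand, ref):
        return True
    if check_revcomp and _one_way(revcomp_pattern(cand), ref):
        return True
    return False


def _more_specific(a: str, b: str):
    """Of an overlapping pair, return the redundant (more specific) pattern.

    Longer patterns are the specific ones (their windows are contained in the
    shorter, more degenerate pattern).  For equal lengths the pattern whose
    position-wise sets are contained in the other's is specific; mutual
    containment (equivalence) is broken by keeping the lexicographically
    smaller pattern.  Returns None when neither direction holds at equal
    length (offset overlap without containment).
    """
    if len(a) > len(b):
        return a
    if len(b) > len(a):
        return b
    a_in_b = _window_subsumed(a, b)
    b_in_a = _window_subsumed(b, a)
    if a_in_b and b_in_a:
        return max(a, b)
    if a_in_b:
        return a
    if b_in_a:
        return b
    return None


def dereplicate(motifs: Sequence[IupacMotif]) -> List[IupacMotif]:
    """Remove motifs subsumed by a more general motif of the same mod type.

    Iterated to a fixed point; the covering (more degenerate) motif is kept.
    Idempotent, and the output is always a subset of the input.
    """
    retained = list(dict.fromkeys(motifs))  # preserve order, drop exact dups
    changed = True
    while changed:
        changed = False
        drop: Set[IupacMotif] = set()
        for a, b in itertools.combinations(retained, 2):
            if a in drop or b in drop or a.mod_type != b.mod_type:
                continue
            if not motif_overlapped(a.pattern, b.pattern):
                continue
            specific = _more_specific(a.pattern, b.pattern)
            if specific == a.pattern:
                drop.add(a)
            elif specific == b.pattern:
                drop.add(b)
        if drop:
            retained = [m for m in retained if m not in drop]
            changed = True
    return retained


def expand_motif(pattern: str, limit: int = 65536) -> List[str]:
    """Enumerate all literal sequences a degenerate pattern stands for."""
    sets = [sorted(iupac_set(s)) for s in _pattern(pattern)]
    n = 1
    for s in sets:
        n *= len(s)
        if n > limit:
            raise ValueError(f"expansion exceeds {limit} sequences")
    return ["".join(t) for t in itertools.product(*sets)]


def scan(sequence: str, motif, both_strands: bool = False) -> List[Tuple[int, str]]:
    """Find occurrences of a motif in a sequence.

    Returns ``(position, strand)`` pairs where position is the 0-based start
    of the matched window on the forward coordinate system.  Reverse-strand
    occurrences (matches of the reverse-complemented pattern on the forward
    sequence) are reported only with ``both_strands``.
    """
    seq = sequence.upper()
    pat = _pattern(motif)
    hits = [(p, "+") for p in _scan_forward(seq, pat)]
    if both_strands:
        hits += [(p, "-") for p in _scan_forward(seq, revcomp_pattern(pat))]
    return sorted(hits)


def _scan_forward(seq: str, pat: str) -> List[int]:
    k = len(pat)
    sets = [iupac_set(s) for s in pat]
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + j] in sets[j] for j in range(k))
    ]


def methylated_positions(
    sequence: str, motif: IupacMotif, both_strands: bool = True
) -> List[Tuple[int, str]]:
    """Forward-coordinate positions of the methylated base of each occurrence.

    For a reverse-strand occurrence starting at forward position ``p`` the
    methylated base sits at ``p + len(pattern) - 1 - methylated_index``.
    """
    out = []
    k = len(motif.pattern)
    for pos, strand in scan(sequence, motif, both_strands=both_strands):
        if strand == "+":
            out.append((pos + motif.methylated_index, "+"))
        else:
            out.append((pos + k - 1 - motif.methylated_index, "-"))
    return sorted(set(out))


def support_filter(
    motif_hits: Mapping, min_genomes: int = 100
) -> List:
    """Keep motifs found in at least ``min_genomes`` distinct genomes."""
    return [m for m, genomes in motif_hits.items() if len(set(genomes)) >= min_genomes]


def reference_overlap(
    motifs: Iterable, reference_motifs: Iterable, check_revcomp: bool = False
) -> Tuple[int, Dict]:
    """Count motifs overlapping any reference motif (relaxed criterion).

    Returns ``(n_overlapping, matches)`` where ``matches`` maps each input
    motif to the list of reference motifs it overlaps (possibly empty).
    """
    refs = list(reference_motifs)
    matches: Dict = {}
    for m in motifs:
        matches[m] = [r for r in refs if motif_overlapped(m, r, check_revcomp)]
    n = sum(1 for v in matches.values() if v)
    return n, matches


def type_union_accounting(
    m4c_motifs: Iterable, m6a_motifs: Iterable
) -> Tuple[int, int, int, int]:
    """Count motifs per type, patterns shared by both types, and the union.

    A motif is "shared" when the same pattern string carries both an m4C and
    an m6A call; the non-redundant total is ``n_m4C + n_m6A - n_shared``.
    """
    p4 = {_pattern(m) for m in m4c_motifs}
    p6 = {_pattern(m) for m in m6a_motifs}
    shared = len(p4 & p6)
    return len(p4), len(p6), shared, len(p4) + len(p6) - shared
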