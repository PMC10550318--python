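"""URS1 core-motif scanning.

The URS1 element recognized by the DNA-binding repressor carries the
invariant core 5'-GGCGGC-3'.  Rather than de-novo discovery, this module scans
gene regions (1 kb upstream, ORF, 1 kb downstream) for exact occurrences of
the core on either strand: a minus-strand hit is an occurrence of the reverse
complement (GCCGCC) on the given sequence.  Coordinates are reported 1-based
inclusive; overlapping occurrences are all reported; matching is
case-insensitive and ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .quantio import REGIONS

URS1_CORE = "GGCGGC"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    pass


class AnnotationError(KeyError):
    pass


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    region: str       # upstream | orf | downstream
    start: int        # 1-based offset within the region
    strand: str       # '+' or '-'


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(seq: str, pattern: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1  # overlapping occurrences all reported


def scan_core(sequence: str, motif: str = URS1_CORE, gene_id: str = "",
              region: str = "upstream") -> list[MotifHit]:
    """All exact occurrences of ``motif`` and its reverse complement.

    Returns hits sorted by 1-based start position; ties (palindromes aside,
    impossible for this core) order '+' before '-'.
    """
    seq = sequence.upper()
    illegal = set(seq) - set("ACGTN")
    if illegal:
        raise SequenceError(f"illegal character(s) in sequence: {sorted(illegal)}")
    motif = motif.upper()
    hits = [MotifHit(gene_id, region, i + 1, "+") for i in _find_all(seq, motif)]
    rc = reverse_complement(motif)
    hits += [MotifHit(gene_id, region, i + 1, "-") for i in _find_all(seq, rc)]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def motif_fraction(targets: Sequence[str],
                   regions: Mapping[str, Mapping[str, str]],
                   motif: str = URS1_CORE):
    """Per-gene hit counts over all three regions and the hit-gene fraction.

    Returns ``(table, fraction)`` where ``table`` has one row per target with
    per-region and total hit counts, and ``fraction`` is the proportion of
    targets with at least one hit in any region.
    """
    if len(targets) == 0:
        raise ValueError("empty target list: fraction undefined")
    rows = []
    for gene in targets:
        if gene not in regions:
            raise AnnotationError(f"gene {gene!r} has no region sequences")
        per = regions[gene]
        missing = [r for r in REGIONS if r not in per]
        if missing:
            raise AnnotationError(f"gene {gene!r} missing region(s): {missing}")
        counts = {r: len(scan_core(per[r], motif, gene, r)) for r in REGIONS}
        counts["total"] = sum(counts.values())
        counts["gene_id"] = gene
        rows.append(counts)
    table = pd.DataFrame(rows).set_index("gene_id")
    fraction = float((table["total"] > 0).mean())
    return table, fraction


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Flatten hits for TSV export (gene_id, region, start, strand)."""
    return pd.DataFrame(
        [{"gene_id": h.gene_id, "region": h.region, "start": h.start,
          "strand": h.strand} for h in hits],
        columns=["gene_id", "region", "start", "strand"])
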