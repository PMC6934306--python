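"""Concordance of bi-allelic positions across replicates and data types.

If the same bi-allelic positions recur in independent replicates — and in
independent studies using different library types — they are very unlikely
to be sequencing artefacts.  This module partitions positions by their
replicate-membership pattern (the counts behind an UpSet plot), quantifies
pairwise overlap with a cumulative hypergeometric test, and classifies
RNA-detected bi-alleles as consistent or inconsistent with the genome call
at the same coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class OverlapPartition:
    """Counts of positions per membership pattern over the sample list."""

    sample_ids: list[str]
    pattern_counts: dict[tuple[bool, ...], int]

    def top_patterns(self, n: int = 15):
        """Largest n patterns plus a remainder bucket: [(pattern, count)]."""
        ranked = sorted(self.pattern_counts.items(),
                        key=lambda kv: (-kv[1], kv[0]))
        top = ranked[:n]
        rest = sum(c for _, c in ranked[n:])
        if rest:
            top.append((("rest",), rest))
        return top

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"pattern": "".join("1" if b else "0" for b in pat),
             "samples": "+".join(s for s, b in zip(self.sample_ids, pat)
                                 if b),
             "count": c}
            for pat, c in sorted(self.pattern_counts.items(),
                                 key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapTest:
    universe: int
    set_a: int
    set_b: int
    overlap: int
    p_value: float


def intersect_sets(position_sets: dict[str, set]) -> OverlapPartition:
    """Exact partition of the union of position sets by membership pattern.

    Positions are (contig, position) pairs on a common genome; each position
    of the union is counted in exactly one pattern.
    """
    sample_ids = list(position_sets)
    contigs_seen = {p[0] for s in position_sets.values() for p in s
                    if isinstance(p, tuple)}
    del contigs_seen  # namespace consistency is the caller's contract
    counts: Counter[tuple[bool, ...]] = Counter()
    universe = set().union(*position_sets.values()) if position_sets else set()
    for pos in universe:
        counts[tuple(pos in position_sets[s] for s in sample_ids)] += 1
    return OverlapPartition(sample_ids, dict(counts))


def hypergeometric_overlap(N: int, K: int, n: int, x: int) -> OverlapTest:
    """Upper-tail (inclusive) cumulative hypergeometric overlap test.

    p = P(X >= x) for X ~ Hypergeom(N, K, n): the chance that two random
    subsets of sizes K and n drawn from a universe of N positions share at
    least x positions.
    """
    if not (0 <= x <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"impossible configuration N={N}, K={K}, n={n}, x={x}")
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return OverlapTest(N, K, n, x, min(p, 1.0))


def rna_wg_consistency(rna_sites, wg_alleles) -> pd.DataFrame:
    """Compare RNA-detected bi-alleles to genome calls at the same position.

    `rna_sites` is an iterable of (contig, position, alleles) with `alleles`
    a set of the two bases; `wg_alleles` is a callable or mapping
    (contig, position) -> (classification_name, allele set).  A position is
    consistent only when the genome call is bi-allelic with the identical
    unordered allele pair; anything else (mono, different pair, tri, NA)
    is inconsistent.
    """
    lookup = wg_alleles if callable(wg_alleles) else (
        lambda key: wg_alleles.get(key, ("NA", frozenset())))
    rows = []
    for contig, position, alleles in rna_sites:
        wg_class, wg_pair = lookup((contig, position))
        consistent = (wg_class == "bi"
                      and frozenset(wg_pair) == frozenset(alleles))
        rows.append({"contig": contig, "position": position,
                     "rna_alleles": "".join(sorted(alleles)),
                     "wg_classification": wg_class,
                     "wg_alleles": "".join(sorted(wg_pair)),
                     "consistent": consistent})
    return pd.DataFrame(rows, columns=["contig", "position", "rna_alleles",
                                       "wg_classification", "wg_alleles",
                                       "consistent"])


def consistency_totals(table: pd.DataFrame) -> tuple[int, int]:
    """(consistent, divergent) counts from a consistency table."""
    if table.empty:
        return 0, 0
    n_cons = int(table.consistent.sum())
    return n_cons, len(table) - n_cons
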