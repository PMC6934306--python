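"""Repeat labelling of predicted ddRAD fragments.

"Repeats" cover interspersed repeats (transposon-like elements) and repeated
elements (multicopy genes, duplicated regions).  Because every repeat
detector has its own stringency, fragments are labelled with three
independent methods so downstream results can be checked for robustness to
the choice:

* M03 — all-vs-all global alignment of fragment sequences; both members of
  any pair reaching the identity threshold are labelled.
* M07 — each fragment searched against the whole genome; more than one
  qualifying locus labels the fragment.  Labels the most fragments of the
  three.
* M12 — seeded mapping reporting all hits within a score band of the best;
  more than one reported hit labels the fragment (medium stringency).

An interspersed-repeat mask is provided as a k-mer multiplicity masker; an
externally produced BED mask may be supplied instead and takes precedence.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
from Bio import Align

from .digest import Fragment, fragment_sequence
from .seqmap import SequenceIndex, map_sequence


def _global_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Identity (matches / alignment columns) of the best global alignment."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def label_m03(fragments: list[Fragment], genome: dict[str, str],
              min_identity: float = 0.80) -> set[int]:
    """All-vs-all global comparison; returns indices of labelled fragments.

    A cheap edlib edit-distance prescreen skips pairs that cannot reach the
    threshold before the exact global alignment (match +1 / mismatch -1 /
    gap -2) is scored.
    """
    seqs = [fragment_sequence(f, genome) for f in fragments]
    aligner = _make_aligner()
    labels: set[int] = set()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            longer = max(len(a), len(b))
            if min(len(a), len(b)) / longer < min_identity:
                continue  # global identity cannot reach the threshold
            budget = int(longer * (1.0 - min_identity)) + 2
            d = edlib.align(a, b, mode="NW", task="distance",
                            k=budget)["editDistance"]
            if d < 0:
                continue
            if _global_identity(a, b, aligner) >= min_identity:
                labels.add(i)
                labels.add(j)
    return labels


def label_m07(fragments: list[Fragment], genome: dict[str, str],
              min_identity: float = 0.80,
              index: SequenceIndex | None = None) -> set[int]:
    """Genome-wide search; >1 qualifying locus labels the fragment.

    The fragment's own locus counts as the first match, so a label means at
    least one *additional* locus reaches the identity threshold.
    """
    index = index or SequenceIndex(genome)
    labels: set[int] = set()
    for i, frag in enumerate(fragments):
        hits = map_sequence(fragment_sequence(frag, genome), index,
                            min_identity=min_identity, both_strands=True,
                            max_hits=2)
        if len(hits) > 1:
            labels.add(i)
    return labels


def label_m12(fragments: list[Fragment], genome: dict[str, str],
              min_identity: float = 0.80, score_band: int = 30,
              max_hits: int = 100,
              index: SequenceIndex | None = None) -> set[int]:
    """Seeded mapping; >1 hit within `score_band` of the best hit labels.

    Scores are match +1 / edit -1 relative units (query_len - 2*edits); the
    band keeps only near-best secondary placements, giving the method its
    medium stringency.
    """
    index = index or SequenceIndex(genome)
    labels: set[int] = set()
    for i, frag in enumerate(fragments):
        hits = map_sequence(fragment_sequence(frag, genome), index,
                            min_identity=min_identity, both_strands=True,
                            max_hits=max_hits)
        if not hits:
            continue
        best = hits[0].score
        in_band = [h for h in hits if h.score >= best - score_band]
        if len(in_band) > 1:
            labels.add(i)
    return labels


def label_fragments(fragments: list[Fragment], genome: dict[str, str],
                    methods=("M03", "M07", "M12"), **kwargs
                    ) -> dict[int, set[str]]:
    """Run the requested methods; fragment index -> set of method labels."""
    index = SequenceIndex(genome)
    out: dict[int, set[str]] = {i: set() for i in range(len(fragments))}
    runners = {
        "M03": lambda: label_m03(fragments, genome,
                                 kwargs.get("min_identity", 0.80)),
        "M07": lambda: label_m07(fragments, genome,
                                 kwargs.get("min_identity", 0.80),
                                 index=index),
        "M12": lambda: label_m12(fragments, genome,
                                 kwargs.get("min_identity", 0.80),
                                 kwargs.get("score_band", 30), index=index),
    }
    for method in methods:
        for i in runners[method]():
            out[i].add(method)
    return out


def kmer_interspersed_mask(genome: dict[str, str], k: int = 15,
                           multiplicity_threshold: int = 4):
    """Mask positions covered by any k-mer occurring >= threshold times.

    A desk-scale stand-in for an interspersed-repeat annotation: high
    genome-wide k-mer multiplicity marks transposon-like and otherwise
    heavily repeated sequence.  Returns merged (contig, start, end)
    intervals, 0-based half-open.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    shortest = min(len(s) for s in genome.values())
    if k > shortest:
        raise ValueError(f"k={k} longer than shortest contig ({shortest} bp)")
    counts: Counter[str] = Counter()
    for seq in genome.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
    intervals = []
    for contig, seq in genome.items():
        seq = seq.upper()
        mask = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - k + 1):
            if counts[seq[i:i + k]] >= multiplicity_threshold:
                mask[i:i + k] = True
        intervals.extend(mask_to_intervals(contig, mask))
    return intervals


def mask_to_intervals(contig: str, mask: np.ndarray):
    """Boolean mask -> merged (contig, start, end) intervals."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for s, e in zip(edges[::2], edges[1::2]):
        out.append((contig, int(s), int(e)))
    return out


def merge_intervals(intervals):
    """Merge overlapping/adjacent (contig, start, end) intervals."""
    out = []
    for contig in sorted({iv[0] for iv in intervals}):
        ivs = sorted((int(s), int(e)) for c, s, e, *_ in intervals
                     if c == contig)
        cur = None
        for s, e in ivs:
            if cur and s <= cur[1]:
                cur[1] = max(cur[1], e)
            else:
                if cur:
                    out.append((contig, cur[0], cur[1]))
                cur = [s, e]
        if cur:
            out.append((contig, cur[0], cur[1]))
    return out
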