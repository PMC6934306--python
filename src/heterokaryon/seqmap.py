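"""Shared sequence utilities and a seeded all-hits mapper.

The mapper is a seed-and-extend search used wherever a fragment, bubble or
transcript has to be located in a larger sequence set with an identity
threshold: repeat labelling of ddRAD fragments against the genome, bubble
placement on the reference transcriptome, and bubble/transcript placement on
the genome.  It reports *every* qualifying hit (up to a cap), because the
downstream questions are of the form "does this sequence occur more than
once?" rather than "what is the best alignment?".

Alignment extension is done with edlib in infix (HW) mode, so the whole query
is aligned against a candidate window and identity is measured as
1 - edit_distance/len(query).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    BASE_CODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_RC)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes 0..3 (255 for anything else)."""
    return BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def count_occurrences(haystacks, needle: str, both_strands: bool = True,
                      max_count: int | None = None) -> int:
    """Count (possibly overlapping) exact occurrences of `needle`.

    `haystacks` is an iterable of sequences (e.g. genome contigs).  With
    `both_strands`, occurrences of the reverse complement are counted too;
    a palindromic needle is only counted once per location.
    """
    patterns = [needle]
    if both_strands:
        rc = revcomp(needle)
        if rc != needle:
            patterns.append(rc)
    n = 0
    for hay in haystacks:
        for pat in patterns:
            i = hay.find(pat)
            while i != -1:
                n += 1
                if max_count is not None and n >= max_count:
                    return n
                i = hay.find(pat, i + 1)
    return n


@dataclass(frozen=True)
class Hit:
    """One qualifying placement of a query on a target sequence."""

    target: str
    start: int           # 0-based, on the target forward strand
    end: int             # half-open
    strand: str          # '+' or '-'
    identity: float      # 1 - edit_distance / len(query)
    score: int           # len(query) - 2 * edit_distance


class SequenceIndex:
    """k-mer seed index over a dict of named target sequences."""

    def __init__(self, targets: dict[str, str], seed_len: int = 13):
        self.targets = {name: seq.upper() for name, seq in targets.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.targets.items():
            for i in range(len(seq) - seed_len + 1):
                self._index[seq[i:i + seed_len]].append((name, i))

    def seed_hits(self, query: str):
        k = self.seed_len
        for qpos in range(len(query) - k + 1):
            for name, tpos in self._index.get(query[qpos:qpos + k], ()):
                yield name, tpos - qpos  # diagonal anchored at query start


def map_sequence(query: str, index: SequenceIndex, min_identity: float = 0.9,
                 both_strands: bool = False, max_hits: int = 100) -> list[Hit]:
    """Find all placements of `query` with identity >= `min_identity`.

    Seed diagonals are clustered into candidate windows; each window is
    aligned with edlib (infix mode) and kept when the full-query identity
    reaches the threshold.  Hits are deduplicated (overlapping placements on
    one target keep the best) and returned sorted by score, best first.
    """
    if not query:
        raise ValueError("empty query sequence")
    query = query.upper()
    qlen = len(query)
    max_dist = int(qlen * (1.0 - min_identity))
    hits: list[Hit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        diags: dict[str, list[int]] = defaultdict(list)
        for name, diag in index.seed_hits(q):
            diags[name].append(diag)
        for name, dlist in diags.items():
            target = index.targets[name]
            dlist.sort()
            # cluster diagonals closer than the gap budget into one window
            clusters: list[list[int]] = []
            for d in dlist:
                if clusters and d - clusters[-1][-1] <= max_dist + 1:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            for cl in clusters:
                lo = max(0, cl[0] - max_dist)
                hi = min(len(target), cl[-1] + qlen + max_dist)
                if hi - lo < qlen - max_dist:
                    continue
                res = edlib.align(q, target[lo:hi], mode="HW",
                                  task="locations", k=max_dist)
                if res["editDistance"] < 0:
                    continue
                dist = res["editDistance"]
                s, e = res["locations"][0]
                hits.append(Hit(name, lo + s, lo + e + 1, strand,
                                1.0 - dist / qlen, qlen - 2 * dist))
    # deduplicate placements that overlap by more than half the query
    hits.sort(key=lambda h: (-h.score, h.target, h.start, h.strand))
    kept: list[Hit] = []
    for h in hits:
        dup = False
        for g in kept:
            if g.target == h.target and g.strand == h.strand:
                ov = min(g.end, h.end) - max(g.start, h.start)
                if ov > 0.5 * qlen:
                    dup = True
                    break
        if not dup:
            kept.append(h)
        if len(kept) >= max_hits:
            break
    return kept
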