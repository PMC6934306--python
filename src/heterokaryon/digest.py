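"""In silico EcoRI/MseI double digestion and fragment anchoring.

A ddRAD library sequences fragments flanked by two different restriction
sites.  To compare ddRAD and whole-genome data over the same territory, the
genome is digested in silico: a candidate fragment spans two *consecutive*
cuts made by different enzymes (no internal cut, matching double-digest
size-selection practice) and is kept when at least 50 bp long.  Fragments are
then re-anchored: a fragment whose sequence occurs at exactly one genomic
locus defines a "predicted ddRAD region"; multi-locus fragments are removed.

Cut offsets follow standard chemistry (EcoRI G^AATTC, MseI T^TAA), reported
as 0-based top-strand coordinates.  Both motifs are palindromic, so scanning
one strand yields all sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Restriction import EcoRI, MseI
from Bio.Seq import Seq

from .seqmap import count_occurrences

ENZYMES = {"EcoRI": EcoRI, "MseI": MseI}
MIN_FRAGMENT_LENGTH = 50  # "longer than 49 bp"


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int            # 0-based half-open, between-cut coordinates
    end: int
    flank5_enzyme: str
    flank3_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PredictedRadRegion:
    """A uniquely re-anchored EcoRI-MseI fragment, the unit of analysis."""

    contig: str
    start: int
    end: int
    flank5_enzyme: str
    flank3_enzyme: str
    uniquely_anchored: bool = True
    repeat_labels: set = field(default_factory=set)
    coding_overlap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def find_cut_sites(sequence: str, enzyme: str) -> list[int]:
    """0-based cut positions of one enzyme, strictly increasing."""
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; "
                         f"expected one of {sorted(ENZYMES)}")
    # Bio.Restriction reports 1-based first-base-after-cut positions
    return [p - 1 for p in ENZYMES[enzyme].search(Seq(sequence.upper()))]


def predict_fragments(genome: dict[str, str],
                      min_length: int = MIN_FRAGMENT_LENGTH,
                      max_length: int | None = None) -> list[Fragment]:
    """Candidate ddRAD fragments between consecutive cuts of differing enzymes."""
    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        cuts = sorted(
            [(p, "EcoRI") for p in find_cut_sites(seq, "EcoRI")]
            + [(p, "MseI") for p in find_cut_sites(seq, "MseI")])
        for (p1, e1), (p2, e2) in zip(cuts, cuts[1:]):
            if e1 == e2:
                continue
            length = p2 - p1
            if length < min_length:
                continue
            if max_length is not None and length > max_length:
                continue
            fragments.append(Fragment(contig, p1, p2, e1, e2))
    return fragments


def fragment_sequence(fragment: Fragment, genome: dict[str, str]) -> str:
    return genome[fragment.contig][fragment.start:fragment.end]


def anchor_fragments(fragments: list[Fragment], genome: dict[str, str],
                     coding_intervals=None) -> list[PredictedRadRegion]:
    """Keep fragments whose sequence occurs at exactly one genomic locus.

    Occurrences are counted exactly on both strands (the desk-scale
    equivalent of re-aligning fragments to the assembly and discarding those
    that place more than once or not at all).  Surviving regions carry a
    coding flag when they overlap >= 1 base of any coding interval.
    """
    coding_intervals = coding_intervals or []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in coding_intervals:
        by_contig.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    regions: list[PredictedRadRegion] = []
    haystacks = list(genome.values())
    for frag in fragments:
        n = count_occurrences(haystacks, fragment_sequence(frag, genome),
                              both_strands=True, max_count=2)
        if n != 1:
            continue
        coding = any(frag.start < e and frag.end > s
                     for s, e in by_contig.get(frag.contig, ()))
        regions.append(PredictedRadRegion(
            frag.contig, frag.start, frag.end, frag.flank5_enzyme,
            frag.flank3_enzyme, uniquely_anchored=True,
            coding_overlap=coding))
    return regions
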