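"""Reference-free discovery of bi-allelic positions in RNA-seq reads.

A SNP expressed from two nucleus genotypes leaves a characteristic motif in
a De Bruijn graph of the reads: two vertex-disjoint paths of k nodes between
a shared source and sink, spelling two sequences of length 2k-1 that differ
only at the centre base ("Type0a bubble").  Enumerating these bubbles calls
bi-allelic transcript positions without any reference genome, so agreement
with genome calls at the same coordinates is an independent confirmation
that the variation is real and transcribed.

The pipeline: read QC (drop reads with Ns, trim low-quality 3' ends, keep
>= 50 bp), graph construction with a k-mer solidity threshold (default
count >= 2), bubble enumeration, bubble filters (total support >= 6, each
allele >= 2, unambiguous placement on a curated reference transcriptome),
ORF-based codon-effect prediction, and placement of bubbles on the genome
to obtain the genomic coordinate of each RNA bi-allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seqmap import SequenceIndex, map_sequence, revcomp

DEFAULT_K = 41
DEFAULT_SOLIDITY = 2
_ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# read QC
# ---------------------------------------------------------------------------

def qc_filter_reads(reads, min_length: int = 50, trim_quality: int = 20):
    """QC of (sequence, quality-string) pairs.

    Reads containing N are dropped; 3' bases are trimmed while their quality
    is below `trim_quality`; reads shorter than `min_length` after trimming
    are dropped.  Yields surviving (sequence, quality) pairs.
    """
    for seq, qual in reads:
        if "N" in seq.upper():
            continue
        cut = len(seq)
        while cut > 0 and ord(qual[cut - 1]) - 33 < trim_quality:
            cut -= 1
        if cut < min_length:
            continue
        yield seq[:cut], qual[:cut]


def read_fastq(path):
    """(sequence, quality) pairs from an uncompressed/gzipped FASTQ."""
    import pysam
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.sequence, entry.quality or ""


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

@dataclass
class DeBruijnGraph:
    """Node-centric stranded De Bruijn graph of solid k-mers."""

    k: int
    counts: dict[str, int]

    def __contains__(self, node: str) -> bool:
        return node in self.counts

    def successors(self, node: str) -> list[str]:
        suffix = node[1:]
        return [suffix + c for c in _ALPHABET if suffix + c in self.counts]

    def predecessors(self, node: str) -> list[str]:
        prefix = node[:-1]
        return [c + prefix for c in _ALPHABET if c + prefix in self.counts]

    def edges(self):
        """(u, v, count) with count = min support of the endpoints."""
        for u in self.counts:
            for v in self.successors(u):
                yield u, v, min(self.counts[u], self.counts[v])


def build_graph(reads, k: int = DEFAULT_K,
                min_count: int = DEFAULT_SOLIDITY,
                stranded: bool = True) -> DeBruijnGraph:
    """Count k-mers of the reads and keep those with count >= min_count.

    Stranded by default (stranded RNA libraries); with `stranded=False`
    k-mers are canonicalised (lexicographic min of k-mer and reverse
    complement) for unstranded data.  k must be odd (palindrome-safe) and
    >= 15.
    """
    if k % 2 == 0 or k < 15:
        raise ValueError("k must be odd and >= 15")
    counts: dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            if not stranded:
                km = min(km, revcomp(km))
            counts[km] = counts.get(km, 0) + 1
    solid = {km: c for km, c in counts.items() if c >= min_count}
    return DeBruijnGraph(k, solid)


# ---------------------------------------------------------------------------
# bubbles
# ---------------------------------------------------------------------------

@dataclass
class Bubble:
    """A Type0a variant: two equal-length paths differing at one base."""

    path_upper: str
    path_lower: str
    variant_offset: int
    allele_upper: str
    allele_lower: str
    count_upper: int
    count_lower: int
    transcript_hit: tuple[str, int, str] | None = None  # (id, start, strand)
    genome_hit: tuple[str, int] | None = None           # (contig, position)
    genome_alleles: frozenset[str] | None = None
    ambiguity_flags: set[str] = field(default_factory=set)
    effect: str = "NA"

    @property
    def k(self) -> int:
        return (len(self.path_upper) + 1) // 2

    @property
    def total_count(self) -> int:
        return self.count_upper + self.count_lower

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_upper, self.allele_lower))


def _spell(path: list[str]) -> str:
    return path[0] + "".join(node[-1] for node in path[1:])


def find_type0a_bubbles(graph: DeBruijnGraph) -> list[Bubble]:
    """Enumerate simple SNP bubbles.

    From every branching source node, pairs of divergent successors are
    extended in lockstep (appending the same base to both paths) for k
    nodes; a bubble is emitted when the two k-node paths reconverge on a
    shared sink.  The two spelled sequences have length 2k-1 and differ
    exactly at the centre (offset k-1); per-path support is the minimum node
    count along the path.
    """
    k = graph.k
    bubbles = []
    for source in graph.counts:
        succ = graph.successors(source)
        if len(succ) < 2:
            continue
        for ai in range(len(succ)):
            for bi in range(ai + 1, len(succ)):
                a, b = succ[ai], succ[bi]
                stack = [([a], [b])]
                while stack:
                    pa, pb = stack.pop()
                    if len(pa) == k:
                        ua, ub = pa[-1], pb[-1]
                        # ua/ub now differ at their first base only; any
                        # shared appended base gives the same sink node
                        if any(ua[1:] + c in graph for c in _ALPHABET):
                            bubbles.append(_make_bubble(graph, pa, pb))
                        continue
                    ua, ub = pa[-1], pb[-1]
                    for c in _ALPHABET:
                        va, vb = ua[1:] + c, ub[1:] + c
                        if va in graph and vb in graph:
                            stack.append((pa + [va], pb + [vb]))
    # deduplicate (a bubble is uniquely identified by its sequence pair)
    seen = set()
    unique = []
    for bub in bubbles:
        key = (bub.path_upper, bub.path_lower)
        if key not in seen:
            seen.add(key)
            unique.append(bub)
    unique.sort(key=lambda b: (b.path_upper, b.path_lower))
    return unique


def _make_bubble(graph: DeBruijnGraph, pa: list[str], pb: list[str]) -> Bubble:
    k = graph.k
    sa, sb = _spell(pa), _spell(pb)
    ca = min(graph.counts[n] for n in pa)
    cb = min(graph.counts[n] for n in pb)
    if sa[k - 1] > sb[k - 1]:
        sa, sb, ca, cb = sb, sa, cb, ca
    return Bubble(sa, sb, k - 1, sa[k - 1], sb[k - 1], ca, cb)


# ---------------------------------------------------------------------------
# mapping and filters
# ---------------------------------------------------------------------------

def filter_bubbles(bubbles: list[Bubble], transcriptome: dict[str, str],
                   min_total: int = 6, min_per_allele: int = 2,
                   min_identity: float = 0.80,
                   index: SequenceIndex | None = None) -> list[Bubble]:
    """Apply the support and placement filters; returns retained bubbles.

    Drops bubbles with total read support < 6 or either allele < 2, bubbles
    hitting more than one transcriptome sequence (or placing ambiguously),
    and bubbles hitting nothing in the curated reference transcriptome.
    Retained bubbles carry their unique transcript_hit.
    """
    index = index or SequenceIndex(transcriptome)
    kept: list[Bubble] = []
    for bub in bubbles:
        if bub.total_count < min_total:
            continue
        if min(bub.count_upper, bub.count_lower) < min_per_allele:
            continue
        hits = map_sequence(bub.path_upper, index, min_identity=min_identity,
                            both_strands=False, max_hits=10)
        if len(hits) == 0:
            bub.ambiguity_flags.add("low_identity")
            continue
        if len(hits) > 1:
            bub.ambiguity_flags.add("multi_transcript")
            continue
        hit = hits[0]
        bub.transcript_hit = (hit.target, hit.start, hit.strand)
        kept.append(bub)
    return kept


# ---------------------------------------------------------------------------
# ORFs and codon effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    start: int   # 0-based, includes the stop codon
    end: int
    frame: int


def find_best_orf(transcript: str) -> Orf | None:
    """Longest ATG-to-stop ORF on the given strand; 5'-most wins ties."""
    if len(transcript) < 3:
        raise ValueError("transcript shorter than one codon")
    seq = transcript.upper()
    best: Orf | None = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                if start is not None:
                    cand = Orf(start, i + 3, frame)
                    if best is None or (cand.end - cand.start
                                        > best.end - best.start) \
                            or (cand.end - cand.start == best.end - best.start
                                and cand.start < best.start):
                        best = cand
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def classify_effect(bubble: Bubble, orf: Orf | None, transcript: str) -> str:
    """synonymous / nonsynonymous / noncoding for a placed bubble.

    The variant transcript coordinate is the hit offset plus k-1 (the bubble
    centre is symmetric, so the same offset applies on either strand); the
    centre base decides coding status when the bubble straddles an ORF
    boundary.  Both alleles are substituted into the codon and translated
    with the standard nuclear code.
    """
    if bubble.transcript_hit is None:
        raise ValueError("bubble has no transcript hit")
    _, start, strand = bubble.transcript_hit
    tpos = start + bubble.k - 1
    if not 0 <= tpos < len(transcript):
        raise ValueError(f"variant offset {tpos} outside transcript "
                         f"of length {len(transcript)}")
    if orf is None or not orf.start <= tpos < orf.end:
        return "noncoding"
    a_up, a_lo = bubble.allele_upper, bubble.allele_lower
    if strand == "-":
        a_up, a_lo = a_up.translate(_COMP), a_lo.translate(_COMP)
    off = (tpos - orf.start) % 3
    cstart = tpos - off
    codon = transcript[cstart:cstart + 3].upper()
    if len(codon) < 3:
        return "noncoding"
    c1 = codon[:off] + a_up + codon[off + 1:]
    c2 = codon[:off] + a_lo + codon[off + 1:]
    aa1 = str(Seq(c1).translate())
    aa2 = str(Seq(c2).translate())
    return "synonymous" if aa1 == aa2 else "nonsynonymous"


def annotate_effects(bubbles: list[Bubble], transcriptome: dict[str, str],
                     orfs: dict[str, Orf | None] | None = None
                     ) -> list[Bubble]:
    """Fill bubble.effect for bubbles with a unique transcript hit."""
    if orfs is None:
        orfs = {tid: find_best_orf(seq)
                for tid, seq in transcriptome.items()}
    for bub in bubbles:
        if bub.transcript_hit is None:
            bub.effect = "NA"
            continue
        tid = bub.transcript_hit[0]
        bub.effect = classify_effect(bub, orfs.get(tid), transcriptome[tid])
    return bubbles


# ---------------------------------------------------------------------------
# genome placement
# ---------------------------------------------------------------------------

def bubble_genome_positions(bubbles: list[Bubble], genome: dict[str, str],
                            min_identity: float = 0.90,
                            index: SequenceIndex | None = None
                            ) -> list[Bubble]:
    """Attach the genomic coordinate of each bubble's bi-allelic position.

    The bubble path is mapped to the genome on both strands; a unique hit
    records (contig, centre position) and the allele pair in genome
    orientation.  Multi-hit and no-hit bubbles are flagged and left without
    coordinates (they are excluded from consistency analysis but reported).
    """
    index = index or SequenceIndex(genome)
    for bub in bubbles:
        hits = map_sequence(bub.path_upper, index, min_identity=min_identity,
                            both_strands=True, max_hits=10)
        if len(hits) == 1:
            hit = hits[0]
            bub.genome_hit = (hit.target, hit.start + bub.k - 1)
            alleles = (bub.allele_upper, bub.allele_lower)
            if hit.strand == "-":
                alleles = tuple(a.translate(_COMP) for a in alleles)
            bub.genome_alleles = frozenset(alleles)
        elif len(hits) > 1:
            bub.ambiguity_flags.add("multi_genome")
        else:
            bub.ambiguity_flags.add("low_identity")
    return bubbles
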