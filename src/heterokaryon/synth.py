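"""Seeded synthetic heterokaryon study generator.

Builds the kind of dataset the analysis pipeline assumes: a haploid genome in
which two nucleus genotypes coexist in one mycelium at ratio p, so that every
planted SNP between the two genotypes appears as a bi-allelic position with
expected minor-allele fraction min(p, 1-p).  The generator emits the study's
standard artefacts — genome FASTA, gene models (GFF3), truth repeat intervals
(BED), whole-genome / ddRAD / RNA reads (FASTQ) with truth alignments (SAM) —
plus machine-readable truth tables, so every downstream stage can be scored
against ground truth without any external data.

Defaults mirror the conditions reported for real R. irregularis isolates:
SNP density in the 0.7-2.8 per kb range (300 SNPs on 200 kb = 1.5/kb),
sequencing depth ~30x (reported ranges 13-47x WG, 22-33x ddRAD), 100 bp
reads, and an AT-rich genome (GC 0.30).

Reads are emitted together with truth alignments, bypassing read mapping
(mapping is out of scope; real-data users supply externally produced
SAM/BAM).  Quality strings are constant Q37; the site classifier models
errors through its own error-rate parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .seqmap import BASES, revcomp, seq_to_codes, codes_to_seq

# restriction motifs that SNP placement must keep intact on both haplotypes
_MOTIFS = ("GAATTC", "TTAA")
_MOTIF_GUARD = 6  # SNPs stay >= this many bases away from any motif

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class SimulationSizeError(ValueError):
    """Requested genes/repeats/SNPs do not fit in the genome."""


@dataclass(frozen=True)
class RepeatSpec:
    n_duplications: int = 0
    duplication_length: int = 2000
    n_interspersed: int = 0
    element_length: int = 500


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 200_000
    gc_fraction: float = 0.30
    n_genes: int = 80
    gene_length: int = 1500
    repeat_spec: RepeatSpec = field(default_factory=RepeatSpec)
    n_snps: int = 300
    ratio_p: float = 0.5          # proportion of nucleus genotype 1
    wg_depth: float = 30.0
    ddrad_depth: float = 30.0
    rna_depth: float = 50.0
    read_length: int = 100
    error_rate: float = 0.005     # per-base substitution probability
    seed: int = 1
    orf_genes: bool = True        # give each gene an ATG..stop ORF body
    expression_mode: str = "lognormal"   # or "uniform"
    expression_sigma: float = 1.0
    single_allele_fraction: float = 0.0  # genes expressing genotype 1 only

    def validate(self) -> None:
        if not 0.0 <= self.ratio_p <= 1.0:
            raise ValueError("ratio_p must be in [0, 1]")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if min(self.wg_depth, self.ddrad_depth, self.rna_depth) < 0:
            raise ValueError("depths must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.genome_length < 10_000:
            raise SimulationSizeError("genome_length must be >= 10000")
        if self.expression_mode not in ("lognormal", "uniform"):
            raise ValueError("expression_mode must be lognormal or uniform")


@dataclass(frozen=True)
class GeneModel:
    contig: str
    start: int   # 0-based half-open
    end: int
    strand: str
    gene_id: str


@dataclass
class NucleusMixtureTruth:
    """Two haplotypes plus the planted-variation truth tables."""

    haplotype1: dict[str, str]
    haplotype2: dict[str, str]
    snp_table: pd.DataFrame          # contig, position, allele1, allele2, flags
    gene_models: list[GeneModel]
    expression_levels: np.ndarray    # per gene, sums to 1
    single_allele_genes: frozenset[str]
    config: SimulationConfig

    def codes(self, hap: int, contig: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_codes", {})
        key = (hap, contig)
        if key not in cache:
            seq = (self.haplotype1 if hap == 1 else self.haplotype2)[contig]
            cache[key] = seq_to_codes(seq)
        return cache[key]


@dataclass(frozen=True)
class SimRead:
    name: str
    contig: str
    start: int
    seq: str
    hap: int


@dataclass
class ReadSet:
    """Simulated reads with their generating (truth) coordinates."""

    reads: list[SimRead]
    ref_lengths: dict[str, int]

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.reads]

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{'F' * len(r.seq)}\n")

    def write_sam(self, path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in self.ref_lengths.items()],
        }
        reads = sorted(self.reads, key=lambda r: (r.contig, r.start))
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for r in reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.name
                a.query_sequence = r.seq
                a.flag = 0
                a.reference_id = out.get_tid(r.contig)
                a.reference_start = r.start
                a.mapping_quality = 60
                a.cigarstring = f"{len(r.seq)}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    "F" * len(r.seq))
                out.write(a)


def _rng(config: SimulationConfig, *stage: int) -> np.random.Generator:
    # per-stage streams: results do not depend on which stages are run
    return np.random.default_rng([config.seed, *stage])


def _base_probs(gc: float) -> list[float]:
    return [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig):
    """Random genome with gene models and planted repeat truth intervals.

    Returns (genome: {contig: seq}, gene_models, repeat_intervals) where
    repeat intervals are (contig, start, end, kind) tuples, 0-based half-open.
    Duplications are exact internal copies; interspersed repeats are copies
    of one random element scattered over the genome.
    """
    config.validate()
    rng = _rng(config, 0)
    L = config.genome_length
    contig = "contig_1"
    codes = rng.choice(4, size=L, p=_base_probs(config.gc_fraction)).astype(
        np.uint8)

    genes: list[GeneModel] = []
    if config.n_genes > 0:
        slot = L // config.n_genes
        if slot < config.gene_length + 2:
            raise SimulationSizeError(
                f"genome_length {L} too short for {config.n_genes} genes of "
                f"{config.gene_length} bp (needs slot >= gene_length + 2)")
        for i in range(config.n_genes):
            off = int(rng.integers(0, slot - config.gene_length + 1))
            start = i * slot + off
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(contig, start, start + config.gene_length,
                                   strand, f"gene{i + 1:04d}"))
            if config.orf_genes:
                _write_orf_body(codes, start, config.gene_length, strand, rng)

    rs = config.repeat_spec
    need = (rs.n_duplications * 2 * rs.duplication_length
            + rs.n_interspersed * rs.element_length)
    if need > 0.5 * L:
        raise SimulationSizeError(
            f"repeats need {need} bp, more than half of genome_length {L}")
    placed: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(2000):
            s = int(rng.integers(0, L - length))
            if all(s + length <= a or s >= b for a, b in placed):
                placed.append((s, s + length))
                return s
        raise SimulationSizeError(
            f"could not place a {length} bp repeat in {L} bp genome")

    repeats: list[tuple[str, int, int, str]] = []
    if rs.n_interspersed > 0:
        elem = rng.choice(4, size=rs.element_length,
                          p=_base_probs(config.gc_fraction)).astype(np.uint8)
        for _ in range(rs.n_interspersed):
            s = place(rs.element_length)
            codes[s:s + rs.element_length] = elem
            repeats.append((contig, s, s + rs.element_length, "interspersed"))
    for _ in range(rs.n_duplications):
        src = place(rs.duplication_length)
        dst = place(rs.duplication_length)
        codes[dst:dst + rs.duplication_length] = codes[src:src
                                                       + rs.duplication_length]
        repeats.append((contig, src, src + rs.duplication_length,
                        "duplication"))
        repeats.append((contig, dst, dst + rs.duplication_length,
                        "duplication"))
    repeats.sort(key=lambda r: r[1])
    return {contig: codes_to_seq(codes)}, genes, repeats


def _write_orf_body(codes: np.ndarray, start: int, length: int, strand: str,
                    rng: np.random.Generator) -> None:
    """Rewrite ~80% of a gene body as an ATG..stop ORF (UTRs on both sides)."""
    utr = max(3, length // 10)
    n_codons = (length - 2 * utr) // 3 - 2
    if n_codons < 2:
        return
    sense = []
    sense.append("ATG")
    while len(sense) < n_codons + 1:
        codon = codes_to_seq(rng.choice(4, size=3).astype(np.uint8))
        if codon not in _STOP_CODONS:
            sense.append(codon)
    sense.append("TAA")
    orf = "".join(sense)
    if strand == "-":
        orf = revcomp(orf)
    codes[start + utr:start + utr + len(orf)] = seq_to_codes(orf)


# ---------------------------------------------------------------------------
# SNP planting
# ---------------------------------------------------------------------------

def _interval_mask(length: int, intervals) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[max(0, start):min(length, end)] = True
    return mask


def plant_heterokaryon_snps(genome: dict[str, str],
                            gene_models: list[GeneModel],
                            repeat_intervals,
                            config: SimulationConfig) -> NucleusMixtureTruth:
    """Plant n_snps substitutions that distinguish the two nucleus genotypes.

    Haplotype 1 is the reference.  SNP positions avoid the neighbourhood of
    any EcoRI/MseI motif and alleles are chosen so that no motif is created,
    so both haplotypes share a single digest map and fragment
    presence/absence never confounds the variant-calling question.
    """
    config.validate()
    rng = _rng(config, 1)
    rows = []
    hap2 = {}
    for contig, seq in genome.items():
        L = len(seq)
        eligible = np.ones(L, dtype=bool)
        for motif in _MOTIFS:
            i = seq.find(motif)
            while i != -1:
                lo = max(0, i - _MOTIF_GUARD)
                eligible[lo:i + len(motif) + _MOTIF_GUARD] = False
                i = seq.find(motif, i + 1)
        pool = np.flatnonzero(eligible)
        if config.n_snps > len(pool):
            raise SimulationSizeError(
                f"n_snps={config.n_snps} exceeds {len(pool)} eligible "
                f"positions on {contig}")
        order = rng.permutation(pool)
        coding = _interval_mask(L, [(g.start, g.end) for g in gene_models
                                    if g.contig == contig])
        repeat = _interval_mask(L, [(s, e) for c, s, e, _ in repeat_intervals
                                    if c == contig])
        h2 = bytearray(seq, "ascii")
        chosen = 0
        for pos in order:
            if chosen >= config.n_snps:
                break
            pos = int(pos)
            ref = seq[pos]
            alts = [b for b in "ACGT" if b != ref]
            alt = None
            for cand in rng.permutation(alts):
                window = (seq[max(0, pos - 5):pos] + cand
                          + seq[pos + 1:pos + 6])
                if not any(m in window or revcomp(m) in window
                           for m in _MOTIFS):
                    alt = cand
                    break
            if alt is None:
                continue
            h2[pos] = ord(alt)
            rows.append((contig, pos, ref, alt, bool(coding[pos]),
                         bool(repeat[pos]), bool(coding[pos])))
            chosen += 1
        if chosen < config.n_snps:
            raise SimulationSizeError(
                f"only {chosen} of {config.n_snps} SNPs placeable on {contig}")
        hap2[contig] = h2.decode()

    snp_table = pd.DataFrame(
        rows, columns=["contig", "position", "allele1", "allele2",
                       "in_coding", "in_repeat", "transcribed"],
    ).sort_values(["contig", "position"]).reset_index(drop=True)

    n_genes = len(gene_models)
    if config.expression_mode == "lognormal" and n_genes:
        levels = rng.lognormal(0.0, config.expression_sigma, n_genes)
    else:
        levels = np.ones(n_genes)
    levels = levels / levels.sum() if n_genes else levels
    n_single = int(round(config.single_allele_fraction * n_genes))
    single = frozenset(
        gene_models[i].gene_id
        for i in rng.choice(n_genes, size=n_single, replace=False)
    ) if n_single else frozenset()

    return NucleusMixtureTruth(dict(genome), hap2, snp_table, gene_models,
                               levels, single, config)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _apply_errors(mat: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return mat
    err = rng.random(mat.shape) < error_rate
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    return mat


def simulate_wg_reads(truth: NucleusMixtureTruth, config: SimulationConfig,
                      replicate: int = 0, prefix: str = "wg") -> ReadSet:
    """Whole-genome shotgun reads from the genotype mixture.

    Each read is drawn from haplotype 1 with probability ratio_p, otherwise
    from haplotype 2, so the expected allele-1 fraction at a planted SNP is
    ratio_p.
    """
    config.validate()
    if config.wg_depth <= 0:
        raise ValueError("wg_depth must be > 0")
    rng = _rng(config, 2, replicate)
    reads: list[SimRead] = []
    rl = config.read_length
    for contig, seq in truth.haplotype1.items():
        L = len(seq)
        n = int(round(config.wg_depth * L / rl))
        starts = rng.integers(0, L - rl + 1, size=n)
        hap1 = rng.random(n) < config.ratio_p
        idx = starts[:, None] + np.arange(rl)
        mat = np.where(hap1[:, None], truth.codes(1, contig)[idx],
                       truth.codes(2, contig)[idx]).astype(np.uint8)
        mat = _apply_errors(mat, config.error_rate, rng)
        for i in range(n):
            reads.append(SimRead(f"{prefix}{replicate}_{contig}_{i:07d}",
                                 contig, int(starts[i]),
                                 codes_to_seq(mat[i]), 1 if hap1[i] else 2))
    return ReadSet(reads, {c: len(s) for c, s in truth.haplotype1.items()})


def simulate_ddrad_reads(truth: NucleusMixtureTruth, predicted_fragments,
                         config: SimulationConfig, replicate: int = 0,
                         prefix: str = "rs") -> ReadSet:
    """ddRAD reads: sampled only from within predicted digest fragments.

    `predicted_fragments` are (contig, start, end) intervals from the digest
    stage run on the reference.  Positions outside every fragment receive
    zero coverage by construction.
    """
    config.validate()
    frags = [(f[0], int(f[1]), int(f[2])) for f in predicted_fragments]
    if not frags:
        raise ValueError("empty predicted-fragment list")
    rng = _rng(config, 3, replicate)
    rl = config.read_length
    reads: list[SimRead] = []
    i = 0
    for contig, start, end in frags:
        flen = end - start
        n = int(rng.poisson(config.ddrad_depth * flen / rl))
        if flen <= rl:
            starts = np.full(n, start)
            length = flen
        else:
            starts = rng.integers(start, end - rl + 1, size=n)
            length = rl
        hap1 = rng.random(n) < config.ratio_p
        for j in range(n):
            hap = 1 if hap1[j] else 2
            s = int(starts[j])
            mat = truth.codes(hap, contig)[s:s + length].copy()[None, :]
            mat = _apply_errors(mat, config.error_rate, rng)
            reads.append(SimRead(f"{prefix}{replicate}_{i:07d}", contig, s,
                                 codes_to_seq(mat[0]), hap))
            i += 1
    return ReadSet(reads, {c: len(s) for c, s in truth.haplotype1.items()})


@dataclass
class RnaSim:
    """RNA read simulation output with per-transcript truth."""

    reads: ReadSet
    transcriptome: dict[str, str]    # gene_id -> haplotype-1 transcript
    transcript_truth: pd.DataFrame   # per gene: reads, hap1 reads, flags
    snp_truth: pd.DataFrame          # per transcribed SNP: transcript coords

    def write_transcriptome(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.transcriptome.items():
                fh.write(f">{name}\n{seq}\n")


def gene_transcripts(truth: NucleusMixtureTruth, gene: GeneModel
                     ) -> tuple[str, str]:
    """The two transcript versions (genotype 1, genotype 2) of a gene."""
    t1 = truth.haplotype1[gene.contig][gene.start:gene.end]
    t2 = truth.haplotype2[gene.contig][gene.start:gene.end]
    if gene.strand == "-":
        t1, t2 = revcomp(t1), revcomp(t2)
    return t1, t2


def simulate_rna_reads(truth: NucleusMixtureTruth, config: SimulationConfig,
                       replicate: int = 0, prefix: str = "rna") -> RnaSim:
    """Stranded RNA reads expressed from both nucleus genotypes.

    Reads of a gene come from the genotype-1 transcript with probability
    ratio_p (or always, for genes flagged single-allele-expressed).  The
    emitted reference transcriptome carries one sequence per gene — the
    haplotype-1 version — standing in for an assembled-transcript reference.
    """
    config.validate()
    if not truth.gene_models:
        raise ValueError("no gene models to transcribe")
    rng = _rng(config, 4, replicate)
    rl = config.read_length
    reads: list[SimRead] = []
    transcriptome: dict[str, str] = {}
    trows = []
    srows = []
    n_genes = len(truth.gene_models)
    snps = truth.snp_table
    ridx = 0
    for gi, gene in enumerate(truth.gene_models):
        t1, t2 = gene_transcripts(truth, gene)
        transcriptome[gene.gene_id] = t1
        tl = len(t1)
        depth_g = config.rna_depth * truth.expression_levels[gi] * n_genes
        n = int(rng.poisson(depth_g * tl / rl))
        single = gene.gene_id in truth.single_allele_genes
        p1 = 1.0 if single else config.ratio_p
        hap1 = rng.random(n) < p1
        length = min(rl, tl)
        starts = (rng.integers(0, tl - length + 1, size=n) if tl > length
                  else np.zeros(n, dtype=int))
        c1, c2 = seq_to_codes(t1), seq_to_codes(t2)
        if n:
            idx = starts[:, None] + np.arange(length)
            mat = np.where(hap1[:, None], c1[idx], c2[idx]).astype(np.uint8)
            mat = _apply_errors(mat, config.error_rate, rng)
            for j in range(n):
                reads.append(SimRead(f"{prefix}{replicate}_{ridx:07d}",
                                     gene.gene_id, int(starts[j]),
                                     codes_to_seq(mat[j]),
                                     1 if hap1[j] else 2))
                ridx += 1
        trows.append((gene.gene_id, tl, n, int(hap1.sum()), single))
        here = snps[(snps.contig == gene.contig)
                    & (snps.position >= gene.start)
                    & (snps.position < gene.end)]
        for _, r in here.iterrows():
            if gene.strand == "+":
                tpos = int(r.position) - gene.start
                a1, a2 = r.allele1, r.allele2
            else:
                tpos = gene.end - 1 - int(r.position)
                a1, a2 = revcomp(r.allele1), revcomp(r.allele2)
            srows.append((gene.gene_id, gene.contig, int(r.position), tpos,
                          a1, a2, single))
    read_set = ReadSet(reads, {g: len(t) for g, t in transcriptome.items()})
    transcript_truth = pd.DataFrame(
        trows, columns=["gene_id", "length", "n_reads", "n_hap1",
                        "single_allele"])
    snp_truth = pd.DataFrame(
        srows, columns=["gene_id", "contig", "genome_pos", "transcript_pos",
                        "allele1", "allele2", "single_allele"])
    return RnaSim(read_set, transcriptome, transcript_truth, snp_truth)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_gff3(path, gene_models: list[GeneModel]) -> None:
    """GFF3 gene models (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.contig}\theterokaryon-synth\tgene\t{g.start + 1}\t"
                     f"{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def read_gff3_genes(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gid = dict(kv.split("=", 1) for kv in f[8].split(";")
                       if "=" in kv).get("ID", f"{f[0]}:{f[3]}")
            genes.append(GeneModel(f[0], int(f[3]) - 1, int(f[4]), f[6], gid))
    return genes


def write_bed(path, intervals) -> None:
    """BED (0-based half-open) intervals: (contig, start, end[, name])."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv[3] if len(iv) > 3 else "."
            fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\t{name}\n")


def read_bed(path):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
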