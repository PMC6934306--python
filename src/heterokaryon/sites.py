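"""Per-sample classification of genomic positions from read pileups.

Every position of every sample is classified as NA (depth < 10), mono-, bi-,
tri- or tetra-allelic: alleles are "recorded" when their frequency reaches
0.1 at a depth of at least 10x, and a multi-allelic call additionally
requires a phred-scaled site quality >= 30.  No allelic-ratio filter is
applied beyond the 0.1 frequency floor, because the analysis is interested
in *all* within-isolate polymorphism, whatever the nucleus-genotype ratio.

Site quality is a binomial-tail score playing the filtering role of a
variant caller's QUAL: q = -10*log10 P(X >= minor_count) with
X ~ Binomial(depth, error_rate/3), i.e. the chance that sequencing error
alone produces at least the observed minor-allele support.

The module also computes bi-allelic densities over predicted ddRAD regions,
allele-frequency distributions with coverage-threshold sweeps, region
coverage, and a heuristic flag for problematic assembly regions (N-run
neighbourhoods and abnormally deep windows) where mis-mapped reads create
spurious bi-alleles.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .seqmap import BASE_CODE

_BASE_ORDER = "ACGT"

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_FREQ = 0.1
DEFAULT_MIN_QUALITY = 30.0
DEFAULT_ERROR_RATE = 0.01
DEFAULT_MIN_BASE_QUALITY = 13

CLASS_NAMES = {0: "NA", 1: "mono", 2: "bi", 3: "tri", 4: "tetra"}


@dataclass
class SiteCall:
    """Classification of one position in one sample."""

    contig: str
    position: int
    depth: int
    allele_counts: dict[str, int]
    allele_freqs: dict[str, float]
    classification: str
    site_quality: float
    in_region: bool = False
    masked: bool = False
    coding: bool = False


@dataclass
class SiteArrays:
    """Vectorised per-contig site calls for a whole sample."""

    contig: str
    counts: np.ndarray          # (4, L) A/C/G/T substitution counts
    depth: np.ndarray           # (L,) counted bases
    classification: np.ndarray  # (L,) codes per CLASS_NAMES
    quality: np.ndarray         # (L,) binomial-tail phred score

    def biallelic_positions(self, extra_mask: np.ndarray | None = None
                            ) -> np.ndarray:
        sel = self.classification == 2
        if extra_mask is not None:
            sel &= extra_mask
        return np.flatnonzero(sel)

    def top2(self):
        """(freq1, freq2, allele1, allele2) arrays; count desc, base lex ties."""
        order = np.argsort(-self.counts, axis=0, kind="stable")
        a1, a2 = order[0], order[1]
        cols = np.arange(self.counts.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            f1 = np.where(self.depth > 0, self.counts[a1, cols] / self.depth, 0)
            f2 = np.where(self.depth > 0, self.counts[a2, cols] / self.depth, 0)
        return f1, f2, a1, a2

    def alleles_at(self, position: int) -> frozenset[str]:
        """Recorded alleles (freq >= 0.1) at a position, as base letters."""
        col = self.counts[:, position]
        depth = self.depth[position]
        if depth == 0:
            return frozenset()
        return frozenset(_BASE_ORDER[i] for i in range(4)
                         if col[i] / depth >= DEFAULT_MIN_FREQ and col[i] > 0)


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup_allele_counts(alignments, genome: dict[str, str],
                         min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
                         ) -> dict[str, np.ndarray]:
    """Per-position A/C/G/T counts from a SAM/BAM file.

    Counts aligned (match/mismatch) read bases with base quality >=
    `min_base_quality`; deletions, reference skips and bases adjacent to
    indels are excluded.  Returns {contig: (4, L) int array}.
    """
    counts = {c: np.zeros((4, len(s)), dtype=np.int32)
              for c, s in genome.items()}
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary):
                continue
            contig = read.reference_name
            if contig not in counts:
                raise ValueError(
                    f"alignment contig {contig!r} absent from genome")
            seq = read.query_sequence
            quals = read.query_qualities
            codes = BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            qarr = (np.asarray(quals, dtype=np.int16) if quals is not None
                    else np.full(len(seq), 255, dtype=np.int16))
            cig = read.cigartuples
            if len(cig) == 1 and cig[0][0] == 0:  # ungapped fast path
                qpos = np.arange(len(seq))
                rpos = read.reference_start + qpos
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
                bad = _indel_adjacent_query_positions(cig)
                pairs = [(q, r) for q, r in pairs if q not in bad]
                if not pairs:
                    continue
                qpos = np.fromiter((q for q, _ in pairs), dtype=np.int64)
                rpos = np.fromiter((r for _, r in pairs), dtype=np.int64)
            valid = (codes[qpos] < 4) & (qarr[qpos] >= min_base_quality)
            np.add.at(counts[contig], (codes[qpos[valid]], rpos[valid]), 1)
    return counts


def _indel_adjacent_query_positions(cigartuples) -> set[int]:
    bad: set[int] = set()
    q = 0
    for op, length in cigartuples:
        if op in (0, 7, 8):        # M/=/X consume query
            q += length
        elif op in (1, 4):         # I/S consume query
            if op == 1:
                bad.update((q - 1, q + length))
            q += length
        elif op == 2:              # D
            bad.update((q - 1, q))
    return bad


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def site_quality(minor_count, depth, error_rate: float = DEFAULT_ERROR_RATE):
    """Phred-scaled probability that error alone yields >= minor_count bases.

    q = -10*log10 P(X >= minor_count), X ~ Binomial(depth, error_rate/3),
    capped at 999.  Accepts scalars or arrays.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    minor = np.asarray(minor_count)
    n = np.asarray(depth)
    if np.any(minor < 0) or np.any(minor > n):
        raise ValueError("minor_count must satisfy 0 <= minor_count <= depth")
    p_tail = stats.binom.sf(minor - 1, n, error_rate / 3.0)
    with np.errstate(divide="ignore"):
        q = np.where(p_tail > 0, -10.0 * np.log10(p_tail), np.inf)
    q = np.minimum(q, 999.0)
    return float(q) if q.ndim == 0 else q


def classify_site(counts: dict[str, int], depth: int | None = None,
                  min_depth: int = DEFAULT_MIN_DEPTH,
                  min_freq: float = DEFAULT_MIN_FREQ,
                  min_quality: float = DEFAULT_MIN_QUALITY,
                  error_rate: float = DEFAULT_ERROR_RATE,
                  contig: str = "", position: int = 0) -> SiteCall:
    """Classify one position from its base counts (pure function).

    Frequencies are raw count/depth fractions (never renormalised over the
    recorded alleles).
    """
    depth = sum(counts.values()) if depth is None else depth
    if depth < min_depth:
        return SiteCall(contig, position, depth, dict(counts), {}, "NA", 0.0)
    freqs = {b: c / depth for b, c in counts.items() if c > 0}
    recorded = {b: c for b, c in counts.items()
                if c > 0 and c / depth >= min_freq}
    rec_freqs = {b: counts[b] / depth for b in recorded}
    if len(recorded) <= 1:
        return SiteCall(contig, position, depth, dict(counts), rec_freqs,
                        "mono", 0.0)
    second = sorted(recorded.values(), reverse=True)[1]
    q = site_quality(second, depth, error_rate)
    if q < min_quality:
        return SiteCall(contig, position, depth, dict(counts), rec_freqs,
                        "mono", q)
    name = CLASS_NAMES[min(len(recorded), 4)]
    return SiteCall(contig, position, depth, dict(counts), rec_freqs, name, q)


def classify_pileup(counts: np.ndarray, contig: str = "",
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    min_freq: float = DEFAULT_MIN_FREQ,
                    min_quality: float = DEFAULT_MIN_QUALITY,
                    error_rate: float = DEFAULT_ERROR_RATE) -> SiteArrays:
    """Vectorised classification of every position of a (4, L) count matrix."""
    counts = np.asarray(counts)
    depth = counts.sum(axis=0)
    L = counts.shape[1]
    cls = np.zeros(L, dtype=np.int8)
    quality = np.zeros(L, dtype=np.float64)
    covered = depth >= min_depth
    cls[covered] = 1
    if covered.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs = np.where(depth > 0, counts / depth, 0.0)
        n_rec = ((freqs >= min_freq) & (counts > 0)).sum(axis=0)
        srt = np.sort(counts, axis=0)            # ascending
        second = srt[-2]
        idx = covered & (n_rec >= 2)
        if idx.any():
            quality[idx] = site_quality(second[idx], depth[idx], error_rate)
            good = idx & (quality >= min_quality)
            cls[good] = np.minimum(n_rec[good], 4).astype(np.int8)
    return SiteArrays(contig, counts, depth, cls, quality)


def ingest_vcf(path, min_depth: int = DEFAULT_MIN_DEPTH,
               min_freq: float = DEFAULT_MIN_FREQ,
               min_quality: float = DEFAULT_MIN_QUALITY) -> list[SiteCall]:
    """SiteCalls from a pre-called VCF (SNP records only).

    Indel/MNP records are dropped, as are records below QUAL 30 or depth 10;
    alleles require frequency >= 0.1.  Per-allele depths are taken from AD
    (ref+alts) or RO/AO.
    """
    calls: list[SiteCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if rec.qual is None or rec.qual < min_quality:
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if any(len(a) != 1 or a not in "ACGT" for a in alleles):
                continue  # indels / MNPs / symbolic
            depths = _allele_depths(rec, len(alleles))
            if depths is None:
                continue
            depth = int(sum(depths))
            if depth < min_depth:
                continue
            counts = {a: int(d) for a, d in zip(alleles, depths)}
            call = classify_site(counts, depth=depth, min_depth=min_depth,
                                 min_freq=min_freq, min_quality=min_quality,
                                 contig=rec.chrom, position=rec.pos - 1)
            call.site_quality = float(rec.qual)
            calls.append(call)
    return calls


def _allele_depths(rec, n_alleles: int):
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is not None and len(ad) == n_alleles:
            return [d or 0 for d in ad]
        ro, ao = sample.get("RO"), sample.get("AO")
        if ro is not None and ao is not None:
            ao = ao if isinstance(ao, (tuple, list)) else (ao,)
            return [ro or 0] + [a or 0 for a in ao]
    return None


# ---------------------------------------------------------------------------
# densities, distributions, coverage
# ---------------------------------------------------------------------------

def biallelic_density(sites: SiteArrays, region_mask: np.ndarray,
                      repeat_mask: np.ndarray | None = None,
                      coding_mask: np.ndarray | None = None,
                      min_depth: int = DEFAULT_MIN_DEPTH):
    """Bi-allelic positions per kb of covered predicted-region territory.

    numerator: bi-allelic positions in non-masked, coding, predicted regions;
    denominator: positions there with depth >= 10.  Returns (density_per_kb,
    n_biallelic, n_covered); density is NaN when nothing is covered.
    """
    sel = region_mask.copy()
    if repeat_mask is not None:
        sel &= ~repeat_mask
    if coding_mask is not None:
        sel &= coding_mask
    num = int(((sites.classification == 2) & sel).sum())
    den = int(((sites.depth >= min_depth) & sel).sum())
    density = 1000.0 * num / den if den else math.nan
    return density, num, den


@dataclass
class FrequencyDistribution:
    """Allele-frequency values entering a density plot, plus its summaries."""

    sample_id: str
    threshold: int
    values: np.ndarray
    hist: np.ndarray                 # counts over 0.01-wide bins
    bin_edges: np.ndarray
    kde_grid: np.ndarray = field(default=None, repr=False)
    kde_density: np.ndarray = field(default=None, repr=False)

    def modal_bin_center(self) -> float:
        i = int(np.argmax(self.hist))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)


def frequency_distribution(sites: SiteArrays, min_depth_threshold: int,
                           sample_id: str = "", seed: int = 1,
                           extra_mask: np.ndarray | None = None
                           ) -> FrequencyDistribution:
    """One randomly chosen allele frequency per bi-allelic site.

    For each bi-allelic site with depth >= threshold, one of the two
    recorded allele frequencies is appended (seeded uniform choice), then a
    0.01-bin histogram and a Gaussian KDE are computed.
    """
    rng = np.random.default_rng(seed)
    sel = (sites.classification == 2) & (sites.depth >= min_depth_threshold)
    if extra_mask is not None:
        sel &= extra_mask
    f1, f2, _, _ = sites.top2()
    pick = rng.random(int(sel.sum())) < 0.5
    values = np.where(pick, f1[sel], f2[sel])
    edges = np.round(np.arange(0, 1.01 + 1e-9, 0.01), 2)
    hist, _ = np.histogram(values, bins=edges)
    grid = kde = None
    if len(values) >= 2 and np.std(values) > 0:
        grid = np.linspace(0, 1, 201)
        kde = stats.gaussian_kde(values)(grid)
    return FrequencyDistribution(sample_id, min_depth_threshold, values,
                                 hist, edges, grid, kde)


def region_coverage(depth: dict[str, np.ndarray], regions,
                    min_mean: float = 10.0):
    """Fraction of regions whose mean depth reaches `min_mean`.

    `regions` are (contig, start, end) intervals.  Returns (covered, total,
    fraction).
    """
    covered = 0
    total = 0
    for contig, start, end in (r[:3] for r in regions):
        total += 1
        if end > start and depth[contig][start:end].mean() >= min_mean:
            covered += 1
    return covered, total, (covered / total if total else math.nan)


def flag_problematic_regions(depth: dict[str, np.ndarray],
                             genome: dict[str, str], window: int = 100,
                             fold: float = 2.0):
    """Flag N-run neighbourhoods and abnormally deep windows.

    Flags (a) fixed windows whose mean depth exceeds `fold` times the
    genome-wide mean and (b) intervals within +-window of any run of Ns —
    the two signatures of assembly problems that concentrate mis-mapped
    reads and spurious 50:50 bi-alleles.  Returns merged intervals.
    """
    total = sum(int(d.sum()) for d in depth.values())
    length = sum(len(d) for d in depth.values())
    mean = total / length if length else 0.0
    flagged = []
    for contig, d in depth.items():
        for start in range(0, len(d), window):
            end = min(start + window, len(d))
            if mean > 0 and d[start:end].mean() > fold * mean:
                flagged.append((contig, start, end))
        for m in re.finditer(r"N+", genome[contig].upper()):
            flagged.append((contig, max(0, m.start() - window),
                            min(len(d), m.end() + window)))
    from .repeats import merge_intervals
    return merge_intervals(flagged)


def depth_from_counts(counts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {c: m.sum(axis=0) for c, m in counts.items()}


def calls_dataframe(sites: SiteArrays) -> pd.DataFrame:
    """Non-NA positions of a sample as a tidy table."""
    pos = np.flatnonzero(sites.classification > 0)
    f1, f2, a1, a2 = sites.top2()
    return pd.DataFrame({
        "contig": sites.contig,
        "position": pos,
        "depth": sites.depth[pos],
        "classification": [CLASS_NAMES[c] for c in
                           sites.classification[pos]],
        "quality": np.round(sites.quality[pos], 2),
        "allele1": [_BASE_ORDER[i] for i in a1[pos]],
        "allele2": [_BASE_ORDER[i] for i in a2[pos]],
        "freq1": np.round(f1[pos], 4),
        "freq2": np.round(f2[pos], 4),
    })
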