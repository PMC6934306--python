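"""End-to-end orchestration: digest -> repeats -> sites -> concord -> RNA.

`run_pipeline` drives the whole analysis from a configuration mapping and
writes versioned TSVs, plots and a run log; `make_demo` generates a small
seeded synthetic study (one heterokaryon, one homokaryon isolate) and runs
the pipeline on both, reproducing the headline contrast: the heterokaryon
shows a 0.5 allele-frequency peak and many RNA bi-alleles consistent with
the genome, the homokaryon almost none.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import bubbles as bub
from . import concord, digest, repeats, sites, synth

DEFAULT_PARAMS = {
    "k": 41,                # De Bruijn k-mer size
    "solidity": 2,          # k-mer count floor
    "min_depth": 10,
    "min_freq": 0.1,
    "min_quality": 30,
    "error_rate": 0.01,
    "min_fragment_length": 50,
    "repeat_identity": 0.80,
    "transcriptome_identity": 0.80,
    "genome_identity": 0.90,
    "mask_k": 15,
    "mask_threshold": 4,
    "freq_thresholds": [10, 20, 40, 60],
    "freq_seed": 1,
    "min_bubble_total": 6,
    "min_bubble_allele": 2,
    "qc_min_length": 50,
}


def _config_hash(config: dict) -> str:
    # outdir is excluded: rerunning one analysis elsewhere is the same run
    config = {k: v for k, v in config.items() if k != "outdir"}
    text = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, seed, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# heterokaryon seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _interval_masks(genome, regions, coding, repeat_intervals):
    masks = {}
    for contig, seq in genome.items():
        L = len(seq)
        region = synth._interval_mask(
            L, [(s, e) for c, s, e in (r[:3] for r in regions)
                if c == contig])
        cod = synth._interval_mask(
            L, [(s, e) for c, s, e in (r[:3] for r in coding) if c == contig])
        rep = synth._interval_mask(
            L, [(s, e) for c, s, e in (r[:3] for r in repeat_intervals)
                if c == contig])
        masks[contig] = (region, cod, rep)
    return masks


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns a summary dictionary.

    Required config keys: seed, outdir, genome (FASTA), gff (gene models).
    Optional: repeat_bed, samples.wg / samples.ddrad ({name: SAM path}),
    samples.rna ({name: FASTQ path}) with transcriptome (FASTA), params.
    """
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    seed = int(config.get("seed", 1))
    cfg_hash = _config_hash(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": seed, "config_hash": cfg_hash, "params": params,
                 "stages": {}}
    summary: dict = {}

    def stage(name):
        log["stages"][name] = {}
        return log["stages"][name]

    try:
        genome = _load_fasta(config["genome"])
        genes = synth.read_gff3_genes(config["gff"])
    except Exception as exc:
        raise PipelineError(f"stage=load inputs={config.get('genome')}: "
                            f"{exc}") from exc

    # --- digest ---
    st = stage("digest")
    frags = digest.predict_fragments(
        genome, min_length=params["min_fragment_length"])
    coding_iv = [(g.contig, g.start, g.end) for g in genes]
    regions = digest.anchor_fragments(frags, genome, coding_iv)
    st["fragments"] = len(frags)
    st["regions"] = len(regions)
    region_iv = [r.interval for r in regions]
    _write_tsv(pd.DataFrame(
        [(r.contig, r.start, r.end, r.flank5_enzyme, r.flank3_enzyme,
          r.coding_overlap) for r in regions],
        columns=["contig", "start", "end", "flank5", "flank3", "coding"]),
        outdir / "predicted_regions.tsv", seed, cfg_hash)

    # --- repeats ---
    st = stage("repeats")
    anchored_frags = [digest.Fragment(r.contig, r.start, r.end,
                                      r.flank5_enzyme, r.flank3_enzyme)
                      for r in regions]
    labels = repeats.label_fragments(anchored_frags, genome,
                                     min_identity=params["repeat_identity"])
    for i, labs in labels.items():
        regions[i].repeat_labels = labs
    if config.get("repeat_bed"):
        mask_iv = synth.read_bed(config["repeat_bed"])
    else:
        mask_iv = repeats.kmer_interspersed_mask(
            genome, k=params["mask_k"],
            multiplicity_threshold=params["mask_threshold"])
    repeat_iv = repeats.merge_intervals(
        list(mask_iv) + [regions[i].interval for i, labs in labels.items()
                         if "M03" in labs])
    st["labelled_m03"] = sum("M03" in l for l in labels.values())
    st["labelled_m07"] = sum("M07" in l for l in labels.values())
    st["labelled_m12"] = sum("M12" in l for l in labels.values())
    _write_tsv(pd.DataFrame(
        [(regions[i].contig, regions[i].start, regions[i].end,
          "M03" in labs, "M07" in labs, "M12" in labs)
         for i, labs in sorted(labels.items())],
        columns=["contig", "start", "end", "M03", "M07", "M12"]),
        outdir / "repeat_labels.tsv", seed, cfg_hash)
    masks = _interval_masks(genome, region_iv, coding_iv, repeat_iv)

    # --- site calls per sample ---
    st = stage("sites")
    samples = config.get("samples", {})
    sample_sites: dict[str, dict[str, sites.SiteArrays]] = {}
    density_rows = []
    freq_rows = []
    for group in ("wg", "ddrad"):
        for name, sam_path in (samples.get(group) or {}).items():
            counts = sites.pileup_allele_counts(sam_path, genome)
            per_contig = {}
            for contig, mat in counts.items():
                sa = sites.classify_pileup(
                    mat, contig, min_depth=params["min_depth"],
                    min_freq=params["min_freq"],
                    min_quality=params["min_quality"],
                    error_rate=params["error_rate"])
                per_contig[contig] = sa
            sample_sites[name] = per_contig
            st[name] = {c: int((sa.classification == 2).sum())
                        for c, sa in per_contig.items()}
            call_tables = [sites.calls_dataframe(sa)
                           for sa in per_contig.values()]
            _write_tsv(pd.concat(call_tables, ignore_index=True),
                       outdir / f"sites_{name}.tsv", seed, cfg_hash)
            for contig, sa in per_contig.items():
                region, cod, rep = masks[contig]
                dens, nbi, ncov = sites.biallelic_density(
                    sa, region, rep, cod, min_depth=params["min_depth"])
                density_rows.append((name, contig, nbi, ncov,
                                     round(dens, 4) if ncov else np.nan))
                for thr in params["freq_thresholds"]:
                    fd = sites.frequency_distribution(
                        sa, thr, sample_id=name, seed=params["freq_seed"],
                        extra_mask=~rep)
                    freq_rows.append((name, contig, thr, len(fd.values),
                                      fd.modal_bin_center()
                                      if len(fd.values) else np.nan))
    if density_rows:
        _write_tsv(pd.DataFrame(density_rows, columns=[
            "sample", "contig", "n_biallelic", "n_covered",
            "density_per_kb"]), outdir / "biallelic_density.tsv", seed,
            cfg_hash)
        _write_tsv(pd.DataFrame(freq_rows, columns=[
            "sample", "contig", "threshold", "n_sites", "modal_bin"]),
            outdir / "frequency_sweep.tsv", seed, cfg_hash)
        _plot_frequency_curves(sample_sites, masks, params, seed,
                               outdir / "allele_frequency_density.png")

    # --- concordance ---
    if len(sample_sites) >= 2:
        st = stage("concord")
        bi_sets = {}
        for name, per_contig in sample_sites.items():
            s = set()
            for contig, sa in per_contig.items():
                region, cod, rep = masks[contig]
                for p in sa.biallelic_positions(region & cod & ~rep):
                    s.add((contig, int(p)))
            bi_sets[name] = s
        part = concord.intersect_sets(bi_sets)
        _write_tsv(part.to_dataframe(), outdir / "overlap_partition.tsv",
                   seed, cfg_hash)
        _plot_partition(part, outdir / "overlap_partition.png")
        test_rows = []
        names = list(bi_sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                universe = _shared_universe(sample_sites[a], sample_sites[b],
                                            masks, params["min_depth"])
                K = len(bi_sets[a] & universe)
                n = len(bi_sets[b] & universe)
                x = len(bi_sets[a] & bi_sets[b] & universe)
                if min(K, n) == 0 or not universe:
                    continue
                t = concord.hypergeometric_overlap(len(universe), K, n, x)
                test_rows.append((a, b, t.universe, t.set_a, t.set_b,
                                  t.overlap, t.p_value))
        if test_rows:
            _write_tsv(pd.DataFrame(test_rows, columns=[
                "sample_a", "sample_b", "N", "K", "n", "x", "p_value"]),
                outdir / "overlap_tests.tsv", seed, cfg_hash)
        st["patterns"] = len(part.pattern_counts)
        summary["largest_pattern"] = (part.top_patterns(1)[0]
                                      if part.pattern_counts else None)

    # --- RNA bubbles + consistency ---
    rna_samples = samples.get("rna") or {}
    if rna_samples:
        st = stage("rna")
        transcriptome = _load_fasta(config["transcriptome"])
        t_index = bub.SequenceIndex(transcriptome)
        g_index = bub.SequenceIndex(genome)
        orfs = {tid: bub.find_best_orf(seq)
                for tid, seq in transcriptome.items()}
        wg_name = config.get("wg_reference_sample") or next(
            iter(samples.get("wg") or {}), None)
        for name, fq in rna_samples.items():
            reads = [s for s, _ in bub.qc_filter_reads(
                bub.read_fastq(fq), min_length=params["qc_min_length"])]
            graph = bub.build_graph(reads, k=params["k"],
                                    min_count=params["solidity"])
            found = bub.find_type0a_bubbles(graph)
            retained = bub.filter_bubbles(
                found, transcriptome, min_total=params["min_bubble_total"],
                min_per_allele=params["min_bubble_allele"],
                min_identity=params["transcriptome_identity"], index=t_index)
            bub.annotate_effects(retained, transcriptome, orfs)
            bub.bubble_genome_positions(
                retained, genome, min_identity=params["genome_identity"],
                index=g_index)
            st[name] = {"reads": len(reads), "bubbles": len(found),
                        "retained": len(retained)}
            _write_tsv(_bubble_table(retained),
                       outdir / f"bubbles_{name}.tsv", seed, cfg_hash)
            if wg_name:
                table = _consistency(retained, sample_sites[wg_name])
                _write_tsv(table, outdir / f"consistency_{name}.tsv",
                           seed, cfg_hash)
                n_cons, n_div = concord.consistency_totals(table)
                summary[f"consistency_{name}"] = {"consistent": n_cons,
                                                  "divergent": n_div}
                st[name]["consistent"] = n_cons
                st[name]["divergent"] = n_div
            _plot_rna_panel(retained, outdir / f"rna_panel_{name}.png")

    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    summary["log"] = log
    return summary


def _shared_universe(sites_a, sites_b, masks, min_depth):
    universe = set()
    for contig, sa in sites_a.items():
        sb = sites_b.get(contig)
        if sb is None:
            continue
        region, cod, rep = masks[contig]
        ok = (region & cod & ~rep & (sa.depth >= min_depth)
              & (sb.depth >= min_depth))
        universe.update((contig, int(p)) for p in np.flatnonzero(ok))
    return universe


def _consistency(retained, wg_per_contig):
    rna_sites = [(b.genome_hit[0], b.genome_hit[1], b.genome_alleles)
                 for b in retained if b.genome_hit is not None]

    def lookup(key):
        contig, pos = key
        sa = wg_per_contig.get(contig)
        if sa is None or not 0 <= pos < len(sa.classification):
            return "NA", frozenset()
        return (sites.CLASS_NAMES[int(sa.classification[pos])],
                sa.alleles_at(pos))

    return concord.rna_wg_consistency(rna_sites, lookup)


def _bubble_table(retained) -> pd.DataFrame:
    rows = []
    for b in retained:
        rows.append({
            "path_upper": b.path_upper, "path_lower": b.path_lower,
            "allele_upper": b.allele_upper, "allele_lower": b.allele_lower,
            "count_upper": b.count_upper, "count_lower": b.count_lower,
            "transcript": b.transcript_hit[0] if b.transcript_hit else "",
            "transcript_pos": (b.transcript_hit[1] + b.k - 1
                               if b.transcript_hit else -1),
            "effect": b.effect,
            "genome_contig": b.genome_hit[0] if b.genome_hit else "",
            "genome_pos": b.genome_hit[1] if b.genome_hit else -1,
            "flags": ",".join(sorted(b.ambiguity_flags)),
        })
    return pd.DataFrame(rows, columns=[
        "path_upper", "path_lower", "allele_upper", "allele_lower",
        "count_upper", "count_lower", "transcript", "transcript_pos",
        "effect", "genome_contig", "genome_pos", "flags"])


def _plot_frequency_curves(sample_sites, masks, params, seed, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, per_contig in sample_sites.items():
        for contig, sa in per_contig.items():
            _, _, rep = masks[contig]
            fd = sites.frequency_distribution(
                sa, params["min_depth"], sample_id=name,
                seed=params["freq_seed"], extra_mask=~rep)
            if fd.kde_grid is not None:
                ax.plot(fd.kde_grid, fd.kde_density, label=name)
    ax.set_xlabel("allele frequency at bi-allelic positions")
    ax.set_ylabel("density")
    if ax.lines:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_partition(part, path):
    top = part.top_patterns(15)
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = ["+".join(s for s, b in zip(part.sample_ids, pat) if b)
              if pat != ("rest",) else "rest" for pat, _ in top]
    ax.bar(range(len(top)), [c for _, c in top], color="0.3")
    ax.set_xticks(range(len(top)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("shared bi-allelic positions")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_rna_panel(retained, path):
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    fracs = [b.count_upper / b.total_count for b in retained
             if b.total_count > 0]
    axes[0].hist(fracs, bins=np.arange(0, 1.05, 0.05), color="0.3")
    axes[0].set_xlabel("allele frequency in bubbles")
    effects = pd.Series([b.effect for b in retained]).value_counts()
    axes[1].bar(effects.index, effects.values, color="0.5")
    axes[1].set_ylabel("bubbles")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# demo study
# ---------------------------------------------------------------------------

def demo_config(seed: int = 1) -> dict[str, synth.SimulationConfig]:
    """The packaged demo: one heterokaryon, one homokaryon isolate."""
    base = dict(genome_length=60_000, n_genes=20, gene_length=1500,
                n_snps=120, wg_depth=30.0, ddrad_depth=30.0, rna_depth=50.0,
                error_rate=0.005, expression_mode="uniform", seed=seed)
    return {
        "HET": synth.SimulationConfig(ratio_p=0.5, **base),
        "HOM": synth.SimulationConfig(ratio_p=1.0,
                                      **{**base, "n_snps": 0,
                                         "seed": seed + 1}),
    }


def make_demo(outdir, seed: int = 1, k: int = 41, run: bool = True) -> dict:
    """Write a seeded synthetic two-isolate study and (optionally) run it.

    Returns {isolate: pipeline summary}; with the default seed the
    heterokaryon yields a modal allele-frequency bin at 0.5 and a large
    consistent-bubble count, while the homokaryon yields almost none.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for isolate, cfg in demo_config(seed).items():
        d = outdir / isolate
        d.mkdir(exist_ok=True)
        genome, genes, repeat_iv = synth.simulate_genome(cfg)
        truth = synth.plant_heterokaryon_snps(genome, genes, repeat_iv, cfg)
        synth.write_fasta(d / "genome.fa", genome)
        synth.write_gff3(d / "genes.gff3", genes)
        synth.write_bed(d / "repeats.bed", repeat_iv)
        wg = synth.simulate_wg_reads(truth, cfg)
        wg.write_sam(d / "wg.sam")
        frags = digest.predict_fragments(genome)
        regions = digest.anchor_fragments(
            frags, genome, [(g.contig, g.start, g.end) for g in genes])
        rs = synth.simulate_ddrad_reads(truth, [r.interval for r in regions],
                                        cfg)
        rs.write_sam(d / "ddrad.sam")
        rna = synth.simulate_rna_reads(truth, cfg)
        rna.reads.write_fastq(d / "rna.fastq")
        rna.write_transcriptome(d / "transcriptome.fa")
        truth.snp_table.to_csv(d / "snp_truth.tsv", sep="\t", index=False)
        config = {
            "seed": cfg.seed,
            "outdir": str(d / "report"),
            "genome": str(d / "genome.fa"),
            "gff": str(d / "genes.gff3"),
            "transcriptome": str(d / "transcriptome.fa"),
            "samples": {
                "wg": {"WG1": str(d / "wg.sam")},
                "ddrad": {"RS1": str(d / "ddrad.sam")},
                "rna": {isolate: str(d / "rna.fastq")},
            },
            "params": {"k": k, "error_rate": cfg.error_rate},
        }
        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
        if run:
            results[isolate] = run_pipeline(config)
    return results
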