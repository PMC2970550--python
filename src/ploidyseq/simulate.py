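"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design: two replicate pairs of haploid
and tetraploid RNA-seq libraries (~9 million reads each at full scale)
drawn multinomially from a shared, heavy-tailed expression-frequency
profile, with a planted subset of fold-changed genes; plus a toy
annotated genome whose promoters carry planted motif sites at an
elevated rate in the planted genes.  A single seed determines every
output; all sub-generators derive independent streams from it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Feature, write_gff3
from .counts import CountTable, write_count_table
from .motifs import LogLikelihoodMatrix, extract_promoter, reverse_complement

ALPHABET = "ACGT"


@dataclass
class GenomeConfig:
    """Toy genome layout: one contig, alternating-strand genes."""

    gene_length: tuple[int, int] = (900, 1500)      # uniform bounds, bp
    intergenic_gap: tuple[int, int] = (200, 6000)   # some gaps exceed 5 kb
    overlapping_feature_every: int = 25  # plant a start-overlapping feature

    def __post_init__(self) -> None:
        if self.gene_length[0] < 1 or self.intergenic_gap[0] < 0:
            raise ValueError("infeasible genome packing parameters")


@dataclass
class MotifPlantConfig:
    motif_id: str = "MOTIF_1"
    plant_fraction: float = 0.8   # fraction of target promoters with a site
    background_rate: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.plant_fraction, self.background_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~9e6 reads/sample, two replicate pairs."""

    seed: int = 0
    n_genes: int = 6000
    depth_per_sample: int = 9_000_000
    freq_log_sd: float = 1.5
    n_de: int = 60
    fold_range: tuple[float, float] = (0.25, 4.0)
    n_replicate_pairs: int = 2
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    motif_plant: MotifPlantConfig = field(default_factory=MotifPlantConfig)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if min(self.fold_range) <= 0:
            raise ValueError("fold_range must exclude 0")
        if self.depth_per_sample < 1:
            raise ValueError("depth_per_sample must be positive")
        if self.freq_log_sd < 0:
            raise ValueError("freq_log_sd must be non-negative")


def _stream_seq(seed: int, *salt: int) -> np.random.Generator:
    """Independent deterministic substream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, *salt]))


def gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{str(i).zfill(width)}" for i in range(1, n_genes + 1)]


def simulate_frequency_profile(config: SimulationConfig) -> np.ndarray:
    """Heavy-tailed per-gene expression frequencies summing to 1.

    Log-normal shape: freq_log_sd is the standard deviation of
    log-expression before normalization; 0 gives a flat profile.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = _stream_seq(config.seed, 1)
    raw = np.exp(rng.normal(0.0, config.freq_log_sd, size=config.n_genes))
    return raw / raw.sum()


def default_de_spec(config: SimulationConfig) -> dict[str, float]:
    """Planted gene -> fold map: n_de genes alternating the two folds.

    The first planted gene gets fold_range[0] (repression in tetraploid),
    the next fold_range[1], and so on; planted genes are drawn without
    replacement from the gene universe.
    """
    rng = _stream_seq(config.seed, 2)
    ids = gene_ids(config.n_genes)
    chosen = rng.choice(config.n_genes, size=config.n_de, replace=False)
    lo, hi = config.fold_range
    return {
        ids[int(g)]: (lo if i % 2 == 0 else hi)
        for i, g in enumerate(sorted(chosen))
    }


def simulate_count_pair(
    freqs: np.ndarray,
    de_spec: Mapping[str, float],
    depths: tuple[int, int],
    seed: int,
    ids: Sequence[str] | None = None,
    pair_label: str = "A",
) -> tuple[CountTable, CountTable]:
    """One haploid/tetraploid library pair by multinomial sampling.

    Haploid counts ~ Multinomial(depth_h, freqs); tetraploid counts use
    the planted folds applied to the shared profile and renormalized, so
    library totals are exact.
    """
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("frequency profile must sum to 1")
    if ids is None:
        ids = gene_ids(len(freqs))
    index = {g: i for i, g in enumerate(ids)}
    folds = np.ones(len(freqs))
    for gene, fold in de_spec.items():
        if fold <= 0:
            raise ValueError(f"planted fold must be positive, got {fold}")
        if gene not in index:
            raise KeyError(f"planted fold for unknown gene {gene!r}")
        folds[index[gene]] = fold
    tet_freqs = freqs * folds
    tet_freqs = tet_freqs / tet_freqs.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    hap_counts = rng.multinomial(depths[0], freqs)
    tet_counts = rng.multinomial(depths[1], tet_freqs)
    hap = CountTable(
        sample_id=f"haploid_{pair_label}", ploidy="1n",
        counts={g: float(hap_counts[i]) for i, g in enumerate(ids)},
        library_total=int(depths[0]),
    )
    tet = CountTable(
        sample_id=f"tetraploid_{pair_label}", ploidy="4n",
        counts={g: float(tet_counts[i]) for i, g in enumerate(ids)},
        library_total=int(depths[1]),
    )
    return hap, tet


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[Feature]]:
    """Random contig with non-overlapping genes on alternating strands.

    Gaps follow the configured distribution, so some genes have upstream
    neighbors nearer than 5 kb and some farther.  Every
    ``overlapping_feature_every``-th gene also receives a small extra
    feature overlapping its coding start, to exercise the rule that such
    features are skipped when bounding promoters.
    """
    g = config.genome
    rng = _stream_seq(config.seed, 4)
    ids = gene_ids(config.n_genes)
    features: list[Feature] = []
    pos = int(rng.integers(g.intergenic_gap[0], g.intergenic_gap[1] + 1))
    for i, gid in enumerate(ids):
        length = int(rng.integers(g.gene_length[0], g.gene_length[1] + 1))
        strand = "+" if i % 2 == 0 else "-"
        features.append(Feature(gid, "chr1", pos, pos + length, strand))
        if g.overlapping_feature_every and i % g.overlapping_feature_every == 3:
            # small feature straddling this gene's coding start
            cs = pos if strand == "+" else pos + length - 1
            features.append(
                Feature(f"OVL_{gid}", "chr1", max(0, cs - 40), cs + 40,
                        "+", kind="misc_feature")
            )
        pos += length + int(
            rng.integers(g.intergenic_gap[0], g.intergenic_gap[1] + 1)
        )
    contig_len = pos + int(rng.integers(g.intergenic_gap[0],
                                        g.intergenic_gap[1] + 1))
    seq = "".join(
        np.array(list(ALPHABET))[rng.integers(0, 4, size=contig_len)]
    )
    return {"chr1": seq}, features


def plant_motif_sites(
    contigs: dict[str, str],
    annotation: Sequence[Feature],
    matrix: LogLikelihoodMatrix,
    target_genes: Sequence[str],
    config: SimulationConfig,
) -> tuple[dict[str, str], list[dict]]:
    """Overwrite promoter sequence with the motif consensus in place.

    Each target promoter receives a maximal-scoring site with probability
    ``plant_fraction``; every other promoter receives one at
    ``background_rate``.  The site lands at a random position on a random
    strand (a minus-strand insertion writes the reverse complement, which
    scores identically under the double-stranded scan).  Coordinates stay
    stable because the insertion overwrites rather than inserts.
    Returns the modified contigs and a log of insertions.
    """
    rng = _stream_seq(config.seed, 5)
    lengths = {c: len(s) for c, s in contigs.items()}
    mutable = {c: list(s) for c, s in contigs.items()}
    consensus = matrix.consensus
    target = set(target_genes)
    genes = [f for f in annotation if f.kind == "gene"]
    log: list[dict] = []
    for feat in sorted(genes, key=lambda f: f.feature_id):
        try:
            region = extract_promoter(feat.feature_id, annotation, lengths)
        except (KeyError, ValueError):
            if feat.feature_id in target:
                raise ValueError(
                    f"target gene {feat.feature_id!r} has no promoter"
                )
            continue
        rate = (config.motif_plant.plant_fraction
                if feat.feature_id in target
                else config.motif_plant.background_rate)
        if rng.random() >= rate:
            continue
        if region.length < matrix.width:
            raise ValueError(
                f"promoter of {feat.feature_id!r} shorter than motif width"
            )
        offset = int(rng.integers(0, region.length - matrix.width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = consensus if strand == "+" else reverse_complement(consensus)
        start = region.start + offset
        mutable[region.contig][start:start + matrix.width] = list(site)
        log.append(
            {"gene_id": feat.feature_id, "contig": region.contig,
             "position": start, "strand": strand,
             "planted": feat.feature_id in target}
        )
    return {c: "".join(s) for c, s in mutable.items()}, log


# ------------------------------------------------------------------ writers

def write_fasta(contigs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(contigs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_manifest(
    de_spec: Mapping[str, float],
    motif_log: Sequence[dict],
    path: str | os.PathLike,
) -> None:
    """Planted truth: gene, fold, motif site positions (if any)."""
    sites: dict[str, list[str]] = {}
    for entry in motif_log:
        sites.setdefault(entry["gene_id"], []).append(
            f"{entry['contig']}:{entry['position']}:{entry['strand']}"
        )
    genes = sorted(set(de_spec) | set(sites))
    with open(path, "w") as fh:
        fh.write("gene_id\tfold\tmotif_sites\n")
        for g in genes:
            fold = de_spec.get(g, "")
            fh.write(f"{g}\t{fold}\t{';'.join(sites.get(g, []))}\n")


def simulate_dataset(config: SimulationConfig, outdir: str | os.PathLike,
                     matrix: LogLikelihoodMatrix | None = None) -> dict:
    """Generate and write the complete synthetic study to ``outdir``.

    Count-table pairs, FASTA genome, GFF3 annotation, planted-truth
    manifest and the config itself (YAML).  Returns paths and in-memory
    objects for downstream use.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    freqs = simulate_frequency_profile(config)
    de_spec = default_de_spec(config)
    labels = [chr(ord("A") + i) for i in range(config.n_replicate_pairs)]
    pairs = []
    for i, label in enumerate(labels):
        pair = simulate_count_pair(
            freqs, de_spec,
            (config.depth_per_sample, config.depth_per_sample),
            seed=config.seed + 1000 * (i + 1),
            pair_label=label,
        )
        for table in pair:
            write_count_table(
                table, os.path.join(outdir, f"counts_{table.sample_id}.tsv")
            )
        pairs.append(pair)
    contigs, features = simulate_genome(config)
    motif_log: list[dict] = []
    if matrix is not None:
        # motif sites enriched in the planted repressed/induced genes
        contigs, motif_log = plant_motif_sites(
            contigs, features, matrix, sorted(de_spec), config
        )
    write_fasta(contigs, os.path.join(outdir, "genome.fasta"))
    write_gff3(features, os.path.join(outdir, "annotation.gff3"),
               {c: len(s) for c, s in contigs.items()})
    write_truth_manifest(de_spec, motif_log,
                         os.path.join(outdir, "truth.tsv"))
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return {
        "pairs": pairs,
        "de_spec": de_spec,
        "contigs": contigs,
        "features": features,
        "motif_log": motif_log,
        "outdir": outdir,
    }
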