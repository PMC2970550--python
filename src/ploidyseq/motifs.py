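"""Promoter motif enrichment with an adaptive score cutoff.

Promoters are defined per gene as the region extending 50 bp downstream
of the annotated coding start plus upstream sequence to the first
annotated feature (any ORF, Ty, tRNA, ... on either strand) or 5 kb,
whichever is nearer; features overlapping the coding start are skipped
when locating that boundary.

Motifs are width-W log-likelihood matrices over A,C,G,T with a positive
maximum score (the sum of per-position maxima); a window scoring zero
matches the background model exactly as well as the motif.  A promoter's
score is the best W-window sum over both strands.  Match cutoffs are
swept over {0.30, 0.35, ..., 1.00} x max_score; at each cutoff the motif
frequency in the query set is compared with the frequency in all genes
by a one-sided binomial test, and the cutoff with the smallest p wins.
Surviving motifs must have p <= 0.005, set frequency >= 25% and a
frequency fold change >= 1.5.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Feature

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_UPSTREAM = 5000
DOWNSTREAM = 50
CUTOFF_GRID = tuple(round(0.30 + 0.05 * i, 2) for i in range(15))

DEFAULT_P_THRESHOLD = 0.005
DEFAULT_MIN_SET_FREQUENCY = 0.25
DEFAULT_MIN_FOLD = 1.5


class NoSignalError(RuntimeError):
    """Every cutoff yields zero matches in both the set and background."""


@dataclass(frozen=True)
class LogLikelihoodMatrix:
    """Width x 4 log-likelihood scores over A,C,G,T."""

    motif_id: str
    scores: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"motif {self.motif_id!r}: empty matrix")
        if self.max_score <= 0:
            raise ValueError(
                f"motif {self.motif_id!r}: maximum score must be positive"
            )

    @property
    def width(self) -> int:
        return len(self.scores)

    @property
    def max_score(self) -> float:
        return float(sum(max(row) for row in self.scores))

    @property
    def consensus(self) -> str:
        """The per-position argmax base string (scores max_score exactly)."""
        return "".join(ALPHABET[int(np.argmax(row))] for row in self.scores)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)

    @classmethod
    def from_probabilities(
        cls, motif_id: str, probs: Sequence[Sequence[float]],
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudo: float = 1e-3,
    ) -> "LogLikelihoodMatrix":
        """Convert a position probability matrix to log-likelihood scores.

        Scores are natural-log likelihood ratios against ``background``
        (default uniform), preserving the property that a background-like
        window scores about zero.
        """
        p = np.asarray(probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probability matrix must be W x 4")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        p = (p + pseudo) / (p + pseudo).sum(axis=1, keepdims=True)
        bg = np.asarray(background, dtype=float)
        llr = np.log(p) - np.log(bg)
        return cls(motif_id, tuple(map(tuple, llr)))


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    contig: str
    start: int              # 0-based half-open
    end: int
    strand: str
    upstream_extent: int    # bases up to and including the coding start
    downstream_extent: int  # bases beyond the coding start (<= 50)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    cutoff_fraction: float
    set_matches: int
    set_size: int
    bg_matches: int
    bg_size: int
    p_binomial: float
    curve: list[tuple[float, int, int, float]] = field(default_factory=list)

    @property
    def set_frequency(self) -> float:
        return self.set_matches / self.set_size

    @property
    def bg_frequency(self) -> float:
        return self.bg_matches / self.bg_size

    @property
    def fold(self) -> float:
        if self.bg_matches == 0:
            return float("inf") if self.set_matches else 0.0
        return self.set_frequency / self.bg_frequency


def extract_promoter(
    gene_id: str,
    annotation: Sequence[Feature],
    contig_lengths: Mapping[str, int],
) -> PromoterRegion:
    """Promoter interval for one gene under the 50 bp / 5 kb / first-feature rules.

    The upstream extent runs from the coding start to the nearest edge of
    the closest feature lying strictly upstream, capped at 5 kb; features
    overlapping the coding start are skipped when locating that boundary.
    Minus-strand genes are mirrored; the interval is clipped to the
    contig.
    """
    by_id = {f.feature_id: f for f in annotation}
    if gene_id not in by_id:
        raise KeyError(f"gene {gene_id!r} not in annotation")
    gene = by_id[gene_id]
    clen = contig_lengths[gene.contig]
    cs = gene.coding_start
    if not 0 <= cs < clen:
        raise ValueError(f"gene {gene_id!r}: coding start outside contig")

    neighbors = [
        f for f in annotation
        if f.contig == gene.contig and f.feature_id != gene_id
        and not f.contains(cs)          # skip features overlapping the start
    ]
    # upstream_extent counts intergenic bases between the coding start and
    # the nearest upstream feature edge (capped at 5 kb); the 50 bp
    # downstream window starts at the coding-start base itself.
    if gene.strand == "+":
        edges = [f.end for f in neighbors if f.end <= cs]
        gap = cs - max(edges) if edges else MAX_UPSTREAM
        upstream = min(MAX_UPSTREAM, gap)
        start = max(0, cs - upstream)
        end = min(clen, cs + DOWNSTREAM)
        upstream = cs - start
        downstream = end - cs
    else:
        edges = [f.start for f in neighbors if f.start >= gene.end]
        gap = min(edges) - gene.end if edges else MAX_UPSTREAM
        upstream = min(MAX_UPSTREAM, gap)
        end = min(clen, gene.end + upstream)
        start = max(0, gene.end - DOWNSTREAM)
        upstream = end - gene.end
        downstream = gene.end - start
    if end <= start:
        raise ValueError(f"gene {gene_id!r}: empty promoter after clipping")
    return PromoterRegion(
        gene_id=gene_id, contig=gene.contig, start=start, end=end,
        strand=gene.strand, upstream_extent=upstream,
        downstream_extent=downstream,
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0..3; any non-ACGT base becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def _window_scores(score_table: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Scores of every W-window of ``idx`` under a (W, 5) score table."""
    w = score_table.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return score_table[np.arange(w), windows].sum(axis=1)


def best_match_score(matrix: LogLikelihoodMatrix, sequence: str) -> float:
    """Best W-window log-likelihood score over both strands.

    Ambiguous bases (N) score the per-position minimum, a conservative
    choice that cannot create a spurious match.
    """
    w = matrix.width
    if len(sequence) < w:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif width {w}"
        )
    fwd = matrix.as_array()
    # reverse-complement scan == scanning the same strand with the matrix
    # reversed position-wise and complemented base-wise
    rev = fwd[::-1, ::-1]
    idx = _encode(sequence)
    best = -np.inf
    for table in (fwd, rev):
        padded = np.column_stack([table, table.min(axis=1)])  # N column
        best = max(best, float(_window_scores(padded, idx).max()))
    return best


def call_matches(
    best_scores: Mapping[str, float],
    matrix: LogLikelihoodMatrix,
    cutoff_fraction: float,
) -> dict[str, bool]:
    """Gene -> whether its best score reaches cutoff x max_score (inclusive)."""
    if not 0.0 < cutoff_fraction <= 1.0:
        raise ValueError(f"cutoff_fraction must be in (0, 1], got "
                         f"{cutoff_fraction}")
    threshold = cutoff_fraction * matrix.max_score
    return {g: s >= threshold for g, s in best_scores.items()}


def binomial_motif_test(set_matches: int, set_size: int,
                        bg_rate: float) -> float:
    """Upper-tail P(X >= set_matches), X ~ Binomial(set_size, bg_rate)."""
    if not 0 <= set_matches <= set_size:
        raise ValueError(f"need 0 <= set_matches <= set_size, got "
                         f"{set_matches}/{set_size}")
    if not 0.0 <= bg_rate <= 1.0:
        raise ValueError(f"bg_rate must be in [0, 1], got {bg_rate}")
    if set_matches == 0:
        return 1.0
    return float(stats.binom.sf(set_matches - 1, set_size, bg_rate))


def optimize_cutoff(
    matrix: LogLikelihoodMatrix,
    set_scores: Mapping[str, float],
    bg_scores: Mapping[str, float],
    grid: Sequence[float] = CUTOFF_GRID,
) -> MotifEnrichmentResult:
    """Sweep the cutoff grid and keep the most significant point.

    Ties break toward the smaller cutoff; the full grid curve
    (cutoff, set matches, background matches, p) is retained.
    """
    if not set_scores or not bg_scores:
        raise ValueError("set and background score maps must be non-empty")
    set_vals = np.fromiter(set_scores.values(), dtype=float)
    bg_vals = np.fromiter(bg_scores.values(), dtype=float)
    curve: list[tuple[float, int, int, float]] = []
    best: tuple[float, float] | None = None  # (p, cutoff)
    best_point: tuple[float, int, int, float] | None = None
    any_matches = False
    for c in grid:
        threshold = c * matrix.max_score
        sm = int((set_vals >= threshold).sum())
        bm = int((bg_vals >= threshold).sum())
        any_matches = any_matches or sm > 0 or bm > 0
        p = binomial_motif_test(sm, len(set_vals), bm / len(bg_vals))
        curve.append((c, sm, bm, p))
        if best is None or p < best[0]:
            best = (p, c)
            best_point = curve[-1]
    if not any_matches:
        raise NoSignalError(
            f"motif {matrix.motif_id!r}: no matches at any cutoff"
        )
    c, sm, bm, p = best_point
    return MotifEnrichmentResult(
        motif_id=matrix.motif_id, cutoff_fraction=c,
        set_matches=sm, set_size=len(set_vals),
        bg_matches=bm, bg_size=len(bg_vals),
        p_binomial=p, curve=curve,
    )


def filter_motif_results(
    results: Iterable[MotifEnrichmentResult],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_set_frequency: float = DEFAULT_MIN_SET_FREQUENCY,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> list[MotifEnrichmentResult]:
    """Keep motifs with p <= 0.005, set frequency >= 25% and fold >= 1.5.

    All three bounds are inclusive.
    """
    return [
        r for r in results
        if r.p_binomial <= p_threshold
        and r.set_frequency >= min_set_frequency
        and r.fold >= min_fold
    ]


def scan_promoters(
    matrix: LogLikelihoodMatrix,
    promoter_seqs: Mapping[str, str],
) -> dict[str, float]:
    """Best-match score per gene; promoters shorter than W score -inf."""
    out = {}
    for gene, seq in promoter_seqs.items():
        if len(seq) < matrix.width:
            out[gene] = float("-inf")
        else:
            out[gene] = best_match_score(matrix, seq)
    return out


def extract_promoter_sequences(
    genes: Iterable[str],
    annotation: Sequence[Feature],
    contigs: Mapping[str, str],
) -> dict[str, str]:
    """Promoter sequences, reported 5'->3' on the gene's strand."""
    lengths = {name: len(seq) for name, seq in contigs.items()}
    out = {}
    for gene in genes:
        region = extract_promoter(gene, annotation, lengths)
        seq = contigs[region.contig][region.start:region.end]
        out[gene] = seq if region.strand == "+" else reverse_complement(seq)
    return out


def run_motif_enrichment(
    matrices: Sequence[LogLikelihoodMatrix],
    query_genes: Iterable[str],
    annotation: Sequence[Feature],
    contigs: Mapping[str, str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_set_frequency: float = DEFAULT_MIN_SET_FREQUENCY,
    min_fold: float = DEFAULT_MIN_FOLD,
    grid: Sequence[float] = CUTOFF_GRID,
) -> tuple[list[MotifEnrichmentResult], list[MotifEnrichmentResult]]:
    """End to end: promoters, scores, adaptive cutoff, filters.

    The background is every annotated gene with a valid promoter.
    Returns (all optimized results, results surviving the filters).
    """
    lengths = {name: len(seq) for name, seq in contigs.items()}
    bg_seqs = {}
    for feat in annotation:
        try:
            region = extract_promoter(feat.feature_id, annotation, lengths)
        except (KeyError, ValueError):
            continue
        seq = contigs[region.contig][region.start:region.end]
        bg_seqs[feat.feature_id] = (
            seq if region.strand == "+" else reverse_complement(seq)
        )
    query = [g for g in query_genes if g in bg_seqs]
    if not query:
        raise ValueError("no query gene has a valid promoter")
    all_results = []
    for matrix in matrices:
        bg_scores = scan_promoters(matrix, bg_seqs)
        set_scores = {g: bg_scores[g] for g in query}
        try:
            all_results.append(optimize_cutoff(matrix, set_scores, bg_scores,
                                               grid=grid))
        except NoSignalError:
            continue
    kept = filter_motif_results(all_results, p_threshold, min_set_frequency,
                                min_fold)
    return all_results, kept


# ---------------------------------------------------------------- motif I/O

def read_motifs_tsv(path: str | os.PathLike) -> list[LogLikelihoodMatrix]:
    """Read motif matrices from a simple TSV block format.

    Each block::

        >MOTIF_ID llr        (or "prob" for probability matrices)
        0.1<TAB>0.2<TAB>0.3<TAB>0.4    # one row per position, A C G T

    Probability matrices are converted to log-likelihood scores against
    a uniform background.
    """
    blocks: list[tuple[str, str, list[list[float]]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                kind = parts[1] if len(parts) > 1 else "llr"
                blocks.append((parts[0], kind, []))
            else:
                if not blocks:
                    raise ValueError("matrix row before any >motif header")
                blocks[-1][2].append([float(x) for x in line.split("\t")])
    out = []
    for motif_id, kind, rows in blocks:
        if kind == "prob":
            out.append(LogLikelihoodMatrix.from_probabilities(motif_id, rows))
        elif kind == "llr":
            out.append(LogLikelihoodMatrix(motif_id, tuple(map(tuple, rows))))
        else:
            raise ValueError(f"motif {motif_id!r}: unknown matrix type "
                             f"{kind!r}")
    return out


def read_motifs_meme(path: str | os.PathLike) -> list[LogLikelihoodMatrix]:
    """Read MEME minimal-format motifs (probability matrices)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        probs = [[m.pwm[b][i] for b in ALPHABET] for i in range(m.length)]
        out.append(LogLikelihoodMatrix.from_probabilities(m.name, probs))
    return out


def write_motif_results(
    results: Iterable[MotifEnrichmentResult], path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tcutoff_fraction\tset_matches\tset_size\t"
                 "bg_matches\tbg_size\tset_frequency\tbg_frequency\t"
                 "fold\tp_binomial\n")
        for r in results:
            fh.write(
                f"{r.motif_id}\t{r.cutoff_fraction:.2f}\t{r.set_matches}\t"
                f"{r.set_size}\t{r.bg_matches}\t{r.bg_size}\t"
                f"{r.set_frequency:.4f}\t{r.bg_frequency:.4f}\t"
                f"{r.fold:.3f}\t{r.p_binomial:.3g}\n"
            )


def write_motif_curves(
    results: Iterable[MotifEnrichmentResult], path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tcutoff_fraction\tset_matches\tbg_matches\tp\n")
        for r in results:
            for c, sm, bm, p in r.curve:
                fh.write(f"{r.motif_id}\t{c:.2f}\t{sm}\t{bm}\t{p:.3g}\n")
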