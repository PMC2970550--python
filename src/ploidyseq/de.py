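"""Differential expression without replicates: reciprocal binomial tails.

For each gene with haploid count :math:`k_h` (library total :math:`N_h`)
and tetraploid count :math:`k_t` (total :math:`N_t`) the caller computes
two one-sided binomial tail probabilities:

* the tetraploid observation under the haploid frequency,
  :math:`X \\sim \\mathrm{Binom}(N_t, k_h/N_h)` — lower tail
  :math:`P(X \\le k_t)` if the tetraploid frequency is below the haploid
  one, upper tail otherwise;
* the reciprocal: the haploid observation under the tetraploid frequency,
  with the opposite tail direction.

A gene is a candidate when it is expressed (count >= 15 in at least one
sample of the pair) and BOTH reciprocal p-values fall below alpha
(default 0.001).  Candidates are ranked by frequency fold change
(tetraploid/haploid), repressed ascending and induced descending.  Two
replicate pairs are then combined by intersecting equal numbers of
top-ranking candidates; the overlap's significance is a hypergeometric
upper tail over the expressed background, and the top-N is chosen as the
largest grid value keeping that tail below ``p_max`` (default 1e-10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .counts import CountTable, filter_expressed

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_COUNT = 15.0
DEFAULT_P_MAX = 1e-10
DEFAULT_TOP_N_GRID = tuple(range(10, 201, 10))

REPRESSED = "repressed-in-tetraploid"
INDUCED = "induced-in-tetraploid"


class ReplicatesInconsistentError(RuntimeError):
    """No top-N grid value yields a significant replicate overlap."""


def binomial_cmf(k: int, n: int, f: float) -> float:
    """P(X <= k) for X ~ Binomial(n, f) (the CMF of the binomial model).

    Evaluated through the regularized incomplete beta function, so it is
    stable for n up to at least 1e8.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {f}")
    return float(stats.binom.cdf(k, n, f))


def _binomial_upper(k: int, n: int, f: float) -> float:
    """P(X >= k); the survival function shifted by one."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, f))


def reciprocal_pvalues(k_h: int, n_h: int, k_t: int,
                       n_t: int) -> tuple[float, float]:
    """One-sided tail probabilities in both directions.

    Returns ``(p_t_given_h, p_h_given_t)``.  The tail is chosen by the
    observed direction: when the tetraploid frequency is at or below the
    haploid one, ``p_t_given_h`` is the lower tail of the tetraploid count
    under Binomial(N_t, f_h) and ``p_h_given_t`` the upper tail of the
    haploid count under Binomial(N_h, f_t); directions swap otherwise.
    A zero reference frequency gives P(X <= k | f=0) = 1 and
    P(X >= k | f=0) = 0 for k > 0.
    """
    if n_h <= 0 or n_t <= 0:
        raise ValueError("library totals must be positive")
    if k_h > n_h or k_t > n_t:
        raise ValueError("counts cannot exceed their library totals")
    if k_h < 0 or k_t < 0:
        raise ValueError("counts must be non-negative")
    f_h = k_h / n_h
    f_t = k_t / n_t
    if f_t <= f_h:
        p_t_given_h = binomial_cmf(k_t, n_t, f_h)
        p_h_given_t = _binomial_upper(k_h, n_h, f_t)
    else:
        p_t_given_h = _binomial_upper(k_t, n_t, f_h)
        p_h_given_t = binomial_cmf(k_h, n_h, f_t)
    return p_t_given_h, p_h_given_t


def fold_change(k_h: float, n_h: int, k_t: float, n_t: int,
                pseudocount: float = 0.5) -> float:
    """Frequency fold change (tetraploid/haploid).

    The pseudocount replaces a zero count (only) so the ratio stays
    finite; it is used for ranking only, never for p-values.
    """
    if n_h <= 0 or n_t <= 0:
        raise ValueError("library totals must be positive")
    num = (k_t if k_t > 0 else pseudocount) / n_t
    den = (k_h if k_h > 0 else pseudocount) / n_h
    return num / den


@dataclass(frozen=True)
class DEGeneRecord:
    gene_id: str
    k_h: float
    k_t: float
    f_h: float
    f_t: float
    fold: float
    p_t_given_h: float
    p_h_given_t: float
    direction: str | None
    passes: bool


@dataclass
class OverlapSelection:
    top_n: int
    candidates_a: list[str]
    candidates_b: list[str]
    overlap: list[str]
    population_size: int
    p_overlap: float
    curve: list[tuple[int, int, float]] = field(default_factory=list)


def _vector_reciprocal(k_h: np.ndarray, n_h: int, k_t: np.ndarray,
                       n_t: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized reciprocal_pvalues over gene arrays of integer counts."""
    f_h = k_h / n_h
    f_t = k_t / n_t
    lower_t = stats.binom.cdf(k_t, n_t, f_h)
    upper_t = np.where(k_t > 0, stats.binom.sf(k_t - 1, n_t, f_h), 1.0)
    lower_h = stats.binom.cdf(k_h, n_h, f_t)
    upper_h = np.where(k_h > 0, stats.binom.sf(k_h - 1, n_h, f_t), 1.0)
    down = f_t <= f_h
    p_t_given_h = np.where(down, lower_t, upper_t)
    p_h_given_t = np.where(down, upper_h, lower_h)
    return p_t_given_h, p_h_given_t


def score_pair(
    haploid: CountTable,
    tetraploid: CountTable,
    pseudocount: float = 0.5,
) -> list[DEGeneRecord]:
    """Per-gene reciprocal p-values and fold changes for one sample pair.

    Fractional counts (1/n multi-map weights) are floored to integers for
    the binomial model, which is defined on integer counts; the fold
    change uses the unfloored values.
    """
    genes = sorted(set(haploid.counts) & set(tetraploid.counts))
    if not genes:
        raise ValueError("count tables share no genes")
    kh_raw = np.array([haploid.counts[g] for g in genes])
    kt_raw = np.array([tetraploid.counts[g] for g in genes])
    kh = np.floor(kh_raw).astype(np.int64)
    kt = np.floor(kt_raw).astype(np.int64)
    n_h = haploid.library_total
    n_t = tetraploid.library_total
    p_th, p_ht = _vector_reciprocal(kh, n_h, kt, n_t)
    f_h = kh / n_h
    f_t = kt / n_t
    out = []
    for i, g in enumerate(genes):
        if f_t[i] < f_h[i]:
            direction = REPRESSED
        elif f_t[i] > f_h[i]:
            direction = INDUCED
        else:
            direction = None
        out.append(
            DEGeneRecord(
                gene_id=g,
                k_h=float(kh_raw[i]),
                k_t=float(kt_raw[i]),
                f_h=float(f_h[i]),
                f_t=float(f_t[i]),
                fold=fold_change(kh_raw[i], n_h, kt_raw[i], n_t, pseudocount),
                p_t_given_h=float(p_th[i]),
                p_h_given_t=float(p_ht[i]),
                direction=direction,
                passes=False,  # set by call_candidates
            )
        )
    return out


def call_candidates(
    haploid: CountTable,
    tetraploid: CountTable,
    alpha: float = DEFAULT_ALPHA,
    min_count: float = DEFAULT_MIN_COUNT,
    pseudocount: float = 0.5,
) -> tuple[list[DEGeneRecord], list[DEGeneRecord]]:
    """Ranked (repressed, induced) candidate lists for one sample pair.

    A gene passes when it is expressed (count >= ``min_count`` in either
    sample) and both reciprocal p-values are below ``alpha``.  Repressed
    genes are ranked by ascending fold change, induced by descending;
    ties break lexicographically on gene id.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    records = score_pair(haploid, tetraploid, pseudocount=pseudocount)
    expressed = set(filter_expressed([haploid, tetraploid], min_count))
    repressed: list[DEGeneRecord] = []
    induced: list[DEGeneRecord] = []
    for rec in records:
        passes = (
            rec.gene_id in expressed
            and rec.p_t_given_h < alpha
            and rec.p_h_given_t < alpha
            and rec.direction is not None
        )
        if not passes:
            continue
        rec = DEGeneRecord(**{**rec.__dict__, "passes": True})
        (repressed if rec.direction == REPRESSED else induced).append(rec)
    repressed.sort(key=lambda r: (r.fold, r.gene_id))
    induced.sort(key=lambda r: (-r.fold, r.gene_id))
    return repressed, induced


def combined_ranking(
    repressed: Sequence[DEGeneRecord],
    induced: Sequence[DEGeneRecord],
) -> list[DEGeneRecord]:
    """Optional single ranking of both directions by |log2 fold|, descending."""
    return sorted(
        list(repressed) + list(induced),
        key=lambda r: (-abs(math.log2(r.fold)), r.gene_id),
    )


def overlap_significance(m: int, n_a: int, n_b: int, population: int) -> float:
    """P(|A ∩ B| >= m) for uniform random subsets of sizes n_a, n_b.

    Hypergeometric upper tail: draw n_a marked items among ``population``,
    then the overlap with an independent size-n_b subset is
    Hypergeometric(population, n_a, n_b).
    """
    if not (0 <= m <= min(n_a, n_b)) or n_a > population or n_b > population:
        raise ValueError(
            f"inconsistent sizes: m={m}, n_a={n_a}, n_b={n_b}, "
            f"population={population}"
        )
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, population, n_a, n_b))


def overlap_top_candidates(
    list_a: Sequence[str],
    list_b: Sequence[str],
    top_n: int,
    population: int,
) -> OverlapSelection:
    """Intersect the first ``top_n`` entries of two ranked gene lists."""
    if top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    if top_n > min(len(list_a), len(list_b)):
        raise ValueError(
            f"top_n={top_n} exceeds a candidate list "
            f"({len(list_a)}, {len(list_b)})"
        )
    head_a = list(list_a[:top_n])
    head_b = list(list_b[:top_n])
    overlap = sorted(set(head_a) & set(head_b))
    p = overlap_significance(len(overlap), top_n, top_n, population)
    return OverlapSelection(
        top_n=top_n,
        candidates_a=head_a,
        candidates_b=head_b,
        overlap=overlap,
        population_size=population,
        p_overlap=p,
    )


def select_top_n(
    list_a: Sequence[str],
    list_b: Sequence[str],
    population: int,
    p_max: float = DEFAULT_P_MAX,
    grid: Iterable[int] = DEFAULT_TOP_N_GRID,
) -> OverlapSelection:
    """Largest grid top-N whose replicate overlap stays significant.

    Evaluates every feasible grid value, records the (top_n, overlap
    size, p) curve, and returns the selection at the largest top_n with
    ``p_overlap < p_max``.  Raises :class:`ReplicatesInconsistentError`
    when no grid value qualifies.
    """
    grid = sorted({n for n in grid if n > 0})
    if not grid:
        raise ValueError("top-N grid is empty")
    limit = min(len(list_a), len(list_b))
    curve: list[tuple[int, int, float]] = []
    best: OverlapSelection | None = None
    for n in grid:
        if n > limit:
            break
        sel = overlap_top_candidates(list_a, list_b, n, population)
        curve.append((n, len(sel.overlap), sel.p_overlap))
        if sel.p_overlap < p_max:
            best = sel
    if best is None:
        raise ReplicatesInconsistentError(
            f"no top-N in {grid} (limit {limit}) reaches overlap "
            f"p < {p_max}; replicates look inconsistent"
        )
    best.curve = curve
    return best


def summarize_de(
    genes: Sequence[str],
    pairs: Sequence[tuple[CountTable, CountTable]],
    pseudocount: float = 0.5,
    ascending: bool = True,
) -> list[dict]:
    """Mean ± SD of fold change per gene across replicate pairs.

    SD is the sample standard deviation (ddof=1); with a single pair it
    is reported as 0.0 with ``sd_defined=False``.  Sorted by mean fold
    (ascending for repressed lists, descending for induced), ties broken
    by gene id.
    """
    rows = []
    for gene in genes:
        folds = []
        for hap, tet in pairs:
            if gene not in hap.counts or gene not in tet.counts:
                raise KeyError(f"gene {gene!r} missing from a sample pair")
            folds.append(
                fold_change(hap.counts[gene], hap.library_total,
                            tet.counts[gene], tet.library_total, pseudocount)
            )
        mean = float(np.mean(folds))
        if len(folds) > 1:
            sd, sd_defined = float(np.std(folds, ddof=1)), True
        else:
            sd, sd_defined = 0.0, False
        rows.append(
            {"gene_id": gene, "mean_fold": mean, "sd_fold": sd,
             "n_pairs": len(folds), "sd_defined": sd_defined}
        )
    rows.sort(key=lambda r: (r["mean_fold"] if ascending else -r["mean_fold"],
                             r["gene_id"]))
    return rows


def run_de_pipeline(
    pairs: Sequence[tuple[CountTable, CountTable]],
    alpha: float = DEFAULT_ALPHA,
    min_count: float = DEFAULT_MIN_COUNT,
    p_max: float = DEFAULT_P_MAX,
    top_n_grid: Iterable[int] = DEFAULT_TOP_N_GRID,
    pseudocount: float = 0.5,
) -> dict:
    """Whole two-replicate procedure: per-pair calls, overlap, summaries.

    Requires exactly two replicate pairs (the overlap construction is
    pairwise).  Returns a dict with per-pair candidate lists, the
    repressed/induced overlap selections, the background size, and the
    per-direction mean-fold summaries.  When a direction's replicate
    overlap never reaches ``p_max`` significance, its final list is
    empty and the selection is None.
    """
    pairs = list(pairs)
    if len(pairs) != 2:
        raise ValueError(
            f"the overlap procedure needs exactly 2 replicate pairs, "
            f"got {len(pairs)}"
        )
    all_tables = [t for pair in pairs for t in pair]
    background = filter_expressed(all_tables, min_count)
    per_pair = [
        call_candidates(hap, tet, alpha=alpha, min_count=min_count,
                        pseudocount=pseudocount)
        for hap, tet in pairs
    ]
    result: dict = {
        "background": background,
        "per_pair": per_pair,
        "alpha": alpha,
        "min_count": min_count,
        "p_max": p_max,
    }
    for idx, direction in ((0, "repressed"), (1, "induced")):
        ids_a = [r.gene_id for r in per_pair[0][idx]]
        ids_b = [r.gene_id for r in per_pair[1][idx]]
        try:
            sel = select_top_n(ids_a, ids_b, population=len(background),
                               p_max=p_max, grid=top_n_grid)
            final = sel.overlap
        except ReplicatesInconsistentError:
            sel, final = None, []
        result[f"selection_{direction}"] = sel
        result[f"final_{direction}"] = summarize_de(
            final, pairs, pseudocount=pseudocount,
            ascending=(direction == "repressed"),
        )
    return result
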