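"""Hypergeometric gene-set enrichment against an expressed background.

Given a query gene list (e.g. the final differentially expressed set)
and a collection of flat gene sets (GO compartment terms, pathway sets)
restricted to the expressed-gene background, each term is scored with
the hypergeometric upper tail: the probability of drawing at least the
observed number of term members in a random query of the same size.
Raw p-values are reported alongside a Bonferroni correction over the
number of terms tested; term assignments are consumed as pre-propagated
flat sets (no ontology DAG handling).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

logger = logging.getLogger(__name__)


def hypergeometric_tail(a: int, n: int, K: int, N: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n).

    ``a`` term members in the query, ``n`` query size, ``K`` term members
    in the background, ``N`` background size.  Computed through scipy's
    log-space survival function; stable for N up to at least 1e5.
    """
    if N < 0 or not (0 <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"inconsistent margins: n={n}, K={K}, N={N}")
    if not 0 <= a <= min(n, K):
        raise ValueError(f"need 0 <= a <= min(n, K): a={a}, n={n}, K={K}")
    if a == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, N, K, n))


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    namespace: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Term -> gene-set map over a declared background universe.

    On construction every term is restricted to the background; terms
    left empty are dropped.
    """

    background: frozenset[str]
    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background gene set is empty")
        restricted = {}
        for tid, gs in self.terms.items():
            genes = frozenset(gs.genes & self.background)
            if genes:
                restricted[tid] = GeneSet(gs.term_id, gs.name, gs.namespace,
                                          genes)
        self.terms = restricted

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    namespace: str
    cluster_count: int      # a: term members in the query
    query_size: int         # n
    background_count: int   # K: term members in the background
    background_size: int    # N
    p_raw: float
    p_bonferroni: float

    @property
    def cluster_frequency(self) -> float:
        return self.cluster_count / self.query_size

    @property
    def background_frequency(self) -> float:
        return self.background_count / self.background_size


def enrich(query: Iterable[str],
           collection: GeneSetCollection) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of a query list over the background.

    Query genes outside the background are dropped with a logged
    warning.  One row per term with at least one query member, sorted by
    raw p ascending (ties by term id); Bonferroni multiplies by the
    number of terms tested, capped at 1.
    """
    query_set = set(query)
    outside = query_set - collection.background
    if outside:
        logger.warning(
            "dropping %d query genes outside the background: %s",
            len(outside), ", ".join(sorted(outside)[:5]),
        )
        query_set -= outside
    n = len(query_set)
    N = len(collection.background)
    n_tested = len(collection.terms)
    rows = []
    for tid, gs in collection.terms.items():
        a = len(query_set & gs.genes)
        if a == 0:
            continue
        p = hypergeometric_tail(a, n, len(gs.genes), N)
        rows.append(
            EnrichmentRow(
                term_id=tid, name=gs.name, namespace=gs.namespace,
                cluster_count=a, query_size=n,
                background_count=len(gs.genes), background_size=N,
                p_raw=p, p_bonferroni=min(1.0, p * n_tested),
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def read_gmt(path: str | os.PathLike, background: Iterable[str],
             namespace: str = "") -> GeneSetCollection:
    """Read gene sets from GMT (term, description, genes...)."""
    terms: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            tid, desc, genes = cols[0], cols[1], cols[2:]
            if tid in terms:
                raise ValueError(f"duplicate term id {tid!r}")
            terms[tid] = GeneSet(tid, desc or tid, namespace,
                                 frozenset(g for g in genes if g))
    return GeneSetCollection(background=frozenset(background), terms=terms)


def read_term_tsv(path: str | os.PathLike, background: Iterable[str],
                  namespace: str = "") -> GeneSetCollection:
    """Read term assignments from a two-column TSV (term_id, gene_id)."""
    assign: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, gene = line.split("\t")[:2]
            assign.setdefault(tid, set()).add(gene)
    terms = {tid: GeneSet(tid, tid, namespace, frozenset(genes))
             for tid, genes in assign.items()}
    return GeneSetCollection(background=frozenset(background), terms=terms)


def write_enrichment_table(rows: Iterable[EnrichmentRow],
                           path: str | os.PathLike) -> None:
    """TSV mirroring the cluster/background frequency report layout."""
    with open(path, "w") as fh:
        fh.write("term_id\tname\tnamespace\tcluster_frequency\t"
                 "background_frequency\tp_raw\tp_bonferroni\n")
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.namespace}\t"
                f"{r.cluster_count}/{r.query_size} "
                f"({100 * r.cluster_frequency:.1f}%)\t"
                f"{r.background_count}/{r.background_size} "
                f"({100 * r.background_frequency:.1f}%)\t"
                f"{r.p_raw:.3g}\t{r.p_bonferroni:.3g}\n"
            )
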