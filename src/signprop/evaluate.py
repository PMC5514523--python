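"""Leave-one-out rank experiments, AUC estimators, baselines, stratification.

Every prediction is one leave-one-out trial: hold out a (unit, gene)
association, seed the prioritizer with the unit's remaining genes, and
record the rank r of the held-out gene among the M non-seed network nodes.
The rank-based AUC is the mean over trials of (M - r) / (M - 1): the
probability that the held-out gene outranks a uniformly drawn negative,
i.e. the Mann-Whitney statistic of the pooled ROC.

Censoring: a DIAMOnD trial whose gene was not absorbed within the iteration
cap has a rank only known to exceed the cap.  Censored trials are excluded
from AUC (their count is reported) and count as misses in top-k curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotate import SignPanel, classify_diseases
from .diamond import diamond_expand, diamond_rank
from .io import AssociationSet, GeneNetwork, NormalizedAdjacency, Ontology, normalize_adjacency
from .rwr import PropagationConfig, SeedVector, rwr_scores, rwr_scores_batch, rwr_rank

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "EvaluationSummary",
    "loo_sign_predictions",
    "loo_disease_predictions",
    "direct_oligogenic_predictions",
    "auc_from_ranks",
    "filter_censored",
    "topk_curve",
    "fpr_at_rank",
    "random_baseline",
    "best_sign_upper_bound",
    "stratify",
    "summarize",
    "write_records",
    "read_records",
    "write_summaries",
]

STRATIFY_FACTORS = (
    "ploidy",
    "inheritance",
    "onset",
    "progression",
    "frequency",
    "sign_class",
    "gene_function",
)


@dataclass(frozen=True)
class PredictionRecord:
    """One leave-one-out trial."""

    unit: str
    unit_kind: str  # sign | disease | random | function_term
    test_gene: str
    method: str  # rwr | diamond
    rank: int
    censored: bool
    M: int
    seed_size: int
    disease_context: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.censored and not 1 <= self.rank <= self.M:
            raise ValueError(
                f"rank {self.rank} outside [1, M={self.M}] for {self.unit}/{self.test_gene}"
            )


@dataclass
class EvaluationSummary:
    """Pooled AUC and top-k recovery for one group of trials."""

    group: str
    n_pairs: int
    auc: float
    n_censored: int = 0
    topk: dict[int, float] = field(default_factory=dict)
    per_set_auc: list[float] | None = None


# ---------------------------------------------------------------------------
# Rank metrics


def filter_censored(
    records: Sequence[PredictionRecord],
) -> tuple[list[PredictionRecord], int]:
    kept = [r for r in records if not r.censored]
    return kept, len(records) - len(kept)


def auc_from_ranks(records: Sequence[PredictionRecord]) -> float:
    """Mean normalized-rank complement, AUC = (1/P) sum (M_i - r_i)/(M_i - 1).

    Requires every record uncensored with candidate pool M > 1; filter
    censored records first with :func:`filter_censored`.
    """
    if not records:
        raise ValueError("no records to evaluate")
    if any(r.censored for r in records):
        raise ValueError("censored records must be filtered before AUC")
    if any(r.M <= 1 for r in records):
        raise ValueError("AUC undefined for candidate pools of size <= 1")
    return float(np.mean([(r.M - r.rank) / (r.M - 1) for r in records]))


def topk_curve(
    records: Sequence[PredictionRecord], k_max: int = 1000
) -> dict[int, float]:
    """True-positive fraction among the top k ranks, for k = 1..k_max.

    Censored records count in the denominator only (they are misses at
    every threshold), so the curve is an honest recovery rate.
    """
    if not records:
        raise ValueError("no records to evaluate")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts = np.zeros(k_max + 1, dtype=int)
    for r in records:
        if not r.censored and r.rank <= k_max:
            counts[r.rank] += 1
    cum = np.cumsum(counts)
    n = len(records)
    return {k: float(cum[k]) / n for k in range(1, k_max + 1)}


def fpr_at_rank(k: int, m: int) -> float:
    """False-positive rate implied by a top-k threshold: k / M negatives."""
    if not 1 <= k <= m:
        raise ValueError(f"require 1 <= k <= M, got k={k}, M={m}")
    return k / m


def summarize(
    records: Sequence[PredictionRecord],
    group: str = "all",
    k_max: int | None = None,
) -> EvaluationSummary:
    """Pooled summary of a record list (AUC over uncensored, optional top-k)."""
    kept, n_cens = filter_censored(records)
    auc = auc_from_ranks(kept) if kept else float("nan")
    topk = topk_curve(records, k_max) if k_max else {}
    return EvaluationSummary(
        group=group, n_pairs=len(records), auc=auc, n_censored=n_cens, topk=topk
    )


# ---------------------------------------------------------------------------
# Leave-one-out drivers


def _loo_ranks_rwr(
    adjacency: NormalizedAdjacency,
    genes: Sequence[str],
    cfg: PropagationConfig,
) -> list[tuple[str, int, int]]:
    """Leave-one-out within one equal-weight gene set, batched over columns.

    Returns (test_gene, rank, M) triples.  Column j is the seed
    distribution omitting gene j; all columns share the power iteration.
    """
    n = adjacency.n
    idx = np.array([adjacency.index[g] for g in genes])
    s = len(genes)
    p0 = np.zeros((n, s))
    p0[idx, :] = 1.0 / (s - 1)
    p0[idx, np.arange(s)] = 0.0
    scores = rwr_scores_batch(adjacency, p0, cfg)
    out = []
    m = n - (s - 1)
    for j, gene in enumerate(genes):
        col = scores[:, j]
        seed_mask = np.zeros(n, dtype=bool)
        seed_mask[idx] = True
        seed_mask[idx[j]] = False
        s_test = col[idx[j]]
        better = int(np.sum((col > s_test) & ~seed_mask))
        tied = int(np.sum((col == s_test) & ~seed_mask)) - 1  # minus the test gene
        out.append((gene, 1 + better + tied, m))
    return out


def loo_sign_predictions(
    panel: SignPanel,
    net: GeneNetwork,
    method: str = "rwr",
    cfg: PropagationConfig = PropagationConfig(),
    diamond_max_iter: int = 1000,
    adjacency: NormalizedAdjacency | None = None,
) -> list[PredictionRecord]:
    """One leave-one-out trial per (sign, gene) pair in the panel.

    RWR seeds are equal-weighted over the sign's remaining genes; DIAMOnD
    ranks are the absorption iteration, censored at ``diamond_max_iter``.
    """
    if method not in {"rwr", "diamond"}:
        raise ValueError(f"unknown method {method!r}")
    records: list[PredictionRecord] = []
    if method == "rwr" and adjacency is None:
        adjacency = normalize_adjacency(net)
    for term in sorted(panel.sets):
        sgs = panel.sets[term]
        genes = sorted(sgs.genes)
        if len(genes) < 2:
            raise ValueError(f"sign {term!r} has < 2 network genes")
        if method == "rwr":
            for gene, rank, m in _loo_ranks_rwr(adjacency, genes, cfg):
                records.append(
                    PredictionRecord(
                        unit=term, unit_kind="sign", test_gene=gene, method="rwr",
                        rank=rank, censored=False, M=m, seed_size=len(genes) - 1,
                        disease_context=frozenset(sgs.source_diseases.get(gene, ())),
                    )
                )
        else:
            for gene in genes:
                seed = set(genes) - {gene}
                trace = diamond_expand(net, seed, max_iter=diamond_max_iter)
                rank, censored, m = diamond_rank(trace, gene)
                records.append(
                    PredictionRecord(
                        unit=term, unit_kind="sign", test_gene=gene, method="diamond",
                        rank=rank, censored=censored, M=m, seed_size=len(seed),
                        disease_context=frozenset(sgs.source_diseases.get(gene, ())),
                    )
                )
    return records


def term_gene_index(
    expanded: dict[str, dict[str, str]],
    assoc: AssociationSet,
    net: GeneNetwork,
) -> dict[str, set[str]]:
    """term -> network genes of diseases annotated (post-expansion) with it."""
    nodes = net.nodes
    out: dict[str, set[str]] = {}
    for disease, term_map in expanded.items():
        genes = assoc.disease_genes.get(disease, set()) & nodes
        if not genes:
            continue
        for term in term_map:
            out.setdefault(term, set()).update(genes)
    return out


def loo_disease_predictions(
    assoc: AssociationSet,
    onto: Ontology,
    expanded: dict[str, dict[str, str]],
    net: GeneNetwork,
    cfg: PropagationConfig = PropagationConfig(),
    adjacency: NormalizedAdjacency | None = None,
) -> list[PredictionRecord]:
    """Leave-one-out over (disease, gene) pairs with sign-derived seeds.

    The seed for predicting gene g of disease d is the union of genes of
    every term annotated to d (ancestors included), minus g.  A seed gene
    appearing under several terms takes weight max_i 1/(n_i - 1), n_i being
    the number of network genes of term i; weights are then normalized to a
    distribution.  Terms with a single gene carry no information (the only
    gene is the one held out) and contribute nothing; pairs with an empty
    seed are skipped with a warning.
    """
    if adjacency is None:
        adjacency = normalize_adjacency(net)
    term_genes = term_gene_index(expanded, assoc, net)
    nodes = net.nodes
    records: list[PredictionRecord] = []
    n_skipped = 0
    for disease in sorted(expanded):
        d_genes = sorted(assoc.disease_genes.get(disease, set()) & nodes)
        terms = expanded[disease]
        if not d_genes or not terms:
            continue
        for gene in d_genes:
            weights: dict[str, float] = {}
            for term in terms:
                tg = term_genes.get(term, set())
                n_i = len(tg)
                if n_i < 2:
                    continue
                w = 1.0 / (n_i - 1)
                for h in tg:
                    if h == gene:
                        continue
                    if w > weights.get(h, 0.0):
                        weights[h] = w
            if not weights:
                n_skipped += 1
                logger.warning(
                    "disease %s gene %s: empty seed (no sign shared with any other gene); skipped",
                    disease,
                    gene,
                )
                continue
            seed = SeedVector(weights)
            result = rwr_scores(adjacency, seed, cfg)
            rank, m = rwr_rank(result.scores, seed, gene)
            records.append(
                PredictionRecord(
                    unit=disease, unit_kind="disease", test_gene=gene, method="rwr",
                    rank=rank, censored=False, M=m, seed_size=len(seed.genes),
                    disease_context=frozenset({disease}),
                )
            )
    if n_skipped:
        logger.info("skipped %d disease-gene pairs with empty seeds", n_skipped)
    return records


def direct_oligogenic_predictions(
    assoc: AssociationSet,
    net: GeneNetwork,
    cfg: PropagationConfig = PropagationConfig(),
    adjacency: NormalizedAdjacency | None = None,
) -> list[PredictionRecord]:
    """Leave-one-out within each oligogenic disease's own gene set.

    The direct alternative to sign-mediated seeds: predict each gene of a
    multi-gene disease from its sibling genes, equal weights.
    """
    if adjacency is None:
        adjacency = normalize_adjacency(net)
    classes = classify_diseases(assoc, net)
    nodes = net.nodes
    records: list[PredictionRecord] = []
    for disease in sorted(d for d, c in classes.items() if c == "oligogenic"):
        genes = sorted(assoc.disease_genes[disease] & nodes)
        for gene, rank, m in _loo_ranks_rwr(adjacency, genes, cfg):
            records.append(
                PredictionRecord(
                    unit=disease, unit_kind="disease", test_gene=gene, method="rwr",
                    rank=rank, censored=False, M=m, seed_size=len(genes) - 1,
                    disease_context=frozenset({disease}),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Baselines and bounds


def random_baseline(
    net: GeneNetwork,
    n_sets: int = 500,
    size_range: tuple[int, int] = (25, 75),
    rng_seed: int = 0,
    cfg: PropagationConfig = PropagationConfig(),
) -> EvaluationSummary:
    """Leave-one-out AUC of random gene sets — the no-signal control.

    Draws ``n_sets`` node sets of size uniform on ``size_range`` (without
    replacement within a set), runs equal-weight RWR leave-one-out inside
    each, and pools.  On any network this should sit near AUC 0.5; the
    per-set breakdown is kept in ``per_set_auc``.
    """
    lo, hi = size_range
    if net.n_nodes <= hi:
        raise ValueError(f"network must have > {hi} nodes")
    rng = np.random.default_rng(rng_seed)
    adjacency = normalize_adjacency(net)
    order = np.array(adjacency.nodes)
    records: list[PredictionRecord] = []
    per_set: list[float] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = sorted(rng.choice(order, size=size, replace=False))
        set_records = [
            PredictionRecord(
                unit=f"random_{i}", unit_kind="random", test_gene=g, method="rwr",
                rank=rank, censored=False, M=m, seed_size=size - 1,
            )
            for g, rank, m in _loo_ranks_rwr(adjacency, genes, cfg)
        ]
        records.extend(set_records)
        per_set.append(auc_from_ranks(set_records))
    summary = summarize(records, group="random_baseline")
    summary.per_set_auc = per_set
    return summary


def best_sign_upper_bound(
    records: Sequence[PredictionRecord],
) -> EvaluationSummary:
    """AUC if the most informative sign for each (disease, gene) were known.

    For every (disease, gene) pair keep only the minimum rank over all sign
    trials of that pair, then pool.  Since min-rank dominates every single
    rank, this is an upper bound on any per-sign restriction of the same
    pairs.
    """
    sign_records = [r for r in records if r.unit_kind == "sign" and not r.censored]
    if not sign_records:
        raise ValueError("no uncensored sign records")
    best: dict[tuple[str, str], PredictionRecord] = {}
    for r in sign_records:
        for disease in r.disease_context:
            key = (disease, r.test_gene)
            cur = best.get(key)
            if cur is None or r.rank < cur.rank:
                best[key] = r
    reduced = list(best.values())
    return EvaluationSummary(
        group="best_sign_upper_bound",
        n_pairs=len(reduced),
        auc=auc_from_ranks(reduced),
    )


# ---------------------------------------------------------------------------
# Stratification


def _record_groups(
    record: PredictionRecord,
    factor: str,
    assoc: AssociationSet,
    onto: Ontology | None,
    classes: dict[str, str] | None,
    expanded: dict[str, dict[str, str]] | None,
    subroot: str | None,
) -> set[str]:
    if factor == "ploidy":
        assert classes is not None
        out = {classes[d] for d in record.disease_context if d in classes}
    elif factor == "inheritance":
        out = {
            assoc.disease_meta[d].inheritance
            for d in record.disease_context
            if d in assoc.disease_meta
        }
    elif factor == "onset":
        out = set()
        for d in record.disease_context:
            if d in assoc.disease_meta:
                out |= assoc.disease_meta[d].onset
    elif factor == "progression":
        out = {
            assoc.disease_meta[d].progression
            for d in record.disease_context
            if d in assoc.disease_meta
        }
    elif factor == "frequency":
        out = set()
        if expanded is not None:
            for d in record.disease_context:
                freq = expanded.get(d, {}).get(record.unit)
                if freq is not None:
                    out.add(freq)
    elif factor == "sign_class":
        out = set()
        if onto is not None and record.unit in onto:
            out = set(onto.top_classes(record.unit, subroot or onto.root))
    elif factor == "gene_function":
        out = set((assoc.gene_functions or {}).get(record.test_gene, set()))
    else:
        raise ValueError(f"unknown stratification factor {factor!r}")
    return out or {"unknown"}


def stratify(
    records: Sequence[PredictionRecord],
    assoc: AssociationSet,
    factor: str,
    onto: Ontology | None = None,
    net: GeneNetwork | None = None,
    expanded: dict[str, dict[str, str]] | None = None,
    subroot: str | None = None,
    mono_only: bool = False,
) -> list[EvaluationSummary]:
    """Per-group AUC over the records matching each level of a factor.

    A record joins every group it matches (a sign can belong to several
    classes; a disease can have several onsets), so group counts may sum to
    more than the record count.  Records lacking the metadata fall into an
    ``unknown`` group.  With ``mono_only`` records are first restricted to
    those tracing to at least one monogenic disease, mirroring the analyses
    that exclude oligogenic contributions.
    """
    if factor not in STRATIFY_FACTORS:
        raise ValueError(f"unknown stratification factor {factor!r}")
    classes = None
    if factor == "ploidy" or mono_only:
        if net is None:
            raise ValueError("factor 'ploidy' and mono_only need the network")
        classes = classify_diseases(assoc, net)
    work = list(records)
    if mono_only:
        work = [
            r
            for r in work
            if any(classes.get(d) == "monogenic" for d in r.disease_context)
        ]
    groups: dict[str, list[PredictionRecord]] = {}
    for r in work:
        for g in _record_groups(r, factor, assoc, onto, classes, expanded, subroot):
            groups.setdefault(g, []).append(r)
    return [summarize(groups[g], group=g) for g in sorted(groups)]


# ---------------------------------------------------------------------------
# Persistence


_RECORD_COLS = [
    "unit",
    "unit_kind",
    "test_gene",
    "method",
    "rank",
    "censored",
    "M",
    "seed_size",
    "disease_context",
]


def write_records(records: Iterable[PredictionRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_RECORD_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.unit}\t{r.unit_kind}\t{r.test_gene}\t{r.method}\t{r.rank}\t"
                f"{int(r.censored)}\t{r.M}\t{r.seed_size}\t"
                f"{';'.join(sorted(r.disease_context))}\n"
            )


def read_records(path: str | Path) -> list[PredictionRecord]:
    records = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _RECORD_COLS:
            raise ValueError(f"{path}: unexpected records header {header}")
        for line in fh:
            u, uk, g, meth, rank, cens, m, ss, ctx = line.rstrip("\n").split("\t")
            records.append(
                PredictionRecord(
                    unit=u, unit_kind=uk, test_gene=g, method=meth, rank=int(rank),
                    censored=bool(int(cens)), M=int(m), seed_size=int(ss),
                    disease_context=frozenset(c for c in ctx.split(";") if c),
                )
            )
    return records


def write_summaries(summaries: Sequence[EvaluationSummary], path: str | Path) -> None:
    payload = [
        {
            "group": s.group,
            "n_pairs": s.n_pairs,
            "auc": None if np.isnan(s.auc) else s.auc,
            "n_censored": s.n_censored,
            "topk": {str(k): v for k, v in s.topk.items()},
        }
        for s in summaries
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
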