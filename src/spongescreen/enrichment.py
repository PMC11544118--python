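"""Preranked gene-set enrichment and per-sample signature scoring.

Genes are ranked by the log2 fold change between high and low hub-
expression groups; enrichment of a set is the weighted Kolmogorov-
Smirnov running-sum statistic (hits advance by |score|^weight normalised
over the set, misses retreat by 1/(N - Nh)), with significance from
gene-label permutations of the set membership.  NES divides the observed
ES by the mean |null ES| of matching sign, and the permutation p is
(1 + #more extreme of matching sign) / (1 + #matching sign).

Per-sample signature abundance (e.g. an IL-10+ tumor-associated-
macrophage signature) is the geometric mean of member counts plus a
pseudocount, correlated downstream against gene expression by Spearman.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .rankstats import bh_adjust, spearman

__all__ = [
    "RankedList", "GeneSet", "GseaResult",
    "rank_by_log2fc", "gsea_es", "gsea_significance", "gsea_batch",
    "signature_score_geomean", "score_correlation",
]


@dataclass
class RankedList:
    """Genes ordered by descending score (log2 fold change)."""

    gene_ids: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSet:
    name: str
    members: tuple

    def __post_init__(self) -> None:
        members = tuple(dict.fromkeys(self.members))  # dedupe, keep order
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.members = members


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    adj_p: float
    leading_edge: tuple = ()
    n_hits: int = 0


def rank_by_log2fc(de_records) -> RankedList:
    """All genes ranked by descending log2FC; ties break by gene id."""
    seen = set()
    rows = []
    for r in de_records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene id {r.gene_id!r}")
        seen.add(r.gene_id)
        rows.append((r.gene_id, float(r.log2fc)))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(gene_ids=[g for g, _ in rows],
                      scores=np.array([s for _, s in rows]))


# ---------------------------------------------------------------------------
# enrichment score


def _es_many(scores: np.ndarray, hits: np.ndarray, weight: float):
    """ES (and running sums) for one or many hit masks over one ranking.

    ``hits`` is a boolean array (n_perm x N); returns (es vector, running
    sums).  Hit steps are |score|^weight normalised by their sum over the
    set; when that sum is zero the set contributes no mass and misses are
    spread over all N positions.  Miss steps are 1/(N - Nh) otherwise.
    """
    n = scores.size
    w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    nh = hits.sum(axis=1)
    if np.any(nh >= n):
        raise ValueError("gene set covers the whole ranked list")
    nr = (hits * w).sum(axis=1)
    denom_miss = np.where(nr > 0, n - nh, n).astype(float)
    hit_inc = np.where(hits, w[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hit_inc = np.where(nr[:, None] > 0, hit_inc / np.where(nr, nr, 1.0)[:, None], 0.0)
    miss_dec = (~hits).astype(float) / denom_miss[:, None]
    running = np.cumsum(hit_inc - miss_dec, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(running.shape[0]), idx]
    return es, running


def gsea_es(ranked: RankedList, gene_set: GeneSet, weight: float = 1.0):
    """Enrichment score and running sum of one set against one ranking."""
    members = set(gene_set.members)
    hits = np.array([[g in members for g in ranked.gene_ids]])
    if not hits.any():
        raise ValueError(f"gene set {gene_set.name!r} has no gene in the ranking")
    es, running = _es_many(ranked.scores, hits, weight)
    return float(es[0]), running[0]


def _leading_edge(ranked, hits_row, running_row, es):
    idx = int(np.argmax(np.abs(running_row)))
    if es >= 0:
        positions = np.nonzero(hits_row[: idx + 1])[0]
    else:
        positions = np.nonzero(hits_row[idx:])[0] + idx
    return tuple(ranked.gene_ids[i] for i in positions)


def gsea_significance(ranked: RankedList, gene_set: GeneSet,
                      n_perm: int = 1000, seed: int = 0,
                      weight: float = 1.0) -> GseaResult:
    """Permutation significance of one gene set (see :func:`gsea_batch`)."""
    return gsea_batch(ranked, [gene_set], n_perm=n_perm, seed=seed,
                      weight=weight)[0]


def gsea_batch(ranked: RankedList, gene_sets, n_perm: int = 1000,
               seed: int = 0, weight: float = 1.0) -> list:
    """GSEA of several sets against one ranking, BH-adjusted across sets.

    The null re-draws the set membership uniformly over ranked genes
    (preranked / gene-label permutation mode).  NES is sign-matched:
    es / mean(|null es| of the same sign); if no null sample matches the
    observed sign, p is reported at its resolution floor 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    results = []
    pvals = []
    for gene_set in gene_sets:
        members = set(gene_set.members)
        hit_row = np.array([g in members for g in ranked.gene_ids])
        nh = int(hit_row.sum())
        if nh == 0:
            raise ValueError(f"gene set {gene_set.name!r} has no gene in the ranking")
        es, running = _es_many(ranked.scores, hit_row[None, :], weight)
        es = float(es[0])
        perm_hits = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            perm_hits[i, rng.choice(n, size=nh, replace=False)] = True
        null_es, _ = _es_many(ranked.scores, perm_hits, weight)
        same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        n_sign = int(same_sign.sum())
        if n_sign == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            extreme = np.abs(null_es[same_sign]) >= abs(es) - 1e-15
            p = (1 + int(extreme.sum())) / (1 + n_sign)
            mean_abs = float(np.mean(np.abs(null_es[same_sign])))
            nes = es / mean_abs if mean_abs > 0 else 0.0
        lead = _leading_edge(ranked, hit_row, running[0], es)
        results.append(GseaResult(set_name=gene_set.name, es=es, nes=nes,
                                  p=float(p), adj_p=np.nan,
                                  leading_edge=lead, n_hits=nh))
        pvals.append(p)
    adj = bh_adjust(pvals)
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return results


# ---------------------------------------------------------------------------
# signature scoring


def signature_score_geomean(expr: ExpressionMatrix, gene_set: GeneSet,
                            pseudocount: float = 1.0):
    """Per-sample geometric mean of member counts (+pseudocount).

    Returns (scores Series, absent member list).  Requires the counts
    scale; at least one member must be present in the matrix.
    """
    if expr.scale != "counts":
        raise ValueError("signature scoring expects the counts scale")
    present = [g for g in gene_set.members if g in expr.values.index]
    absent = [g for g in gene_set.members if g not in expr.values.index]
    if not present:
        raise ValueError(f"no member of {gene_set.name!r} present in matrix")
    mat = expr.values.loc[present].to_numpy(float) + pseudocount
    if (mat <= 0).any():
        raise ValueError("counts + pseudocount must be positive for the geomean")
    scores = np.exp(np.log(mat).mean(axis=0))
    return pd.Series(scores, index=expr.sample_ids, name=gene_set.name), absent


def score_correlation(scores: pd.Series, gene_values: pd.Series) -> dict:
    """Spearman correlation of a signature score with one gene's expression.

    Computed over the shared samples; the result carries n and a hash of
    the sample list for provenance.
    """
    shared = scores.index.intersection(gene_values.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    res = spearman(scores.loc[shared].to_numpy(float),
                   gene_values.loc[shared].to_numpy(float))
    sample_hash = hashlib.sha256("\n".join(map(str, shared)).encode()).hexdigest()[:12]
    return {"result": res, "n": len(shared), "sample_hash": sample_hash}
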