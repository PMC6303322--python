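"""Gene-level scoring of screens by rank-order hypergeometric tests.

All sgRNAs are ranked by log-fold-change (ascending for depletion screens,
descending for enrichment/positive-selection screens; ties broken by sgRNA
identifier so the ranking is deterministic). For a gene whose ``s`` sgRNAs sit
at sorted ranks ``r_1 < ... < r_s`` among ``N`` scored sgRNAs, each rank
yields a hypergeometric tail

    P[X >= k],   X ~ Hypergeometric(population N, successes s, draws r_k),

which is exactly the one-sided Fisher's exact test on the 2x2 table
{top-r_k vs rest} x {gene vs rest}. The gene's canonical ``pvalue`` is the
minimum of these tails over ``k = 1..s``, uncorrected for taking the minimum.
That statistic uses every guide of the gene but is *not* uniformly
distributed under a random ranking (it is super-uniform only in the
Bonferroni sense, ``P[p <= a] <= s*a``). For calibration work the module can
therefore also report ``calibrated_pvalue``: the exact probability, under a
uniformly random placement of the gene's ``s`` ranks among ``N``, that the
min-tail statistic is at most the observed value. The calibrated p-value is
uniform under the null by construction; it is computed with an
order-statistic boundary-crossing count (no resampling).

Null calibration against real libraries uses *dummy genes*: random,
seed-deterministic groupings of the non-targeting control sgRNAs into
pseudo-genes of the library's per-gene set size. Empirical false discovery
rates walk the gene ranking (most extreme average LFC first) and report the
monotonized fraction of negative-labelled genes above each rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import LibraryReference
from .normalize import LfcTable

__all__ = [
    "build_dummy_genes",
    "rank_hypergeometric",
    "min_tail_null_cdf",
    "empirical_fdr",
    "score_screen",
    "DUMMY_GENE_PREFIX",
]

DUMMY_GENE_PREFIX = "DUMMY"

DIRECTIONS = ("depletion", "enrichment")


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


# ---------------------------------------------------------------------------
# Dummy genes
# ---------------------------------------------------------------------------

def build_dummy_genes(
    reference: LibraryReference,
    set_size: int,
    seed: int,
    prefix: str = DUMMY_GENE_PREFIX,
) -> dict[str, list[str]]:
    """Randomly group non-targeting control sgRNAs into dummy genes.

    Produces ``floor(n_controls / set_size)`` dummy genes of exactly
    ``set_size`` controls each, sampled without replacement; leftovers are
    unused. Deterministic given ``seed``.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    controls = sorted(reference.control_ids)
    if len(controls) < set_size:
        raise ValueError(
            f"need at least {set_size} control sgRNAs, library has {len(controls)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(controls))
    n_dummy = len(controls) // set_size
    out: dict[str, list[str]] = {}
    for g in range(n_dummy):
        ids = [controls[i] for i in order[g * set_size : (g + 1) * set_size]]
        out[f"{prefix}_{g + 1:04d}"] = sorted(ids)
    return out


# ---------------------------------------------------------------------------
# Rank-order hypergeometric test
# ---------------------------------------------------------------------------

def _rank_sgrnas(lfc: pd.Series, direction: str) -> pd.Series:
    """1-based ranks: most depleted (or most enriched) sgRNA gets rank 1."""
    df = pd.DataFrame({"value": lfc.astype(float), "id": lfc.index.astype(str)})
    ascending = direction == "depletion"
    order = df.sort_values(["value", "id"], ascending=[ascending, True]).index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.reindex(lfc.index)


def min_tail_null_cdf(t_values: np.ndarray, n_total: int, set_size: int) -> np.ndarray:
    """Exact null CDF of the min-of-tails statistic at each value of ``t``.

    Under a uniformly random placement of ``set_size`` ranks among
    ``n_total``, returns ``P[min_k tail_k <= t]`` where ``tail_k`` is the
    hypergeometric survival probability at the gene's k-th best rank. The
    event ``{tail_k <= t}`` is ``{r_k <= q_k(t)}`` for a threshold ``q_k``
    (the tail is non-decreasing in the draw count), so the CDF is one minus
    the fraction of rank placements whose k-th order statistic exceeds
    ``q_k(t)`` for every k — a boundary-non-crossing count evaluated by
    dynamic programming over order statistics.
    """
    s, N = set_size, n_total
    rgrid = np.arange(0, N + 1)
    # tails[k-1, r] = P[X >= k | draws r]; non-decreasing in r
    tails = np.vstack([hypergeom.sf(k - 1, N, s, rgrid) for k in range(1, s + 1)])
    total = float(comb(N, s))
    out = np.empty(len(t_values), dtype=float)
    for i, t in enumerate(np.asarray(t_values, dtype=float)):
        q = np.array(
            [np.searchsorted(tails[k], np.nextafter(t, np.inf)) - 1 for k in range(s)]
        )
        # count placements r_1 < ... < r_s with r_k > q_k for all k
        g = np.zeros(N + 1)
        g[max(int(q[0]) + 1, 1) :] = 1.0
        for k in range(1, s):
            prev = np.concatenate(([0.0], np.cumsum(g)[:-1]))
            lo = max(int(q[k]) + 1, 1)
            g = np.where(rgrid >= lo, prev, 0.0)
        out[i] = 1.0 - g.sum() / total
    return out


def rank_hypergeometric(
    lfc: pd.Series,
    gene_map: Mapping[str, Iterable[str]],
    direction: str = "depletion",
    calibrated: bool = False,
) -> pd.DataFrame:
    """Per-gene average LFC and rank-order hypergeometric p-value.

    Returns a DataFrame indexed by gene with columns ``n_sgrnas``,
    ``avg_lfc`` and ``pvalue`` (plus ``calibrated_pvalue`` when requested).
    Every mapped sgRNA must have an LFC; a gene with zero scored sgRNAs
    raises ``ValueError``.
    """
    _check_direction(direction)
    lfc = lfc.astype(float)
    N = len(lfc)
    ranks = _rank_sgrnas(lfc, direction)

    genes: list[str] = []
    sizes: list[int] = []
    avg: list[float] = []
    gene_ranks: list[np.ndarray] = []
    for gene, ids in gene_map.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"gene {gene!r} has zero sgRNAs")
        missing = [i for i in ids if i not in lfc.index]
        if missing:
            raise ValueError(f"gene {gene!r}: sgRNA {missing[0]!r} has no LFC")
        r = np.sort(ranks.loc[ids].to_numpy())
        genes.append(gene)
        sizes.append(len(ids))
        avg.append(float(lfc.loc[ids].mean()))
        gene_ranks.append(r)
    if any(s > N for s in sizes):
        raise ValueError("a gene has more sgRNAs than there are scored sgRNAs")

    # vectorized tails: one sf() call over all (gene, k) pairs, grouped by set size
    sizes_arr = np.asarray(sizes)
    pvals = np.ones(len(genes))
    flat_k = np.concatenate([np.arange(1, s + 1) for s in sizes_arr]) if genes else np.array([])
    flat_r = np.concatenate(gene_ranks) if genes else np.array([])
    flat_s = np.repeat(sizes_arr, sizes_arr) if genes else np.array([])
    flat_gene = np.repeat(np.arange(len(genes)), sizes_arr) if genes else np.array([])
    if len(flat_k):
        tails = hypergeom.sf(flat_k - 1, N, flat_s, flat_r)
        np.minimum.at(pvals, flat_gene, tails)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {"n_sgrnas": sizes_arr, "avg_lfc": avg, "pvalue": pvals},
        index=pd.Index(genes, name="gene"),
    )
    if calibrated:
        cal = np.empty(len(genes))
        for s in np.unique(sizes_arr):
            mask = sizes_arr == s
            cal[mask] = min_tail_null_cdf(pvals[mask], N, int(s))
        out["calibrated_pvalue"] = np.clip(cal, np.finfo(float).tiny, 1.0)
    return out


# ---------------------------------------------------------------------------
# Empirical FDR
# ---------------------------------------------------------------------------

def empirical_fdr(
    scores: pd.DataFrame,
    negatives: Iterable[str],
    direction: str = "enrichment",
    hit_threshold: float = 0.05,
    rescale: bool = False,
) -> pd.DataFrame:
    """Empirical FDR from the fraction of negative-labelled genes per rank.

    Genes are walked from the most extreme ``avg_lfc`` in the scoring
    direction; the raw FDR at rank ``i`` is the fraction of negatives among
    the top ``i`` genes (or, with ``rescale=True``, that count scaled by the
    ratio of total genes to total negatives), monotonized from the bottom so
    FDR never decreases as the ranking worsens. Adds ``is_negative_control``,
    ``empirical_fdr`` and ``hit`` columns (hits are non-negative genes below
    ``hit_threshold``).
    """
    _check_direction(direction)
    negatives = set(negatives)
    if not negatives:
        raise ValueError("need at least one negative-labelled gene")
    df = scores.copy()
    df["is_negative_control"] = [g in negatives for g in df.index]
    # deterministic tie-break by gene name
    tmp = pd.DataFrame({"v": df["avg_lfc"], "g": df.index.astype(str)})
    order = tmp.sort_values(["v", "g"], ascending=[direction == "depletion", True]).index

    is_neg = df.loc[order, "is_negative_control"].to_numpy()
    i = np.arange(1, len(order) + 1)
    if rescale:
        n_neg = is_neg.sum()
        raw = (np.cumsum(is_neg) / n_neg) * (len(order) / i)
    else:
        raw = np.cumsum(is_neg) / i
    fdr = np.minimum.accumulate(raw[::-1])[::-1]
    fdr = np.clip(fdr, 0.0, 1.0)
    df.loc[order, "empirical_fdr"] = fdr
    df["hit"] = (df["empirical_fdr"] < hit_threshold) & ~df["is_negative_control"]
    return df


# ---------------------------------------------------------------------------
# Full screen scoring
# ---------------------------------------------------------------------------

def score_screen(
    lfc: pd.Series | LfcTable,
    reference: LibraryReference,
    direction: str = "enrichment",
    seed: int = 0,
    dummy_set_size: int | None = None,
    contrast: str | None = None,
    negatives: Iterable[str] | None = None,
    calibrated: bool = False,
    hit_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score targeting genes plus dummy genes for one screen direction.

    Builds dummy genes from the library's non-targeting controls (set size
    defaults to the modal per-gene sgRNA count), computes per-gene average
    LFC and rank-order hypergeometric p-values over targeting + dummy genes
    together, and — when ``negatives`` is given — an empirical FDR with dummy
    genes automatically included in the negative set. The ``is_dummy`` column
    marks dummy genes so hit counts can exclude them.
    """
    if isinstance(lfc, LfcTable):
        if contrast is None:
            if lfc.lfc.shape[1] != 1:
                raise ValueError("contrast must be named when the LFC table has several")
            contrast = lfc.lfc.columns[0]
        lfc = lfc.column(contrast)
    gene_map = reference.gene_map(include_controls=False)
    if dummy_set_size is None:
        sizes = [len(v) for v in gene_map.values()]
        dummy_set_size = int(pd.Series(sizes).mode().iloc[0]) if sizes else 1
    dummies = build_dummy_genes(reference, dummy_set_size, seed)
    full_map = {**gene_map, **dummies}
    table = rank_hypergeometric(lfc, full_map, direction=direction, calibrated=calibrated)
    table["is_dummy"] = table.index.str.startswith(DUMMY_GENE_PREFIX + "_")
    if negatives is not None:
        neg = set(negatives) | set(dummies)
        table = empirical_fdr(
            table, neg, direction=direction, hit_threshold=hit_threshold
        )
    return table
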