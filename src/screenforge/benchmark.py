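"""Library-performance benchmarking: depletion AUC, dAUC/ddAUC, gene ROC-AUC.

The sgRNA-level metric ranks the whole library by log-fold-change (most
depleted first) and traces, for a gene set, the cumulative fraction of the
set's sgRNAs recovered as a function of the fraction of the ranked library
traversed; the trapezoidal area under that curve is the depletion AUC. A
random placement gives 0.5, concentration at the depleted end gives > 0.5.
Because every sgRNA enters the ranking (non-targeting controls included in
the denominator) and no pre-filtering is applied, the metric does not favour
larger libraries. dAUC = AUC(essential) - AUC(non-essential) summarizes a
screen in one number; ddAUC is the change in dAUC after filtering the library
to the top fraction of sgRNAs under some scoring scheme.

The gene-level metric averages a gene's sgRNA LFCs and computes the ROC-AUC
separating essential genes (true positives) from non-essential genes (false
positives), equal to the normalized Mann-Whitney U with ties counted 1/2.
Subsampling draws n sgRNAs per gene without replacement before averaging, to
ask how many guides per gene a library actually needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "GeneSet",
    "AucReport",
    "SubsampleReport",
    "DdaucReport",
    "depletion_auc",
    "dauc",
    "gene_roc_auc",
    "gene_pr_auc",
    "subsample_roc",
    "filtered_ddauc",
    "build_stop_gene_set",
]

GENE_SET_ROLES = ("essential", "nonessential", "nontargeting", "stop", "custom")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a benchmarking role."""

    name: str
    members: frozenset[str]
    role: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.role not in GENE_SET_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {GENE_SET_ROLES}")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str], role: str = "custom") -> "GeneSet":
        return cls(name=name, members=frozenset(members), role=role)

    @classmethod
    def from_file(cls, path, name: str | None = None, role: str = "custom") -> "GeneSet":
        """One gene symbol per line; blank lines ignored."""
        with open(path) as fh:
            members = frozenset(line.strip() for line in fh if line.strip())
        return cls(name=name or str(path), members=members, role=role)

    def resolve(self, known_genes: Iterable[str]) -> tuple[set[str], set[str]]:
        """(resolved, unresolved) membership against the gene universe."""
        known = set(known_genes)
        return self.members & known, self.members - known


@dataclass(frozen=True)
class AucReport:
    auc_essential: float
    auc_nonessential: float
    auc_nontargeting: float | None
    dauc: float
    n_sgrnas_per_set: dict[str, int]

    def __post_init__(self) -> None:
        for a in (self.auc_essential, self.auc_nonessential, self.auc_nontargeting):
            if a is not None and not (0.0 <= a <= 1.0):
                raise ValueError(f"AUC out of [0,1]: {a}")
        if not (-1.0 <= self.dauc <= 1.0):
            raise ValueError(f"dAUC out of [-1,1]: {self.dauc}")


@dataclass(frozen=True)
class SubsampleReport:
    n: int
    iterations: int
    seed: int
    mean_roc_auc: float
    sd_roc_auc: float
    per_iteration: tuple[float, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class DdaucReport:
    dauc_full: float
    dauc_filtered: float
    ddauc: float
    n_retained: int


# ---------------------------------------------------------------------------
# sgRNA-level AUC
# ---------------------------------------------------------------------------

def depletion_auc(values: pd.Series, subset: Iterable[str]) -> float:
    """Trapezoidal area under the cumulative-recovery curve of ``subset``.

    Items are sorted ascending by value (most depleted first; ties broken by
    id); the curve passes through ``(i/N, c_i/|S|)`` where ``c_i`` counts
    subset members among the top ``i`` items.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("subset is empty")
    missing = subset - set(values.index)
    if missing:
        raise ValueError(f"subset item without a value, e.g. {sorted(missing)[0]!r}")
    df = pd.DataFrame({"v": values.astype(float), "g": values.index.astype(str)})
    order = df.sort_values(["v", "g"], ascending=[True, True]).index
    member = np.fromiter((i in subset for i in order), dtype=float, count=len(order))
    c = np.concatenate(([0.0], np.cumsum(member))) / len(subset)
    # uniform x spacing of 1/N -> trapezoid area
    return float(np.trapezoid(c, dx=1.0 / len(order)))


def _set_sgrnas(gene_map: Mapping[str, Iterable[str]], genes: Iterable[str]) -> set[str]:
    genes = set(genes)
    out: set[str] = set()
    for g, ids in gene_map.items():
        if g in genes:
            out.update(ids)
    return out


def dauc(
    lfc: pd.Series,
    gene_map: Mapping[str, Iterable[str]],
    essential: GeneSet,
    nonessential: GeneSet,
    nontargeting_ids: Iterable[str] | None = None,
) -> AucReport:
    """AUCs for essential / non-essential (and optionally non-targeting)
    sgRNA sets over the full ranked library, and their difference.

    ``nontargeting_ids`` are sgRNA identifiers (controls have no gene), while
    the essential / non-essential sets are resolved through ``gene_map``. A
    gene set resolving to zero scored sgRNAs raises ``ValueError``.
    """
    sets = {
        "essential": _set_sgrnas(gene_map, essential.members),
        "nonessential": _set_sgrnas(gene_map, nonessential.members),
    }
    if nontargeting_ids is not None:
        sets["nontargeting"] = set(nontargeting_ids)
    scored = set(lfc.index)
    aucs: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for name, ids in sets.items():
        ids = ids & scored
        if not ids:
            raise ValueError(f"gene set {name!r} resolves to zero scored sgRNAs")
        aucs[name] = depletion_auc(lfc, ids)
        sizes[name] = len(ids)
    return AucReport(
        auc_essential=aucs["essential"],
        auc_nonessential=aucs["nonessential"],
        auc_nontargeting=aucs.get("nontargeting"),
        dauc=aucs["essential"] - aucs["nonessential"],
        n_sgrnas_per_set=sizes,
    )


# ---------------------------------------------------------------------------
# Gene-level ROC
# ---------------------------------------------------------------------------

def _roc_inputs(
    gene_scores: pd.Series, positives: GeneSet, negatives: GeneSet
) -> tuple[np.ndarray, np.ndarray]:
    overlap = positives.members & negatives.members
    if overlap:
        raise ValueError(f"positive and negative sets overlap, e.g. {sorted(overlap)[0]!r}")
    pos, _ = positives.resolve(gene_scores.index)
    neg, _ = negatives.resolve(gene_scores.index)
    if not pos or not neg:
        raise ValueError("both gene sets must resolve to at least one scored gene")
    genes = sorted(pos) + sorted(neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    # stronger depletion (more negative LFC) = higher score
    scores = -gene_scores.loc[genes].to_numpy(dtype=float)
    return y, scores


def gene_roc_auc(gene_scores: pd.Series, positives: GeneSet, negatives: GeneSet) -> float:
    """ROC-AUC separating positives from negatives by gene-averaged LFC.

    Score = -avg_lfc, so stronger depletion ranks higher; equals the
    normalized Mann-Whitney U with ties counted 1/2.
    """
    y, scores = _roc_inputs(gene_scores, positives, negatives)
    return float(roc_auc_score(y, scores))


def gene_pr_auc(gene_scores: pd.Series, positives: GeneSet, negatives: GeneSet) -> float:
    """Average precision (PR-AUC) companion to :func:`gene_roc_auc`."""
    y, scores = _roc_inputs(gene_scores, positives, negatives)
    return float(average_precision_score(y, scores))


def subsample_roc(
    lfc: pd.Series,
    gene_map: Mapping[str, Iterable[str]],
    n: int,
    iterations: int,
    positives: GeneSet,
    negatives: GeneSet,
    seed: int = 0,
) -> SubsampleReport:
    """ROC-AUC after random draws of ``n`` sgRNAs per gene.

    Per iteration, ``min(n, available)`` sgRNAs are sampled per gene without
    replacement, averaged, and the gene-level ROC-AUC computed; the report
    carries the mean and s.d. over iterations (s.d. 0 for one iteration).
    """
    if n < 1 or iterations < 1:
        raise ValueError("n and iterations must be >= 1")
    rng = np.random.default_rng(seed)
    members = {
        g: np.asarray(lfc.loc[list(ids)].to_numpy(dtype=float))
        for g, ids in gene_map.items()
        if len(list(ids))
    }
    genes = sorted(members)
    vals = np.empty(iterations)
    for it in range(iterations):
        means = {}
        for g in genes:
            v = members[g]
            take = min(n, len(v))
            idx = rng.choice(len(v), size=take, replace=False)
            means[g] = v[idx].mean()
        vals[it] = gene_roc_auc(pd.Series(means), positives, negatives)
    sd = float(np.std(vals, ddof=1)) if iterations > 1 else 0.0
    return SubsampleReport(
        n=n,
        iterations=iterations,
        seed=seed,
        mean_roc_auc=float(vals.mean()),
        sd_roc_auc=sd,
        per_iteration=tuple(float(v) for v in vals),
    )


# ---------------------------------------------------------------------------
# Scheme filtering (ddAUC)
# ---------------------------------------------------------------------------

def filtered_ddauc(
    lfc: pd.Series,
    gene_map: Mapping[str, Iterable[str]],
    scheme_scores: pd.Series,
    essential: GeneSet,
    nonessential: GeneSet,
    fraction: float = 0.10,
) -> DdaucReport:
    """dAUC gain from keeping the library-wide top fraction of sgRNAs.

    Retains the top ``ceil(fraction * N)`` sgRNAs by scheme score (ties by
    id), recomputes the dAUC on the retained sgRNAs only, and reports
    ``ddauc = dauc_filtered - dauc_full``. The filter is applied library-wide
    rather than per gene.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    missing = set(lfc.index) - set(scheme_scores.index)
    if missing:
        raise ValueError(f"scheme score missing for sgRNA {sorted(missing)[0]!r}")
    full = dauc(lfc, gene_map, essential, nonessential)
    k = ceil(fraction * len(lfc))
    df = pd.DataFrame(
        {"v": scheme_scores.loc[lfc.index].to_numpy(dtype=float), "g": lfc.index.astype(str)}
    )
    keep = df.sort_values(["v", "g"], ascending=[False, True]).head(k)["g"]
    filtered = dauc(lfc.loc[keep], gene_map, essential, nonessential)
    return DdaucReport(
        dauc_full=full.dauc,
        dauc_filtered=filtered.dauc,
        ddauc=filtered.dauc - full.dauc,
        n_retained=k,
    )


# ---------------------------------------------------------------------------
# STOP gene sets from ORF screens
# ---------------------------------------------------------------------------

def build_stop_gene_set(
    orf_tables: Mapping[str, pd.DataFrame],
    held_out: str,
    pvalue_cutoff: float = 1e-4,
) -> GeneSet:
    """Growth-inhibitory (STOP) gene set from held-out ORF screen tables.

    ``orf_tables`` maps cell-line name to a table with columns ``gene``,
    ``log2`` (proliferation effect) and ``pvalue``. A gene qualifies when it
    is present (non-missing) in *all* tables and has a negative log2 effect
    with ``pvalue`` strictly below the cutoff in **both** non-held-out lines.
    """
    if held_out not in orf_tables:
        raise ValueError(f"held-out line {held_out!r} not among tables")
    others = [name for name in orf_tables if name != held_out]
    if len(others) < 2:
        raise ValueError("need at least 2 non-held-out tables")

    def complete(df: pd.DataFrame) -> pd.DataFrame:
        sub = df[["gene", "log2", "pvalue"]].dropna()
        return sub.set_index("gene")

    frames = {name: complete(df) for name, df in orf_tables.items()}
    present = set.intersection(*(set(f.index) for f in frames.values()))
    members = set()
    for gene in present:
        ok = all(
            frames[name].loc[gene, "log2"] < 0 and frames[name].loc[gene, "pvalue"] < pvalue_cutoff
            for name in others
        )
        if ok:
            members.add(gene)
    return GeneSet.from_iterable(f"STOP_holdout_{held_out}", members, role="stop")
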