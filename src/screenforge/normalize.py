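"""Count normalization and per-sgRNA log2-fold-changes.

Counts are scaled to reads-per-million within each condition
(``count / total * 1e6``), then log2-transformed after adding a pseudocount
of one — the pseudocount is applied to the RPM value, not the raw count, so
an sgRNA with zero reads maps exactly to 0. Log-fold-changes are differences
of these log-normalized abundances: relative to the plasmid DNA pool for
dropout screens, or relative to the untreated (dropout) arm for positive
selection screens. Replicates are combined by averaging LFCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["LfcTable", "lognorm", "log_fold_change", "average_replicates"]


def lognorm(matrix: CountMatrix) -> pd.DataFrame:
    """log2(reads-per-million + 1) per sgRNA and condition.

    Raises ``ValueError`` naming the condition if any condition has zero
    total reads (a normalization to RPM is undefined there).
    """
    counts = matrix.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"condition {zero.index[0]!r} has zero total reads")
    rpm = counts / totals * 1e6
    return np.log2(rpm + 1.0)


@dataclass
class LfcTable:
    """Per-sgRNA log2-fold-changes, one column per contrast.

    ``contrasts`` maps each column name to its (condition, reference) pair;
    ``replicate_of`` optionally maps column names to replicate group labels.
    """

    lfc: pd.DataFrame
    contrasts: dict[str, tuple[str, str]]
    replicate_of: dict[str, str] | None = None

    def column(self, name: str) -> pd.Series:
        return self.lfc[name]


def log_fold_change(
    norm: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
) -> LfcTable:
    """LFC = lognorm(condition) - lognorm(reference) for each contrast.

    Contrast columns are named ``"<condition>_vs_<reference>"``. Unknown
    condition names raise ``KeyError``.
    """
    cols: dict[str, pd.Series] = {}
    meta: dict[str, tuple[str, str]] = {}
    for cond, ref in contrasts:
        for name in (cond, ref):
            if name not in norm.columns:
                raise KeyError(f"unknown condition {name!r}")
        label = f"{cond}_vs_{ref}"
        cols[label] = norm[cond] - norm[ref]
        meta[label] = (cond, ref)
    return LfcTable(lfc=pd.DataFrame(cols, index=norm.index), contrasts=meta)


def average_replicates(lfc: LfcTable, groups: Mapping[str, Iterable[str]]) -> LfcTable:
    """Arithmetic mean of member contrast columns per replicate group.

    Single-member groups pass through unchanged; an empty group raises
    ``ValueError``.
    """
    cols: dict[str, pd.Series] = {}
    meta: dict[str, tuple[str, str]] = {}
    for group, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {group!r} is empty")
        for m in members:
            if m not in lfc.lfc.columns:
                raise KeyError(f"unknown contrast {m!r} in group {group!r}")
        cols[group] = lfc.lfc[members].mean(axis=1)
        meta[group] = lfc.contrasts[members[0]]
    return LfcTable(
        lfc=pd.DataFrame(cols, index=lfc.lfc.index),
        contrasts=meta,
        replicate_of={g: g for g in groups},
    )
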