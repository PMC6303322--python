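"""CRISPRi/CRISPRa sgRNA library design by TSS-window round relaxation.

The heuristic targets a window around each gene's transcription start site:
repression works best just downstream of the TSS (+25..+75 nt), activation
just upstream (-150..-75 nt). TSS positions are resolved from CAGE peak
annotations first (the representative p1 promoter), falling back to Ensembl
and then NCBI when a gene has no CAGE record. All candidate protospacers with
an NGG PAM within -300..+300 of the TSS are enumerated on both strands, then
picked in successive *rounds*: the first round demands the preferred window,
at most one perfect-match genomic site and a high on-target score, and each
later round relaxes one or more of the three criteria — never tightening any
— until a quota of six sgRNAs per gene is filled. Within a round candidates
rank by on-target score (ties by sequence). The top three picks form Set A,
the next three Set B. A standard complement of non-targeting controls (992
by default), random 20-mers with zero perfect-match sites, completes a
library.

Offsets use an explicit convention: the signed distance from the TSS to the
PAM-proximal base of the protospacer, positive in the direction of
transcription, measured on the gene's strand. The window bounds are
inclusive.

Oligos for array synthesis embed each protospacer between fixed BsmBI
(CGTCTC) flanks so Golden Gate cloning releases the CACCG/GTTT overhangs, and
are bracketed by one of six subpool-specific primer pairs; the reverse primer
is appended as the reverse complement of its 5'->3' sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

__all__ = [
    "TssRecord",
    "SgRnaCandidate",
    "PickingRound",
    "PickingPolicy",
    "LibraryPick",
    "PickResult",
    "RoundAssignment",
    "resolve_tss",
    "enumerate_candidates",
    "annotate_candidates",
    "pick_sgrnas",
    "assign_rounds",
    "add_controls",
    "SequenceGenomeIndex",
    "assemble_oligos",
    "p1_fraction",
    "PRIMER_SETS",
    "OLIGO_FLANK_5",
    "OLIGO_FLANK_3",
    "CRISPRI_WINDOW",
    "CRISPRA_WINDOW",
    "ENUMERATION_WINDOW",
]

#: subpool amplification primer pairs (forward, reverse), both written 5'->3'
PRIMER_SETS: dict[int, tuple[str, str]] = {
    1: ("AGGCACTTGCTCGTACGACG", "ATGTGGGCCCGGCACCTTAA"),
    2: ("GTGTAACCCGTAGGGCACCT", "GTCGAGAGCAGTCCTTCGAC"),
    3: ("CAGCGCCAATGGGCTTTCGA", "AGCCGCTTAAGAGCCTGTCG"),
    4: ("CTACAGGTACCGGTCCTGAG", "GTACCTAGCGTGACGATCCG"),
    5: ("CATGTTGCCCTGAGGCACAG", "CCGTTAGGTCCCGAAAGGCT"),
    6: ("GGTCGTCGCATCACAATGCG", "TCTCGAGCGCCAATGTGACG"),
}

#: BsmBI site + CACC overhang + leading G, 5' of the protospacer
OLIGO_FLANK_5 = "CGTCTCACACCG"
#: GTTT overhang + BsmBI site (reverse strand), 3' of the protospacer
OLIGO_FLANK_3 = "GTTTCGAGACG"

CRISPRI_WINDOW = (25, 75)    # optimal repression window, nt downstream of TSS
CRISPRA_WINDOW = (-150, -75)  # optimal activation window, nt upstream of TSS
ENUMERATION_WINDOW = (-300, 300)

TSS_SOURCES = ("FANTOM_CAGE", "Ensembl", "NCBI")


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    position: int  # 1-based genomic coordinate
    strand: str
    source: str
    p1_reads: int | None = None
    total_promoter_reads: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.gene}: TSS position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be + or -")
        if self.source not in TSS_SOURCES:
            raise ValueError(f"{self.gene}: unknown TSS source {self.source!r}")


@dataclass(frozen=True)
class SgRnaCandidate:
    sequence: str         # 20-nt protospacer, 5'->3' on its own strand
    pam: str              # 3-nt NGG
    strand: str           # genomic strand of the protospacer
    tss_offset: int       # PAM-proximal base offset from TSS, + downstream
    on_target_score: float | None = None
    perfect_match_sites: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != 20:
            raise ValueError(f"protospacer must be 20 nt: {self.sequence!r}")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG: {self.pam!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class PickingRound:
    """Eligibility predicate of one relaxation round (all bounds inclusive)."""

    window: tuple[int, int]
    max_perfect_match_sites: int
    min_on_target_score: float | None

    def eligible(self, cand: SgRnaCandidate) -> bool:
        if cand.on_target_score is None or cand.perfect_match_sites is None:
            return False
        lo, hi = self.window
        if not (lo <= cand.tss_offset <= hi):
            return False
        if cand.perfect_match_sites > self.max_perfect_match_sites:
            return False
        if self.min_on_target_score is not None and cand.on_target_score < self.min_on_target_score:
            return False
        return True


@dataclass(frozen=True)
class PickingPolicy:
    """Ordered, strictly non-tightening relaxation rounds plus the quota.

    The shipped defaults are a reconstruction of the published heuristic's
    shape (preferred window, then window relaxation, then off-target
    relaxation, then dropping the score floor); the exact published
    per-round thresholds live in supplementary material not reproduced here.
    """

    modality: str  # "CRISPRi" or "CRISPRa"
    rounds: tuple[PickingRound, ...]
    quota: int = 6

    def __post_init__(self) -> None:
        if self.modality not in ("CRISPRi", "CRISPRa"):
            raise ValueError("modality must be CRISPRi or CRISPRa")
        if self.quota < 1:
            raise ValueError("quota must be >= 1")
        if not self.rounds:
            raise ValueError("policy needs at least one round")
        for prev, cur in zip(self.rounds, self.rounds[1:]):
            if cur.window[0] > prev.window[0] or cur.window[1] < prev.window[1]:
                raise ValueError("rounds must not tighten the TSS window")
            if cur.max_perfect_match_sites < prev.max_perfect_match_sites:
                raise ValueError("rounds must not tighten the off-target bound")
            prev_floor = -np.inf if prev.min_on_target_score is None else prev.min_on_target_score
            cur_floor = -np.inf if cur.min_on_target_score is None else cur.min_on_target_score
            if cur_floor > prev_floor:
                raise ValueError("rounds must not tighten the score floor")

    @classmethod
    def default(cls, modality: str, quota: int = 6) -> "PickingPolicy":
        preferred = CRISPRI_WINDOW if modality == "CRISPRi" else CRISPRA_WINDOW
        return cls(
            modality=modality,
            quota=quota,
            rounds=(
                PickingRound(preferred, 1, 0.5),
                PickingRound(ENUMERATION_WINDOW, 1, 0.5),
                PickingRound(ENUMERATION_WINDOW, 5, 0.5),
                PickingRound(ENUMERATION_WINDOW, 5, None),
            ),
        )


@dataclass(frozen=True)
class LibraryPick:
    gene: str
    sgrna: SgRnaCandidate
    round_index: int       # 1-based
    rank_within_gene: int  # 1..quota
    set_assignment: str    # "A" = ranks 1-3, "B" = ranks 4-6


@dataclass
class PickResult:
    picks: list[LibraryPick]
    shortfall: dict[str, int]  # gene -> picks obtained, for genes under quota

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": p.gene,
                "sequence": p.sgrna.sequence,
                "pam": p.sgrna.pam,
                "strand": p.sgrna.strand,
                "tss_offset": p.sgrna.tss_offset,
                "on_target_score": p.sgrna.on_target_score,
                "perfect_match_sites": p.sgrna.perfect_match_sites,
                "round_index": p.round_index,
                "rank_within_gene": p.rank_within_gene,
                "set_assignment": p.set_assignment,
            }
            for p in self.picks
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSS resolution
# ---------------------------------------------------------------------------

def _table_lookup(df: pd.DataFrame | None) -> dict[str, pd.Series]:
    if df is None or len(df) == 0:
        return {}
    first = df.drop_duplicates(subset="gene", keep="first")
    return {str(r["gene"]): r for _, r in first.iterrows()}


def resolve_tss(
    cage_table: pd.DataFrame | None,
    ensembl_table: pd.DataFrame | None,
    ncbi_table: pd.DataFrame | None,
    genes: Iterable[str],
) -> tuple[dict[str, TssRecord], list[str]]:
    """Resolve one TSS per gene: CAGE first, then Ensembl, then NCBI.

    Tables need columns ``gene``, ``chrom``, ``position``, ``strand``; the
    CAGE table may also carry ``p1_reads`` and ``total_promoter_reads``.
    Genes absent from all three sources are returned in the undesignable
    list rather than silently dropped.
    """
    sources = [
        ("FANTOM_CAGE", _table_lookup(cage_table)),
        ("Ensembl", _table_lookup(ensembl_table)),
        ("NCBI", _table_lookup(ncbi_table)),
    ]
    records: dict[str, TssRecord] = {}
    undesignable: list[str] = []
    for gene in genes:
        for source, lookup in sources:
            row = lookup.get(gene)
            if row is None:
                continue
            records[gene] = TssRecord(
                gene=gene,
                chrom=str(row["chrom"]),
                position=int(row["position"]),
                strand=str(row["strand"]),
                source=source,
                p1_reads=int(row["p1_reads"]) if "p1_reads" in row and pd.notna(row["p1_reads"]) else None,
                total_promoter_reads=(
                    int(row["total_promoter_reads"])
                    if "total_promoter_reads" in row and pd.notna(row["total_promoter_reads"])
                    else None
                ),
            )
            break
        else:
            undesignable.append(gene)
    return records, undesignable


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

class LocusTooShortError(ValueError):
    pass


def enumerate_candidates(
    locus_sequence: str,
    tss_index: int,
    gene_strand: str = "+",
    window: tuple[int, int] = ENUMERATION_WINDOW,
) -> list[SgRnaCandidate]:
    """All NGG-adjacent 20-mers on either strand within the TSS window.

    ``locus_sequence`` is the genomic plus strand; ``tss_index`` is the
    0-based index of the TSS base within it. The candidate offset is the
    signed distance from the TSS to the PAM-proximal protospacer base,
    positive in the direction of transcription (``gene_strand``); the window
    bounds are inclusive. The locus must span the window plus 30 nt of
    context on each side.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be + or -")
    seq = locus_sequence.upper()
    lo, hi = window
    span = max(abs(lo), abs(hi)) + 30
    if tss_index < span or (len(seq) - 1 - tss_index) < span:
        raise LocusTooShortError(
            f"locus must span TSS +/- {span} nt; have {tss_index} upstream and "
            f"{len(seq) - 1 - tss_index} downstream"
        )
    sign = 1 if gene_strand == "+" else -1
    out: list[SgRnaCandidate] = []
    # plus strand: protospacer [i, i+19], PAM [i+20, i+22], proximal base i+19
    for i in range(0, len(seq) - 22):
        if seq[i + 21 : i + 23] == "GG":
            offset = sign * ((i + 19) - tss_index)
            if lo <= offset <= hi:
                out.append(
                    SgRnaCandidate(
                        sequence=seq[i : i + 20],
                        pam=seq[i + 20 : i + 23],
                        strand="+",
                        tss_offset=offset,
                    )
                )
        # minus strand: PAM complement CCN at [i, i+2], protospacer [i+3, i+22],
        # PAM-proximal base at genomic index i+3
        if seq[i : i + 2] == "CC":
            offset = sign * ((i + 3) - tss_index)
            if lo <= offset <= hi:
                out.append(
                    SgRnaCandidate(
                        sequence=reverse_complement(seq[i + 3 : i + 23]),
                        pam=reverse_complement(seq[i : i + 3]),
                        strand="-",
                        tss_offset=offset,
                    )
                )
    return out


def annotate_candidates(
    candidates: Iterable[SgRnaCandidate],
    scores: Mapping[str, float],
    offtargets: Mapping[str, int],
) -> list[SgRnaCandidate]:
    """Attach precomputed on-target scores and perfect-match site counts."""
    out = []
    for c in candidates:
        out.append(
            SgRnaCandidate(
                sequence=c.sequence,
                pam=c.pam,
                strand=c.strand,
                tss_offset=c.tss_offset,
                on_target_score=scores.get(c.sequence, c.on_target_score),
                perfect_match_sites=offtargets.get(c.sequence, c.perfect_match_sites),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------

def _set_for_rank(rank: int) -> str:
    return "A" if rank <= 3 else "B"


def pick_sgrnas(
    candidates: Mapping[str, Sequence[SgRnaCandidate]],
    policy: PickingPolicy,
) -> PickResult:
    """Fill the per-gene quota round by round.

    Rounds run in order; within a round, eligible not-yet-picked candidates
    are ranked by on-target score descending (ties by sequence) and taken
    until the quota fills. Each pick records the round that admitted it.
    Genes that exhaust all rounds below quota emit what they have and are
    listed in ``shortfall`` — shortfalls are data, not errors.
    """
    picks: list[LibraryPick] = []
    shortfall: dict[str, int] = {}
    for gene in sorted(candidates):
        chosen: list[tuple[SgRnaCandidate, int]] = []
        taken: set[str] = set()
        for round_index, rnd in enumerate(policy.rounds, start=1):
            if len(chosen) >= policy.quota:
                break
            eligible = [
                c
                for c in candidates[gene]
                if c.sequence not in taken and rnd.eligible(c)
            ]
            eligible.sort(key=lambda c: (-c.on_target_score, c.sequence))
            for c in eligible:
                if len(chosen) >= policy.quota:
                    break
                chosen.append((c, round_index))
                taken.add(c.sequence)
        for rank, (c, round_index) in enumerate(chosen, start=1):
            picks.append(
                LibraryPick(
                    gene=gene,
                    sgrna=c,
                    round_index=round_index,
                    rank_within_gene=rank,
                    set_assignment=_set_for_rank(rank),
                )
            )
        if len(chosen) < policy.quota:
            shortfall[gene] = len(chosen)
    return PickResult(picks=picks, shortfall=shortfall)


@dataclass
class RoundAssignment:
    """Per-sgRNA earliest-round labels for an external library."""

    labels: list[int | str]  # round index, "none", or "unassignable"
    fractions: dict[str, float]

    def fraction(self, round_index: int) -> float:
        return self.fractions.get(str(round_index), 0.0)


def assign_rounds(
    library: Iterable[SgRnaCandidate],
    policy: PickingPolicy,
) -> RoundAssignment:
    """Label each sgRNA with the earliest round whose predicate it satisfies.

    sgRNAs missing score or off-target annotations are labelled
    ``"unassignable"``; ones satisfying no round are ``"none"``. Fractions
    over {rounds, none, unassignable} sum to 1.
    """
    labels: list[int | str] = []
    for cand in library:
        if cand.on_target_score is None or cand.perfect_match_sites is None:
            labels.append("unassignable")
            continue
        for round_index, rnd in enumerate(policy.rounds, start=1):
            if rnd.eligible(cand):
                labels.append(round_index)
                break
        else:
            labels.append("none")
    n = len(labels)
    tally: dict[str, int] = {}
    for lab in labels:
        key = str(lab)
        tally[key] = tally.get(key, 0) + 1
    fractions = {key: cnt / n for key, cnt in tally.items()} if n else {}
    return RoundAssignment(labels=labels, fractions=fractions)


# ---------------------------------------------------------------------------
# Non-targeting controls
# ---------------------------------------------------------------------------

class SequenceGenomeIndex:
    """Perfect-match lookup over explicit genomic sequences.

    Counts occurrences of protospacer+NGG (23-mers) on both strands of the
    provided sequences by exact string search.
    """

    def __init__(self, sequences: Iterable[str]):
        seqs = [s.upper() for s in sequences]
        self._texts = seqs + [reverse_complement(s) for s in seqs]

    def perfect_match_sites(self, protospacer: str) -> int:
        protospacer = protospacer.upper()
        n = 0
        for pam_n in "ACGT":
            target = protospacer + pam_n + "GG"
            for text in self._texts:
                start = text.find(target)
                while start >= 0:
                    n += 1
                    start = text.find(target, start + 1)
        return n


def add_controls(
    genome_index: SequenceGenomeIndex | Callable[[str], int],
    n: int = 992,
    seed: int = 0,
    max_attempts: int | None = None,
) -> pd.DataFrame:
    """Generate ``n`` non-targeting control sgRNAs (zero perfect-match sites).

    Random 20-mers are drawn and kept only if the genome index reports no
    perfect-match protospacer+NGG site. Deterministic given ``seed``; raises
    ``RuntimeError`` if the attempt budget (default ``1000 * n``) runs out.
    """
    count = (
        genome_index.perfect_match_sites
        if isinstance(genome_index, SequenceGenomeIndex)
        else genome_index
    )
    rng = np.random.default_rng(seed)
    max_attempts = max_attempts or 1000 * n
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {n} non-targeting controls in {max_attempts} attempts"
            )
        attempts += 1
        seq = "".join(bases[rng.integers(0, 4, size=20)])
        if seq in seen:
            continue
        seen.add(seq)
        if count(seq) == 0:
            out.append(seq)
    return pd.DataFrame(
        {
            "sgrna_sequence": out,
            "sgrna_id": [f"NO_SITE_{i + 1:04d}" for i in range(n)],
            "gene": ["NO_SITE"] * n,
            "is_control": [True] * n,
            "perfect_match_sites": [0] * n,
        }
    )


# ---------------------------------------------------------------------------
# Oligo assembly
# ---------------------------------------------------------------------------

def assemble_oligos(protospacers: Iterable[str], primer_set: int) -> list[str]:
    """Full-length synthesis oligos for a subpool.

    oligo = forward_primer + CGTCTCACACCG + protospacer + GTTTCGAGACG +
    reverse-complement(reverse primer). With 20-nt primers and a 20-nt
    protospacer each oligo is 83 nt.
    """
    if primer_set not in PRIMER_SETS:
        raise ValueError(f"unknown primer set {primer_set}; expected 1..6")
    fwd, rev = PRIMER_SETS[primer_set]
    rev_rc = reverse_complement(rev)
    out = []
    for p in protospacers:
        p = p.upper()
        if len(p) != 20 or set(p) - set("ACGT"):
            raise ValueError(f"protospacer must be a 20-nt DNA string: {p!r}")
        out.append(f"{fwd}{OLIGO_FLANK_5}{p}{OLIGO_FLANK_3}{rev_rc}")
    return out


# ---------------------------------------------------------------------------
# TSS confidence
# ---------------------------------------------------------------------------

def p1_fraction(promoter_reads: pd.DataFrame) -> float:
    """Fraction of a gene's CAGE peak reads assigned to its p1 promoter.

    ``promoter_reads`` has columns ``promoter_rank`` (1 = p1) and ``reads``.
    A gene whose promoters carry zero total reads raises ``ValueError``.
    """
    reads = promoter_reads["reads"].astype(float)
    if (reads < 0).any():
        raise ValueError("negative read counts")
    total = reads.sum()
    if total <= 0:
        raise ValueError("zero total promoter reads")
    p1 = reads[promoter_reads["promoter_rank"] == 1].sum()
    return float(p1 / total)
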