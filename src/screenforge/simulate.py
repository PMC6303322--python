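"""Synthetic pooled screens with known ground truth.

The generator mimics the structure of a real pooled screen: sgRNA abundances
in the plasmid pool are log-normally skewed (cloning bottleneck), each sgRNA
carries an efficacy drawn from a Beta distribution (design quality), and its
deterministic log2 effect is the product of gene effect and efficacy — an
inactive guide shows no phenotype. In knockout mode every targeting guide
additionally pays a cutting-toxicity offset (double-strand-break growth
penalty) that non-targeting controls escape. Positive-selection (drug)
screens add an enrichment effect for planted resistance genes in the
treatment arm. Post-selection proportions are the plasmid proportions scaled
by 2^(true LFC + replicate noise) and sequencing counts are drawn
multinomially at the configured depth, optionally overdispersed through a
Dirichlet-multinomial with a single dispersion scalar (multinomial limit as
dispersion -> 0). Everything is deterministic given the seed.

The companion :func:`simulate_fastq` renders a count matrix into raw reads
(random-length stagger + vector context ending in the CACCG anchor +
protospacer + scaffold) so the whole deconvolution path can be exercised,
and :func:`make_design_fixture` plants PAM sites with controlled annotations
into synthetic loci so the picking heuristic has a unique known answer.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import PickingPolicy, SgRnaCandidate
from .io import CountMatrix, LibraryReference, SampleSheet, TALLY_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimScreen",
    "DesignFixture",
    "simulate_screen",
    "simulate_fastq",
    "make_design_fixture",
    "DEFAULT_VECTOR_PREFIX",
    "DEFAULT_VECTOR_SUFFIX",
]

#: U6 cassette junction ending in the CACCG anchor (its only occurrence)
DEFAULT_VECTOR_PREFIX = "TTGTGGAAAGGACGAAACACCG"
#: start of the sgRNA scaffold, 3' of the protospacer
DEFAULT_VECTOR_SUFFIX = "GTTTTAGAGCTAGAAATAGCAAGTT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults emulate a compact genome-wide knockout dropout screen: 4 guides
    per gene, ~20% essential genes with a strong mean depletion effect
    (-3 log2 units at full efficacy), guide efficacies skewed high
    (Beta(5,1), a well-designed library), a modest cutting-toxicity offset
    for all targeting guides, 500x sequencing coverage and light
    overdispersion. Setting ``n_resistance > 0`` adds a drug-treatment arm
    with planted enrichment genes (positive selection, CRISPRa-style).
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 4
    n_controls: int = 992
    frac_essential: float = 0.2
    essential_effect: float = -3.0
    n_resistance: int = 0
    resistance_effect: float = 3.0
    efficacy_beta: tuple[float, float] = (5.0, 1.0)
    modality: str = "crisprko"  # "crisprko" | "crispri" | "crispra"
    cutting_penalty: float = -0.5  # applied to targeting guides in crisprko only
    noise_sd: float = 0.25
    depth: int | None = None  # reads per condition; default 500x coverage
    dispersion: float = 0.01
    pdna_sigma: float = 0.5  # log-normal sigma of plasmid abundances
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_essential <= 1.0):
            raise ValueError("frac_essential must be in [0,1]")
        if self.n_genes < 1 or self.sgrnas_per_gene < 1 or self.replicates < 1:
            raise ValueError("n_genes, sgrnas_per_gene and replicates must be >= 1")
        if self.n_resistance > self.n_genes:
            raise ValueError("n_resistance cannot exceed n_genes")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise_sd must be non-negative")
        if self.modality not in ("crisprko", "crispri", "crispra"):
            raise ValueError("modality must be crisprko, crispri or crispra")
        a, b = self.efficacy_beta
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError("efficacy_beta parameters must be positive and finite")

    @property
    def effective_depth(self) -> int:
        n_sgrnas = self.n_genes * self.sgrnas_per_gene + self.n_controls
        return self.depth if self.depth is not None else 500 * n_sgrnas


@dataclass
class SimTruth:
    """Ground truth: per-gene class and per-sgRNA efficacy / true LFC.

    ``genes`` columns: gene, gene_class (essential | resistance |
    nonessential | control). ``sgrnas`` columns: sgrna_id, gene, efficacy,
    true_lfc_dropout, true_lfc_treatment (deterministic effects, before
    replicate noise).
    """

    genes: pd.DataFrame
    sgrnas: pd.DataFrame


@dataclass
class SimScreen:
    counts: CountMatrix
    reference: LibraryReference
    samples: SampleSheet
    truth: SimTruth
    config: SimConfig


def _unique_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        batch = ["".join(bases[rng.integers(0, 4, size=k)]) for _ in range(n - len(out))]
        for s in batch:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _draw_counts(
    rng: np.random.Generator, props: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    """Multinomial draw, Dirichlet-overdispersed when ``dispersion > 0``.

    ``dispersion`` is the squared coefficient of variation of the
    extra-multinomial abundance noise for an equi-abundant guide: the
    Dirichlet concentration is ``n / dispersion`` so a typical guide's
    proportion fluctuates with CV ~ sqrt(dispersion). Multinomial (Poisson)
    limit as dispersion -> 0.
    """
    props = props / props.sum()
    if dispersion > 0:
        props = rng.dirichlet(props * len(props) / dispersion)
    return rng.multinomial(depth, props)


def simulate_screen(config: SimConfig) -> SimScreen:
    """Simulate counts, library reference, sample sheet and ground truth."""
    rng = np.random.default_rng(config.seed)
    n_targeting = config.n_genes * config.sgrnas_per_gene
    n_sgrnas = n_targeting + config.n_controls

    # gene classes: essential, then resistance, remainder nonessential
    n_ess = int(round(config.frac_essential * config.n_genes))
    n_res = config.n_resistance
    if n_ess + n_res > config.n_genes:
        raise ValueError("essential + resistance genes exceed n_genes")
    classes = (
        ["essential"] * n_ess
        + ["resistance"] * n_res
        + ["nonessential"] * (config.n_genes - n_ess - n_res)
    )
    genes = [
        f"{cls[:3].upper()}{i + 1:05d}" for i, cls in enumerate(classes)
    ]  # ESS / RES / NON prefixes

    gene_dropout_effect = np.where(
        np.array(classes) == "essential", config.essential_effect, 0.0
    )
    gene_treatment_extra = np.where(
        np.array(classes) == "resistance", config.resistance_effect, 0.0
    )

    # per-sgRNA structure
    sg_gene_idx = np.repeat(np.arange(config.n_genes), config.sgrnas_per_gene)
    a, b = config.efficacy_beta
    efficacy_t = rng.beta(a, b, size=n_targeting)
    penalty = config.cutting_penalty if config.modality == "crisprko" else 0.0
    true_dropout_t = gene_dropout_effect[sg_gene_idx] * efficacy_t + penalty
    true_treatment_t = true_dropout_t + gene_treatment_extra[sg_gene_idx] * efficacy_t

    efficacy = np.concatenate([efficacy_t, np.zeros(config.n_controls)])
    true_dropout = np.concatenate([true_dropout_t, np.zeros(config.n_controls)])
    true_treatment = np.concatenate([true_treatment_t, np.zeros(config.n_controls)])

    sg_ids = [
        f"{genes[g]}_sg{j + 1}"
        for g, j in zip(sg_gene_idx, itertools.cycle(range(config.sgrnas_per_gene)))
    ] + [f"NO_SITE_{i + 1:04d}" for i in range(config.n_controls)]
    sg_genes = [genes[g] for g in sg_gene_idx] + ["NO_SITE"] * config.n_controls
    is_control = [False] * n_targeting + [True] * config.n_controls
    sequences = _unique_kmers(rng, n_sgrnas, 20)

    reference = LibraryReference(
        pd.DataFrame(
            {
                "sgrna_sequence": sequences,
                "sgrna_id": sg_ids,
                "gene": sg_genes,
                "is_control": is_control,
            }
        )
    )

    # conditions
    drug = n_res > 0
    rows = [
        {"condition": "pDNA", "barcode": "", "replicate": "pDNA", "arm": "pDNA", "treatment_label": ""}
    ]
    for r in range(1, config.replicates + 1):
        rows.append(
            {"condition": f"dropout_rep{r}", "barcode": "", "replicate": f"rep{r}", "arm": "dropout", "treatment_label": ""}
        )
    if drug:
        for r in range(1, config.replicates + 1):
            rows.append(
                {
                    "condition": f"treatment_rep{r}",
                    "barcode": "",
                    "replicate": f"rep{r}",
                    "arm": "treatment",
                    "treatment_label": "drug",
                }
            )
    barcodes = _unique_kmers(rng, len(rows), 8)
    for row, bc in zip(rows, barcodes):
        row["barcode"] = bc
    samples = SampleSheet(pd.DataFrame(rows))

    # abundances and counts
    depth = config.effective_depth
    pdna_props = np.exp(rng.normal(0.0, config.pdna_sigma, size=n_sgrnas))
    pdna_props /= pdna_props.sum()
    count_cols: dict[str, np.ndarray] = {
        "pDNA": _draw_counts(rng, pdna_props, depth, config.dispersion)
    }
    for r in range(1, config.replicates + 1):
        noise = rng.normal(0.0, config.noise_sd, size=n_sgrnas)
        props = pdna_props * np.exp2(true_dropout + noise)
        count_cols[f"dropout_rep{r}"] = _draw_counts(rng, props, depth, config.dispersion)
        if drug:
            noise_t = rng.normal(0.0, config.noise_sd, size=n_sgrnas)
            props_t = pdna_props * np.exp2(true_treatment + noise_t)
            count_cols[f"treatment_rep{r}"] = _draw_counts(
                rng, props_t, depth, config.dispersion
            )

    counts = CountMatrix(
        counts=pd.DataFrame(
            count_cols, index=pd.Index(sg_ids, name="sgrna_id")
        )[samples.conditions]
    )

    truth = SimTruth(
        genes=pd.DataFrame({"gene": genes, "gene_class": classes}),
        sgrnas=pd.DataFrame(
            {
                "sgrna_id": sg_ids,
                "gene": sg_genes,
                "efficacy": efficacy,
                "true_lfc_dropout": true_dropout,
                "true_lfc_treatment": true_treatment,
            }
        ),
    )
    return SimScreen(counts=counts, reference=reference, samples=samples, truth=truth, config=config)


# ---------------------------------------------------------------------------
# FASTQ rendering
# ---------------------------------------------------------------------------

_STAGGER_BASES = "ACT"  # no G, so the stagger can never complete a CACCG anchor


def simulate_fastq(
    matrix: CountMatrix,
    reference: LibraryReference,
    samples: SampleSheet,
    reads_path: str | Path,
    index_path: str | Path,
    seed: int = 0,
    vector_prefix: str = DEFAULT_VECTOR_PREFIX,
    vector_suffix: str = DEFAULT_VECTOR_SUFFIX,
    stagger_max: int = 7,
    junk_reads: int = 0,
    anchor: str = "CACCG",
) -> int:
    """Render a count matrix into primary-read + index-read FASTQ files.

    Emits exactly ``count`` reads per (sgRNA, condition); each read is a
    random 0..``stagger_max`` nt stagger (drawn from A/C/T so no anchor can
    form upstream), the vector prefix whose first anchor occurrence must end
    it, the protospacer, and the scaffold suffix. The condition's barcode
    goes into the matching index read. ``junk_reads`` extra anchor-free reads
    (valid barcodes, cycled over conditions) can be injected. Read order is
    shuffled; everything is deterministic given ``seed``. Returns the number
    of reads written. Output is gzipped when the path ends in ``.gz``.
    """
    pos = vector_prefix.find(anchor)
    if pos < 0 or pos + len(anchor) != len(vector_prefix):
        raise ValueError(
            "vector_prefix must contain the anchor exactly at its 3' end "
            "(first occurrence defines the insert start)"
        )
    rng = np.random.default_rng(seed)
    id_to_seq = {v: k for k, v in reference.sequence_to_id().items()}
    cond_to_bc = {c: b for b, c in samples.barcode_to_condition().items()}

    entries: list[tuple[str, str]] = []  # (read sequence, barcode)
    for cond in matrix.conditions:
        bc = cond_to_bc[cond]
        col = matrix.counts[cond]
        for sid, cnt in col.items():
            if cnt == 0:
                continue
            proto = id_to_seq[sid]
            for _ in range(int(cnt)):
                stag_len = int(rng.integers(0, stagger_max + 1))
                stagger = "".join(
                    _STAGGER_BASES[i] for i in rng.integers(0, len(_STAGGER_BASES), stag_len)
                )
                entries.append((stagger + vector_prefix + proto + vector_suffix, bc))
    conds = matrix.conditions
    junk_len = len(vector_prefix) + 27
    for j in range(junk_reads):
        seq = "".join(
            _STAGGER_BASES[i] for i in rng.integers(0, len(_STAGGER_BASES), junk_len)
        )
        entries.append((seq, cond_to_bc[conds[j % len(conds)]]))

    order = rng.permutation(len(entries))
    opener = lambda p: gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
    with opener(reads_path) as r1, opener(index_path) as i1:
        for k, idx in enumerate(order):
            seq, bc = entries[idx]
            r1.write(f"@read{k}\n{seq}\n+\n{'I' * len(seq)}\n")
            i1.write(f"@read{k}\n{bc}\n+\n{'I' * len(bc)}\n")
    return len(entries)


# ---------------------------------------------------------------------------
# Design fixtures with planted candidates
# ---------------------------------------------------------------------------

@dataclass
class DesignFixture:
    """Synthetic loci with planted PAM sites and a unique expected pick table."""

    loci: dict[str, str]            # gene -> plus-strand locus sequence
    tss_index: dict[str, int]       # gene -> 0-based TSS index in the locus
    tss_table: pd.DataFrame
    scores: dict[str, float]        # protospacer -> on-target score
    offtargets: dict[str, int]      # protospacer -> perfect-match site count
    expected_picks: pd.DataFrame
    policy: PickingPolicy
    candidates: dict[str, list[SgRnaCandidate]] = field(default_factory=dict)


# offset slots per round, spaced 10 nt so planted PAMs never collide;
# rounds 2-4 sit outside / fail earlier-round predicates by construction
_ROUND_SLOTS = {
    1: [25 + 10 * k for k in range(6)],      # inside the CRISPRi window, pm<=1, score>=0.5
    2: [100 + 10 * k for k in range(12)],    # outside round-1 window, pm<=1, score>=0.5
    3: [-300 + 10 * k for k in range(12)],   # pm in 2..5 fails rounds 1-2
    4: [-90 + 10 * k for k in range(6)],     # score < 0.5 fails rounds 1-3
}


def make_design_fixture(
    n_genes: int,
    plants_per_round: Mapping[int, int],
    seed: int = 0,
    quota: int = 6,
) -> DesignFixture:
    """Plant candidates at known offsets so the picking outcome is forced.

    Loci are A/T background (no PAM can occur) with ``TGG`` PAMs inserted at
    the requested offsets; each plant's protospacer is the 20-mer preceding
    its PAM, so the enumerated candidate set equals the planted set exactly.
    Plants intended for round r carry annotations that satisfy round r and
    fail every earlier round. The expected pick table is derived directly
    from the planted metadata — sorted by (round, score descending,
    sequence) and cut at the quota — independently of the picker.
    """
    policy = PickingPolicy.default("CRISPRi", quota=quota)
    bad = set(plants_per_round) - set(_ROUND_SLOTS)
    if bad:
        raise ValueError(f"infeasible plant request: unknown round(s) {sorted(bad)}")
    for r, cnt in plants_per_round.items():
        if cnt < 0 or cnt > len(_ROUND_SLOTS[r]):
            raise ValueError(
                f"infeasible plant request: round {r} supports at most "
                f"{len(_ROUND_SLOTS[r])} plants, asked {cnt}"
            )
    rng = np.random.default_rng(seed)
    L = 350  # TSS index; locus length 2L+1 covers the enumeration window + context
    loci: dict[str, str] = {}
    tss_index: dict[str, int] = {}
    scores: dict[str, float] = {}
    offtargets: dict[str, int] = {}
    rows = []
    expected_rows = []
    seen_protospacers: set[str] = set()

    for g in range(n_genes):
        gene = f"GENE{g + 1:04d}"
        for attempt in range(100):
            background = "".join("AT"[i] for i in rng.integers(0, 2, size=2 * L + 1))
            locus = list(background)
            plant_meta = []  # (round, offset, protospacer)
            ok = True
            for r in sorted(plants_per_round):
                for offset in _ROUND_SLOTS[r][: plants_per_round[r]]:
                    pam_start = L + offset + 1  # PAM-proximal base at L+offset
                    locus[pam_start : pam_start + 3] = list("TGG")
            seq = "".join(locus)
            for r in sorted(plants_per_round):
                for offset in _ROUND_SLOTS[r][: plants_per_round[r]]:
                    i = L + offset - 19
                    proto = seq[i : i + 20]
                    if proto in seen_protospacers:
                        ok = False
                        break
                    plant_meta.append((r, offset, proto))
                if not ok:
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not generate unique protospacers")
        for r, offset, proto in plant_meta:
            seen_protospacers.add(proto)
            if r == 4:
                score = float(rng.uniform(0.05, 0.45))
            else:
                score = float(rng.uniform(0.55, 0.95))
            pm = 3 if r == 3 else (int(rng.integers(0, 2)) if r != 4 else 4)
            scores[proto] = score
            offtargets[proto] = pm
        loci[gene] = seq
        tss_index[gene] = L
        rows.append(
            {"gene": gene, "chrom": f"chr_{gene}", "position": L + 1, "strand": "+", "source": "FANTOM_CAGE"}
        )
        ordered = sorted(
            plant_meta, key=lambda m: (m[0], -scores[m[2]], m[2])
        )[:quota]
        for rank, (r, offset, proto) in enumerate(ordered, start=1):
            expected_rows.append(
                {
                    "gene": gene,
                    "sequence": proto,
                    "tss_offset": offset,
                    "round_index": r,
                    "rank_within_gene": rank,
                    "set_assignment": "A" if rank <= 3 else "B",
                }
            )

    return DesignFixture(
        loci=loci,
        tss_index=tss_index,
        tss_table=pd.DataFrame(rows),
        scores=scores,
        offtargets=offtargets,
        expected_picks=pd.DataFrame(expected_rows),
        policy=policy,
    )
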