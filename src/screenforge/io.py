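"""File formats and read deconvolution for pooled CRISPR screens.

The on-disk formats are deliberately plain:

* **chip file** — tab- (or comma-) delimited library reference mapping each
  20-nt sgRNA sequence to a unique identifier and a gene symbol, optionally
  with a control flag and per-sgRNA feature columns (on-target score,
  perfect-match off-target count).
* **sample sheet** — one row per sequencing condition with its 8-nt sample
  barcode, replicate label and screen arm (``pDNA``, ``dropout`` or
  ``treatment``).
* **count matrix** — TSV with the sgRNA identifier in the first column and
  one integer column per condition; per-condition read tallies live in a
  ``#``-prefixed metadata block at the top of the file so the round trip is
  lossless.

Deconvolution follows the vector-anchor rule: the first occurrence of the
anchor (``CACCG`` by default, the 3' end of the human U6 priming region) in
the primary read marks the start of the sgRNA insert; the next 20 nt are
matched exactly against the library reference. The sample barcode comes from
a separate index read or from a fixed in-read offset.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_ANCHOR = "CACCG"
#: reserved gene-label prefix for non-targeting control entries
CONTROL_GENE_PREFIX = "NO_SITE"

__all__ = [
    "LibraryReference",
    "SampleSheet",
    "CountMatrix",
    "ParseError",
    "ValidationError",
    "parse_library_reference",
    "parse_sample_sheet",
    "deconvolute_reads",
    "read_count_matrix",
    "write_count_matrix",
]


class ParseError(ValueError):
    """A malformed row or header in an input file (reports the line number)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


def _is_dna(s: str, length: int | None = None) -> bool:
    return (length is None or len(s) == length) and set(s) <= DNA_ALPHABET


# ---------------------------------------------------------------------------
# LibraryReference
# ---------------------------------------------------------------------------

_SEQ_ALIASES = {"sgrna_sequence", "sequence", "sgrna_seq", "seq"}
_ID_ALIASES = {"sgrna_id", "id", "sgrna", "guide_id"}
_GENE_ALIASES = {"gene", "gene_symbol", "annotated_gene_symbol"}
_CONTROL_ALIASES = {"is_control", "control"}
_SCORE_ALIASES = {"on_target_score", "score", "on_target_efficacy_score"}
_PM_ALIASES = {"perfect_match_sites", "off_targets", "perfect_match_off_targets"}


@dataclass(frozen=True)
class LibraryReference:
    """Validated sgRNA library reference ("chip file").

    ``table`` columns: ``sgrna_sequence`` (20-nt, unique), ``sgrna_id``
    (unique), ``gene``, ``is_control`` (bool) and optionally
    ``on_target_score`` / ``perfect_match_sites``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sgrna_sequence", "sgrna_id", "gene", "is_control"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"library reference missing columns: {missing}")
        bad = [s for s in t["sgrna_sequence"] if not _is_dna(str(s), 20)]
        if bad:
            raise ValidationError(
                f"{len(bad)} sgRNA sequence(s) are not 20-nt A/C/G/T strings, "
                f"e.g. {bad[0]!r}"
            )
        for col in ("sgrna_sequence", "sgrna_id"):
            dup = t[col][t[col].duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {col}: {dup.iloc[0]!r}")
        ctrl = t.loc[t["is_control"].astype(bool), "gene"]
        offenders = ctrl[~ctrl.astype(str).str.startswith(CONTROL_GENE_PREFIX)]
        if len(offenders):
            raise ValidationError(
                "control entries must use the reserved gene namespace "
                f"{CONTROL_GENE_PREFIX!r}; found {offenders.iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.table["sgrna_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_control"].astype(bool), "sgrna_id"])

    def sequence_to_id(self) -> dict[str, str]:
        return dict(zip(self.table["sgrna_sequence"], self.table["sgrna_id"]))

    def gene_map(self, include_controls: bool = False) -> dict[str, list[str]]:
        """gene -> list of sgrna_ids for targeting (and optionally control) entries."""
        t = self.table if include_controls else self.table[~self.table["is_control"].astype(bool)]
        out: dict[str, list[str]] = {}
        for gene, sub in t.groupby("gene", sort=True):
            out[str(gene)] = list(sub["sgrna_id"])
        return out

    def id_to_gene(self) -> dict[str, str]:
        return dict(zip(self.table["sgrna_id"], self.table["gene"]))


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    groups = [
        ("sgrna_sequence", _SEQ_ALIASES),
        ("sgrna_id", _ID_ALIASES),
        ("gene", _GENE_ALIASES),
        ("is_control", _CONTROL_ALIASES),
        ("on_target_score", _SCORE_ALIASES),
        ("perfect_match_sites", _PM_ALIASES),
    ]
    lowered = {c.lower(): c for c in columns}
    for canonical, aliases in groups:
        for alias in aliases:
            if alias in lowered:
                mapping[lowered[alias]] = canonical
                break
    return mapping


def parse_library_reference(path: str | Path, sep: str | None = None) -> LibraryReference:
    """Parse a chip file into a validated :class:`LibraryReference`.

    The header must name at least sequence, id and gene columns (a handful of
    common aliases are accepted). Tab-delimited by default; comma-delimited
    ``.csv`` files are detected from the extension unless ``sep`` is given.
    Malformed rows raise :class:`ParseError` with a 1-based line number
    (header = line 1); duplicate sequences or ids raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = _resolve_columns(df.columns)
    df = df.rename(columns=mapping)
    for col in ("sgrna_sequence", "sgrna_id", "gene"):
        if col not in df.columns:
            raise ParseError(f"{path}: header must name a {col} column")
    for i, seq in enumerate(df["sgrna_sequence"]):
        if not _is_dna(str(seq).upper(), 20):
            raise ParseError(
                f"{path}: line {i + 2}: sgRNA sequence {seq!r} is not a 20-nt "
                "A/C/G/T string"
            )
    for i, (sid, gene) in enumerate(zip(df["sgrna_id"], df["gene"])):
        if not str(sid) or not str(gene):
            raise ParseError(f"{path}: line {i + 2}: empty sgrna_id or gene field")
    df["sgrna_sequence"] = df["sgrna_sequence"].str.upper()
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].str.lower().isin({"1", "true", "yes"})
    else:
        df["is_control"] = df["gene"].astype(str).str.startswith(CONTROL_GENE_PREFIX)
    for col in ("on_target_score",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "perfect_match_sites" in df.columns:
        df["perfect_match_sites"] = pd.to_numeric(df["perfect_match_sites"], errors="coerce")
    return LibraryReference(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

ARMS = ("pDNA", "dropout", "treatment")


@dataclass(frozen=True)
class SampleSheet:
    """One row per condition: name, 8-nt barcode, replicate, arm, treatment label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["condition", "barcode", "replicate", "arm"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if t["condition"].duplicated().any():
            raise ValidationError("condition names must be unique")
        bad = [b for b in t["barcode"] if not _is_dna(str(b), 8)]
        if bad:
            raise ValidationError(f"barcodes must be unique 8-nt DNA strings; bad: {bad[0]!r}")
        if t["barcode"].duplicated().any():
            raise ValidationError("barcodes must be unique")
        unknown = set(t["arm"]) - set(ARMS)
        if unknown:
            raise ValidationError(f"unknown arm label(s): {sorted(unknown)}; expected {ARMS}")
        if not set(t["arm"]) & {"pDNA", "dropout"}:
            raise ValidationError(
                "sample sheet needs at least one pDNA or dropout reference condition"
            )

    @property
    def conditions(self) -> list[str]:
        return list(self.table["condition"])

    def barcode_to_condition(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["condition"]))


def parse_sample_sheet(path: str | Path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "treatment_label" not in df.columns:
        df["treatment_label"] = ""
    return SampleSheet(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

TALLY_COLUMNS = ("n_assigned", "n_no_anchor", "n_unmapped_insert")


@dataclass
class CountMatrix:
    """sgRNA x condition integer read counts plus deconvolution tallies.

    ``counts`` is indexed by ``sgrna_id`` with one column per condition.
    ``tallies`` is indexed by condition with columns ``n_assigned``,
    ``n_no_anchor`` and ``n_unmapped_insert``; reads whose sample barcode
    could not be resolved are counted once in the global
    ``n_unassigned_barcode``. Per input FASTQ,
    ``n_assigned + n_no_anchor + n_unmapped_insert + n_unassigned_barcode``
    equals the total number of reads processed.
    """

    counts: pd.DataFrame
    tallies: pd.DataFrame = None  # type: ignore[assignment]
    n_unassigned_barcode: int = 0

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.tallies is None:
            self.tallies = pd.DataFrame(
                0, index=self.counts.columns, columns=list(TALLY_COLUMNS), dtype=np.int64
            )
        self.tallies = self.tallies.astype(np.int64, copy=False)
        if (self.tallies.to_numpy() < 0).any() or self.n_unassigned_barcode < 0:
            raise ValidationError("tallies must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> int:
        """Total reads accounted for across all tallies (assigned + rejected)."""
        return int(
            self.tallies[["n_assigned", "n_no_anchor", "n_unmapped_insert"]].to_numpy().sum()
            + self.n_unassigned_barcode
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.tallies.reindex_like(other.tallies).equals(other.tallies)
            and self.n_unassigned_barcode == other.n_unassigned_barcode
        )


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

def _hamming1_resolver(barcodes: Mapping[str, str]):
    """Return barcode -> condition lookup tolerating <=1 mismatch, rejecting ambiguity."""
    exact = dict(barcodes)

    def resolve(bc: str) -> str | None:
        hit = exact.get(bc)
        if hit is not None:
            return hit
        matches = [
            cond
            for known, cond in exact.items()
            if sum(a != b for a, b in zip(known, bc)) <= 1
        ]
        if len(matches) == 1:
            return matches[0]
        return None  # unmatched or ambiguous

    return resolve


def _fastq_records(path: str | Path):
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.sequence.upper()


def deconvolute_reads(
    read_files: str | Path | Sequence[str | Path],
    reference: LibraryReference,
    samples: SampleSheet,
    index_files: str | Path | Sequence[str | Path] | None = None,
    barcode_offset: int | None = None,
    barcode_mismatches: int = 0,
    anchor: str = DEFAULT_ANCHOR,
) -> CountMatrix:
    """Count sgRNA reads per condition from raw FASTQ files.

    Each read is first assigned to a condition via its 8-nt sample barcode,
    taken either from a parallel index FASTQ (``index_files``) or from a fixed
    0-based offset within the read itself (``barcode_offset``). Reads with an
    unresolvable (or, at one allowed mismatch, ambiguous) barcode increment
    the global ``n_unassigned_barcode`` tally. The sgRNA insert is the 20 nt
    following the **first** occurrence of ``anchor``; inserts are matched by
    exact string equality against the library reference. Reads lacking the
    anchor increment ``n_no_anchor``; anchored reads whose insert is truncated
    or unknown increment ``n_unmapped_insert``.
    """
    if (index_files is None) == (barcode_offset is None):
        raise ValueError("exactly one of index_files or barcode_offset must be given")
    if barcode_mismatches not in (0, 1):
        raise ValueError("barcode_mismatches must be 0 or 1")
    read_files = [read_files] if isinstance(read_files, (str, Path)) else list(read_files)
    if index_files is not None:
        index_files = (
            [index_files] if isinstance(index_files, (str, Path)) else list(index_files)
        )
        if len(index_files) != len(read_files):
            raise ValueError("need one index FASTQ per read FASTQ")

    seq_to_id = reference.sequence_to_id()
    bc_map = samples.barcode_to_condition()
    resolve = bc_map.get if barcode_mismatches == 0 else _hamming1_resolver(bc_map)
    conditions = samples.conditions
    cond_idx = {c: j for j, c in enumerate(conditions)}
    id_idx = {sid: i for i, sid in enumerate(reference.sgrna_ids)}

    counts = np.zeros((len(reference), len(conditions)), dtype=np.int64)
    tallies = np.zeros((len(conditions), 3), dtype=np.int64)  # assigned, no_anchor, unmapped
    n_unassigned = 0

    for fi, rpath in enumerate(read_files):
        reads = _fastq_records(rpath)
        if index_files is not None:
            index = _fastq_records(index_files[fi])
            pairs = zip(reads, index, strict=True)
        else:
            pairs = ((r, None) for r in reads)
        for seq, idx_seq in pairs:
            if idx_seq is not None:
                bc = idx_seq[:8]
            else:
                bc = seq[barcode_offset : barcode_offset + 8]  # type: ignore[operator]
            cond = resolve(bc) if len(bc) == 8 else None
            if cond is None:
                n_unassigned += 1
                continue
            j = cond_idx[cond]
            pos = seq.find(anchor)
            if pos < 0:
                tallies[j, 1] += 1
                continue
            insert = seq[pos + len(anchor) : pos + len(anchor) + 20]
            sid = seq_to_id.get(insert) if len(insert) == 20 else None
            if sid is None:
                tallies[j, 2] += 1
            else:
                counts[id_idx[sid], j] += 1
                tallies[j, 0] += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=reference.sgrna_ids.rename("sgrna_id"), columns=conditions),
        tallies=pd.DataFrame(tallies, index=pd.Index(conditions, name="condition"), columns=list(TALLY_COLUMNS)),
        n_unassigned_barcode=n_unassigned,
    )
    return cm


# ---------------------------------------------------------------------------
# Count matrix round trip
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts + tallies to TSV (tallies in a ``#`` metadata block)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("# screenforge count matrix v1\n")
        fh.write(f"# n_unassigned_barcode\t{matrix.n_unassigned_barcode}\n")
        for cond, row in matrix.tallies.iterrows():
            fh.write(
                f"# tally\t{cond}\t{row['n_assigned']}\t{row['n_no_anchor']}"
                f"\t{row['n_unmapped_insert']}\n"
            )
        cols = "\t".join(str(c) for c in matrix.counts.columns)
        fh.write(f"sgrna_id\t{cols}\n" if len(matrix.counts.columns) else "sgrna_id\n")
        for sid, row in matrix.counts.iterrows():
            vals = "\t".join(str(int(v)) for v in row)
            fh.write(f"{sid}\t{vals}\n" if len(row) else f"{sid}\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a count matrix written by :func:`write_count_matrix`.

    Negative or non-integer counts raise :class:`ValidationError`. A matrix
    with zero sgRNAs round-trips to an empty matrix.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    tallies: dict[str, list[int]] = {}
    n_unassigned = 0
    header: list[str] | None = None
    rows: list[list[str]] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "n_unassigned_barcode":
                    n_unassigned = int(parts[1])
                elif parts[0] == "tally":
                    tallies[parts[1]] = [int(x) for x in parts[2:5]]
                continue
            if header is None:
                header = line.split("\t")
                if header[0] != "sgrna_id":
                    raise ParseError(f"{path}: line {lineno}: first column must be sgrna_id")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ParseError(f"{path}: no header line found")
    conditions = header[1:]
    index = [r[0] for r in rows]
    data = np.zeros((len(rows), len(conditions)), dtype=np.int64)
    for i, r in enumerate(rows):
        if len(r) != len(header):
            raise ParseError(f"{path}: row {i + 1} has {len(r)} fields, expected {len(header)}")
        for j, v in enumerate(r[1:]):
            try:
                iv = int(v)
            except ValueError as exc:
                raise ValidationError(f"{path}: non-integer count {v!r} for {r[0]}") from exc
            if iv < 0:
                raise ValidationError(f"{path}: negative count {iv} for {r[0]}")
            data[i, j] = iv
    counts = pd.DataFrame(data, index=pd.Index(index, name="sgrna_id"), columns=conditions)
    tally_df = pd.DataFrame(
        [tallies.get(c, [0, 0, 0]) for c in conditions],
        index=pd.Index(conditions, name="condition"),
        columns=list(TALLY_COLUMNS),
        dtype=np.int64,
    )
    return CountMatrix(counts=counts, tallies=tally_df, n_unassigned_barcode=n_unassigned)
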