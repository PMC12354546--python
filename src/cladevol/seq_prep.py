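"""Alignment preparation: translation, back-translation, gap filtering,
percent identity.

A protein multiple sequence alignment plus the matching unaligned coding
sequences are turned into an in-frame codon alignment (each residue column
becomes one codon column, protein gaps become ``---``), the substrate for
all codon-level likelihood analyses.  Columns dominated by gaps are removed
before model fitting; pairwise percent identity uses pairwise deletion
(columns with a gap in either sequence are excluded from both numerator and
denominator) — 'X' counts as comparable but never matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Alignment",
    "ProteinAlignment",
    "CodonAlignment",
    "IdentityMatrix",
    "batch_translate",
    "back_translate",
    "filter_gap_columns",
    "percent_identity",
    "identity_matrix",
    "group_average_identity",
    "read_fasta",
    "write_fasta",
]

GAP = "-"


class FrameError(ValueError):
    """Coding sequence length not divisible by 3."""


class BackTranslationError(ValueError):
    """CDS does not translate to the aligned protein row."""


@dataclass
class Alignment:
    """An aligned set of equal-length sequences over some residue alphabet."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon identifiers")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])


class ProteinAlignment(Alignment):
    """Amino-acid alignment: residues, gap '-', ambiguity 'X'."""

    def __post_init__(self):
        super().__post_init__()
        if self.n_taxa < 2:
            raise ValueError("alignment needs at least 2 taxa")


@dataclass
class CodonAlignment:
    """In-frame codon alignment: rows over {A,C,G,T,-}, length 3×L.

    Every codon column is either ``---`` or a gap-free nucleotide triplet.
    """

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon identifiers")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("unequal row lengths")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")
        for taxon, row in zip(self.taxa, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if GAP in codon and codon != "---":
                    raise ValueError(
                        f"partial-gap codon {codon!r} at column {i // 3} in {taxon}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codon(self, row_idx: int, col: int) -> str:
        return self.rows[row_idx][3 * col : 3 * col + 3]

    def codon_columns(self) -> list[list[str]]:
        return [
            [self.codon(r, c) for r in range(self.n_taxa)]
            for c in range(self.n_codons)
        ]

    def to_protein(self) -> ProteinAlignment:
        rows = []
        for row in self.rows:
            rows.append(
                "".join(
                    "-" if row[i : i + 3] == "---" else batch_translate(row[i : i + 3])
                    for i in range(0, len(row), 3)
                )
            )
        return ProteinAlignment(list(self.taxa), rows)


@dataclass
class IdentityMatrix:
    taxa: list[str]
    values: np.ndarray  # percent, symmetric, diag 100; NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


# ----------------------------------------------------------------- FASTA io


def read_fasta(path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    return [r.id for r in records], [str(r.seq).upper() for r in records]


def write_fasta(path, taxa: list[str], rows: list[str], width: int | None = 60) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(taxa, rows):
            fh.write(f">{taxon}\n")
            if width:
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")
            else:
                fh.write(row + "\n")


# -------------------------------------------------------------- operations


def batch_translate(cds: str) -> str:
    """Translate a coding sequence under the standard genetic code.

    Internal stop codons are rendered as '*'; the caller decides whether
    that is an error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


def back_translate(
    aln: ProteinAlignment, cds_by_taxon: dict[str, str]
) -> CodonAlignment:
    """Thread unaligned CDSs onto a protein alignment (PAL2NAL-style).

    Residue column i maps to codon column i; protein gaps become ``---``.
    The translation of each CDS must equal the ungapped protein row exactly
    ('X' in the protein row accepts any codon).
    """
    out_rows = []
    for taxon, prot_row in zip(aln.taxa, aln.rows):
        if taxon not in cds_by_taxon:
            raise BackTranslationError(f"missing CDS for taxon {taxon!r}")
        cds = cds_by_taxon[taxon].upper().replace("U", "T")
        translated = batch_translate(cds)
        ungapped = prot_row.replace(GAP, "")
        if len(translated) != len(ungapped):
            raise BackTranslationError(
                f"{taxon}: CDS translates to {len(translated)} residues, "
                f"alignment row has {len(ungapped)}"
            )
        for pos, (a, b) in enumerate(zip(translated, ungapped)):
            if a != b and b != "X":
                raise BackTranslationError(
                    f"{taxon}: translation mismatch at residue {pos + 1} "
                    f"({a!r} from CDS vs {b!r} in alignment)"
                )
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(translated))]
        it = iter(codons)
        out_rows.append(
            "".join("---" if ch == GAP else next(it) for ch in prot_row)
        )
    return CodonAlignment(list(aln.taxa), out_rows)


def _is_gap_column_entry(entry: str) -> bool:
    return set(entry) == {GAP}


def filter_gap_columns(aln, max_gap_fraction: float = 0.5):
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    Works on either a protein or a codon alignment (column = codon).
    Returns (filtered alignment, list of removed 0-based column indices).
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    is_codon = isinstance(aln, CodonAlignment)
    ncol = aln.n_codons if is_codon else aln.n_columns
    step = 3 if is_codon else 1
    removed = []
    kept = []
    for c in range(ncol):
        entries = [row[step * c : step * c + step] for row in aln.rows]
        gap_fraction = sum(_is_gap_column_entry(e) for e in entries) / len(entries)
        (removed if gap_fraction > max_gap_fraction else kept).append(c)
    new_rows = [
        "".join(row[step * c : step * c + step] for c in kept) for row in aln.rows
    ]
    if not kept:
        warnings.warn("all columns removed by gap filter")
    cls = type(aln)
    return cls(list(aln.taxa), new_rows), removed


def percent_identity(a: str, b: str, ambiguous: str = "X") -> float:
    """Pairwise percent identity under pairwise deletion.

    Columns with a gap in either row are excluded entirely; ambiguity
    characters count in the denominator but never match.  Returns NaN when
    no comparable columns remain.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y and x != ambiguous:
            matches += 1
    if comparable == 0:
        return float("nan")
    return 100.0 * matches / comparable


def identity_matrix(aln: Alignment) -> IdentityMatrix:
    n = aln.n_taxa
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = percent_identity(aln.rows[i], aln.rows[j])
    return IdentityMatrix(list(aln.taxa), values)


def group_average_identity(
    m: IdentityMatrix, groups: dict[str, str]
) -> pd.DataFrame:
    """Mean identity between and within named groups.

    Between-group cells average all cross pairs; within-group cells average
    distinct pairs only (NaN for singleton groups).
    """
    missing = [t for t in m.taxa if t not in groups]
    if missing:
        raise ValueError(f"unlabeled taxa: {missing}")
    labels = sorted(set(groups.values()))
    idx = {g: [i for i, t in enumerate(m.taxa) if groups[t] == g] for g in labels}
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for gi in labels:
        for gj in labels:
            ii, jj = idx[gi], idx[gj]
            if gi == gj:
                vals = [m.values[a, b] for k, a in enumerate(ii) for b in ii[k + 1:]]
            else:
                vals = [m.values[a, b] for a in ii for b in jj]
            if vals:
                out.loc[gi, gj] = float(np.nanmean(vals))
    return out
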