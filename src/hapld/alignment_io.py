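"""Reading, validating and site-classifying phased haplotype alignments.

The input is a multi-FASTA of gap-aligned, experimentally phased haplotype
sequences for one gene in one species (each individual may contribute up to
two records).  Columns are classified into monomorphic / usable biallelic /
excluded classes; only usable biallelic columns (two states over {A,C,G,T},
no gap or N anywhere in the column) enter downstream LD analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, ConfigurationError, InsufficientDataError, InvalidSymbolError

VALID_SYMBOLS = frozenset("ACGT-N")
NUCLEOTIDES = frozenset("ACGT")

#: site classes
MONOMORPHIC = "monomorphic"
USABLE_BIALLELIC = "usable_biallelic"
EXCLUDED_GAP = "excluded_gap"
EXCLUDED_MULTIALLELIC = "excluded_multiallelic"
EXCLUDED_AMBIGUOUS = "excluded_ambiguous"

SITE_CLASSES = (
    MONOMORPHIC,
    USABLE_BIALLELIC,
    EXCLUDED_GAP,
    EXCLUDED_MULTIALLELIC,
    EXCLUDED_AMBIGUOUS,
)


@dataclass(frozen=True)
class HaplotypeAlignment:
    """A gap-aligned set of phased haplotype sequences for one gene x species.

    Coordinates are 0-based aligned columns; distances downstream are measured
    in aligned bp, so alignment insertions count toward distance.

    Parameters
    ----------
    gene_id, species_id
        Free-text labels carried through all outputs.
    names, sequences
        Parallel tuples; record order is preserved from the input file.
    cds_intervals
        Optional non-overlapping ``(start, end)`` half-open column intervals
        whose concatenation, in order, is the coding sequence (frame 0 after
        concatenation).  Required for synonymous/non-synonymous diversity.
    """

    gene_id: str
    species_id: str
    names: tuple[str, ...]
    sequences: tuple[str, ...]
    cds_intervals: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences must be parallel")
        if not self.sequences:
            raise InsufficientDataError("alignment contains no sequences")
        L = len(self.sequences[0])
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"unequal aligned lengths: {name!r} has {len(seq)}, expected {L}"
                )
            bad = set(seq) - VALID_SYMBOLS
            if bad:
                raise InvalidSymbolError(
                    f"invalid symbol(s) {sorted(bad)} in record {name!r}"
                )
        if self.cds_intervals is not None:
            prev_end = 0
            total = 0
            for start, end in self.cds_intervals:
                if not (0 <= start < end <= L):
                    raise ConfigurationError(
                        f"cds interval [{start}, {end}) outside alignment [0, {L})"
                    )
                if start < prev_end:
                    raise ConfigurationError("cds intervals overlap or are unsorted")
                prev_end = end
                total += end - start
            if total % 3 != 0:
                raise ConfigurationError(
                    f"total coding length {total} is not a multiple of 3"
                )

    @property
    def n(self) -> int:
        """Number of haplotype records."""
        return len(self.sequences)

    @property
    def L(self) -> int:
        """Aligned length in columns."""
        return len(self.sequences[0])

    def column(self, j: int) -> str:
        """The j-th aligned column, one character per haplotype."""
        return "".join(seq[j] for seq in self.sequences)


def read_alignment(
    path,
    gene_id: str = "",
    species_id: str = "",
    cds_spec: Sequence[tuple[int, int]] | None = None,
) -> HaplotypeAlignment:
    """Read a multi-FASTA haplotype alignment.

    Sequences are uppercased; record order is preserved.  Raises
    :class:`AlignmentError` for unequal lengths, :class:`InvalidSymbolError`
    for characters outside {A,C,G,T,-,N} and :class:`InsufficientDataError`
    for fewer than two records.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise InsufficientDataError(
            f"{path}: need at least 2 haplotype records, found {len(records)}"
        )
    names = tuple(rec.id for rec in records)
    seqs = tuple(str(rec.seq).upper() for rec in records)
    cds = tuple((int(s), int(e)) for s, e in cds_spec) if cds_spec is not None else None
    return HaplotypeAlignment(
        gene_id=gene_id, species_id=species_id, names=names, sequences=seqs,
        cds_intervals=cds,
    )


def write_alignment(aln: HaplotypeAlignment, path, width: int = 70) -> None:
    """Write the alignment back to multi-FASTA (round-trips modulo wrapping)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(aln.names, aln.sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_cds_annotation(path, gene_id: str) -> tuple[tuple[int, int], ...]:
    """Read coding intervals for ``gene_id`` from a tab-separated annotation.

    Columns: gene_id, cds_start, cds_end, frame (0-based half-open columns).
    A non-zero frame trims that many columns from the interval start so the
    concatenated intervals begin on a codon boundary.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] != gene_id:
                continue
            start, end = int(parts[1]), int(parts[2])
            frame = int(parts[3]) if len(parts) > 3 else 0
            intervals.append((start + frame, end))
    if not intervals:
        raise ConfigurationError(f"no cds annotation for gene {gene_id!r} in {path}")
    return tuple(sorted(intervals))


@dataclass(frozen=True)
class Site:
    column: int
    counts: tuple[tuple[str, int], ...]  # (state, count), states sorted
    site_class: str

    @property
    def alleles(self) -> tuple[str, ...]:
        """Observed nucleotide states (gaps/Ns not included), sorted."""
        return tuple(s for s, _ in self.counts if s in NUCLEOTIDES)

    @property
    def is_singleton(self) -> bool:
        """True for a usable biallelic site whose minor allele occurs once."""
        if self.site_class != USABLE_BIALLELIC:
            return False
        return min(c for s, c in self.counts if s in NUCLEOTIDES) == 1


@dataclass
class SiteTable:
    """Per-column classification of an alignment; every column appears once."""

    sites: list[Site] = field(default_factory=list)

    @property
    def n_polymorphic(self) -> int:
        """S: columns with >=2 distinct states over {A,C,G,T}."""
        return sum(
            1 for s in self.sites
            if len(s.alleles) >= 2
        )

    def usable_columns(self, drop_singletons: bool = False) -> list[int]:
        """Columns passing the usable-site filter, in genomic order."""
        cols = []
        for s in self.sites:
            if s.site_class != USABLE_BIALLELIC:
                continue
            if drop_singletons and s.is_singleton:
                continue
            cols.append(s.column)
        return cols

    @property
    def n_usable(self) -> int:
        return len(self.usable_columns())

    def class_counts(self) -> Counter:
        return Counter(s.site_class for s in self.sites)

    def site(self, column: int) -> Site:
        return self.sites[column]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "column": s.column,
                "alleles": "/".join(st for st, _ in s.counts),
                "counts": "/".join(str(c) for _, c in s.counts),
                "class": s.site_class,
            }
            for s in self.sites
        ]
        return pd.DataFrame(rows, columns=["column", "alleles", "counts", "class"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify_column(column: str) -> str:
    """Classify one aligned column.

    Precedence: fewer than two nucleotide states -> monomorphic; more than
    two -> excluded_multiallelic; exactly two with any gap -> excluded_gap,
    with any N -> excluded_ambiguous, otherwise usable_biallelic.
    """
    states = set(column) & NUCLEOTIDES
    if len(states) < 2:
        return MONOMORPHIC
    if len(states) > 2:
        return EXCLUDED_MULTIALLELIC
    if "-" in column:
        return EXCLUDED_GAP
    if "N" in column:
        return EXCLUDED_AMBIGUOUS
    return USABLE_BIALLELIC


def extract_sites(aln: HaplotypeAlignment) -> SiteTable:
    """Classify every aligned column of ``aln``.

    The result is invariant to haplotype order.  A monomorphic alignment
    yields S = 0 and no usable sites; that is not an error.
    """
    sites = []
    for j in range(aln.L):
        col = aln.column(j)
        counts = tuple(sorted(Counter(col).items()))
        sites.append(Site(column=j, counts=counts, site_class=classify_column(col)))
    return SiteTable(sites=sites)
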