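"""Polymorphism summaries: haplotype counts, S, and nucleotide diversity.

Nucleotide diversity pi is the average over all sequence pairs of the
per-pair p-distance (differences / compared sites), with pairwise-complete
column comparison and no multiple-hit correction — the uncorrected "Pi"
convention of standard polymorphism software.  Synonymous and
non-synonymous diversity use the Nei & Gojobori (1986) codon-pathway
method restricted to the annotated coding intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment_io import HaplotypeAlignment, SiteTable, extract_sites
from .errors import ConfigurationError, InsufficientDataError

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOPS = frozenset(_STANDARD.stop_codons)
_BASES = "ACGT"


def count_haplotypes(aln: HaplotypeAlignment) -> int:
    """Number of distinct haplotype sequences (exact aligned-string equality)."""
    return len(set(aln.sequences))


def _encoded(aln: HaplotypeAlignment) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer("".join(aln.sequences).encode("ascii"), dtype="S1")
    arr = arr.reshape(aln.n, aln.L)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    return arr, valid


def nucleotide_diversity(aln: HaplotypeAlignment) -> float:
    """Per-site nucleotide diversity pi over all C(n,2) sequence pairs.

    A column contributes to a pair only if both sequences carry an
    unambiguous nucleotide there.  Pairs with no comparable column are
    skipped (degenerate alignments only).
    """
    if aln.n < 2:
        raise InsufficientDataError("nucleotide diversity requires >= 2 haplotypes")
    arr, valid = _encoded(aln)
    ratios = []
    for i, j in itertools.combinations(range(aln.n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            continue
        d = int(((arr[i] != arr[j]) & both).sum())
        ratios.append(d / m)
    if not ratios:
        raise InsufficientDataError("no comparable sites in any sequence pair")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) codon machinery


@lru_cache(maxsize=None)
def codon_synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3), stop-excluded.

    At each codon position the fraction of the possible single-nucleotide
    changes that are synonymous is computed; changes creating a stop codon
    are removed from both numerator and denominator.  The three fractions
    sum to the synonymous site count; non-synonymous sites are 3 minus it.
    """
    if codon in _STOPS or codon not in _CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = _CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            valid += 1
            if _CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def codon_pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    All mutational pathways (orderings of the differing positions) are
    weighted equally; pathways passing through a stop codon are excluded.
    If every pathway crosses a stop, all pathways are used as a fallback.
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for through, steps in paths if not through]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if a in _STOPS or b in _STOPS:
                # fallback path through a stop: count the step non-synonymous
                nonsyn += 1
            elif _CODON_TO_AA[a] == _CODON_TO_AA[b]:
                syn += 1
            else:
                nonsyn += 1
    k = len(usable)
    return syn / k, nonsyn / k


def _coding_columns(aln: HaplotypeAlignment) -> list[int]:
    cols: list[int] = []
    for start, end in aln.cds_intervals or ():
        cols.extend(range(start, end))
    return cols


def synonymous_nonsynonymous_diversity(aln: HaplotypeAlignment) -> tuple[float, float]:
    """(pi_syn, pi_nonsyn): per-synonymous-site and per-non-synonymous-site
    diversity by Nei–Gojobori pathway counting over ``cds_intervals``.

    For each sequence pair, codons with any gap/N (or a stop codon) in
    either sequence are skipped entirely; per-pair proportions
    p_s = Sd/Ss and p_n = Nd/Ns are then averaged over pairs.
    """
    if aln.cds_intervals is None:
        raise ConfigurationError("coding partition requested without cds_intervals")
    if aln.n < 2:
        raise InsufficientDataError("diversity requires >= 2 haplotypes")
    cols = _coding_columns(aln)
    codon_cols = [tuple(cols[i : i + 3]) for i in range(0, len(cols), 3)]
    cds = ["".join(seq[c] for c in cols) for seq in aln.sequences]
    n_codons = len(codon_cols)

    ps_vals, pn_vals = [], []
    for i, j in itertools.combinations(range(aln.n), 2):
        Ss = Ns = Sd = Nd = 0.0
        for c in range(n_codons):
            c1 = cds[i][3 * c : 3 * c + 3]
            c2 = cds[j][3 * c : 3 * c + 3]
            if any(b not in _BASES for b in c1 + c2):
                continue
            if c1 in _STOPS or c2 in _STOPS:
                continue
            s1 = codon_synonymous_sites(c1)
            s2 = codon_synonymous_sites(c2)
            Ss += 0.5 * (s1 + s2)
            Ns += 3.0 - 0.5 * (s1 + s2)
            sd, nd = codon_pathway_differences(c1, c2)
            Sd += sd
            Nd += nd
        if Ss > 0:
            ps_vals.append(Sd / Ss)
        if Ns > 0:
            pn_vals.append(Nd / Ns)
    pi_syn = float(np.mean(ps_vals)) if ps_vals else float("nan")
    pi_nonsyn = float(np.mean(pn_vals)) if pn_vals else float("nan")
    return pi_syn, pi_nonsyn


@dataclass(frozen=True)
class PolymorphismSummary:
    """One summary row per gene x species dataset."""

    gene_id: str
    species_id: str
    n_sequences: int
    length: int
    n_haplotypes: int
    n_polymorphic: int
    pi_total: float
    pi_syn: float | None = None
    pi_nonsyn: float | None = None

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "species": self.species_id,
            "n": self.n_sequences,
            "length_bp": self.length,
            "n_haplotypes": self.n_haplotypes,
            "S": self.n_polymorphic,
            "pi_total": self.pi_total,
            "pi_syn": self.pi_syn,
            "pi_nonsyn": self.pi_nonsyn,
        }


def polymorphism_summary(
    aln: HaplotypeAlignment, site_table: SiteTable | None = None
) -> PolymorphismSummary:
    """Combine haplotype count, S and diversity into one summary row.

    The coding partition is included only when the alignment carries
    ``cds_intervals``.
    """
    if site_table is None:
        site_table = extract_sites(aln)
    pi_syn = pi_nonsyn = None
    if aln.cds_intervals is not None:
        pi_syn, pi_nonsyn = synonymous_nonsynonymous_diversity(aln)
    return PolymorphismSummary(
        gene_id=aln.gene_id,
        species_id=aln.species_id,
        n_sequences=aln.n,
        length=aln.L,
        n_haplotypes=count_haplotypes(aln),
        n_polymorphic=site_table.n_polymorphic,
        pi_total=nucleotide_diversity(aln),
        pi_syn=pi_syn,
        pi_nonsyn=pi_nonsyn,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
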