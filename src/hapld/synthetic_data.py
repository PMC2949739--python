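"""Coalescent haplotype simulator with intra-gene recombination.

Generates phased haplotype alignments under the neutral coalescent with
recombination (Hudson's back-in-time algorithm): lineages carry intervals
of ancestral material, recombination splits a lineage at a uniform
breakpoint at rate rho/2 per bp of ancestral span per lineage, and pairs of
lineages coalesce at rate 1 per pair, all in units of 2N generations.
Mutations are laid on the resulting marginal genealogies at rate theta/2
per bp per unit branch length.  Under the default infinite-sites model
every mutation creates a new biallelic column (ancestral A, derived C), so
Watterson's E[S] = theta*L*sum_{i<n} 1/i holds exactly in expectation.

A finite-sites mode (recurrent Jukes-Cantor-style hits on a random
background) and a gap-injection rate exist to exercise the usable-site
exclusion filters; an exponential-growth mode rescales the coalescence
intensity backward in time.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment_io import HaplotypeAlignment

# lineage segment: (left, right, node, n_sample_descendants)
_Segment = tuple[float, float, int, int]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated gene x species dataset.

    theta and rho are the population-scaled per-bp rates (4*N*mu and 4*N*c);
    identical (params, seed) always yields an identical alignment.
    """

    n: int
    L: int
    theta: float
    rho: float
    seed: int = 0
    gene_id: str = "simgene"
    species_id: str = "simpop"
    gap_rate: float = 0.0
    finite_sites: bool = False
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 haplotypes")
        if self.L < 1:
            raise ValueError("need L >= 1 bp")
        if self.theta < 0 or self.rho < 0 or self.gap_rate < 0 or self.growth_rate < 0:
            raise ValueError("rates must be non-negative")


def _simulate_arg(
    n: int, L: float, rho: float, rng: np.random.Generator, growth: float = 0.0
) -> tuple[list[tuple[int, int, float, float]], list[float]]:
    """Ancestral recombination graph for n samples on [0, L).

    Returns tskit-style edges (child, parent, left, right) and node times.
    Material that has found its MRCA is dropped, so the walk terminates
    once every position has fully coalesced.
    """
    node_time: list[float] = [0.0] * n
    lineages: list[list[_Segment]] = [[(0.0, L, i, 1)] for i in range(n)]
    edges: list[tuple[int, int, float, float]] = []
    t = 0.0
    while len(lineages) >= 2:
        k = len(lineages)
        spans = np.array([lin[-1][1] - lin[0][0] for lin in lineages])
        recomb_rate = 0.5 * rho * float(spans.sum())
        coal_pairs = k * (k - 1) / 2.0

        w_recomb = rng.exponential(1.0 / recomb_rate) if recomb_rate > 0 else math.inf
        unit = rng.exponential(1.0)
        if growth > 0:
            # coalescence intensity grows as e^{growth * t} backward in time
            w_coal = math.log1p(growth * unit * math.exp(-growth * t) / coal_pairs) / growth
        else:
            w_coal = unit / coal_pairs

        if w_recomb < w_coal:
            t += w_recomb
            li = int(rng.choice(k, p=spans / spans.sum()))
            lin = lineages.pop(li)
            bp = rng.uniform(lin[0][0], lin[-1][1])
            left = [s for s in lin if s[1] <= bp]
            right = [s for s in lin if s[0] >= bp]
            for s in lin:
                if s[0] < bp < s[1]:
                    left.append((s[0], bp, s[2], s[3]))
                    right.append((bp, s[1], s[2], s[3]))
            left.sort()
            right.sort()
            if left and right:
                lineages.append(left)
                lineages.append(right)
            else:  # breakpoint outside ancestral material: no-op
                lineages.append(lin)
        else:
            t += w_coal
            i, j = rng.choice(k, size=2, replace=False)
            li, lj = lineages[int(i)], lineages[int(j)]
            for idx in sorted((int(i), int(j)), reverse=True):
                lineages.pop(idx)
            parent = len(node_time)
            node_time.append(t)
            merged = _merge_lineages(li, lj, parent, n, edges)
            if merged:
                lineages.append(merged)
    return edges, node_time


def _merge_lineages(
    l1: list[_Segment],
    l2: list[_Segment],
    parent: int,
    n: int,
    edges: list[tuple[int, int, float, float]],
) -> list[_Segment]:
    """Coalesce two segment lists into their common ancestor.

    Overlapping material is joined under ``parent`` (recording edges) and
    dropped once it carries all n samples; non-overlapping material passes
    through untouched, still labeled with its original node.
    """
    points = sorted({p for seg in l1 + l2 for p in (seg[0], seg[1])})
    out: list[_Segment] = []

    def cover(segs: list[_Segment], a: float, b: float) -> _Segment | None:
        for s in segs:
            if s[0] <= a and b <= s[1]:
                return s
        return None

    for a, b in zip(points[:-1], points[1:]):
        s1 = cover(l1, a, b)
        s2 = cover(l2, a, b)
        if s1 is not None and s2 is not None:
            edges.append((s1[2], parent, a, b))
            edges.append((s2[2], parent, a, b))
            k = s1[3] + s2[3]
            if k < n:
                out.append((a, b, parent, k))
        elif s1 is not None:
            out.append((a, b, s1[2], s1[3]))
        elif s2 is not None:
            out.append((a, b, s2[2], s2[3]))
    # stitch adjacent pieces that still belong to the same node
    stitched: list[_Segment] = []
    for seg in out:
        if stitched and stitched[-1][2] == seg[2] and stitched[-1][1] == seg[0] \
                and stitched[-1][3] == seg[3]:
            prev = stitched.pop()
            stitched.append((prev[0], seg[1], seg[2], seg[3]))
        else:
            stitched.append(seg)
    return stitched


@dataclass(frozen=True)
class _Mutation:
    position: float
    time: float
    child: int
    edge_left: float
    edge_right: float


def _place_mutations(
    edges: list[tuple[int, int, float, float]],
    node_time: list[float],
    theta: float,
    rng: np.random.Generator,
) -> list[_Mutation]:
    if not edges or theta <= 0:
        return []
    weights = np.array(
        [(r - l) * (node_time[p] - node_time[c]) for c, p, l, r in edges]
    )
    total = 0.5 * theta * float(weights.sum())
    n_mut = int(rng.poisson(total))
    if n_mut == 0:
        return []
    probs = weights / weights.sum()
    picks = rng.choice(len(edges), size=n_mut, p=probs)
    muts = []
    for e in picks:
        c, p, l, r = edges[int(e)]
        muts.append(
            _Mutation(
                position=float(rng.uniform(l, r)),
                time=float(rng.uniform(node_time[c], node_time[p])),
                child=c,
                edge_left=l,
                edge_right=r,
            )
        )
    return muts


def _carriers(
    node: int, pos: float, children: dict[int, list[tuple[int, float, float]]], n: int
) -> list[int]:
    """Sample indices below ``node`` on the marginal tree at ``pos``."""
    out: list[int] = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
            continue
        for child, l, r in children.get(v, ()):
            if l <= pos < r:
                stack.append(child)
    return sorted(out)


def simulate_haplotypes(params: SimParams) -> HaplotypeAlignment:
    """Simulate one phased haplotype alignment under the given parameters.

    Deterministic under ``params.seed``.  theta=0 yields a monomorphic
    alignment; rho=0 collapses to a single genealogy shared by all sites.
    """
    rng = np.random.default_rng(params.seed)
    edges, node_time = _simulate_arg(
        params.n, float(params.L), params.rho, rng, growth=params.growth_rate
    )
    muts = _place_mutations(edges, node_time, params.theta, rng)
    children: dict[int, list[tuple[int, float, float]]] = {}
    for c, p, l, r in edges:
        children.setdefault(p, []).append((c, l, r))

    if params.finite_sites:
        bg = rng.choice(list("ACGT"), size=params.L)
        seqs = np.tile(bg, (params.n, 1))
        for mut in sorted(muts, key=lambda m: -m.time):  # oldest first
            col = int(mut.position)
            carry = _carriers(mut.child, mut.position, children, params.n)
            if not carry:
                continue
            current = seqs[carry[0], col]
            new = rng.choice([b for b in "ACGT" if b != current])
            seqs[carry, col] = new
    else:
        seqs = np.full((params.n, params.L), "A", dtype="<U1")
        used: set[int] = set()
        for mut in muts:
            pos, col = mut.position, int(mut.position)
            tries = 0
            while col in used and tries < 100:
                pos = float(rng.uniform(mut.edge_left, mut.edge_right))
                col = int(pos)
                tries += 1
            if col in used:
                continue  # interval saturated; drop the mutation
            used.add(col)
            carry = _carriers(mut.child, pos, children, params.n)
            if 0 < len(carry) < params.n:
                seqs[carry, col] = "C"

    if params.gap_rate > 0:
        mask = rng.random((params.n, params.L)) < params.gap_rate
        seqs[mask] = "-"

    names = tuple(
        f"{params.gene_id}_{params.species_id}_h{i + 1:02d}" for i in range(params.n)
    )
    return HaplotypeAlignment(
        gene_id=params.gene_id,
        species_id=params.species_id,
        names=names,
        sequences=tuple("".join(row) for row in seqs),
    )


def to_ms_text(aln: HaplotypeAlignment, ancestral: str = "A") -> str:
    """ms-style text block (segsites, relative positions, 0/1 rows) for
    cross-checking against established coalescent simulators."""
    seg_cols = [
        j for j in range(aln.L)
        if len({s[j] for s in aln.sequences} - {"-", "N"}) > 1
    ]
    buf = io.StringIO()
    buf.write("//\n")
    buf.write(f"segsites: {len(seg_cols)}\n")
    buf.write(
        "positions: " + " ".join(f"{(c + 0.5) / aln.L:.5f}" for c in seg_cols) + "\n"
    )
    for seq in aln.sequences:
        buf.write("".join("0" if seq[c] == ancestral else "1" for c in seg_cols) + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Study-scale designs

GENES = ("Gambicin", "NOS", "REL2", "FBN9")
SPECIES = (
    "gambiae_M", "gambiae_S", "arabiensis", "bwambae",
    "melas", "merus", "quadriannulatus",
)

#: aligned lengths (bp) of the four immunity-gene fragments
GENE_LENGTHS = {"Gambicin": 1108, "NOS": 1238, "REL2": 834, "FBN9": 735}

#: per-bp theta targets = observed per-site diversity of each fragment
GENE_THETA = {"Gambicin": 0.0253, "NOS": 0.0247, "REL2": 0.0099, "FBN9": 0.0159}

#: field-collected individuals per gene x species; haplotypes = 2x (cloned,
#: phased sequences, two per individual)
INDIVIDUALS = {
    "Gambicin": {"gambiae_M": 16, "gambiae_S": 5, "arabiensis": 6, "bwambae": 6,
                 "melas": 6, "merus": 5, "quadriannulatus": 5},
    "NOS": {"gambiae_M": 16, "gambiae_S": 6, "arabiensis": 5, "bwambae": 7,
            "melas": 5, "merus": 6, "quadriannulatus": 5},
    "REL2": {"gambiae_M": 16, "gambiae_S": 14, "arabiensis": 10, "bwambae": 6,
             "melas": 8, "merus": 7, "quadriannulatus": 8},
    "FBN9": {"gambiae_M": 16, "gambiae_S": 7, "arabiensis": 7, "bwambae": 7,
             "melas": 7, "merus": 7, "quadriannulatus": 7},
}

#: default per-bp population recombination rate: strong enough that the
#: expected r2 decay crosses 0.3 within ~100-150 aligned bp
DEFAULT_RHO = 0.02

#: dataset simulated as invariant (the study design contains one
#: monomorphic gene x species cell)
MONOMORPHIC_CELL = ("REL2", "bwambae")


def default_study_design(seed: int = 0, rho: float = DEFAULT_RHO) -> list[SimParams]:
    """The default 4-gene x 7-taxon simulated study.

    Per-dataset seeds are derived deterministically from ``seed``; the
    REL2 x An. bwambae cell is simulated with theta=0 so the pipeline's
    degenerate "0 pairs / NA" path is always exercised.
    """
    rng = np.random.default_rng(seed)
    design = []
    for gene in GENES:
        for species in SPECIES:
            sub = int(rng.integers(0, 2**31 - 1))
            theta = 0.0 if (gene, species) == MONOMORPHIC_CELL else GENE_THETA[gene]
            design.append(
                SimParams(
                    n=2 * INDIVIDUALS[gene][species],
                    L=GENE_LENGTHS[gene],
                    theta=theta,
                    rho=rho,
                    seed=sub,
                    gene_id=gene,
                    species_id=species,
                )
            )
    return design


@dataclass
class StudyBundle:
    alignments: dict[tuple[str, str], HaplotypeAlignment] = field(default_factory=dict)
    manifest: pd.DataFrame | None = None


def simulate_study(
    design: list[SimParams] | None = None,
    seed: int = 0,
    out_dir=None,
) -> StudyBundle:
    """Simulate every dataset of a study design (default: the 4x7 layout).

    With ``out_dir`` the alignments are written as one FASTA per dataset
    plus a ``manifest.tsv`` (gene, species, n, L, theta, rho, seed, path),
    byte-identical across reruns with the same design."""
    from .alignment_io import write_alignment  # local to avoid cycle at import

    if design is None:
        design = default_study_design(seed=seed)
    bundle = StudyBundle()
    rows = []
    for params in design:
        aln = simulate_haplotypes(params)
        bundle.alignments[(params.gene_id, params.species_id)] = aln
        row = {
            "gene": params.gene_id, "species": params.species_id,
            "n": params.n, "L": params.L, "theta": params.theta,
            "rho": params.rho, "seed": params.seed,
        }
        if out_dir is not None:
            import os

            os.makedirs(out_dir, exist_ok=True)
            fname = f"{params.gene_id}_{params.species_id}.fasta"
            write_alignment(aln, os.path.join(out_dir, fname))
            # manifest paths are relative to the manifest itself, keeping
            # the bundle relocatable and byte-identical across reruns
            row["path"] = fname
        rows.append(row)
    bundle.manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import os

        bundle.manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return bundle
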