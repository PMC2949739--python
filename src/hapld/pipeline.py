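"""End-to-end orchestration: diversity -> LD -> decay -> grids -> comparison.

Runs the full gene x species design from either a manifest of FASTA files
or a simulation design, and writes plain-text tab-separated outputs:

    table1.tsv        one polymorphism-summary row per dataset
    table2.tsv        pair counts, significant counts, mean +/- SD r2
    pairwise/         one TSV of all site pairs per dataset
    decay/            fitted decay curves (parametric + nonparametric)
    grids/            r2 matrices and haploblock lists
    segments.tsv      per-segment mean r2
    comparison_by_gene.tsv / comparison_by_species.tsv
    run_log.txt       every excluded site class count and failed fit

Table TSVs print floats at 4 significant digits with "NA" for undefined
cells; a ``*_full.tsv`` companion keeps full precision.  Reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment_io, group_comparison, ld_decay, ld_pairwise, polymorphism
from .errors import ConfigurationError, HapLDError
from .synthetic_data import SimParams, simulate_haplotypes


@dataclass(frozen=True)
class DatasetSpec:
    gene_id: str
    species_id: str
    path: str
    cds_path: str | None = None


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    manifest: list[DatasetSpec] | None = None
    design: list[SimParams] | None = None
    alpha: float = 0.05
    n_segments: int = 4
    block_r2_threshold: float = 0.8
    decay_model: str = "hill-weir"
    drop_singletons: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if not self.manifest and not self.design:
            raise ConfigurationError("empty manifest: nothing to analyse")


@dataclass
class RunResult:
    table1: pd.DataFrame
    table2: pd.DataFrame
    segments: pd.DataFrame
    comparison_by_gene: pd.DataFrame
    comparison_by_species: pd.DataFrame
    pairs: dict[tuple[str, str], list] = field(default_factory=dict)
    decay_fits: dict[tuple[str, str], dict] = field(default_factory=dict)
    failures: list[tuple[str, str, str]] = field(default_factory=list)
    out_dir: str = ""


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def _write_formatted(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col in out.columns:
        out[col] = [_fmt(v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)
    base, ext = os.path.splitext(path)
    df.to_csv(base + "_full" + ext, sep="\t", index=False, na_rep="NA")


def run_full_analysis(config: RunConfig) -> RunResult:
    """Run the whole analysis over the configured design.

    Per-dataset failures are recorded in the report and the log without
    aborting the run; every number in the output tables is recomputable by
    calling the module operations directly.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    for sub in ("pairwise", "decay", "grids"):
        os.makedirs(os.path.join(config.out_dir, sub), exist_ok=True)
    log: list[str] = [f"run: alpha={config.alpha} n_segments={config.n_segments} "
                      f"block_r2_threshold={config.block_r2_threshold} "
                      f"decay_model={config.decay_model} seed={config.seed}"]

    t1_rows, t2_rows, seg_summaries = [], [], []
    result = RunResult(
        table1=pd.DataFrame(), table2=pd.DataFrame(), segments=pd.DataFrame(),
        comparison_by_gene=pd.DataFrame(), comparison_by_species=pd.DataFrame(),
        out_dir=config.out_dir,
    )

    for gene, species, item in _iter_safe(config, log, result):
        aln = item
        tag = f"{gene}_{species}"
        sites = alignment_io.extract_sites(aln)
        cc = sites.class_counts()
        log.append(
            f"{tag}: n={aln.n} L={aln.L} S={sites.n_polymorphic} "
            f"usable={sites.n_usable} excluded_gap={cc.get('excluded_gap', 0)} "
            f"excluded_multiallelic={cc.get('excluded_multiallelic', 0)} "
            f"excluded_ambiguous={cc.get('excluded_ambiguous', 0)}"
        )
        summary = polymorphism.polymorphism_summary(aln, sites)
        t1_rows.append(summary.to_dict())

        pairs, scan = ld_pairwise.pairwise_ld_scan(
            aln, alpha=config.alpha, site_table=sites,
            drop_singletons=config.drop_singletons,
        )
        t2_rows.append(scan.to_dict())
        result.pairs[(gene, species)] = pairs
        ld_pairwise.pairs_to_frame(pairs).to_csv(
            os.path.join(config.out_dir, "pairwise", f"{tag}.tsv"),
            sep="\t", index=False, na_rep="NA",
        )

        if pairs:
            grid = ld_pairwise.build_grid(pairs, config.block_r2_threshold)
            grid.to_frame().to_csv(
                os.path.join(config.out_dir, "grids", f"{tag}_matrix.tsv"), sep="\t"
            )
            with open(os.path.join(config.out_dir, "grids", f"{tag}_blocks.tsv"), "w") as fh:
                fh.write("first_site\tlast_site\tspan_bp\n")
                for (a, b), span in zip(grid.blocks, grid.block_spans_bp()):
                    fh.write(f"{grid.site_columns[a]}\t{grid.site_columns[b]}\t{span}\n")

        fits = {}
        distances = np.array([p.distance for p in pairs], float)
        r2s = np.array([p.r2 for p in pairs], float)
        # rho fitting restricted to common variants (MAF >= 0.1); rare
        # alleles cap r2 regardless of distance and bias the estimate
        common = ld_pairwise.filter_pairs_by_maf(pairs, sites, aln.n, min_maf=0.1)
        try:
            fits["parametric"] = ld_decay.fit_parametric_decay(
                np.array([p.distance for p in common], float),
                np.array([p.r2 for p in common], float),
                n=aln.n, model=config.decay_model,
            )
            if not fits["parametric"].converged:
                log.append(
                    f"{tag}: parametric decay fit not converged "
                    f"({fits['parametric'].status}: {fits['parametric'].failure_reason})"
                )
        except HapLDError as exc:
            log.append(f"{tag}: parametric decay fit skipped ({exc})")
        try:
            fits["nonparametric"] = ld_decay.fit_nonparametric_decay(distances, r2s)
        except HapLDError as exc:
            log.append(f"{tag}: nonparametric decay fit skipped ({exc})")
        result.decay_fits[(gene, species)] = fits
        _write_decay(fits, os.path.join(config.out_dir, "decay", f"{tag}.tsv"))

        seg_summaries.extend(
            group_comparison.segment_means(
                pairs, aln.L, config.n_segments, gene_id=gene, species_id=species
            )
        )

    result.table1 = pd.DataFrame(t1_rows)
    result.table2 = pd.DataFrame(t2_rows)
    result.segments = group_comparison.segments_to_frame(seg_summaries)
    _write_formatted(result.table1, os.path.join(config.out_dir, "table1.tsv"))
    _write_formatted(result.table2, os.path.join(config.out_dir, "table2.tsv"))
    _write_formatted(result.segments, os.path.join(config.out_dir, "segments.tsv"))

    if seg_summaries:
        by_gene = group_comparison.compare_groups(seg_summaries, "by_gene")
        by_species = group_comparison.compare_groups(seg_summaries, "by_species")
        result.comparison_by_gene = by_gene.results
        result.comparison_by_species = by_species.results
        _write_formatted(
            by_gene.results, os.path.join(config.out_dir, "comparison_by_gene.tsv")
        )
        _write_formatted(
            by_species.results,
            os.path.join(config.out_dir, "comparison_by_species.tsv"),
        )

    for gene, species, reason in result.failures:
        log.append(f"{gene}_{species}: FAILED ({reason})")
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return result


def _iter_safe(config: RunConfig, log: list[str], result: RunResult):
    for gene, species, aln_or_exc in _load_guard(config):
        if isinstance(aln_or_exc, Exception):
            result.failures.append((gene, species, str(aln_or_exc)))
            continue
        yield gene, species, aln_or_exc


def _load_guard(config: RunConfig):
    if config.design:
        for params in config.design:
            try:
                yield params.gene_id, params.species_id, simulate_haplotypes(params)
            except Exception as exc:
                yield params.gene_id, params.species_id, exc
    if config.manifest:
        for spec in config.manifest:
            try:
                cds = None
                if spec.cds_path:
                    cds = alignment_io.read_cds_annotation(spec.cds_path, spec.gene_id)
                yield spec.gene_id, spec.species_id, alignment_io.read_alignment(
                    spec.path, spec.gene_id, spec.species_id, cds_spec=cds
                )
            except Exception as exc:
                yield spec.gene_id, spec.species_id, exc


def _write_decay(fits: dict, path: str) -> None:
    rows = []
    for method, fit in fits.items():
        for dgrid, val in zip(fit.grid, fit.curve):
            rows.append(
                {
                    "method": method,
                    "distance_bp": dgrid,
                    "fitted_r2": val,
                    "rho_hat": fit.rho_hat,
                    "converged": fit.converged,
                    "status": fit.status,
                }
            )
    pd.DataFrame(
        rows,
        columns=["method", "distance_bp", "fitted_r2", "rho_hat", "converged", "status"],
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_manifest(path: str) -> list[DatasetSpec]:
    """Read a dataset manifest TSV with columns gene, species, path[, cds].

    Relative dataset paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    specs = []
    for _, row in df.iterrows():
        specs.append(
            DatasetSpec(
                gene_id=str(row["gene"]),
                species_id=str(row["species"]),
                path=resolve(str(row["path"])),
                cds_path=resolve(str(row["cds"]))
                if "cds" in df.columns and pd.notna(row.get("cds"))
                else None,
            )
        )
    return specs
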