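import numpy as np
import pytest

from hapld.alignment_io import extract_sites
from hapld.ld_pairwise import pairwise_ld_scan
from hapld.polymorphism import nucleotide_diversity
from hapld.synthetic_data import (
    GENE_LENGTHS,
    INDIVIDUALS,
    SimParams,
    default_study_design,
    simulate_haplotypes,
    simulate_study,
    to_ms_text,
)


class TestSimulateHaplotypes:
    def test_theta_zero_is_monomorphic(self):
        aln = simulate_haplotypes(SimParams(n=8, L=300, theta=0.0, rho=0.02, seed=1))
        assert extract_sites(aln).n_polymorphic == 0
        assert set("".join(aln.sequences)) == {"A"}

    def test_deterministic_under_seed(self):
        p = SimParams(n=10, L=400, theta=0.015, rho=0.02, seed=42)
        a1 = simulate_haplotypes(p)
        a2 = simulate_haplotypes(p)
        assert a1.sequences == a2.sequences
        a3 = simulate_haplotypes(SimParams(n=10, L=400, theta=0.015, rho=0.02, seed=43))
        assert a1.sequences != a3.sequences

    def test_two_samples_always_in_perfect_ld(self):
        # with n=2 every segregating site splits the pair identically, so all
        # pairwise r2 = 1 whatever the recombination rate
        for seed in range(5):
            aln = simulate_haplotypes(
                SimParams(n=2, L=500, theta=0.02, rho=0.05, seed=seed)
            )
            pairs, summary = pairwise_ld_scan(aln, compute_fisher=False)
            if summary.n_pairs:
                assert all(p.r2 == pytest.approx(1.0) for p in pairs)

    def test_sites_are_biallelic_ac_under_infinite_sites(self):
        aln = simulate_haplotypes(SimParams(n=16, L=500, theta=0.02, rho=0.02, seed=3))
        table = extract_sites(aln)
        for s in table.sites:
            assert s.site_class in ("monomorphic", "usable_biallelic")
            assert set(s.alleles) <= {"A", "C"}

    def test_site_frequency_spectrum_neutral(self):
        # aggregated derived-allele counts follow E[xi_i] proportional to 1/i
        reps, n = 150, 10
        counts = np.zeros(n)
        per_rep = []
        for i in range(reps):
            aln = simulate_haplotypes(
                SimParams(n=n, L=800, theta=0.0125, rho=0.0, seed=9000 + i)
            )
            rep = np.zeros(n)
            for s in extract_sites(aln).sites:
                if len(s.alleles) == 2:
                    derived = dict(s.counts)["C"]
                    rep[derived] += 1
            counts += rep
            per_rep.append(rep)
        per_rep = np.array(per_rep)
        theta_l = 0.0125 * 800
        for i in range(1, n):
            expected = theta_l / i
            se = per_rep[:, i].std(ddof=1) / np.sqrt(reps)
            assert abs(counts[i] / reps - expected) < 4 * se + 0.05

    def test_mean_r2_decreases_with_rho(self):
        # medians over 50 replicates per rho level, distant-pair r2 monotone
        medians = []
        for rho in (0.0, 0.01, 0.05):
            means = []
            for i in range(50):
                aln = simulate_haplotypes(
                    SimParams(n=16, L=400, theta=0.02, rho=rho, seed=100_000 + i)
                )
                pairs, _ = pairwise_ld_scan(aln, compute_fisher=False)
                far = [p.r2 for p in pairs if p.distance > 100]
                if far:
                    means.append(float(np.mean(far)))
            medians.append(float(np.median(means)))
        assert medians[0] > medians[1] > medians[2]

    def test_rho_zero_fit_pins_rho_at_grid_minimum(self):
        from hapld.ld_decay import RHO_GRID_MIN, fit_parametric_decay
        from hapld.ld_pairwise import filter_pairs_by_maf

        estimates = []
        for i in range(5):
            aln = simulate_haplotypes(
                SimParams(n=16, L=600, theta=0.02, rho=0.0, seed=600 + i)
            )
            table = extract_sites(aln)
            pairs, _ = pairwise_ld_scan(aln, site_table=table, compute_fisher=False)
            common = filter_pairs_by_maf(pairs, table, aln.n)
            fit = fit_parametric_decay(
                [p.distance for p in common], [p.r2 for p in common], n=aln.n
            )
            estimates.append(fit.rho_hat)
        assert np.median(estimates) < 100 * RHO_GRID_MIN

    def test_gap_injection_exercises_exclusion(self):
        aln = simulate_haplotypes(
            SimParams(n=10, L=500, theta=0.02, rho=0.01, seed=4, gap_rate=0.05)
        )
        table = extract_sites(aln)
        assert table.class_counts().get("excluded_gap", 0) > 0
        assert table.n_usable <= table.n_polymorphic

    def test_finite_sites_mode_can_produce_multiallelic(self):
        hit = False
        for seed in range(8):
            aln = simulate_haplotypes(
                SimParams(n=12, L=100, theta=0.2, rho=0.0, seed=seed, finite_sites=True)
            )
            if extract_sites(aln).class_counts().get("excluded_multiallelic", 0):
                hit = True
                break
        assert hit

    def test_growth_skews_spectrum_toward_singletons(self):
        # star-like genealogies under rapid growth inflate the singleton share
        def singleton_share(growth, seeds):
            single = total = 0
            for seed in seeds:
                aln = simulate_haplotypes(
                    SimParams(n=12, L=600, theta=0.02, rho=0.0, seed=seed,
                              growth_rate=growth)
                )
                for s in extract_sites(aln).sites:
                    if len(s.alleles) == 2:
                        total += 1
                        if dict(s.counts)["C"] == 1:
                            single += 1
            return single / total

        flat = singleton_share(0.0, range(300, 330))
        grown = singleton_share(20.0, range(300, 330))
        assert grown > flat

    def test_watterson_mean_with_recombination(self):
        # recombination leaves E[S] unchanged
        reps = 80
        S = [
            extract_sites(
                simulate_haplotypes(
                    SimParams(n=10, L=500, theta=0.01, rho=0.05, seed=7000 + i)
                )
            ).n_polymorphic
            for i in range(reps)
        ]
        expected = 0.01 * 500 * sum(1 / i for i in range(1, 10))
        se = np.std(S, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(S) - expected) < 4 * se


class TestCrossCheck:
    def test_matches_msprime_summaries(self):
        """Independent oracle: an established coalescent simulator should give
        the same mean S, pi and distant-pair r2 at matched parameters."""
        msprime = pytest.importorskip("msprime")
        from hapld.alignment_io import HaplotypeAlignment

        n, L, theta, rho, reps = 12, 600, 0.015, 0.02, 60
        ne = 10_000

        def msprime_alignment(seed):
            # haploid samples: pairwise coalescence rate is 1/Ne per
            # generation, so theta = 2*Ne*mu and rho = 2*Ne*c
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, sequence_length=L,
                recombination_rate=rho / (2 * ne), population_size=ne,
                random_seed=seed,
            )
            ts = msprime.sim_mutations(
                ts, rate=theta / (2 * ne), random_seed=seed,
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            geno = ts.genotype_matrix().T  # samples x sites
            seqs = np.full((n, L), "A", dtype="<U1")
            for k, site in enumerate(ts.sites()):
                col = min(int(site.position), L - 1)
                seqs[geno[:, k] > 0, col] = "C"
            return HaplotypeAlignment(
                gene_id="ms", species_id="ms",
                names=tuple(f"h{i}" for i in range(n)),
                sequences=tuple("".join(row) for row in seqs),
            )

        def summarize(alns):
            S, pi, far_r2 = [], [], []
            for aln in alns:
                S.append(extract_sites(aln).n_polymorphic)
                pi.append(nucleotide_diversity(aln))
                pairs, _ = pairwise_ld_scan(aln, compute_fisher=False)
                vals = [p.r2 for p in pairs if p.distance > 150]
                if vals:
                    far_r2.append(float(np.mean(vals)))
            return np.mean(S), np.mean(pi), np.mean(far_r2)

        ours = summarize(
            simulate_haplotypes(SimParams(n=n, L=L, theta=theta, rho=rho, seed=50 + i))
            for i in range(reps)
        )
        theirs = summarize(msprime_alignment(1 + i) for i in range(reps))
        assert ours[0] == pytest.approx(theirs[0], rel=0.15)
        assert ours[1] == pytest.approx(theirs[1], rel=0.15)
        assert ours[2] == pytest.approx(theirs[2], rel=0.35)


class TestStudyBundle:
    def test_default_design_uses_study_sample_sizes(self):
        design = default_study_design(seed=0)
        assert len(design) == 28
        by_key = {(p.gene_id, p.species_id): p for p in design}
        assert by_key[("Gambicin", "gambiae_M")].n == 32  # 16 individuals, phased
        assert by_key[("REL2", "gambiae_S")].n == 28  # 14 individuals
        assert by_key[("REL2", "bwambae")].theta == 0.0
        for p in design:
            assert p.L == GENE_LENGTHS[p.gene_id]
            assert p.n == 2 * INDIVIDUALS[p.gene_id][p.species_id]

    def test_bundle_round_trip_and_determinism(self, tmp_path):
        design = [
            SimParams(n=6, L=120, theta=0.02, rho=0.02, seed=5, gene_id="g1",
                      species_id="s1"),
            SimParams(n=4, L=90, theta=0.0, rho=0.02, seed=6, gene_id="g2",
                      species_id="s2"),
        ]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(design, out_dir=d1)
        simulate_study(design, out_dir=d2)
        for name in ("g1_s1.fasta", "g2_s2.fasta", "manifest.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_ms_text_output(self):
        aln = simulate_haplotypes(SimParams(n=6, L=200, theta=0.02, rho=0.01, seed=8))
        text = to_ms_text(aln)
        S = extract_sites(aln).n_polymorphic
        assert f"segsites: {S}" in text
        assert text.count("\n") == 3 + aln.n
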