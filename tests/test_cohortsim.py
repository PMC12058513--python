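import numpy as np
import pytest

from rohkit.cohortsim import (
    ConfigError,
    SegmentLaw,
    SimConfig,
    build_pedigree,
    genotypes_from_haps,
    inject_errors,
    make_array_mask,
    simulate_cohort,
    simulate_founders,
    simulate_sites,
    transmit_pedigree,
)
from rohkit.genomic_io import GeneticMap, GenotypeMatrix, write_vcf
from rohkit.pedigree_qc import site_error_scan


def cfg_1chrom(**kw):
    defaults = dict(chrom_lengths={"chr1": 10_000_000}, seed=0, site_density=100.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateSites:
    def test_fixed_spacing_count(self):
        sites = simulate_sites(cfg_1chrom(fixed_spacing=True))
        assert sites.n_sites == 1000
        assert np.all(np.diff(sites.pos) > 0)

    def test_beta_mean_within_3se(self):
        # Beta(0.5, 0.5): mean 1/2, var = ab/((a+b)^2 (a+b+1)) = 1/8
        cfg = SimConfig(
            chrom_lengths={"chr1": 1_000_000_000}, seed=3, site_density=100.0,
            af_law=(0.5, 0.5),
        )
        sites = simulate_sites(cfg)
        n = sites.n_sites
        assert n == 100_000
        se = np.sqrt(0.125 / n)
        assert abs(sites.af.mean() - 0.5) < 3 * se

    def test_two_chromosomes_sorted(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 5_000_000, "chr2": 3_000_000}, seed=1,
            site_density=50.0,
        )
        sites = simulate_sites(cfg)
        labels = set(sites.chrom.astype(str))
        assert labels == {"chr1", "chr2"}
        for c in labels:
            block = sites.chrom_block(c)
            assert np.all(np.diff(sites.pos[block]) > 0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ConfigError):
            cfg_1chrom(site_density=0)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(chrom_lengths={"chr1": 0}, site_density=10)


class TestSimulateFounders:
    def test_no_het_inside_planted_segment(self):
        cfg = cfg_1chrom(
            planted_segments=[SegmentLaw(count=1, law="fixed", length_bp=2_000_000)]
        )
        rng = np.random.default_rng(cfg.seed)
        sites = simulate_sites(cfg, rng)
        haps, truth = simulate_founders(sites, cfg, ["f1"], rng)
        (chrom, start, end) = truth.planted_for("f1")[0]
        geno = haps["f1"].sum(axis=0)
        inside = (sites.pos >= start) & (sites.pos <= end)
        assert inside.sum() > 0
        assert not np.any(geno[inside] == 1)

    def test_hwe_het_fraction_at_half(self):
        cfg = SimConfig(chrom_lengths={"chr1": 100_000_000}, seed=9, site_density=100.0)
        rng = np.random.default_rng(cfg.seed)
        sites = simulate_sites(cfg, rng)
        sites.af[:] = 0.5
        haps, _ = simulate_founders(sites, cfg, ["f1"], rng)
        het = (haps["f1"].sum(axis=0) == 1).mean()
        se = np.sqrt(0.25 / sites.n_sites)  # Bernoulli(2pq = 0.5)
        assert abs(het - 0.5) < 3 * se

    def test_fixed_law_truth_lengths(self):
        cfg = cfg_1chrom(
            planted_segments=[SegmentLaw(count=5, law="fixed", length_bp=300_000)]
        )
        rng = np.random.default_rng(0)
        sites = simulate_sites(cfg, rng)
        _, truth = simulate_founders(sites, cfg, ["f1"], rng)
        lengths = [e - s + 1 for _c, s, e in truth.planted_for("f1")]
        assert lengths == [300_000] * 5

    def test_segment_longer_than_chromosome_rejected(self):
        cfg = cfg_1chrom(
            planted_segments=[SegmentLaw(count=1, law="fixed", length_bp=20_000_000)]
        )
        rng = np.random.default_rng(0)
        sites = simulate_sites(cfg, rng)
        with pytest.raises(ConfigError):
            simulate_founders(sites, cfg, ["f1"], rng)


class TestTransmission:
    def test_mendelian_consistent_before_errors(self, pedigree_cohort):
        report = site_error_scan(pedigree_cohort.clean_gm, pedigree_cohort.pedigree)
        assert report.n_inconsistent.sum() == 0
        assert not report.flagged.any()

    def test_both_parents_homref_gives_homref_child(self, pedigree_cohort):
        gm = pedigree_cohort.clean_gm
        fa, mo, ch = pedigree_cohort.pedigree.trios()[0]
        f = gm.calls[:, gm.sample_index(fa)]
        m = gm.calls[:, gm.sample_index(mo)]
        c = gm.calls[:, gm.sample_index(ch)]
        both0 = (f == 0) & (m == 0)
        assert both0.sum() > 0
        assert np.all(c[both0] == 0)

    def test_zero_map_length_means_no_crossover(self):
        cfg = cfg_1chrom(pedigree_spec={"trio": 1}, map_rate_cm_per_mb=1.0)
        rng = np.random.default_rng(4)
        sites = simulate_sites(cfg, rng)
        ped = build_pedigree(cfg)
        founder_ids = [i.iid for i in ped.founders()]
        haps, _ = simulate_founders(sites, cfg, founder_ids, rng)
        flat_map = GeneticMap({"chr1": ([1, 10_000_000], [0.0, 0.0])})
        all_haps = transmit_pedigree(haps, ped, sites, flat_map, rng)
        child = ped.offspring()[0]
        ch = all_haps[child.iid]
        pa = haps[child.father]
        ma = haps[child.mother]
        assert any(np.array_equal(ch[0], pa[k]) for k in (0, 1))
        assert any(np.array_equal(ch[1], ma[k]) for k in (0, 1))

    def test_crossover_count_poisson_mean(self):
        # 100 cM chromosome; observable haplotype switches ~ Poisson(1)
        from rohkit.cohortsim import _gamete

        rng = np.random.default_rng(7)
        n_sites = 2000
        site_cm = np.linspace(0.0, 100.0, n_sites)
        parent = np.vstack([np.zeros(n_sites, dtype=np.int8), np.ones(n_sites, dtype=np.int8)])
        counts = []
        for _ in range(300):
            g = _gamete(parent, site_cm, (0.0, 100.0), rng)
            counts.append(int((np.diff(g.astype(int)) != 0).sum()))
        se = np.sqrt(1.0 / len(counts))
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_unmapped_chromosome_raises(self):
        from rohkit.genomic_io import MapCoverageError

        cfg = cfg_1chrom(pedigree_spec={"trio": 1})
        rng = np.random.default_rng(4)
        sites = simulate_sites(cfg, rng)
        ped = build_pedigree(cfg)
        haps, _ = simulate_founders(sites, cfg, [i.iid for i in ped.founders()], rng)
        wrong_map = GeneticMap({"chrX": ([1, 2], [0.0, 0.1])})
        with pytest.raises(MapCoverageError):
            transmit_pedigree(haps, ped, sites, wrong_map, rng)


class TestInjectErrors:
    def _all_hom_gm(self, n_sites=2000, length=100_000_000):
        pos = np.linspace(1, length, n_sites).astype(np.int64)
        return GenotypeMatrix(
            chrom=np.full(n_sites, "chr1", dtype=object),
            pos=pos,
            ref=np.full(n_sites, "A", dtype=object),
            alt=np.full(n_sites, "T", dtype=object),
            calls=np.zeros((n_sites, 1), dtype=np.int8),
            samples=["s1"],
            af=np.full(n_sites, 0.5),
        )

    def test_zero_rates_identity(self):
        gm = self._all_hom_gm()
        cfg = SimConfig(chrom_lengths={"chr1": 100_000_000}, het_error_rate=0.0)
        out, truth = inject_errors(gm, cfg, np.random.default_rng(0))
        assert np.all(out.calls == gm.calls)
        assert truth.per_genotype_flips == []

    def test_flip_count_at_paper_rate(self):
        # 4.5 errors/Mb on a 100 Mb all-homozygous genome: Poisson(450)
        gm = self._all_hom_gm()
        cfg = SimConfig(chrom_lengths={"chr1": 100_000_000}, het_error_rate=4.5)
        out, truth = inject_errors(gm, cfg, np.random.default_rng(10))
        n_flips = int((out.calls == 1).sum())
        assert n_flips == len(truth.per_genotype_flips)
        assert abs(n_flips - 450) < 3 * np.sqrt(450)

    def test_fixed_seed_reproducible(self):
        gm = self._all_hom_gm()
        cfg = SimConfig(
            chrom_lengths={"chr1": 100_000_000}, het_error_rate=4.5,
            bad_site_fraction=0.05, bad_site_error_prob=0.3,
        )
        out1, t1 = inject_errors(gm, cfg, np.random.default_rng(42))
        out2, t2 = inject_errors(gm, cfg, np.random.default_rng(42))
        assert np.all(out1.calls == out2.calls)
        assert t1.per_genotype_flips == t2.per_genotype_flips
        assert t1.error_sites == t2.error_sites

    def test_flips_recorded_at_existing_sites(self):
        gm = self._all_hom_gm()
        cfg = SimConfig(
            chrom_lengths={"chr1": 100_000_000}, het_error_rate=1.0,
            bad_site_fraction=0.02, bad_site_error_prob=0.5,
        )
        out, truth = inject_errors(gm, cfg, np.random.default_rng(3))
        site_keys = set(zip(gm.chrom.astype(str), gm.pos.tolist()))
        for _s, c, p, orig, new in truth.per_genotype_flips:
            assert (c, p) in site_keys
            assert orig != new


class TestArrayMask:
    def test_full_fraction_keeps_all(self):
        cfg = cfg_1chrom(array_mask_fraction=1.0)
        sites = simulate_sites(cfg)
        mask = make_array_mask(sites, cfg, np.random.default_rng(0))
        assert len(mask) == sites.n_sites

    def test_floor_rule(self):
        cfg = cfg_1chrom(array_mask_fraction=0.1)
        sites = simulate_sites(cfg)
        mask = make_array_mask(sites, cfg, np.random.default_rng(0))
        assert len(mask) == 100

    def test_seed_determinism(self):
        cfg = cfg_1chrom(array_mask_fraction=0.3)
        sites = simulate_sites(cfg)
        m1 = make_array_mask(sites, cfg, np.random.default_rng(5))
        m2 = make_array_mask(sites, cfg, np.random.default_rng(5))
        m3 = make_array_mask(sites, cfg, np.random.default_rng(6))
        assert np.all(m1.start == m2.start)
        assert not np.array_equal(m1.start, m3.start)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            cfg_1chrom(array_mask_fraction=0.0)


class TestFullCohort:
    def test_bitwise_reproducibility(self, tmp_path):
        cfg = cfg_1chrom(
            n_founders=4,
            pedigree_spec={"trio": 1},
            het_error_rate=2.0,
            planted_segments=[SegmentLaw(count=1, law="fixed", length_bp=1_000_000)],
        )
        r1 = simulate_cohort(cfg)
        r2 = simulate_cohort(cfg)
        assert r1.gm.equal_calls(r2.gm)
        assert r1.truth.planted == r2.truth.planted
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(r1.gm, p1, cfg.chrom_lengths)
        write_vcf(r2.gm, p2, cfg.chrom_lengths)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pedigree_template_sizes(self):
        cfg = cfg_1chrom(pedigree_spec={"trio": 2, "septet": 1, "octet": 1})
        ped = build_pedigree(cfg)
        assert len(ped) == 2 * 3 + 7 + 8

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = cfg_1chrom(
            planted_segments=[SegmentLaw(count=2, law="uniform", min_bp=1e5, max_bp=9e5)],
            pedigree_spec={"septet": 2},
            het_error_rate=4.5,
        )
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SimConfig.from_yaml(p)
        assert back.chrom_lengths == cfg.chrom_lengths
        assert back.planted_segments == cfg.planted_segments
        assert back.het_error_rate == cfg.het_error_rate
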