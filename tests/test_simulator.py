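import numpy as np
import pytest

from grab import SimConfig
from grab.formats_io import read_genotypes
from grab.ibs_core import ErrorModelConfig, ibs_states, make_windows
from grab.pedigree import default_family_pedigree
from grab.pipeline import pair_metrics_fast
from grab.simulate import (
    apply_error,
    export_ped_map,
    export_vcf,
    gene_drop,
    make_site_panel,
    meiosis,
    read_truth_table,
    simulate_founders,
    thin_to_array_density,
    write_truth_table,
)
from tests.conftest import SMALL_LENGTHS


@pytest.fixture(scope="module")
def mini_cfg():
    return SimConfig(
        n_sites=5_000, chrom_lengths={"1": 50_000_000, "2": 40_000_000}, seed=99
    )


@pytest.fixture(scope="module")
def mini_panel(mini_cfg):
    return make_site_panel(mini_cfg, np.random.default_rng(99))


class TestFounders:
    def test_seed_determinism(self, mini_cfg):
        a = simulate_founders(mini_cfg, 4, np.random.default_rng(1), panel=None)
        b = simulate_founders(mini_cfg, 4, np.random.default_rng(1), panel=None)
        assert np.array_equal(a.haps, b.haps)
        assert np.array_equal(a.panel.pos, b.panel.pos)

    def test_fixed_allele_frequency_extremes(self, mini_cfg, mini_panel):
        panel = mini_panel
        fixed = panel.freq.copy()
        panel_fixed = type(panel)(
            chrom=panel.chrom, pos=panel.pos, ref=panel.ref, alt=panel.alt,
            freq=np.ones_like(fixed), chrom_lengths=panel.chrom_lengths,
        )
        f = simulate_founders(mini_cfg, 3, np.random.default_rng(0), panel=panel_fixed)
        assert (f.haps == 1).all()  # frequency 1.0 -> all homozygous alt

    def test_founder_frequencies_track_panel(self, mini_cfg, mini_panel):
        f = simulate_founders(mini_cfg, 60, np.random.default_rng(5), panel=mini_panel)
        observed = f.haps.mean(axis=(0, 1))
        # 120 haplotypes per site: observed frequency ~ panel frequency
        err = observed - mini_panel.freq
        assert abs(err.mean()) < 0.01


class TestMeiosis:
    def test_no_recombination_returns_intact_haplotype(self, mini_panel):
        rng = np.random.default_rng(10)
        parent = (rng.random((2, mini_panel.n_sites)) < 0.5).astype(np.uint8)
        gamete = meiosis(parent, mini_panel, 0.0, rng)
        per_chrom_ok = []
        for _c, sl in mini_panel.chrom_slices():
            per_chrom_ok.append(
                np.array_equal(gamete[sl], parent[0, sl])
                or np.array_equal(gamete[sl], parent[1, sl])
            )
        assert all(per_chrom_ok)

    def test_crossover_count_matches_poisson_mean(self, mini_cfg):
        """Mean switch count over many meioses ~ Poisson(L * rate)."""
        panel = make_site_panel(
            SimConfig(n_sites=2_000, chrom_lengths={"1": 100_000_000}, seed=2),
            np.random.default_rng(2),
        )
        rng = np.random.default_rng(3)
        parent = np.zeros((2, panel.n_sites), dtype=np.uint8)
        parent[1] = 1  # tagged haplotypes: gamete value reveals source
        n_rep = 3_000
        switches = np.empty(n_rep)
        for r in range(n_rep):
            g = meiosis(parent, panel, 1e-8, rng)
            switches[r] = (g[1:] != g[:-1]).sum()
        # observed switches undercount crossovers only via double-hits
        # between adjacent sites (negligible at this density)
        expected = 1.0  # 100 Mb * 1e-8
        se = np.sqrt(expected / n_rep)
        assert abs(switches.mean() - expected) < 4 * se


class TestGeneDrop:
    def test_child_shares_allele_with_each_parent(self, small_family):
        """Mendelian consequence: no IBS0 site in any parent-child pair."""
        ped, dip = small_family
        gt = dip.genotypes()
        for child in ("B1", "D3", "G2"):
            member = ped.members[child]
            gc = gt[:, dip.member_index(child)]
            for parent in (member.father, member.mother):
                gp = gt[:, dip.member_index(parent)]
                assert (ibs_states(gc, gp) == 0).sum() == 0

    def test_trio_mendelian_consistency(self, small_family):
        """Child genotype is achievable from parental genotypes at every site."""
        ped, dip = small_family
        gt = dip.genotypes()
        for child in ped.nonfounders:
            member = ped.members[child]
            gc = gt[:, dip.member_index(child)]
            gf = gt[:, dip.member_index(member.father)]
            gm_ = gt[:, dip.member_index(member.mother)]
            # impossible: child hom-ref with a hom-alt parent and vice versa
            bad = ((gc == 0) & ((gf == 2) | (gm_ == 2))) | (
                (gc == 2) & ((gf == 0) | (gm_ == 0))
            )
            assert bad.sum() == 0

    def test_pairwise_sharing_matches_kinship_theory(self, small_family, small_cfg):
        """Class-mean IW fraction tracks expected IBD>=1 sharing:
        PO=1 exactly, FS~3/4, then halving per degree (windows only
        partially covered by an IBD segment erode the fractions a
        little, and single families fluctuate, hence the tolerances)."""
        ped, dip = small_family
        gm = apply_error(dip, 0.0, np.random.default_rng(0))
        windows = make_windows(small_cfg.chrom_lengths, 1_000_000)
        cfg = ErrorModelConfig(se=0.0)
        fracs: dict[str, list[float]] = {"PO": [], "FS": [], "D2": [], "D3": []}
        for a, b, label in ped.pair_labels():
            if label in fracs:
                m = pair_metrics_fast(gm, a, b, windows, cfg)
                fracs[label].append(m.iw_frac)
        assert all(f == 1.0 for f in fracs["PO"])  # every window shares a haplotype
        assert np.mean(fracs["FS"]) == pytest.approx(0.75, abs=0.1)
        assert np.mean(fracs["D2"]) == pytest.approx(0.5, abs=0.1)
        assert np.mean(fracs["D3"]) == pytest.approx(0.25, abs=0.1)
        # monotone halving pattern
        assert (
            1.0
            > np.mean(fracs["FS"]) + 0.05
            > np.mean(fracs["D2"])
            > np.mean(fracs["D3"])
        )

    def test_replicates_are_independent_but_seeded(self, mini_cfg, mini_panel):
        ped = default_family_pedigree()
        def drop(seed):
            rng = np.random.default_rng(seed)
            founders = simulate_founders(
                mini_cfg, 10, rng, panel=mini_panel, ids=ped.founders
            )
            return gene_drop(ped, founders, mini_cfg, rng)
        a1, a2, b = drop(7), drop(7), drop(8)
        assert np.array_equal(a1.haps, a2.haps)
        assert not np.array_equal(a1.haps, b.haps)


class TestErrorChannel:
    def test_zero_error_is_identity(self, small_family):
        _ped, dip = small_family
        gm = apply_error(dip, 0.0, np.random.default_rng(1))
        assert np.array_equal(gm.calls, dip.genotypes())

    def test_error_rate_within_binomial_tolerance(self, small_family):
        _ped, dip = small_family
        se = 0.01
        gm = apply_error(dip, se, np.random.default_rng(1))
        n = gm.calls.size
        flipped = (gm.calls != dip.genotypes()).sum()
        sd = np.sqrt(n * se * (1 - se))
        assert abs(flipped - n * se) < 4 * sd

    def test_po_p0_stays_below_cutoff(self, small_family, small_cfg):
        """Parent-offspring at SE=0.001: error-induced IBS0 stays below
        the scheduled cutoff in almost all windows."""
        ped, dip = small_family
        se = 0.001
        gm = apply_error(dip, se, np.random.default_rng(12))
        windows = make_windows(small_cfg.chrom_lengths, 1_000_000)
        cfg = ErrorModelConfig(se=se)
        # ~250 sites/window: the cutoff admits no IBS0 count, so the IW
        # rate is P(zero error-induced IBS0 sites) ~ exp(-0.11) ~ 0.9
        m = pair_metrics_fast(gm, "A1", "B1", windows, cfg)
        assert m.iw_frac > 0.8


class TestExport:
    def test_vcf_round_trip(self, small_family, tmp_path):
        _ped, dip = small_family
        gm = apply_error(dip, 0.0, np.random.default_rng(0))
        sub = gm.subset_sites(np.arange(gm.n_sites) < 500)
        path = tmp_path / "fam.vcf"
        export_vcf(sub, path, chrom_lengths=dict(SMALL_LENGTHS))
        back = read_genotypes(path, "vcf")
        assert back.samples == sub.samples
        assert np.array_equal(back.calls, sub.calls)
        assert back.pos.tolist() == sub.pos.tolist()

    def test_ped_map_round_trip(self, small_family, tmp_path):
        _ped, dip = small_family
        gm = apply_error(dip, 0.0, np.random.default_rng(0))
        sub = gm.subset_sites(np.arange(gm.n_sites) < 300)
        export_ped_map(sub, tmp_path / "fam")
        back = read_genotypes(tmp_path / "fam.ped", "ped_map")
        assert back.samples == sub.samples
        # PED carries no REF/ALT polarity; IBS statistics are invariant
        # under code flips, so compare up to per-site polarity
        for i in range(back.n_sites):
            got, want = back.calls[i], sub.calls[i]
            assert np.array_equal(got, want) or np.array_equal(2 - got, want)

    def test_truth_table_lists_all_pairs(self, tmp_path):
        ped = default_family_pedigree()
        path = tmp_path / "truth.tsv"
        write_truth_table(ped, path)
        rows = read_truth_table(path)
        assert len(rows) == 325  # 26 choose 2
        labels = {lab for _, _, lab in rows}
        assert {"FS", "PO", "D2", "D7", "UN"} <= labels

    def test_array_thinning(self, small_family):
        _ped, dip = small_family
        gm = apply_error(dip, 0.0, np.random.default_rng(0))
        thin = thin_to_array_density(gm, 10_000, np.random.default_rng(3))
        assert thin.n_sites == 10_000
        # sites remain sorted within chromosomes
        for c in np.unique(thin.chrom):
            assert np.all(np.diff(thin.pos[thin.chrom == c]) > 0)
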