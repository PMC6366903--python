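import numpy as np
import pandas as pd
import pytest

from suppscreen.effect import annotate
from suppscreen.refmodel import CodonTable
from suppscreen.simscreen import (
    CATEGORY_GENES,
    SimConfig,
    make_design,
    simulate_counts,
    simulate_genome,
    simulate_screen,
    simulate_strains,
)
from suppscreen.sitecounts import COUNT_COLUMNS


def small_config(**kw):
    base = dict(seed=9, n_suppressor_strains=5, n_other_genes=50,
                genome_length=22_000, ancestral_variant_count=8)
    base.update(kw)
    return SimConfig(**base)


class TestSimConfig:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimConfig()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="error_rate"):
            SimConfig(seed=1, error_rate=-1)

    def test_category_probs_validated(self):
        with pytest.raises(ValueError, match="unknown causal categories"):
            SimConfig(seed=1, causal_category_probs={"nope": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestSimulateGenome:
    def test_every_orf_passes_validation(self, table):
        genome, orfs, _ = simulate_genome(small_config(), table)
        for orf in orfs:
            orf.validate(genome, table)

    def test_gene_sets_partition_pathway_genes(self):
        _, orfs, sets = simulate_genome(small_config())
        ids = {o.gene_id for o in orfs}
        for cat, genes in CATEGORY_GENES.items():
            assert set(sets[cat]) == set(genes)
            assert set(genes) <= ids

    def test_deterministic_files(self, tmp_path):
        a = simulate_screen(small_config())
        b = simulate_screen(small_config())
        pa, pb = a.write(tmp_path / "a"), b.write(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_orfs_must_fit(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_genome(small_config(genome_length=5_000))

    def test_zero_orfs_allowed_with_warning(self):
        cfg = small_config(n_other_genes=0, include_pathway_genes=False,
                           causal_category_probs={}, genome_length=2_000)
        with pytest.warns(UserWarning, match="empty gene model"):
            genome, orfs, _ = simulate_genome(cfg)
        assert orfs == [] and len(genome.contigs["chr1"]) == 2_000


class TestSimulateStrains:
    def test_degenerate_poisson_only_causal_and_ancestral(self):
        cfg = small_config(background_nonsilent_mean=0.0, background_silent_mean=0.0)
        genome, orfs, sets = simulate_genome(cfg)
        truth = simulate_strains(genome, orfs, sets, cfg)
        roles = truth.variants["role"].value_counts().to_dict()
        assert roles == {"causal": 5, "ancestral": 8}

    def test_background_count_matches_poisson_mean(self, table):
        cfg = SimConfig(seed=77, n_suppressor_strains=95, n_other_genes=300,
                        genome_length=110_000, ancestral_variant_count=5,
                        background_silent_mean=0.0)
        genome, orfs, sets = simulate_genome(cfg, table)
        truth = simulate_strains(genome, orfs, sets, cfg, table)
        bg = truth.variants[truth.variants["role"] == "background_nonsilent"]
        per_strain = bg.groupby("sample").size().reindex(
            truth.strains["sample"], fill_value=0)
        lam = cfg.background_nonsilent_mean
        se = np.sqrt(lam / len(per_strain))
        assert abs(per_strain.mean() - lam) < 3 * se

    def test_exactly_one_causal_per_strain(self, small_screen):
        causal = small_screen.truth.variants.query("role == 'causal'")
        assert causal.groupby("sample").size().eq(1).all()
        assert len(causal) == small_screen.config.n_suppressor_strains

    def test_causal_annotates_as_nonsense_through_independent_path(self, table):
        """The annotator (coordinate arithmetic) must agree with the simulator
        (codon-table construction) on every planted causal stop-gain."""
        fx_truth, genome, orfs = None, None, None
        cfg = small_config(seed=33)
        genome, orfs, sets = simulate_genome(cfg, table)
        truth = simulate_strains(genome, orfs, sets, cfg, table)
        causal = truth.variants.query("role == 'causal'")
        for row in causal.itertuples():
            anns = annotate(row.contig, int(row.pos), row.ref, row.alt,
                            genome, orfs, table)
            assert any(a.effect == "nonsense" and a.gene_id == row.gene_id
                       for a in anns)

    def test_ancestral_shared_by_construction(self, small_screen):
        anc = small_screen.truth.ancestral
        assert (anc["sample"] == "all").all()
        assert len(anc) == small_screen.config.ancestral_variant_count


class TestSimulateCounts:
    def test_no_noise_limit_emits_exactly_truth_sites(self):
        cfg = small_config(error_rate=0.0, multiallelic_noise_rate=0.0)
        genome, orfs, sets = simulate_genome(cfg)
        truth = simulate_strains(genome, orfs, sets, cfg)
        design = make_design(cfg)
        counts = simulate_counts(truth, genome, design, cfg)
        emitted = set(counts.records["pos"])
        assert emitted == set(truth.variants["pos"])
        # every sample present at every truth site
        per_site = counts.records.groupby("pos", observed=True)["sample"].nunique()
        assert (per_site == len(design.samples)).all()

    def test_ancestral_af_high_in_controls_and_strains(self, small_screen):
        rec = small_screen.counts.records
        anc = small_screen.truth.ancestral
        merged = rec.merge(anc[["pos", "alt"]], on="pos")
        alt_counts = np.array([merged.iloc[i][f"n{a}"]
                               for i, a in enumerate(merged["alt"])])
        depth = merged[COUNT_COLUMNS].sum(axis=1).to_numpy()
        af = alt_counts / np.maximum(depth, 1)
        assert (af > 0.8).mean() > 0.99

    def test_truth_variants_visible_when_expected(self, small_screen):
        """Every planted variant with AF × expected depth ≥ 10 shows ≥1 alt read."""
        rec = small_screen.counts.records.set_index(["pos", "sample"]).sort_index()
        tv = small_screen.truth.variants
        checked = 0
        for row in tv.itertuples():
            if row.true_af * small_screen.config.coverage_mean < 10:
                continue
            carriers = (small_screen.design.samples
                        if row.sample == "all" else [row.sample])
            for s in carriers:
                r = rec.loc[(row.pos, s)]
                if int(r[COUNT_COLUMNS].sum()) == 0:
                    continue  # a zero-depth draw carries no evidence
                assert int(r[f"n{row.alt}"]) >= 1
                checked += 1
        assert checked > 50

    def test_controls_carry_only_ancestral_signal(self, small_screen):
        """No private (causal/background) variant shows clonal-level AF in a control."""
        rec = small_screen.counts.records
        ctrl = rec[rec["sample"].isin(small_screen.design.controls)]
        private = small_screen.truth.variants.query("role != 'ancestral'")
        merged = ctrl.merge(private[["pos", "alt"]], on="pos")
        depth = merged[COUNT_COLUMNS].sum(axis=1).to_numpy()
        alt_counts = np.array([merged.iloc[i][f"n{a}"]
                               for i, a in enumerate(merged["alt"])])
        af = alt_counts / np.maximum(depth, 1)
        assert (af < 0.1).all()

    def test_depth_distribution_matches_coverage_mean(self):
        cfg = SimConfig(seed=13, n_suppressor_strains=3, n_other_genes=80,
                        genome_length=40_000, ancestral_variant_count=5)
        fx = simulate_screen(cfg)
        depth = fx.counts.depth().to_numpy()
        assert len(depth) >= 10_000
        mean, r = cfg.coverage_mean, cfg.coverage_dispersion
        # NB variance = m + m^2/r; allow 4 SE on the sample mean, plus the
        # mild upward bias from the depth >= error-count floor
        sd = np.sqrt(mean + mean**2 / r)
        assert abs(depth.mean() - mean) < 4 * sd / np.sqrt(len(depth)) + 1.0

    def test_multiallelic_noise_sites_have_two_alts(self):
        cfg = small_config(multiallelic_noise_rate=2e-4)  # ~4 sites in 22 kb
        fx = simulate_screen(cfg)
        truth_pos = set(fx.truth.variants["pos"])
        rec = fx.counts.records
        noise = rec[~rec["pos"].isin(truth_pos)]
        # at least one injected site with two distinct alt alleles at high count
        found = 0
        for pos, grp in noise.groupby("pos", observed=True):
            strong = set()
            for _, r in grp.iterrows():
                for b in "ACGT":
                    if b != r["ref"] and r[f"n{b}"] >= 20:
                        strong.add(b)
            if len(strong) >= 2:
                found += 1
        assert found >= 1
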