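"""Synthetic-study generator: determinism, planted truth, emission noise."""

import numpy as np
import pytest
import scipy.stats as sps

from evohotspot import simdata
from evohotspot.simdata import (
    BiasConfig,
    CallerProfile,
    SimConfig,
    emit_caller_calls,
    generate_genome,
    simulate_cohort,
    simulate_coverage_track,
    simulate_dose_response,
    simulate_flow_sample,
    simulate_growth,
)


class TestGenome:
    def test_deterministic_and_sized(self):
        cfg = SimConfig(seed=1)
        g1 = generate_genome(cfg)
        g2 = generate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert len(g1.sequences) == 2
        assert all(len(s) == 100_000 for s in g1.sequences.values()) or all(
            len(s) == cfg.chromosome_length_bp for s in g1.sequences.values()
        )
        assert len(g1.genes) >= 3

    def test_flat_gc_profile_realized_within_binomial_bound(self):
        cfg = SimConfig(seed=2, gc_amplitude=0.0, gc_base=0.40)
        g = generate_genome(cfg)
        seq = g.sequences["chr1"]
        for start in range(0, len(seq) - 5000, 5000):
            window = seq[start : start + 5000]
            # intergenic windows only: gene placement overrides base content
            gc = (window.count("G") + window.count("C")) / 5000
            assert gc == pytest.approx(0.40, abs=0.03)

    def test_minus_strand_cds_stored_ascending(self):
        g = generate_genome(SimConfig(seed=1))
        minus = [gm for gm in g.genes if gm.strand == "-"]
        assert minus
        for gm in minus:
            assert all(s < e for s, e in gm.cds)
            starts = [s for s, _ in gm.cds]
            assert starts == sorted(starts)

    def test_oversized_gene_request_errors(self):
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(
                SimConfig(seed=1, genes_per_chromosome=40, gene_spacing_bp=20_000)
            )

    def test_hotspot_gene_encoded_with_start_and_stop(self):
        g = generate_genome(SimConfig(seed=5))
        gene = g.gene("FUR1")
        s, e = gene.span
        cds = g.sequences[gene.chrom][s:e]
        if gene.strand == "-":
            from Bio.Seq import Seq

            cds = str(Seq(cds).reverse_complement())
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")


class TestCohortTruth:
    def test_all_causal_in_hotspot_when_fraction_one(self):
        cfg = SimConfig(seed=3, n_mutants_per_background=25, hotspot_fraction=1.0)
        truth = simulate_cohort(generate_genome(cfg), cfg)
        assert len(truth.mutants) == 50
        assert all(
            m.causal is not None and m.causal.gene_id == "FUR1"
            for m in truth.mutants
        )

    def test_hotspot_count_within_binomial_interval(self):
        # 276 mutants at 90%: the 99% binomial interval around 248.4
        cfg = SimConfig(seed=9)
        truth = simulate_cohort(generate_genome(cfg), cfg)
        n_hot = sum(
            1 for m in truth.mutants if m.causal and m.causal.gene_id == "FUR1"
        )
        lo, hi = sps.binom.interval(0.99, 276, 0.9)
        assert lo <= n_hot <= hi

    def test_zero_mutants_is_empty_not_error(self):
        cfg = SimConfig(seed=3, n_mutants_per_background=0)
        truth = simulate_cohort(generate_genome(cfg), cfg)
        assert truth.mutants == ()

    def test_shared_preculture_members_carry_identical_variant(self):
        cfg = SimConfig(seed=4, n_mutants_per_background=60, shared_preculture_size=39)
        truth = simulate_cohort(generate_genome(cfg), cfg)
        shared = [m for m in truth.mutants if m.preculture == "A_p00"]
        assert len(shared) == 39
        keys = {m.causal.key for m in shared}
        assert len(keys) == 1

    def test_causal_variants_never_shared_across_precultures(self):
        cfg = SimConfig(seed=6, shared_preculture_size=10)
        truth = simulate_cohort(generate_genome(cfg), cfg)
        owner = {}
        for m in truth.mutants:
            if m.causal is None:
                continue
            owner.setdefault(m.causal.key, set()).add(m.preculture)
        assert all(len(pcs) == 1 for pcs in owner.values())

    def test_causal_variants_lie_inside_their_gene(self, genome, truth):
        for m in truth.mutants:
            if m.causal is None:
                continue
            gene = genome.gene(m.causal.gene_id)
            s, e = gene.span
            assert gene.chrom == m.causal.chrom
            assert s - gene.promoter_window_bp <= m.causal.pos0 < e

    def test_parental_variants_identical_within_background(self, truth):
        assert set(truth.parental_variants) == {"A", "B"}
        assert len(truth.parental_variants["A"]) == truth.config.parental_variant_count


class TestCallerEmission:
    def test_noiseless_channel_reproduces_truth(self, truth):
        profile = CallerProfile(
            name="perfect",
            sensitivity=1.0,
            fp_rate=0.0,
            true_fail_fraction=0.0,
            contamination_rate=0.0,
            low_dp_rate=0.0,
        )
        table = emit_caller_calls(truth, profile, "A")
        expected = set()
        for m in truth.by_background("A"):
            if m.causal:
                expected.add(m.causal.key)
            expected.update(v.key for v in m.background_variants)
        expected.update(v.key for v in truth.parental_variants["A"])
        assert {r.key for r in table.records} == expected
        # every carrier genotype is present (round-trip invariant)
        for rec in table.records:
            assert any(c.gt == 1 for c in rec.calls.values())

    def test_zero_sensitivity_leaves_only_false_positives(self, truth):
        profile = CallerProfile(name="blind", sensitivity=0.0, fp_rate=3.0)
        table = emit_caller_calls(truth, profile, "A")
        truth_keys = {
            v.key
            for m in truth.by_background("A")
            for v in ([m.causal] if m.causal else []) + list(m.background_variants)
        } | {v.key for v in truth.parental_variants["A"]}
        assert table.records  # Poisson(3) per genome: emission is non-empty
        assert not truth_keys & {r.key for r in table.records}

    def test_emission_deterministic(self, truth):
        profile = simdata.DEFAULT_CALLER_PROFILES["stringent"]
        t1 = emit_caller_calls(truth, profile, "B")
        t2 = emit_caller_calls(truth, profile, "B")
        assert [r.key for r in t1.records] == [r.key for r in t2.records]
        assert [r.qual for r in t1.records] == [r.qual for r in t2.records]
        for r1, r2 in zip(t1.records, t2.records):
            assert r1.annotations == r2.annotations
            assert all(
                r1.calls[s].ad == r2.calls[s].ad and r1.calls[s].dp == r2.calls[s].dp
                for s in t1.samples
            )

    def test_tolerant_caller_detects_more_genes_than_stringent(self):
        """Monte-Carlo: the permissive profile yields more mutated genes."""
        from evohotspot import variants as vmod

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_mutants_per_background=15, n_precultures=5)
            genome = generate_genome(cfg)
            truth = simulate_cohort(genome, cfg)
            counts = {}
            for name in ("tolerant", "stringent"):
                profile = simdata.DEFAULT_CALLER_PROFILES[name]
                table = emit_caller_calls(truth, profile, "A")
                ann = vmod.annotate_effects(table, genome.genes, genome.sequences)
                genes = {
                    r.effect.gene_id
                    for r in ann
                    if r.effect and r.effect.gene_id is not None
                }
                counts[name] = len(genes)
            wins += counts["tolerant"] >= counts["stringent"]
        assert wins >= 15  # clear majority across seeds


class TestCoverage:
    def test_unbiased_grand_mean_within_one_percent(self):
        cfg = SimConfig(seed=10)
        # plain windows over a uniform profile; >= 1,000 windows
        genome_seqs = {"c1": "ACGT" * 1_500_000}

        class G:
            sequences = genome_seqs

        track = simulate_coverage_track(G(), cfg, BiasConfig(base_depth=100))
        assert len(track) >= 1000
        assert track["raw_mean_count"].mean() == pytest.approx(100.0, rel=0.01)

    def test_planted_cnv_windows_scaled(self, genome):
        plant = ("chr1", 50_000, 65_000, 5.0)
        cfg = SimConfig(seed=7, cnv_plants=(plant,))
        track = simulate_coverage_track(genome, cfg, BiasConfig(base_depth=100))
        inside = track[
            (track["chrom"] == "chr1")
            & (track["start"] >= 50_000)
            & (track["end"] <= 65_000)
        ]
        outside = track[(track["chrom"] == "chr1") & (track["start"] >= 100_000)]
        assert len(inside) == 3
        assert inside["raw_mean_count"].mean() == pytest.approx(
            5 * outside["raw_mean_count"].mean(), rel=0.05
        )

    def test_end_ramp_doubles_terminal_windows(self):
        cfg = SimConfig(seed=12)
        genome = simdata.generate_genome(cfg)
        bias = BiasConfig(base_depth=100, end_ramp_factor=2.0)
        # average window means over replicate draws
        terminal, middle = [], []
        for rep in range(50):
            track = simulate_coverage_track(genome, cfg, bias, seed_extra=rep)
            sub = track[track["chrom"] == "chr1"]
            terminal.append(sub["raw_mean_count"].iloc[0])
            middle.append(sub["raw_mean_count"].iloc[len(sub) // 2])
        expected = bias.end_multiplier(2500.0) / bias.end_multiplier(100_000.0)
        ratio = np.mean(terminal) / np.mean(middle)
        assert ratio == pytest.approx(expected, rel=0.05)
        assert ratio > 1.7  # terminal windows roughly doubled


class TestGrowthAndDose:
    def test_replicate_count_contract(self, truth):
        df = simulate_growth(truth, strains=[truth.mutants[0].mutant_id])
        reps = df.groupby(["strain", "medium"])["replicate"].nunique()
        assert (reps == 4).all()

    def test_noise_free_identical_params_give_unit_fitness(self, truth):
        from evohotspot.fitness import GrowthCurve, auc, relative_fitness

        panel = {
            (cls, med): simdata.GrowthParams(k=1.0, r=0.3)
            for cls in ("wt", "resistant", "sensitive")
            for med in ("minimal", "minimal+drug")
        }
        df = simulate_growth(
            truth, media_panel=panel, noise_sd=0.0,
            strains=[truth.mutants[0].mutant_id],
        )
        aucs = {}
        for (strain, medium, rep), grp in df.groupby(["strain", "medium", "replicate"]):
            grp = grp.sort_values("time_h")
            c = GrowthCurve(strain, medium, rep, grp["time_h"].to_numpy(), grp["value"].to_numpy())
            aucs.setdefault((strain, medium), []).append(auc(c, 22))
        strain = truth.mutants[0].mutant_id
        rec = relative_fitness(aucs[(strain, "minimal")], aucs[("WT_A", "minimal")])
        assert rec.relative_fitness == pytest.approx(1.0)

    def test_resistant_class_outgrows_wt_in_drug(self, truth):
        from evohotspot.fitness import GrowthCurve, auc, relative_fitness

        resistant = next(m for m in truth.mutants if m.causal is not None)
        df = simulate_growth(truth, noise_sd=0.0, strains=[resistant.mutant_id])
        aucs = {}
        for (strain, medium, rep), grp in df.groupby(["strain", "medium", "replicate"]):
            grp = grp.sort_values("time_h")
            c = GrowthCurve(strain, medium, rep, grp["time_h"].to_numpy(), grp["value"].to_numpy())
            aucs.setdefault((strain, medium), []).append(auc(c, 22))
        in_drug = relative_fitness(
            aucs[(resistant.mutant_id, "minimal+drug")], aucs[("WT_A", "minimal+drug")]
        ).relative_fitness
        no_drug = relative_fitness(
            aucs[(resistant.mutant_id, "minimal")], aucs[("WT_A", "minimal")]
        ).relative_fitness
        assert in_drug > 1.0
        assert no_drug <= 1.0

    def test_dose_response_anchors(self):
        concs = [0.0, 0.1, 0.2, 0.4, 0.8]
        obs = simulate_dose_response(0.4, 2.0, concs, noise_sd=0.0, seed=1)
        prof = obs.groupby("concentration")["response"].mean()
        assert prof.loc[0.0] == 1.0
        assert prof.loc[0.4] == pytest.approx(0.5)

    def test_dose_response_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            simulate_dose_response(0.4, 2.0, [-1.0, 0.0, 1.0], seed=1)

    def test_growth_validates_parameters(self):
        with pytest.raises(ValueError):
            simdata.GrowthParams(k=-1.0, r=0.3)


class TestFlow:
    def test_event_count(self):
        ev = simulate_flow_sample([(1.0, simdata.FlowPopulation())], n_events=2000, seed=1)
        assert len(ev) == 2000

    def test_low_fsc_fraction_removed_by_gate(self):
        import math

        from evohotspot.fitness import gate_flow_events

        main = simdata.FlowPopulation()
        debris = simdata.FlowPopulation(fsc_log_mean=math.log(500.0), fsc_log_sd=0.3)
        ev = simulate_flow_sample([(0.95, main), (0.05, debris)], n_events=4000, seed=2)
        kept = gate_flow_events(ev)
        removed = 1 - len(kept) / len(ev)
        assert removed == pytest.approx(0.05, abs=0.02)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_flow_sample([(0.6, simdata.FlowPopulation())], seed=1)
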