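import math

import numpy as np
import pytest

from notocrm import caller
from notocrm.motif import CORE_PATTERN
from notocrm.nullstats import UNIFORM, BackgroundModel, expected_count
from notocrm.scan import scan, scan_and_annotate, spacing
from notocrm.simulate import (
    CLASS_SPECS,
    DEFAULT_STAGES,
    PlantSpec,
    expected_onset_stage,
    gen_background,
    gen_embryo_counts,
    gen_genome,
    gen_qpcr,
    plant_crm,
)


class TestGenBackground:
    def test_deterministic(self):
        assert gen_background(500, 0.5, 13) == gen_background(500, 0.5, 13)

    def test_seed_changes_sequence(self):
        assert gen_background(500, 0.5, 13) != gen_background(500, 0.5, 14)

    def test_invalid_gc(self):
        for gc in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                gen_background(100, gc, 0)

    def test_gc_content_close(self):
        s = gen_background(20000, 0.62, 5)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.62, abs=0.02)

    def test_extreme_gc_kills_core_hits(self):
        s = gen_background(2000, 0.999, 0)
        assert len(scan(s, "x")) <= 1

    def test_mean_count_matches_null(self):
        n = 300
        counts = [
            len(scan(gen_background(1200, 0.5, s), "x", strands="forward"))
            for s in range(n)
        ]
        lam = expected_count(1200, CORE_PATTERN, UNIFORM, 1)
        se = np.std(counts, ddof=1) / math.sqrt(n)
        assert abs(np.mean(counts) - lam) < 3 * se


class TestPlantCrm:
    def test_two_site_geometry_recovered(self, catalog):
        bg = gen_background(600, 0.35, 7)
        seq, truth = plant_crm(bg, CLASS_SPECS["early"], 100, 7, catalog)
        conf = [
            m
            for m in scan_and_annotate(seq, "x", catalog)
            if caller.is_confident(m, catalog)
            and (m.start, m.strand) in {(s.core_start, s.strand) for s in truth.sites}
        ]
        assert len(conf) == 2
        rep = spacing(sorted(conf, key=lambda m: m.start))
        assert rep.pairs[0][2] == 35

    def test_single_site(self, catalog):
        bg = gen_background(300, 0.35, 8)
        seq, truth = plant_crm(bg, CLASS_SPECS["middle"], 50, 8, catalog)
        assert len(truth.sites) == 1
        hits = scan(seq, "x")
        assert any(m.start == truth.sites[0].core_start for m in hits)

    def test_empty_spec_is_identity(self, catalog):
        bg = gen_background(300, 0.5, 9)
        seq, truth = plant_crm(
            bg, CLASS_SPECS["late_or_indirect"], 50, 9, catalog
        )
        assert seq == bg
        assert truth.sites == ()

    def test_minus_strand_plant(self, catalog):
        spec = PlantSpec(
            cores=(("TGGCAC", "-", "exact_consensus"),), intended_class="middle"
        )
        bg = gen_background(200, 0.35, 10)
        seq, truth = plant_crm(bg, spec, 60, 10, catalog)
        s = truth.sites[0]
        hits = [
            m for m in scan(seq, "x") if m.start == s.core_start and m.strand == "-"
        ]
        assert hits and hits[0].core == "TGGCAC"

    def test_overflow_rejected(self, catalog):
        with pytest.raises(IndexError):
            plant_crm("ACGT" * 5, CLASS_SPECS["early"], 10, 0, catalog)

    def test_spacing_count_validated(self):
        with pytest.raises(ValueError):
            PlantSpec(
                cores=(("TAACAC", "+", "random"), ("TCACAC", "+", "random")),
                spacings=(),
                intended_class="early",
            )

    def test_class_consistency_validated(self):
        with pytest.raises(ValueError):
            PlantSpec(cores=(("TAACAC", "+", "random"),), intended_class="early")


class TestGenGenome:
    def test_scrubbed_recovery_is_exact(self, catalog):
        genome, truths = gen_genome(12, (1 / 3, 1 / 3, 1 / 3), 600, 0.4, 5)
        assert len(genome) == 12
        for t in truths:
            seq = genome[t.locus_id]
            matches = scan_and_annotate(seq, t.locus_id, catalog)
            cands = caller.call_candidates(matches, catalog)
            if not cands:
                cands = [
                    caller.candidate_from_interval(
                        t.locus_id, 0, len(seq), matches, catalog
                    )
                ]
            assert len(cands) == 1
            assert caller.predict_onset(cands[0]).onset_class == t.intended_class

    def test_all_late_mix_has_no_sites(self):
        genome, truths = gen_genome(5, (0.0, 0.0, 1.0), 400, 0.4, 2)
        assert all(t.sites == () for t in truths)

    def test_unscrubbed_still_plants_truth(self, catalog):
        genome, truths = gen_genome(6, (0.5, 0.5, 0.0), 600, 0.4, 3, scrub=False)
        for t in truths:
            hits = {(m.start, m.strand) for m in scan(genome[t.locus_id], "x")}
            for s in t.sites:
                assert (s.core_start, s.strand) in hits

    def test_deterministic(self):
        g1, t1 = gen_genome(4, (0.5, 0.25, 0.25), 500, 0.4, 11)
        g2, t2 = gen_genome(4, (0.5, 0.25, 0.25), 500, 0.4, 11)
        assert g1 == g2
        assert t1 == t2

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            gen_genome(4, (0.5, 0.5, 0.5), 500, 0.4, 0)

    def test_class_counts_largest_remainder(self):
        _, truths = gen_genome(30, (1 / 3, 1 / 3, 1 / 3), 400, 0.4, 1, scrub=False)
        from collections import Counter

        counts = Counter(t.intended_class for t in truths)
        assert counts == {"early": 10, "middle": 10, "late_or_indirect": 10}


class TestGenEmbryoCounts:
    def test_onset_recovery_rate(self):
        from notocrm.assays import onset_from_timecourse

        ok = 0
        runs = 60
        for seed in range(runs):
            cls = ("early", "middle", "late_or_indirect")[seed % 3]
            t = gen_embryo_counts(cls, n_per_stage=100, seed=seed)
            want = expected_onset_stage(cls)
            ok += onset_from_timecourse(t, 0.10) == want
        assert ok / runs >= 0.95

    def test_expected_onset_stages_ordered(self):
        stages = list(DEFAULT_STAGES)
        idx = {
            cls: stages.index(expected_onset_stage(cls))
            for cls in ("early", "middle", "late_or_indirect")
        }
        assert idx["early"] < idx["middle"] < idx["late_or_indirect"]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            gen_embryo_counts("early", n_per_stage=0)

    def test_deterministic(self):
        a = gen_embryo_counts("middle", seed=4).data
        b = gen_embryo_counts("middle", seed=4).data
        assert a.equals(b)

    def test_counts_total_per_stage(self):
        t = gen_embryo_counts("early", n_per_stage=80, seed=1)
        totals = t.data.groupby("stage")["count"].sum()
        assert (totals == 80).all()


class TestGenQpcr:
    def test_zero_noise_exact(self):
        from notocrm.assays import chip_enrichment, standard_curve

        run = gen_qpcr(enrichment_fold=8.0, efficiency=1.0, sigma_ct=0.0, seed=0)
        assert standard_curve(run.standards, run.start_mass).efficiency == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert chip_enrichment(run).fold_change == pytest.approx(8.0, rel=1e-9)

    def test_deterministic(self):
        a, b = gen_qpcr(seed=3), gen_qpcr(seed=3)
        assert a.standards == b.standards
        assert a.samples.equals(b.samples)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            gen_qpcr(enrichment_fold=0.0)
        with pytest.raises(ValueError):
            gen_qpcr(efficiency=1.5)

    def test_standard_layout(self):
        run = gen_qpcr(seed=0)
        dils = [d for d, _ in run.standards]
        assert dils == [5.0, 5.0, 50.0, 50.0, 500.0, 500.0, 5000.0, 5000.0]
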