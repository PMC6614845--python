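"""Generator determinism, planted structure, and end-to-end recoverability."""

import numpy as np
import pandas as pd
import pytest

from h1splice import annotation, metaprofile, pipeline
from h1splice import synthetic_data as sd
from h1splice.psi import estimate_psi
from h1splice.signal_tracks import validate_methylation_table


class TestDeterminism:
    def test_identical_output_under_fixed_seed(self):
        cfg = sd.SimConfig(n_genes=8)
        g1, m1, t1 = sd.simulate_genome_and_annotation(cfg, seed=3)
        g2, m2, t2 = sd.simulate_genome_and_annotation(cfg, seed=3)
        assert g1 == g2
        assert m1 == m2
        pd.testing.assert_frame_equal(t1, t2)

    def test_full_study_reads_deterministic(self):
        cfg = sd.SimConfig(n_genes=6)
        s1 = sd.simulate_study(cfg, seed=5)
        s2 = sd.simulate_study(cfg, seed=5)
        for name in s1.chip_reads:
            pd.testing.assert_frame_equal(s1.chip_reads[name], s2.chip_reads[name])
        pd.testing.assert_frame_equal(s1.rna_reads["wt"], s2.rna_reads["wt"])
        pd.testing.assert_frame_equal(s1.methylation, s2.methylation)

    def test_different_seeds_differ(self):
        cfg = sd.SimConfig(n_genes=4)
        g1, _, _ = sd.simulate_genome_and_annotation(cfg, seed=1)
        g2, _, _ = sd.simulate_genome_and_annotation(cfg, seed=2)
        assert g1 != g2


class TestGenomeAndAnnotation:
    def test_every_intron_starts_gt_and_ends_ag(self, small_study):
        seq = small_study.genome["chr1"]
        for m in small_study.models:
            for s, e in m.introns:
                intron = seq[s:e]
                if m.strand == "-":
                    from h1splice.splice_strength import reverse_complement

                    intron = reverse_complement(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_exon_gc_exceeds_intron_gc_in_long_intron_genes(self):
        cfg = sd.SimConfig(n_genes=40, frac_short_intron_genes=0.0)
        genome, models, truth = sd.simulate_genome_and_annotation(cfg, seed=9)
        seq = genome[cfg.chrom]

        def gc(s, e):
            w = seq[s:e]
            return (w.count("G") + w.count("C")) / len(w)

        wins = 0
        for m in models:
            exon_gc = np.mean([gc(s, e) for s, e in m.exons])
            intron_gc = np.mean([gc(s, e) for s, e in m.introns])
            wins += exon_gc > intron_gc
        assert wins >= 0.95 * len(models)

    def test_genes_have_at_least_four_exons(self, small_study):
        assert all(len(m.exons) >= 4 for m in small_study.models)

    def test_marked_exons_are_short_with_documented_quartile(self):
        cfg = sd.SimConfig(n_genes=300)
        _, _, truth = sd.simulate_genome_and_annotation(cfg, seed=1)
        marked = truth[truth["klass"].str.startswith("marked")]["length"]
        assert 100 <= marked.median() <= 120
        assert np.percentile(marked, 75) <= 135
        assert marked.max() <= cfg.wrap_bp
        unmarked = truth[truth["klass"] == "unmarked"]["length"]
        assert unmarked.median() > marked.median()

    def test_truth_geometry_invariants(self, small_study):
        cfg = small_study.config
        for rec in small_study.truth.itertuples():
            if rec.klass in ("marked_3ss", "marked_5ss"):
                assert rec.h1_sites and rec.nuc_dyad >= 0
                assert rec.psi_kd <= rec.psi_wt
                site = int(rec.h1_sites)
                offset = cfg.wrap_bp + cfg.linker_offset
                if rec.klass == "marked_5ss":
                    expected = (
                        rec.pos_5ss + (offset - cfg.upstream_edge_offset - rec.length) + 1
                        if rec.strand == "+"
                        else rec.pos_5ss - (offset - cfg.upstream_edge_offset - rec.length) - 1
                    )
                    # site sits offset - edge bp past the exon start, i.e.
                    # offset - edge - length past the 5'ss
                    assert abs(site - expected) <= 1
            elif rec.klass == "distant":
                sites = [int(v) for v in rec.h1_sites.split(";")]
                assert len(sites) == 2
                for site in sites:
                    d = min(abs(site - rec.start), abs(site - rec.end))
                    assert cfg.distant_lo - 1 <= d <= cfg.distant_hi + 1
            else:
                assert rec.h1_sites == ""
                assert rec.psi_kd == rec.psi_wt

    def test_internal_exon_table_matches_truth(self, small_study):
        assert {e.exon_id for e in small_study.exons} == set(
            small_study.truth["exon_id"]
        )


class TestChipLibraries:
    def test_null_enrichment_is_indistinguishable_from_input(self):
        cfg = sd.SimConfig(n_genes=30, chip_enrichment=1.0)
        ss = np.random.SeedSequence(2).generate_state(2) % (2**31)
        genome, models, truth = sd.simulate_genome_and_annotation(cfg, int(ss[0]))
        sizes = {c: len(s) for c, s in genome.items()}
        regions = annotation.derive_region_sets(models, annotation.build_internal_exon_table(models))
        space = annotation.gene_region_set(models)
        rng = np.random.default_rng(int(ss[1]))
        pvals = []
        for _ in range(40):
            chip = sd.simulate_chip_libraries(truth, cfg, sizes, seed=rng)
            track = pipeline.chip_occupancy_track(
                chip["h1"], chip["input"], sizes, cfg.chip_read_len, cfg.chip_frag_len
            )
            res = metaprofile.randomization_test(
                track, regions["junction"], space, 500, 50, 100, seed=rng
            )
            pvals.append(res.p_enriched)
        # p roughly uniform: no mass collapse at either end
        assert 0.2 <= np.mean(pvals) <= 0.8
        assert min(pvals) < 0.5 < max(pvals)

    def test_planted_enrichment_detected_on_junctions(self, recovery_study):
        models = recovery_study["models"]
        regions = annotation.derive_region_sets(models, recovery_study["exons"])
        space = annotation.gene_region_set(models)
        res = metaprofile.randomization_test(
            recovery_study["track"], regions["junction"], space,
            10_000, 50, 200, seed=1,
        )
        assert res.p_enriched <= 0.05

    def test_shifted_reads_center_on_planted_sites(self, small_study):
        from h1splice.signal_tracks import fragment_midpoint_shift, shift_reads

        cfg = small_study.config
        sites = []
        for s in small_study.truth["h1_sites"]:
            if s:
                sites.extend(int(v) for v in s.split(";"))
        sites = np.array(sorted(sites))
        shift = fragment_midpoint_shift(cfg.chip_read_len, cfg.chip_frag_len)
        shifted = shift_reads(
            small_study.chip_reads["h1"], shift, small_study.genome_sizes
        )
        mids = ((shifted["start"] + shifted["end"]) // 2).to_numpy()
        # per site, mean midpoint of reads within +-40 bp is within +-5 bp
        deviations = []
        for site in sites:
            near = mids[(mids > site - 40) & (mids < site + 40)]
            if len(near) >= 30:
                deviations.append(near.mean() - site)
        assert len(deviations) > 0.8 * len(sites)
        assert abs(np.mean(deviations)) <= 5.0


class TestRnaLibraries:
    def test_constitutive_exons_have_no_skipping_reads(self, small_study):
        truth = small_study.truth
        cw = pipeline.estimate_condition_psi(
            small_study.rna_reads["wt"], truth, "wt"
        )
        for rec in truth.itertuples():
            if rec.psi_wt == 1.0:
                assert cw[rec.exon_id].exclusion_reads == 0

    def test_deep_coverage_concentrates_on_planted_psi(self):
        # one-exon check at ~10k informative reads: binomial concentration
        cfg = sd.SimConfig(n_genes=3, rna_depth=7000, frac_constitutive=0.0,
                           p_marked_3ss=0, p_marked_5ss=0, p_distant=0,
                           frac_short_intron_genes=0.0)
        genome, models, truth = sd.simulate_genome_and_annotation(cfg, seed=21)
        truth.loc[:, "psi_wt"] = np.where(truth["psi_wt"] < 1.0, 0.5, truth["psi_wt"])
        reads = sd.simulate_rna_libraries(truth, cfg, "wt", models, seed=4)
        counts = pipeline.estimate_condition_psi(reads, truth, "wt")
        checked = 0
        for rec in truth.itertuples():
            if rec.psi_wt == 0.5:
                est = estimate_psi(counts[rec.exon_id])
                assert est.informative >= 7000
                assert est.psi == pytest.approx(0.5, abs=0.02)
                checked += 1
        assert checked >= 2

    def test_knockdown_lowers_only_marked_exons(self, small_study):
        truth = small_study.truth
        marked = truth["klass"].str.startswith("marked")
        assert (truth.loc[marked, "psi_kd"]
                <= truth.loc[marked, "psi_wt"] - 0.2).all()
        assert (truth.loc[~marked, "psi_kd"] == truth.loc[~marked, "psi_wt"]).all()


class TestMethylation:
    def test_counts_are_internally_consistent(self, small_study):
        validate_methylation_table(small_study.methylation)

    def test_elevation_around_marked_exons_recovered(self, small_study):
        from h1splice.metaprofile import AnchorSpec, aggregate, extract_matrix
        from h1splice.signal_tracks import methylation_track

        track = methylation_track(small_study.methylation, small_study.genome_sizes)
        truth = small_study.truth
        spec = AnchorSpec("exon_start", 150, 150)
        by_class = {}
        for klass, want in (("marked_3ss", True), ("unmarked", False)):
            ids = set(truth.loc[truth["klass"] == klass, "exon_id"])
            exons = [e for e in small_study.exons if e.exon_id in ids]
            mat = extract_matrix(track, exons, spec)
            prof = aggregate(mat)
            by_class[klass] = np.nanmean(prof.mean)
        assert by_class["marked_3ss"] - by_class["unmarked"] >= 0.2

    def test_background_only_profile_is_flat(self):
        cfg = sd.SimConfig(n_genes=10, meth_elevated=0.4)  # no contrast planted
        genome, models, truth = sd.simulate_genome_and_annotation(cfg, seed=6)
        meth = sd.simulate_methylation(truth, cfg, genome, seed=7)
        prop = meth["methylated_reads"] / meth["total_reads"]
        assert prop.mean() == pytest.approx(0.4, abs=0.02)


class TestWriters:
    def test_written_study_reparses_end_to_end(self, tmp_path):
        cfg = sd.SimConfig(n_genes=6)
        study = sd.simulate_study(cfg, seed=13)
        sd.write_study(study, tmp_path)
        models = annotation.parse_gene_models(tmp_path / "annotation.gtf")
        assert models == study.models
        exons = annotation.read_exon_table(tmp_path / "internal_exons.tsv")
        assert exons == study.exons
        from h1splice.signal_tracks import read_alignments, read_methylation_table

        reads = read_alignments(tmp_path / "reads_h1.tsv")
        pd.testing.assert_frame_equal(reads, study.chip_reads["h1"])
        meth = read_methylation_table(tmp_path / "methylation.tsv")
        assert len(meth) == len(study.methylation)
        from pyfaidx import Fasta

        with Fasta(str(tmp_path / "genome.fa")) as fa:
            assert str(fa["chr1"][:]) == study.genome["chr1"]
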