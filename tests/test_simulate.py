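"""Paired-callset simulator: truth invariants, determinism, depth coupling."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from rnatmb import (
    CohortSimConfig,
    ContractError,
    default_exome_regions,
    depth_sweep,
    read_callset,
    read_regions,
    simulate_cohort,
)


def file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class TestSimulateCohort:
    def test_zero_samples_valid_empty_outputs(self, tmp_path):
        cohort = simulate_cohort(CohortSimConfig(n_samples=0, seed=1), tmp_path)
        assert cohort.sample_ids == []
        assert cohort.truth.empty
        assert read_regions(cohort.bed_path).total_megabases > 0

    def test_byte_identical_for_same_seed(self, tmp_path):
        c1 = simulate_cohort(CohortSimConfig(n_samples=3, seed=5), tmp_path / "a")
        c2 = simulate_cohort(CohortSimConfig(n_samples=3, seed=5), tmp_path / "b")
        for sid in c1.sample_ids:
            assert file_hash(c1.rnaseq_paths[sid]) == file_hash(c2.rnaseq_paths[sid])
            assert file_hash(c1.wes_paths[sid]) == file_hash(c2.wes_paths[sid])
        assert file_hash(c1.bed_path) == file_hash(c2.bed_path)

    def test_different_seeds_differ(self, tmp_path):
        c1 = simulate_cohort(CohortSimConfig(n_samples=2, seed=5), tmp_path / "a")
        c2 = simulate_cohort(CohortSimConfig(n_samples=2, seed=6), tmp_path / "b")
        assert file_hash(c1.rnaseq_paths["S001"]) != file_hash(c2.rnaseq_paths["S001"])

    def test_truth_tmb_is_somatic_count_over_mb(self, small_cohort):
        mb = small_cohort.regions.total_megabases
        somatic = small_cohort.truth.query("var_class == 'somatic'")
        for sid in small_cohort.sample_ids:
            count = int((somatic["sample_id"] == sid).sum())
            assert small_cohort.true_tmb[sid] == pytest.approx(count / mb)

    def test_ffpe_ct_enrichment_matches_config(self, tmp_path):
        config = CohortSimConfig(n_samples=10, seed=21, ffpe_artifact_per_mb=60.0)
        cohort = simulate_cohort(config, tmp_path)
        artifacts = cohort.truth.query("var_class == 'ffpe_artifact'")
        is_ct = (
            ((artifacts["ref"] == "C") & (artifacts["alt"] == "T"))
            | ((artifacts["ref"] == "G") & (artifacts["alt"] == "A"))
        )
        n, p = len(artifacts), config.ffpe_ct_fraction
        observed = is_ct.mean()
        # random substitutions also land on C>T ~1/12 of the time
        expected = p + (1 - p) / 12
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < tol

    def test_vcfs_reingest_to_emitted_truth(self, small_cohort):
        truth = small_cohort.truth
        for sid in small_cohort.sample_ids[:2]:
            rna = read_callset(small_cohort.rnaseq_paths[sid], "rnaseq_tumor_only")
            expected = truth.query("sample_id == @sid and emitted_rnaseq")
            assert rna.keys() == {
                (r.chrom, r.pos, r.ref, r.alt) for r in expected.itertuples()
            }
            wes = read_callset(small_cohort.wes_paths[sid], "wes_matched")
            expected_wes = truth.query("sample_id == @sid and emitted_wes")
            assert len(wes) == len(expected_wes)

    def test_degenerate_config_rnaseq_equals_wes_somatic_truth(self, tmp_path):
        # no artifacts/noise/germline, detection probability exactly 1:
        # the RNA-seq callset is the somatic truth, so isec TMB agrees exactly
        config = CohortSimConfig(
            n_samples=4,
            seed=13,
            germline_per_mb=0.0,
            ffpe_artifact_per_mb=0.0,
            rna_noise_per_mb=0.0,
            detection_max=1.0,
            detection_half_saturation=0.0,
        )
        cohort = simulate_cohort(config, tmp_path)
        assert config.detection_probability(config.mean_gene_mapped_reads) == 1.0
        for sid in cohort.sample_ids:
            rna = read_callset(cohort.rnaseq_paths[sid], "rnaseq_tumor_only")
            wes = read_callset(cohort.wes_paths[sid], "wes_matched")
            assert rna.keys() == wes.keys()
            mb = cohort.regions.total_megabases
            assert len(rna) / mb == pytest.approx(cohort.true_tmb[sid])

    def test_matched_mode_germline_flagged_non_pass(self, small_cohort):
        wes = read_callset(small_cohort.wes_paths["S001"], "wes_matched")
        truth = small_cohort.truth.query(
            "sample_id == 'S001' and emitted_wes and var_class == 'germline'"
        )
        germline_keys = {(r.chrom, r.pos, r.ref, r.alt) for r in truth.itertuples()}
        for v in wes:
            if v.key in germline_keys:
                assert not v.is_pass
            else:
                assert v.is_pass

    def test_tumor_only_mode_germline_pass_with_annotations(self, tmp_path):
        config = CohortSimConfig(n_samples=2, seed=17, wes_mode="tumor_only")
        cohort = simulate_cohort(config, tmp_path)
        wes = read_callset(cohort.wes_paths["S001"], "wes_tumor_only")
        truth = cohort.truth.query(
            "sample_id == 'S001' and emitted_wes and var_class == 'germline'"
        )
        germline_keys = {(r.chrom, r.pos, r.ref, r.alt) for r in truth.itertuples()}
        flagged = [v for v in wes if v.key in germline_keys]
        assert flagged and all(v.is_pass for v in flagged)
        assert np.mean([v.in_dbsnp for v in flagged]) > 0.8

    def test_invalid_configs_rejected(self):
        with pytest.raises(ContractError):
            CohortSimConfig(germline_per_mb=-1)
        with pytest.raises(ContractError):
            CohortSimConfig(ffpe_ct_fraction=1.5)
        with pytest.raises(ContractError):
            CohortSimConfig(n_samples=-1)
        with pytest.raises(ContractError):
            CohortSimConfig(wes_mode="paired")


class TestDepthSweep:
    def test_detection_curve_monotone(self):
        config = CohortSimConfig()
        probs = [config.detection_probability(d) for d in (5e6, 11e6, 23e6, 68e6)]
        assert probs == sorted(probs)
        assert all(0 <= p <= 1 for p in probs)

    def test_shared_truth_and_monotone_detection(self, tmp_path):
        config = CohortSimConfig(n_samples=3, seed=9)
        sweep = depth_sweep(config, [11e6, 23e6, 68e6], tmp_path)
        truths = {lvl: c.truth for lvl, c in sweep.items()}
        base = truths[11e6][["sample_id", "chrom", "pos", "ref", "alt", "var_class"]]
        for lvl in (23e6, 68e6):
            other = truths[lvl][base.columns]
            assert base.equals(other)  # identical truth across levels
        detected = {
            lvl: set(
                map(
                    tuple,
                    t.query("emitted_rnaseq and var_class in ('somatic','germline')")[
                        ["sample_id", "chrom", "pos"]
                    ].values,
                )
            )
            for lvl, t in truths.items()
        }
        assert detected[11e6] <= detected[23e6] <= detected[68e6]

    def test_per_sample_counts_non_decreasing(self, tmp_path):
        config = CohortSimConfig(n_samples=1, seed=19)
        sweep = depth_sweep(config, [11e6, 68e6], tmp_path)
        counts = [
            len(read_callset(sweep[lvl].rnaseq_paths["S001"], "rnaseq_tumor_only"))
            for lvl in (11e6, 68e6)
        ]
        assert counts[0] <= counts[1]

    def test_bad_levels_rejected(self, tmp_path):
        config = CohortSimConfig(n_samples=1)
        with pytest.raises(ContractError):
            depth_sweep(config, [23e6], tmp_path)
        with pytest.raises(ContractError):
            depth_sweep(config, [23e6, -1], tmp_path)


def test_default_regions_cover_three_megabases():
    regions = default_exome_regions()
    assert regions.total_megabases == pytest.approx(3.0, rel=1e-3)
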