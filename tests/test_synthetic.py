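"""Synthetic-study generator: determinism, validity of emitted formats,
and the planted/decoy design contracts."""

from __future__ import annotations

from pathlib import Path

import pytest

from famprior import io
from famprior.filters import FilterConfig, apply_depth_mask, fill_local_freq, frequency_pass
from famprior.regulatory5p import read_chromatin_profiles
from famprior.scores import conservation_composite
from famprior.segregation import classify_family, segregates_in_family
from famprior.synthetic import SynthConfig, SyntheticStudy, generate_study


def _read_all_bytes(root: Path) -> dict:
    return {p.name: p.read_bytes() for p in sorted(root.iterdir()) if p.is_file()}


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SynthConfig(seed=11, n_families=4)
        generate_study(cfg, tmp_path / "a")
        generate_study(cfg, tmp_path / "b")
        a, b = _read_all_bytes(tmp_path / "a"), _read_all_bytes(tmp_path / "b")
        assert a.keys() == b.keys()
        for name in a:
            assert a[name] == b[name], name

    def test_different_seed_differs(self, tmp_path):
        generate_study(SynthConfig(seed=1, n_families=4), tmp_path / "a")
        generate_study(SynthConfig(seed=2, n_families=4), tmp_path / "b")
        assert (tmp_path / "a" / "cohort.vcf").read_bytes() != (
            tmp_path / "b" / "cohort.vcf"
        ).read_bytes()


class TestCohortDesign:
    def test_family_structure(self, small_study):
        cfg, manifest, _ = small_study
        families = io.read_pedigree(manifest["files"]["ped"], manifest["files"]["phenotypes"])
        assert len(families) == cfg.n_families
        for fam in families:
            cases = [m for m in fam.members if m.individual_id.split("_")[1].startswith("C")]
            assert len(cases) >= 2

    def test_young_unaffected_exercises_age_rule(self, small_study):
        from famprior.segregation import CarrierStatus

        _, manifest, _ = small_study
        families = io.read_pedigree(manifest["files"]["ped"], manifest["files"]["phenotypes"])
        for fam in families:
            statuses = classify_family(fam)
            young = [m for m in fam.members if "_Y" in m.individual_id]
            assert young and all(
                statuses[m.individual_id] is CarrierStatus.POSSIBLE_CARRIER for m in young
            )

    def test_variant_count_matches_spec(self, small_study):
        cfg, manifest, _ = small_study
        expected = cfg.n_planted_5p + cfg.n_planted_3p + sum(cfg.decoy_spec.values())
        assert len(manifest["truth"]) == expected


class TestPlantedVariantsPassEarlyStages:
    def test_planted_survive_frequency_depth_and_segregation(self, small_study):
        _, manifest, _ = small_study
        families = io.read_pedigree(manifest["files"]["ped"], manifest["files"]["phenotypes"])
        samples = [m.individual_id for f in families for m in f.members]
        variants = fill_local_freq(io.read_vcf(manifest["files"]["vcf"], samples))
        statuses = {f.family_id: classify_family(f) for f in families}
        by_key = {v.key: v for v in variants}
        for key, fate in manifest["truth"].items():
            if not fate.startswith("planted"):
                continue
            v = apply_depth_mask(by_key[key], FilterConfig())
            assert frequency_pass(v, FilterConfig())
            assert any(
                segregates_in_family(v, f, statuses[f.family_id]) for f in families
            )

    def test_conservation_decoy_has_zero_composite(self, small_study):
        _, manifest, _ = small_study
        (key,) = [k for k, f in manifest["truth"].items() if f == "decoy:conservation"]
        scores = io.read_score_table(manifest["files"]["scores"])
        chrom, pos, ref, alt = key.split("_")
        comp = conservation_composite(scores[(chrom, int(pos), ref, alt)])
        assert comp.score == 0


class TestGeneratedFilesAreValidInputs:
    def test_round_trips(self, small_study):
        _, manifest, _ = small_study
        files = manifest["files"]
        assert len(io.read_bed(files["promoters"], "p")) > 0
        assert len(io.read_bed(files["mirna_atlas"], "a")) > 0
        pwms = io.read_pfm_jaspar(files["pfm"])
        assert all(p.length >= 1 for p in pwms)
        coll = io.read_gmt(files["gmt"])
        assert "PLANTED_PATHWAY" in coll.sets
        profiles = read_chromatin_profiles(files["chromatin"], files["segway"])
        assert profiles
        # chromatin panels have the emulated sizes
        some = next(iter(profiles.values()))
        assert len(some.chmm_states) == 127
        assert len(some.histone_marks) == 14
        windows = io.read_fasta_windows(files["windows"])
        for key, fate in manifest["truth"].items():
            assert len(windows[key]) == 21 or fate.startswith("decoy")

    def test_windows_match_vcf_ref_alleles(self, small_study):
        _, manifest, _ = small_study
        windows = io.read_fasta_windows(manifest["files"]["windows"])
        for key in manifest["truth"]:
            ref = key.split("_")[2]
            assert windows[key][10 : 10 + len(ref)] == ref


class TestConfigValidation:
    def test_infeasible_config_errors(self):
        with pytest.raises(ValueError):
            SynthConfig(n_families=0)
        with pytest.raises(ValueError):
            SynthConfig(n_planted_5p=-1)
        with pytest.raises(ValueError):
            SynthConfig(decoy_spec={"bogus_stage": 1})
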