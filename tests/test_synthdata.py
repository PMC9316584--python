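"""Synthetic case/dataset generator: class logic, determinism, allocation."""

import numpy as np
import pytest

from skindx.labels import MASK_CODES, DiagnosisClass
from skindx.maskops import write_mask
from skindx.synthdata import (DEFAULT_CLASS_PROPORTIONS, SynthConfig,
                              audit_class_logic, generate_case,
                              generate_dataset, largest_remainder, load_case,
                              read_manifest, split_class_counts)

DMN_M = MASK_CODES["DMN_M"]


class TestGenerateCase:
    def test_benign_cases_have_zero_melanoma_nest_pixels(self, synth_config):
        for cls in (DiagnosisClass.MMD, DiagnosisClass.MIS):
            for seed in range(5):
                case = generate_case(synth_config, cls, seed)
                assert all((m == DMN_M).sum() == 0 for _, m in case.slices)

    def test_invasive_cases_have_melanoma_nest_pixels(self, synth_config):
        for cls in (DiagnosisClass.T1a, DiagnosisClass.T1b):
            for seed in range(5):
                case = generate_case(synth_config, cls, seed)
                assert sum(int((m == DMN_M).sum()) for _, m in case.slices) > 0

    def test_identical_inputs_give_bit_identical_output(self, synth_config):
        a = generate_case(synth_config, DiagnosisClass.T1a, 9)
        b = generate_case(synth_config, DiagnosisClass.T1a, 9)
        assert a.n_slices == b.n_slices
        for (rgb1, m1), (rgb2, m2) in zip(a.slices, b.slices):
            assert np.array_equal(rgb1, rgb2)
            assert np.array_equal(m1, m2)
        assert a.roi == b.roi

    def test_roi_lies_inside_its_slice(self, synth_config):
        for seed in range(8):
            case = generate_case(synth_config, DiagnosisClass.MIS, seed)
            idx, (r0, c0, r1, c1) = case.roi
            h, w = case.slices[idx][1].shape
            assert 0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w

    def test_mask_codes_stay_in_declared_table(self, t1b_case):
        codes = set(MASK_CODES.values())
        for _, mask in t1b_case.slices:
            assert set(np.unique(mask)) <= codes

    def test_t1b_denser_in_melanoma_nests_than_t1a(self, synth_config):
        def mean_fraction(cls):
            fracs = []
            for seed in range(25):
                case = generate_case(synth_config, cls, seed)
                px = sum(int((m == DMN_M).sum()) for _, m in case.slices)
                tot = sum(m.size for _, m in case.slices)
                fracs.append(px / tot)
            return np.mean(fracs)

        assert mean_fraction(DiagnosisClass.T1b) > mean_fraction(DiagnosisClass.T1a)

    def test_infeasible_nest_radius_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SynthConfig(slice_size=(64, 64), nest_radius_range=(20, 25))


class TestAllocation:
    def test_table_proportions_at_240_cases(self):
        counts = largest_remainder(DEFAULT_CLASS_PROPORTIONS, 240)
        assert counts == [61, 60, 72, 47]

    def test_uniform_four_cases_one_per_class(self):
        assert largest_remainder((0.25,) * 4, 4) == [1, 1, 1, 1]

    @pytest.mark.parametrize("n", [7, 53, 240, 999])
    def test_allocation_sums_and_stays_near_exact(self, n):
        props = (0.3, 0.25, 0.25, 0.2)
        counts = largest_remainder(props, n)
        assert sum(counts) == n
        for c, p in zip(counts, props):
            assert abs(c - p * n) < 1

    def test_split_halves_differ_by_at_most_one_per_class(self):
        counts = [61, 60, 72, 47]
        train, test = split_class_counts(counts)
        assert sum(train) == sum(test) == 120
        for tr, te, c in zip(train, test, counts):
            assert tr + te == c
            assert abs(tr - c / 2) <= 0.5 and abs(te - c / 2) <= 0.5


class TestDataset:
    def test_manifest_counts_and_split(self, small_dataset):
        root, manifest = small_dataset
        per_case = manifest.drop_duplicates("case_id")
        assert len(per_case) == 16
        assert set(per_case["diagnosis"].value_counts()) == {4}
        for cls, grp in per_case.groupby("diagnosis"):
            assert sorted(grp["split"].value_counts()) == [2, 2]

    def test_refuses_overwrite_without_force(self, small_dataset,
                                             masked_signal_config):
        root, _ = small_dataset
        with pytest.raises(FileExistsError):
            generate_dataset(masked_signal_config, 16, root)

    def test_loaded_case_matches_generated(self, small_dataset,
                                           masked_signal_config):
        root, manifest = small_dataset
        cid = manifest["case_id"].iloc[0]
        case = load_case(manifest, root, cid)
        assert case.n_slices == (manifest["case_id"] == cid).sum()
        assert case.roi is not None

    def test_exactly_one_roi_slice_per_case(self, small_dataset):
        _, manifest = small_dataset
        for cid, grp in manifest.groupby("case_id"):
            assert (grp["roi"] != "").sum() == 1


class TestAudit:
    def test_generated_dataset_is_clean(self, small_dataset):
        root, _ = small_dataset
        assert audit_class_logic(root / "manifest.csv") == []

    def test_hand_edited_benign_mask_is_flagged_once(self, tmp_path,
                                                     masked_signal_config):
        generate_dataset(masked_signal_config, 8, tmp_path)
        manifest = read_manifest(tmp_path / "manifest.csv")
        row = manifest[manifest["diagnosis"] == "MMD"].iloc[0]
        from skindx.maskops import read_mask
        mask = read_mask(tmp_path / row["mask_path"])
        mask[-5:, -5:] = DMN_M
        write_mask(tmp_path / row["mask_path"], mask)
        violations = audit_class_logic(tmp_path / "manifest.csv")
        assert violations == [(row["case_id"], int(row["slice_id"][1:]))]

    def test_missing_mask_file_errors_with_path(self, tmp_path,
                                                masked_signal_config):
        generate_dataset(masked_signal_config, 8, tmp_path)
        manifest = read_manifest(tmp_path / "manifest.csv")
        victim = manifest[manifest["diagnosis"] == "MMD"].iloc[0]["mask_path"]
        (tmp_path / victim).unlink()
        with pytest.raises(FileNotFoundError, match=victim.split("/")[-1]):
            audit_class_logic(tmp_path / "manifest.csv")

    def test_empty_manifest_gives_empty_report(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text("case_id,slice_id,rgb_path,mask_path,diagnosis,split,roi\n")
        assert audit_class_logic(path) == []
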