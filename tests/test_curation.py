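import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cxrqc.curation import (age_midpoint, apply_inclusion_filters,
                            largest_remainder, select_one_per_patient,
                            stratified_partition)


def make_table(n, seed=0, missing_rate=0.0, images_per_patient=1):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        pid = f"P{i // images_per_patient:05d}"
        row = {"image_id": f"img{i:05d}", "patient_id": pid,
               "manufacturer": rng.choice(["Vendor A", "Vendor B"]),
               "deviation_index": round(float(rng.normal(0, 2)), 2),
               "sex": rng.choice(["M", "F"]),
               "age": float(rng.uniform(18, 95)),
               "ethnicity": rng.choice(["White", "Black", "Asian", "Mixed"])}
        if rng.random() < missing_rate:
            row[rng.choice(["manufacturer", "deviation_index", "sex", "age",
                            "ethnicity"])] = None
        rows.append(row)
    return pd.DataFrame(rows)


class TestAgeMidpoint:
    @pytest.mark.parametrize("value,expected", [
        ("40-49", 44.5), (63, 63.0), ("unknown", None),
        ("045Y", 45.0), ("", None), (None, None), (70.5, 70.5),
        ("18 - 29", 23.5),
    ])
    def test_cases(self, value, expected):
        assert age_midpoint(value) == expected

    def test_nan_is_missing(self):
        assert age_midpoint(float("nan")) is None


class TestInclusion:
    def test_complete_table_untouched(self):
        t = make_table(20)
        kept, log = apply_inclusion_filters(t)
        assert len(kept) == 20 and log.empty

    def test_single_missing_field_logged(self):
        t = make_table(5)
        t.loc[2, "sex"] = None
        kept, log = apply_inclusion_filters(t)
        assert len(kept) == 4
        assert log.iloc[0]["image_id"] == t.loc[2, "image_id"]
        assert log.iloc[0]["missing_field"] == "sex"

    def test_counted_exclusions(self):
        t = make_table(10)
        for i in (1, 4, 7):
            t.loc[i, "ethnicity"] = None
        kept, log = apply_inclusion_filters(t)
        assert len(kept) == 7 and len(log) == 3

    def test_unparseable_age_counts_as_missing(self):
        t = make_table(4)
        t["age"] = t["age"].astype(object)
        t.loc[0, "age"] = "adult"
        kept, log = apply_inclusion_filters(t)
        assert len(kept) == 3
        assert log.iloc[0]["missing_field"] == "age"


class TestOnePerPatient:
    def test_unique_patients_identity(self):
        t = make_table(15)
        out = select_one_per_patient(t, seed=0)
        assert sorted(out.image_id) == sorted(t.image_id)

    def test_multi_image_patients_reduced_to_one(self):
        t = make_table(15, images_per_patient=3)
        out = select_one_per_patient(t, seed=0)
        assert len(out) == 5
        assert out.patient_id.is_unique

    def test_seed_determinism_and_sensitivity(self):
        t = make_table(300, images_per_patient=3)
        a = select_one_per_patient(t, seed=1)
        b = select_one_per_patient(t, seed=1)
        c = select_one_per_patient(t, seed=2)
        assert a.image_id.tolist() == b.image_id.tolist()
        assert a.image_id.tolist() != c.image_id.tolist()


class TestLargestRemainder:
    def test_exact_fractions(self):
        assert largest_remainder(1000, (0.64, 0.16, 0.20)) == [640, 160, 200]

    def test_ten_rows(self):
        assert largest_remainder(10, (0.64, 0.16, 0.20)) == [6, 2, 2]

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 500))
    def test_matches_bruteforce_oracle(self, n):
        fractions = (0.64, 0.16, 0.20)
        counts = largest_remainder(n, fractions)
        # oracle: floor everything, then hand out leftovers by sorted remainder
        quotas = [n * f for f in fractions]
        floors = [math.floor(q) for q in quotas]
        rem = sorted(range(3), key=lambda i: (-(quotas[i] - floors[i]), i))
        expect = list(floors)
        for i in rem[: n - sum(floors)]:
            expect[i] += 1
        assert counts == expect
        assert sum(counts) == n


class TestPartition:
    def test_split_sizes_exact_for_1000(self):
        t = apply_inclusion_filters(make_table(1000, seed=3))[0]
        assign = stratified_partition(t, seed=5)
        counts = assign.value_counts()
        assert counts["train"] == 640 and counts["tune"] == 160 and counts["test"] == 200

    def test_disjoint_cover_and_determinism(self):
        t = apply_inclusion_filters(make_table(400, seed=4))[0]
        a = stratified_partition(t, seed=6)
        b = stratified_partition(t, seed=6)
        assert a.equals(b)
        assert set(a.index) == set(t.image_id)
        assert a.isin(["train", "tune", "test"]).all()

    def test_stratification_preserves_sex_proportions(self):
        t = apply_inclusion_filters(make_table(1000, seed=7))[0]
        assign = stratified_partition(t, seed=8)
        merged = t.merge(assign.rename("split"), left_on="image_id",
                         right_index=True)
        overall = (merged.sex == "M").mean()
        for split in ("train", "tune", "test"):
            frac = (merged[merged.split == split].sex == "M").mean()
            assert abs(frac - overall) <= 0.02

    def test_patient_straddling_splits_rejected(self):
        t = make_table(60, images_per_patient=3)
        with pytest.raises(ValueError, match="deduplicate"):
            stratified_partition(t, seed=0)

    def test_bad_fractions_rejected(self):
        t = apply_inclusion_filters(make_table(50))[0]
        with pytest.raises(ValueError):
            stratified_partition(t, fractions=(0.5, 0.3, 0.3), seed=0)
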