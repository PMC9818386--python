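"""Carrier classification and the co-segregation predicate, checked against
an independent brute-force enumeration."""

from __future__ import annotations

import itertools

import pytest

from famprior.segregation import (
    CarrierStatus,
    SegregationConfig,
    classify_member,
    filter_segregating,
    segregates_in_family,
)
from famprior.types import Diagnosis, Family, Genotype, Individual


def _member(iid, diagnosis, dx_age=None, fu_age=None, fid="F1"):
    return Individual(
        individual_id=iid,
        family_id=fid,
        diagnosis=diagnosis,
        age_at_diagnosis=dx_age,
        age_at_last_followup=fu_age,
    )


def _family(members, fid="F1"):
    return Family(fid, members)


class TestClassifyMember:
    def test_case_diagnoses(self):
        fam = _family([_member("c", Diagnosis.MGUS, dx_age=45)])
        assert classify_member(fam.members[0], fam) is CarrierStatus.CASE

    def test_plasma_cell_anomaly_is_possible_carrier(self):
        fam = _family(
            [_member("c", Diagnosis.MM, dx_age=45), _member("p", Diagnosis.SOLITARY_PLASMACYTOMA)]
        )
        assert classify_member(fam.members[1], fam) is CarrierStatus.POSSIBLE_CARRIER

    @pytest.mark.parametrize(
        "fu_age,expected",
        [
            (30, CarrierStatus.POSSIBLE_CARRIER),  # 30 < 45 - 10
            (34.9, CarrierStatus.POSSIBLE_CARRIER),
            (35, CarrierStatus.NON_CARRIER),  # strict inequality: 35 >= 35
            (40, CarrierStatus.NON_CARRIER),
        ],
    )
    def test_young_unaffected_age_gap(self, fu_age, expected):
        fam = _family(
            [_member("c", Diagnosis.MM, dx_age=45), _member("h", Diagnosis.HEALTHY, fu_age=fu_age)]
        )
        assert classify_member(fam.members[1], fam) is expected

    def test_missing_followup_age_cannot_prove_noncarrier(self, caplog):
        fam = _family(
            [_member("c", Diagnosis.MM, dx_age=45), _member("h", Diagnosis.HEALTHY)]
        )
        with caplog.at_level("WARNING"):
            status = classify_member(fam.members[1], fam)
        assert status is CarrierStatus.POSSIBLE_CARRIER

    def test_family_without_case_ages_warns(self, caplog):
        fam = _family([_member("h", Diagnosis.HEALTHY, fu_age=50)])
        with caplog.at_level("WARNING"):
            assert classify_member(fam.members[0], fam) is CarrierStatus.POSSIBLE_CARRIER


def _variant_with(make_variant, carry_states):
    """carry_states: iid -> 'carry' | 'absent' | 'missing'."""
    genotypes = {}
    for iid, state in carry_states.items():
        if state == "carry":
            genotypes[iid] = Genotype(1, 30)
        elif state == "absent":
            genotypes[iid] = Genotype(0, 30)
        else:
            genotypes[iid] = Genotype(None, 30, missing=True)
    return make_variant(genotypes=genotypes)


def _brute_force(statuses, carries):
    """Independent enumeration of the segregation rule: every case carries,
    every non-carrier is demonstrably free of the variant, missing genotypes
    in either group are disqualifying, possible carriers unconstrained."""
    if CarrierStatus.CASE not in statuses:
        return False
    for status, state in zip(statuses, carries):
        if status is CarrierStatus.CASE and state != "carry":
            return False
        if status is CarrierStatus.NON_CARRIER and state != "absent":
            return False
    return True


STATUSES = [CarrierStatus.CASE, CarrierStatus.POSSIBLE_CARRIER, CarrierStatus.NON_CARRIER]
STATES = ["carry", "absent", "missing"]


class TestSegregatesInFamily:
    def test_textbook_positive(self, make_variant):
        fam = _family(
            [
                _member("c1", Diagnosis.MM, dx_age=50),
                _member("c2", Diagnosis.MM, dx_age=55),
                _member("n1", Diagnosis.HEALTHY, fu_age=60),
            ]
        )
        statuses = {
            "c1": CarrierStatus.CASE,
            "c2": CarrierStatus.CASE,
            "n1": CarrierStatus.NON_CARRIER,
        }
        v = _variant_with(make_variant, {"c1": "carry", "c2": "carry", "n1": "absent"})
        assert segregates_in_family(v, fam, statuses)
        v2 = _variant_with(make_variant, {"c1": "carry", "c2": "absent", "n1": "absent"})
        assert not segregates_in_family(v2, fam, statuses)

    def test_possible_carrier_unconstrained(self, make_variant):
        fam = _family(
            [
                _member("c1", Diagnosis.MM, dx_age=50),
                _member("p1", Diagnosis.PLASMA_CELL_DYSCRASIA),
            ]
        )
        statuses = {"c1": CarrierStatus.CASE, "p1": CarrierStatus.POSSIBLE_CARRIER}
        for state in STATES:
            v = _variant_with(make_variant, {"c1": "carry", "p1": state})
            assert segregates_in_family(v, fam, statuses)

    def test_matches_bruteforce_for_four_member_families(self, make_variant):
        iids = ["m1", "m2", "m3", "m4"]
        fam = _family([_member(i, Diagnosis.HEALTHY) for i in iids])
        for status_combo in itertools.product(STATUSES, repeat=4):
            statuses = dict(zip(iids, status_combo))
            for state_combo in itertools.product(STATES, repeat=4):
                v = _variant_with(make_variant, dict(zip(iids, state_combo)))
                assert segregates_in_family(v, fam, statuses) == _brute_force(
                    status_combo, state_combo
                )

    def test_relabeling_noncarrier_as_possible_is_monotone(self, make_variant):
        """Relaxing a NON_CARRIER to POSSIBLE_CARRIER never breaks segregation."""
        iids = ["m1", "m2", "m3"]
        fam = _family([_member(i, Diagnosis.HEALTHY) for i in iids])
        for status_combo in itertools.product(STATUSES, repeat=3):
            for state_combo in itertools.product(STATES, repeat=3):
                statuses = dict(zip(iids, status_combo))
                v = _variant_with(make_variant, dict(zip(iids, state_combo)))
                before = segregates_in_family(v, fam, statuses)
                for i, s in enumerate(status_combo):
                    if s is CarrierStatus.NON_CARRIER:
                        relaxed = dict(statuses)
                        relaxed[iids[i]] = CarrierStatus.POSSIBLE_CARRIER
                        if before:
                            assert segregates_in_family(v, fam, relaxed)

    def test_ignore_missing_policy(self, make_variant):
        fam = _family([_member("c1", Diagnosis.MM, dx_age=50), _member("c2", Diagnosis.MM, dx_age=52)])
        statuses = {"c1": CarrierStatus.CASE, "c2": CarrierStatus.CASE}
        v = _variant_with(make_variant, {"c1": "carry", "c2": "missing"})
        assert not segregates_in_family(v, fam, statuses)
        lenient = SegregationConfig(missing_fails=False)
        assert segregates_in_family(v, fam, statuses, lenient)


class TestFilterSegregating:
    def test_keeps_variants_with_at_least_one_family(self, make_variant):
        famA = _family(
            [_member("a1", Diagnosis.MM, dx_age=50), _member("a2", Diagnosis.HEALTHY, fu_age=60)],
            fid="A",
        )
        famB = _family(
            [_member("b1", Diagnosis.MM, dx_age=50), _member("b2", Diagnosis.HEALTHY, fu_age=60)],
            fid="B",
        )
        seg = _variant_with(
            make_variant, {"a1": "carry", "a2": "absent", "b1": "absent", "b2": "absent"}
        )
        only_noncarrier = _variant_with(
            make_variant, {"a1": "absent", "a2": "carry", "b1": "absent", "b2": "absent"}
        )
        results = filter_segregating([seg, only_noncarrier], [famA, famB])
        assert len(results) == 1
        assert results[0].families_segregating == ["A"]
        detail = dict(results[0].per_family_detail)
        assert {row[0] for row in detail["A"]} == {"a1", "a2"}
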