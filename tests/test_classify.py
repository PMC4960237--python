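"""The consensus localization classifier and the genome-wide screen."""

import math

import pytest

from omproteome import (
    ClassifierConfig,
    Compartment,
    Condition,
    Fraction,
    LipoproteinClass,
    SampleMeta,
    assign_compartment,
    benchmark_scenario,
    classify_detected,
    generate,
    genome_screen,
    impute_missing,
    om_criteria,
    preliminary_candidates,
    run_all,
)

from conftest import build_table, make_profile
from _oracles import expected_om_recovery

OM = Compartment.OUTER_MEMBRANE


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "overrides, expected",
    [
        ({"cello_label": OM, "psortb_label": OM}, {"C1_dual_om"}),
        ({"cello_label": OM}, set()),  # one predictor is not enough
        (
            {"lipoprotein_class": LipoproteinClass.LIPOPROTEIN},
            {"C2_lipoprotein"},
        ),
        (
            {"lipoprotein_class": LipoproteinClass.OTHER_CLEAVED},
            set(),  # SpI-cleaved proteins are not lipoproteins
        ),
        ({"bomp_category": 1}, {"C3_beta_barrel"}),
        ({"bomp_category": 5}, {"C3_beta_barrel"}),
        ({"secretomep_score": 0.8}, {"C4_nonclassical"}),
        ({"secretomep_score": 0.8, "has_signal_peptide": True}, set()),
        ({"secretomep_score": 0.5}, set()),  # cutoff is strict
        (
            {"cello_label": OM, "psortb_label": OM, "bomp_category": 2},
            {"C1_dual_om", "C3_beta_barrel"},
        ),
    ],
)
def test_om_criteria_fire_independently(overrides, expected):
    assert om_criteria(make_profile("P", **overrides)) == expected


def test_criteria_monotone_never_lose_om_status():
    base = make_profile("P", bomp_category=1)
    assert assign_compartment(base, om_criteria(base)).is_om
    stronger = make_profile(
        "P", bomp_category=1, cello_label=OM, psortb_label=OM
    )
    assert assign_compartment(stronger, om_criteria(stronger)).is_om


# ---------------------------------------------------------------------------
# compartment assignment
# ---------------------------------------------------------------------------

def test_any_fired_criterion_confirms_om():
    profile = make_profile("P", bomp_category=1)
    call = assign_compartment(profile, {"C3_beta_barrel"})
    assert call.label == "om_confirmed"
    assert call.criterion_fired == {"C3_beta_barrel"}


def test_signal_without_criteria_falls_back_to_periplasmic():
    profile = make_profile("P", has_signal_peptide=True)
    call = assign_compartment(profile, set())
    assert call.label == "periplasmic"


def test_no_signal_no_criteria_keeps_primary_label():
    profile = make_profile("P", cello_label=Compartment.CYTOPLASMIC)
    assert assign_compartment(profile, set()).label == "cytoplasmic"


def test_every_protein_gets_exactly_one_label():
    profiles = [
        make_profile("A", cello_label=OM, psortb_label=OM),
        make_profile("B", has_signal_peptide=True),
        make_profile("C"),
        make_profile("D", bomp_category=3, has_signal_peptide=True),
    ]
    calls = [assign_compartment(p, om_criteria(p)) for p in profiles]
    assert [c.protein_id for c in calls] == ["A", "B", "C", "D"]
    assert [c.label for c in calls] == [
        "om_confirmed", "periplasmic", "cytoplasmic", "om_confirmed",
    ]


# ---------------------------------------------------------------------------
# preliminary candidates
# ---------------------------------------------------------------------------

def _candidate_setup():
    metas = [SampleMeta("om_mucin", Fraction.OM_SARKOSYL, Condition.MUCIN)]
    data = {
        "om_mucin": {
            "HIGH": 9.0,      # above threshold, predictors non-OM
            "PRED": 8.4,      # below threshold, CELLO says OM
            "EDGE": 8.5,      # exactly at the strict threshold
            "LOW": 7.0,
            "MISS": None,     # undetected
        }
    }
    table = build_table(data, metas)
    profiles = [
        make_profile("HIGH"),
        make_profile("PRED", cello_label=OM),
        make_profile("EDGE"),
        make_profile("LOW"),
        make_profile("MISS", cello_label=OM, psortb_label=OM),
    ]
    return table, profiles


def test_candidates_are_union_of_lfq_and_predictor_arms():
    table, profiles = _candidate_setup()
    cands = preliminary_candidates(table, profiles, ["om_mucin"])
    assert cands == {"HIGH", "PRED"}


def test_exact_threshold_excluded_under_strict_reading():
    table, profiles = _candidate_setup()
    strict = preliminary_candidates(table, profiles, ["om_mucin"])
    assert "EDGE" not in strict
    lax = preliminary_candidates(
        table, profiles, ["om_mucin"], ClassifierConfig(strict_threshold=False)
    )
    assert "EDGE" in lax


def test_undetected_proteins_never_become_candidates():
    table, profiles = _candidate_setup()
    imputed = impute_missing(table)
    cands = preliminary_candidates(imputed, profiles, ["om_mucin"])
    assert "MISS" not in cands


def test_empty_om_sample_list_is_an_error():
    table, profiles = _candidate_setup()
    with pytest.raises(ValueError, match="om_samples"):
        preliminary_candidates(table, profiles, [])


# ---------------------------------------------------------------------------
# classify_detected / genome screen
# ---------------------------------------------------------------------------

def test_classify_detected_counts_om_calls():
    profiles = [make_profile(f"P{i}") for i in range(6)] + [
        make_profile(f"Q{i}", bomp_category=1) for i in range(4)
    ]
    calls = classify_detected({p.protein_id for p in profiles}, profiles)
    assert sum(1 for c in calls if c.is_om) == 4
    assert all(c.in_preliminary_list for c in calls)


def test_classify_detected_requires_profiles():
    with pytest.raises(ValueError, match="without predictor profiles"):
        classify_detected({"GHOST"}, [make_profile("P")])


def test_union_of_disjoint_condition_sets():
    profiles = [make_profile(f"P{i}", bomp_category=1) for i in range(4)]
    a = classify_detected({"P0", "P1"}, profiles)
    b = classify_detected({"P2", "P3"}, profiles)
    ids = {c.protein_id for c in a} | {c.protein_id for c in b}
    assert len(ids) == 4


def test_genome_screen_flags_undetected_om_proteins():
    profiles = [make_profile(f"P{i}") for i in range(15)] + [
        make_profile("U1", lipoprotein_class=LipoproteinClass.LIPOPROTEIN),
        make_profile("U2", lipoprotein_class=LipoproteinClass.LIPOPROTEIN),
        make_profile("U3"),
        make_profile("U4"),
        make_profile("U5"),
    ]
    detected = {f"P{i}" for i in range(15)}
    calls = genome_screen(profiles, detected)
    assert {c.protein_id for c in calls} == {"U1", "U2"}
    assert all(not c.detected_in_proteomics for c in calls)


def test_genome_screen_empty_when_everything_detected():
    profiles = [make_profile("P", bomp_category=1)]
    assert genome_screen(profiles, {"P"}) == []


def test_classifier_is_deterministic():
    table, profiles = _candidate_setup()
    runs = [
        classify_detected(
            preliminary_candidates(table, profiles, ["om_mucin"]), profiles
        )
        for _ in range(3)
    ]
    assert runs[0] == runs[1] == runs[2]


# ---------------------------------------------------------------------------
# synthetic recovery
# ---------------------------------------------------------------------------

def test_noiseless_scenario_recovers_ground_truth_exactly():
    cfg = benchmark_scenario("noiseless")
    records, profiles, table, truth = generate(cfg)
    result = run_all(records, profiles, table)
    recovered = result.om_ids | {c.protein_id for c in result.genome_calls}
    assert recovered == truth.om_ids


def test_noisy_recovery_matches_closed_form_expectation():
    cfg = benchmark_scenario("paper_like")
    records, profiles, table, truth = generate(cfg)
    result = run_all(records, profiles, table)
    recovered = (
        result.om_ids | {c.protein_id for c in result.genome_calls}
    ) & truth.om_ids
    p = expected_om_recovery(
        cfg.predictor_error_rate,
        cfg.p_lipoprotein_om,
        cfg.p_barrel_om,
        cfg.p_signal_om,
    )
    n = len(truth.om_ids)
    sd = math.sqrt(n * p * (1 - p))
    assert abs(len(recovered) - n * p) <= 3 * sd
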