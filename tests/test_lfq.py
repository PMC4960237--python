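"""LFQ processing: imputation, shares, composition, enrichment, gradient."""

import itertools

import numpy as np
import pytest

from omproteome import (
    Compartment,
    CompartmentDistribution,
    Condition,
    Fraction,
    SampleMeta,
    compartment_distribution,
    enrichment_factor,
    impute_missing,
    relative_abundance,
    sucrose_gradient_profile,
)

from conftest import build_table
from _oracles import (
    brute_compartment_shares,
    brute_enrichment,
    brute_impute,
    brute_shares,
)

OM = Compartment.OUTER_MEMBRANE
CYTO = Compartment.CYTOPLASMIC


def _single_sample_table(values: dict, floor=4.0):
    meta = [SampleMeta("s1", Fraction.OM_SARKOSYL, Condition.MUCIN)]
    return build_table({"s1": values}, meta, floor=floor)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_fills_below_sample_minimum():
    table = _single_sample_table({"P1": 6.2, "P2": 7.0, "P3": None})
    out = impute_missing(table, offset=0.5, floor=4.0)
    assert out.log10_lfq.at["P3", "s1"] == pytest.approx(5.7)
    assert bool(out.detected.at["P3", "s1"]) is False
    # detected cells untouched
    assert out.log10_lfq.at["P1", "s1"] == 6.2
    out.validate_imputed()


def test_impute_floor_binds_near_detection_limit():
    table = _single_sample_table({"P1": 4.2, "P2": None})
    out = impute_missing(table, offset=0.5, floor=4.0)
    assert out.log10_lfq.at["P2", "s1"] == pytest.approx(4.0)


def test_impute_identity_when_nothing_missing():
    table = _single_sample_table({"P1": 6.0, "P2": 7.0})
    out = impute_missing(table)
    assert out.log10_lfq.equals(table.log10_lfq)
    assert out.imputed


def test_impute_errors_when_sample_has_no_detected_values():
    table = _single_sample_table({"P1": None, "P2": None})
    with pytest.raises(ValueError, match="no detected values"):
        impute_missing(table)


def test_impute_monotone_in_offset():
    table = _single_sample_table({"P1": 6.2, "P2": None, "P3": None})
    small = impute_missing(table, offset=0.3)
    large = impute_missing(table, offset=0.9)
    assert (
        large.log10_lfq.at["P2", "s1"] <= small.log10_lfq.at["P2", "s1"]
    )


# ---------------------------------------------------------------------------
# relative abundance
# ---------------------------------------------------------------------------

def test_shares_are_linear_scale():
    table = _single_sample_table({"P1": 9.0, "P2": 8.0})
    shares = relative_abundance(table, "s1")
    assert shares["P1"] == pytest.approx(10 / 11)
    assert shares["P2"] == pytest.approx(1 / 11)


def test_single_protein_has_share_one():
    table = _single_sample_table({"P1": 7.3})
    assert relative_abundance(table, "s1")["P1"] == pytest.approx(1.0)


def test_named_subset_share_matches_hand_sum():
    # hand-built 5-protein toy: linear intensities 2, 1, 1, 3.2, 2.8 (x1e7)
    vals = {
        "P1": np.log10(2.0e7),
        "P2": np.log10(1.0e7),
        "P3": np.log10(1.0e7),
        "P4": np.log10(3.2e7),
        "P5": np.log10(2.8e7),
    }
    table = _single_sample_table(vals)
    shares = relative_abundance(table, "s1")
    subset = {"P2", "P3", "P5"}  # (1 + 1 + 2.8) / 10 = 0.48
    assert sum(shares[p] for p in subset) == pytest.approx(0.48)
    assert round(100 * sum(shares[p] for p in subset)) == 48


def test_unknown_sample_raises():
    table = _single_sample_table({"P1": 7.0})
    with pytest.raises(KeyError):
        relative_abundance(table, "nope")


def test_detected_only_excludes_imputed_cells():
    table = impute_missing(_single_sample_table({"P1": 8.0, "P2": None}))
    shares = relative_abundance(table, "s1", detected_only=True)
    assert shares["P2"] == 0.0
    assert shares["P1"] == pytest.approx(1.0)
    both = relative_abundance(table, "s1", detected_only=False)
    assert both["P2"] > 0.0
    assert sum(both.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# compartment composition and enrichment
# ---------------------------------------------------------------------------

def test_all_om_labels_give_unit_share():
    table = _single_sample_table({"P1": 8.0, "P2": 7.0})
    dist = compartment_distribution(table, {"P1": OM, "P2": OM}, "s1")
    assert dist.shares == {OM: pytest.approx(1.0)}


def test_toy_composition_matches_arithmetic():
    table = _single_sample_table(
        {"A": 9.0, "B": 9.0, "C": 8.0, "D": 8.0}
    )
    labels = {"A": OM, "B": OM, "C": CYTO, "D": CYTO}
    dist = compartment_distribution(table, labels, "s1")
    assert dist.shares[OM] == pytest.approx(20 / 22)
    assert dist.shares[CYTO] == pytest.approx(2 / 22)


def test_composition_invariant_under_protein_permutation():
    vals = {"A": 9.0, "B": 8.5, "C": 7.0}
    labels = {"A": OM, "B": CYTO, "C": OM}
    d1 = compartment_distribution(_single_sample_table(vals), labels, "s1")
    permuted = {k: vals[k] for k in ["C", "A", "B"]}
    d2 = compartment_distribution(_single_sample_table(permuted), labels, "s1")
    for comp in d1.shares:
        assert d1.shares[comp] == pytest.approx(d2.shares[comp])


def test_missing_label_counts_as_unknown():
    table = _single_sample_table({"A": 8.0, "B": 8.0})
    dist = compartment_distribution(table, {"A": OM}, "s1")
    assert dist.shares[Compartment.UNKNOWN] == pytest.approx(0.5)


def test_enrichment_identity_and_ratio():
    d1 = CompartmentDistribution("t", {OM: 0.40, CYTO: 0.60})
    d2 = CompartmentDistribution("r", {OM: 0.02, CYTO: 0.98})
    assert enrichment_factor(d1, d1, OM).factor == pytest.approx(1.0)
    assert enrichment_factor(d1, d2, OM).factor == pytest.approx(20.0)


def test_enrichment_reciprocity():
    d1 = CompartmentDistribution("t", {OM: 0.40, CYTO: 0.60})
    d2 = CompartmentDistribution("r", {OM: 0.02, CYTO: 0.98})
    fwd = enrichment_factor(d1, d2, OM).factor
    rev = enrichment_factor(d2, d1, OM).factor
    assert fwd * rev == pytest.approx(1.0, abs=1e-9)


def test_enrichment_zero_reference_is_an_error():
    d1 = CompartmentDistribution("t", {OM: 0.5, CYTO: 0.5})
    d2 = CompartmentDistribution("r", {OM: 0.0, CYTO: 1.0})
    with pytest.raises(ValueError, match="undefined enrichment"):
        enrichment_factor(d1, d2, OM)


def test_enrichment_missing_compartment_is_an_error():
    d1 = CompartmentDistribution("t", {CYTO: 1.0})
    d2 = CompartmentDistribution("r", {OM: 0.1, CYTO: 0.9})
    with pytest.raises(KeyError):
        enrichment_factor(d1, d2, OM)


def test_benchmark_enrichment_factor_in_expected_band():
    """Default benchmark mixture at seed 1: OM enrichment lands in 15-30x."""
    from omproteome import benchmark_scenario, generate, impute_missing

    cfg = benchmark_scenario("paper_like")
    cfg.seed = 1
    _, _, raw, truth = generate(cfg)
    table = impute_missing(raw)
    d_om = compartment_distribution(table, truth.compartment, "om_glucose")
    d_wp = compartment_distribution(table, truth.compartment, "wp_glucose")
    factor = enrichment_factor(d_om, d_wp, OM).factor
    assert 15.0 <= factor <= 30.0


# ---------------------------------------------------------------------------
# sucrose gradient
# ---------------------------------------------------------------------------

def _gradient_table(om_vals, order=None):
    n = len(om_vals)
    indices = list(range(1, n + 1))
    if order:
        indices = [indices[k] for k in order]
        om_vals = [om_vals[k] for k in order]
    metas = [
        SampleMeta(
            f"f{idx:02d}", Fraction.SUCROSE_GRADIENT, Condition.MUCIN,
            gradient_index=idx,
        )
        for idx in indices
    ]
    data = {
        m.sample_id: {"OMP": v, "CYT": 8.0}
        for m, v in zip(metas, om_vals)
    }
    return build_table(data, metas)


LABELS = {"OMP": OM, "CYT": CYTO}


def test_increasing_gradient_has_positive_monotonicity():
    om_vals = [6.0 + 0.1 * k for k in range(24)]
    shares, sign = sucrose_gradient_profile(_gradient_table(om_vals), LABELS)
    assert len(shares) == 24
    assert all(b > a for a, b in zip(shares, shares[1:]))
    assert sign == +1


def test_constant_gradient_has_zero_sign():
    shares, sign = sucrose_gradient_profile(_gradient_table([7.0] * 6), LABELS)
    assert sign == 0


def test_gradient_ordering_by_index_not_file_order():
    om_vals = [6.0 + 0.2 * k for k in range(6)]
    fwd = sucrose_gradient_profile(_gradient_table(om_vals), LABELS)
    rev = sucrose_gradient_profile(
        _gradient_table(om_vals, order=list(reversed(range(6)))), LABELS
    )
    assert fwd[0] == pytest.approx(rev[0])
    assert fwd[1] == rev[1] == +1


def test_gradient_duplicate_index_rejected():
    metas = [
        SampleMeta("a", Fraction.SUCROSE_GRADIENT, Condition.MUCIN, gradient_index=1),
        SampleMeta("b", Fraction.SUCROSE_GRADIENT, Condition.MUCIN, gradient_index=1),
    ]
    table = build_table({"a": {"P": 7.0}, "b": {"P": 7.0}}, metas)
    with pytest.raises(ValueError, match="duplicate gradient_index"):
        sucrose_gradient_profile(table, {"P": OM})


# ---------------------------------------------------------------------------
# oracle equivalence on small random tables
# ---------------------------------------------------------------------------

def test_operations_match_brute_force_on_small_tables():
    """Shares, composition, enrichment, imputation vs first principles."""
    rng = np.random.default_rng(42)
    comps = [OM, CYTO, Compartment.PERIPLASMIC]
    for trial in range(25):
        n_prot = int(rng.integers(2, 7))
        n_samp = int(rng.integers(2, 4))
        pids = [f"P{i}" for i in range(n_prot)]
        metas = [
            SampleMeta(f"s{j}", Fraction.OM_SARKOSYL, Condition.MUCIN)
            for j in range(n_samp)
        ]
        data = {}
        for m in metas:
            col = {}
            for i, pid in enumerate(pids):
                col[pid] = float(rng.uniform(5, 10))
            data[m.sample_id] = col
        # ensure at least one missing but never a fully-missing sample
        data[metas[0].sample_id][pids[-1]] = None if n_prot > 1 else 6.0
        labels = {pid: comps[i % 3] for i, pid in enumerate(pids)}
        table = build_table(data, metas)

        imputed = impute_missing(table, offset=0.5, floor=4.0)
        for m in metas:
            vals = data[m.sample_id]
            det = {p: v is not None for p, v in vals.items()}
            raw = {p: (v if v is not None else np.nan) for p, v in vals.items()}
            expect = brute_impute(raw, det, 0.5, 4.0)
            for pid in pids:
                assert imputed.log10_lfq.at[pid, m.sample_id] == pytest.approx(
                    expect[pid], rel=1e-12
                )
            shares = relative_abundance(imputed, m.sample_id)
            bshares = brute_shares(
                {p: imputed.log10_lfq.at[p, m.sample_id] for p in pids}, det
            )
            for pid in pids:
                assert shares[pid] == pytest.approx(bshares[pid], rel=1e-12, abs=1e-15)
            dist = compartment_distribution(imputed, labels, m.sample_id)
            bdist = brute_compartment_shares(bshares, labels)
            for comp, share in bdist.items():
                assert dist.shares[comp] == pytest.approx(share, rel=1e-12, abs=1e-15)
        for sa, sb in itertools.combinations([m.sample_id for m in metas], 2):
            da = compartment_distribution(imputed, labels, sa)
            db = compartment_distribution(imputed, labels, sb)
            for comp in set(da.shares) & set(db.shares):
                if db.shares[comp] > 0 and da.shares[comp] > 0:
                    f = enrichment_factor(da, db, comp).factor
                    bsa = brute_compartment_shares(
                        brute_shares(
                            {p: imputed.log10_lfq.at[p, sa] for p in pids},
                            {p: bool(imputed.detected.at[p, sa]) for p in pids},
                        ),
                        labels,
                    )
                    bsb = brute_compartment_shares(
                        brute_shares(
                            {p: imputed.log10_lfq.at[p, sb] for p in pids},
                            {p: bool(imputed.detected.at[p, sb]) for p in pids},
                        ),
                        labels,
                    )
                    assert f == pytest.approx(
                        brute_enrichment(bsa, bsb, comp), rel=1e-12
                    )
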