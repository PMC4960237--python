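"""Synthetic proteome/LFQ generator with full ground truth.

The generator emulates the statistical structure the analysis assumes:

* compartments drawn from a probability vector over the five
  Gram-negative compartments;
* log10 LFQ intensities per (protein, sample) drawn from a compartment-
  and fraction-specific normal (i.e. log-normal intensities), left-
  censored at a detection limit — censored cells are "not quantified";
* the sarkosyl OM fraction enriches OM proteins (mean shifted up
  +1.3 log10 by default) and depletes cytoplasmic/inner-membrane ones;
* external-predictor outputs derived deterministically from the true
  compartment (with Bernoulli lipoprotein/barrel/signal attributes for
  OM proteins), then corrupted per field with a configurable error
  rate: with probability ``predictor_error_rate`` the field is replaced
  by a uniform draw over the other admissible values (booleans flip,
  the SecretomeP score resamples Uniform(0,1));
* condition effects additive on the log10 scale, applied to the mucin
  condition (glucose is the reference state): ``n_responsive`` OM
  proteins get +/-``responsive_effect``, and ``n_exclusive_per_condition``
  OM proteins per side are forced undetected in the other condition
  (detection-limit semantics, not zero intensity);
* random sequences from a fixed amino-acid background table, with a
  literal PEP-CTERM construct (hydrophilic linker + PEP + hydrophobic
  segment + basic tail) planted at the C-terminus of flagged proteins.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import AbundanceTable, DISPLAY_FLOOR
from .types import (
    Compartment,
    Condition,
    Fraction,
    LipoproteinClass,
    PredictorProfile,
    ProteinRecord,
    SampleMeta,
)

log = logging.getLogger("omproteome")

SIM_COMPARTMENTS = (
    Compartment.CYTOPLASMIC,
    Compartment.INNER_MEMBRANE,
    Compartment.PERIPLASMIC,
    Compartment.OUTER_MEMBRANE,
    Compartment.EXTRACELLULAR,
)

#: Background amino-acid frequencies (typical Gram-negative proteome usage).
AA_BACKGROUND = {
    "A": 0.089, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.011,
    "Q": 0.044, "E": 0.061, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.106, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.015, "Y": 0.029, "V": 0.074,
}

HYDROPHOBIC = set("AILMFVWC")


def default_lfq_means() -> dict:
    """Compartment x fraction log10 means of the intensity mixture.

    Whole proteome is flat at 7.0.  The sarkosyl OM fraction shifts OM
    proteins up by 1.3 log10 and depletes cytoplasmic/inner-membrane
    proteins; the intracellular fraction does the opposite.  Sucrose-
    gradient baselines are flat (an OM ramp along the gradient is added
    separately, see ``gradient_om_ramp``).
    """
    C, I, P, O, E = SIM_COMPARTMENTS
    wp, ic, om, su = (
        Fraction.WHOLE_PROTEOME,
        Fraction.INTRACELLULAR,
        Fraction.OM_SARKOSYL,
        Fraction.SUCROSE_GRADIENT,
    )
    means = {}
    for comp in SIM_COMPARTMENTS:
        means[(comp, wp)] = 7.0
    means.update({(C, ic): 7.3, (I, ic): 6.6, (P, ic): 7.1, (O, ic): 6.0, (E, ic): 6.6})
    means.update({(C, om): 6.0, (I, om): 6.5, (P, om): 7.0, (O, om): 8.3, (E, om): 7.0})
    means.update({(C, su): 6.5, (I, su): 7.0, (P, su): 6.8, (O, su): 7.0, (E, su): 6.8})
    return means


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the `paper_like` shape."""

    n_proteins: int = 2176
    compartment_proportions: dict = field(
        default_factory=lambda: {
            Compartment.CYTOPLASMIC: 0.60,
            Compartment.INNER_MEMBRANE: 0.16,
            Compartment.PERIPLASMIC: 0.10,
            Compartment.OUTER_MEMBRANE: 0.04,
            Compartment.EXTRACELLULAR: 0.10,
        }
    )
    predictor_error_rate: float = 0.05
    lfq_means: dict = field(default_factory=default_lfq_means)
    lfq_sd: float = 0.4
    detection_limit: float = 6.0       # log10; censored below
    n_responsive: int = 23
    responsive_effect: float = 1.3     # log10 units (20-fold)
    n_exclusive_per_condition: int = 2
    n_pepcterm: int = 23
    gradient_fractions: int = 0        # 0 disables sucrose samples
    gradient_om_ramp: float = 2.0      # log10 span of the OM ramp
    p_lipoprotein_om: float = 0.3
    p_barrel_om: float = 0.6
    p_signal_om: float = 0.7
    min_length: int = 100
    max_length: int = 400
    display_floor: float = DISPLAY_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.compartment_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment proportions sum to {total}, not 1")
        if not 0.0 <= self.predictor_error_rate < 1.0:
            raise ValueError("predictor_error_rate must lie in [0, 1)")
        if self.detection_limit < self.display_floor:
            raise ValueError("detection_limit must be >= display floor")
        if self.lfq_sd <= 0:
            raise ValueError("lfq_sd must be positive")
        need = self.n_responsive + 2 * self.n_exclusive_per_condition
        if need > self.n_proteins:
            raise ValueError("responsive + exclusive counts exceed n_proteins")


@dataclass
class GroundTruth:
    """Per-protein truth the tests compare pipeline output against."""

    compartment: dict
    condition_effect: dict            # log10, added to mucin samples
    responsive_ids: set
    exclusive_mucin: set              # detected only under mucin
    exclusive_glucose: set
    pepcterm_ids: set
    true_profiles: list               # PredictorProfile before corruption

    @property
    def om_ids(self) -> set:
        return {
            pid
            for pid, comp in self.compartment.items()
            if comp is Compartment.OUTER_MEMBRANE
        }


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _true_profile(pid, comp, rng, cfg) -> PredictorProfile:
    if comp is Compartment.OUTER_MEMBRANE:
        lipo = rng.random() < cfg.p_lipoprotein_om
        barrel = rng.random() < cfg.p_barrel_om
        signal = rng.random() < cfg.p_signal_om
        return PredictorProfile(
            protein_id=pid,
            has_signal_peptide=signal,
            lipoprotein_class=(
                LipoproteinClass.LIPOPROTEIN
                if lipo
                else (
                    LipoproteinClass.OTHER_CLEAVED
                    if signal
                    else LipoproteinClass.NONE
                )
            ),
            secretomep_score=0.2 if signal else 0.8,
            tm_helix_count=0,
            bomp_category=1 if barrel else 0,
            cello_label=Compartment.OUTER_MEMBRANE,
            psortb_label=Compartment.OUTER_MEMBRANE,
        )
    signal = comp in (Compartment.PERIPLASMIC, Compartment.EXTRACELLULAR)
    tm = int(rng.integers(2, 12)) if comp is Compartment.INNER_MEMBRANE else 0
    return PredictorProfile(
        protein_id=pid,
        has_signal_peptide=signal,
        lipoprotein_class=(
            LipoproteinClass.OTHER_CLEAVED if signal else LipoproteinClass.NONE
        ),
        secretomep_score=0.2,
        tm_helix_count=tm,
        bomp_category=0,
        cello_label=comp,
        psortb_label=comp,
    )


_COMPARTMENT_VALUES = list(Compartment)
_LIPO_VALUES = list(LipoproteinClass)


def _corrupt_profile(profile: PredictorProfile, rng, eps: float) -> PredictorProfile:
    """Per-field corruption: replace with a uniform draw over other values."""

    def other(values, current):
        pool = [v for v in values if v != current]
        return pool[rng.integers(len(pool))]

    kwargs = {
        "protein_id": profile.protein_id,
        "has_signal_peptide": profile.has_signal_peptide,
        "lipoprotein_class": profile.lipoprotein_class,
        "secretomep_score": profile.secretomep_score,
        "tm_helix_count": profile.tm_helix_count,
        "bomp_category": profile.bomp_category,
        "cello_label": profile.cello_label,
        "psortb_label": profile.psortb_label,
    }
    if rng.random() < eps:
        kwargs["has_signal_peptide"] = not profile.has_signal_peptide
    if rng.random() < eps:
        kwargs["lipoprotein_class"] = other(_LIPO_VALUES, profile.lipoprotein_class)
    if rng.random() < eps:
        kwargs["secretomep_score"] = float(rng.random())
    if rng.random() < eps:
        kwargs["tm_helix_count"] = int(
            other(list(range(11)), profile.tm_helix_count)
        )
    if rng.random() < eps:
        kwargs["bomp_category"] = int(
            other(list(range(6)), profile.bomp_category)
        )
    if rng.random() < eps:
        kwargs["cello_label"] = other(_COMPARTMENT_VALUES, profile.cello_label)
    if rng.random() < eps:
        kwargs["psortb_label"] = other(_COMPARTMENT_VALUES, profile.psortb_label)
    return PredictorProfile(**kwargs)


def _random_sequence(rng, length, alphabet, probs) -> str:
    return "".join(rng.choice(alphabet, size=length, p=probs))


def plant_pepcterm_tail(rng) -> str:
    """A C-terminal construct meeting all scanner thresholds with margin.

    Hydrophilic linker, literal PEP, an 18-residue strongly hydrophobic
    segment, and four basic residues.
    """
    linker = "".join(rng.choice(list("DENQST"), size=3))
    tm = "".join(rng.choice(list("LIVF"), size=18))
    basics = "".join(rng.choice(list("KR"), size=4))
    return linker + "PEP" + tm + basics


def random_hydrophilic_records(
    n: int, seed: int, min_length: int = 80, max_length: int = 300
) -> list:
    """Random sequences weighted against hydrophobic residues.

    Negative control for the PEP-CTERM scanner's false-positive rate.
    """
    rng = np.random.default_rng(seed)
    weights = {
        aa: (f * 0.15 if aa in HYDROPHOBIC else f)
        for aa, f in AA_BACKGROUND.items()
    }
    alphabet = list(weights)
    probs = np.array([weights[a] for a in alphabet])
    probs = probs / probs.sum()
    records = []
    for i in range(n):
        length = int(rng.integers(min_length, max_length + 1))
        records.append(
            ProteinRecord(
                id=f"RAND_{i:04d}",
                sequence=_random_sequence(rng, length, alphabet, probs),
                description="synthetic hydrophilic background sequence",
            )
        )
    return records


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def _sample_plan(cfg: SimulationConfig) -> list:
    metas = []
    for cond in (Condition.MUCIN, Condition.GLUCOSE):
        metas.append(
            SampleMeta(f"wp_{cond.value}", Fraction.WHOLE_PROTEOME, cond)
        )
        metas.append(
            SampleMeta(f"ic_{cond.value}", Fraction.INTRACELLULAR, cond)
        )
        metas.append(SampleMeta(f"om_{cond.value}", Fraction.OM_SARKOSYL, cond))
        for k in range(1, cfg.gradient_fractions + 1):
            metas.append(
                SampleMeta(
                    f"suc_{cond.value}_f{k:02d}",
                    Fraction.SUCROSE_GRADIENT,
                    cond,
                    gradient_index=k,
                )
            )
    return metas


def generate(cfg: SimulationConfig):
    """Generate ``(records, profiles, table, truth)`` from the config.

    ``profiles`` are the corrupted (observed) predictor outputs; the
    pre-noise truth lives in ``truth.true_profiles``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = [f"SYN_{i:04d}" for i in range(n)]

    comps = rng.choice(
        len(SIM_COMPARTMENTS),
        size=n,
        p=[cfg.compartment_proportions[c] for c in SIM_COMPARTMENTS],
    )
    compartment = {pid: SIM_COMPARTMENTS[k] for pid, k in zip(ids, comps)}
    om_ids = [pid for pid in ids if compartment[pid] is Compartment.OUTER_MEMBRANE]

    need = cfg.n_responsive + 2 * cfg.n_exclusive_per_condition
    if len(om_ids) < need:
        raise ValueError(
            f"infeasible counts: drew {len(om_ids)} OM proteins but need "
            f"{need} for responsive/exclusive roles; raise the OM proportion "
            "or lower the counts"
        )
    special = rng.choice(len(om_ids), size=need, replace=False)
    special_ids = [om_ids[k] for k in special]
    responsive_ids = set(special_ids[: cfg.n_responsive])
    k = cfg.n_responsive
    exclusive_mucin = set(special_ids[k : k + cfg.n_exclusive_per_condition])
    k += cfg.n_exclusive_per_condition
    exclusive_glucose = set(special_ids[k : k + cfg.n_exclusive_per_condition])

    # signed condition effects (log10, added to mucin samples); alternate sign
    condition_effect = {pid: 0.0 for pid in ids}
    for j, pid in enumerate(sorted(responsive_ids)):
        sign = 1.0 if j % 2 == 0 else -1.0
        condition_effect[pid] = sign * cfg.responsive_effect

    pepcterm_ids = set(
        ids[k] for k in rng.choice(n, size=min(cfg.n_pepcterm, n), replace=False)
    )

    # sequences
    alphabet = list(AA_BACKGROUND)
    probs = np.array([AA_BACKGROUND[a] for a in alphabet])
    probs = probs / probs.sum()
    records = []
    for pid in ids:
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        desc = f"synthetic {compartment[pid].value} protein"
        if pid in pepcterm_ids:
            tail = plant_pepcterm_tail(rng)
            body = _random_sequence(rng, max(40, length - len(tail)), alphabet, probs)
            seq = body + tail
            desc += " with PEP-CTERM sorting signal"
        else:
            seq = _random_sequence(rng, length, alphabet, probs)
        records.append(ProteinRecord(id=pid, sequence=seq, description=desc))

    # predictor profiles: truth, then per-field corruption
    true_profiles = [
        _true_profile(pid, compartment[pid], rng, cfg) for pid in ids
    ]
    profiles = [
        _corrupt_profile(p, rng, cfg.predictor_error_rate)
        for p in true_profiles
    ]

    # LFQ intensities
    metas = _sample_plan(cfg)
    values = np.zeros((n, len(metas)))
    for j, meta in enumerate(metas):
        for i, pid in enumerate(ids):
            comp = compartment[pid]
            mu = cfg.lfq_means[(comp, meta.fraction)]
            if (
                meta.fraction is Fraction.SUCROSE_GRADIENT
                and comp is Compartment.OUTER_MEMBRANE
                and cfg.gradient_fractions > 1
            ):
                frac_pos = (meta.gradient_index - 1) / (cfg.gradient_fractions - 1)
                mu += cfg.gradient_om_ramp * (frac_pos - 0.5)
            if meta.condition is Condition.MUCIN:
                mu += condition_effect[pid]
            values[i, j] = rng.normal(mu, cfg.lfq_sd)

    detected = values >= cfg.detection_limit
    # forced condition exclusivity (detection-limit semantics)
    for i, pid in enumerate(ids):
        off = None
        if pid in exclusive_mucin:
            off = Condition.GLUCOSE
        elif pid in exclusive_glucose:
            off = Condition.MUCIN
        if off is not None:
            for j, meta in enumerate(metas):
                if meta.condition is off:
                    detected[i, j] = False
    # every sample keeps at least one detected value
    for j in range(len(metas)):
        if not detected[:, j].any():
            detected[np.argmax(values[:, j]), j] = True

    log_vals = np.where(detected, values, np.nan)
    table = AbundanceTable(
        log10_lfq=pd.DataFrame(log_vals, index=ids, columns=[m.sample_id for m in metas]),
        detected=pd.DataFrame(detected, index=ids, columns=[m.sample_id for m in metas]),
        samples=metas,
        display_floor=cfg.display_floor,
    )
    truth = GroundTruth(
        compartment=compartment,
        condition_effect=condition_effect,
        responsive_ids=responsive_ids,
        exclusive_mucin=exclusive_mucin,
        exclusive_glucose=exclusive_glucose,
        pepcterm_ids=pepcterm_ids,
        true_profiles=true_profiles,
    )
    log.info(
        "generate: n=%d (%d OM), %d samples, %d censored cells",
        n,
        len(om_ids),
        len(metas),
        int((~detected).sum()),
    )
    return records, profiles, table, truth


def benchmark_scenario(name: str) -> SimulationConfig:
    """Named, fully specified scenarios with fixed seeds.

    ``paper_like`` mirrors the study's shape (2176 proteins, 4% OM, two
    growth conditions, 23 responsive proteins, condition-exclusive
    proteins, 23 PEP-CTERM proteins); ``noiseless`` removes predictor
    noise and censoring so ground truth is recoverable exactly;
    ``sparse`` raises the detection limit to stress missing-value
    handling.
    """
    if name == "paper_like":
        return SimulationConfig(seed=1157)
    if name == "noiseless":
        return SimulationConfig(
            predictor_error_rate=0.0,
            lfq_sd=0.05,
            detection_limit=4.5,
            seed=1157,
        )
    if name == "sparse":
        return SimulationConfig(
            detection_limit=7.5,
            lfq_sd=0.5,
            seed=1157,
        )
    raise KeyError(f"unknown scenario {name!r}")
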