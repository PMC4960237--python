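"""Core domain types shared by all pipeline stages.

The pipeline works on three kinds of evidence for each protein of a
Gram-negative proteome: its sequence (:class:`ProteinRecord`), the outputs
of external localization/topology predictors (:class:`PredictorProfile`),
and label-free quantification (LFQ) intensities across subcellular
fractions and growth conditions (see :mod:`omproteome.table`).  The final
product of the classifier is a :class:`LocalizationCall` per protein.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field


class Compartment(str, enum.Enum):
    """Subcellular compartments of a Gram-negative cell (plus 'unknown')."""

    CYTOPLASMIC = "cytoplasmic"
    INNER_MEMBRANE = "inner_membrane"
    PERIPLASMIC = "periplasmic"
    OUTER_MEMBRANE = "outer_membrane"
    EXTRACELLULAR = "extracellular"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Compartment":
        """Parse a compartment label leniently ('inner membrane', 'OM', ...).

        Unrecognized strings map to UNKNOWN (callers may warn).
        """
        key = re.sub(r"[\s\-]+", "_", str(text).strip().lower())
        aliases = {
            "om": cls.OUTER_MEMBRANE,
            "outermembrane": cls.OUTER_MEMBRANE,
            "im": cls.INNER_MEMBRANE,
            "innermembrane": cls.INNER_MEMBRANE,
            "cytoplasm": cls.CYTOPLASMIC,
            "periplasm": cls.PERIPLASMIC,
        }
        if key in aliases:
            return aliases[key]
        try:
            return cls(key)
        except ValueError:
            return cls.UNKNOWN


class Fraction(str, enum.Enum):
    """Subcellular fractionation route a sample came from."""

    WHOLE_PROTEOME = "whole_proteome"
    INTRACELLULAR = "intracellular"
    OM_SARKOSYL = "om_sarkosyl"
    SUCROSE_GRADIENT = "sucrose_gradient"


class Condition(str, enum.Enum):
    """Growth substrate of the culture a sample derives from."""

    MUCIN = "mucin"
    GLUCOSE = "glucose"


class LipoproteinClass(str, enum.Enum):
    """LipoP-style classification: SpII lipoprotein, SpI-cleaved, or neither."""

    NONE = "none"
    LIPOPROTEIN = "lipoprotein"
    OTHER_CLEAVED = "other-cleaved"


# OM-confirmation criteria of the consensus classifier.
C1_DUAL_OM = "C1_dual_om"
C2_LIPOPROTEIN = "C2_lipoprotein"
C3_BETA_BARREL = "C3_beta_barrel"
C4_NONCLASSICAL = "C4_nonclassical"
ALL_CRITERIA = (C1_DUAL_OM, C2_LIPOPROTEIN, C3_BETA_BARREL, C4_NONCLASSICAL)

#: Label used for proteins confirmed as outer-membrane by >=1 criterion.
OM_CONFIRMED = "om_confirmed"

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry (locus-tag style id, e.g. ``Amuc_1098``)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictorProfile:
    """One protein's row of external-predictor outputs.

    The seven upstream tools are consumed, never re-implemented: signal
    peptide (SignalP-style boolean), lipoprotein class (LipoP-style),
    non-classical secretion score in [0, 1] (SecretomeP-style),
    transmembrane-helix count (TMHMM-style), beta-barrel category 0-5
    (BOMP-style; 0 = no barrel), and two independent whole-cell
    localization labels (CELLO- and PSORTb-style).
    """

    protein_id: str
    has_signal_peptide: bool
    lipoprotein_class: LipoproteinClass
    secretomep_score: float
    tm_helix_count: int
    bomp_category: int
    cello_label: Compartment
    psortb_label: Compartment

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not 0.0 <= self.secretomep_score <= 1.0:
            raise ValueError(
                f"{self.protein_id}: secretomep_score "
                f"{self.secretomep_score} outside [0, 1]"
            )
        if self.tm_helix_count < 0:
            raise ValueError(f"{self.protein_id}: negative tm_helix_count")
        if not 0 <= self.bomp_category <= 5:
            raise ValueError(
                f"{self.protein_id}: bomp_category {self.bomp_category} "
                "outside 0-5"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one LFQ sample: fraction, optional gradient index, condition."""

    sample_id: str
    fraction: Fraction
    condition: Condition
    gradient_index: int | None = None

    def __post_init__(self) -> None:
        if self.fraction is Fraction.SUCROSE_GRADIENT:
            if self.gradient_index is None:
                raise ValueError(
                    f"{self.sample_id}: sucrose-gradient sample needs a "
                    "gradient_index"
                )
            if not 1 <= self.gradient_index <= 24:
                raise ValueError(
                    f"{self.sample_id}: gradient_index "
                    f"{self.gradient_index} outside [1, 24]"
                )
        elif self.gradient_index is not None:
            raise ValueError(
                f"{self.sample_id}: gradient_index only valid for "
                "sucrose_gradient samples"
            )


@dataclass(frozen=True)
class LocalizationCall:
    """Final compartment assignment for one protein.

    ``label`` is either a :class:`Compartment` value or ``om_confirmed``;
    ``criterion_fired`` records which OM criteria supported the call.
    """

    protein_id: str
    label: str
    criterion_fired: frozenset = frozenset()
    in_preliminary_list: bool = False
    detected_in_proteomics: bool = True

    def __post_init__(self) -> None:
        fired = frozenset(self.criterion_fired)
        unknown = fired - set(ALL_CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        object.__setattr__(self, "criterion_fired", fired)
        if (self.label == OM_CONFIRMED) != bool(fired):
            raise ValueError(
                f"{self.protein_id}: label {self.label!r} inconsistent with "
                f"fired criteria {sorted(fired)}"
            )

    @property
    def is_om(self) -> bool:
        return self.label == OM_CONFIRMED


class Exclusivity(str, enum.Enum):
    """Detection exclusivity of a protein between two compared samples."""

    NONE = "none"
    ONLY_A = "only_a"
    ONLY_B = "only_b"


@dataclass(frozen=True)
class FoldChangeRecord:
    """Linear fold change a/b for one protein between two samples."""

    protein_id: str
    log10_a: float
    log10_b: float
    fold_change: float
    responsive: bool
    exclusivity: Exclusivity = Exclusivity.NONE

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.protein_id}: fold_change must be > 0")


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding-window mean hydropathy of one sequence.

    ``values[i]`` is the mean over the full window ``[i, i + window)``;
    positions without a full window are not represented, so
    ``len(values) == len(seq) - window + 1``.  ``residue_values`` keeps the
    per-residue scale values so interval refinement can trim charged flanks.
    """

    protein_id: str
    window: int
    values: tuple
    residue_values: tuple

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        expected = len(self.residue_values) - self.window + 1
        if len(self.values) != expected:
            raise ValueError(
                f"{self.protein_id}: profile length {len(self.values)} != "
                f"sequence length - window + 1 = {expected}"
            )


@dataclass(frozen=True)
class PepCtermHit:
    """A C-terminal sorting-signal hit: PEP motif, TM segment, basic cluster.

    All coordinates are 0-based, half-open on the protein sequence.
    """

    protein_id: str
    pep_start: int
    tm_interval: tuple
    basic_cluster_interval: tuple
    n_basic: int
    score: float
    sequence_length: int

    def __post_init__(self) -> None:
        ts, te = self.tm_interval
        bs, be = self.basic_cluster_interval
        ok = (
            0 <= self.pep_start < ts < te <= be <= self.sequence_length
            and ts <= bs
        )
        if not ok:
            raise ValueError(
                f"{self.protein_id}: inconsistent hit coordinates "
                f"pep={self.pep_start} tm={self.tm_interval} "
                f"basic={self.basic_cluster_interval} "
                f"len={self.sequence_length}"
            )
        if self.n_basic < 0:
            raise ValueError("n_basic must be non-negative")


@dataclass
class AuditTrail:
    """Ordered record of (stage, count, description) for the filtering chain."""

    stages: list = field(default_factory=list)

    def add(self, name: str, count: int, description: str = "") -> None:
        if count < 0:
            raise ValueError(f"stage {name!r}: negative count")
        self.stages.append((name, int(count), description))

    def counts(self) -> dict:
        return {name: count for name, count, _ in self.stages}

    def to_json_obj(self) -> list:
        return [
            {"stage": n, "count": c, "description": d}
            for n, c, d in self.stages
        ]

    @classmethod
    def from_json_obj(cls, obj: list) -> "AuditTrail":
        trail = cls()
        for item in obj:
            trail.add(item["stage"], item["count"], item.get("description", ""))
        return trail

    def to_text(self) -> str:
        lines = [
            f"{name:<28s} {count:>8d}  {desc}"
            for name, count, desc in self.stages
        ]
        return "\n".join(lines)
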