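"""Pipeline configuration: every threshold in one serializable place.

Defaults reflect the analysis conventions of the study design this
package implements: the preliminary OM candidate threshold at log10 LFQ
8.5, the display/imputation floor at 4.0, the >10-fold responsiveness
rule, a SecretomeP non-classical-secretion cutoff of 0.5, and standard
Kyte-Doolittle sliding-window parameters for the PEP-CTERM scanner.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class ClassifierConfig:
    """Thresholds of the preliminary filter and the four OM criteria."""

    lfq_threshold: float = 8.5      # log10 LFQ; candidates must exceed it
    secretomep_cutoff: float = 0.5  # non-classical secretion score cutoff
    strict_threshold: bool = True   # 'above 8.5' read as strictly greater
    display_floor: float = 4.0
    min_bomp_category: int = 1      # BOMP category >= this counts as a barrel

    def __post_init__(self) -> None:
        if not 0.0 <= self.secretomep_cutoff <= 1.0:
            raise ValueError("secretomep_cutoff must lie in [0, 1]")
        if self.lfq_threshold < self.display_floor:
            raise ValueError("lfq_threshold must be >= display floor")


@dataclass
class PepCtermConfig:
    """Heuristic scanner parameters for the C-terminal sorting signal."""

    window: int = 11            # hydropathy window (residues, odd)
    hydropathy_threshold: float = 1.6
    tm_min_len: int = 15        # residues
    tm_max_len: int = 25
    tm_len_slack: int = 5       # tolerance above tm_max_len after smoothing
    merge_gap: int = 2          # sub-threshold positions bridged within a run
    search_region: int = 35     # C-terminal residues searched for the motif
    motif: str = "PEP"
    max_gap_after_motif: int = 5
    basic_window: int = 10      # residues after the TM checked for basics
    min_basic: int = 2
    min_length: int = 60        # shortest protein scanned

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        if self.tm_min_len > self.tm_max_len:
            raise ValueError("tm_min_len must be <= tm_max_len")


@dataclass
class PipelineConfig:
    """Top-level configuration for `run-all` style analyses."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    pepcterm: PepCtermConfig = field(default_factory=PepCtermConfig)
    impute_offset: float = 0.5      # log10 units below the detected minimum
    fold_threshold: float = 10.0    # linear fold change for 'responsive'
    detected_only_shares: bool = True

    def __post_init__(self) -> None:
        if self.impute_offset <= 0:
            raise ValueError("impute_offset must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {}
        for name, sub_cls in (
            ("classifier", ClassifierConfig),
            ("pepcterm", PepCtermConfig),
        ):
            raw = data.pop(name, {})
            known = {f.name for f in fields(sub_cls)}
            extra = set(raw) - known
            if extra:
                raise ValueError(f"unknown {name} options: {sorted(extra)}")
            sub[name] = sub_cls(**raw)
        known = {f.name for f in fields(cls)} - {"classifier", "pepcterm"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown options: {sorted(extra)}")
        return cls(**sub, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
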