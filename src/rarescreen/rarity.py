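"""Common/rare variant classification and incidence-derived MAF thresholds.

For a Mendelian-dominant model a causal allele cannot be more frequent than
the disease itself, so the dominant MAF bound equals the disease incidence.
Under a recessive model affected individuals are homozygotes with frequency
p^2 = incidence, so the carrier-allele bound is p = sqrt(incidence); the
bound is expressed as 1/ceil(sqrt(1/incidence)), rounding the denominator
up so the threshold is conservative (incidence 1/5000 -> bound 1/71).

A variant is *common* when any public database reports a MAF at or above
the model threshold, or when more than ``max_control_carriers`` in-study
control samples carry it; *rare* when every known frequency is below the
threshold; and *unknown-rare* when it is absent from all databases and from
the control cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .cohort_io import CohortVariant, MafTable

__all__ = [
    "Rarity",
    "RarityConfig",
    "dominant_threshold",
    "recessive_threshold",
    "classify_variant",
    "is_rare",
    "partition_by_maf_knowledge",
]


class Rarity(str, Enum):
    RARE = "rare"
    COMMON = "common"
    UNKNOWN_RARE = "unknown_rare"


def dominant_threshold(incidence: float) -> float:
    """Dominant-model MAF bound: the incidence itself."""
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must lie in (0, 1)")
    return incidence


def recessive_threshold(incidence: float) -> float:
    """Recessive-model MAF bound 1/ceil(sqrt(1/incidence))."""
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must lie in (0, 1)")
    # tolerance keeps exact squares exact despite float noise in sqrt(1/x)
    return 1.0 / math.ceil(math.sqrt(1.0 / incidence) - 1e-9)


@dataclass
class RarityConfig:
    incidence: float = 1.0 / 5000.0
    max_control_carriers: int = 2
    dominant_maf_max: float = field(init=False)
    recessive_maf_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.dominant_maf_max = dominant_threshold(self.incidence)
        self.recessive_maf_max = recessive_threshold(self.incidence)
        assert self.recessive_maf_max >= self.dominant_maf_max

    def threshold(self, model: str) -> float:
        if model == "dominant":
            return self.dominant_maf_max
        if model == "recessive":
            return self.recessive_maf_max
        raise ValueError(f"unknown inheritance model {model!r}")


def classify_variant(
    v: CohortVariant, mafs: MafTable, cfg: RarityConfig, model: str = "dominant"
) -> Rarity:
    """Classify one QC-surviving variant against public MAFs and controls."""
    threshold = cfg.threshold(model)
    rec = mafs.lookup(v)
    if rec is None:
        return Rarity.UNKNOWN_RARE
    if any(af >= threshold for af in rec.known_afs()):
        return Rarity.COMMON
    if rec.hu_control_carriers > cfg.max_control_carriers:
        return Rarity.COMMON
    if not rec.known_afs() and rec.hu_control_carriers == 0:
        return Rarity.UNKNOWN_RARE
    return Rarity.RARE


def is_rare(v: CohortVariant, mafs: MafTable, cfg: RarityConfig, model: str = "dominant") -> bool:
    return classify_variant(v, mafs, cfg, model) is not Rarity.COMMON


def partition_by_maf_knowledge(
    variants: Sequence[CohortVariant], mafs: MafTable
) -> tuple[list[CohortVariant], list[CohortVariant]]:
    """Split variants into (known public MAF, no public MAF) strata."""
    known: list[CohortVariant] = []
    unknown: list[CohortVariant] = []
    for v in variants:
        rec = mafs.lookup(v)
        if rec is not None and rec.known_afs():
            known.append(v)
        else:
            unknown.append(v)
    return known, unknown
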