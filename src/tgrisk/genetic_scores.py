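"""Polygenic and causal-allele scoring with top-decile risk flags.

The weighted PRS multiplies each participant's effect-allele dosage at every
scored locus by the locus beta and sums across loci.  The causal-allele
count tallies TG-increasing alleles over a fixed panel of fine-mapped
variants (maximum 2 x panel size).  Two distinct top-decile rules are
provided because the PRS threshold is defined on the normal-TG reference
group (minimum score of its top 10%, ties flagged with >=) while the
causal-count threshold is the strict 90th percentile of the whole cohort
(flag only values strictly above it, so heavy integer ties can push the
flagged fraction past the nominal 10%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variant_classification import GenotypeMatrix

__all__ = [
    "PRSWeight",
    "PRSWeights",
    "CausalPanel",
    "RiskProfile",
    "score_prs",
    "count_causal_alleles",
    "top_decile_flag",
    "collective_flag",
    "build_risk_profiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRSWeight:
    variant_id: str
    effect_allele: str
    beta: float


@dataclass(frozen=True)
class PRSWeights:
    """PGS-catalog-style scoring entries (variant id, effect allele, beta)."""

    entries: tuple[PRSWeight, ...]

    def __post_init__(self) -> None:
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in PRS weights")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CausalPanel:
    """Fixed panel of potentially causal variants with their TG-increasing allele."""

    entries: tuple[tuple[str, str], ...]  # (variant_id, tg_increasing_allele)

    def __post_init__(self) -> None:
        ids = [vid for vid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in causal panel")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_alleles(self) -> int:
        return 2 * len(self.entries)


@dataclass(frozen=True)
class RiskProfile:
    """Per-participant derived genetic risk quantities."""

    participant_id: str
    prs: float
    causal_allele_count: int
    rare_carrier: bool = False
    common_carrier: bool = False
    top10_prs: bool = False
    top10_causal: bool = False
    any_risk: bool = False


def _oriented_dosage(
    genotypes: GenotypeMatrix,
    variant_id: str,
    allele: str,
    lookup: Mapping[str, tuple[str, str]],
    mismatches: list[str],
) -> np.ndarray:
    """Dosage of ``allele`` at a locus, resolved against VCF ref/alt.

    Missing genotypes contribute 0.  Records a mismatch when the allele is
    neither ref nor alt.
    """
    dos = genotypes.dosage(variant_id).astype(np.float64)
    missing = dos < 0
    ref, alt = lookup[variant_id]
    if allele == alt:
        out = dos
    elif allele == ref:
        out = 2.0 - dos
    else:
        mismatches.append(variant_id)
        return np.zeros_like(dos)
    out = out.copy()
    out[missing] = 0.0
    return out


def score_prs(
    genotypes: GenotypeMatrix,
    weights: PRSWeights,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Weighted polygenic score per participant: sum of effect-allele dosage x beta.

    ``alleles`` maps variant id -> (ref, alt) for effect-allele orientation;
    when omitted the effect allele is assumed to be the ALT allele of every
    locus.  A weight whose variant id is absent from the genotype matrix, or
    whose effect allele matches neither ref nor alt, raises a ValueError
    listing the offending ids.  Missing dosages contribute 0 (logged).
    """
    unknown = [e.variant_id for e in weights.entries if e.variant_id not in genotypes]
    if unknown:
        raise ValueError(f"PRS weights reference unknown variant ids: {unknown}")
    n = genotypes.n_participants
    scores = np.zeros(n)
    mismatches: list[str] = []
    n_missing = 0
    for e in weights.entries:
        if alleles is None:
            dos = genotypes.dosage(e.variant_id).astype(np.float64)
            miss = dos < 0
            dos = np.where(miss, 0.0, dos)
        else:
            raw = genotypes.dosage(e.variant_id)
            miss = raw < 0
            dos = _oriented_dosage(genotypes, e.variant_id, e.effect_allele, alleles, mismatches)
        n_missing += int(miss.sum())
        scores += dos * e.beta
    if mismatches:
        raise ValueError(f"effect allele matches neither ref nor alt for: {mismatches}")
    if n_missing:
        logger.info("score_prs: %d missing genotypes contributed 0", n_missing)
    return dict(zip(genotypes.participant_ids, scores.tolist()))


def count_causal_alleles(
    genotypes: GenotypeMatrix,
    panel: CausalPanel,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, int]:
    """TG-increasing allele count per participant over the causal panel.

    Integer in [0, 2 x panel size]; missing genotypes contribute 0.
    """
    unknown = [vid for vid, _ in panel.entries if vid not in genotypes]
    if unknown:
        raise KeyError(f"causal panel references unknown variant ids: {unknown}")
    counts = np.zeros(genotypes.n_participants)
    mismatches: list[str] = []
    for vid, inc_allele in panel.entries:
        if alleles is None:
            dos = genotypes.dosage(vid).astype(np.float64)
            dos = np.where(dos < 0, 0.0, dos)
        else:
            dos = _oriented_dosage(genotypes, vid, inc_allele, alleles, mismatches)
        counts += dos
    if mismatches:
        raise ValueError(f"increasing allele matches neither ref nor alt for: {mismatches}")
    return {pid: int(c) for pid, c in zip(genotypes.participant_ids, counts)}


def top_decile_flag(
    values: Mapping[str, float],
    reference_group: Iterable[str],
    rule: str,
    decile: float = 0.10,
) -> dict[str, bool]:
    """Flag participants in the top decile of a score.

    rule="min_top10_of_reference" (PRS): the threshold is the smallest value
    among the top ceil(decile * |reference|) reference members; every
    participant with value >= threshold is flagged (the threshold-setting
    member is flagged).

    rule="strict_gt_cohort_p90" (causal counts): the threshold is the
    (1 - decile) percentile over all participants in ``values``; only values
    strictly above it are flagged, so nobody is flagged when all values tie.
    """
    if rule == "min_top10_of_reference":
        ref = [values[p] for p in reference_group]
        if not ref:
            raise ValueError("empty reference group")
        k = math.ceil(decile * len(ref))
        threshold = sorted(ref, reverse=True)[k - 1]
        return {p: v >= threshold for p, v in values.items()}
    if rule == "strict_gt_cohort_p90":
        if not values:
            raise ValueError("empty cohort")
        threshold = float(np.percentile(list(values.values()), 100 * (1 - decile)))
        return {p: v > threshold for p, v in values.items()}
    raise ValueError(f"unknown rule {rule!r}")


def collective_flag(profiles: Sequence[RiskProfile]) -> list[RiskProfile]:
    """Set any_risk = OR of the four factor flags on every profile."""
    return [
        replace(
            p,
            any_risk=p.rare_carrier or p.common_carrier or p.top10_prs or p.top10_causal,
        )
        for p in profiles
    ]


def build_risk_profiles(
    prs: Mapping[str, float],
    causal_counts: Mapping[str, int],
    rare_carrier: Mapping[str, bool],
    common_carrier: Mapping[str, bool],
    top10_prs: Mapping[str, bool],
    top10_causal: Mapping[str, bool],
) -> list[RiskProfile]:
    """Assemble per-participant profiles and set the collective flag."""
    profiles = [
        RiskProfile(
            participant_id=pid,
            prs=prs[pid],
            causal_allele_count=causal_counts.get(pid, 0),
            rare_carrier=bool(rare_carrier.get(pid, False)),
            common_carrier=bool(common_carrier.get(pid, False)),
            top10_prs=bool(top10_prs.get(pid, False)),
            top10_causal=bool(top10_causal.get(pid, False)),
        )
        for pid in sorted(prs)
    ]
    return collective_flag(profiles)
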