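"""Variant classification and carriage calling in the canonical TG genes.

Variants inside the five canonical triglyceride-metabolism genes (LPL,
GPIHBP1, APOA5, LMF1, APOC2) are split into rare (cohort MAF <= 1%) and
common (MAF > 1%) sets, filtered to those predicted functional in silico
(CADD PHRED > 10 plus a damaging/deleterious call by at least one of
PolyPhen-2, SIFT or MutationTaster when any such classification is
available), and each participant's carriage per gene is called as biallelic
(a homozygous-minor variant, or two or more heterozygous variants in one
gene — a phase-unaware compound-heterozygous proxy), heterozygous, or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CANONICAL_GENES",
    "GENE_REGIONS",
    "AnnotatedVariant",
    "GenotypeMatrix",
    "CarriageCall",
    "compute_maf",
    "minor_allele_dosages",
    "is_likely_functional",
    "split_by_maf",
    "call_carriage",
    "any_carrier",
    "write_gene_bed",
    "read_gene_bed",
]

CANONICAL_GENES = ("LPL", "GPIHBP1", "APOA5", "LMF1", "APOC2")

# GRCh38 coordinates of the canonical TG gene regions (1-based inclusive).
GENE_REGIONS: dict[str, tuple[str, int, int]] = {
    "LPL": ("chr8", 19939253, 19967259),
    "GPIHBP1": ("chr8", 143213218, 143217170),
    "APOA5": ("chr11", 116789373, 116792420),
    "LMF1": ("chr16", 853634, 970984),
    "APOC2": ("chr19", 44946051, 44949565),
}


@dataclass
class AnnotatedVariant:
    """One biallelic variant with gene label and deleteriousness annotations.

    ``polyphen`` is "damaging"/"benign" or None (absent); ``sift`` is
    "deleterious"/"tolerated" or None; ``mtaster_score`` in [0, 1] or None.
    ``maf`` is the minor allele frequency in the analysis cohort (filled in
    by :func:`compute_maf` when read from a VCF without it).
    """

    variant_id: str
    gene: Optional[str]
    chrom: str
    pos: int
    ref: str
    alt: str
    cadd_phred: Optional[float] = None
    polyphen: Optional[str] = None
    sift: Optional[str] = None
    mtaster_score: Optional[float] = None
    clinvar_class: Optional[str] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene is not None and self.gene not in CANONICAL_GENES:
            raise ValueError(f"unknown gene label {self.gene!r}; expected one of {CANONICAL_GENES}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF must lie in [0, 0.5] after minor-allele orientation, got {self.maf}")
        if self.polyphen is not None and self.polyphen not in ("damaging", "benign"):
            raise ValueError(f"polyphen must be 'damaging'/'benign'/None, got {self.polyphen!r}")
        if self.sift is not None and self.sift not in ("deleterious", "tolerated"):
            raise ValueError(f"sift must be 'deleterious'/'tolerated'/None, got {self.sift!r}")


class GenotypeMatrix:
    """Participants x variants allele-dosage table.

    Dosages count ALT alleles: 0, 1, 2, or -1 for a missing genotype.
    Missing genotypes are excluded from allele-frequency denominators and
    contribute nothing to dosage sums.
    """

    def __init__(
        self,
        participant_ids: Sequence[str],
        variant_ids: Sequence[str],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(participant_ids), len(variant_ids)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(participant_ids)} participants x {len(variant_ids)} variants"
            )
        bad = ~np.isin(dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1 (missing), 0, 1, 2}")
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("variant ids must be unique")
        self.participant_ids = list(participant_ids)
        self.variant_ids = list(variant_ids)
        self.dosages = dosages
        self._vidx = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._vidx

    def dosage(self, variant_id: str) -> np.ndarray:
        """ALT-allele dosage column for one variant (length n_participants)."""
        try:
            return self.dosages[:, self._vidx[variant_id]]
        except KeyError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None


@dataclass(frozen=True)
class CarriageCall:
    """Carriage status of one participant in one gene."""

    participant_id: str
    gene: str
    status: str  # "BIALLELIC" | "HETEROZYGOUS" | "NONE"
    contributing_variants: tuple[str, ...] = ()


def compute_maf(genotypes: GenotypeMatrix, variant_id: str) -> float:
    """Cohort minor allele frequency of one variant.

    Allele count of the less-frequent allele over 2 x non-missing
    participants; missing genotypes are excluded from the denominator.
    """
    dos = genotypes.dosage(variant_id)
    ok = dos >= 0
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"all genotypes missing for {variant_id!r}")
    af = float(dos[ok].sum()) / (2 * n)
    return min(af, 1.0 - af)


def minor_allele_dosages(genotypes: GenotypeMatrix, variant_id: str) -> np.ndarray:
    """Dosage column oriented to the minor allele (missing stays -1)."""
    dos = genotypes.dosage(variant_id)
    ok = dos >= 0
    if not ok.any():
        raise ValueError(f"all genotypes missing for {variant_id!r}")
    af = float(dos[ok].sum()) / (2 * int(ok.sum()))
    if af <= 0.5:
        return dos
    flipped = (2 - dos).astype(np.int8)
    flipped[~ok] = -1
    return flipped


def is_likely_functional(
    variant: AnnotatedVariant,
    cadd_threshold: float = 10.0,
    mtaster_threshold: float = 0.5,
    strict: bool = False,
) -> bool:
    """In-silico deleteriousness filter.

    True iff CADD PHRED > ``cadd_threshold`` AND at least one secondary
    predictor calls the variant damaging: PolyPhen-2 "damaging", SIFT
    "deleterious", or MutationTaster score > ``mtaster_threshold``.  When no
    secondary classification is available the second clause is vacuously
    satisfied, unless ``strict`` is set (then at least one available
    secondary call is required).
    """
    if variant.cadd_phred is None or variant.cadd_phred <= cadd_threshold:
        return False
    available = [
        variant.polyphen is not None,
        variant.sift is not None,
        variant.mtaster_score is not None,
    ]
    if not any(available):
        return not strict
    return (
        variant.polyphen == "damaging"
        or variant.sift == "deleterious"
        or (variant.mtaster_score is not None and variant.mtaster_score > mtaster_threshold)
    )


def split_by_maf(
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    maf_threshold: float = 0.01,
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Split variants into (rare, common) by cohort MAF; fills ``maf`` in place.

    Rare means MAF <= ``maf_threshold`` in the analysis cohort (not an
    external reference); common means MAF > threshold.  The two sets are
    analyzed separately downstream.
    """
    rare, common = [], []
    for v in variants:
        v.maf = compute_maf(genotypes, v.variant_id)
        (rare if v.maf <= maf_threshold else common).append(v)
    return rare, common


def call_carriage(
    genotypes: GenotypeMatrix,
    functional_variants: Sequence[AnnotatedVariant],
    maf_class: str = "rare",
    maf_threshold: float = 0.01,
) -> list[CarriageCall]:
    """Call per-participant, per-gene carriage of functional variants.

    For each gene: BIALLELIC if the participant is homozygous for the minor
    allele of any functional variant or heterozygous at >= 2 distinct
    functional variants in that gene (phase-unaware compound-het proxy);
    else HETEROZYGOUS if heterozygous at >= 1; else NONE.  Only variants in
    the requested MAF class ("rare": MAF <= threshold; "common": MAF >
    threshold) contribute — rare and common carriage are analyzed
    separately.  Returns one call per participant per canonical gene.
    """
    if maf_class not in ("rare", "common"):
        raise ValueError(f"maf_class must be 'rare' or 'common', got {maf_class!r}")
    by_gene: dict[str, list[AnnotatedVariant]] = {g: [] for g in CANONICAL_GENES}
    for v in functional_variants:
        if v.variant_id not in genotypes:
            raise KeyError(f"unknown variant id {v.variant_id!r}")
        if v.gene is None:
            continue
        maf = v.maf if v.maf is not None else compute_maf(genotypes, v.variant_id)
        in_class = maf <= maf_threshold if maf_class == "rare" else maf > maf_threshold
        if in_class:
            by_gene[v.gene].append(v)

    calls: list[CarriageCall] = []
    pids = genotypes.participant_ids
    for gene in CANONICAL_GENES:
        vs = by_gene[gene]
        if not vs:
            calls.extend(CarriageCall(pid, gene, "NONE") for pid in pids)
            continue
        dmat = np.stack([minor_allele_dosages(genotypes, v.variant_id) for v in vs], axis=1)
        carried = dmat >= 1  # missing (-1) never counts as carried
        hom = (dmat == 2).any(axis=1)
        n_carried = carried.sum(axis=1)
        for i, pid in enumerate(pids):
            if hom[i] or n_carried[i] >= 2:
                status = "BIALLELIC"
            elif n_carried[i] == 1:
                status = "HETEROZYGOUS"
            else:
                status = "NONE"
            contrib = tuple(v.variant_id for j, v in enumerate(vs) if carried[i, j]) if status != "NONE" else ()
            calls.append(CarriageCall(pid, gene, status, contrib))
    return calls


def any_carrier(calls: Iterable[CarriageCall]) -> dict[str, bool]:
    """Overall any-gene carriage flag (heterozygous or biallelic in any gene)."""
    flag: dict[str, bool] = {}
    for c in calls:
        flag.setdefault(c.participant_id, False)
        if c.status != "NONE":
            flag[c.participant_id] = True
    return flag


def write_gene_bed(path, regions: Mapping[str, tuple[str, int, int]] = GENE_REGIONS) -> None:
    """Write gene regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for gene, (chrom, start, end) in regions.items():
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")


def read_gene_bed(path) -> dict[str, tuple[str, int, int]]:
    """Read gene regions from BED; returns {gene: (chrom, start_1based, end)}."""
    regions: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            regions[name] = (chrom, int(start) + 1, int(end))
    return regions
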