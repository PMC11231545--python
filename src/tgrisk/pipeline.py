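"""End-to-end pipeline: phenotyping -> classification -> scoring -> enrichment,
with small-cell privacy masking on every human-readable output.

The masking layer mirrors restricted-data reporting policy: any count below
the threshold (default 20) is rendered as "<=20" and its percentage as a
5-point band ("35–40%"); when the parent group total is itself below the
threshold, its percentage is banded as well.  An alternative mode renders
the percentage of a hidden subgroup of a disclosed parent as an upper bound
("<=50%").
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .enrichment_stats import ContingencyTable2x2, EnrichmentResult, select_and_run_test, additive_regression
from .genetic_scores import (
    CausalPanel,
    PRSWeights,
    build_risk_profiles,
    count_causal_alleles,
    score_prs,
    top_decile_flag,
)
from .synthetic_cohort import SimulationConfig, SyntheticCohort, simulate_cohort
from .tg_phenotyping import AdjustmentTable, ParticipantRecord, phenotype_cohort
from .variant_classification import (
    AnnotatedVariant,
    GenotypeMatrix,
    any_carrier,
    call_carriage,
    is_likely_functional,
    minor_allele_dosages,
    split_by_maf,
)

__all__ = ["PipelineConfig", "MaskedCount", "mask_count", "run_pipeline", "analyze_cohort"]

logger = logging.getLogger(__name__)

FACTORS = ("rare_carrier", "common_carrier", "top10_prs", "top10_causal", "any_risk")
PRIMARY_CASE_GROUPS = ("SEVERE", "MILD_MODERATE")
SENSITIVITY_CASE_GROUPS = ("AHA_SEVERE", "TOP1PCT")


@dataclass
class PipelineConfig:
    """Every fixed constant of the analysis, in one overridable place."""

    input_dir: Optional[str] = None  # read a written cohort; None = simulate
    severe_tg: float = 885.0  # mg/dl (10 mmol/L)
    mild_lower: float = 300.0
    aha_severe_tg: float = 500.0
    top_percent: float = 0.01
    normal_band: tuple[float, float] = (0.25, 0.75)
    maf_threshold: float = 0.01
    cadd_threshold: float = 10.0
    mtaster_threshold: float = 0.5
    strict_functional: bool = False
    decile: float = 0.10
    common_assoc_p: float = 0.05
    masking_enabled: bool = True
    mask_n_threshold: int = 20
    mask_pct_band: int = 5
    mask_le_mode: bool = False
    seed: int = 0
    adjustment_factors: dict[str, float] = field(
        default_factory=lambda: dict(AdjustmentTable.default().factors)
    )
    simulation: dict = field(default_factory=dict)  # overrides for SimulationConfig

    def __post_init__(self) -> None:
        for name in ("severe_tg", "mild_lower", "aha_severe_tg", "maf_threshold", "cadd_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if 100 % self.mask_pct_band != 0:
            raise ValueError(f"mask_pct_band must divide 100, got {self.mask_pct_band}")

    @property
    def adjustment(self) -> AdjustmentTable:
        return AdjustmentTable(self.adjustment_factors)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "normal_band" in data:
            data["normal_band"] = tuple(data["normal_band"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["normal_band"] = list(self.normal_band)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class MaskedCount:
    """A count with its privacy-safe rendering."""

    raw_n: int
    display: str
    pct_display: str


def mask_count(
    n: int,
    group_n: int,
    n_threshold: int = 20,
    pct_band: int = 5,
    enabled: bool = True,
    le_mode: bool = False,
) -> MaskedCount:
    """Render a subgroup count under the small-cell reporting policy.

    Counts >= the threshold print exactly with the percentage to one
    decimal.  Smaller counts print as "<=<threshold>" with the percentage as
    a ``pct_band``-point band containing the true value; if the parent group
    is itself at or under the threshold its percentage is banded too.  With
    ``le_mode`` the hidden percentage of a disclosed parent is instead an
    upper bound ("<=x%", x = the percentage the threshold count represents).
    """
    if n < 0 or n > group_n:
        raise ValueError(f"need 0 <= n <= group_n, got n={n}, group_n={group_n}")
    if group_n == 0:
        raise ValueError("group_n must be positive")
    pct = 100.0 * n / group_n
    if not enabled or (n >= n_threshold and group_n > n_threshold):
        return MaskedCount(n, str(n), f"{pct:.1f}%")
    display = f"≤{n_threshold}" if n < n_threshold else str(n)
    if le_mode and group_n > n_threshold:
        bound = 100.0 * n_threshold / group_n
        return MaskedCount(n, display, f"≤{bound:.0f}%")
    lo = pct_band * math.floor(pct / pct_band)
    if lo >= 100:
        lo = 100 - pct_band
    return MaskedCount(n, display, f"{lo}–{lo + pct_band}%")


def _mask(cfg: PipelineConfig, n: int, group_n: int) -> MaskedCount:
    return mask_count(
        n,
        group_n,
        n_threshold=cfg.mask_n_threshold,
        pct_band=cfg.mask_pct_band,
        enabled=cfg.masking_enabled,
        le_mode=cfg.mask_le_mode,
    )


def analyze_cohort(
    participants: Sequence[ParticipantRecord],
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeMatrix,
    prs_weights: PRSWeights,
    causal_panel: CausalPanel,
    config: PipelineConfig,
) -> dict:
    """Run phenotyping, classification, scoring and enrichment; return all tables."""
    pheno = phenotype_cohort(
        participants,
        config.adjustment,
        severe_threshold=config.severe_tg,
        mild_lower=config.mild_lower,
        aha_threshold=config.aha_severe_tg,
        normal_band=config.normal_band,
        top_percent=config.top_percent,
    )
    logger.info(
        "phenotyping: %d participants in, %d with measurements, %d excluded",
        len(participants), len(pheno), int(pheno["excluded"].sum()),
    )
    analyzed = pheno[~pheno["excluded"]]
    tg_map = dict(zip(analyzed["participant_id"], analyzed["adjusted_median_tg"]))

    canonical = [v for v in variants if v.gene is not None]
    rare, common = split_by_maf(canonical, genotypes, config.maf_threshold)
    func_kw = dict(
        cadd_threshold=config.cadd_threshold,
        mtaster_threshold=config.mtaster_threshold,
        strict=config.strict_functional,
    )
    rare_func = [v for v in rare if is_likely_functional(v, **func_kw)]
    common_func = [v for v in common if is_likely_functional(v, **func_kw)]
    logger.info(
        "classification: %d canonical variants, %d rare (%d functional), %d common (%d functional)",
        len(canonical), len(rare), len(rare_func), len(common), len(common_func),
    )

    # data-driven common-variant selection: keep functional common variants
    # positively associated with adjusted TG (additive model on log TG)
    selected_common: list[AnnotatedVariant] = []
    for v in common_func:
        dos = minor_allele_dosages(genotypes, v.variant_id)
        dmap = {pid: int(d) for pid, d in zip(genotypes.participant_ids, dos) if pid in tg_map}
        try:
            beta, _, p = additive_regression(tg_map, dmap)
        except ValueError:
            continue
        if beta > 0 and p <= config.common_assoc_p:
            selected_common.append(v)
    logger.info("common-variant selection: %d of %d kept", len(selected_common), len(common_func))

    rare_calls = call_carriage(genotypes, rare_func, "rare", config.maf_threshold)
    common_calls = call_carriage(genotypes, selected_common, "common", config.maf_threshold)
    rare_carrier = any_carrier(rare_calls)
    common_carrier = any_carrier(common_calls)

    alleles = {v.variant_id: (v.ref, v.alt) for v in variants}
    prs = score_prs(genotypes, prs_weights, alleles)
    causal_counts = count_causal_alleles(genotypes, causal_panel, alleles)

    cat_map = dict(zip(analyzed["participant_id"], analyzed["category"]))
    normal_ids = [pid for pid, c in cat_map.items() if c == "NORMAL"]
    scored = {pid: prs[pid] for pid in cat_map}  # non-excluded, phenotyped participants
    top10_prs = top_decile_flag(scored, normal_ids, "min_top10_of_reference", config.decile)
    counts_scored = {pid: causal_counts[pid] for pid in cat_map}
    top10_causal = top_decile_flag(counts_scored, normal_ids, "strict_gt_cohort_p90", config.decile)

    profiles = build_risk_profiles(
        scored, counts_scored, rare_carrier, common_carrier, top10_prs, top10_causal
    )

    flags_by_pid = {
        p.participant_id: {f: getattr(p, f) for f in FACTORS} for p in profiles
    }
    groups: dict[str, list[str]] = {g: [] for g in PRIMARY_CASE_GROUPS + SENSITIVITY_CASE_GROUPS + ("NORMAL",)}
    for row in analyzed.to_dict("records"):
        pid = row["participant_id"]
        if row["category"] in groups:
            groups[row["category"]].append(pid)
        if row["aha_severe"]:
            groups["AHA_SEVERE"].append(pid)
        if row["top1pct"]:
            groups["TOP1PCT"].append(pid)

    results: list[EnrichmentResult] = []
    controls = groups["NORMAL"]
    for case_group in PRIMARY_CASE_GROUPS + SENSITIVITY_CASE_GROUPS:
        cases = groups[case_group]
        if not cases:
            logger.warning("skipping empty case group %s", case_group)
            continue
        for factor in FACTORS:
            a = sum(flags_by_pid[pid][factor] for pid in cases)
            c = sum(flags_by_pid[pid][factor] for pid in controls)
            table = ContingencyTable2x2(a=a, b=len(cases) - a, c=c, d=len(controls) - c)
            results.append(select_and_run_test(table, label=f"{factor}:{case_group}_vs_NORMAL"))

    return {
        "phenotypes": pheno,
        "rare_calls": rare_calls,
        "common_calls": common_calls,
        "selected_common": selected_common,
        "rare_functional": rare_func,
        "profiles": profiles,
        "groups": groups,
        "enrichment": results,
        "participants": list(participants),
    }


def _median_iqr(values: Sequence[float]) -> str:
    if len(values) == 0:
        return "-"
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{med:.1f} [{q1:.1f}–{q3:.1f}]"


def _write_report(out_dir: str, res: dict, cfg: PipelineConfig) -> None:
    pheno = res["phenotypes"]
    groups = res["groups"]
    profiles = {p.participant_id: p for p in res["profiles"]}
    demo = {p.participant_id: p for p in res["participants"]}
    lines = ["# HTG genetic risk profile report", ""]
    lines.append(
        f"Thresholds: severe > {cfg.severe_tg:g} mg/dl; mild-to-moderate "
        f"{cfg.mild_lower:g}–{cfg.severe_tg:g} mg/dl; AHA severe > {cfg.aha_severe_tg:g} mg/dl; "
        f"rare MAF ≤ {cfg.maf_threshold:g}; CADD > {cfg.cadd_threshold:g}; "
        f"masking {'on' if cfg.masking_enabled else 'off'}."
    )
    lines.append("")

    # cohort characteristics by primary category
    tg_by = {pid: tg for pid, tg in zip(pheno["participant_id"], pheno["adjusted_median_tg"])}
    lines.append("## Cohort characteristics")
    lines.append("")
    lines.append("| | " + " | ".join(("SEVERE", "MILD_MODERATE", "NORMAL")) + " |")
    lines.append("|---|---|---|---|")
    row_n, row_age, row_f, row_bmi, row_tg = ["| N "], ["| Age, median [IQR] "], ["| Female, n (%) "], ["| BMI, median [IQR] "], ["| Adjusted TG, median [IQR] "]
    total = len(pheno[~pheno["excluded"]])
    for g in ("SEVERE", "MILD_MODERATE", "NORMAL"):
        ids = groups[g]
        gn = len(ids)
        mc = _mask(cfg, gn, max(total, 1))
        row_n.append(f"| {mc.display} ")
        ages = [demo[i].age_years for i in ids]
        bmis = [demo[i].bmi for i in ids]
        tgs = [tg_by[i] for i in ids]
        row_age.append(f"| {_median_iqr(ages)} ")
        if gn:
            nf = sum(1 for i in ids if demo[i].sex == "F")
            f_mc = _mask(cfg, nf, gn)
            row_f.append(f"| {f_mc.display} ({f_mc.pct_display}) ")
        else:
            row_f.append("| - ")
        row_bmi.append(f"| {_median_iqr(bmis)} ")
        row_tg.append(f"| {_median_iqr(tgs)} ")
    for row in (row_n, row_age, row_f, row_bmi, row_tg):
        lines.append("".join(row) + "|")
    lines.append("")

    # frequency table (factor x category)
    lines.append("## Genetic risk factor frequencies")
    lines.append("")
    all_groups = PRIMARY_CASE_GROUPS + ("NORMAL",) + SENSITIVITY_CASE_GROUPS
    lines.append("| factor | " + " | ".join(all_groups) + " |")
    lines.append("|" + "---|" * (len(all_groups) + 1))
    freq_rows = []
    for factor in FACTORS:
        cells = [f"| {factor} "]
        for g in all_groups:
            ids = groups[g]
            if not ids:
                cells.append("| - ")
                continue
            nf = sum(1 for i in ids if getattr(profiles[i], factor))
            mc = _mask(cfg, nf, len(ids))
            cells.append(f"| {mc.display} ({mc.pct_display}) ")
            freq_rows.append(
                {"factor": factor, "group": g, "n": mc.display, "pct": mc.pct_display, "group_n": _mask(cfg, len(ids), max(total, 1)).display}
            )
        lines.append("".join(cells) + "|")
    lines.append("")
    pd.DataFrame(freq_rows, columns=["factor", "group", "n", "pct", "group_n"]).to_csv(
        os.path.join(out_dir, "frequencies.csv"), index=False
    )

    # enrichment / forest table
    lines.append("## Enrichment (case group vs NORMAL)")
    lines.append("")
    lines.append("| comparison | test | OR | 95% CI | p |")
    lines.append("|---|---|---|---|---|")
    for r in res["enrichment"]:
        lines.append(
            f"| {r.label} | {r.test_used} | {r.odds_ratio:.2f} | "
            f"[{r.ci95[0]:.2f}–{r.ci95[1]:.2f}] | {r.p_value:.3g} |"
        )
    lines.append("")
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write("\n".join(lines))


def run_pipeline(config: PipelineConfig, out_dir, cohort: SyntheticCohort | None = None) -> dict:
    """Execute all stages and write the report bundle to ``out_dir``.

    Inputs come from (in order of precedence) the ``cohort`` argument, the
    files under ``config.input_dir``, or a fresh simulation seeded with
    ``config.seed``.
    """
    os.makedirs(out_dir, exist_ok=True)
    if cohort is not None:
        participants = cohort.participants
        variants, genotypes = cohort.variants, cohort.genotypes
        prs_weights, causal_panel = cohort.prs_weights, cohort.causal_panel
    elif config.input_dir:
        participants = _io.read_participant_tables(config.input_dir)
        variants, genotypes = _io.read_vcf(os.path.join(config.input_dir, "genotypes.vcf"))
        prs_weights = _io.read_prs_weights(os.path.join(config.input_dir, "prs_weights.txt"))
        causal_panel = _io.read_causal_panel(os.path.join(config.input_dir, "causal_panel.csv"))
    else:
        sim = simulate_cohort(SimulationConfig(seed=config.seed, **config.simulation))
        participants = sim.participants
        variants, genotypes = sim.variants, sim.genotypes
        prs_weights, causal_panel = sim.prs_weights, sim.causal_panel

    res = analyze_cohort(participants, variants, genotypes, prs_weights, causal_panel, config)

    res["phenotypes"].to_csv(os.path.join(out_dir, "phenotypes.csv"), index=False)

    common_by = {(c.participant_id, c.gene): c.status for c in res["common_calls"]}
    carriage_rows = [
        {
            "participant_id": c.participant_id,
            "gene": c.gene,
            "rare_status": c.status,
            "common_status": common_by.get((c.participant_id, c.gene), "NONE"),
        }
        for c in res["rare_calls"]
    ]
    pd.DataFrame(carriage_rows, columns=["participant_id", "gene", "rare_status", "common_status"]).to_csv(
        os.path.join(out_dir, "carriage.csv"), index=False
    )

    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "prs": p.prs,
                "causal_allele_count": p.causal_allele_count,
                "rare_carrier": p.rare_carrier,
                "common_carrier": p.common_carrier,
                "top10_prs": p.top10_prs,
                "top10_causal": p.top10_causal,
                "any_risk": p.any_risk,
            }
            for p in res["profiles"]
        ]
    ).to_csv(os.path.join(out_dir, "risk_profiles.csv"), index=False)

    enr_rows = []
    for r in res["enrichment"]:
        cells = {"a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d}
        if config.masking_enabled:
            rendered = {
                k: _mask(config, v, r.table.n_cases if k in "ab" else r.table.n_controls).display
                for k, v in cells.items()
            }
        else:
            rendered = {k: str(v) for k, v in cells.items()}
        enr_rows.append(
            {
                "comparison": r.label,
                **rendered,
                "test": r.test_used,
                "OR": round(r.odds_ratio, 4),
                "ci_low": round(r.ci95[0], 4),
                "ci_high": round(r.ci95[1], 4),
                "p": r.p_value,
                "haldane_corrected": r.haldane_corrected,
            }
        )
    enr_df = pd.DataFrame(
        enr_rows,
        columns=["comparison", "a", "b", "c", "d", "test", "OR", "ci_low", "ci_high", "p", "haldane_corrected"],
    )
    enr_df.to_csv(os.path.join(out_dir, "enrichment.csv"), index=False)
    enr_df[["comparison", "OR", "ci_low", "ci_high", "p"]].to_csv(
        os.path.join(out_dir, "forest.tsv"), sep="\t", index=False
    )

    _write_report(out_dir, res, config)
    return res
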