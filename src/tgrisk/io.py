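"""Readers and writers for the pipeline's file formats.

Genotypes travel as uncompressed VCF 4.2 (biallelic records only; per-variant
annotations in INFO keys CADD, POLYPHEN, SIFT, MTASTER, GENE; genotypes in
GT).  TG measurements, medication exposures and demographics are header-row
CSVs; PRS weights use the tab-separated PGS-catalog scoring-file dialect
(comment lines prefixed ``#``); the causal panel is a two-column CSV.
"""

from __future__ import annotations

import datetime as _dt
import os
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genetic_scores import CausalPanel, PRSWeight, PRSWeights
from .tg_phenotyping import EXCLUSION_FLAGS, ParticipantRecord
from .variant_classification import AnnotatedVariant, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_prs_weights",
    "read_prs_weights",
    "write_causal_panel",
    "read_causal_panel",
    "write_participant_tables",
    "read_participant_tables",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_INFO_HEADERS = [
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD PHRED-scaled deleteriousness score">',
    '##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen-2 call (damaging/benign)">',
    '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call (deleterious/tolerated)">',
    '##INFO=<ID=MTASTER,Number=1,Type=Float,Description="MutationTaster score in [0,1]">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Canonical TG gene label">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Optional ClinVar classification">',
]


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_vcf(path, variants: Sequence[AnnotatedVariant], genotypes: GenotypeMatrix) -> None:
    """Write biallelic records sorted by chromosome/position with GT genotypes."""
    order = sorted(range(len(variants)), key=lambda i: (_chrom_key(variants[i].chrom), variants[i].pos))
    chroms: list[str] = []
    for i in order:
        if variants[i].chrom not in chroms:
            chroms.append(variants[i].chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tgrisk-synthetic-cohort\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        for line in _INFO_HEADERS:
            fh.write(line + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if genotypes.n_participants:
            cols += ["FORMAT"] + genotypes.participant_ids
        fh.write("\t".join(cols) + "\n")
        for i in order:
            v = variants[i]
            info = []
            if v.cadd_phred is not None:
                info.append(f"CADD={v.cadd_phred:.4g}")
            if v.polyphen is not None:
                info.append(f"POLYPHEN={v.polyphen}")
            if v.sift is not None:
                info.append(f"SIFT={v.sift}")
            if v.mtaster_score is not None:
                info.append(f"MTASTER={v.mtaster_score:.4g}")
            if v.gene is not None:
                info.append(f"GENE={v.gene}")
            if v.clinvar_class is not None:
                info.append(f"CLNSIG={v.clinvar_class}")
            fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", ";".join(info) or "."]
            if genotypes.n_participants:
                dos = genotypes.dosage(v.variant_id)
                fields += ["GT"] + [_GT[int(d)] for d in dos]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[list[AnnotatedVariant], GenotypeMatrix]:
    """Read an annotated VCF into variants plus an ALT-dosage genotype matrix.

    Multi-allelic records are rejected — split them (e.g. ``bcftools norm -m-``)
    before loading.
    """
    vcf = VCF(os.fspath(path), gts012=True)
    participant_ids = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.REF}->{rec.ALT}); "
                "split multi-allelic sites before loading"
            )
        mt = rec.INFO.get("MTASTER")
        cadd = rec.INFO.get("CADD")
        variants.append(
            AnnotatedVariant(
                variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                gene=rec.INFO.get("GENE"),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                cadd_phred=float(cadd) if cadd is not None else None,
                polyphen=rec.INFO.get("POLYPHEN"),
                sift=rec.INFO.get("SIFT"),
                mtaster_score=float(mt) if mt is not None else None,
                clinvar_class=rec.INFO.get("CLNSIG"),
            )
        )
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # gts012: 0/1/2, 3 = missing
        gt[gt == 3] = -1
        columns.append(gt)
    dosages = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(participant_ids), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(participant_ids, [v.variant_id for v in variants], dosages)
    return variants, matrix


def write_prs_weights(path, weights: PRSWeights, trait: str = "triglycerides") -> None:
    """Write a PGS-catalog-style scoring file (tab-separated, ``#`` header lines)."""
    with open(path, "w") as fh:
        fh.write("### PGS scoring file (tgrisk synthetic)\n")
        fh.write(f"#trait_reported={trait}\n")
        fh.write(f"#variants_number={len(weights)}\n")
        fh.write("rsID\teffect_allele\teffect_weight\n")
        for e in weights.entries:
            fh.write(f"{e.variant_id}\t{e.effect_allele}\t{e.beta!r}\n")


def read_prs_weights(path) -> PRSWeights:
    """Read a PGS-catalog scoring file.

    Accepts ``rsID`` or ``chr_position``-style variant id columns; requires
    ``effect_allele`` and ``effect_weight``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    id_col = next((c for c in ("rsID", "chr_position", "variant_id") if c in df.columns), None)
    if id_col is None or not {"effect_allele", "effect_weight"} <= set(df.columns):
        raise ValueError(
            "scoring file must have an rsID/chr_position column plus effect_allele and effect_weight"
        )
    entries = tuple(
        PRSWeight(str(r[id_col]), str(r["effect_allele"]), float(r["effect_weight"]))
        for r in df.to_dict("records")
    )
    return PRSWeights(entries)


def write_causal_panel(path, panel: CausalPanel) -> None:
    pd.DataFrame(panel.entries, columns=["variant_id", "increasing_allele"]).to_csv(path, index=False)


def read_causal_panel(path) -> CausalPanel:
    df = pd.read_csv(path)
    if not {"variant_id", "increasing_allele"} <= set(df.columns):
        raise ValueError("causal panel needs columns variant_id, increasing_allele")
    return CausalPanel(tuple((str(v), str(a)) for v, a in zip(df["variant_id"], df["increasing_allele"])))


def write_participant_tables(out_dir, participants: Sequence[ParticipantRecord]) -> dict[str, str]:
    """Write measurements/medications/demographics CSVs; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    meas, meds, demo = [], [], []
    for p in participants:
        for day, tg in p.measurements:
            meas.append({"participant_id": p.participant_id, "date": day.isoformat(), "tg_mg_dl": tg})
        for cls, (start, stop) in p.med_exposures:
            meds.append(
                {
                    "participant_id": p.participant_id,
                    "class": cls,
                    "start": start.isoformat(),
                    "stop": stop.isoformat() if stop else "",
                }
            )
        row = {"participant_id": p.participant_id, "sex": p.sex, "age": p.age_years, "bmi": p.bmi}
        for flag in EXCLUSION_FLAGS:
            row[flag] = bool(p.excluded_flags.get(flag, False))
        demo.append(row)
    paths = {
        "measurements": os.path.join(out_dir, "measurements.csv"),
        "medications": os.path.join(out_dir, "medications.csv"),
        "demographics": os.path.join(out_dir, "demographics.csv"),
    }
    pd.DataFrame(meas, columns=["participant_id", "date", "tg_mg_dl"]).to_csv(paths["measurements"], index=False)
    pd.DataFrame(meds, columns=["participant_id", "class", "start", "stop"]).to_csv(paths["medications"], index=False)
    pd.DataFrame(demo, columns=["participant_id", "sex", "age", "bmi", *EXCLUSION_FLAGS]).to_csv(
        paths["demographics"], index=False
    )
    return paths


def _parse_date(s: str) -> _dt.date:
    return _dt.date.fromisoformat(str(s))


def read_participant_tables(in_dir) -> list[ParticipantRecord]:
    """Assemble ParticipantRecords from the three cohort CSVs."""
    meas = pd.read_csv(os.path.join(in_dir, "measurements.csv"), float_precision="round_trip")
    meds = pd.read_csv(os.path.join(in_dir, "medications.csv"))
    demo = pd.read_csv(os.path.join(in_dir, "demographics.csv"))
    meas_by = {pid: g for pid, g in meas.groupby("participant_id")}
    meds_by = {pid: g for pid, g in meds.groupby("participant_id")}
    records = []
    for row in demo.to_dict("records"):
        pid = row["participant_id"]
        measurements = []
        if pid in meas_by:
            g = meas_by[pid].sort_values("date")
            measurements = [(_parse_date(d), float(t)) for d, t in zip(g["date"], g["tg_mg_dl"])]
        exposures = []
        if pid in meds_by:
            for m in meds_by[pid].to_dict("records"):
                stop = m.get("stop")
                stop_d = None if (stop is None or (isinstance(stop, float) and np.isnan(stop)) or stop == "") else _parse_date(stop)
                exposures.append((str(m["class"]), (_parse_date(m["start"]), stop_d)))
        flags = {f: bool(row.get(f, False)) for f in EXCLUSION_FLAGS}
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                sex=str(row.get("sex", "")),
                age_years=float(row.get("age", np.nan)),
                bmi=float(row.get("bmi", np.nan)),
                measurements=measurements,
                med_exposures=exposures,
                excluded_flags=flags,
            )
        )
    return records
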