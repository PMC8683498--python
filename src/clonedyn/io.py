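"""Flat-file dialects: mutation TSV, VCF (AD/DP), SEG-like copy-number TSV,
purity table, survival table.  Coordinates are 1-based inclusive throughout
(VCF/SEG convention).  Example files live in docs/examples/."""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .ccf import MutationCall
from .cohort import SurvivalRecord
from .errors import InputError

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "total_reads", "gene",
]


def write_mutation_tsv(
    calls: Iterable[MutationCall], path, header_comment: str | None = None
) -> None:
    rows = [
        (c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.alt_reads, c.total_reads,
         c.gene if c.gene is not None else "")
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_mutation_tsv(path) -> Dict[str, List[MutationCall]]:
    """Mutation table -> calls grouped by sample id."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as exc:
        raise InputError(f"cannot parse mutation TSV {path}: {exc}") from exc
    missing = set(MUTATION_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise InputError(f"mutation TSV {path} lacks columns {sorted(missing)}")
    out: Dict[str, List[MutationCall]] = {}
    for row in frame.itertuples(index=False):
        gene = getattr(row, "gene", None)
        if gene is not None and (pd.isna(gene) or gene == ""):
            gene = None
        try:
            call = MutationCall(
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                alt_reads=int(row.alt_reads),
                total_reads=int(row.total_reads),
                gene=gene,
            )
        except (TypeError, ValueError) as exc:
            raise InputError(f"bad mutation row in {path}: {exc}") from exc
        out.setdefault(call.sample_id, []).append(call)
    return out


def write_seg(
    segments_by_sample: Mapping[str, Sequence[tuple]], path,
    header_comment: str | None = None,
) -> None:
    rows = [
        (s, chrom, start, end, cn)
        for s, segs in segments_by_sample.items()
        for chrom, start, end, cn in segs
    ]
    frame = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "total_cn"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_seg(path) -> Dict[str, List[tuple]]:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as exc:
        raise InputError(f"cannot parse SEG file {path}: {exc}") from exc
    needed = {"sample_id", "chrom", "start", "end", "total_cn"}
    if not needed <= set(frame.columns):
        raise InputError(f"SEG file {path} lacks columns {sorted(needed - set(frame.columns))}")
    out: Dict[str, List[tuple]] = {}
    for row in frame.itertuples(index=False):
        try:
            seg = (str(row.chrom), int(row.start), int(row.end), int(row.total_cn))
        except (TypeError, ValueError) as exc:
            raise InputError(f"bad segment row in {path}: {exc}") from exc
        out.setdefault(str(row.sample_id), []).append(seg)
    return out


def write_purity_tsv(purities: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"sample_id": list(purities), "purity": list(purities.values())}
    ).to_csv(path, sep="\t", index=False)


def read_purity_tsv(path) -> Dict[str, float]:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise InputError(f"cannot parse purity TSV {path}: {exc}") from exc
    if not {"sample_id", "purity"} <= set(frame.columns):
        raise InputError(f"purity TSV {path} needs sample_id and purity columns")
    return {str(r.sample_id): float(r.purity) for r in frame.itertuples(index=False)}


def write_survival_tsv(records: Iterable[SurvivalRecord], path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.time, int(r.event)) for r in records],
        columns=["patient_id", "time_days", "event"],
    ).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path) -> List[SurvivalRecord]:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise InputError(f"cannot parse survival TSV {path}: {exc}") from exc
    if not {"patient_id", "time_days", "event"} <= set(frame.columns):
        raise InputError(f"survival TSV {path} needs patient_id/time_days/event")
    if len(frame) == 0:
        raise InputError(f"survival TSV {path} is empty")
    records = []
    for row in frame.itertuples(index=False):
        flag = row.event
        if flag not in (0, 1, True, False):
            raise InputError(f"event flag must be 0/1, got {flag!r}")
        records.append(SurvivalRecord(str(row.patient_id), float(row.time_days), bool(flag)))
    return records


# ---------------------------------------------------------------------------
# VCF (one sample per file; AD holds ref,alt depths)


def write_vcf(calls: Sequence[MutationCall], path, sample_id: str | None = None) -> None:
    calls = list(calls)
    if not calls:
        raise InputError("no calls to write")
    sample_id = sample_id or calls[0].sample_id
    header = pysam.VariantHeader()
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths (ref, alt)")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Total depth")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Gene symbol")],
    )
    max_pos: Dict[str, int] = {}
    for c in calls:
        max_pos[c.chrom] = max(max_pos.get(c.chrom, 0), c.pos)
    for chrom, length in sorted(max_pos.items()):
        header.contigs.add(chrom, length=length + 1000)
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt)
            )
            if c.gene:
                rec.info["GENE"] = c.gene
            rec.samples[sample_id]["AD"] = (c.total_reads - c.alt_reads, c.alt_reads)
            rec.samples[sample_id]["DP"] = c.total_reads
            vcf.write(rec)


def read_vcf(path) -> Dict[str, List[MutationCall]]:
    """VCF -> calls per sample; alt depth from AD, total from DP or sum(AD)."""
    out: Dict[str, List[MutationCall]] = {}
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise InputError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            gene = rec.info.get("GENE")
            for sample_id, sdata in rec.samples.items():
                ad = sdata.get("AD")
                if ad is None or ad[0] is None:
                    continue
                alt_reads = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                dp = sdata.get("DP")
                total = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                out.setdefault(sample_id, []).append(
                    MutationCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        alt_reads=alt_reads,
                        total_reads=total,
                        gene=gene,
                    )
                )
    return out
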