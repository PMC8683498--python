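"""Cancer cell fraction (CCF) computation.

A somatic variant observed at allele fraction ``VAF = alt/total`` in a biopsy
with tumor purity ``rho`` and local total copy number ``CN_t`` is carried by a
fraction

    CCF = VAF * (rho * CN_t + (1 - rho) * 2) / (rho * m)

of the cancer cells, where ``m`` is the mutation multiplicity (number of
mutated copies per tumor cell).  Normal cells are assumed diploid at every
autosomal site.  The raw (unclamped) value is kept for QC and downstream
density estimation; the reported CCF is clamped at 1.

Variance is obtained by first-order (delta-method) propagation of the
binomial read-sampling variance of the VAF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, UncoveredSiteError

logger = logging.getLogger(__name__)

NORMAL_CN = 2  # diploid normal cells at autosomal sites

#: default minimum depth for declaring a site "covered but mutation-absent"
DEFAULT_MIN_DEPTH = 20


@dataclass(frozen=True)
class MutationCall:
    """One somatic variant observation in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.alt_reads < 0:
            raise InputError(f"negative read counts at {self.chrom}:{self.pos}")
        if self.alt_reads > self.total_reads:
            raise InputError(
                f"alt_reads > total_reads at {self.chrom}:{self.pos} "
                f"({self.alt_reads} > {self.total_reads})"
            )
        if self.pos < 1:
            raise InputError(f"positions are 1-based; got {self.pos}")

    @property
    def key(self) -> tuple:
        """Sample-independent mutation identity."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        if self.total_reads == 0:
            raise UncoveredSiteError(f"zero depth at {self.chrom}:{self.pos}")
        return self.alt_reads / self.total_reads


@dataclass(frozen=True)
class CCFRecord:
    """Purity/CN-corrected cancer cell fraction for one call."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    multiplicity: int
    ccf: float
    raw_ccf: float
    variance: float
    cn_total: int
    purity: float

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def _check_purity_cn(purity: float, cn_total: int) -> None:
    if not 0 < purity <= 1:
        raise InputError(f"purity must be in (0, 1]; got {purity}")
    if cn_total < 1:
        raise InputError(f"total copy number must be >= 1; got {cn_total}")


def estimate_multiplicity(vaf: float, purity: float, cn_total: int) -> int:
    """Nearest-integer multiplicity estimate, clamped to [1, cn_total].

    The expected VAF of a mutation at multiplicity m is
    ``m * purity / (purity * cn_total + (1 - purity) * 2)`` (per cancer cell
    carrying it clonally), so inverting at the observed VAF and rounding
    half-up gives the most plausible integer copy count.
    """
    _check_purity_cn(purity, cn_total)
    denom = purity * cn_total + (1.0 - purity) * NORMAL_CN
    m_hat = vaf * denom / purity
    m = int(math.floor(m_hat + 0.5))  # ties at .5 round half-up
    return max(1, min(m, cn_total))


def compute_ccf(
    call: MutationCall,
    purity: float,
    cn_total: int,
    multiplicity: int | str = "auto",
) -> CCFRecord:
    """Convert one mutation call into a :class:`CCFRecord`.

    ``multiplicity="auto"`` applies :func:`estimate_multiplicity`.
    Raises :class:`UncoveredSiteError` on zero depth so the caller can decide
    between "missing" and "absent".
    """
    _check_purity_cn(purity, cn_total)
    if call.total_reads == 0:
        raise UncoveredSiteError(f"zero depth at {call.chrom}:{call.pos}")
    vaf = call.vaf
    if multiplicity == "auto":
        m = estimate_multiplicity(vaf, purity, cn_total)
    else:
        m = int(multiplicity)
        if not 1 <= m <= cn_total:
            raise InputError(f"multiplicity {m} outside [1, {cn_total}]")
    denom = purity * cn_total + (1.0 - purity) * NORMAL_CN
    scale = denom / (purity * m)  # d(ccf)/d(vaf)
    raw = vaf * scale
    var = scale * scale * vaf * (1.0 - vaf) / call.total_reads
    return CCFRecord(
        sample_id=call.sample_id,
        chrom=call.chrom,
        pos=call.pos,
        ref=call.ref,
        alt=call.alt,
        multiplicity=m,
        ccf=min(raw, 1.0),
        raw_ccf=raw,
        variance=var,
        cn_total=cn_total,
        purity=purity,
    )


def cn_at(
    segments: Optional[Sequence[tuple]],
    chrom: str,
    pos: int,
    default: int = NORMAL_CN,
) -> int:
    """Total copy number of the segment covering ``chrom:pos``.

    Segments are ``(chrom, start, end, total_cn)`` with 1-based inclusive
    coordinates; uncovered positions fall back to the diploid default.
    """
    if segments:
        for seg_chrom, start, end, cn in segments:
            if seg_chrom == chrom and start <= pos <= end:
                return int(cn)
    return default


@dataclass
class CCFMatrix:
    """Mutation x sample CCF matrix plus companion raw/variance/depth tables.

    Rows are indexed by the mutation key ``(chrom, pos, ref, alt)`` in
    deterministic (chrom, pos) order.  ``NaN`` encodes "uncovered/missing";
    an exact 0 encodes "covered but absent".
    """

    ccf: pd.DataFrame
    raw: pd.DataFrame
    variance: pd.DataFrame
    depth: pd.DataFrame
    gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def samples(self) -> list[str]:
        return list(self.ccf.columns)

    @property
    def n_mutations(self) -> int:
        return len(self.ccf)

    def subset(self, samples: Sequence[str]) -> "CCFMatrix":
        missing = [s for s in samples if s not in self.ccf.columns]
        if missing:
            raise InputError(f"samples not in matrix: {missing}")
        cols = list(samples)
        return CCFMatrix(
            ccf=self.ccf[cols].copy(),
            raw=self.raw[cols].copy(),
            variance=self.variance[cols].copy(),
            depth=self.depth[cols].copy(),
            gene=self.gene.copy(),
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        long = self.ccf.copy()
        long.columns = [f"ccf_{s}" for s in long.columns]
        raw = self.raw.copy()
        raw.columns = [f"raw_ccf_{s}" for s in raw.columns]
        out = pd.concat([long, raw], axis=1)
        out.insert(0, "gene", self.gene.reindex(out.index))
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.reset_index(names=["chrom", "pos", "ref", "alt"]).to_csv(
                fh, sep="\t", index=False, float_format="%.6g"
            )


def ccf_matrix(
    calls_by_sample: Mapping[str, Iterable[MutationCall]],
    purities: Mapping[str, float],
    segments: Optional[Mapping[str, Sequence[tuple]]] = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    multiplicity: int | str = "auto",
) -> CCFMatrix:
    """Harmonize mutation calls from >=1 samples into a :class:`CCFMatrix`.

    The mutation universe is the union over samples.  For a given sample a
    mutation is:

    * present (its CCF) when called with depth >= 1 and alt reads > 0;
    * covered-absent (CCF 0) when its record has ``total_reads >= min_depth``
      and zero alt reads;
    * missing (NaN) when uncalled or when depth < ``min_depth`` with zero
      alt reads.

    Rows that are missing in every sample are dropped (count logged).
    """
    samples = list(calls_by_sample)
    if not samples:
        raise InputError("no samples provided")
    for s in samples:
        if s not in purities:
            raise InputError(f"no purity for sample {s!r}")

    records: dict[str, dict[tuple, CCFRecord]] = {}
    depths: dict[str, dict[tuple, float]] = {}
    genes: dict[tuple, str] = {}
    universe: set[tuple] = set()
    for s in samples:
        per: dict[tuple, CCFRecord] = {}
        dep: dict[tuple, float] = {}
        segs = segments.get(s) if segments else None
        for call in calls_by_sample[s]:
            key = call.key
            universe.add(key)
            dep[key] = call.total_reads
            if call.gene is not None and key not in genes:
                genes[key] = call.gene
            if call.total_reads == 0:
                continue  # uncovered -> missing
            if call.alt_reads == 0 and call.total_reads < min_depth:
                continue  # insufficiently covered to call absence
            cn = cn_at(segs, call.chrom, call.pos)
            per[key] = compute_ccf(call, purities[s], cn, multiplicity)
        records[s] = per
        depths[s] = dep

    if not universe:
        raise InputError("empty mutation universe")
    keys = sorted(universe, key=lambda k: (k[0], k[1], k[2], k[3]))
    index = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos", "ref", "alt"])

    def table(attr: str) -> pd.DataFrame:
        data = {
            s: [getattr(records[s][k], attr) if k in records[s] else np.nan for k in keys]
            for s in samples
        }
        return pd.DataFrame(data, index=index, columns=samples, dtype=float)

    depth_tab = pd.DataFrame(
        {s: [depths[s].get(k, np.nan) for k in keys] for s in samples},
        index=index,
        columns=samples,
        dtype=float,
    )
    mat = CCFMatrix(
        ccf=table("ccf"),
        raw=table("raw_ccf"),
        variance=table("variance"),
        depth=depth_tab,
        gene=pd.Series({k: genes.get(k) for k in keys}, dtype=object).set_axis(index),
    )
    all_missing = mat.ccf.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d all-missing mutation rows", int(all_missing.sum()))
        mat = CCFMatrix(
            ccf=mat.ccf[~all_missing],
            raw=mat.raw[~all_missing],
            variance=mat.variance[~all_missing],
            depth=mat.depth[~all_missing],
            gene=mat.gene[~all_missing],
        )
    if mat.n_mutations == 0:
        raise InputError("all mutation rows missing in every sample")
    return mat
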