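"""Synthetic multi-region tumor data with known ground truth.

The generator inverts the CCF correction: given a clone tree with per-sample
cancer cell fractions, a biopsy's mutations are emitted at expected allele
fraction

    E[VAF] = m * purity * CCF / (purity * CN_t + (1 - purity) * 2)

with total depth drawn Poisson(mean_depth) and alt reads Binomial(depth,
E[VAF]).  Mutations absent from a sample (CCF 0) are emitted with zero alt
reads rather than omitted, so downstream "absent vs missing" handling is
exercised.  No sequencing error, strand bias, germline contamination or FFPE
artifact model is included.

Three scenarios are packaged; ``p04_like`` mirrors the worked multi-biopsy
example with clones C0-C4 over a peritoneal and two longitudinal liver
biopsies and a 60/40 terminal split in the peritoneal sample.

Also provided: Bliss-structured dose-response matrices for the synergy
scorer and the packaged six-patient overall-survival table.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .ccf import NORMAL_CN, MutationCall, cn_at
from .cohort import SurvivalRecord
from .errors import InputError, ModelAssumptionError
from .pharmacology import DoseResponseMatrix

PACKAGED_SCENARIOS = ("p04_like", "single_clone", "two_sample_branching")


class CloneSpec(BaseModel):
    """One clone: its parent, private mutation count and per-sample CCFs."""

    clone_id: str
    parent_id: Optional[str] = None
    n_private_mutations: int = Field(150, ge=0)
    per_sample_ccf: Dict[str, float]
    marker_gene: Optional[str] = None  # gene label for the first private mutation

    @field_validator("per_sample_ccf")
    @classmethod
    def _ccf_range(cls, v: Dict[str, float]) -> Dict[str, float]:
        for s, c in v.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"CCF {c} for sample {s!r} outside [0, 1]")
        return v


class SampleSpec(BaseModel):
    """One biopsy: purity, mean depth and a SEG-like copy-number profile."""

    sample_id: str
    purity: float = Field(gt=0.0, le=1.0)
    mean_depth: float = Field(gt=0.0)
    cn_profile: List[Tuple[str, int, int, int]] = Field(default_factory=list)

    @field_validator("cn_profile")
    @classmethod
    def _segments_valid(cls, v):
        by_chrom: Dict[str, list] = {}
        for chrom, start, end, cn in v:
            if start < 1 or end < start:
                raise ValueError(f"bad 1-based segment {chrom}:{start}-{end}")
            if cn < 1:
                raise ValueError(f"total CN must be >= 1 in {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, _) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping segments on {chrom}")
        return v


class Scenario(BaseModel):
    """A validated clone tree plus biopsies; the unit of simulation."""

    name: str = "custom"
    clones: List[CloneSpec]
    samples: List[SampleSpec]
    seed: int = 0

    @model_validator(mode="after")
    def _validate_tree(self) -> "Scenario":
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids")
        by_id = {c.clone_id: c for c in self.clones}
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"exactly one root clone required, found {len(roots)}")
        sample_ids = {s.sample_id for s in self.samples}
        for c in self.clones:
            extra = set(c.per_sample_ccf) - sample_ids
            if extra:
                raise ValueError(f"clone {c.clone_id} references unknown samples {extra}")
            if c.parent_id is not None and c.parent_id not in by_id:
                raise ValueError(f"clone {c.clone_id} has unknown parent {c.parent_id}")
        # containment: child CCF <= parent CCF in every sample
        for c in self.clones:
            if c.parent_id is None:
                continue
            parent = by_id[c.parent_id]
            for s in sample_ids:
                if c.per_sample_ccf.get(s, 0.0) > parent.per_sample_ccf.get(s, 0.0) + 1e-9:
                    raise ValueError(
                        f"sum rule violation: clone {c.clone_id} CCF exceeds parent "
                        f"{c.parent_id} in sample {s}"
                    )
        # pigeonhole sum rule: children CCFs sum to at most the parent CCF
        children: Dict[str, list] = {c.clone_id: [] for c in self.clones}
        for c in self.clones:
            if c.parent_id is not None:
                children[c.parent_id].append(c)
        for c in self.clones:
            for s in sample_ids:
                total = sum(ch.per_sample_ccf.get(s, 0.0) for ch in children[c.clone_id])
                if total > c.per_sample_ccf.get(s, 0.0) + 1e-9:
                    raise ValueError(
                        f"sum rule violation: children of {c.clone_id} sum to {total:.3f} "
                        f"> parent CCF in sample {s}"
                    )
        return self

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise InputError(f"unknown sample {sample_id!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        try:
            with open(path) as fh:
                payload = yaml.safe_load(fh)
        except (OSError, yaml.YAMLError) as exc:
            raise InputError(f"cannot read scenario config {path}: {exc}") from exc
        return cls.model_validate(payload)


def expected_vaf(ccf: float, purity: float, cn_total: int, multiplicity: int = 1) -> float:
    """Closed-form expected allele fraction of a mutation at the given CCF."""
    return multiplicity * purity * ccf / (purity * cn_total + (1.0 - purity) * NORMAL_CN)


# ---------------------------------------------------------------------------
# packaged scenarios


def _diploid_profile(chrom: str = "1", end: int = 10_000_000) -> list:
    return [(chrom, 1, end, 2)]


def _p04_like() -> Scenario:
    samples = [
        SampleSpec(sample_id=s, purity=0.7, mean_depth=150.0, cn_profile=_diploid_profile())
        for s in ("peritoneal", "liver1", "liver2")
    ]
    ccf = {
        "C0": (1.0, 1.0, 1.0),
        "C1": (1.0, 0.0, 0.0),
        "C3": (0.4, 0.0, 0.0),
        "C2": (0.0, 1.0, 1.0),
        "C4": (0.0, 0.0, 1.0),
    }
    parents = {"C0": None, "C1": "C0", "C3": "C1", "C2": "C0", "C4": "C2"}
    markers = {
        "C0": "EGFR_del19",   # truncal driver, clonal everywhere
        "C1": "EGFR_T790M",   # private to the peritoneal metastasis
        "C2": "BRAF_V600E",   # private to the liver lineage
    }
    order = ["C0", "C1", "C3", "C2", "C4"]
    clones = [
        CloneSpec(
            clone_id=cid,
            parent_id=parents[cid],
            n_private_mutations=150,
            per_sample_ccf=dict(zip(("peritoneal", "liver1", "liver2"), ccf[cid])),
            marker_gene=markers.get(cid),
        )
        for cid in order
    ]
    return Scenario(name="p04_like", clones=clones, samples=samples)


def _single_clone() -> Scenario:
    return Scenario(
        name="single_clone",
        clones=[
            CloneSpec(
                clone_id="C0", parent_id=None, n_private_mutations=150,
                per_sample_ccf={"s1": 1.0},
            )
        ],
        samples=[
            SampleSpec(sample_id="s1", purity=0.7, mean_depth=150.0,
                       cn_profile=_diploid_profile())
        ],
    )


def _two_sample_branching() -> Scenario:
    samples = [
        SampleSpec(sample_id=s, purity=0.7, mean_depth=150.0, cn_profile=_diploid_profile())
        for s in ("a", "b")
    ]
    clones = [
        CloneSpec(clone_id="C0", parent_id=None, n_private_mutations=200,
                  per_sample_ccf={"a": 1.0, "b": 1.0}),
        CloneSpec(clone_id="C1", parent_id="C0", n_private_mutations=150,
                  per_sample_ccf={"a": 1.0, "b": 0.0}),
        CloneSpec(clone_id="C2", parent_id="C0", n_private_mutations=180,
                  per_sample_ccf={"a": 0.0, "b": 1.0}),
    ]
    return Scenario(name="two_sample_branching", clones=clones, samples=samples)


def build_scenario(name: str) -> Scenario:
    """Return a packaged scenario by name, or load a YAML config by path."""
    if name == "p04_like":
        return _p04_like()
    if name == "single_clone":
        return _single_clone()
    if name == "two_sample_branching":
        return _two_sample_branching()
    import os

    if os.path.exists(name):
        return Scenario.from_yaml(name)
    raise InputError(
        f"unknown scenario {name!r}; packaged: {', '.join(PACKAGED_SCENARIOS)}"
    )


# ---------------------------------------------------------------------------
# biopsy simulation


def mutation_catalog(scenario: Scenario) -> list[dict]:
    """Deterministic genomic placement of every clone-private mutation.

    Positions are spaced 1 kb apart on chromosome 1 in clone order; the
    first private mutation of a clone carries its marker gene label.
    """
    bases = ("A", "C", "G", "T")
    catalog = []
    pos = 0
    for clone in scenario.clones:
        for i in range(clone.n_private_mutations):
            pos += 1000
            ref = bases[pos // 1000 % 4]
            alt = bases[(pos // 1000 + 1) % 4]
            catalog.append(
                {
                    "clone_id": clone.clone_id,
                    "chrom": "1",
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": clone.marker_gene if i == 0 else None,
                    "multiplicity": 1,
                }
            )
    return catalog


def simulate_biopsy(
    scenario: Scenario, sample_id: str, seed: int
) -> Tuple[List[MutationCall], SampleSpec]:
    """Simulate read counts for every catalog mutation in one biopsy."""
    spec = scenario.sample(sample_id)
    rng = np.random.default_rng(seed)
    ccf_by_clone = {c.clone_id: c.per_sample_ccf.get(sample_id, 0.0) for c in scenario.clones}
    calls: List[MutationCall] = []
    for entry in mutation_catalog(scenario):
        ccf = ccf_by_clone[entry["clone_id"]]
        cn = cn_at(spec.cn_profile, entry["chrom"], entry["pos"])
        vaf = expected_vaf(ccf, spec.purity, cn, entry["multiplicity"])
        if vaf > 1.0 + 1e-12:
            raise ModelAssumptionError(
                f"expected VAF {vaf:.3f} > 1 at {entry['chrom']}:{entry['pos']} "
                "(inconsistent multiplicity/CN/purity)"
            )
        depth = int(rng.poisson(spec.mean_depth))
        alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
        calls.append(
            MutationCall(
                sample_id=sample_id,
                chrom=entry["chrom"],
                pos=entry["pos"],
                ref=entry["ref"],
                alt=entry["alt"],
                alt_reads=alt,
                total_reads=depth,
                gene=entry["gene"],
            )
        )
    return calls, spec


def simulate_all_biopsies(
    scenario: Scenario, seed: int
) -> Dict[str, List[MutationCall]]:
    """One independent substream per sample, derived from ``seed``."""
    root = np.random.SeedSequence(seed)
    out: Dict[str, List[MutationCall]] = {}
    for child, sample_id in zip(root.spawn(len(scenario.samples)), scenario.sample_ids):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out[sample_id], _ = simulate_biopsy(scenario, sample_id, sub_seed)
    return out


def random_scenario(
    rng: np.random.Generator,
    n_clones: int = 6,
    n_samples: int = 3,
    n_private_mutations: int = 150,
    purity: float = 0.7,
    mean_depth: float = 150.0,
) -> Scenario:
    """Random clone tree with sum-rule-consistent per-sample CCFs.

    Used for recovery experiments: the root is clonal everywhere; each
    further clone picks a random parent among earlier clones and, per sample,
    either is absent or takes a large random share (55-95%) of the parent's
    remaining (unallocated) CCF.  Children thereby nearly exhaust their
    parents, which is what makes the topology identifiable from CCFs alone;
    loosely packed trees admit many sum-rule-feasible alternatives.  Subclone
    CCFs are capped at 0.8 so no subclone is near-clonal in every sample,
    which would make the root ambiguous.
    """
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    clone_ids = [f"C{i}" for i in range(n_clones)]
    parents: Dict[str, Optional[str]] = {clone_ids[0]: None}
    ccfs: Dict[str, Dict[str, float]] = {clone_ids[0]: {s: 1.0 for s in sample_ids}}
    remaining: Dict[str, Dict[str, float]] = {clone_ids[0]: {s: 1.0 for s in sample_ids}}
    for cid in clone_ids[1:]:
        parent = clone_ids[int(rng.integers(0, clone_ids.index(cid)))]
        parents[cid] = parent
        my_ccf: Dict[str, float] = {}
        for s in sample_ids:
            avail = min(remaining[parent][s], 0.8)
            if avail < 0.15 or rng.random() < 0.35:
                my_ccf[s] = 0.0
            else:
                my_ccf[s] = float(np.round(avail * rng.uniform(0.55, 0.95), 3))
            remaining[parent][s] = remaining[parent][s] - my_ccf[s]
        ccfs[cid] = my_ccf
        remaining[cid] = dict(my_ccf)
    clones = [
        CloneSpec(
            clone_id=cid,
            parent_id=parents[cid],
            n_private_mutations=n_private_mutations,
            per_sample_ccf=ccfs[cid],
        )
        for cid in clone_ids
    ]
    samples = [
        SampleSpec(sample_id=s, purity=purity, mean_depth=mean_depth,
                   cn_profile=_diploid_profile())
        for s in sample_ids
    ]
    return Scenario(name="random", clones=clones, samples=samples)


# ---------------------------------------------------------------------------
# dose-response matrices


def _dose_axis(top: float, n: int = 5, dilution: float = 4.0) -> np.ndarray:
    doses = top / dilution ** np.arange(n)[::-1]
    return np.concatenate([[0.0], doses])


def simulate_dose_response(
    ec50_a: float = 2e-8,
    ec50_b: float = 6e-9,
    slopes: Tuple[float, float] = (1.0, 1.0),
    delta_true: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    top_a: float = 3e-7,
    top_b: float = 1e-7,
    emax_a: float = 1.0,
    emax_b: float = 1.0,
    third_drug_inhibition: float = 0.0,
    conc_c: Optional[float] = None,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
) -> DoseResponseMatrix:
    """Bliss-structured 6x6 viability matrix (5 four-fold dilutions + DMSO).

    Monotherapies follow log-logistic curves; combination inhibition is Bliss
    independence plus ``delta_true`` on double-dosed wells plus Gaussian noise
    on every treated well, clipped to [0, 1].  ``third_drug_inhibition`` folds
    a constant third-drug effect into the whole layer (for 3-D stacks).
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if not 0.0 <= third_drug_inhibition < 1.0:
        raise InputError("third_drug_inhibition must be in [0, 1)")
    rng = np.random.default_rng(seed)
    conc_a = _dose_axis(top_a)
    conc_b = _dose_axis(top_b)

    def hill(x, ec50, slope, emax):
        y = np.zeros_like(x)
        pos = x > 0
        y[pos] = emax / (1.0 + (ec50 / x[pos]) ** slope)
        return y

    ya = hill(conc_a, ec50_a, slopes[0], emax_a)
    yb = hill(conc_b, ec50_b, slopes[1], emax_b)
    yc = third_drug_inhibition
    inh = 1.0 - np.outer(1.0 - yb, 1.0 - ya) * (1.0 - yc)
    both = np.outer(conc_b > 0, conc_a > 0)
    inh = inh + delta_true * both
    treated = ~(np.outer(conc_b == 0, conc_a == 0))
    if noise_sd > 0:
        inh = inh + rng.normal(0.0, noise_sd, size=inh.shape) * treated
    inh = np.clip(inh, 0.0, 1.0)
    if yc == 0.0:
        inh[0, 0] = 0.0  # normalized DMSO reference
    return DoseResponseMatrix(
        drug_a=drug_a,
        drug_b=drug_b,
        conc_a=conc_a,
        conc_b=conc_b,
        viability=1.0 - inh,
        drug_c="drug_c" if conc_c is not None else None,
        conc_c=conc_c,
    )


# ---------------------------------------------------------------------------
# packaged survival table


def packaged_survival_table() -> List[SurvivalRecord]:
    """Overall survival after detection of acquired resistance for the six
    evaluable patients (days; one censored alive)."""
    return [
        SurvivalRecord("P01", 636.0, False),
        SurvivalRecord("P04", 287.0, True),
        SurvivalRecord("P12", 101.0, True),
        SurvivalRecord("P13", 239.0, True),
        SurvivalRecord("P14", 359.0, True),
        SurvivalRecord("P15", 219.0, True),
    ]
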