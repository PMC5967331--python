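"""Somatic-variant filtering for diagnosis/remission/relapse trios.

The filter chain, applied to each candidate site:

1. **Quality gate** — within a capture bait, depth >= 10 reads,
   >= 5 alt-supporting reads, QPHRED >= 20 for SNVs / >= 30 for indels.
2. **Single-sample somatic status** — VAF >= 0.15 in the tumor and < 0.05
   in the matched remission sample.
3. **Cross-tumor rescue** — a variant somatic in exactly one tumor is
   promoted to shared if the other tumor shows VAF >= 0.05 or at least two
   alt-supporting reads (clonality or coverage may hide it there).
4. **Population exclusion** — known germline variants with population minor
   allele frequency > 1% are removed; a missing frequency keeps the site.

Boundary semantics are exactly the printed inequalities (>= 0.15, < 0.05,
>= 0.05, >= 2 reads, > 1%) and are pinned by tests.  Without a remission
sample (pairs-only patients) diagnosis-side somatic status is undetermined
("ND*"); only relapse-acquired events are classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trio_io import (
    CODING_CLASSES,
    SITE_KEY,
    BaitIntervals,
    SiteObservation,
    TrioDataset,
    TrioValidationError,
)

STATUSES = ("somatic_diagnosis", "somatic_relapse", "somatic_shared",
            "non_somatic", "undetermined")
PARTITIONS = ("common", "diagnosis_specific", "relapse_specific", "undetermined")


@dataclass
class FilterConfig:
    """Thresholds of the somatic filter chain (defaults = the study's rules)."""

    min_depth: int = 10
    min_alt_calls: int = 5
    min_qphred_snv: float = 20.0
    min_qphred_indel: float = 30.0
    vaf_somatic_tumor: float = 0.15
    vaf_max_remission: float = 0.05
    rescue_vaf: float = 0.05
    rescue_min_reads: int = 2
    pop_af_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("vaf_somatic_tumor", "vaf_max_remission", "rescue_vaf", "pop_af_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.rescue_vaf > self.vaf_somatic_tumor:
            raise ValueError("rescue_vaf must not exceed vaf_somatic_tumor")
        if self.min_depth < 0 or self.min_alt_calls < 0 or self.rescue_min_reads < 0:
            raise ValueError("read-count thresholds must be non-negative")


@dataclass(frozen=True)
class SampleEvidence:
    depth: int
    alt_reads: int

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else float("nan")


@dataclass
class SomaticEvent:
    """A somatic mutation with trio-level status and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    functional: str
    per_sample: dict[str, SampleEvidence]
    status: str
    gene: str | None = None
    pop_af: float | None = None
    qphred: float | None = None
    rescued: bool = False
    ccf: dict[str, object] = field(default_factory=dict)
    partition: str = "undetermined"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "SNV"

    @property
    def is_coding(self) -> bool:
        return self.functional in CODING_CLASSES

    def vaf(self, role: str) -> float:
        ev = self.per_sample.get(role)
        return ev.vaf if ev is not None else float("nan")

    def somatic_in(self, role: str) -> bool:
        if self.status == "somatic_shared":
            return role in ("diagnosis", "relapse")
        return self.status == f"somatic_{role}"


def compute_vaf(alt_reads: int, depth: int) -> float:
    """Variant allele fraction; NaN when depth is zero."""
    if depth < 0 or alt_reads < 0:
        raise ValueError("negative read count")
    if alt_reads > depth:
        raise ValueError(f"alt_reads ({alt_reads}) > depth ({depth})")
    if depth == 0:
        return float("nan")
    return alt_reads / depth


def pass_quality(obs: SiteObservation, baits: BaitIntervals, cfg: FilterConfig) -> bool:
    """Quality gate: in-bait, depth, alt-read and QPHRED thresholds."""
    if not baits.contains(obs.chrom, obs.pos):
        return False
    if obs.depth < cfg.min_depth or obs.alt_reads < cfg.min_alt_calls:
        return False
    min_q = cfg.min_qphred_indel if obs.is_indel else cfg.min_qphred_snv
    return obs.qphred >= min_q


def somatic_status_single(
    tumor: SiteObservation,
    remission: SiteObservation | None,
    cfg: FilterConfig,
) -> str:
    """Single-tumor somatic call against the matched remission sample.

    Returns ``"somatic"``, ``"not_somatic"`` or ``"unassessable"`` (no
    remission sample, or remission depth 0).
    """
    if remission is None or remission.depth == 0:
        return "unassessable"
    tumor_vaf = tumor.vaf
    if math.isnan(tumor_vaf):
        return "not_somatic"
    if tumor_vaf >= cfg.vaf_somatic_tumor and remission.vaf < cfg.vaf_max_remission:
        return "somatic"
    return "not_somatic"


def rescue_cross_tumor(events: list[SomaticEvent], cfg: FilterConfig) -> list[SomaticEvent]:
    """Promote one-tumor somatic events to shared on cross-tumor evidence.

    Monotone: statuses are only ever promoted, never demoted.
    """
    for e in events:
        if e.status == "somatic_diagnosis":
            other = "relapse"
        elif e.status == "somatic_relapse":
            other = "diagnosis"
        else:
            continue
        ev = e.per_sample.get(other)
        if ev is None:
            continue
        vaf = ev.vaf
        if (not math.isnan(vaf) and vaf >= cfg.rescue_vaf) or ev.alt_reads >= cfg.rescue_min_reads:
            e.status = "somatic_shared"
            e.rescued = True
    return events


def exclude_population_variants(
    events: list[SomaticEvent], cfg: FilterConfig
) -> list[SomaticEvent]:
    """Drop known germline variants with population MAF > ``pop_af_max``.

    Missing frequencies are kept: absence of database evidence must not
    delete a candidate somatic call.
    """
    return [e for e in events if e.pop_af is None or e.pop_af <= cfg.pop_af_max]


def call_trio(trio: TrioDataset, cfg: FilterConfig | None = None) -> list[SomaticEvent]:
    """Run the full filter chain on one trio and return somatic events.

    With a remission sample, every retained event carries one of the
    somatic statuses; in pairs-only mode only relapse-acquired events get a
    somatic status, diagnosis-side candidates are ``undetermined``.
    """
    cfg = cfg or FilterConfig()
    tumors = ("diagnosis", "relapse")
    idx = {role: trio.indexed(role) for role in trio.samples}
    for role, t in idx.items():
        if not t.index.is_unique:
            dup = t.index[t.index.duplicated()][0]
            raise TrioValidationError(f"sample {role!r}: duplicate site key {dup}")

    # quality gate + tumor-VAF screen, vectorized per tumor
    candidate_sites: dict[tuple, None] = {}
    qual: dict[str, pd.Index] = {}
    for role in tumors:
        t = idx[role]
        if t.empty:
            qual[role] = t.index
            continue
        chrom = t.index.get_level_values(0).to_numpy()
        pos = t.index.get_level_values(1).to_numpy()
        in_bait = trio.baits.contains_many(chrom, pos)
        is_indel = (t["variant_class"] != "SNV").to_numpy()
        min_q = np.where(is_indel, cfg.min_qphred_indel, cfg.min_qphred_snv)
        ok = (
            in_bait
            & (t["depth"].to_numpy() >= cfg.min_depth)
            & (t["alt_reads"].to_numpy() >= cfg.min_alt_calls)
            & (t["qphred"].to_numpy() >= min_q)
        )
        depth = t["depth"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, t["alt_reads"].to_numpy() / np.maximum(depth, 1), np.nan)
        cand = ok & (vaf >= cfg.vaf_somatic_tumor)
        qual[role] = t.index[ok]
        for site in t.index[cand]:
            candidate_sites[site] = None

    remission = idx.get("remission")
    events: list[SomaticEvent] = []
    for site in candidate_sites:
        rows = {role: (idx[role].loc[site] if site in idx[role].index else None)
                for role in trio.samples}
        per_sample: dict[str, SampleEvidence] = {}
        for role, row in rows.items():
            if row is not None:
                per_sample[role] = SampleEvidence(int(row["depth"]), int(row["alt_reads"]))
            else:
                per_sample[role] = SampleEvidence(0, 0)
        rem_ev = per_sample.get("remission") if remission is not None else None

        per_tumor: dict[str, str] = {}
        for role in tumors:
            row = rows.get(role)
            if row is None or site not in qual[role]:
                per_tumor[role] = "not_somatic"
                continue
            ev = per_sample[role]
            if rem_ev is None or rem_ev.depth == 0:
                per_tumor[role] = "unassessable"
            elif ev.vaf >= cfg.vaf_somatic_tumor and rem_ev.vaf < cfg.vaf_max_remission:
                per_tumor[role] = "somatic"
            else:
                per_tumor[role] = "not_somatic"

        if remission is not None:
            if per_tumor["diagnosis"] == "somatic" and per_tumor["relapse"] == "somatic":
                status = "somatic_shared"
            elif per_tumor["diagnosis"] == "somatic":
                status = "somatic_diagnosis"
            elif per_tumor["relapse"] == "somatic":
                status = "somatic_relapse"
            elif "unassessable" in per_tumor.values():
                status = "undetermined"
            else:
                status = "non_somatic"
        else:
            # pairs-only: relapse-acquired iff relapse passes the tumor VAF
            # screen and diagnosis shows no rescue-level evidence
            d_ev, r_ev = per_sample["diagnosis"], per_sample["relapse"]
            r_cand = site in qual["relapse"] and not math.isnan(r_ev.vaf) \
                and r_ev.vaf >= cfg.vaf_somatic_tumor
            d_evidence = (not math.isnan(d_ev.vaf) and d_ev.vaf >= cfg.rescue_vaf) \
                or d_ev.alt_reads >= cfg.rescue_min_reads
            status = "somatic_relapse" if (r_cand and not d_evidence) else "undetermined"

        anyrow = next(r for r in rows.values() if r is not None)
        paf = anyrow["pop_af"]
        gene = anyrow.get("gene")
        events.append(SomaticEvent(
            chrom=site[0], pos=int(site[1]), ref=site[2], alt=site[3],
            variant_class=str(anyrow["variant_class"]),
            functional=str(anyrow["functional"]),
            per_sample=per_sample, status=status,
            gene=None if gene is None or gene != gene else str(gene),
            pop_af=None if paf is None or paf != paf else float(paf),
            qphred=float(anyrow["qphred"]),
        ))

    if remission is not None:
        events = rescue_cross_tumor(events, cfg)
    events = exclude_population_variants(events, cfg)
    return [e for e in events if e.status != "non_somatic"]


def summarize_burden(events: list[SomaticEvent]) -> dict[str, dict[str, int]]:
    """Count coding somatic substitutions and indels at diagnosis and
    acquired at relapse.

    Substitutions are SNVs with a non-synonymous functional class; indels
    are insertion/deletion events in a coding class.  "Diagnosis" counts
    everything somatic in the diagnosis sample (shared events included);
    "relapse_acquired" counts relapse-only events.
    """
    out = {"diagnosis": {"substitutions": 0, "indels": 0},
           "relapse_acquired": {"substitutions": 0, "indels": 0}}
    for e in events:
        if not e.is_coding:
            continue
        kind = "indels" if e.is_indel else "substitutions"
        if e.status in ("somatic_diagnosis", "somatic_shared"):
            out["diagnosis"][kind] += 1
        if e.status == "somatic_relapse":
            out["relapse_acquired"][kind] += 1
    return out


def coverage_qc(per_target_depth) -> dict[str, float]:
    """Coverage summary: unweighted mean of per-target mean depths and the
    fraction of targets covered >= 25x."""
    depths = np.asarray(
        per_target_depth["mean_depth"] if isinstance(per_target_depth, pd.DataFrame)
        else per_target_depth,
        dtype=float,
    )
    if depths.size == 0:
        raise ValueError("coverage_qc: empty depth table")
    return {
        "mean_depth": float(depths.mean()),
        "fraction_ge_25x": float((depths >= 25).mean()),
    }
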