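"""Clonal progression trees for diagnosis/relapse pairs.

Every patient's history is summarized by a four-node diagram: cell of
origin -> fusion-bearing common ancestor -> diagnosis clone and relapse
clone.  Somatic events are first harmonized for coverage (an event seen in
only one tumor but covered by fewer than 10 reads in the other may simply
be undetectable there and is set aside), then partitioned into events
common to both tumors, diagnosis-specific and relapse-specific.  The
partition determines the mode of evolution:

* **linear** — no diagnosis-specific events: the relapse derives from the
  diagnosis clone itself (the ancestor node collapses onto diagnosis);
* **branched** — both tumors carry private events on top of a substantial
  shared trunk: the relapse derives from a subclone of the primary tumor;
* **ancestral** — the tumors share essentially nothing beyond the fusion
  (at most ``ancestral_max_shared`` non-fusion coding events): the relapse
  re-emerged from a pre-leukemic fusion-bearing clone.

The PML/RARA fusion is an input annotation, common to both tumors by
definition, and is never counted among shared events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cna import CopyNumberSegment
from .filtering import SomaticEvent
from .trio_io import TrioDataset

#: recurrent driver genes annotated on tree edges
DEFAULT_DRIVER_GENES = (
    "FLT3", "WT1", "NRAS", "KRAS", "RARA", "NT5C2", "NSD1", "SALL4",
    "MED12", "KDM6A", "ASXL1", "ETV6", "MYC",
)

MODES = ("linear", "branched", "ancestral")
EDGES = ("origin->ancestor", "ancestor->diagnosis", "ancestor->relapse")


@dataclass
class CnaChange:
    """A copy-number aberration treated as one progression-tree event."""

    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int
    labels: tuple[str, ...]

    @classmethod
    def from_segment(cls, s: CopyNumberSegment) -> "CnaChange":
        return cls(s.chrom, s.start, s.end, int(s.cn_total), int(s.cn_minor),
                   tuple(sorted(s.labels)))


@dataclass
class EventPartition:
    common: list[SomaticEvent] = field(default_factory=list)
    diagnosis_specific: list[SomaticEvent] = field(default_factory=list)
    relapse_specific: list[SomaticEvent] = field(default_factory=list)
    discarded_low_coverage: list[SomaticEvent] = field(default_factory=list)
    cna_common: list[CnaChange] = field(default_factory=list)
    cna_diagnosis: list[CnaChange] = field(default_factory=list)
    cna_relapse: list[CnaChange] = field(default_factory=list)
    cna_discordant: list[tuple[CnaChange, CnaChange]] = field(default_factory=list)

    def shared_coding_count(self) -> int:
        return sum(1 for e in self.common if e.is_coding)


@dataclass
class ProgressionTree:
    """Four-node evolution diagram with per-edge event counts."""

    patient_id: str
    mode: str
    fusion_breakpoint: str
    edges: dict[str, dict]
    ancestor_is_diagnosis: bool = False
    no_relapse_driver: bool = False
    ancestral_max_shared: int = 5

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mode": self.mode,
            "fusion_breakpoint": self.fusion_breakpoint,
            "ancestor_is_diagnosis": self.ancestor_is_diagnosis,
            "no_relapse_driver": self.no_relapse_driver,
            "ancestral_max_shared": self.ancestral_max_shared,
            "edges": self.edges,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionTree":
        return cls(
            patient_id=d["patient_id"], mode=d["mode"],
            fusion_breakpoint=d["fusion_breakpoint"], edges=d["edges"],
            ancestor_is_diagnosis=d.get("ancestor_is_diagnosis", False),
            no_relapse_driver=d.get("no_relapse_driver", False),
            ancestral_max_shared=d.get("ancestral_max_shared", 5),
        )

    def to_dot(self) -> str:
        """Graphviz rendering of the four-node diagram."""
        lines = ["digraph progression {", "  rankdir=LR;"]
        style = {
            "origin": 'label="cell of origin", fillcolor=white',
            "ancestor": f'label="PML/RARA ancestor\\n({self.fusion_breakpoint})", fillcolor=lightblue',
            "diagnosis": 'label="diagnosis", fillcolor=dodgerblue4, fontcolor=white',
            "relapse": 'label="relapse", fillcolor=darkgreen, fontcolor=white',
        }
        nodes = ["origin", "ancestor", "diagnosis", "relapse"]
        if self.ancestor_is_diagnosis:
            style["ancestor"] = ('label="diagnosis\\n(= common ancestor, '
                                 f'{self.fusion_breakpoint})", fillcolor=dodgerblue4, fontcolor=white')
            nodes.remove("diagnosis")
        for n in nodes:
            lines.append(f'  {n} [shape=circle, style=filled, {style[n]}];')
        for edge, (a, b) in zip(EDGES, (("origin", "ancestor"),
                                        ("ancestor", "diagnosis"),
                                        ("ancestor", "relapse"))):
            if self.ancestor_is_diagnosis and edge == "ancestor->diagnosis":
                continue
            info = self.edges[edge]
            drv = ",".join(info["drivers"]) if info["drivers"] else ""
            label = f'{info["coding_mutations"]}'
            if drv:
                label += f"\\n{drv}"
            lines.append(f'  {a} -> {b} [label="{label}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def harmonize_coverage(events: Iterable[SomaticEvent], trio: TrioDataset | None = None,
                       min_depth: int = 10) -> tuple[list[SomaticEvent], list[SomaticEvent]]:
    """Set aside one-tumor events under-covered (< min_depth reads) in the
    other tumor: their absence there may be purely technical.

    Shared events are never discarded.  Returns (retained, discarded).
    """
    retained: list[SomaticEvent] = []
    discarded: list[SomaticEvent] = []
    for e in events:
        other = {"somatic_diagnosis": "relapse", "somatic_relapse": "diagnosis"}.get(e.status)
        if other is not None:
            ev = e.per_sample.get(other)
            depth = ev.depth if ev is not None else 0
            if depth < min_depth:
                discarded.append(e)
                continue
        retained.append(e)
    return retained, discarded


def _reciprocal_overlap(a: CnaChange, b: CnaChange) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start + 1), inter / (b.end - b.start + 1))


def partition_cna(diagnosis: Sequence[CnaChange], relapse: Sequence[CnaChange],
                  min_overlap: float = 0.5) -> tuple[list, list, list, list]:
    """Match aberrant segments across samples: the same event requires
    reciprocal overlap >= min_overlap and an identical fitted state."""
    common: list[CnaChange] = []
    discordant: list[tuple[CnaChange, CnaChange]] = []
    rel_left = list(relapse)
    diag_only: list[CnaChange] = []
    for d in diagnosis:
        match = None
        for r in rel_left:
            if _reciprocal_overlap(d, r) >= min_overlap:
                if (d.cn_total, d.cn_minor) == (r.cn_total, r.cn_minor):
                    match = r
                    break
                discordant.append((d, r))
        if match is not None:
            common.append(d)
            rel_left.remove(match)
        else:
            diag_only.append(d)
    return common, diag_only, rel_left, discordant


def partition_events(
    events: Iterable[SomaticEvent],
    cna_diagnosis: Sequence[CnaChange] = (),
    cna_relapse: Sequence[CnaChange] = (),
    discarded: Sequence[SomaticEvent] = (),
) -> EventPartition:
    """Partition harmonized events into common / diagnosis-specific /
    relapse-specific; rescued variants are shared by construction."""
    p = EventPartition(discarded_low_coverage=list(discarded))
    for e in events:
        if e.status == "somatic_shared":
            e.partition = "common"
            p.common.append(e)
        elif e.status == "somatic_diagnosis":
            e.partition = "diagnosis_specific"
            p.diagnosis_specific.append(e)
        elif e.status == "somatic_relapse":
            e.partition = "relapse_specific"
            p.relapse_specific.append(e)
        else:
            e.partition = "undetermined"
    p.cna_common, p.cna_diagnosis, p.cna_relapse, p.cna_discordant = partition_cna(
        [c for c in cna_diagnosis], [c for c in cna_relapse]
    )
    return p


def classify_mode(p: EventPartition, ancestral_max_shared: int = 5) -> str:
    """Mode of evolution from the partition.

    Linear when nothing is diagnosis-specific; otherwise ancestral when at
    most ``ancestral_max_shared`` non-fusion coding events are shared
    (the fusion is not in the partition at all); otherwise branched.
    """
    if not p.diagnosis_specific and not p.cna_diagnosis:
        return "linear"
    if p.shared_coding_count() + len(p.cna_common) <= ancestral_max_shared:
        return "ancestral"
    return "branched"


def _edge_info(events: Sequence[SomaticEvent], cnas: Sequence[CnaChange],
               driver_genes: Sequence[str]) -> dict:
    drivers = sorted({e.gene for e in events if e.gene and e.gene in driver_genes})
    return {
        "coding_mutations": sum(1 for e in events if e.is_coding),
        "all_events": len(events) + len(cnas),
        "cna_events": len(cnas),
        "drivers": drivers,
        "cna_labels": sorted({lab for c in cnas for lab in c.labels if lab != "normal"}),
    }


def build_tree(
    p: EventPartition,
    patient_id: str = "",
    fusion_breakpoint: str = "unknown",
    driver_genes: Sequence[str] = DEFAULT_DRIVER_GENES,
    ancestral_max_shared: int = 5,
) -> ProgressionTree:
    """Assemble the four-node progression tree from a partition.

    Edge counts report protein-coding mutations (the printed convention),
    with all-event counts retained alongside.  In linear mode the ancestor
    coincides with the diagnosis clone.
    """
    mode = classify_mode(p, ancestral_max_shared)
    edges = {
        "origin->ancestor": _edge_info(p.common, p.cna_common, driver_genes),
        "ancestor->diagnosis": _edge_info(p.diagnosis_specific, p.cna_diagnosis, driver_genes),
        "ancestor->relapse": _edge_info(p.relapse_specific, p.cna_relapse, driver_genes),
    }
    edges["origin->ancestor"]["fusion"] = fusion_breakpoint
    relapse_edge = edges["ancestor->relapse"]
    return ProgressionTree(
        patient_id=patient_id,
        mode=mode,
        fusion_breakpoint=fusion_breakpoint,
        edges=edges,
        ancestor_is_diagnosis=(mode == "linear"),
        no_relapse_driver=(relapse_edge["all_events"] > 0 and not relapse_edge["drivers"]),
        ancestral_max_shared=ancestral_max_shared,
    )


def cohort_summary(trees: Sequence[ProgressionTree]) -> dict:
    """Cohort roll-up: mode counts, burden medians and the driver-by-patient
    matrix (gene -> patient -> edges it appears on)."""
    if not trees:
        raise ValueError("cohort_summary: no trees")
    mode_counts = {m: 0 for m in MODES}
    diag_burden: list[int] = []
    relapse_acquired: list[int] = []
    driver_matrix: dict[str, dict[str, list[str]]] = {}
    for t in trees:
        mode_counts[t.mode] += 1
        diag_burden.append(t.edges["origin->ancestor"]["coding_mutations"]
                           + t.edges["ancestor->diagnosis"]["coding_mutations"])
        relapse_acquired.append(t.edges["ancestor->relapse"]["coding_mutations"])
        for edge in EDGES:
            for g in t.edges[edge]["drivers"]:
                driver_matrix.setdefault(g, {}).setdefault(t.patient_id, []).append(edge)
    return {
        "n_patients": len(trees),
        "mode_counts": mode_counts,
        "median_diagnosis_coding_mutations": float(np.median(diag_burden)),
        "median_relapse_acquired_coding_mutations": float(np.median(relapse_acquired)),
        "driver_matrix": driver_matrix,
    }
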