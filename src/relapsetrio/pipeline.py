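"""End-to-end orchestration: filter -> copy number -> CCF -> ITD -> tree.

``run_trio`` drives one patient from parsed inputs to a TrioReport and,
when an output directory is given, writes every stage artifact (filtered
VCF, burden TSV, segment TSVs, ploidy/purity fit JSONs, ITD call JSON,
tree JSON + DOT, report JSON) with fixed float precision so reruns are
byte-identical.  ``run_cohort`` maps it over a manifest, isolating
per-patient failures, and rolls the trees up into a cohort summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ccf as ccf_mod
from .cna import CbsConfig, GapConfig, call_cna, segment_lookup
from .filtering import FilterConfig, call_trio, coverage_qc, summarize_burden
from .itd import ItdConfig, screen_sample
from .trees import (
    DEFAULT_DRIVER_GENES,
    CnaChange,
    build_tree,
    cohort_summary,
    harmonize_coverage,
    partition_events,
)
from .trio_io import (
    TrioDataset,
    load_trio,
    write_json,
    write_segments_tsv,
    write_tree_json,
    write_vcf,
)

log = logging.getLogger("relapsetrio")


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    cbs: CbsConfig = field(default_factory=CbsConfig)
    gap: GapConfig = field(default_factory=GapConfig)
    itd: ItdConfig = field(default_factory=ItdConfig)
    min_cross_coverage: int = 10
    ancestral_max_shared: int = 5
    driver_genes: tuple[str, ...] = DEFAULT_DRIVER_GENES
    purity_override: dict[str, float] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["itd"]["region"] = list(d["itd"]["region"])
        d["driver_genes"] = list(self.driver_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kw = {}
        if "filter" in d:
            kw["filter"] = FilterConfig(**d["filter"])
        if "cbs" in d:
            kw["cbs"] = CbsConfig(**d["cbs"])
        if "gap" in d:
            kw["gap"] = GapConfig(**d["gap"])
        if "itd" in d:
            itd = dict(d["itd"])
            if "region" in itd:
                itd["region"] = tuple(itd["region"])
            kw["itd"] = ItdConfig(**itd)
        for k in ("min_cross_coverage", "ancestral_max_shared", "purity_override"):
            if k in d:
                kw[k] = d[k]
        if "driver_genes" in d:
            kw["driver_genes"] = tuple(d["driver_genes"])
        return cls(**kw)


@dataclass
class TrioReport:
    patient_id: str
    burden: dict
    qc: dict
    mode: str | None
    tree: object | None
    fits: dict
    itd_calls: dict
    n_events: int
    n_discarded_low_coverage: int
    pairs_only: bool

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "burden": self.burden,
            "qc": {k: round(v, 4) for k, v in self.qc.items()},
            "mode": self.mode,
            "tree": self.tree.to_dict() if self.tree is not None else None,
            "fits": self.fits,
            "itd_calls": self.itd_calls,
            "n_events": self.n_events,
            "n_discarded_low_coverage": self.n_discarded_low_coverage,
            "pairs_only": self.pairs_only,
        }


def _aberrant_changes(segments) -> list[CnaChange]:
    return [CnaChange.from_segment(s) for s in segments if s.labels - {"normal"}]


def run_trio(
    trio: TrioDataset,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    snp_signals: dict[str, pd.DataFrame] | None = None,
    itd_counts: dict[str, pd.DataFrame] | None = None,
) -> TrioReport:
    """Run the full pipeline on one trio.

    ``snp_signals`` maps tumor role -> SNP B-allele count table (the
    copy-number stage is skipped for roles without one); ``itd_counts``
    maps sample role -> per-position mismatch table.
    """
    cfg = cfg or PipelineConfig()
    snp_signals = snp_signals or {}
    itd_counts = itd_counts or {}
    pid = trio.patient_id
    pairs_only = not trio.has_remission

    events = call_trio(trio, cfg.filter)
    log.info("%s: filtering retained %d somatic/candidate events", pid, len(events))

    segments_by_role: dict[str, list] = {}
    fits: dict[str, dict] = {}
    for role in ("diagnosis", "relapse"):
        sig = snp_signals.get(role)
        if sig is None:
            continue
        segments, fit = call_cna(sig, cfg.cbs, cfg.gap)
        segments_by_role[role] = segments
        fits[role] = {
            "purity": fit.purity, "ploidy": fit.ploidy,
            "contamination": fit.contamination, "fit_score": round(fit.fit_score, 6),
            "ambiguous": fit.ambiguous,
            "candidates": [list(c) for c in fit.candidates],
        }
        log.info("%s/%s: %d segments, purity %.2f ploidy %.2f",
                 pid, role, len(segments), fit.purity, fit.ploidy)

    contexts = {}
    for role in ("diagnosis", "relapse"):
        purity = cfg.purity_override.get(role)
        if purity is None:
            purity = fits.get(role, {}).get("purity", 1.0)
        lookup = segment_lookup(segments_by_role.get(role, []))

        def ctx_of(chrom, pos, _purity=purity, _lookup=lookup):
            seg = _lookup(chrom, pos)
            if seg is None or seg.cn_total is None:
                return ccf_mod.LocalContext(_purity, 2, 1)
            if seg.cn_total == 0:
                return None
            return ccf_mod.LocalContext(_purity, seg.cn_total, seg.cn_minor)

        contexts[role] = ctx_of
    ccf_mod.annotate_events(events, contexts)

    itd_calls = {}
    for role, counts in itd_counts.items():
        call = screen_sample(counts, cfg.itd)
        itd_calls[role] = {
            "flagged": call.flagged, "peak_fraction": round(call.peak_fraction, 4),
            "support_width": call.support_width, "zero_coverage": call.zero_coverage,
        }
        log.info("%s/%s: ITD %s (peak %.3f, width %d)", pid, role,
                 "FLAGGED" if call.flagged else "negative",
                 call.peak_fraction, call.support_width)

    tree = None
    mode = None
    n_discarded = 0
    if not pairs_only:
        retained, discarded = harmonize_coverage(events, trio, cfg.min_cross_coverage)
        n_discarded = len(discarded)
        partition = partition_events(
            retained,
            cna_diagnosis=_aberrant_changes(segments_by_role.get("diagnosis", [])),
            cna_relapse=_aberrant_changes(segments_by_role.get("relapse", [])),
            discarded=discarded,
        )
        tree = build_tree(
            partition, patient_id=pid, fusion_breakpoint=trio.fusion_breakpoint,
            driver_genes=cfg.driver_genes,
            ancestral_max_shared=cfg.ancestral_max_shared,
        )
        mode = tree.mode
        log.info("%s: partition common=%d diagnosis=%d relapse=%d -> %s",
                 pid, len(partition.common), len(partition.diagnosis_specific),
                 len(partition.relapse_specific), mode)

    burden = summarize_burden(events)
    qc = coverage_qc(trio.samples["diagnosis"]["depth"].to_numpy())
    report = TrioReport(
        patient_id=pid, burden=burden, qc=qc, mode=mode, tree=tree,
        fits=fits, itd_calls=itd_calls, n_events=len(events),
        n_discarded_low_coverage=n_discarded, pairs_only=pairs_only,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(events, outdir / f"{pid}.somatic.vcf")
        pd.DataFrame([
            {"patient": pid, "sample": "diagnosis", **burden["diagnosis"]},
            {"patient": pid, "sample": "relapse_acquired", **burden["relapse_acquired"]},
        ]).to_csv(outdir / f"{pid}.burden.tsv", sep="\t", index=False)
        for role, segments in segments_by_role.items():
            write_segments_tsv(segments, outdir / f"{pid}.{role}.segments.tsv", role)
            write_json(fits[role], outdir / f"{pid}.{role}.fit.json")
        if itd_calls:
            write_json(itd_calls, outdir / f"{pid}.itd.json")
        if tree is not None:
            write_tree_json(tree, outdir / f"{pid}.tree.json")
            (outdir / f"{pid}.tree.dot").write_text(tree.to_dot())
        write_json(report.to_dict(), outdir / f"{pid}.report.json")
    return report


def run_trio_files(
    patient_id: str,
    diagnosis: str | Path,
    relapse: str | Path,
    baits: str | Path,
    remission: str | Path | None = None,
    snps_diagnosis: str | Path | None = None,
    snps_relapse: str | Path | None = None,
    itd_files: dict[str, str | Path] | None = None,
    fusion_breakpoint: str = "unknown",
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> TrioReport:
    """Path-based entry point (the CLI's backend)."""
    from .cna import read_snp_signals
    from .itd import read_mismatch_counts

    trio = load_trio(patient_id, diagnosis, relapse, baits, remission,
                     fusion_breakpoint)
    snp_signals = {}
    for role, p in (("diagnosis", snps_diagnosis), ("relapse", snps_relapse)):
        if p is not None:
            snp_signals[role] = read_snp_signals(p)
    itd_counts = {}
    for role, p in (itd_files or {}).items():
        itd_counts[role] = read_mismatch_counts(p)
    return run_trio(trio, cfg, outdir, snp_signals, itd_counts)


def run_cohort(
    manifest: list[dict],
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[TrioReport], dict, list[dict]]:
    """Run every patient in a manifest (list of run_trio_files kwarg dicts).

    Failures are isolated per patient and returned as records; the cohort
    summary covers the successful trios with a tree.
    """
    if not manifest:
        raise ValueError("run_cohort: empty manifest")
    reports: list[TrioReport] = []
    failures: list[dict] = []
    for entry in manifest:
        pid = entry.get("patient_id", "?")
        try:
            sub = Path(outdir) / pid if outdir is not None else None
            reports.append(run_trio_files(cfg=cfg, outdir=sub, **entry))
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failures
            log.error("%s: FAILED (%s)", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    trees = [r.tree for r in reports if r.tree is not None]
    summary = cohort_summary(trees) if trees else {}
    if outdir is not None and reports:
        rows = []
        for r in reports:
            rows.append({
                "patient": r.patient_id, "mode": r.mode or "ND*",
                "diagnosis_substitutions": r.burden["diagnosis"]["substitutions"],
                "diagnosis_indels": r.burden["diagnosis"]["indels"],
                "relapse_acquired_substitutions": r.burden["relapse_acquired"]["substitutions"],
                "relapse_acquired_indels": r.burden["relapse_acquired"]["indels"],
            })
        pd.DataFrame(rows).to_csv(Path(outdir) / "cohort.tsv", sep="\t", index=False)
        write_json({"summary": summary, "failures": failures},
                   Path(outdir) / "cohort_summary.json")
    return reports, summary, failures
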