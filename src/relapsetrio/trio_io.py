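"""I/O layer and shared trio data model.

All external formats enter and leave the pipeline here: per-sample
allele-count tables (TSV), exome capture-bait intervals (BED), the
filtered-variant VCF export, SEG-style segment tables and progression-tree
JSON.  Every internal coordinate is 1-based (VCF convention); BED input is
converted on read.

The allele-count TSV contract (tab-separated, header required)::

    chrom  pos  ref  alt  depth  alt_reads  qphred  variant_class  functional  pop_af

with an optional trailing ``gene`` column carrying a symbol for driver
annotation.  ``pop_af`` may be empty (no population-database evidence).
"""

from __future__ import annotations

import bisect
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("diagnosis", "remission", "relapse")

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})
FUNCTIONAL_CLASSES = frozenset(
    {"synonymous", "missense", "nonsense", "splice", "frameshift", "inframe_indel", "noncoding"}
)
#: functional classes counted as protein-coding, non-synonymous events
CODING_CLASSES = frozenset({"missense", "nonsense", "splice", "frameshift", "inframe_indel"})

ALLELE_COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "alt_reads",
    "qphred", "variant_class", "functional", "pop_af",
]

SITE_KEY = ["chrom", "pos", "ref", "alt"]


class TrioFormatError(ValueError):
    """A file does not follow its declared format (missing columns, bad BED)."""


class TrioValidationError(ValueError):
    """A well-formed file carries values violating the data-model invariants."""


@dataclass(frozen=True)
class SiteObservation:
    """One sample's sequencing evidence at one genomic site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    qphred: float
    variant_class: str
    functional: str
    pop_af: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise TrioValidationError(f"{self.site}: pos must be >= 1")
        if self.ref == self.alt:
            raise TrioValidationError(f"{self.site}: ref == alt")
        if self.depth < 0 or self.alt_reads < 0 or self.qphred < 0:
            raise TrioValidationError(f"{self.site}: negative count or quality")
        if self.alt_reads > self.depth:
            raise TrioValidationError(
                f"{self.site}: alt_reads ({self.alt_reads}) > depth ({self.depth})"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise TrioValidationError(f"{self.site}: unknown variant_class {self.variant_class!r}")
        if self.functional not in FUNCTIONAL_CLASSES:
            raise TrioValidationError(f"{self.site}: unknown functional class {self.functional!r}")
        is_snv_shape = len(self.ref) == 1 and len(self.alt) == 1
        if (self.variant_class == "SNV") != is_snv_shape:
            raise TrioValidationError(
                f"{self.site}: variant_class {self.variant_class!r} inconsistent with alleles"
            )
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise TrioValidationError(f"{self.site}: pop_af outside [0,1]")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "SNV"

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else float("nan")


def read_allele_counts(path: str | Path, sample_role: str = "diagnosis") -> pd.DataFrame:
    """Parse one sample's allele-count TSV, enforcing the site invariants.

    Returns a DataFrame with the contract columns (plus ``gene`` if present).
    Rows violating an invariant abort the parse with a line-numbered error;
    the first data row is line 2 (line 1 is the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    except pd.errors.EmptyDataError:
        raise TrioFormatError(f"{path}: empty file, expected a header line") from None
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise TrioFormatError(f"{path}: missing required column(s) {missing}")
    if "gene" not in df.columns:
        df["gene"] = None
    df = df[ALLELE_COUNT_COLUMNS + ["gene"]].copy()
    if df.empty:
        return df

    lineno = df.index.to_numpy() + 2  # header is line 1

    def _fail(mask: np.ndarray, reason: str) -> None:
        if mask.any():
            i = int(np.argmax(mask))
            r = df.iloc[i]
            raise TrioValidationError(
                f"{path}:{lineno[i]} ({r.chrom}:{r.pos} {r.ref}>{r.alt}): {reason}"
            )

    pos = df["pos"].to_numpy()
    depth = df["depth"].to_numpy()
    alt_reads = df["alt_reads"].to_numpy()
    _fail(pos < 1, "pos must be >= 1")
    _fail((df["ref"] == df["alt"]).to_numpy(), "ref == alt")
    _fail((depth < 0) | (alt_reads < 0), "negative read count")
    _fail(alt_reads > depth, "alt_reads > depth")
    _fail((df["qphred"] < 0).to_numpy(), "negative qphred")
    _fail(~df["variant_class"].isin(VARIANT_CLASSES).to_numpy(), "unknown variant_class")
    _fail(~df["functional"].isin(FUNCTIONAL_CLASSES).to_numpy(), "unknown functional class")
    snv_shape = ((df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)).to_numpy()
    _fail((df["variant_class"] == "SNV").to_numpy() != snv_shape,
          "variant_class inconsistent with allele lengths")
    paf = df["pop_af"].to_numpy(dtype=float)
    _fail((~np.isnan(paf)) & ((paf < 0) | (paf > 1)), "pop_af outside [0,1]")
    dup = df.duplicated(SITE_KEY, keep=False).to_numpy()
    _fail(dup, f"duplicate site key within sample {sample_role!r}")
    return df


def observation_from_row(row: Mapping) -> SiteObservation:
    """Build a single :class:`SiteObservation` from one table row."""
    paf = row["pop_af"]
    gene = row.get("gene") if hasattr(row, "get") else row["gene"]
    if gene is not None and (gene != gene or gene == ""):  # NaN / empty -> absent
        gene = None
    return SiteObservation(
        chrom=str(row["chrom"]), pos=int(row["pos"]), ref=str(row["ref"]), alt=str(row["alt"]),
        depth=int(row["depth"]), alt_reads=int(row["alt_reads"]), qphred=float(row["qphred"]),
        variant_class=str(row["variant_class"]), functional=str(row["functional"]),
        pop_af=None if paf is None or paf != paf else float(paf),
        gene=gene,
    )


class BaitIntervals:
    """Merged exome capture-bait intervals with 1-based membership queries.

    Stored internally as sorted, non-overlapping 0-based half-open intervals
    per chromosome, exactly as read from BED.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise TrioFormatError(f"bait interval {chrom}:{start}-{end}: start >= end")
            if start < 0:
                raise TrioFormatError(f"bait interval {chrom}:{start}-{end}: negative start")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, path: str | Path) -> "BaitIntervals":
        ivs: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise TrioFormatError(f"{path}:{ln}: expected at least 3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise TrioFormatError(f"{path}:{ln}: non-integer BED coordinates") from None
                if start >= end:
                    raise TrioFormatError(f"{path}:{ln}: start >= end")
                ivs.append((parts[0], start, end))
        return cls(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based *pos* lies inside a bait on *chrom*."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p0 = pos - 1  # 0-based
        i = bisect.bisect_right(starts, p0) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def contains_many(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for i, (c, p) in enumerate(zip(chrom, pos)):
            out[i] = self.contains(c, int(p))
        return out

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e)
            for c in sorted(self._starts)
            for s, e in zip(self._starts[c], self._ends[c])
        ]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")


read_baits = BaitIntervals.from_bed


@dataclass
class TrioDataset:
    """All per-sample allele-count tables of one patient plus the bait set.

    Diagnosis and relapse are mandatory; remission is optional (pairs-only
    patients, in which somatic status at diagnosis is not assessable).
    """

    patient_id: str
    samples: dict[str, pd.DataFrame]
    baits: BaitIntervals
    fusion_breakpoint: str = "unknown"

    def __post_init__(self) -> None:
        for role in ("diagnosis", "relapse"):
            if role not in self.samples:
                raise TrioValidationError(f"patient {self.patient_id}: sample {role!r} is required")
        for role in self.samples:
            if role not in ROLES:
                raise TrioValidationError(f"patient {self.patient_id}: unknown role {role!r}")

    @property
    def has_remission(self) -> bool:
        return "remission" in self.samples

    def indexed(self, role: str) -> pd.DataFrame:
        """Sample table indexed by (chrom, pos, ref, alt) for site lookup."""
        return self.samples[role].set_index(SITE_KEY)


def load_trio(
    patient_id: str,
    diagnosis: str | Path,
    relapse: str | Path,
    baits: str | Path,
    remission: str | Path | None = None,
    fusion_breakpoint: str = "unknown",
) -> TrioDataset:
    samples = {
        "diagnosis": read_allele_counts(diagnosis, "diagnosis"),
        "relapse": read_allele_counts(relapse, "relapse"),
    }
    if remission is not None:
        samples["remission"] = read_allele_counts(remission, "remission")
    return TrioDataset(
        patient_id=patient_id,
        samples=samples,
        baits=read_baits(baits),
        fusion_breakpoint=fusion_breakpoint,
    )


# ---------------------------------------------------------------------------
# VCF export


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):09d}") if c.isdigit() else (1, c)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=relapse-trio
##INFO=<ID=SS,Number=1,Type=String,Description="Trio somatic status">
##INFO=<ID=PART,Number=1,Type=String,Description="Progression-tree partition label">
##INFO=<ID=RESCUED,Number=0,Type=Flag,Description="Promoted to shared by the cross-tumor rescue rule">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=CCF_D,Number=1,Type=Float,Description="Cancer cell fraction at diagnosis">
##INFO=<ID=CCF_R,Number=1,Type=Float,Description="Cancer cell fraction at relapse">
##INFO=<ID=SUBCLONAL_D,Number=1,Type=Integer,Description="Subclonal at diagnosis (CCF CI upper < 0.95)">
##INFO=<ID=SUBCLONAL_R,Number=1,Type=Integer,Description="Subclonal at relapse (CCF CI upper < 0.95)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">
##FORMAT=<ID=VF,Number=1,Type=Float,Description="Variant allele fraction">
"""


def write_vcf(events: Iterable, path: str | Path) -> None:
    """Write filtered somatic events as a VCF 4.2 file.

    Events are :class:`relapsetrio.filtering.SomaticEvent`; they are sorted
    on write.  Sample columns follow trio order (diagnosis, remission,
    relapse), restricted to roles present on at least one event.
    """
    events = sorted(events, key=lambda e: (_chrom_sort_key(e.chrom), e.pos, e.ref, e.alt))
    roles = [r for r in ROLES if any(r in e.per_sample for e in events)] or list(ROLES)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(e.chrom for e in events):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(r.upper() for r in roles)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for e in events:
            info = [f"SS={e.status}", f"PART={e.partition}", f"FCLASS={e.functional}"]
            if e.rescued:
                info.append("RESCUED")
            if e.gene:
                info.insert(2, f"GENE={e.gene}")
            for role, tag in (("diagnosis", "D"), ("relapse", "R")):
                est = e.ccf.get(role) if e.ccf else None
                if est is not None:
                    info.append(f"CCF_{tag}={est.ccf:.4f}")
                    info.append(f"SUBCLONAL_{tag}={int(est.subclonal)}")
            fmt = []
            for role in roles:
                ev = e.per_sample.get(role)
                if ev is None:
                    fmt.append(".:.:.")
                else:
                    vf = "." if ev.depth == 0 else f"{ev.alt_reads / ev.depth:.4f}"
                    fmt.append(f"{ev.depth}:{ev.alt_reads}:{vf}")
            qual = f"{e.qphred:.0f}" if e.qphred is not None else "."
            fh.write(
                f"{e.chrom}\t{e.pos}\t.\t{e.ref}\t{e.alt}\t{qual}\tPASS\t"
                + ";".join(info) + "\tDP:AD:VF\t" + "\t".join(fmt) + "\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read back a trio VCF (via htslib/cyvcf2) into a flat table.

    Used for round-trip checks and downstream consumption; one row per
    record with per-sample DP/AD and the trio INFO annotations.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [s.lower() for s in vcf.samples]
    rows = []
    for rec in vcf:
        row: dict = {
            "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0],
            "status": rec.INFO.get("SS"), "partition": rec.INFO.get("PART"),
            "gene": rec.INFO.get("GENE"), "functional": rec.INFO.get("FCLASS"),
            "rescued": rec.INFO.get("RESCUED") is not None,
        }
        dp = rec.format("DP")
        ad = rec.format("AD")
        for i, s in enumerate(samples):
            row[f"depth_{s}"] = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else None
            row[f"alt_reads_{s}"] = int(ad[i][0]) if ad is not None and ad[i][0] >= 0 else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segments and trees


def write_segments_tsv(segments: Iterable, path: str | Path, sample: str = "") -> None:
    """Write copy-number segments as a SEG-style TSV."""
    rows = []
    for s in segments:
        rows.append({
            "sample": sample, "chrom": s.chrom, "start": s.start, "end": s.end,
            "n_snps": s.n_snps,
            "lrr_mean": round(s.lrr_mean, 4),
            "baf_dev": round(s.baf_dev, 4) if s.baf_dev == s.baf_dev else "",
            "cn_total": s.cn_total if s.cn_total is not None else "",
            "cn_minor": s.cn_minor if s.cn_minor is not None else "",
            "labels": ",".join(sorted(s.labels)),
        })
    pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "n_snps", "lrr_mean",
                 "baf_dev", "cn_total", "cn_minor", "labels"],
    ).to_csv(path, sep="\t", index=False)


def write_tree_json(tree, path: str | Path) -> None:
    """Serialize a ProgressionTree to JSON (lossless round trip)."""
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_tree_json(path: str | Path):
    from .trees import ProgressionTree

    with open(path) as fh:
        return ProgressionTree.from_dict(json.load(fh))


def write_json(obj, path: str | Path) -> None:
    """Write a plain JSON artifact with stable key order and float precision."""

    def _default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return round(float(o), 6)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
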