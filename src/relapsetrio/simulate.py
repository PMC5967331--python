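"""Synthetic diagnosis/remission/relapse trio generator.

Emulates the study design on a configurable mini-genome: a germline SNP
background shared by all three samples, clone-structured somatic mutations
(ancestral = shared by both tumors, diagnosis-specific, relapse-specific),
binomially sampled read counts at a configurable mean depth (default 91x,
Poisson per site), tumor purity, per-base sequencing error, allele-specific
copy-number aberrations (including copy-neutral LOH with duplication of a
contained mutant allele) and an optional FLT3-ITD-like mismatch signal.

Expected VAF of a somatic mutation carried at cancer cell fraction c with
multiplicity m in a sample of purity alpha and local total copy number n:

    p = alpha * m * c / (alpha * n + 2 * (1 - alpha))

Read counts are Binomial(depth, p') with p' folded with the symmetric
per-base error rate; germline het/hom sites sit at p = 0.5 / 1.0 in every
sample.  Every output is deterministic given the seed, and a truth set
records clone assignments, true CCFs, multiplicities, copy-number states,
purities and the true mode, so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .itd import DEFAULT_REGION
from .trio_io import BaitIntervals, TrioDataset, write_json

CLONES = ("ancestral", "diagnosis_specific", "relapse_specific")
_BASES = np.array(list("ACGT"))


def default_chrom_sizes() -> dict[str, int]:
    return {f"chr{i}": 30_000_000 for i in range(1, 14)}


@dataclass(frozen=True)
class CnaSpec:
    """One simulated copy-number aberration."""

    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int
    samples: tuple[str, ...] = ("diagnosis", "relapse")


@dataclass(frozen=True)
class ItdSpec:
    carrier_fraction: float
    length: int = 30
    samples: tuple[str, ...] = ("diagnosis",)


@dataclass(frozen=True)
class LohInjection:
    """A cn-LOH segment duplicating one contained somatic mutation (m=2)."""

    spec: CnaSpec
    clone: str


@dataclass
class SimulationConfig:
    seed: int = 0
    mode: str = "linear"
    mean_depth: float = 91.0
    purity_diagnosis: float = 0.9
    purity_relapse: float = 0.85
    n_germline_snps: int = 2000
    rare_germline_fraction: float = 0.05
    n_ancestral_passengers: int = 12
    n_diagnosis_specific: int = 0
    n_relapse_specific: int = 3
    subclone_ccf: float | None = None
    cna_events: tuple[CnaSpec, ...] = ()
    loh_injection: LohInjection | None = None
    itd: ItdSpec | None = None
    error_rate: float = 0.001
    off_bait_fraction: float = 0.02
    indel_fraction: float = 0.15
    n_cna_snps: int = 1500
    het_snp_fraction: float = 0.7
    chrom_sizes: dict[str, int] = field(default_factory=default_chrom_sizes)
    fusion_breakpoint: str = "bcr1"
    driver_events: tuple[tuple[str, str], ...] = ()   # (gene symbol, clone)
    include_remission: bool = True
    ancestral_max_shared: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "branched", "ancestral"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.n_germline_snps, self.n_ancestral_passengers,
               self.n_diagnosis_specific, self.n_relapse_specific) < 0:
            raise ValueError("counts must be non-negative")
        for name in ("purity_diagnosis", "purity_relapse"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0,1]")
        if self.mode == "linear" and self.n_diagnosis_specific != 0:
            raise ValueError("linear mode requires n_diagnosis_specific = 0")
        if self.mode == "ancestral" and self.n_ancestral_passengers > self.ancestral_max_shared:
            raise ValueError(
                "ancestral mode requires n_ancestral_passengers <= "
                f"ancestral_max_shared ({self.ancestral_max_shared})"
            )

    @classmethod
    def for_mode(cls, mode: str, seed: int = 0, **kw) -> "SimulationConfig":
        """Study-condition defaults per evolution mode (diagnosis burden
        ~12-13 coding mutations, ~3 acquired at relapse)."""
        counts = {
            "linear": dict(n_ancestral_passengers=12, n_diagnosis_specific=0,
                           n_relapse_specific=3),
            "branched": dict(n_ancestral_passengers=9, n_diagnosis_specific=4,
                             n_relapse_specific=5),
            "ancestral": dict(n_ancestral_passengers=2, n_diagnosis_specific=11,
                              n_relapse_specific=3),
        }[mode]
        counts.update(kw)
        return cls(seed=seed, mode=mode, **counts)


@dataclass
class SimulatedTrio:
    config: SimulationConfig
    trio: TrioDataset
    snp_signals: dict[str, pd.DataFrame]      # tumor role -> SNP-signal table
    itd_counts: dict[str, pd.DataFrame]       # sample role -> mismatch table
    truth: dict


def inject_cn_loh(cfg: SimulationConfig, chrom: str = "chr11",
                  start: int = 1, end: int = 3_000_000,
                  samples: tuple[str, ...] = ("diagnosis", "relapse"),
                  clone: str | None = None) -> SimulationConfig:
    """Add a copy-neutral LOH segment duplicating one contained mutation.

    The first mutation of the chosen clone is relocated into the span and
    carried at multiplicity 2 in every sample bearing the segment.  The
    clone defaults to the earliest clone carried by all ``samples``.
    """
    if clone is None:
        if set(samples) == {"diagnosis", "relapse"}:
            clone = "ancestral"
        elif samples == ("diagnosis",):
            clone = "diagnosis_specific" if cfg.n_diagnosis_specific > 0 else "ancestral"
        else:
            clone = "relapse_specific" if cfg.n_relapse_specific > 0 else "ancestral"
    spec = CnaSpec(chrom, start, end, cn_total=2, cn_minor=0, samples=tuple(samples))
    return replace(cfg, cna_events=cfg.cna_events + (spec,),
                   loh_injection=LohInjection(spec, clone))


# ---------------------------------------------------------------------------
# internals

_SLOT = 1000  # candidate sites sit on a sparse grid, >=1 kb apart


def _draw_positions(rng: np.random.Generator, cfg: SimulationConfig, n: int,
                    exclude_spans: list[tuple[str, int, int]]) -> list[tuple[str, int]]:
    chroms = list(cfg.chrom_sizes)
    slots_per = {c: cfg.chrom_sizes[c] // _SLOT for c in chroms}
    offsets = np.cumsum([0] + [slots_per[c] for c in chroms])
    total = int(offsets[-1])
    want = n
    out: list[tuple[str, int]] = []
    taken: set[int] = set()
    while len(out) < want:
        draw = rng.choice(total, size=min(total, 2 * (want - len(out)) + 16), replace=False)
        for slot in draw:
            if int(slot) in taken:
                continue
            ci = int(np.searchsorted(offsets, slot, side="right")) - 1
            chrom = chroms[ci]
            pos = int(slot - offsets[ci]) * _SLOT + _SLOT // 2
            if any(c == chrom and s <= pos <= e for c, s, e in exclude_spans):
                continue
            taken.add(int(slot))
            out.append((chrom, pos))
            if len(out) == want:
                break
    return out


def _alleles(rng: np.random.Generator, variant_class: str) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if variant_class == "SNV":
        alt = str(rng.choice(_BASES[_BASES != ref]))
        return ref, alt
    tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    if variant_class == "insertion":
        return ref, ref + tail
    return ref + tail, ref


def _functional(rng: np.random.Generator, variant_class: str, somatic: bool) -> str:
    if not somatic:
        return str(rng.choice(["noncoding", "synonymous", "missense"], p=[0.7, 0.2, 0.1]))
    if variant_class == "SNV":
        return str(rng.choice(["missense", "nonsense", "splice"], p=[0.8, 0.12, 0.08]))
    return str(rng.choice(["frameshift", "inframe_indel"], p=[0.8, 0.2]))


def _effective_p(p: np.ndarray, err: float) -> np.ndarray:
    """Fold the true allele fraction with symmetric per-base miscalls."""
    return np.clip(p * (1.0 - err) + (1.0 - p) * err / 3.0, 0.0, 1.0)


def _sample_counts(rng: np.random.Generator, p_true: np.ndarray, mean_depth: float,
                   err: float) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(mean_depth, size=len(p_true))
    alt = rng.binomial(depth, _effective_p(p_true, err))
    return depth, alt


def _segment_state(cfg: SimulationConfig, role: str, chrom: str, pos: int
                   ) -> tuple[int, int]:
    for ev in cfg.cna_events:
        if role in ev.samples and ev.chrom == chrom and ev.start <= pos <= ev.end:
            return ev.cn_total, ev.cn_minor
    return 2, 1


def _sample_psi(cfg: SimulationConfig, role: str) -> float:
    total_len = float(sum(cfg.chrom_sizes.values()))
    psi = 2.0 * total_len
    for ev in cfg.cna_events:
        if role in ev.samples:
            psi += (ev.cn_total - 2) * (ev.end - ev.start + 1)
    return psi / total_len


def simulate_trio(cfg: SimulationConfig, outdir: str | Path | None = None
                  ) -> SimulatedTrio:
    """Generate one trio: allele-count tables, bait BED, per-tumor SNP
    signals, optional ITD profiles, and the truth set.

    Deterministic given ``cfg.seed``; with ``outdir`` set, every table is
    also written in the exact formats the pipeline consumes.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = ["diagnosis", "relapse"] + (["remission"] if cfg.include_remission else [])
    purity = {"diagnosis": cfg.purity_diagnosis, "relapse": cfg.purity_relapse}
    exclude = [(e.chrom, e.start, e.end) for e in cfg.cna_events]
    exclude.append(DEFAULT_REGION)

    n_som = cfg.n_ancestral_passengers + cfg.n_diagnosis_specific + cfg.n_relapse_specific
    positions = _draw_positions(rng, cfg, cfg.n_germline_snps + n_som, exclude)
    germ_pos = positions[:cfg.n_germline_snps]
    som_pos = positions[cfg.n_germline_snps:]
    clone_of = (["ancestral"] * cfg.n_ancestral_passengers
                + ["diagnosis_specific"] * cfg.n_diagnosis_specific
                + ["relapse_specific"] * cfg.n_relapse_specific)

    # cn-LOH injection relocates the first mutation of its clone into the span
    loh_site_idx: int | None = None
    if cfg.loh_injection is not None:
        inj = cfg.loh_injection
        idxs = [i for i, c in enumerate(clone_of) if c == inj.clone]
        if not idxs:
            raise ValueError(f"cn-LOH injection: clone {inj.clone!r} has no mutations")
        loh_site_idx = idxs[0]
        mid = (inj.spec.start + inj.spec.end) // 2
        som_pos[loh_site_idx] = (inj.spec.chrom, (mid // _SLOT) * _SLOT + _SLOT // 2)

    carriers = {
        "ancestral": ("diagnosis", "relapse"),
        "diagnosis_specific": ("diagnosis",),
        "relapse_specific": ("relapse",),
    }

    sites: list[dict] = []
    truth_mut: list[dict] = []
    for i, (chrom, pos) in enumerate(germ_pos):
        het = rng.random() < 2.0 / 3.0
        rare = rng.random() < cfg.rare_germline_fraction
        if rare:
            pop_af = float("nan") if rng.random() < 0.5 else round(float(rng.uniform(0, 0.01)), 4)
        else:
            pop_af = round(float(rng.uniform(0.05, 0.5)), 4)
        ref, alt = _alleles(rng, "SNV")
        sites.append(dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class="SNV",
            functional=_functional(rng, "SNV", somatic=False), pop_af=pop_af,
            gene="", germline=True, het=het, clone=None, in_bait=rng.random() >= cfg.off_bait_fraction,
        ))
    driver_pool = {clone: [g for g, c in cfg.driver_events if c == clone] for clone in CLONES}
    passenger_no = 0
    for i, (chrom, pos) in enumerate(som_pos):
        clone = clone_of[i]
        vclass = "SNV" if rng.random() >= cfg.indel_fraction else \
            str(rng.choice(["insertion", "deletion"]))
        ref, alt = _alleles(rng, vclass)
        if driver_pool[clone]:
            gene = driver_pool[clone].pop(0)
        else:
            passenger_no += 1
            gene = f"GENE{passenger_no:03d}"
        sites.append(dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=vclass,
            functional=_functional(rng, vclass, somatic=True), pop_af=float("nan"),
            gene=gene, germline=False, het=None, clone=clone,
            in_bait=rng.random() >= cfg.off_bait_fraction,
        ))

    # expected allele fraction per site per sample + read counts
    tables: dict[str, pd.DataFrame] = {}
    for role in roles:
        p_true = np.zeros(len(sites))
        for k, s in enumerate(sites):
            if s["germline"]:
                p_true[k] = 0.5 if s["het"] else 1.0
            elif role in ("diagnosis", "relapse") and role in carriers[s["clone"]]:
                a = purity[role]
                n_t, _ = _segment_state(cfg, role, s["chrom"], s["pos"])
                m = 2 if (loh_site_idx is not None
                          and s is sites[cfg.n_germline_snps + loh_site_idx]
                          and role in cfg.loh_injection.spec.samples) else 1
                ccf = 1.0
                if s["clone"] == "diagnosis_specific" and cfg.subclone_ccf is not None:
                    ccf = cfg.subclone_ccf
                p_true[k] = a * m * ccf / (a * n_t + 2.0 * (1.0 - a))
        depth, alt_reads = _sample_counts(rng, p_true, cfg.mean_depth, cfg.error_rate)
        carrier = p_true > 0
        qphred = np.where(carrier, rng.uniform(40, 80, len(sites)),
                          rng.uniform(2, 15, len(sites))).round(1)
        tables[role] = pd.DataFrame({
            "chrom": [s["chrom"] for s in sites],
            "pos": [s["pos"] for s in sites],
            "ref": [s["ref"] for s in sites],
            "alt": [s["alt"] for s in sites],
            "depth": depth, "alt_reads": alt_reads, "qphred": qphred,
            "variant_class": [s["variant_class"] for s in sites],
            "functional": [s["functional"] for s in sites],
            "pop_af": [s["pop_af"] for s in sites],
            "gene": [s["gene"] for s in sites],
        })

    for i, s in enumerate(sites[cfg.n_germline_snps:]):
        ccf = {role: 0.0 for role in ("diagnosis", "relapse")}
        for role in carriers[s["clone"]]:
            c = 1.0
            if s["clone"] == "diagnosis_specific" and cfg.subclone_ccf is not None:
                c = cfg.subclone_ccf
            ccf[role] = c
        m = 2 if loh_site_idx is not None and i == loh_site_idx else 1
        truth_mut.append(dict(
            chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
            clone=s["clone"], gene=s["gene"], functional=s["functional"],
            variant_class=s["variant_class"],
            coding=s["functional"] in ("missense", "nonsense", "splice",
                                       "frameshift", "inframe_indel"),
            ccf=ccf, multiplicity=m, in_bait=bool(s["in_bait"]),
        ))

    baits = BaitIntervals(
        (s["chrom"], s["pos"] - 101, s["pos"] + 100) for s in sites if s["in_bait"]
    )

    # --- per-tumor SNP signals for the copy-number stage
    snp_signals: dict[str, pd.DataFrame] = {}
    chroms = list(cfg.chrom_sizes)
    per_chrom = cfg.n_cna_snps // len(chroms) if cfg.n_cna_snps > 0 else 0
    snp_chrom: list[str] = []
    snp_pos: list[int] = []
    for c in chroms:
        step = cfg.chrom_sizes[c] // (per_chrom + 1)
        for k in range(1, per_chrom + 1):
            snp_chrom.append(c)
            snp_pos.append(k * step)
    snp_chrom_a = np.array(snp_chrom)
    snp_pos_a = np.array(snp_pos, dtype=int)
    is_het = rng.random(len(snp_pos_a)) < cfg.het_snp_fraction
    normal_depth = rng.poisson(cfg.mean_depth, len(snp_pos_a))
    normal_b = rng.binomial(normal_depth, np.where(is_het, 0.5, cfg.error_rate))
    for role in ("diagnosis", "relapse") if per_chrom > 0 else ():
        a = purity[role]
        psi = _sample_psi(cfg, role)
        n_tot = np.empty(len(snp_pos_a))
        n_b = np.empty(len(snp_pos_a))
        for k in range(len(snp_pos_a)):
            n, nb = _segment_state(cfg, role, snp_chrom_a[k], int(snp_pos_a[k]))
            flip = rng.random() < 0.5
            n_tot[k] = n
            n_b[k] = (n - nb) if flip else nb
        copies = a * n_tot + 2.0 * (1.0 - a)
        t_depth = rng.poisson(cfg.mean_depth * copies / (a * psi + 2.0 * (1.0 - a)))
        p_b = np.where(
            is_het,
            np.clip((a * n_b + (1.0 - a)) / np.maximum(copies, 1e-9),
                    cfg.error_rate, 1.0 - cfg.error_rate),
            cfg.error_rate,
        )
        t_b = rng.binomial(t_depth, p_b)
        snp_signals[role] = pd.DataFrame({
            "chrom": snp_chrom_a, "pos": snp_pos_a,
            "tumor_depth": t_depth, "tumor_b_reads": t_b,
            "normal_depth": normal_depth, "normal_b_reads": normal_b,
        })

    # --- ITD mismatch profiles
    itd_counts: dict[str, pd.DataFrame] = {}
    if cfg.itd is not None:
        chrom, start, end = DEFAULT_REGION
        n = end - start + 1
        mid = n // 2
        block = slice(mid - cfg.itd.length // 2, mid - cfg.itd.length // 2 + cfg.itd.length)
        for role in roles:
            depth = rng.poisson(cfg.mean_depth, n)
            mutated = rng.binomial(depth, cfg.error_rate)
            if role in cfg.itd.samples:
                # ITD-supporting reads span the whole short duplication, so
                # the mutated-base signal is coherent along the block: draw
                # the carrier reads once, then add per-position jitter
                n_carrier = rng.binomial(int(round(cfg.mean_depth)),
                                         cfg.itd.carrier_fraction)
                blk = np.arange(n)[block]
                depth[blk] = np.maximum(depth[blk], n_carrier)
                mutated[blk] = np.minimum(
                    n_carrier + rng.binomial(depth[blk] - n_carrier,
                                             cfg.error_rate),
                    depth[blk])
            itd_counts[role] = pd.DataFrame({
                "chrom": chrom, "pos": np.arange(start, end + 1),
                "depth": depth, "mutated_bases": mutated,
            })

    truth = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "purity": purity,
        "ploidy": {role: _sample_psi(cfg, role) for role in ("diagnosis", "relapse")},
        "fusion_breakpoint": cfg.fusion_breakpoint,
        "n_germline_snps": cfg.n_germline_snps,
        "mutations": truth_mut,
        "cna_events": [dataclasses.asdict(e) for e in cfg.cna_events],
        "itd": dataclasses.asdict(cfg.itd) if cfg.itd is not None else None,
    }

    patient_id = f"SIM{cfg.seed}"
    trio = TrioDataset(
        patient_id=patient_id,
        samples={r: tables[r] for r in roles},
        baits=baits,
        fusion_breakpoint=cfg.fusion_breakpoint,
    )
    sim = SimulatedTrio(config=cfg, trio=trio, snp_signals=snp_signals,
                        itd_counts=itd_counts, truth=truth)
    if outdir is not None:
        write_trio_files(sim, outdir)
    return sim


def write_trio_files(sim: SimulatedTrio, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated table in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = sim.trio.patient_id
    paths: dict[str, Path] = {}
    for role, table in sim.trio.samples.items():
        p = outdir / f"{pid}_{role}.tsv"
        t = table.copy()
        t["qphred"] = t["qphred"].map(lambda v: f"{v:.1f}")
        t["pop_af"] = t["pop_af"].map(lambda v: "" if v != v else f"{v:.4f}")
        t.to_csv(p, sep="\t", index=False)
        paths[role] = p
    bed = outdir / f"{pid}_baits.bed"
    sim.trio.baits.to_bed(bed)
    paths["baits"] = bed
    for role, table in sim.snp_signals.items():
        p = outdir / f"{pid}_{role}_snps.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"snps_{role}"] = p
    for role, table in sim.itd_counts.items():
        p = outdir / f"{pid}_{role}_itd.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"itd_{role}"] = p
    truth_path = outdir / f"{pid}_truth.json"
    write_json(sim.truth, truth_path)
    paths["truth"] = truth_path
    return paths


def simulate_cohort(
    n_per_mode: tuple[int, int, int] = (9, 4, 5),
    seed: int = 0,
    base: SimulationConfig | None = None,
    median_diagnosis_burden: float = 12.5,
    median_relapse_acquired: float = 3.0,
    outdir: str | Path | None = None,
) -> list[SimulatedTrio]:
    """Simulate a cohort with the given number of linear / branched /
    ancestral trios; per-trio burdens are drawn around the configured
    medians and per-trio seeds derive deterministically from ``seed``.
    """
    if sum(n_per_mode) < 1:
        raise ValueError("cohort must contain at least one trio")
    master = np.random.default_rng(seed)
    sims: list[SimulatedTrio] = []
    pid_no = 0
    for mode, n in zip(("linear", "branched", "ancestral"), n_per_mode):
        for _ in range(n):
            pid_no += 1
            trio_seed = int(master.integers(0, 2**31 - 1))
            diag_total = max(4, int(master.poisson(median_diagnosis_burden)))
            rel = int(master.poisson(median_relapse_acquired))
            if mode == "linear":
                anc, dspec, rspec = diag_total, 0, rel
            elif mode == "branched":
                dspec = max(1, int(round(diag_total * 0.3)))
                anc = max(7, diag_total - dspec)   # branched trunks share many events
                rspec = max(1, rel)
            else:
                anc = int(master.integers(0, 4))
                dspec = max(1, diag_total - anc)
                rspec = rel
            pur_d = float(master.uniform(0.65, 0.95))
            pur_r = float(master.uniform(0.65, 0.95))
            kw = {} if base is None else {
                f.name: getattr(base, f.name) for f in dataclasses.fields(base)
                if f.name not in ("seed", "mode", "n_ancestral_passengers",
                                  "n_diagnosis_specific", "n_relapse_specific",
                                  "purity_diagnosis", "purity_relapse")
            }
            cfg = SimulationConfig(
                seed=trio_seed, mode=mode,
                n_ancestral_passengers=anc, n_diagnosis_specific=dspec,
                n_relapse_specific=rspec,
                purity_diagnosis=pur_d, purity_relapse=pur_r, **kw,
            )
            sim = simulate_trio(cfg)
            sim.trio.patient_id = f"P{pid_no:02d}"
            sim.truth["patient_id"] = f"P{pid_no:02d}"
            if outdir is not None:
                write_trio_files(sim, Path(outdir) / sim.trio.patient_id)
            sims.append(sim)
    return sims
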