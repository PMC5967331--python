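"""Cancer cell fraction (CCF) estimation.

For a somatic mutation observed at variant allele fraction ``vaf`` in a
tumor sample of purity alpha, lying in a region of total tumor copy number
n_t (normal cells assumed diploid), the fraction of tumor cells carrying
the mutation on m copies is

    CCF = vaf * (alpha * n_t + 2 * (1 - alpha)) / (alpha * m)

The multiplicity m is chosen as the integer in [1, n_t - cn_minor] whose
expected VAF is nearest the observed one.  Uncertainty comes from the
binomial sampling of alt reads: an exact Clopper-Pearson 95% interval on
the VAF is mapped through the (monotone) CCF transform.  A mutation is
subclonal when the upper CCF bound is below 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: raw CCF values are truncated to this ceiling (noise can push past 1)
CCF_MAX = 1.5
SUBCLONAL_UPPER = 0.95


@dataclass(frozen=True)
class LocalContext:
    """Purity and local allele-specific copy number at a mutated site."""

    purity: float
    cn_total: int = 2
    cn_minor: int = 1
    normal_copies: int = 2  # 1 on male sex chromosomes

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0,1], got {self.purity}")
        if self.cn_total < 0 or self.cn_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.cn_minor > self.cn_total - self.cn_minor:
            raise ValueError("cn_minor must not exceed the major copy number")

    @property
    def tumor_fraction_denominator(self) -> float:
        """alpha*n_t + c_n*(1-alpha): average copies per cell in the sample."""
        a = self.purity
        return a * self.cn_total + self.normal_copies * (1.0 - a)


@dataclass(frozen=True)
class CCFEstimate:
    ccf: float                # truncated to [0, 1]
    ccf_raw: float            # untruncated point estimate
    ccf_ci: tuple[float, float]
    multiplicity: int
    subclonal: bool


def estimate_multiplicity(vaf: float, ctx: LocalContext) -> int:
    """Number of mutated copies per carrying cell, by nearest-expected-VAF
    rounding, clamped to [1, major copy number]."""
    if not 0.0 < vaf <= 1.0:
        raise ValueError(f"vaf must be in (0,1], got {vaf}")
    if ctx.cn_total < 1:
        raise ValueError("cn_total must be >= 1 to estimate multiplicity")
    raw = vaf * ctx.tumor_fraction_denominator / ctx.purity
    m = int(np.floor(raw + 0.5))
    upper = max(1, ctx.cn_total - ctx.cn_minor)
    return min(max(m, 1), upper)


def compute_ccf(vaf: float, ctx: LocalContext, m: int) -> float:
    """Raw (untruncated) CCF for a given multiplicity."""
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    return vaf * ctx.tumor_fraction_denominator / (ctx.purity * m)


def ccf_confidence_interval(
    alt_reads: int, depth: int, ctx: LocalContext, m: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact Clopper-Pearson interval on the VAF mapped through the CCF
    transform, truncated to [0, CCF_MAX]."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads outside [0, depth]")
    a = (1.0 - level) / 2.0
    lo = 0.0 if alt_reads == 0 else float(stats.beta.ppf(a, alt_reads, depth - alt_reads + 1))
    hi = 1.0 if alt_reads == depth else float(stats.beta.ppf(1 - a, alt_reads + 1, depth - alt_reads))
    lo_ccf = min(max(compute_ccf(lo, ctx, m), 0.0), CCF_MAX)
    hi_ccf = min(max(compute_ccf(hi, ctx, m), 0.0), CCF_MAX)
    return (lo_ccf, hi_ccf)


def call_subclonal(upper_ci: float) -> bool:
    """Subclonal iff the 95% CI upper bound on the CCF is below 0.95."""
    return upper_ci < SUBCLONAL_UPPER


def estimate_ccf(alt_reads: int, depth: int, ctx: LocalContext) -> CCFEstimate:
    """Full CCF estimate for one mutation: multiplicity, point estimate,
    exact CI and the subclonality call.

    Sites in homozygously deleted segments (cn_total = 0) are inconsistent
    with carrying a mutation and raise ValueError.
    """
    if ctx.cn_total == 0:
        raise ValueError("mutation in a homozygous deletion (cn_total=0) is inconsistent")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    vaf = alt_reads / depth
    m = estimate_multiplicity(vaf, ctx) if vaf > 0 else 1
    raw = compute_ccf(vaf, ctx, m)
    ci = ccf_confidence_interval(alt_reads, depth, ctx, m)
    return CCFEstimate(
        ccf=min(max(raw, 0.0), 1.0),
        ccf_raw=raw,
        ccf_ci=ci,
        multiplicity=m,
        subclonal=call_subclonal(ci[1]),
    )


def annotate_events(events, contexts) -> None:
    """Attach CCF estimates to somatic events, in place.

    ``contexts`` maps tumor role -> callable(chrom, pos) -> LocalContext
    (typically a segment lookup built from the copy-number fit).
    """
    for e in events:
        for role, ctx_of in contexts.items():
            if not e.somatic_in(role):
                continue
            ev = e.per_sample.get(role)
            if ev is None or ev.depth < 1:
                continue
            ctx = ctx_of(e.chrom, e.pos)
            if ctx is None or ctx.cn_total == 0:
                continue
            e.ccf[role] = estimate_ccf(ev.alt_reads, ev.depth, ctx)
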