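"""Allele-specific copy-number analysis from exome SNP signals.

Pipeline: per-SNP LRR/BAF computation from tumor/normal allele counts ->
circular binary segmentation (CBS) of LRR and of mirrored BAF deviation ->
joint ploidy/contamination grid fit against the allele-specific
copy-number lattice -> per-segment state assignment and aberration labels.

Signals
-------
LRR is the median-centered log2 ratio of tumor to normal depth; BAF the
tumor B-allele fraction at SNPs heterozygous in the normal (remission)
sample.  Phase is discarded: segmentation and fitting use the mirrored
deviation |BAF - 0.5|.

Lattice model
-------------
For tumor purity alpha and sample ploidy psi, a segment in allele-specific
state (n_A, n_B), n = n_A + n_B, is expected at

    LRR     = log2((alpha*n + 2(1-alpha)) / (alpha*psi + 2(1-alpha)))
    BAF dev = |alpha*n_B + (1-alpha) - (alpha*n + 2(1-alpha))/2|
              / (alpha*n + 2(1-alpha))

The grid fit minimizes the SNP-weighted squared distance of observed
segment (LRR, BAF dev) pairs to their nearest lattice point.

Aberration labels, with psi rounded to the nearest integer: gain when
n >= psi+1, loss when n <= psi-1, high-level amplification when n > psi+2,
homozygous deletion when n = 0, LOH when n_B = 0 (copy-neutral when
additionally n equals the rounded ploidy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_SIGNAL_COLUMNS = ["chrom", "pos", "tumor_depth", "tumor_b_reads",
                      "normal_depth", "normal_b_reads"]


@dataclass
class CbsConfig:
    n_permutations: int = 1000
    alpha: float = 0.01
    min_width: int = 5
    seed: int = 20170915


@dataclass
class GapConfig:
    """Grid and lattice bounds of the ploidy/contamination fit."""

    alpha_min: float = 0.2
    alpha_max: float = 1.0
    alpha_step: float = 0.01
    psi_min: float = 1.5
    psi_max: float = 5.0
    psi_step: float = 0.05
    max_total_cn: int = 8
    outlier_distance: float = 0.5      # squared-distance flag threshold
    lrr_winsor: float = 3.0            # |LRR| cap, observed and expected
    # Denser high-ploidy lattices always fit residual noise better, and the
    # doubling (alpha, psi) -> (alpha/(2-alpha), 2*psi) is an exact model
    # degeneracy.  The reported solution is therefore the lowest ploidy
    # whose best score is within this ratio of the global optimum (the
    # parsimony preference of ploidy callers generally).
    ploidy_tie_ratio: float = 3.0
    psi_cluster_width: float = 0.3


@dataclass
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    n_snps: int
    lrr_mean: float
    baf_dev: float                      # NaN when the segment has no het SNPs
    lrr_sem: float = float("nan")       # standard error of lrr_mean
    baf_dev_sem: float = float("nan")
    cn_total: int | None = None
    cn_minor: int | None = None
    labels: set[str] = field(default_factory=set)
    outlier: bool = False

    @property
    def has_baf(self) -> bool:
        return self.baf_dev == self.baf_dev


@dataclass
class PloidyPurityFit:
    ploidy: float
    purity: float
    fit_score: float
    candidates: list[tuple[float, float, float]]  # (purity, ploidy, score), ranked
    ambiguous: bool = False

    @property
    def contamination(self) -> float:
        return 1.0 - self.purity


def read_snp_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SNP-signal column(s) {missing}")
    return df


def compute_lrr_baf(signals: pd.DataFrame, min_normal_depth: int = 10) -> pd.DataFrame:
    """Per-SNP LRR/BAF table from tumor/normal depths and B-allele counts.

    Sites with zero normal depth are dropped; het status comes from the
    normal-sample BAF lying in [0.25, 0.75] at adequate normal depth.
    """
    df = signals.copy()
    df = df[df["normal_depth"] > 0].reset_index(drop=True)
    t_dep = df["tumor_depth"].to_numpy(dtype=float)
    n_dep = df["normal_depth"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        lrr = np.log2(np.maximum(t_dep, 0.5) / n_dep)
    lrr -= np.median(lrr)
    n_baf = df["normal_b_reads"].to_numpy(dtype=float) / n_dep
    is_het = (n_baf >= 0.25) & (n_baf <= 0.75) & (n_dep >= min_normal_depth)
    with np.errstate(invalid="ignore"):
        baf = np.where(t_dep > 0, df["tumor_b_reads"].to_numpy(dtype=float) / np.maximum(t_dep, 1), np.nan)
    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "lrr": lrr, "baf": baf, "is_het": is_het,
    })
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Circular binary segmentation


def _max_circular_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t| over circular arcs [i, j) of x, with both the arc and its
    complement at least ``min_width`` long.  Returns (t_max, i, j)."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sd = x.std()
    if sd == 0 or n < 2 * min_width:
        return (0.0, 0, n)
    best_t, best_i, best_j = 0.0, 0, n
    for w in range(min_width, n - min_width + 1):
        arc = s[w:] - s[:-w]                      # sums of arcs of width w
        mean_in = arc / w
        mean_out = (total - arc) / (n - w)
        t = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / w + 1.0 / (n - w)))
        k = int(np.argmax(t))
        if t[k] > best_t:
            best_t, best_i, best_j = float(t[k]), k, k + w
    return best_t, best_i, best_j


def cbs_changepoints(x: np.ndarray, cfg: CbsConfig | None = None,
                     rng: np.random.Generator | None = None) -> list[int]:
    """CBS changepoint indices of a 1-D signal.

    Recursive maximal circular t-statistic splits with a permutation test
    (p < alpha); segments shorter than 2*min_width are never split.  The
    permutation stream is seeded for determinism.
    """
    cfg = cfg or CbsConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = np.asarray(x, dtype=float)
    # exceedance count above which p >= alpha is certain: p = (k+1)/(nperm+1)
    max_exceed = int(np.ceil(cfg.alpha * (cfg.n_permutations + 1))) - 1
    out: list[int] = []

    def _significant(seg: np.ndarray, t_obs: float) -> bool:
        if t_obs <= 0:
            return False
        exceed = 0
        perm = seg.copy()
        for _ in range(cfg.n_permutations):
            rng.shuffle(perm)
            t_p, _, _ = _max_circular_t(perm, cfg.min_width)
            if t_p >= t_obs:
                exceed += 1
                if exceed > max_exceed:
                    return False
        return True

    def _recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * cfg.min_width:
            return
        t_obs, i, j = _max_circular_t(seg, cfg.min_width)
        if not _significant(seg, t_obs):
            return
        cuts = sorted({c for c in (i, j) if 0 < c < len(seg)})
        bounds = [lo] + [lo + c for c in cuts] + [hi]
        out.extend(b for b in bounds[1:-1])
        for a, b in zip(bounds[:-1], bounds[1:]):
            _recurse(a, b)

    _recurse(0, len(x))
    return sorted(set(out))


def segment_profile(signals: pd.DataFrame, cfg: CbsConfig | None = None
                    ) -> list[CopyNumberSegment]:
    """Segment a per-SNP LRR/BAF profile chromosome by chromosome.

    CBS runs independently on the LRR track (all SNPs) and on the mirrored
    BAF deviation of het SNPs; the union of breakpoints cuts the profile,
    so allelic-imbalance-only events (e.g. copy-neutral LOH) are found even
    when the LRR track is flat.
    """
    cfg = cfg or CbsConfig()
    segments: list[CopyNumberSegment] = []
    for chrom, grp in signals.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable").reset_index(drop=True)
        rng = np.random.default_rng(cfg.seed)
        cuts = set(cbs_changepoints(grp["lrr"].to_numpy(), cfg, rng))
        het = grp[grp["is_het"]]
        if len(het) >= 2 * cfg.min_width:
            dev = np.abs(het["baf"].to_numpy() - 0.5)
            het_cuts = cbs_changepoints(dev, cfg, rng)
            het_idx = het.index.to_numpy()
            cuts.update(int(het_idx[c]) for c in het_cuts)
        bounds = [0] + sorted(cuts) + [len(grp)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a == b:
                continue
            block = grp.iloc[a:b]
            hets = block[block["is_het"]]
            dev = np.abs(hets["baf"].to_numpy() - 0.5)
            segments.append(CopyNumberSegment(
                chrom=str(chrom),
                start=int(block["pos"].iloc[0]),
                end=int(block["pos"].iloc[-1]),
                n_snps=len(block),
                lrr_mean=float(block["lrr"].mean()),
                baf_dev=float(dev.mean()) if len(hets) else float("nan"),
                lrr_sem=float(block["lrr"].std(ddof=1) / np.sqrt(len(block)))
                if len(block) > 1 else float("nan"),
                baf_dev_sem=float(dev.std(ddof=1) / np.sqrt(len(dev)))
                if len(dev) > 1 else float("nan"),
            ))
    return segments


# ---------------------------------------------------------------------------
# Ploidy/contamination lattice fit


def _lattice_states(max_total: int) -> np.ndarray:
    """(n_total, n_minor) pairs with n_minor <= n_total/2, n_total <= max."""
    states = [(n, b) for n in range(0, max_total + 1) for b in range(0, n // 2 + 1)]
    return np.array(states, dtype=float)


def _expected_signals(alpha: float, psi: float, states: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    n = states[:, 0]
    nb = states[:, 1]
    copies = alpha * n + 2.0 * (1.0 - alpha)
    copies = np.maximum(copies, 0.05)          # keep log finite at (alpha=1, n=0)
    denom = alpha * psi + 2.0 * (1.0 - alpha)
    elrr = np.log2(copies / denom)
    edev = np.abs(alpha * nb + (1.0 - alpha) - copies / 2.0) / copies
    return elrr, edev


def fit_ploidy_purity(segments: list[CopyNumberSegment], cfg: GapConfig | None = None
                      ) -> PloidyPurityFit:
    """Grid search for (purity, ploidy) minimizing the SNP-weighted squared
    distance of segments to the allele-specific copy-number lattice.

    Segments without het SNPs contribute through LRR only.  Near-ties are
    resolved toward the lowest ploidy and flagged ambiguous (a genome with
    a single copy-number state cannot identify purity).
    """
    cfg = cfg or GapConfig()
    if not segments:
        raise ValueError("fit_ploidy_purity: no segments")
    if not any(s.has_baf for s in segments):
        raise ValueError("fit_ploidy_purity: no segment has het SNPs")
    states = _lattice_states(cfg.max_total_cn)
    lrr = np.clip([s.lrr_mean for s in segments], -cfg.lrr_winsor, cfg.lrr_winsor)
    dev = np.array([s.baf_dev for s in segments])
    w = np.array([s.n_snps for s in segments], dtype=float)
    has_baf = ~np.isnan(dev)
    dev_f = np.where(has_baf, dev, 0.0)

    alphas = np.round(np.arange(cfg.alpha_min, cfg.alpha_max + 1e-9, cfg.alpha_step), 10)
    psis = np.round(np.arange(cfg.psi_min, cfg.psi_max + 1e-9, cfg.psi_step), 10)
    scores = np.empty((len(alphas), len(psis)))
    n = states[:, 0]
    nb = states[:, 1]
    for ia, a in enumerate(alphas):
        copies = np.maximum(a * n + 2.0 * (1.0 - a), 0.05)
        edev = np.abs(a * nb + (1.0 - a) - copies / 2.0) / copies
        log_copies = np.log2(copies)
        d_dev2 = np.where(has_baf[:, None], (dev_f[:, None] - edev[None, :]) ** 2, 0.0)
        for ip, p in enumerate(psis):
            elrr = np.clip(log_copies - np.log2(a * p + 2.0 * (1.0 - a)),
                           -cfg.lrr_winsor, cfg.lrr_winsor)
            d2 = (lrr[:, None] - elrr[None, :]) ** 2 + d_dev2
            scores[ia, ip] = float(np.sum(w * d2.min(axis=1)))

    per_psi = scores.min(axis=0)                    # best score at each ploidy
    best_score = float(per_psi.min())
    # expected score of a correct model: each segment mean sits ~1 SEM from
    # its lattice point, contributing n * sem^2; three times that is the
    # slack granted to lower-ploidy solutions over denser (overfitting)
    # high-ploidy lattices
    noise = 0.0
    for s in segments:
        if s.lrr_sem == s.lrr_sem:
            noise += s.n_snps * s.lrr_sem**2
        if s.has_baf and s.baf_dev_sem == s.baf_dev_sem:
            noise += s.n_snps * s.baf_dev_sem**2
    tol = max(best_score * cfg.ploidy_tie_ratio, best_score + 3.0 * noise, best_score + 1e-12)
    psi_star = float(psis[np.argmax(per_psi <= tol)])  # lowest acceptable ploidy
    cluster = (psis >= psi_star) & (psis <= psi_star + cfg.psi_cluster_width)
    sub = np.where(cluster, per_psi, np.inf)
    ip = int(np.argmin(sub))
    ia = int(np.argmin(scores[:, ip]))
    chosen_score = float(scores[ia, ip])
    # ambiguous when purity is unidentifiable: the score is exactly flat
    # across alpha at the chosen ploidy (e.g. an all-normal profile, where
    # every balanced state fits any purity).  Scaled higher-ploidy
    # solutions always exist and are reported among the candidates instead.
    tie_eps = chosen_score * 1e-6 + 1e-9
    alpha_range = float(scores[:, ip].max() - chosen_score)
    ambiguous = bool(alpha_range <= tie_eps)

    # runner-up solutions: per-ploidy optima away from the chosen cluster
    chosen = (float(alphas[ia]), float(psis[ip]), chosen_score)
    runner_psis = np.argsort(per_psi, kind="stable")
    cands = [chosen]
    for p_i in runner_psis:
        if abs(psis[p_i] - psis[ip]) <= cfg.psi_cluster_width:
            continue
        a_i = int(np.argmin(scores[:, p_i]))
        cands.append((float(alphas[a_i]), float(psis[p_i]), float(scores[a_i, p_i])))
        if len(cands) >= 5:
            break
    return PloidyPurityFit(
        ploidy=chosen[1], purity=chosen[0], fit_score=chosen[2],
        candidates=cands, ambiguous=ambiguous,
    )


def assign_allele_specific_cn(segments: list[CopyNumberSegment], fit: PloidyPurityFit,
                              cfg: GapConfig | None = None) -> list[CopyNumberSegment]:
    """Assign each segment the lattice state nearest its (LRR, BAF dev).

    Ties break toward the lowest total copy number, then the highest minor
    copy number (parsimony toward normal states).  Distances above the
    outlier threshold keep their state but set the outlier flag.
    """
    cfg = cfg or GapConfig()
    states = _lattice_states(cfg.max_total_cn)
    # tie-break ordering: sort states by (n_total asc, n_minor desc)
    order = np.lexsort((-states[:, 1], states[:, 0]))
    states = states[order]
    elrr, edev = _expected_signals(fit.purity, fit.ploidy, states)
    elrr = np.clip(elrr, -cfg.lrr_winsor, cfg.lrr_winsor)
    for s in segments:
        d2 = (np.clip(s.lrr_mean, -cfg.lrr_winsor, cfg.lrr_winsor) - elrr) ** 2
        if s.has_baf:
            d2 = d2 + (s.baf_dev - edev) ** 2
        k = int(np.argmin(d2))  # first minimum respects the tie-break order
        s.cn_total = int(states[k, 0])
        s.cn_minor = int(states[k, 1])
        s.outlier = bool(d2[k] > cfg.outlier_distance)
    return segments


def classify_aberrations(segments: list[CopyNumberSegment], fit: PloidyPurityFit
                         ) -> list[CopyNumberSegment]:
    """Label segments: gain / loss / high_amplification / homozygous_deletion
    / LOH / cn_neutral_LOH / normal, relative to the rounded sample ploidy."""
    psi = int(np.floor(fit.ploidy + 0.5))
    for s in segments:
        if s.cn_total is None:
            raise ValueError("classify_aberrations: states not assigned")
        labels: set[str] = set()
        if s.cn_total >= psi + 1:
            labels.add("gain")
        if s.cn_total <= psi - 1:
            labels.add("loss")
        if s.cn_total > psi + 2:
            labels.add("high_amplification")
        if s.cn_total == 0:
            labels.add("homozygous_deletion")
        if s.cn_minor == 0 and s.cn_total >= 1:
            labels.add("LOH")
            if s.cn_total == psi:
                labels.add("cn_neutral_LOH")
        if not labels:
            labels.add("normal")
        s.labels = labels
    return segments


def call_cna(signals: pd.DataFrame, cbs_cfg: CbsConfig | None = None,
             gap_cfg: GapConfig | None = None
             ) -> tuple[list[CopyNumberSegment], PloidyPurityFit]:
    """Full copy-number pipeline: segment, fit, assign, label."""
    segments = segment_profile(compute_lrr_baf(signals), cbs_cfg)
    fit = fit_ploidy_purity(segments, gap_cfg)
    assign_allele_specific_cn(segments, fit, gap_cfg)
    classify_aberrations(segments, fit)
    return segments, fit


def segment_lookup(segments: list[CopyNumberSegment]):
    """Point-in-segment lookup: (chrom, pos) -> CopyNumberSegment or None."""
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.start)

    def lookup(chrom: str, pos: int) -> CopyNumberSegment | None:
        for s in by_chrom.get(chrom, ()):
            if s.start <= pos <= s.end:
                return s
        return None

    return lookup
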