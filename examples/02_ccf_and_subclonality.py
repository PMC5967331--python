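"""Cancer cell fraction and subclonality of individual mutations.

Shows the purity/copy-number correction CCF = VAF*(alpha*n_t + 2(1-alpha))
/ (alpha*m) and the exact binomial confidence interval behind the
subclonality call (upper bound < 0.95 -> subclonal).
"""

from relapsetrio import LocalContext
from relapsetrio.ccf import estimate_ccf

cases = [
    ("clonal het, pure diploid tumor", 45, 91, LocalContext(1.0, 2, 1)),
    ("clonal het at 50% purity", 23, 91, LocalContext(0.5, 2, 1)),
    ("subclonal mutation (20% of cells)", 9, 91, LocalContext(1.0, 2, 1)),
    ("mutant allele duplicated by cn-LOH", 80, 91, LocalContext(0.9, 2, 0)),
]

print(f"{'case':38s} {'VAF':>6s} {'m':>2s} {'CCF':>5s} {'95% CI':>14s}  call")
for label, alt, depth, ctx in cases:
    est = estimate_ccf(alt, depth, ctx)
    lo, hi = est.ccf_ci
    call = "subclonal" if est.subclonal else "clonal"
    print(f"{label:38s} {alt/depth:6.3f} {est.multiplicity:2d} {est.ccf:5.2f} "
          f"[{lo:5.2f}, {hi:5.2f}]  {call}")

print("\nm is the inferred number of mutated copies per carrying cell; the")
print("cn-LOH case reads ~0.9 VAF because both retained copies are mutant.")
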