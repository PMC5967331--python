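"""Filter somatic mutations from one diagnosis/remission/relapse trio.

Generates a small synthetic trio (germline SNP background + clone-structured
somatic mutations at ~91x), applies the quality/somatic/rescue/population
filter chain, and prints the per-status tally and burden summary.
"""

from collections import Counter

from relapsetrio import call_trio, summarize_burden
from relapsetrio.simulate import SimulationConfig, simulate_trio

cfg = SimulationConfig.for_mode("branched", seed=11, n_germline_snps=500,
                                n_cna_snps=0)
sim = simulate_trio(cfg)
events = call_trio(sim.trio)

print(f"{len(sim.trio.samples['diagnosis'])} input sites per sample "
      f"-> {len(events)} somatic events after filtering")
for status, n in sorted(Counter(e.status for e in events).items()):
    print(f"  {status:20s} {n}")

burden = summarize_burden(events)
print(f"burden at diagnosis: {burden['diagnosis']} "
      f"(truth: {cfg.n_ancestral_passengers + cfg.n_diagnosis_specific} coding mutations)")
print(f"acquired at relapse: {burden['relapse_acquired']} "
      f"(truth: {cfg.n_relapse_specific})")
print("\nShared events were acquired in the common ancestor of both tumors;")
print("diagnosis-/relapse-specific events are private to one clone.")
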