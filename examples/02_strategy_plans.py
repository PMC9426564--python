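"""Expand the four assembly-binning strategies into concrete work plans.

For N samples and G coassembly groups the four strategies cost very
different numbers of read-mapping jobs: single-binning maps each sample
only to its own assembly (N jobs), while cobinning maps every sample to
every assembly (N^2 jobs for single assemblies, N*G for coassemblies).
"""

import coamag as cm

samples = [f"s{i}" for i in range(1, 5)]
groups = cm.CoassemblyPlan(groups={1: ["s1", "s2", "s3"], 2: ["s4"]}, source_k=2)

for strategy in ("SASB", "SACB", "CASB", "CACB"):
    plan = cm.plan_strategy(samples, groups, strategy)
    print(f"{strategy}: {len(plan.assembly_units)} assembly units, "
          f"{len(plan.mapping_jobs)} mapping jobs")
    for unit in plan.assembly_units:
        print(f"    {unit.unit_id}: assembles {', '.join(unit.member_samples)}")

# SACB's 16 = N^2 jobs are the price of co-abundance across the whole
# dataset; CACB needs only N*G = 8 because coassembly reduced the number of
# assemblies to map against.  The plan files (emit_plan) are the contract
# handed to the external assembler/aligner.
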