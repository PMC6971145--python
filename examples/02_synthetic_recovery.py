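"""Plant structure, recover it, and audit the PCR-error singletons.

Generates a noisy synthetic dataset (3 allele groups per locus, 2-3 protein
variants per group, 10% once-observed PCR-error singletons 1-2 nt off a real
allele), curates it, and scores recovery against the generator's truth
table.
"""

from bfbl import SynthConfig, curate, generate, score_recovery

gen = generate(SynthConfig(seed=42))
print(f"emitted {len(gen.records)} records, "
      f"{int(gen.truth.is_pcr_error.sum())} planted PCR-error singletons")

result = curate(gen.records, gen.evidence)
scores = score_recovery(result, gen.truth)
for key, value in scores.items():
    print(f"  {key}: {value:g}")

# 100% locus/group/variant recovery means the threshold clustering rebuilt
# exactly the planted partition of valid identity classes; flagged_pct=100
# with named=0 means every planted PCR artefact was caught by the
# replication requirement and the 1-2 nt proximity flag, and none was given
# an allele name.
for cid, flag in sorted(result.suspect_flags.items()):
    print(f"  provisional {cid}: {flag}")
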