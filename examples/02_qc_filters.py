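"""Variant and sample quality control on a simulated cohort.

Applies the four-step variant filter (INFO, MAF, missingness, HWE),
trims extreme BMD values, and shows the KING-robust kinship estimator
distinguishing a duplicated sample from unrelated ones.
"""

from prsport import qc
from prsport import simulate as sim
from prsport.io import GenotypeMatrix

spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(500,),
                          ancestral_maf_range=(0.0005, 0.5))
freqs = sim.simulate_population_frequencies(spec, 3000, seed=4)
geno, _, variants = sim.simulate_genotypes(freqs, (500,),
                                           sim.LDBlockSpec(1, 0.0), seed=5,
                                           missing_rate=0.02)
gm = GenotypeMatrix(geno, [f"S{i}" for i in range(500)],
                    variants[["chrom", "pos", "id", "ref", "alt"]])

kept, tally = qc.variant_qc(gm)
print(f"variant QC kept {len(kept)}/{gm.m}; removed by filter: {tally}")

cohort, _ = sim.simulate_phenotypes(geno, variants,
                                    sim.TraitArchitecture(), seed=6)
trimmed, log = qc.exclude_bmd_outliers(cohort, pct=0.1)
print(f"BMD outlier trim removed {len(log)} samples "
      f"(0.1th/99.9th percentile, union over both sites)")

phi_dup = qc.estimate_kinship(geno[0], geno[0], min_overlap=1000)
phi_unrel = qc.estimate_kinship(geno[0], geno[1], min_overlap=1000)
print(f"kinship: duplicate pair {phi_dup:.3f} (expected 0.5), "
      f"unrelated pair {phi_unrel:.3f} (expected ~0)")
print(f"HWE exact p for counts (30, 20, 50): "
      f"{qc.hwe_exact_test(30, 20, 50):.3e}  # heterozygote deficit")
# A kinship of 0.5 marks duplicates/identical twins; the 0.0442 cutoff
# in prune_related removes third-degree or closer relatives.
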