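"""Tandem-repeat classification, motif fraction tables and fingerprints.

Classifies a synthetic pool against the standard motif panel (>= 7 copies
for 1-3 nt motifs, 6 for 4 nt, 4 for 6-8 nt), then compares two conditions
as fingerprints, and evaluates how (im)probable a long repeat is by chance.
"""

from doodlekit.motifs import (
    Fingerprint,
    fingerprint_change,
    motif_fraction_table,
    motif_probability,
)
from doodlekit.simulate import LengthModel, PoolComponent, PoolSpec, simulate_pool

spec = PoolSpec(
    components=(
        PoolComponent("GT", 0.5),
        PoolComponent("CTATAG", 0.2),
        PoolComponent("RANDOM", 0.3),
    ),
    length_model=LengthModel(modes=((200.0, 0.3, 1.0),)),
    n_reads=2000,
    seed=7,
    target_median_q=20,
)
pool = simulate_pool(spec)

table = motif_fraction_table(pool, n_sample=600, seed=1)
print("motif fractions (600 sampled reads > 65 nt):")
print(table[table["fraction"] > 0])
# fractions approximate the generator's 0.5 / 0.2 mixture weights; random
# reads essentially never reach 7 exact tandem copies.

fp_65 = Fingerprint({"CTATAG": 0.02, "TCATGA": 0.40, "CTTAAG": 0.30}, 600)
fp_74 = Fingerprint({"CTATAG": 0.40, "TCATGA": 0.20, "CTTAAG": 0.001}, 600)
print("\nfingerprint change between two conditions:")
print(fingerprint_change(fp_65, fp_74)[["percent_change", "fold_change"]])

p = motif_probability(30)
print(f"\nP(specific 30-mer at one position | uniform bases) = {p:.3g}")
# ~8.67e-19: a perfect (CTATAG)^5 is vanishingly unlikely by chance.
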