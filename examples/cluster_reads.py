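"""Hierarchically cluster reads on composition/transition/autocorrelation features.

Two repeat classes separate cleanly; each top cluster is labelled by the
motif passing its copy threshold in a majority of member reads.
"""

from doodlekit.clustering import featurize_reads, hierarchical_top_clusters, label_clusters
from doodlekit.simulate import LengthModel, PoolComponent, PoolSpec, simulate_pool

spec = PoolSpec(
    components=(PoolComponent("GT", 0.5), PoolComponent("AATT", 0.5)),
    length_model=LengthModel(modes=((200.0, 0.25, 1.0),)),
    n_reads=120,
    seed=3,
    target_median_q=25,
)
pool = simulate_pool(spec)

features = featurize_reads(pool, max_lag=24)
result = label_clusters(pool, hierarchical_top_clusters(features, n_top=2))

truth = {r.id: r.meta["true_class"] for r in pool}
for cid, members in enumerate(result.top_clusters):
    classes = [truth[m] for m in members]
    purity = max(classes.count(c) for c in set(classes)) / len(members)
    print(f"cluster {cid}: size={len(members)}  label={result.labels[cid]}  purity={purity:.2f}")
# purity ~1.0: the feature blocks (composition, transitions, r(k)) suffice
# to separate distinct tandem-repeat families.
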