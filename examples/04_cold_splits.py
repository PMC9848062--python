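"""Cold-split protocols and the similarity-filtered hard setting.

Shows the three protocols (novel pair / compound / protein), the dropped
straddler count of the pair protocol, and how the 0.3 similarity filter
thins the novel-pair test set.
"""

from cpifuse import (
    generate_synthetic, split_novel_pair, split_novel_compound,
    split_novel_protein, filter_hard, kfold,
)
from cpifuse.splits import check_disjoint

ds = generate_synthetic(n_compounds=20, n_proteins=10, density=0.6,
                        noise_sd=0.3, seed=3, length_range=(40, 80))

for fn in (split_novel_pair, split_novel_compound, split_novel_protein):
    asg = fn(ds, test_fraction=0.3, seed=1)
    checks = check_disjoint(asg, ds)
    print(f"{asg.protocol:15s} train={len(asg.indices('train')):3d} "
          f"val={len(asg.indices('validation')):3d} "
          f"test={len(asg.indices('test')):3d} dropped={asg.n_dropped:3d} "
          f"disjoint={all(checks.values())}")

asg = split_novel_pair(ds, test_fraction=0.3, seed=1)
test = [ds.records[i] for i in asg.indices("test")]
train = [ds.records[i] for i in
         asg.indices("train") + asg.indices("validation")]
for thr in (0.9, 0.5, 0.3):
    kept = filter_hard(test, train, threshold=thr)
    print(f"hard filter at {thr}: {len(kept)}/{len(test)} test records kept")
# A smaller threshold keeps a subset of a larger threshold's records.

folds = kfold(ds, k=5, protocol="novel_compound", seed=2)
print("5-fold novel-compound test sizes:",
      [len(a.indices('test')) for a in folds])
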