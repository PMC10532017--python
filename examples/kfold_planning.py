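"""Patient-wise 10-fold cross-validation planning.

922 patients do not divide by 10: each fold gets floor(922/10) = 92
patients and the 2 leftover patients join every training set (they are
never tested), so every fold trains on 830 and tests on 92.
"""

from lesionprep import fold_split, make_fold_plan

ids = [f"patient_{i:03d}" for i in range(922)]
plan = make_fold_plan(ids, k=10, seed=42)

print(f"{len(ids)} patients, k = {plan.k}, seed = {plan.seed}")
print(f"remainder (always train): {sorted(plan.remainder())}")
for i in range(plan.k):
    train, test = fold_split(plan, i)
    print(f"fold {i}: train {len(train)}, test {len(test)}")
# Every non-remainder patient appears in exactly one test set; no patient
# is ever on both sides of a fold.
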