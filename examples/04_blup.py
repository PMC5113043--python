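"""REML variance components and BLUPs for an augmented field trial.

Fits y = checks(fixed) + row + column + accession + error by REML for
one trait in one environment of a simulated augmented design, and
compares the estimated variance components with the realized variances
of the effects the simulator actually drew.
"""

from durmap import SimConfig, fit_augmented_reml, generate_collection
from durmap.simulate import generate_trial

config = SimConfig(seed=1, environments=("C",))
dataset, ledger = generate_collection(config)
trial = generate_trial(dataset, config, ledger)

vc, blups = fit_augmented_reml(trial, "plant_height", "C")
truth = ledger.variance_truth.iloc[0]
print("variance components (REML estimate vs realized):")
for name, key in [("row", "realized_var_row"), ("col", "realized_var_col"),
                  ("accession", "realized_var_acc"), ("error", "realized_var_e")]:
    est = vc.as_dict()[f"sigma2_{name if name != 'accession' else 'acc'}"
                       if name != "error" else "sigma2_e"]
    print(f"  {name:9s}: {est:6.3f}  vs {truth[key]:6.3f}")
print(f"converged: {vc.converged}, REML loglik: {vc.reml_loglik:.2f}")
top = blups.predicted.sort_values(ascending=False).head(3)
print("highest predicted accessions:")
print(top.round(2).to_string())
# The predicted value is intercept + accession BLUP: the accession's
# phenotype freed of check, row and column effects.
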