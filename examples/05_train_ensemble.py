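"""Train the four-submodel voting ensemble on a synthetic cohort.

Labels: bad prognosis = MIBC death within 60 months; good = survived the
cut-off; patients censored earlier are excluded.  The ensemble calls a
patient high-risk when ≥ 2 submodels vote bad prognosis.

Runs in a few minutes on one CPU (120 patients, 10-configuration search).
"""

import immunocontext as ic

config = ic.CohortConfig(
    n_patients=120,
    seed=5,
    effect_sizes={"TB_density_core": 1.0, "cytotoxic_T_density_frontin": -1.0},
)
result = ic.run_study(config, n_configs=10)

rep = result.label_report
print(f"labels: {rep.n_bad} bad / {rep.n_good} good / {rep.n_excluded} excluded")
print(f"split: {len(result.train_ids)} train / {len(result.test_ids)} test")

for sub in result.ensemble.submodels:
    print(f"  {sub.family:>15} on {sub.feature_set:<22} "
          f"train AUROC {sub.train_auc:.2f} threshold {sub.threshold:.3f}")

er = result.ensemble_report
print(f"\nheld-out ensemble: AUROC {er['auroc']:.1f}%  accuracy {er['accuracy']:.1f}%")
print(f"TNM baseline:      AUROC {result.tnm_report['auroc']:.1f}%")
# the ensemble's score is the 0–4 bad-prognosis vote count; with planted
# immune-contexture effects it should clearly beat the anatomical baseline
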