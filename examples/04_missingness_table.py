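"""Missing-data comparison table (logistic link, MCAR + mean imputation).

Runs the missingness grid {0, 25, 50}% at a reduced replicate count and
renders the comparison table: predictive performance (ROC AUC) and summed
attribution fidelity for the agnostic and informed networks.
"""

from pesnet.experiments import ExperimentConfig, render_table1, run_experiment

cfg = ExperimentConfig(
    experiment="exp1_logistic", n_replicates=2, seed=0,
    missing_grid=(0.0, 0.25, 0.5), shap_samples=128,
)
df = run_experiment(cfg)
print(render_table1(df).to_string(index=False, float_format="%.3f"))
print(
    "\nAs cells go missing, the agnostic network's captured relationships"
    "\ndrift (Sum Δ Shap grows) while the informed network, anchored by"
    "\nodds-ratio priors on all three predictors, degrades far less."
)
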