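"""Full pipeline on a synthetic study: generate, featurize, train, evaluate.

Generates a cluster-structured network with planted domain-disease signal,
computes Feature-II tables on the leakage-controlled network, trains the
gradient-boosted classifier, and prints the held-out AUC and F1 for both
leakage modes, plus the signal-ablation control.
"""

from hetpath import SyntheticConfig, run_study

config = SyntheticConfig(seed=1)  # 200 domains, 400 proteins, 60 diseases
print("study conditions:", config)

result = run_study(config, preset="Feature-II")
print(f"\npaper-style leakage (test edges removed): "
      f"AUC {result.report.auc:.3f}  F1 {result.report.f1:.3f}")
print("  -> ranking survives, but probabilities are miscalibrated because")
print("     training positives keep their own label edges in the network.")

strict = run_study(config, preset="Feature-II", mask_mode="strict")
print(f"strict leakage (every pair's own edge masked): "
      f"AUC {strict.report.auc:.3f}  F1 {strict.report.f1:.3f}")

ablated = run_study(config, preset="Feature-II", ablate_signal=True)
print(f"signal ablation (labels decoupled from network): "
      f"AUC {ablated.report.auc:.3f}")
print("\nAUC near 0.5 under ablation confirms the classifier is reading")
print("genuine network structure, not an artifact of the protocol.")
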