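{
  "name": "ar-binding-consensus-logistic",
  "version": "1.0",
  "feature_names": [
    "ChimpDockScore",
    "avgD_Act",
    "avgD_Inact",
    "P_Act_dockChimp",
    "P_Inact"
  ],
  "beta": 26.169,
  "alphas": [-0.0175, -98.582, 66.953, 3.584, -8.594],
  "ll": -407.619,
  "meta": {
    "description": "Published five-descriptor consensus logistic model for androgen-receptor binding: chimp docking score (kcal/mol), average Tanimoto distances to known binders/non-binders, and class-conditional Gaussian densities of the docking score.",
    "training": "CoMPARA training set, n=1685 (205 binders / 1480 non-binders)",
    "threshold": 0.5
  }
}
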