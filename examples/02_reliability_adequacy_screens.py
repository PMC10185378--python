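"""Screen characteristics for inter-rater reliability (ICC) and sampling
adequacy (KMO/MSA, Bartlett) before factoring.

One characteristic is deliberately corrupted to pure rater noise: the ICC
screen should flag it, mirroring how poorly-agreed-on rating scales are
dropped before a factor analysis."""
import numpy as np

import actionspace as a

cfg = a.default_config(n_actions=120, seed=7)
sim = a.simulate_study(cfg)
records = sim.study.records.copy()
rng = np.random.default_rng(0)
mask = records["characteristic"] == "char_05"
records.loc[mask, "rating"] = rng.integers(1, 10, size=int(mask.sum()))
study = a.RatingStudy(records=records, characteristics=sim.study.characteristics)

report = a.reliability_screen(study, threshold=0.5)
print(report.to_frame()[["characteristic", "kappa", "band", "excluded"]]
      .head(8).to_string(index=False))
print(f"excluded for poor agreement (ICC < .5): {report.excluded}")

matrix = a.aggregate_means(study).subset(characteristics=report.retained)
adq = a.adequacy_screen(matrix, msa_threshold=0.6)
print(f"overall KMO on retained set: {adq.kmo_overall:.3f} "
      "(values above ~.7 indicate a factorable correlation matrix)")
print(f"Bartlett chi2({adq.bartlett_df}) = {adq.bartlett_chi2:.1f}, "
      f"p = {adq.bartlett_p:.2e} (rejects an identity correlation matrix)")
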