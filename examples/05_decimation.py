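"""Decimation robustness: does the winning factor count survive fewer
actions or fewer raters?

Actions are removed at random down to a 7:1 action-to-characteristic ratio
(and rater pools shrunk), re-running the split-half comparison at each
level.  Positive AIC differences mean the four-factor model stays optimal;
the five-factor model often runs close, since an extra factor costs only a
small AIC penalty against whatever chance structure it absorbs."""
import actionspace as a

cfg = a.default_config(seed=1)
sim = a.simulate_study(cfg)
matrix = a.aggregate_means(sim.study)

curve = a.decimate_actions(matrix, ks=(2, 4, 5), grid=(240, 180, 140),
                           n_sims=10, master_seed=1)
print("action decimation (level = number of actions kept):")
print(curve[curve["k"] != 4][["level", "k", "delta_aic_mean", "ci_low",
                              "ci_high", "winner_k"]].round(2)
      .to_string(index=False))

raters = a.decimate_raters(sim.study, ks=(2, 4), rater_counts=(10, 4),
                           n_sims=6, master_seed=1)
print("\nrater decimation (mean ratings from fewer participants):")
print(raters[raters["k"] == 2][["rater_count", "delta_aic_mean", "ci_low",
                                "ci_high", "winner_k"]].round(2)
      .to_string(index=False))
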