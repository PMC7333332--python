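"""Choose the penalty by StARS subsampling stability.

Refits the differential network on 50 random half-subsamples of the bins
at every grid penalty and prints the instability profile: D_hat is the
average edge-selection disagreement across subsamples, D_bar its monotone
envelope along increasing network density. The selected penalty is the
densest network whose envelope stays below beta.
"""

import warnings

import tfrewire as tw

warnings.filterwarnings("ignore")

truth = tw.make_truth(J=10, n_shared_edges=6, n_diff_edges=4,
                      effect_size=0.8, seed=2)
X0, X1 = tw.sample_paired(truth, n=2000, seed=3)

profile = tw.instability_profile(X0, X1, S=50, fraction=0.5, seed=4)
lam, profile = tw.select_lambda(profile, beta=0.005)

print(profile.summary_frame().to_string(index=False,
                                        float_format=lambda v: f"{v:.4f}"))
print(f"\nselected lambda = {lam:.4f} "
      f"(largest density with D_bar <= {profile.beta})")
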