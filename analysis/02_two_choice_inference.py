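"""Two-choice inference: Poisson mixed model and the Bayesian choice posterior.

Reads results/data/nights.csv (run 01_simulate_datasets.py first), excludes
nights without laying, fits the cluster-count GLMM, and computes the
posterior of the per-cluster probability of choosing the playback side.
Writes results/two_choice.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ovisound import bayes_choice_posterior, exclude_empty_nights, fit_poisson_glmm
from ovisound.io import read_nights

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"

nights = read_nights(ROOT / "data" / "nights.csv")
kept, dropped = exclude_empty_nights(nights)
print(f"{len(nights)} arena-nights, {dropped} with no laying excluded")

fit = fit_poisson_glmm(kept, exclude_empty=False)
est, se, p = fit.beta["treatment"], fit.se["treatment"], fit.p["treatment"]
print(
    f"playback effect (log rate ratio): {est:.2f} ± {se:.2f}, p = {p:.2g} "
    f"-> ×{np.exp(est):.2f} clusters on the playback side"
)

# per-cluster choices: 1 = playback side
choices = pd.DataFrame(
    {
        "choice01": np.r_[
            np.ones(int(kept["clusters_treatment"].sum())),
            np.zeros(int(kept["clusters_control"].sum())),
        ],
        "n_females": np.r_[
            np.repeat(kept["n_females"], kept["clusters_treatment"]),
            np.repeat(kept["n_females"], kept["clusters_control"]),
        ],
    }
)
post = bayes_choice_posterior(choices, seed=SEED)
print(
    f"posterior P(playback side): {post.mean:.2f} "
    f"[{post.ci95[0]:.2f}, {post.ci95[1]:.2f}] from {post.n_obs} clusters"
)

out = {
    "n_nights": len(nights),
    "n_excluded": dropped,
    "glmm": {
        "estimate": est,
        "se": se,
        "p": p,
        "sigma_u": fit.sigma_u,
        "converged": fit.converged,
    },
    "bayes": post.summary(),
}
(ROOT / "two_choice.json").write_text(json.dumps(out, indent=2))
print("wrote results/two_choice.json")
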