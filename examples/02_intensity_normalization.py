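"""α-stable intensity normalization of a cohort with scanner-gain spread.

Each image's extra-striatal background is fitted with an α-stable law; the
per-image (γ, δ) are mapped onto the cohort means (γ*, δ*) by the linear
transform y = a·x + b with a = γ*/γ and b = δ* − a·δ.
"""

import numpy as np

from datfuse import PhantomConfig, generate_cohort, normalize_cohort
from datfuse.stable_norm import background_mask, fit_stable

cohort = generate_cohort(
    PhantomConfig(n_hc=3, n_pd=3, grid_shape=(40, 48, 40), gain_sd=0.4, seed=3)
)
ids = list(cohort.subject_ids)
volumes = [cohort.volumes[s] for s in ids]

normalized, params, ref = normalize_cohort(volumes, cohort.atlas, subject_ids=ids)
print(f"reference: gamma* = {ref.gamma_star:.3f}, delta* = {ref.delta_star:.3f}")
for sid, p in zip(ids, params):
    print(f"{sid}: alpha={p.alpha:.3f} gamma={p.gamma:.3f} "
          f"delta={p.delta:.3f} ({p.method})")

spread_pre = np.std([p.delta for p in params])
refits = [fit_stable(v.data[background_mask(v, cohort.atlas)]) for v in normalized]
spread_post = np.std([p.delta for p in refits])
print(f"between-image delta spread: {spread_pre:.3f} -> {spread_post:.3f}")
# The simulated gains spread the per-image locations; after normalization the
# refitted locations collapse onto delta*, so the spread drops sharply.
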