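"""Grid-search mechanism selection for one metabolite/gene pair.

Builds a noisy experiment-shaped pair in which the metabolite follows the
monotone-increasing archetype (M-1) and its matched uptake gene the
noon-peaking diel archetype (G-1), sweeps all eight mechanism variants and
ranks them by adjusted mean correlation.
"""

from dielflux import ExperimentDesign
from dielflux.fitting import default_grid, grid_search, select_variant
from dielflux.model import VARIANTS
from dielflux.synthetic import archetype_pair_series

design = ExperimentDesign()
pair = archetype_pair_series("M-1", design, noise_sd=0.3, seed=0)

results = {}
for variant in VARIANTS:
    res = grid_search(default_grid(variant), design,
                      pair["met_series"], pair["gene_series"])
    results[variant] = res
    print(f"{variant:4s}: {res.n_saved:4d}/{res.n_combinations} parameter "
          f"sets pass the dual p<0.05 screen"
          + (f"; best mean r = {res.best.mean_r:.3f}" if res.best else ""))

report = select_variant(results, n=design.n_timepoints, mode="printed")
print("\nwinner:", report.winner)
# A monotone-increasing endometabolite paired with noon-peaking uptake
# cannot be produced by passive diffusion alone: the winning variant
# includes the bacterial-response term b.
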