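"""Localize a simulated movie and estimate the accuracy from the data alone.

The NeNA estimate uses only nearest-neighbor distances between localizations
in adjacent frames, so it is independent of photon-count-based accuracy
predictions.  With a photo-bleaching non-switching background the estimate
improves over the acquisition, which the per-epoch trend makes visible.
"""

import smlmclem as sm

movie, schedule, emitters, psf = sm.bleaching_background_movie(seed=1)
print(f"movie: {movie.n_frames} frames, background bleaching over the acquisition")

table = sm.localize_for_nena(movie, psf)
print(f"{len(table)} localizations (unmerged; adjacent-frame repeats kept)")

overall = sm.estimate_accuracy_nena(table)
print(f"overall accuracy sigma = {overall.sigma_loc:.1f} nm "
      f"from {overall.n_pairs} adjacent-frame pairs")

trend = sm.accuracy_trend(table, n_epochs=3)
for est in trend:
    print(f"  frames {est.epoch[0]:4d}-{est.epoch[1]:4d}: "
          f"sigma = {est.sigma_loc:.1f} nm  ({est.n_pairs} pairs)")
# The accuracy improves from ~17 nm to ~12-13 nm as the non-switching
# population photo-bleaches and the background drops.
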