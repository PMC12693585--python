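"""Code promoter alignments into events and score hotspot accumulation (d).

Simulates promoter alignments for a 'hotspot' gene group (4x event rate in
the promoter region) and a control group, codes each species against the
reference into 0/1 events, tallies them, and computes the d score of each
group against the control baseline Se^C with a chi-squared comparison.
"""

import numpy as np

from promevol import (
    DEFAULT_REGION,
    compare_groups_chi2,
    control_baseline,
    d_score,
    pairwise_events,
    sliding_event_score,
    tally_events,
    trim_to_window,
)
from promevol.simulate import AlignmentConfig, simulate_promoter_alignment

rng = np.random.default_rng(3)
n_genes = 8
configs = {
    "hotspot": AlignmentConfig(hotspot_multiplier=4.0),
    "control": AlignmentConfig(hotspot_multiplier=1.0),
}

tallies = {}
for name, cfg in configs.items():
    vectors = []
    for i in range(n_genes):
        aln, _truth = simulate_promoter_alignment(cfg, f"{name}{i}", rng)
        aln = trim_to_window(aln)  # reference offsets [-1000, +300)
        vectors += [pairwise_events(aln, sp, mode="all") for sp in cfg.species]
    tallies[name] = tally_events(vectors, group=name)

se_c = control_baseline([sliding_event_score(tallies["control"])], DEFAULT_REGION)
print(f"control baseline Se^C over {DEFAULT_REGION}: {se_c:.3f}")

scores = {}
for name, tally in tallies.items():
    scores[name] = d_score(sliding_event_score(tally), tally, se_c, DEFAULT_REGION)
    s = scores[name]
    print(f"{name:8s}: {s.n_events:4d} events, {s.n_exceeding:4d} exceed Se^C "
          f"-> d = {s.d:5.1f}%")

chi2, p, p_bonf = compare_groups_chi2(
    scores["hotspot"].n_exceeding, scores["hotspot"].n_events,
    scores["control"].n_exceeding, scores["control"].n_events,
)
print(f"chi-squared = {chi2:.1f}, p = {p:.2e} (Bonferroni x1: {p_bonf:.2e})")
# d is the percentage of promoter-region events sitting in windows busier
# than the control average; the hotspot group should score markedly higher.
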