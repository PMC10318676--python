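"""Discover duration-labeled stages from a synthetic cohort.

Runs the core chain — overlapping 5-year duration windows, covariate-
adjusted case-control t-maps per indicator, affinity propagation with
Calinski-Harabasz state selection, cross-indicator alignment, and
Liptak-Stouffer stage z-maps — then scores recovery against the planted
stages.
"""

import logging

import numpy as np
from sklearn.metrics import adjusted_rand_score

from stagetraj import synthetic as syn
from stagetraj.stages import discover_stages
from stagetraj.synthetic import planted_window_stages
from stagetraj.types import RunConfig

logging.basicConfig(level=logging.WARNING)

parc = syn.make_parcellation(seed=0)
gt = syn.default_ground_truth(parc, seed=0)
records, gt = syn.make_cohort(gt, 90, 120, parc)
patients = [r for r in records if r.is_patient]
controls = [r for r in records if not r.is_patient]

cfg = RunConfig(n_perm=199, rng_seed=0)
res = discover_stages(patients, controls, cfg)

print(f"{len(res.windows)} duration windows (L = "
      f"{cfg.window_length_years} y)")
for fi, ss in res.state_sets.items():
    print(f"  {fi:6s}: {ss.n_states} states (CH = {ss.ch_score:.1f})")
print(f"{len(res.stages)} aligned stages:")
for st in res.stages:
    mean, lo, hi = st.duration_label
    n_sig = int(st.sig_masks["fused"].sum())
    print(f"  stage {st.id}: windows {st.member_windows[0]}-"
          f"{st.member_windows[-1]}, duration {mean:.1f} "
          f"({lo:.0f}-{hi:.0f}) y, {n_sig}/246 parcels FDR-significant")

truth = planted_window_stages(gt, res.windows, patients)
recov = {w: st.id for st in res.stages for w in st.member_windows}
ws = sorted(truth)
ari = adjusted_rand_score([truth[w] for w in ws], [recov[w] for w in ws])
print(f"window-to-stage recovery vs planted truth: ARI = {ari:.2f}")
# ARI of 1.0 means every window landed in its planted stage; the duration
# labels (mean and range per stage) are the clinically interpretable output.
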