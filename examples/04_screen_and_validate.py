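"""Screen actives + property-matched decoys and compute enrichment metrics.

Uses the reduced study pipeline, then prints the decoy-screen report: EF, GH,
%YA, %RA and ROC AUC — plus the same GH formula evaluated on the counts of a
published HDAC1 benzamide screen as a desk check.
"""

import warnings

from pharmqsar import gh_score, enrichment_factor, yield_and_ratio
from pharmqsar.pipeline import run_synthetic_study
from pharmqsar.synthlib import SyntheticLibrarySpec

warnings.filterwarnings("ignore")

spec = SyntheticLibrarySpec(
    n_actives=15, n_moderate=40, n_inactive=25, n_decoys_per_active=15, seed=5
)
res = run_synthetic_study(seed=5, spec=spec, n_pharm_actives=12,
                          n_pharm_inactives=12, hit_count=10)
r = res.report
print("decoy screen on the synthetic library:")
print(f"  library D={r.D}  actives A={r.A}  hit list Ht={r.Ht}  retrieved Ha={r.Ha}")
print(f"  EF  = {r.ef:.2f}   (maximum possible {r.D / r.A:.2f})")
print(f"  GH  = {r.gh:.3f}  (>0.5 indicates a reliable model)")
print(f"  %YA = {r.pct_ya:.1f}   %RA = {r.pct_ra:.1f}")
print(f"  AUC = {r.auc:.3f}  (1.0 = perfect active/decoy separation)")

# desk check on published screening counts (Ha=26 of Ht=30 hits, A=106
# actives in a D=5870 library):
ha, ht, a, d = 26, 30, 106, 5870
ya, ra = yield_and_ratio(ha, ht, a)
print("\nreference counts (Ha=26, Ht=30, A=106, D=5870):")
print(f"  EF = {float(enrichment_factor(ha, ht, a, d)):.2f}"
      f"   GH = {float(gh_score(ha, ht, a, d)):.2f}"
      f"   %YA = {ya:.2f}   %RA = {ra:.2f}")
# GH of 0.71 on those counts reproduces the published value; an EF near 48
# means hits are ~48x enriched in actives relative to random picking.
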