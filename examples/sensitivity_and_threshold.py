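"""Uncertainty analysis: tornado, PSA, CEAC and the price threshold.

One-way analysis perturbs each published range end separately; the PSA
redraws all uncertain parameters together 500 times; the threshold search
finds the joint EV + pembrolizumab price multiplier at which the
combination would just meet the willingness-to-pay threshold.
"""

import numpy as np

import evcea
from evcea import ceac, run_owsa, run_psa, threshold_price

cfg = evcea.default_config()

print("tornado (top five ICER spreads):")
for e in run_owsa(cfg)[:5]:
    print(f"  {e.path:<42}{e.icer_low:>12,.0f} .. {e.icer_high:>12,.0f}"
          f"   spread {e.spread:>10,.0f}")

psa = run_psa(cfg, n=500, seed=cfg.seed)
s = psa.summary
print(f"\nPSA ({s['n_draws']} draws, seed {s['seed']}):")
print(f"  mean incremental cost  ${s['mean_delta_cost']:,.0f}")
print(f"  mean incremental QALYs {s['mean_delta_qalys']:.3f}")
print(f"  P(cost-effective at ${s['wtp']:,.0f}/QALY) = "
      f"{s['prob_cost_effective_at_wtp']:.3f}")

grid = np.arange(0, 400_001, 50_000)
curve = ceac(psa, grid)
print("\nCEAC (probability cost-effective by WTP):")
for wtp, p in zip(curve["wtp"], curve["prob_cost_effective"]):
    print(f"  ${wtp:>9,.0f}: {p:.2f}")

res = threshold_price(cfg)
print(f"\nprice threshold: both drugs at {res.multiplier:.1%} of current "
      f"prices\n  enfortumab vedotin ${res.prices['enfortumab_vedotin']:,.1f}"
      f" per 30 mg vial\n  pembrolizumab      "
      f"${res.prices['pembrolizumab']:,.1f} per 100 mg vial")
# At base prices no draw is cost-effective; only an ~87% price cut to both
# drugs brings the ICER down to the threshold.
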