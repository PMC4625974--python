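"""Find succinate-forcing metabolite targets in a mixed-acid fermentation toy.

The reduced anaerobic network ferments glucose to lactate, acetate, formate,
ethanol and succinate from the common PEP/pyruvate branch point.  Pyruvate
competes with the succinate branch for PEP, so *attenuating* pyruvate
turnover redirects carbon through PEP carboxylase toward succinate — but
over-attenuation also starves ATP regeneration and kills uptake, giving the
characteristic triangular production-vs-k profile.
"""

from fluxsum import make_mixed_acid_fixture, production_profile, scan

model = make_mixed_acid_fixture()
report = scan(model, target_exchange_id="EX_succ", goal="maximize")

print(f"wild-type growth:            {report.wt_growth:.3f}")
print(f"wild-type worst-case succ:   {report.wt_production:.3f} mmol/gDCW-hr")
print("targets (metabolite, direction, best k, guaranteed production):")
for met, direction, best_k, best_prod, growth in report.targets:
    print(f"  {met:>5} {direction:<16} k={best_k:.1f} "
          f"production={best_prod:.2f} (growth {growth:.2f})")
print()
print("pyruvate attenuation profile (triangular):")
print(f"{'k':>4}  {'growth':>7}  {'guaranteed succinate':>20}")
for k, growth, production in production_profile(report, "pyr", "attenuation"):
    print(f"{k:>4.1f}  {growth:>7.2f}  {production:>20.2f}")
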