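"""Who reaches clinical equipoise for a xenotransplant, and at which n?

A patient is viable when n + p_relist * LE_relist (life expectancy with a
xenograft that survives n years) strictly exceeds their conditional life
expectancy on the waitlist.  Since the xenograft survival n is unknown,
the comparison is swept over n = 0.5 ... 5 years.
"""

import xenoeq as xq
from xenoeq.incentives import ModelSet

bundle = xq.generate_registry(xq.default_config(seed=1, n_patients=5000))
pats = bundle.patients[bundle.patients["active"]].reset_index(drop=True)
models = ModelSet(xq.fit_model(pats, "waitlist_death"),
                  xq.fit_model(pats, "time_to_transplant"),
                  xq.fit_model(pats, "post_transplant_death"))

relist = xq.estimate_relist_probability(pats)
print(f"relist probability after graft failure: {relist.probability:.3f} "
      f"({relist.n_events} failures observed)")

results = xq.identify_viable(pats, models, xq.XenoAssumptions(),
                             relist=relist, donors=bundle.donors)
table = xq.sensitivity_table(results)
print(table.to_string(index=False,
                      float_format=lambda x: f"{x:.3f}"))

# Each row: for that assumed xenograft survival n, the fraction and count
# of active patients whose expected life years improve by accepting the
# xenotransplant.  Viable sets are nested: raising n only adds patients.
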