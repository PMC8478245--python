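"""Aggregate the program cost ledger into arm-level and per-child costs.

The ledger prices every implementation input — personnel, training travel,
participant incentives, administrative overhead — and adds societal costs:
mothers' and health volunteers' time at imputed local wages, plus venue
rental a scaled program would pay. Costs are 2020 USD.
"""

import ecdeval as e

lines = e.gen_cost_ledger()
for arm in ("group_only", "mixed"):
    b = e.aggregate(lines, arm, n_children=400)
    print(f"\n{arm} (n={b.n_children} children)")
    print(f"  direct provider costs    US${b.direct_provider:>9,.0f}")
    print(f"  indirect provider costs  US${b.indirect_provider:>9,.0f}")
    print(f"  total provider costs     US${b.total_provider:>9,.0f}"
          f"  (US${b.per_child_provider:.0f} per child)")
    print(f"  present societal costs   US${b.societal_present:>9,.0f}"
          f"  (US${b.per_child_societal:.0f} per child)")
    print(f"  total costs              US${b.total:>9,.0f}"
          f"  (US${b.per_child_total:.0f} per child)")

# Opportunity-cost building blocks behind the societal lines:
sched = e.default_schedules()["group_only"]
params = e.TimeUseParams()
hours = e.mother_session_hours(sched)
print(f"\nA group-only mother spends ~{hours:.1f} h attending and travelling")
print(f"to sessions; priced at US${params.mother_wage}/h that is "
      f"US${e.price_time(hours, params.mother_wage):.2f} per mother,")
print("before adding one weekly hour of home stimulation practice for 3 years"
      f" (US${e.price_time(156, params.mother_wage):.2f}).")
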