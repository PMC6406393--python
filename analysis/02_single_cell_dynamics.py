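#!/usr/bin/env python
"""Single-cell circuit dynamics: free-running oscillation and its quench
under continuous androgen deprivation.

Simulates one cell on the attractor without treatment, then with full ADT
switched on at t = 600 h, and extracts the oscillation period and the
time treatment needs to quench the oscillation (amplitude < 5% of the
pre-treatment swing).
"""

import json
from pathlib import Path

from page4.calibrate import default_params
from page4.circuit import CircuitState, simulate
from page4.cohort import limit_cycle
from page4.oscillation import detect_period, quench_time
from page4.protocols import constant_adt

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = default_params()
cyc = limit_cycle(params)
ic = CircuitState.from_array(cyc.states[0])

free = simulate(params, None, ic, (0.0, 2000.0))
free.to_frame().to_csv(OUT / "trajectory_free.csv", index=False)
s = detect_period(free, "H", burn_in=200.0)

T_ON = 600.0
treated = simulate(params, constant_adt(t_on=T_ON), ic, (0.0, 1600.0))
treated.to_frame().to_csv(OUT / "trajectory_adt.csv", index=False)
q = quench_time(treated, "H", t_on=T_ON, frac=0.05)

summary = {
    "period_h": round(s.period, 2),
    "relative_amplitude_H": round(s.amplitude / free.species("H").mean(), 3),
    "adt_onset_h": T_ON,
    "quench_after_h": round(q - T_ON, 1),
    "quench_after_weeks": round((q - T_ON) / 168.0, 2),
    "post_adt_endpoint": dict(zip("WHCKA", map(float, treated.states[-1]))),
}
(OUT / "single_cell_summary.json").write_text(
    json.dumps(summary, indent=2) + "\n")

print(f"Free-running HIPK1-PAGE4 period: {s.period:.1f} h "
      f"(amplitude {summary['relative_amplitude_H']:.0%} of mean)")
print(f"Full ADT at t={T_ON:.0f} h quenches the oscillation after "
      f"{q - T_ON:.0f} h (~{(q - T_ON) / 168:.1f} weeks)")
print(f"Post-ADT state is androgen-independent-like: "
      f"H={summary['post_adt_endpoint']['H']:.3f}, "
      f"C={summary['post_adt_endpoint']['C']:.3f}")
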