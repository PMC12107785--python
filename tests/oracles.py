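"""Independent brute-force oracles used by the acceptance checks.

Deliberately plain-python, patient-by-patient and day-by-day, sharing no
code with the package's vectorized estimator.
"""

import numpy as np

DAYS = 365.25


def daily_step_net_survival(cohort, annual_hazard, horizon_days=1826):
    """Discrete-time (daily) inverse-weighted net survival at the horizon.

    ``annual_hazard(age)`` returns the population hazard at an attained
    integer age; each patient's cumulative hazard is accumulated day by day.
    """
    exits, events, age0 = [], [], []
    for p in cohort:
        fd = max(p.followup_days, 1)
        exits.append(min(fd, horizon_days))
        events.append(p.vital_status == "dead" and fd <= horizon_days)
        age0.append(p.age_at_diagnosis)
    n = len(cohort)
    cum = [0.0] * n
    ns = 1.0
    for day in range(1, max(exits) + 1):
        t1, t0 = day / DAYS, (day - 1) / DAYS
        num_d = num_p = den = 0.0
        for i in range(n):
            if exits[i] < day:
                continue
            h = annual_hazard(int(np.floor(age0[i] + (t0 + t1) / 2)))
            cum[i] += h * (t1 - t0)
            w = np.exp(cum[i])
            den += w
            num_p += w * h * (t1 - t0)
            if exits[i] == day and events[i]:
                num_d += w
        if den > 0:
            ns *= 1.0 - (num_d - num_p) / den
    return ns
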