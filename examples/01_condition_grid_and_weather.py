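"""The growth-chamber design and the synthetic field weather.

The chamber design crosses photoperiod with light-phase and dark-phase
temperature: 5 photoperiods (0, 8, 12, 16, 24 h of light) x 21 light
temperatures (20-40 degC) x 21 dark temperatures (15-35 degC), keeping only
combinations where the two temperatures differ and collapsing the dark
temperature for constant-light (24L) and the light temperature for
constant-dark (0L) conditions — 73 conditions in all.  Sampling each with
2 cultivars at 8 time points plans 1168 libraries.

Field weather is different in kind: temperature and irradiance share the
solar cycle, so the two candidate drivers are correlated in exactly the way
the chamber design avoids.
"""

import numpy as np

from fieldfit import enumerate_conditions, field_env_series, gc_env_series
from fieldfit.synthdata import make_study_samples

conditions = enumerate_conditions()
print(f"{len(conditions)} chamber conditions")
plan = make_study_samples(conditions, timepoints_per_condition=8, cultivars=2)
print(f"{len(plan)} planned samples")

# one chamber condition: square-wave temperature, square-wave light
cond = next(c for c in conditions if c.light_hours == 12
            and c.light_temp == 30 and c.dark_temp == 20)
env = gc_env_series(cond, days=4)  # 3 acclimation days + 1 sampling day
print(f"\ncondition {cond.condition_id}: temperature range "
      f"{env.temperature.min():.0f}-{env.temperature.max():.0f} degC")

# pooled over the whole design, temperature and irradiance are only weakly
# correlated; in synthetic field weather they share the solar cycle
pooled_t, pooled_i = [], []
for c in conditions:
    e = gc_env_series(c, days=4)
    pooled_t.append(e.temperature)
    pooled_i.append(e.irradiance)
r_gc = np.corrcoef(np.concatenate(pooled_t), np.concatenate(pooled_i))[0, 1]

field = field_env_series(days=30, seed=0)
r_field = np.corrcoef(field.temperature, field.irradiance)[0, 1]
print(f"\ncorr(temperature, irradiance): chamber pool {r_gc:.2f}, "
      f"field {r_field:.2f}")
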