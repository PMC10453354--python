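"""Apply the impairment and PSCI rules to a handful of hand-made patients.

Shows the three classification outcomes: present (>=1 impaired domain),
absent (no impaired domain, >=3 domains assessed) and indeterminate
(cannot rule PSCI out from <3 assessed domains).
"""

import pandas as pd

from pscikit import DOMAINS, classify_participants

rows = []
# Ada: verbal memory clearly impaired (percentile 2 of 3 tests < 5)
for test, pct in [("t1", 1.0), ("t2", 3.0), ("t3", 40.0)]:
    rows.append({"id": "ada", "domain": "verbal_memory",
                 "percentile": pct, "impaired": pct < 5})
for d in DOMAINS[:3]:
    rows.append({"id": "ada", "domain": d, "percentile": 60.0,
                 "impaired": False})

# Ben: five domains assessed, all intact
for d in DOMAINS[:5]:
    rows.append({"id": "ben", "domain": d, "percentile": 55.0,
                 "impaired": False})

# Cho: only two domains assessed, both intact -> cannot rule PSCI out
for d in DOMAINS[:2]:
    rows.append({"id": "cho", "domain": d, "percentile": 70.0,
                 "impaired": False})

out = classify_participants(pd.DataFrame(rows))
print(out[["id", "n_domains_available", "n_domains_impaired", "psci"]]
      .to_string(index=False))
# ada is 'present' (verbal memory: 2/3 tests impaired beats the strict
# >50% rule), ben is 'absent', and cho is 'indeterminate' because ruling
# PSCI out needs at least three assessed domains.
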