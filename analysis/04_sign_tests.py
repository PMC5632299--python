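#!/usr/bin/env python
"""Direction-of-effect sign tests for energy-related gene comparisons.

Recomputes the exact two-sided binomial sign tests for the nuclear and
mitochondrial OXPHOS gene comparisons: per gene, which pooled branch
class (flightless vs flying) shows the higher fitted dN/dS, then a
binomial test at p = 1/2 on the direction counts. The 12-of-14 nuclear
OXPHOS split and the 11-of-13 mitochondrial split are the study's
headline inputs; the mitochondrial case prints 0.0225 under the
double-smaller-tail convention.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT))

from flightsel.comparative import direction_sign_test

cases = {
    "nuclear OXPHOS (12 of 14 higher in flying)":
        ["flying"] * 12 + ["flightless"] * 2,
    "mitochondrial OXPHOS (11 of 13 higher in flightless)":
        ["flightless"] * 11 + ["flying"] * 2,
}
for label, directions in cases.items():
    out = direction_sign_test(directions)
    print(f"{label}: counts={out['counts']} p={out['p']:.4f}")
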