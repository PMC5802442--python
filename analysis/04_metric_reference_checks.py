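#!/usr/bin/env python
"""Verify the outcome-metric definitions against the bundled reference table.

Feeds the raw national-scale aggregate counts (deaths by smoker type, deaths
avoided, overdiagnoses, screens, cases, the adherence sweep) through the
package's metric functions and prints each derived quantity next to nothing —
the point is that every ratio, share, decline and scaling is *recomputed*,
never stored. Writes results/reference_checks.csv.
"""

import os

import pandas as pd

from lungsim.metrics import verify_reference_arithmetic

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    values = verify_reference_arithmetic()
    table = pd.DataFrame(sorted(values.items()), columns=["quantity", "value"])
    os.makedirs(OUT, exist_ok=True)
    path = os.path.join(OUT, "reference_checks.csv")
    table.to_csv(path, index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
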