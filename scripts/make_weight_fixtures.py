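"""Regenerate the shipped fixture weight tables.

Variant counts per score mirror the published instrument sets; frequencies
and per-allele weights are synthetic, drawn once from a fixed seed and
rescaled so each score's theoretical Hardy-Weinberg SD hits the calibration
target (chosen so median-split group contrasts land at the published
forest-plot magnitudes).  Run from the repository root:

    python scripts/make_weight_fixtures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "src" / "factorialmr" / "data" / "weights"

#: score -> (number of variants, target theoretical score SD in trait units)
SPECS = {
    "lpa": (43, 12.33),      # mg/dL; lower-vs-higher contrast ~ -19.7
    "hmgcr": (26, 1.566),    # mg/dL LDL-C; contrast ~ -2.50
    "npc1l1": (6, 0.664),    # ~ -1.06
    "pcsk9": (42, 1.692),    # ~ -2.70
    "ldlr": (52, 2.419),     # ~ -3.86
    "ldl": (237, 6.0),       # overall LDL-C positive control
    "bmi": (62, 0.9),        # kg/m2
    "sbp": (455, 2.5),       # mmHg
    "smoking": (248, 0.30),  # SD units
    "alcohol": (98, 0.30),
    "activity": (16, 0.20),
}


def main() -> None:
    rng = np.random.default_rng(20260929)
    alleles = np.array(list("ACGT"))
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (m, sd) in SPECS.items():
        f = rng.uniform(0.05, 0.95, m)
        b = rng.normal(0.0, 1.0, m)
        b *= sd / np.sqrt(np.sum(2 * f * (1 - f) * b**2))
        pd.DataFrame(
            {
                "variant_id": [f"{name}_snp{i:04d}" for i in range(m)],
                "effect_allele": rng.choice(alleles, m),
                "eaf": np.round(f, 4),
                "beta": np.round(b, 6),
                "trait": name,
            }
        ).to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
        print(f"{name}: {m} variants, target score SD {sd}")


if __name__ == "__main__":
    main()
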