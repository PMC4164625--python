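"""Simulate the study's assay tables from the published parameter sets.

Writes one noise-free rate table per design (the reference surfaces used
by the round-trip fits) plus a noisy 3-replicate version of each inhibition
grid, under results/data/.
"""

from pathlib import Path

from sirtkin import io
from sirtkin.reference import SIRT1_NAM, SIRT3_ISONAM, SIRT3_NAM
from sirtkin.synth import builtin_design, generate_rates

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

PLANS = [
    ("sirt3_nam", SIRT3_NAM, None),
    ("sirt1_nam", SIRT1_NAM, None),
    ("sirt3_isonam", SIRT3_ISONAM, None),
    ("sirt3_derepression", SIRT3_NAM, SIRT3_ISONAM.ki),
]


def main() -> None:
    for name, params, ki in PLANS:
        design = builtin_design(name)
        exact = generate_rates(params, design.with_noise(0.0, 1, 0),
                               ki_competitor=ki)
        io.write_rate_table(exact, OUT / f"{name}_exact.csv")
        noisy = generate_rates(params, design.with_noise(0.05, 3, 20240915),
                               ki_competitor=ki)
        io.write_rate_table(noisy, OUT / f"{name}_cv05.csv")
        print(f"{name}: {len(exact)} exact rows, {len(noisy)} noisy rows")


if __name__ == "__main__":
    main()
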