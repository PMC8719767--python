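"""Blue-morph frequency by sex with a chi-squared test of independence.
Writes morph_frequency.csv."""

import pandas as pd

from _common import parse_args, study_run_config
from lingcod_burden import run_pipeline


def main() -> None:
    args = parse_args()
    manifest = run_pipeline(study_run_config(args, ("simulate", "frequency")))
    table = pd.read_csv(f"{args.outdir}/morph_frequency.csv", comment="#")
    print(f"frequency: {manifest.stages['frequency']}")
    print(table.to_string(index=False))
    row = table.iloc[0]
    print(
        f"\nchi-squared = {row['chi_squared']:.3f} (df={int(row['df'])}, "
        f"p={row['p']:.4f}) for independence of sex and color"
    )


if __name__ == "__main__":
    main()
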