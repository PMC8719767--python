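"""Parasite community composition: Bray-Curtis dissimilarities between fish
and a sequential-SS PERMANOVA over sex-color combination, sampling location
and depth. Writes permanova.csv."""

import pandas as pd

from _common import parse_args, study_run_config
from lingcod_burden import run_pipeline


def main() -> None:
    args = parse_args()
    manifest = run_pipeline(study_run_config(args, ("simulate", "permanova")))
    table = pd.read_csv(f"{args.outdir}/permanova.csv", comment="#")
    print(f"permanova: {manifest.stages['permanova']}")
    print(table.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
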