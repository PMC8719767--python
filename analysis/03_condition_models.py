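"""Body-condition models: Fulton's K (mass/length^3) and fourth-root HSI,
each ~ depth + sex + color + sex:color with location-in-region random
intercepts. Writes condition_fits.csv."""

import pandas as pd

from _common import parse_args, study_run_config
from lingcod_burden import run_pipeline


def main() -> None:
    args = parse_args()
    manifest = run_pipeline(study_run_config(args, ("simulate", "condition")))
    table = pd.read_csv(f"{args.outdir}/condition_fits.csv", comment="#")
    print(f"condition: {manifest.stages['condition']}")
    for model, sub in table.groupby("model"):
        print(f"\n[{model}]")
        out = sub.drop(columns=["model"]).copy()
        for col in ("estimate", "se"):
            out[col] = out[col].map("{:.3e}".format)
        out[["z", "p"]] = out[["z", "p"]].round(4)
        print(out.to_string(index=False))


if __name__ == "__main__":
    main()
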