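"""Both constrained color-relabeling permutation tests for the sex x color
interaction: males-only (4 blue males drawn at random, females untouched)
and both-sexes (additionally 11 random blue females).  Each replicate refits
the full burden model.  Writes permutation_<scheme>.csv.

Replicates default to 99 to keep the driver's runtime in minutes; pass
--replicates 500 for a full-length run.
"""

import pandas as pd

from _common import parse_args, study_run_config
from lingcod_burden import run_pipeline


def main() -> None:
    args = parse_args(extra={"--replicates": {"type": int, "default": 99}})
    cfg = study_run_config(
        args, ("simulate", "burden", "permute"),
        n_permutation_replicates=args.replicates,
        outer_tol=1e-5,
    )
    manifest = run_pipeline(cfg)
    print(f"permute: {manifest.stages['permute']}")
    for mode in ("males_only", "both_sexes"):
        path = f"{args.outdir}/permutation_{mode}.csv"
        header = open(path, encoding="utf-8").readline().strip("#\n ")
        reps = pd.read_csv(path, comment="#")
        n_ok = int(reps["converged"].sum())
        print(f"[{mode}] {header}")
        print(f"  converged replicates: {n_ok}/{len(reps)}")


if __name__ == "__main__":
    main()
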