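"""Shared run configuration for the numbered analysis drivers.

Every driver operates on the same synthetic study (seeded via --seed,
default 1) and accumulates its outputs and the manifest under
``results/study/``.
"""

from __future__ import annotations

import argparse

from lingcod_burden import GeneratorConfig, RunConfig


def parse_args(extra=None) -> argparse.Namespace:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/study")
    for name, kwargs in (extra or {}).items():
        parser.add_argument(name, **kwargs)
    return parser.parse_args()


def study_run_config(args, stages, **overrides) -> RunConfig:
    return RunConfig(
        outdir=args.outdir,
        stages=stages,
        seed=args.seed,
        generator=GeneratorConfig(seed=args.seed),
        **overrides,
    )
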