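"""Generate the synthetic study: 89 lingcod across 26 sites in 4 regions,
25 parasite taxa, unbalanced sex-color cells, NB2 counts with a log-length
offset. Writes hosts.csv and counts.csv under results/study/."""

from _common import parse_args, study_run_config

from lingcod_burden import run_pipeline
from lingcod_burden.io import read_count_table, read_host_table


def main() -> None:
    args = parse_args()
    manifest = run_pipeline(study_run_config(args, ("simulate",)))
    hosts = read_host_table(f"{args.outdir}/hosts.csv")
    counts = read_count_table(f"{args.outdir}/counts.csv", hosts)
    total = counts.frame["count"].sum()
    cells = {}
    for h in hosts:
        cells[f"{h.sex}-{h.color}"] = cells.get(f"{h.sex}-{h.color}", 0) + 1
    print(f"simulate: {manifest.stages['simulate']}")
    print(f"hosts: {len(hosts)} fish, cells {cells}")
    print(f"counts: {len(counts)} (fish x taxon) observations, "
          f"{total} parasite detections in total")


if __name__ == "__main__":
    main()
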