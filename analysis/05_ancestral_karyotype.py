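"""Ancestral chromosome reconstruction and rearrangement classification.

Twenty seeded six-tip clades evolve from an 8-chromosome ancestor by one
reciprocal translocation and one inversion per tip. For each clade the
pairwise collinear blocks are partitioned into ancestral blocks, block
adjacencies are voted across species under a Dollo criterion on the
species tree, and the consensus is linearised into contiguous ancestral
regions (CARs). Recovery means: 8 CARs, and per-tip event counts of
exactly one translocation and one inversion with no fusion or fission —
mirroring a history in which chromosome number never changed.
"""

import argparse
import json
from pathlib import Path

from syntevo.studies import karyotype_recovery_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=20)
    args = ap.parse_args()

    res = karyotype_recovery_study(seed=args.seed, n_replicates=args.replicates)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "karyotype_recovery.json").write_text(
        json.dumps(res, indent=1, sort_keys=True) + "\n"
    )
    with open(RESULTS / "karyotype_recovery.tsv", "w") as fh:
        fh.write("replicate\tn_cars\trecovered\n")
        for i, n in enumerate(res["car_counts"]):
            fh.write(f"{i}\t{n}\t{int(n == 8)}\n")
    print(f"{res['n_recovered_8']}/{res['n_replicates']} replicates recover "
          f"the 8-chromosome ancestor (modal CAR count {res['modal_car_count']})")
    print(f"{res['n_events_exact']}/{res['n_recovered_8']} recovered replicates also "
          f"reproduce every tip's event counts exactly (1 translocation + 1 inversion, "
          f"no fusion/fission)")
    print(f"wrote {RESULTS / 'karyotype_recovery.json'}")


if __name__ == "__main__":
    main()
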