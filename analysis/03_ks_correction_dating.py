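"""Ks estimation, gamma-peak fitting, evolutionary-rate correction and
dating of the shared triplication.

Three simulated lineages share one whole-genome triplication (true Ks
1.22) but evolve at different synonymous rates (x0.8, x1.0, x1.3). Their
uncorrected gamma peaks disagree by tens of percent — exactly the bias
that motivates using the shared event as a benchmark. A single
multiplicative factor per lineage aligns every peak to the reference, and
T = Ks/(2r) with the simulation's true rate r dates the event.
"""

import argparse
import json
from pathlib import Path

from syntevo.studies import TRUE_RATE_R, rate_correction_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    res = rate_correction_study(seed=args.seed)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ks_correction.json").write_text(json.dumps(res, indent=1, sort_keys=True) + "\n")
    with open(RESULTS / "ks_peaks.tsv", "w") as fh:
        fh.write("lineage\tn_pairs\tgamma_peak_uncorrected\tfactor\tgamma_peak_corrected\n")
        for tip in res["uncorrected_peaks"]:
            fh.write(f"{tip}\t{res['n_pairs'][tip]}\t{res['uncorrected_peaks'][tip]:.4f}\t"
                     f"{res['factors'][tip]:.4f}\t{res['corrected_peaks'][tip]:.4f}\n")
    print("uncorrected gamma peaks:",
          {t: round(v, 3) for t, v in res["uncorrected_peaks"].items()},
          f"(spread {res['uncorrected_spread']:.1%})")
    print("corrected gamma peaks:",
          {t: round(v, 3) for t, v in res["corrected_peaks"].items()},
          f"(spread {res['corrected_spread']:.1%})")
    print(f"dated at r = {TRUE_RATE_R:g}/site/yr: {res['date_mya']:.1f} Mya "
          f"(truth {res['true_date_mya']:.1f} Mya)")
    print(f"wrote {RESULTS / 'ks_correction.json'} and {RESULTS / 'ks_peaks.tsv'}")


if __name__ == "__main__":
    main()
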