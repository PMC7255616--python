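#!/usr/bin/env python
"""Detect a planted expressed retrocopy and estimate its relative expression.

Simulates the default gene, plants a 5%-diverged intronless copy, expresses
it at 25% of the parent in a 100k-read library, scans the genome with the
parent exons, chains the homology blocks, classifies the hit and recovers
the expression ratio from discriminating probes.  Also reports the
20-seed detection sensitivity / false-call study at 10% divergence.
Writes results/retrocopy_calls.tsv.
"""

from pathlib import Path

import pandas as pd

from locuskit import io as lio
from locuskit.validation import paralog_ratio_study, retrocopy_detection_study


def main() -> None:
    ratio = paralog_ratio_study(true_ratio_pct=25.0, seed=31, n_reads=100_000)
    print(f"planted expression ratio 25.0% -> measured "
          f"{ratio['measured_ratio_pct']:.1f}% "
          f"({ratio['n_probes']} discriminating probes per gene, "
          f"{ratio['n_reads']} reads)")

    study = retrocopy_detection_study(n_seeds=20, divergence=0.10,
                                      base_seed=600)
    print(f"detection at 10% divergence over {study['n_seeds']} seeds: "
          f"sensitivity {study['sensitivity_pct']:.0f}%, "
          f"{study['false_calls']} false calls on copy-free genomes")

    frame = pd.DataFrame([{
        "true_ratio_pct": ratio["true_ratio_pct"],
        "measured_ratio_pct": round(ratio["measured_ratio_pct"], 1),
        "n_reads": ratio["n_reads"],
        "sensitivity_pct": study["sensitivity_pct"],
        "false_calls": study["false_calls"],
        "n_seeds": study["n_seeds"],
    }])
    Path("results").mkdir(exist_ok=True)
    lio.write_tsv("results/retrocopy_calls.tsv", frame, index=False)
    print("wrote results/retrocopy_calls.tsv")


if __name__ == "__main__":
    main()
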