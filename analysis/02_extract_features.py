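#!/usr/bin/env python
"""Extract the eight resting-state EEG features for every patient recording
(preprocess -> spectra -> dwPLI -> density-averaged graph metrics) and merge
them into the cohort table."""

import argparse
from pathlib import Path

import pandas as pd

from comanet import eeg_io
from comanet.montage_validation import features_for_recording


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--in", dest="in_dir", type=Path,
                    default=Path("results/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/cohort_features.csv"))
    args = ap.parse_args()

    table = eeg_io.read_cohort(args.in_dir / "cohort.csv")
    montage = eeg_io.load_montage("ld1020")
    rows = []
    for pid in table["id"]:
        rec = eeg_io.read_edf(args.in_dir / f"patient_{pid:03d}.edf")
        rows.append(features_for_recording(rec, montage, seed=args.seed))
        print(f"patient {pid}: alpha power {rows[-1]['alpha_rel_power']:.3f}, "
              f"median alpha dwPLI {rows[-1]['alpha_median_dwpli']:.3f}")
    merged = pd.concat([table.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    eeg_io.write_cohort(merged, args.out)
    print(f"wrote merged feature table to {args.out}")


if __name__ == "__main__":
    main()
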