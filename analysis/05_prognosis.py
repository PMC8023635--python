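#!/usr/bin/env python
"""Prognostic stepwise regression: GOSE outcome (rank-inverse-normal
transformed) on five clinical candidates plus the EEG features, at 3 and 6
months, reporting standardized betas, adjusted R^2 and the R^2 gain of the
selected model over GCS alone."""

import argparse
import json
from pathlib import Path

import pandas as pd

from comanet import inference
from comanet.network_metrics import FEATURE_KEYS


def fit_outcome(table: pd.DataFrame, outcome: str) -> dict:
    table = table.copy()
    table["sex_male"] = (table["sex"].astype(str).str.lower() == "male").astype(int)
    clinical = ["age_years", "sex_male", "ct_grade", "days_since_injury",
                "gcs_total"]
    eeg = [c for c in FEATURE_KEYS if c in table.columns]
    complete = table.dropna(subset=[outcome])
    y = inference.rank_inverse_normal(complete[outcome].astype(float).to_numpy())
    res = inference.stepwise_regression(
        pd.Series(y, index=complete.index), complete[clinical + eeg].astype(float)
    )
    summary = {
        "outcome": outcome,
        "n_used": res.n_used,
        "selected": res.selected,
        "betas": {k: round(float(v), 4) for k, v in res.betas.items()},
        "p_values": {k: round(v, 4) for k, v in res.p_values.items()},
        "adj_r_squared": round(res.adj_r_squared, 4),
        "f_statistic": round(res.f_statistic, 4) if not res.empty else None,
        "df": list(res.df),
    }
    if "gcs_total" in res.selected and len(res.selected) > 1:
        summary["r2_change_vs_gcs_alone"] = round(
            inference.r2_change(res, ["gcs_total"]), 4
        )
    return summary


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path,
                    default=Path("results/cohort_features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/prognosis.json"))
    args = ap.parse_args()

    table = pd.read_csv(args.cohort)
    payload = [fit_outcome(table, o) for o in ("gose_3mo", "gose_6mo")]
    for s in payload:
        terms = ", ".join(
            f"{k} (beta={s['betas'][k]}, p={s['p_values'][k]})"
            for k in s["selected"]
        ) or "(empty model)"
        print(f"{s['outcome']}: {terms}; adjusted R^2 = {s['adj_r_squared']}"
              + (f"; R^2 change vs GCS alone = {s['r2_change_vs_gcs_alone']}"
                 if "r2_change_vs_gcs_alone" in s else ""))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
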