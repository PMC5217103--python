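#!/usr/bin/env python
"""Test the reporter traces for circadian rhythmicity.

Drops the first day, detrends with a 24 h centered moving average, fits a
sine and a line to each replicate, and compares the fits by AICc: the sine
model's Akaike weight is the probability a sine fits better than a line.
Summarizes period (mean +/- sd) and circular mean phase over the rhythmic
replicates and compares them with the planted truth.
"""

import argparse
import json
from pathlib import Path

from regulonscope import io as rio
from regulonscope.rhythm import preprocess, rhythm_test, summarize_replicates

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "rhythm")
    ap.add_argument("--threshold", type=float, default=0.95)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    series = rio.read_timeseries_csv(args.data / "luciferase.csv")
    truth = json.loads((args.data / "truth.json").read_text())["luciferase"]

    calls, records = [], []
    for ts in series:
        call = rhythm_test(preprocess(ts), args.threshold)
        calls.append(call)
        records.append({
            "replicate": ts.replicate_id,
            "p_sine_better": call.p_sine_better,
            "rhythmic": call.rhythmic,
            "period_h": call.sine.period,
            "phase_h": call.sine.phase,
            "amplitude": call.sine.amplitude,
        })
    (args.out / "replicate_calls.json").write_text(json.dumps(records, indent=1))

    s = summarize_replicates(calls)
    (args.out / "summary.json").write_text(json.dumps(s, indent=1))
    print(f"{s['n_rhythmic']}/{s['n_total']} replicates rhythmic at weight >= {args.threshold}")
    print(f"period {s['mean_period']:.2f} +/- {s['sd_period']:.2f} h "
          f"(planted {truth['T']} h); circular mean phase {s['mean_phase']:.1f} h")
    print("note: the plain-sine fit shortens the apparent period slightly on "
          "damped traces; the bias stays well inside +/-0.5 h at the default damping")


if __name__ == "__main__":
    main()
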